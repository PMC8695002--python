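"""Elastic net penalized proportional-odds regression with a BIC-selected
regularization path.

The penalized objective, on the mean log-likelihood scale, is

    l_en(gamma, beta) = -(1/N) log L + lambda [ w sum_j |beta_j|
                                               + (1-w)/2 sum_j beta_j^2 ],

with mixing weight w in [0, 1] (w = 1: LASSO, w = 0: ridge) and strength
lambda >= 0 (lambda = 0 recovers the ML fit). Category intercepts are never
penalized: the penalty sums over the p slopes only, and shrinking intercepts
would distort the cumulative probabilities themselves.

Fitting is proximal Newton: at each outer iteration the smooth part is
replaced by its local quadratic model (analytic gradient and Hessian) and
minimized by cyclic coordinate descent with soft-thresholding on the slopes,
followed by a backtracking line search on the true objective. Covariates are
standardized to unit sample SD internally by default (the penalty is
scale-sensitive); coefficients are reported on the original scale.

A descending geometric lambda path is generated from lambda_max -- the
smallest lambda at which the KKT conditions hold with all slopes zero at the
intercept-only fit -- and fitted with warm starts; the working lambda is the
BIC minimizer along the path, where BIC = -2 logL_lambda + log(N) * N_nonzero
counts nonzero parameters including the intercepts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ordinal import OrdinalLogit

__all__ = [
    "penalty_term",
    "bic",
    "ElasticNetOrdinalLogit",
    "PenalizedOrdinalResults",
    "OrdinalPathResults",
    "PathFailureError",
]

#: coefficients (standardized scale) below this magnitude count as zero in BIC
ZERO_TOL = 1e-8

#: floor on the mixing weight used only inside the lambda_max formula --
#: pure ridge has no finite lambda that zeroes the slopes
_W_FLOOR = 0.01


class PathFailureError(RuntimeError):
    """Every lambda on the path failed to converge."""


def penalty_term(slopes, lam: float, weight_w: float) -> float:
    """Elastic net penalty lambda [ w sum|b| + (1-w)/2 sum b^2 ] (slopes only)."""
    if not 0.0 <= weight_w <= 1.0:
        raise ValueError("weight_w must lie in [0, 1]")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    b = np.asarray(slopes, dtype=float)
    return float(lam * (weight_w * np.sum(np.abs(b))
                        + 0.5 * (1.0 - weight_w) * np.sum(b * b)))


def bic(loglik_unpenalized: float, n_obs: int, n_nonzero: int) -> float:
    """BIC = -2 logL + log(N) * N_nonzero (natural log, intercepts included)."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return -2.0 * loglik_unpenalized + np.log(n_obs) * n_nonzero


def _solve_quadratic_l1(g, H, theta, n_alpha, lam, w):
    """Minimize the local penalized quadratic model exactly (active set).

    Minimizes  g'(phi - theta) + 1/2 (phi - theta)' H (phi - theta)
               + lam*w * sum_j |phi_j| + lam*(1-w)/2 * sum_j phi_j^2
    over phi, the sums running over the slope coordinates (index >= n_alpha).
    Intercepts are always free; slopes enter and leave the active set by the
    KKT conditions of the LASSO part. The problem is a handful of dimensions,
    so each iteration is one small linear solve; the caller's line search on
    the true objective guards against an inexact subproblem solution.
    """
    k = theta.shape[0]
    l1 = lam * w
    l2 = lam * (1.0 - w)
    d2 = np.zeros(k)
    d2[n_alpha:] = l2
    active = np.ones(k, dtype=bool)
    if l1 > 0:
        active[n_alpha:] = theta[n_alpha:] != 0.0
    signs = np.sign(theta)
    signs[:n_alpha] = 0.0
    phi = theta.copy()
    for _ in range(4 * (k - n_alpha) + 4):
        A = np.flatnonzero(active)
        d = -theta.copy()  # inactive slopes sit at zero
        s_A = signs[A] * (np.arange(k)[A] >= n_alpha)
        HA = H[np.ix_(A, A)] + np.diag(d2[A])
        rhs = -(g[A] + H[A][:, ~active] @ d[~active] + d2[A] * theta[A] + l1 * s_A)
        try:
            dA = np.linalg.solve(HA, rhs)
        except np.linalg.LinAlgError:
            dA = np.linalg.solve(HA + 1e-10 * np.eye(len(A)), rhs)
        d[A] = dA
        phi = theta + d
        if l1 == 0:
            break
        # a slope whose sign flipped leaves the active set
        crossed = active & (np.arange(k) >= n_alpha) & (np.sign(phi) * signs < 0)
        if np.any(crossed):
            worst = np.flatnonzero(crossed)[np.argmax(np.abs(phi[crossed]))]
            active[worst] = False
            phi[~active] = 0.0
            continue
        phi[~active] = 0.0
        signs[active] = np.sign(phi[active])
        signs[:n_alpha] = 0.0
        # KKT screen for inactive slopes
        grad_q = g + H @ (phi - theta) + d2 * phi
        viol = ~active & (np.abs(grad_q) > l1 * (1 + 1e-12) + 1e-12)
        if not np.any(viol):
            break
        worst = np.flatnonzero(viol)[np.argmax(np.abs(grad_q[viol]))]
        active[worst] = True
        signs[worst] = -np.sign(grad_q[worst])
    phi[~active] = 0.0
    return phi


class ElasticNetOrdinalLogit(OrdinalLogit):
    """Elastic net penalized proportional-odds model.

    Parameters
    ----------
    endog, exog, exog_names
        As in :class:`OrdinalLogit`.
    weight_w : float in [0, 1]
        Elastic net mixing weight (1 = LASSO, 0 = ridge).
    standardize : bool
        Scale covariates to zero mean / unit SD before fitting and map the
        coefficients back. Default True.
    """

    def __init__(self, endog, exog=None, weight_w: float = 1.0,
                 standardize: bool = True, exog_names=None):
        if not 0.0 <= weight_w <= 1.0:
            raise ValueError("weight_w must lie in [0, 1]")
        super().__init__(endog, exog, exog_names=exog_names)
        self.weight_w = float(weight_w)
        self.standardize = bool(standardize)
        X = self._lik.exog
        if self.standardize and X.shape[1]:
            self._x_mean = X.mean(axis=0)
            sd = X.std(axis=0)
            sd[sd < 1e-12] = 1.0  # constant column: leave unscaled, slope stays 0
            self._x_sd = sd
            Xs = (X - self._x_mean) / self._x_sd
        else:
            self._x_mean = np.zeros(X.shape[1])
            self._x_sd = np.ones(X.shape[1])
            Xs = X
        # internal likelihood on the standardized design
        self._plik = type(self._lik)(self._lik.codes, Xs, self.n_cat)

    # -- parameter-scale transforms -------------------------------------
    def _to_original(self, params_std: np.ndarray) -> np.ndarray:
        na = self._plik.n_alpha
        gamma = params_std[:na].copy()
        beta_std = params_std[na:]
        beta = beta_std / self._x_sd
        gamma -= float(beta_std @ (self._x_mean / self._x_sd))
        return np.concatenate([gamma, beta])

    def _objective(self, params_std: np.ndarray, lam: float) -> float:
        return self._plik.nll(params_std) / self.n_obs + penalty_term(
            params_std[self._plik.n_alpha:], lam, self.weight_w
        )

    def _null_start(self) -> np.ndarray:
        """Intercept-only ML fit (slopes zero) as the path head warm start."""
        null_model = OrdinalLogit(self._lik.codes, None)
        res = null_model.fit()
        params = np.zeros(self._plik.k)
        params[: self._plik.n_alpha] = res.params
        return params

    def lambda_sequence(self, n_lambda: int = 20, min_ratio: float = 0.01,
                        ) -> np.ndarray:
        """Descending geometric lambda path from lambda_max to lambda_max*min_ratio.

        lambda_max = max_j |(1/N) d(-logL)/d(beta_j)| / max(w, 0.01), the KKT
        bound at the intercept-only fit; by construction the w >= 0.01 fit at
        lambda_max has all slopes exactly zero.
        """
        if n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")
        if not 0.0 < min_ratio < 1.0:
            raise ValueError("min_ratio must lie in (0, 1)")
        params0 = self._null_start()
        _, g, _ = self._plik.nll_grad_hess(params0)
        g_slopes = g[self._plik.n_alpha:] / self.n_obs
        lam_max = np.max(np.abs(g_slopes)) / max(self.weight_w, _W_FLOOR)
        lam_max = max(lam_max, 1e-12)
        return lam_max * np.power(min_ratio, np.linspace(0.0, 1.0, n_lambda))

    def fit(self, lam: float = 0.0, start_params=None, tol: float = 1e-7,
            max_iter: int = 200) -> "PenalizedOrdinalResults":
        """Minimize the penalized objective at a single (lambda, w).

        ``start_params`` warm-starts from a previous fit's *standardized*
        parameter vector (as stored on :class:`PenalizedOrdinalResults`).
        ``tol`` bounds the KKT (subgradient) residual at the solution.
        """
        if lam < 0:
            raise ValueError("lambda must be >= 0")
        lik = self._plik
        n = self.n_obs
        na, p = lik.n_alpha, lik.n_slopes
        w = self.weight_w
        params = (np.array(start_params, dtype=float) if start_params is not None
                  else self._null_start())
        obj = self._objective(params, lam)
        converged = False
        n_iter = 0
        while n_iter < max_iter:
            n_iter += 1
            nll, g, H = lik.nll_grad_hess(params)
            g = g / n
            H = H / n
            phi = _solve_quadratic_l1(g, H, params, na, lam, w)
            direction = phi - params
            if np.max(np.abs(direction)) < 1e-14:
                converged = True
                break
            t = 1.0
            accepted = False
            for _ in range(50):
                cand = params + t * direction
                obj_new = self._objective(cand, lam)
                if obj_new <= obj + 1e-15:
                    accepted = True
                    break
                t *= 0.5
            if not accepted:
                converged = True  # no descent along the model direction
                break
            rel = abs(obj - obj_new) / (abs(obj) + 1e-12)
            params, obj = cand, obj_new
            if rel < 1e-12:
                converged = True
                break
        # KKT residual check (subgradient stationarity of the LASSO part)
        _, g, _ = lik.nll_grad_hess(params)
        g = g / n
        kkt = np.max(np.abs(g[:na])) if na else 0.0
        for m in range(na, na + p):
            gm = g[m] + lam * (1.0 - w) * params[m]
            if params[m] != 0.0:
                kkt = max(kkt, abs(gm + lam * w * np.sign(params[m])))
            else:
                kkt = max(kkt, max(abs(gm) - lam * w, 0.0))
        converged = converged and kkt <= max(tol, 1e-7)
        llf = -lik.nll(params)
        n_nonzero = int(np.sum(np.abs(params) > ZERO_TOL))
        return PenalizedOrdinalResults(
            model=self, params=self._to_original(params), params_std=params,
            llf=llf, objective=obj, lam=float(lam), weight_w=w,
            n_nonzero=n_nonzero, converged=bool(converged), n_iter=n_iter,
            kkt_residual=float(kkt),
        )

    def fit_path(self, n_lambda: int = 20, min_ratio: float = 0.01,
                 lambdas=None, tol: float = 1e-7, max_iter: int = 200,
                 ) -> "OrdinalPathResults":
        """Fit the descending lambda path with warm starts and select by BIC.

        Non-converged path entries are flagged and excluded from selection;
        BIC ties break toward the larger (more regularized) lambda.
        """
        if lambdas is None:
            lambdas = self.lambda_sequence(n_lambda=n_lambda, min_ratio=min_ratio)
        else:
            lambdas = np.asarray(lambdas, dtype=float)
            if lambdas.ndim != 1 or lambdas.size == 0:
                raise ValueError("lambdas must be a non-empty 1-D sequence")
            if lambdas.size > 1 and np.any(np.diff(lambdas) >= 0):
                raise ValueError("lambdas must be strictly decreasing")
        fits: list[PenalizedOrdinalResults] = []
        start = self._null_start()
        for lam in lambdas:
            fit = self.fit(lam=lam, start_params=start, tol=tol, max_iter=max_iter)
            fits.append(fit)
            if fit.converged:
                start = fit.params_std
        bics = np.array([
            bic(f.llf, self.n_obs, f.n_nonzero) if f.converged else np.inf
            for f in fits
        ])
        if not np.any(np.isfinite(bics)):
            raise PathFailureError("no lambda on the path converged")
        selected = int(np.argmin(bics))  # argmin takes the first (largest-lambda) tie
        return OrdinalPathResults(
            model=self, lambdas=np.asarray(lambdas), fits=fits,
            bic_values=bics, selected_index=selected,
        )


@dataclass
class PenalizedOrdinalResults:
    """Elastic net penalized fit at one (lambda, w).

    ``params`` is on the original covariate scale; ``params_std`` on the
    standardized scale used internally (warm starts, zero counting).
    ``llf`` is the *unpenalized* log-likelihood at the penalized solution;
    ``objective`` the penalized objective value.
    """

    model: ElasticNetOrdinalLogit
    params: np.ndarray
    params_std: np.ndarray
    llf: float
    objective: float
    lam: float
    weight_w: float
    n_nonzero: int
    converged: bool
    n_iter: int
    kkt_residual: float

    @property
    def intercepts(self) -> np.ndarray:
        return self.params[: self.model.n_cat - 1]

    @property
    def slopes(self) -> np.ndarray:
        return self.params[self.model.n_cat - 1:]

    @property
    def slopes_std(self) -> np.ndarray:
        return self.params_std[self.model.n_cat - 1:]

    def summary(self) -> str:
        lines = [
            "Elastic net penalized proportional-odds fit",
            f"lambda = {self.lam:.6g}   w = {self.weight_w:g}   "
            f"logL = {self.llf:.4f}   objective = {self.objective:.6f}",
            f"n_nonzero (incl. intercepts) = {self.n_nonzero}   "
            f"converged = {self.converged}",
            f"{'parameter':<16}{'estimate':>12}",
        ]
        originals = sorted(self.model.category_map, key=self.model.category_map.get)
        names = [f"gamma_{self.model.category_map[c]}|{c}" for c in originals[:-1]] \
            + list(self.model.exog_names)
        for name, est in zip(names, self.params):
            lines.append(f"{name:<16}{est:>12.4f}")
        return "\n".join(lines)


@dataclass
class OrdinalPathResults:
    """A fitted lambda path with per-lambda BIC and the selected index."""

    model: ElasticNetOrdinalLogit
    lambdas: np.ndarray
    fits: list = field(default_factory=list)
    bic_values: np.ndarray = None
    selected_index: int = 0

    @property
    def selected(self) -> PenalizedOrdinalResults:
        return self.fits[self.selected_index]

    @property
    def selected_lambda(self) -> float:
        return float(self.lambdas[self.selected_index])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "lambda": self.lambdas,
            "bic": self.bic_values,
            "loglik": [f.llf for f in self.fits],
            "n_nonzero": [f.n_nonzero for f in self.fits],
            "converged": [int(f.converged) for f in self.fits],
            "selected": [int(i == self.selected_index)
                         for i in range(len(self.fits))],
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        head = (f"Elastic net lambda path (w = {self.model.weight_w:g}, "
                f"{len(self.fits)} values); selected lambda = "
                f"{self.selected_lambda:.6g} by BIC")
        return head + "\n" + self.to_frame().to_string(index=False)
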