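"""Proportional-odds (cumulative logit) regression by maximum likelihood.

The model for an ordinal outcome Y in 1..J with covariate row x is

    logit P(Y <= j) = gamma_j + x' beta,   j = 1..J-1,

with category-specific intercepts gamma_1 < ... < gamma_{J-1} and slopes
shared across categories. Fitting is exact Newton with analytic gradient and
Hessian and step-halving; the log-likelihood is concave in (gamma, beta), so
the monotone-intercept constraint is active only through the likelihood
itself (any crossing makes a category probability negative, which the line
search rejects).

Unobserved outcome categories are collapsed away (relabelled onto the
observed, ordered categories) and the mapping recorded, since the cumulative
model is unidentifiable for empty categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2

__all__ = [
    "OrdinalLogit",
    "OrdinalLogitResults",
    "lr_test",
    "DegenerateOutcomeError",
    "ConvergenceError",
    "NestingViolationError",
    "SeparationWarning",
]

_SEPARATION_BOUND = 30.0


class DegenerateOutcomeError(ValueError):
    """Outcome uses fewer than two observed categories."""


class ConvergenceError(RuntimeError):
    """Optimizer failed to converge within the iteration budget."""

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params


class NestingViolationError(ValueError):
    """Full-model log-likelihood below the reduced model's beyond slack."""


class SeparationWarning(UserWarning):
    """A slope diverged, suggesting (quasi-)complete separation."""


class _CumulativeLogitLik:
    """Negative log-likelihood, gradient and Hessian of the cumulative logit.

    Parameter vector is theta = (gamma_1..gamma_{m-1}, beta_1..beta_p) where
    m is the number of observed outcome categories. Each observation with
    (0-based) category c contributes log(F(u) - F(v)) with
    u = gamma_{c+1} + eta (or +inf for the top category) and
    v = gamma_c + eta (or -inf for the bottom one), F the logistic CDF.
    """

    def __init__(self, codes: np.ndarray, exog: np.ndarray, n_cat: int):
        self.codes = codes
        self.exog = exog
        self.n_cat = n_cat
        self.n_obs = codes.shape[0]
        self.n_alpha = n_cat - 1
        self.n_slopes = exog.shape[1]
        self.k = self.n_alpha + self.n_slopes
        n = self.n_obs
        self.mask_u = codes <= n_cat - 2
        self.mask_v = codes >= 1
        # dense derivative maps d(u)/d(theta), d(v)/d(theta); rows at the
        # boundary categories get zero weight in every contraction below
        U = np.zeros((n, self.k))
        V = np.zeros((n, self.k))
        rows = np.arange(n)
        U[rows[self.mask_u], codes[self.mask_u]] = 1.0
        V[rows[self.mask_v], codes[self.mask_v] - 1] = 1.0
        U[:, self.n_alpha:] = exog
        V[:, self.n_alpha:] = exog
        self.U = U
        self.V = V

    def _uv(self, params):
        gamma = params[: self.n_alpha]
        beta = params[self.n_alpha:]
        eta = self.exog @ beta if self.n_slopes else np.zeros(self.n_obs)
        u = np.where(self.mask_u, gamma[np.minimum(self.codes, self.n_alpha - 1)], np.inf)
        v = np.where(self.mask_v, gamma[np.maximum(self.codes - 1, 0)], -np.inf)
        return u + eta, v + eta

    def nll(self, params) -> float:
        u, v = self._uv(params)
        p = expit(u) - expit(v)
        if np.any(p <= 0) or not np.all(np.isfinite(p)):
            return np.inf
        return -float(np.sum(np.log(p)))

    def nll_grad_hess(self, params):
        u, v = self._uv(params)
        su, sv = expit(u), expit(v)
        p = su - sv
        if np.any(p <= 0) or not np.all(np.isfinite(p)):
            return np.inf, None, None
        nll = -float(np.sum(np.log(p)))
        fu = su * (1.0 - su)  # logistic density; exactly 0 at +-inf
        fv = sv * (1.0 - sv)
        A = fu / p
        B = fv / p
        grad_ll = self.U.T @ A - self.V.T @ B
        l_uu = fu * (1.0 - 2.0 * su) / p - A * A
        l_vv = -fv * (1.0 - 2.0 * sv) / p - B * B
        l_uv = A * B
        UW = self.U * l_uu[:, None]
        VW = self.V * l_vv[:, None]
        UX = self.U * l_uv[:, None]
        hess_ll = UW.T @ self.U + VW.T @ self.V + UX.T @ self.V + self.V.T @ UX
        return nll, -grad_ll, -hess_ll


def _collapse_outcome(endog: np.ndarray):
    """Map outcome values onto 0-based codes over the observed categories."""
    y = np.asarray(endog)
    if y.ndim != 1:
        raise ValueError("endog must be 1-D")
    if not np.issubdtype(y.dtype, np.integer):
        if not np.all(y == np.round(y)):
            raise ValueError("endog must be integer-coded ordinal categories")
        y = y.astype(np.int64)
    observed = np.unique(y)
    if observed.size < 2:
        raise DegenerateOutcomeError(
            "outcome uses a single observed category; cumulative model undefined"
        )
    codes = np.searchsorted(observed, y)
    category_map = {int(orig): j + 1 for j, orig in enumerate(observed)}
    return codes, category_map


class OrdinalLogit:
    """Proportional-odds model for an ordinal outcome.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Integer ordinal outcome. Unobserved categories are collapsed and
        recorded in ``category_map`` on the results.
    exog : array-like, shape (n, p) or None
        Covariate matrix (no constant column -- the category intercepts play
        that role). ``None`` or an empty matrix fits the intercept-only model.
    exog_names : sequence of str, optional
    """

    def __init__(self, endog, exog=None, exog_names=None):
        codes, category_map = _collapse_outcome(endog)
        if exog is None:
            X = np.empty((codes.shape[0], 0))
        else:
            X = np.atleast_2d(np.asarray(exog, dtype=float))
            if X.shape[0] == 1 and codes.shape[0] != 1:
                X = X.T
        if X.shape[0] != codes.shape[0]:
            raise ValueError("endog and exog lengths differ")
        self.category_map = category_map
        self.n_cat = len(category_map)
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{j + 1}" for j in range(X.shape[1])]
        )
        if len(self.exog_names) != X.shape[1]:
            raise ValueError("exog_names length mismatch")
        self._lik = _CumulativeLogitLik(codes, X, self.n_cat)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str, covariates=()):
        cov = list(covariates)
        return cls(
            data[outcome].to_numpy(),
            data[cov].to_numpy(dtype=float) if cov else None,
            exog_names=cov,
        )

    @property
    def n_obs(self) -> int:
        return self._lik.n_obs

    @property
    def n_params(self) -> int:
        return self._lik.k

    def start_params(self) -> np.ndarray:
        """Intercepts at logits of empirical cumulative proportions, slopes 0."""
        lik = self._lik
        counts = np.bincount(lik.codes, minlength=self.n_cat)
        cum = np.cumsum(counts)[:-1] / lik.n_obs
        cum = np.clip(cum, 1e-10, 1 - 1e-10)
        params = np.zeros(lik.k)
        params[: lik.n_alpha] = np.log(cum / (1 - cum))
        return params

    def loglike(self, params) -> float:
        """Log-likelihood at an arbitrary parameter vector."""
        return -self._lik.nll(np.asarray(params, dtype=float))

    def score(self, params) -> np.ndarray:
        """Gradient of the log-likelihood."""
        _, g, _ = self._lik.nll_grad_hess(np.asarray(params, dtype=float))
        return -g

    def fit(self, start_params=None, tol: float = 1e-10, gtol: float = 1e-8,
            max_iter: int = 100) -> "OrdinalLogitResults":
        """Newton maximization with step-halving.

        Converges when the relative log-likelihood change drops below ``tol``
        or the gradient max-norm below ``gtol``.
        """
        lik = self._lik
        params = np.asarray(start_params, dtype=float) if start_params is not None \
            else self.start_params()
        nll, g, H = lik.nll_grad_hess(params)
        if not np.isfinite(nll):
            raise ValueError("infeasible starting values")
        n_iter = 0
        converged = np.max(np.abs(g)) < gtol
        while not converged and n_iter < max_iter:
            n_iter += 1
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                step = np.linalg.solve(H + 1e-8 * np.eye(lik.k), g)
            t = 1.0
            for _ in range(40):
                cand = params - t * step
                nll_new = lik.nll(cand)
                if nll_new < nll + 1e-14:
                    break
                t *= 0.5
            else:
                # the objective is concave: no descent direction means the
                # iterate is the optimum to within rounding
                converged = True
                break
            rel_change = abs(nll - nll_new) / (abs(nll) + 1.0)
            params = cand
            nll, g, H = lik.nll_grad_hess(params)
            if np.max(np.abs(g)) < gtol or rel_change < tol:
                converged = True
        if not converged:
            raise ConvergenceError(
                f"Newton did not converge in {max_iter} iterations "
                f"(gradient max-norm {np.max(np.abs(g)):.3e})",
                last_params=params,
            )
        separation = bool(np.any(np.abs(params[lik.n_alpha:]) > _SEPARATION_BOUND))
        if separation:
            warnings.warn(
                "a slope estimate diverged; data may be separated", SeparationWarning
            )
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.full((lik.k, lik.k), np.nan)
        return OrdinalLogitResults(
            model=self, params=params, llf=-nll, cov_params=cov,
            converged=True, n_iter=n_iter, separation=separation,
        )


@dataclass
class OrdinalLogitResults:
    """ML fit of a proportional-odds model."""

    model: OrdinalLogit
    params: np.ndarray
    llf: float
    cov_params: np.ndarray
    converged: bool
    n_iter: int
    separation: bool = False

    @property
    def intercepts(self) -> np.ndarray:
        return self.params[: self.model.n_cat - 1]

    @property
    def slopes(self) -> np.ndarray:
        return self.params[self.model.n_cat - 1:]

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def param_names(self) -> list[str]:
        originals = sorted(self.model.category_map, key=self.model.category_map.get)
        return [f"gamma_{self.model.category_map[c]}|{c}" for c in originals[:-1]] + \
            list(self.model.exog_names)

    @property
    def category_map(self) -> dict:
        return self.model.category_map

    def summary(self) -> str:
        lines = [
            "Proportional-odds (cumulative logit) model, ML fit",
            f"n_obs = {self.model.n_obs}   categories = {self.model.n_cat}   "
            f"logL = {self.llf:.4f}   iterations = {self.n_iter}",
            f"{'parameter':<16}{'estimate':>12}{'std.err':>12}",
        ]
        for name, est, se in zip(self.param_names, self.params, self.bse):
            lines.append(f"{name:<16}{est:>12.4f}{se:>12.4f}")
        if self.separation:
            lines.append("warning: possible separation (diverged slope)")
        return "\n".join(lines)

    def to_report(self) -> str:
        """Plain-text key-value serialization of the fit."""
        pairs = [("loglik", f"{self.llf:.10g}"), ("converged", str(self.converged)),
                 ("n_iter", str(self.n_iter))]
        pairs += [(n, f"{v:.10g}") for n, v in zip(self.param_names, self.params)]
        return "\n".join(f"{k}: {v}" for k, v in pairs)


def lr_test(loglik_reduced: float, loglik_full: float, df: int = 1,
            slack: float = 1e-6):
    """Likelihood-ratio test of nested ML fits against chi-square(df).

    Returns ``(statistic, p_value)`` with statistic = 2(l_full - l_reduced)
    clipped at zero. A deficit beyond ``slack`` signals a fitting failure in
    the supposedly-nested pair and raises ``NestingViolationError``.
    """
    delta = loglik_full - loglik_reduced
    if delta < -slack:
        raise NestingViolationError(
            f"full-model log-likelihood below reduced model's by {-delta:.3e}"
        )
    stat = max(0.0, 2.0 * delta)
    return stat, float(chi2.sf(stat, df))
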