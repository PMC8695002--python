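"""Samejima's graded response model (GRM) simulator.

Generates ordinal (Likert-type) item responses for a reference and a focal
group from a common latent trait, with optional uniform DIF injected into
one item by shifting its focal-group threshold parameters by a constant.

The GRM defines, for item *i* with discrimination ``a_i`` and ordered
thresholds ``b_i1 < ... < b_i,J-1``, the probability of responding in or
above category ``j+1`` as a two-parameter logistic in the latent trait:

    P(Y >= j+1 | theta) = 1 / (1 + exp(-a_i (theta - b_ij)))

Category probabilities follow by differencing adjacent cumulative curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "ItemBank",
    "DIFSpec",
    "ResponseDataset",
    "sample_item_bank",
    "apply_uniform_dif",
    "grm_cumulative_prob",
    "grm_category_probs",
    "simulate_responses",
]


@dataclass(frozen=True)
class ItemBank:
    """GRM item parameters: discriminations and ordered thresholds.

    Parameters
    ----------
    discriminations : ndarray, shape (I,)
        Item discriminations ``a_i``; strictly positive.
    thresholds : ndarray, shape (I, J-1)
        Per-item threshold (difficulty) parameters on the latent scale,
        strictly increasing within each item.
    """

    discriminations: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self):
        a = np.atleast_1d(np.asarray(self.discriminations, dtype=float))
        b = np.atleast_2d(np.asarray(self.thresholds, dtype=float))
        if a.ndim != 1 or b.ndim != 2 or b.shape[0] != a.shape[0]:
            raise ValueError(
                "discriminations must be (I,) and thresholds (I, J-1) with matching I"
            )
        if np.any(a <= 0):
            raise ValueError("discriminations must be strictly positive")
        if b.shape[1] < 1:
            raise ValueError("need at least one threshold per item (J >= 2)")
        if np.any(np.diff(b, axis=1) <= 0):
            raise ValueError("thresholds must be strictly increasing within each item")
        object.__setattr__(self, "discriminations", a)
        object.__setattr__(self, "thresholds", b)

    @property
    def n_items(self) -> int:
        return self.discriminations.shape[0]

    @property
    def n_categories(self) -> int:
        return self.thresholds.shape[1] + 1


@dataclass(frozen=True)
class DIFSpec:
    """Uniform DIF: a constant shift of one item's focal-group thresholds.

    ``target_item`` is 1-based; ``magnitude`` >= 0 on the latent scale
    (0 encodes the null, no-DIF condition).
    """

    target_item: int
    magnitude: float

    def __post_init__(self):
        if self.target_item < 1:
            raise IndexError("target_item is 1-based and must be >= 1")
        if self.magnitude < 0:
            raise ValueError("DIF magnitude must be >= 0")


@dataclass(frozen=True)
class ResponseDataset:
    """Persons x items ordinal response matrix with a group indicator.

    ``responses`` holds integers in 1..J; ``group`` is 0 for the reference
    group and 1 for the focal group. ``theta_true`` keeps the generating
    latent traits for diagnostics only -- the detection code never sees it
    (matching is on the observed total score).
    """

    responses: np.ndarray
    group: np.ndarray
    theta_true: np.ndarray | None = field(default=None)

    def __post_init__(self):
        resp = np.asarray(self.responses)
        grp = np.asarray(self.group)
        if resp.ndim != 2:
            raise ValueError("responses must be 2-D (persons x items)")
        if grp.shape != (resp.shape[0],):
            raise ValueError("group vector length must equal the number of response rows")
        if not np.issubdtype(resp.dtype, np.integer):
            if not np.all(resp == np.round(resp)):
                raise ValueError("responses must be integers")
            resp = resp.astype(np.int64)
        if np.any(resp < 1):
            raise ValueError("responses must be coded 1..J")
        if not np.all(np.isin(grp, (0, 1))):
            raise ValueError("group must be coded 0 (reference) / 1 (focal)")
        object.__setattr__(self, "responses", resp)
        object.__setattr__(self, "group", grp.astype(np.int64))
        if self.theta_true is not None:
            th = np.asarray(self.theta_true, dtype=float)
            if th.shape != (resp.shape[0],):
                raise ValueError("theta_true length must equal the number of rows")
            object.__setattr__(self, "theta_true", th)

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def n_ref(self) -> int:
        return int(np.sum(self.group == 0))

    @property
    def n_focal(self) -> int:
        return int(np.sum(self.group == 1))

    def to_frame(self, include_theta: bool = False) -> pd.DataFrame:
        cols = {f"item_{i + 1}": self.responses[:, i] for i in range(self.n_items)}
        cols["group"] = self.group
        if include_theta and self.theta_true is not None:
            cols["theta"] = self.theta_true
        return pd.DataFrame(cols)


def _as_rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def sample_item_bank(n_items: int, n_categories: int, seed=None) -> ItemBank:
    """Draw a random GRM item bank.

    Discriminations are i.i.d. Uniform(1, 2); each item's J-1 thresholds are
    independent standard-normal draws sorted ascending (sorting guarantees a
    valid GRM: unordered thresholds would produce negative category
    probabilities). Floating-point ties after sorting are perturbed by 1e-9
    increments to keep the ordering strict.
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    if n_categories < 2:
        raise ValueError("n_categories must be >= 2")
    rng = _as_rng(seed)
    a = rng.uniform(1.0, 2.0, size=n_items)
    b = np.sort(rng.standard_normal((n_items, n_categories - 1)), axis=1)
    # strict ordering even in the probability-zero event of an exact tie
    ties = np.diff(b, axis=1) <= 0
    if np.any(ties):
        b += np.arange(n_categories - 1) * 1e-9
        b = np.sort(b, axis=1)
    return ItemBank(discriminations=a, thresholds=b)


def apply_uniform_dif(bank: ItemBank, dif: DIFSpec) -> ItemBank:
    """Return the focal-group bank with the target item's thresholds shifted.

    Every threshold of ``dif.target_item`` is increased by ``dif.magnitude``
    (making the item uniformly harder for the focal group); all other items
    and the input bank itself are untouched.
    """
    if dif.target_item > bank.n_items:
        raise IndexError(
            f"target_item {dif.target_item} out of range for a {bank.n_items}-item bank"
        )
    if dif.magnitude == 0:
        return replace(bank)
    b = bank.thresholds.copy()
    b[dif.target_item - 1] += dif.magnitude
    return ItemBank(discriminations=bank.discriminations.copy(), thresholds=b)


def grm_cumulative_prob(a: float, theta, b) -> np.ndarray | float:
    """GRM cumulative probability P(Y >= j+1 | theta) = expit(a (theta - b))."""
    if np.any(np.asarray(a) <= 0):
        raise ValueError("discrimination must be positive")
    return expit(a * (np.asarray(theta, dtype=float) - np.asarray(b, dtype=float)))


def grm_category_probs(a: float, theta, thresholds) -> np.ndarray:
    """Category probabilities P(Y = j), j = 1..J, by differencing the GRM curves.

    With P(Y >= 1) = 1 and P(Y >= J+1) = 0, P(Y = j) = P(Y >= j) - P(Y >= j+1).
    Supports a vector ``theta``, returning an array of shape (..., J).
    """
    b = np.asarray(thresholds, dtype=float)
    if b.ndim != 1:
        raise ValueError("thresholds must be a 1-D vector")
    if np.any(np.diff(b) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    theta = np.asarray(theta, dtype=float)
    cum = grm_cumulative_prob(a, theta[..., None], b)  # (..., J-1), decreasing in j
    ones = np.ones(theta.shape + (1,))
    zeros = np.zeros(theta.shape + (1,))
    upper = np.concatenate([ones, cum], axis=-1)
    lower = np.concatenate([cum, zeros], axis=-1)
    return upper - lower


def simulate_responses(
    ref_bank: ItemBank,
    focal_bank: ItemBank,
    n_ref: int,
    n_focal: int,
    seed=None,
) -> ResponseDataset:
    """Simulate a two-group response dataset from the GRM.

    Latent traits are standard normal in both groups; each person's response
    to each item is a categorical draw from ``grm_category_probs`` using the
    bank of that person's group. Reference rows come first.
    """
    if (
        ref_bank.n_items != focal_bank.n_items
        or ref_bank.n_categories != focal_bank.n_categories
    ):
        raise ValueError("reference and focal banks must share I and J")
    if n_ref < 1 or n_focal < 1:
        raise ValueError("group sizes must be >= 1")
    rng = _as_rng(seed)
    n = n_ref + n_focal
    theta = rng.standard_normal(n)
    group = np.concatenate([np.zeros(n_ref, dtype=np.int64), np.ones(n_focal, dtype=np.int64)])
    responses = np.empty((n, ref_bank.n_items), dtype=np.int64)
    u = rng.uniform(size=(n, ref_bank.n_items))
    for i in range(ref_bank.n_items):
        for g, bank in ((0, ref_bank), (1, focal_bank)):
            rows = group == g
            # P(Y >= j+1) for j = 1..J-1, decreasing in j; inverse-CDF draw:
            # Y = 1 + #{j : u < P(Y >= j+1)}
            cum = grm_cumulative_prob(
                bank.discriminations[i], theta[rows, None], bank.thresholds[i]
            )
            responses[rows, i] = 1 + np.sum(u[rows, i][:, None] < cum, axis=1)
    return ResponseDataset(responses=responses, group=group, theta_true=theta)
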