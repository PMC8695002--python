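"""Monte Carlo power / type-I-error study of the DIF tests.

Each replication draws a fresh GRM item bank, injects uniform DIF into item 1
of the focal group, simulates a two-group dataset, and applies every
configured method (nonregularized ML and/or elastic net at each mixing weight
w) to the *same* dataset -- a paired design, so method comparisons are
variance-reduced. Power is the rejection proportion on the DIF item; the
type-I error rate pools rejections over the DIF-free items.

Replications in which any required fit is degenerate or non-convergent are
discarded and redrawn from a derived seed stream (up to 10 attempts), with
the discard count reported. Seeding is hierarchical (base seed, replication
index, attempt), so results are reproducible independently of the worker
count or the order conditions run in.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .dif import DIFConfig, analyze_scale
from .grm import DIFSpec, apply_uniform_dif, sample_item_bank, simulate_responses

__all__ = [
    "DEFAULT_W_GRID",
    "SimulationCondition",
    "SimulationSummary",
    "run_replication",
    "run_condition",
    "run_grid",
    "load_grid_config",
    "plot_power",
]

logger = logging.getLogger(__name__)

#: the study's mixing-weight grid (ridge ... LASSO); "ml" is the
#: nonregularized reference method
DEFAULT_W_GRID = (0.0, 0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.1, 0.5, 1.0)

_MAX_ATTEMPTS = 10
_BANK_STREAM_TAG = 104729  # distinct entropy tag for the fixed-bank stream


def method_label(method) -> str:
    return method if isinstance(method, str) else f"w={method:g}"


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of the simulation design.

    ``methods`` mixes the string ``"ml"`` with numeric elastic net mixing
    weights. ``ratio`` is n_ref / n_focal; group sizes round as
    n_ref = round(N * R / (R + 1)). ``items`` restricts which items are
    tested (1-based; None tests all). ``fixed_bank`` holds the item bank
    fixed across replications instead of redrawing it.
    """

    n_total: int
    ratio: int = 1
    n_items: int = 5
    n_categories: int = 5
    dif_magnitude: float = 0.0
    methods: tuple = ("ml",) + DEFAULT_W_GRID
    n_replications: int = 1000
    base_seed: int = 0
    alpha: float = 0.05
    score_type: str = "total"
    lr_loglik: str = "unpenalized_at_estimates"
    n_lambda: int = 20
    min_ratio: float = 0.01
    fixed_bank: bool = False
    items: tuple | None = None

    def __post_init__(self):
        if self.n_total < 2 or self.ratio < 1:
            raise ValueError("need n_total >= 2 and ratio >= 1")
        if self.n_focal < 1:
            raise ValueError("focal group size rounds to zero")
        if self.dif_magnitude < 0:
            raise ValueError("dif_magnitude must be >= 0")
        if not self.methods:
            raise ValueError("methods must be non-empty")
        if self.items is not None:
            bad = [i for i in self.items if not 1 <= i <= self.n_items]
            if bad:
                raise ValueError(f"items out of range: {bad}")

    @property
    def n_ref(self) -> int:
        return int(round(self.n_total * self.ratio / (self.ratio + 1)))

    @property
    def n_focal(self) -> int:
        return self.n_total - self.n_ref

    @property
    def tested_items(self) -> tuple:
        return tuple(self.items) if self.items is not None \
            else tuple(range(1, self.n_items + 1))

    @property
    def method_labels(self) -> tuple:
        return tuple(method_label(m) for m in self.methods)

    def dif_config(self, method) -> DIFConfig:
        if method == "ml":
            return DIFConfig(method="ml", alpha=self.alpha,
                             score_type=self.score_type, test_nonuniform=False)
        return DIFConfig(
            method="elastic_net", weight_w=float(method), alpha=self.alpha,
            score_type=self.score_type, lr_loglik=self.lr_loglik,
            n_lambda=self.n_lambda, min_ratio=self.min_ratio,
            test_nonuniform=False,
        )

    def describe(self) -> dict:
        return {
            "n_total": self.n_total, "ratio": self.ratio,
            "n_items": self.n_items, "n_categories": self.n_categories,
            "dif": self.dif_magnitude,
        }


def run_replication(condition: SimulationCondition, rep_index: int):
    """One paired replication: rejection indicators per (method, tested item).

    Returns ``(indicators, info)`` where ``indicators`` has shape
    (n_methods, n_tested_items) with 0/1 entries, and ``info`` carries the
    attempt count and the selected lambdas of the elastic net fits.
    """
    items = condition.tested_items
    last_error = None
    for attempt in range(_MAX_ATTEMPTS):
        rng = np.random.default_rng(
            np.random.SeedSequence([condition.base_seed, rep_index, attempt])
        )
        bank_rng = (
            np.random.default_rng(
                np.random.SeedSequence([condition.base_seed, _BANK_STREAM_TAG])
            )
            if condition.fixed_bank else rng
        )
        bank = sample_item_bank(condition.n_items, condition.n_categories, bank_rng)
        focal = (
            apply_uniform_dif(bank, DIFSpec(1, condition.dif_magnitude))
            if condition.dif_magnitude > 0 else bank
        )
        dataset = simulate_responses(
            bank, focal, condition.n_ref, condition.n_focal, rng
        )
        indicators = np.zeros((len(condition.methods), len(items)), dtype=np.int8)
        lambdas: dict[str, list] = {}
        failed = False
        for mi, method in enumerate(condition.methods):
            scan = analyze_scale(dataset, condition.dif_config(method), items=items)
            if any(not r.ok for r in scan):
                last_error = next(r.error for r in scan if not r.ok)
                failed = True
                break
            for ji, r in enumerate(scan):
                indicators[mi, ji] = int(r.flagged_uniform)
            if method != "ml":
                lams = [r.diagnostics[k] for r in scan
                        for k in ("lambda_model1", "lambda_model2")
                        if k in r.diagnostics]
                lambdas[method_label(method)] = lams
        if not failed:
            return indicators, {"attempts": attempt + 1, "lambdas": lambdas}
        logger.debug("replication %d attempt %d discarded: %s",
                     rep_index, attempt + 1, last_error)
    raise RuntimeError(
        f"replication {rep_index} failed {_MAX_ATTEMPTS} attempts "
        f"(last error: {last_error})"
    )


@dataclass
class SimulationSummary:
    """Power / type-I estimates per method for one condition."""

    condition: SimulationCondition
    table: pd.DataFrame
    n_discarded: int = 0

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        for k, v in self.condition.describe().items():
            out.insert(0, k, v)
        return out

    def estimate(self, method, metric: str) -> float:
        t = self.table
        row = t[(t["method"] == method_label(method)) & (t["metric"] == metric)]
        if row.empty:
            raise KeyError(f"no {metric} estimate for {method!r}")
        return float(row["estimate"].iloc[0])

    def summary(self) -> str:
        c = self.condition
        head = (f"Condition N={c.n_total} R={c.ratio} I={c.n_items} "
                f"J={c.n_categories} DIF={c.dif_magnitude:g} "
                f"({c.n_replications} replications, {self.n_discarded} redrawn)")
        return head + "\n" + self.table.to_string(index=False)


def run_condition(condition: SimulationCondition, n_jobs: int = 1,
                  ) -> SimulationSummary:
    """Aggregate ``run_replication`` over the condition's replication count."""
    reps = range(condition.n_replications)
    if n_jobs == 1:
        results = [run_replication(condition, r) for r in reps]
    else:
        results = Parallel(n_jobs=n_jobs)(
            delayed(run_replication)(condition, r) for r in reps
        )
    indicators = np.stack([ind for ind, _ in results])  # (reps, methods, items)
    n_discarded = sum(info["attempts"] - 1 for _, info in results)
    items = condition.tested_items
    dif_cols = [j for j, it in enumerate(items)
                if condition.dif_magnitude > 0 and it == 1]
    null_cols = [j for j in range(len(items)) if j not in dif_cols]
    lam_sums: dict[str, list] = {}
    for _, info in results:
        for lab, lams in info["lambdas"].items():
            lam_sums.setdefault(lab, []).extend(lams)
    rows = []
    n_reps = condition.n_replications
    for mi, lab in enumerate(condition.method_labels):
        mean_lam = float(np.mean(lam_sums[lab])) if lab in lam_sums else np.nan
        if dif_cols:
            p_hat = float(indicators[:, mi, dif_cols].mean())
            rows.append({
                "method": lab, "metric": "power", "estimate": p_hat,
                "mc_se": float(np.sqrt(p_hat * (1 - p_hat) / n_reps)),
                "n_effective": n_reps, "mean_selected_lambda": mean_lam,
            })
        if null_cols:
            pooled = indicators[:, mi, null_cols]
            p_hat = float(pooled.mean())
            n_pool = pooled.size
            rows.append({
                "method": lab, "metric": "type1", "estimate": p_hat,
                "mc_se": float(np.sqrt(p_hat * (1 - p_hat) / n_pool)),
                "n_effective": n_pool, "mean_selected_lambda": mean_lam,
            })
    return SimulationSummary(condition=condition, table=pd.DataFrame(rows),
                             n_discarded=n_discarded)


def run_grid(conditions, parallel_workers: int = 1) -> pd.DataFrame:
    """Run a list of conditions; long-format table, one row per
    (condition, method, metric). Failures are reported per condition and the
    remaining conditions still complete."""
    conditions = list(conditions)
    if not conditions:
        raise ValueError("empty condition list")

    def _one(cond):
        try:
            return run_condition(cond).to_frame()
        except Exception as exc:  # noqa: BLE001 - report and continue
            logger.error("condition %s failed: %s", cond.describe(), exc)
            frame = pd.DataFrame([{**cond.describe(), "method": "", "metric": "error",
                                   "estimate": np.nan, "mc_se": np.nan,
                                   "n_effective": 0,
                                   "mean_selected_lambda": np.nan}])
            return frame

    if parallel_workers == 1:
        frames = [_one(c) for c in conditions]
    else:
        frames = Parallel(n_jobs=parallel_workers)(
            delayed(_one)(c) for c in conditions
        )
    return pd.concat(frames, ignore_index=True)


def _derive_seed(seed: int, index: int) -> int:
    """Stable per-condition sub-seed below 2**31."""
    state = np.random.SeedSequence([int(seed), int(index)]).generate_state(1)
    return int(state[0] % (2**31))


def load_grid_config(config: dict | str) -> list:
    """Expand a grid config (dict or YAML path) into SimulationCondition list.

    Recognized keys: grid section ``n_total``, ``ratio``, ``n_items``, ``dif``
    (lists), plus scalars ``n_categories``, ``w_grid``, ``include_ml``,
    ``replications``, ``seed``, ``alpha``, ``score_type``, ``lr_loglik``,
    ``n_lambda``, ``min_ratio``, ``fixed_bank``, ``items``. Unknown keys are
    rejected.
    """
    if isinstance(config, str):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = dict(config)
    grid = dict(config.pop("grid", {}))
    known_grid = {"n_total", "ratio", "n_items", "dif"}
    unknown = set(grid) - known_grid
    if unknown:
        raise ValueError(f"unknown grid keys: {sorted(unknown)}")
    known = {"n_categories", "w_grid", "include_ml", "replications", "seed",
             "alpha", "score_type", "lr_loglik", "n_lambda", "min_ratio",
             "fixed_bank", "items"}
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    w_grid = config.get("w_grid", list(DEFAULT_W_GRID))
    methods = (("ml",) if config.get("include_ml", True) else ()) + \
        tuple(float(w) for w in w_grid)
    seed = int(config.get("seed", 0))
    axes = [
        [int(n) for n in grid.get("n_total", [100])],
        [int(r) for r in grid.get("ratio", [1])],
        [int(i) for i in grid.get("n_items", [5])],
        [float(d) for d in grid.get("dif", [0.0])],
    ]
    conditions = []
    for idx, (n, r, i, d) in enumerate(itertools.product(*axes)):
        conditions.append(SimulationCondition(
            n_total=n, ratio=r, n_items=i,
            n_categories=int(config.get("n_categories", 5)),
            dif_magnitude=d, methods=methods,
            n_replications=int(config.get("replications", 1000)),
            base_seed=_derive_seed(seed, idx),
            alpha=float(config.get("alpha", 0.05)),
            score_type=config.get("score_type", "total"),
            lr_loglik=config.get("lr_loglik", "unpenalized_at_estimates"),
            n_lambda=int(config.get("n_lambda", 20)),
            min_ratio=float(config.get("min_ratio", 0.01)),
            fixed_bank=bool(config.get("fixed_bank", False)),
            items=tuple(config["items"]) if config.get("items") else None,
        ))
    return conditions


def plot_power(table: pd.DataFrame, metric: str = "power", ax=None):
    """Line plot of a metric vs N, one line per method (Figures-style view)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sub = table[table["metric"] == metric]
    for lab, grp in sub.groupby("method"):
        grp = grp.sort_values("n_total")
        ax.plot(grp["n_total"], grp["estimate"], marker="o", label=lab)
    ax.set_xlabel("total sample size N")
    ax.set_ylabel(metric)
    ax.legend(fontsize="small")
    if metric == "type1":
        ax.axhline(0.05, color="grey", ls=":", lw=1)
    return ax
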