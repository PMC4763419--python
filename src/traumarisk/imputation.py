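"""Multiple imputation by chained equations, run separately per hospital.

Missing vitals are assumed missing at random and handled by chained-equation
multiple imputation with predictive-mean matching (PMM): each incomplete
variable is regressed on the other predictors, regression parameters are
perturbed by a draw from their approximate posterior, and every missing cell
receives the *observed* value of a donor whose predicted mean is among the
closest to the missing cell's prediction.  PMM keeps imputations inside the
observed support (GCS stays an integer in 3-15, pressures stay positive).

Three study-specific rules:

* **Per-hospital imputation.**  Each hospital is imputed separately with the
  same imputation model and the results are combined; the chain for hospital
  *h* sees only rows of hospital *h*, with its RNG seeded deterministically
  from (master seed, dataset index, hospital id) so the separation is exact.
* **Outcome in the imputation model.**  Early mortality is always included
  as a predictor of the missing vitals.
* **Number of imputed datasets.**  ``m`` equals the percentage of incomplete
  observations in the hospital with the highest such percentage (an
  "incomplete observation" lacks at least one of the variables needed to
  apply the models: SBP, HR, GCS, age — configurable).

Hypothesis tests performed on multiply imputed data are pooled by the median
P-value with its IQR across the ``m`` datasets; median P < 0.05 is deemed
significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_cohort import COHORT_COLUMNS, MISSABLE_FIELDS

__all__ = [
    "ImputationResult",
    "ImputationError",
    "incomplete_fractions",
    "choose_m",
    "impute",
    "pool_pvalues",
    "write_imputed_stack",
    "read_imputed_stack",
]

#: Variables counted when deciding whether an observation is "incomplete"
#: (the set required to apply all compared risk models).
MODEL_VARIABLES = ("sbp", "hr", "gcs", "age")

#: Default predictor set of each chained-equation conditional model.
DEFAULT_PREDICTORS = ("sbp", "hr", "gcs", "delay_h", "age", "male", "transferred",
                      "early_death")

PMM_DONORS = 5
BURN_IN_CYCLES = 10


class ImputationError(RuntimeError):
    pass


def incomplete_fractions(
    cohort: pd.DataFrame, variables: tuple[str, ...] = MODEL_VARIABLES
) -> dict[str, float]:
    """Per-hospital fraction of rows missing >= 1 model variable."""
    incomplete = cohort[list(variables)].isna().any(axis=1)
    return {
        str(h): float(incomplete[cohort["hospital_id"] == h].mean())
        for h in sorted(cohort["hospital_id"].unique())
    }


def choose_m(per_hospital_incomplete_fraction: dict[str, float]) -> int:
    """Number of imputed datasets: the worst hospital's incomplete percentage.

    ``m = round(100 * max fraction)``, floored at 2 whenever any data are
    missing; 0 (no imputation needed) when every hospital is complete.
    """
    fracs = list(per_hospital_incomplete_fraction.values())
    if not fracs or any(not 0 <= f <= 1 for f in fracs):
        raise ValueError("incomplete fractions must be in [0, 1]")
    worst = max(fracs)
    if worst == 0:
        return 0
    return max(2, int(round(100 * worst)))


@dataclass(frozen=True)
class ImputationResult:
    """m completed copies of a cohort plus provenance."""

    m: int
    datasets: tuple[pd.DataFrame, ...]
    per_hospital_incomplete_fraction: dict[str, float]
    seed: int

    def __post_init__(self) -> None:
        assert len(self.datasets) == self.m or self.m == 0


def _draw_regression(rng, X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-perturbed OLS: returns (predictions from beta_hat, from beta_star).

    Ridge-stabilised normal equations; Bayesian draw of (sigma, beta) as in
    standard PMM implementations.
    """
    n, p = X.shape
    XtX = X.T @ X + 1e-6 * np.eye(p)
    beta_hat = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta_hat
    dof = max(n - p, 1)
    sigma2 = (resid @ resid) / max(rng.chisquare(dof), 1e-12)
    cov = np.linalg.inv(XtX)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(p))
    beta_star = beta_hat + np.sqrt(sigma2) * (L @ rng.standard_normal(p))
    return beta_hat, beta_star


def _pmm_impute_hospital(
    block: pd.DataFrame,
    targets: list[str],
    predictors: tuple[str, ...],
    rng: np.random.Generator,
    hospital: str,
) -> pd.DataFrame:
    work = block.copy()
    num = {
        c: work[c].astype(float).to_numpy(copy=True)
        for c in predictors
        if c in work.columns
    }
    miss = {v: np.isnan(num[v]) for v in targets}

    # initial fill: random draws from the observed values of the same hospital
    for v in targets:
        obs = num[v][~miss[v]]
        if obs.size == 0:
            raise ImputationError(
                f"hospital {hospital!r}: variable {v!r} has no observed values"
            )
        num[v][miss[v]] = rng.choice(obs, size=int(miss[v].sum()), replace=True)

    for _ in range(BURN_IN_CYCLES):
        for v in targets:
            mv = miss[v]
            if not mv.any():
                continue
            others = [c for c in num if c != v]
            X = np.column_stack([np.ones(len(work))] + [num[c] for c in others])
            beta_hat, beta_star = _draw_regression(rng, X[~mv], num[v][~mv])
            pred_obs = X[~mv] @ beta_hat
            pred_mis = X[mv] @ beta_star
            obs_vals = num[v][~mv]
            # k nearest observed predictions donate their observed value
            k = min(PMM_DONORS, obs_vals.size)
            dist = np.abs(pred_obs[None, :] - pred_mis[:, None])
            nearest = np.argpartition(dist, k - 1, axis=1)[:, :k]
            pick = rng.integers(0, k, int(mv.sum()))
            num[v][mv] = obs_vals[nearest[np.arange(int(mv.sum())), pick]]

    for v in targets:
        col = num[v]
        if v == "gcs":
            col = np.clip(np.round(col), 3, 15)
        work[v] = col
    return work


def impute(
    cohort: pd.DataFrame,
    m: int,
    seed: int = 0,
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
) -> ImputationResult:
    """Produce ``m`` completed copies of ``cohort`` by per-hospital PMM MICE.

    Observed cells are identical across copies and identical to the input;
    only originally missing cells of ``sbp``, ``hr``, ``gcs``, ``delay_h``
    vary.  Deterministic in ``seed``.
    """
    if m < 2:
        raise ValueError("m must be >= 2 (use choose_m; m=0 means nothing missing)")
    targets = [v for v in MISSABLE_FIELDS if cohort[v].isna().any()]
    if not targets:
        return ImputationResult(
            m=m,
            datasets=tuple(cohort.copy() for _ in range(m)),
            per_hospital_incomplete_fraction=incomplete_fractions(cohort),
            seed=seed,
        )
    hospitals = sorted(cohort["hospital_id"].unique())
    pred = tuple(p for p in predictors if p in cohort.columns)
    seed_base = list(seed) if isinstance(seed, (list, tuple)) else [seed]

    datasets = []
    for d in range(1, m + 1):
        completed = cohort.copy()
        bools = {c: completed[c].dtype == bool for c in pred}
        for c, is_bool in bools.items():
            if is_bool:
                completed[c] = completed[c].astype(float)
        for h_idx, h in enumerate(hospitals):
            sel = completed["hospital_id"] == h
            rng = np.random.default_rng(seed_base + [d, h_idx])
            completed.loc[sel] = _pmm_impute_hospital(
                completed.loc[sel], targets, pred, rng, str(h)
            )
        for c, is_bool in bools.items():
            if is_bool:
                completed[c] = completed[c].astype(bool)
        datasets.append(completed)
    return ImputationResult(
        m=m,
        datasets=tuple(datasets),
        per_hospital_incomplete_fraction=incomplete_fractions(cohort),
        seed=seed,
    )


def pool_pvalues(p_values) -> tuple[float, tuple[float, float], bool]:
    """Median P, (25th, 75th) percentile range, and median-P < 0.05 flag."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no P-values to pool")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("P-values must lie in [0, 1]")
    med = float(np.median(p))
    q1, q3 = (float(v) for v in np.percentile(p, [25, 75]))
    return med, (q1, q3), med < 0.05


# ---------------------------------------------------------------------------
# Stacked-file I/O: one delimited file, `imputation` column 0 = original
# (with missing values), 1..m = completed copies.
# ---------------------------------------------------------------------------

def write_imputed_stack(original: pd.DataFrame, result: ImputationResult, path) -> None:
    frames = [original.assign(imputation=0)]
    frames += [d.assign(imputation=i + 1) for i, d in enumerate(result.datasets)]
    stack = pd.concat(frames, ignore_index=True)
    stack["arrival_time"] = pd.to_datetime(stack["arrival_time"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    stack.to_csv(path, index=False)


def read_imputed_stack(path) -> tuple[pd.DataFrame, list[pd.DataFrame]]:
    stack = pd.read_csv(path, parse_dates=["arrival_time"])
    original = stack[stack["imputation"] == 0].drop(columns="imputation")
    m = int(stack["imputation"].max())
    datasets = [
        stack[stack["imputation"] == i].drop(columns="imputation").reset_index(drop=True)
        for i in range(1, m + 1)
    ]
    original = original.reset_index(drop=True)
    for frame in [original] + datasets:
        for b in ("male", "transferred", "early_death"):
            frame[b] = frame[b].astype(bool)
    return original[COHORT_COLUMNS], [d[COHORT_COLUMNS] for d in datasets]
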