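"""Discrimination and calibration of risk models, pooled across imputations.

Validation step of the analysis.  Each model is assessed on the validation
sample by:

* **AUROCC** — area under the receiver operating characteristics curve,
  equal to the Mann-Whitney concordance probability (ties count one half).
  Correlated AUROCCs of two models evaluated on the same patients are
  compared with DeLong's nonparametric test.
* **Calibration slope** — the slope from a logistic regression of the
  observed outcome on the model's linear predictor; 1 is ideal, below 1 the
  predictions are too extreme (overfitting), above 1 too moderate.  Slopes
  of two models are compared by a paired patient-level bootstrap of the
  slope difference.
* **Sensitivity / specificity** at a classification threshold (default
  0.05, the threshold probability emphasised by the decision analysis).
* **Calibration plot data** — observed event fraction against mean
  predicted probability across ten quantile groups, plus a lowess smooth.

With multiply imputed validation data every metric is computed per imputed
dataset and pooled as median with IQR; comparison tests are pooled by the
median P-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_auc_score
from statsmodels.nonparametric.smoothers_lowess import lowess

from .risk_models import logit as _logit
from .updating import NonConvergenceError, _ml_logit

__all__ = [
    "auroc",
    "compare_auroc",
    "calibration_slope",
    "compare_calibration_slope",
    "sens_spec",
    "CalibrationPlotData",
    "calibration_plot_data",
    "pool_metric",
]


def _check_two_classes(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).astype(float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("outcomes must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    return y


def auroc(p, y) -> float:
    """Mann-Whitney concordance: P(case ranked above non-case), ties = 1/2."""
    y = _check_two_classes(y)
    return float(roc_auc_score(y, np.asarray(p, dtype=float)))


def _delong_components(p: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUROCC plus the per-case and per-control placement values."""
    cases = p[y == 1]
    controls = p[y == 0]
    m, n = cases.size, controls.size
    all_ranks = rankdata(np.concatenate([cases, controls]))
    case_ranks = rankdata(cases)
    control_ranks = rankdata(controls)
    v10 = (all_ranks[:m] - case_ranks) / n           # per-case placements
    v01 = 1.0 - (all_ranks[m:] - control_ranks) / m  # per-control placements
    theta = v10.mean()
    return theta, v10, v01


def compare_auroc(p_a, p_b, y) -> float:
    """DeLong's two-sided test for two correlated AUROCCs on the same patients.

    Returns 1.0 when the predictions are identical (the variance of the
    difference degenerates to zero).
    """
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    y = _check_two_classes(y)
    if p_a.shape != p_b.shape or p_a.shape != y.shape:
        raise ValueError("prediction vectors and outcomes must have equal length")
    th_a, v10_a, v01_a = _delong_components(p_a, y)
    th_b, v10_b, v01_b = _delong_components(p_b, y)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]))
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 0 or not np.isfinite(var):
        return 1.0
    z = (th_a - th_b) / np.sqrt(var)
    return float(2 * norm.sf(abs(z)))


def calibration_slope(lp, y) -> float:
    """Slope of logistic regression of the outcome on the linear predictor."""
    lp = np.asarray(lp, dtype=float)
    y = _check_two_classes(y)
    if np.any(~np.isfinite(lp)):
        raise ValueError("linear predictor must be finite")
    res = _ml_logit(y, np.column_stack([np.ones(lp.size), lp]),
                    context="calibration slope")
    return float(res.params[1])


def _newton_slopes(y: np.ndarray, lp: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Vectorised Newton fits of (intercept, slope) over bootstrap index rows.

    ``idx`` is (B, n); returns B slopes.  Used only inside the paired
    bootstrap where statsmodels-per-resample would dominate the runtime; the
    single-fit path stays on statsmodels and the two are cross-checked in
    the test-suite.
    """
    yb = y[idx]
    xb = lp[idx]
    B, n = idx.shape
    a = np.zeros(B)
    b = np.ones(B)
    for _ in range(25):
        eta = np.clip(a[:, None] + b[:, None] * xb, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        r = yb - mu
        g0 = r.sum(axis=1)
        g1 = (r * xb).sum(axis=1)
        h00 = w.sum(axis=1)
        h01 = (w * xb).sum(axis=1)
        h11 = (w * xb * xb).sum(axis=1)
        det = h00 * h11 - h01 * h01
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        da = (h11 * g0 - h01 * g1) / det
        db = (h00 * g1 - h01 * g0) / det
        a += da
        b += db
        if max(np.abs(da).max(), np.abs(db).max()) < 1e-10:
            break
    return b


def compare_calibration_slope(lp_a, lp_b, y, n_boot: int = 1000, seed: int = 0) -> float:
    """Paired bootstrap two-sided test of a calibration-slope difference.

    Patients are resampled with replacement; both slopes are refitted on each
    resample and the two-sided P-value is read off the bootstrap distribution
    of the difference (twice the smaller tail fraction at zero).
    """
    lp_a = np.asarray(lp_a, dtype=float)
    lp_b = np.asarray(lp_b, dtype=float)
    y = _check_two_classes(y)
    if lp_a.shape != lp_b.shape or lp_a.shape != y.shape:
        raise ValueError("linear predictors and outcomes must have equal length")
    if np.array_equal(lp_a, lp_b):
        return 1.0
    rng = np.random.default_rng(seed)
    n = y.size
    idx = rng.integers(0, n, size=(n_boot, n))
    # guard against single-class resamples (rare unless events are very few)
    ok = (y[idx].sum(axis=1) > 0) & (y[idx].sum(axis=1) < n)
    idx = idx[ok]
    if idx.shape[0] == 0:
        raise NonConvergenceError("all bootstrap resamples were single-class")
    delta = _newton_slopes(y, lp_a, idx) - _newton_slopes(y, lp_b, idx)
    lo = float(np.mean(delta <= 0))
    hi = float(np.mean(delta >= 0))
    return float(min(1.0, 2 * min(lo, hi)))


def sens_spec(p, y, threshold: float = 0.05) -> tuple[float, float]:
    """Sensitivity and specificity classifying positive when p >= threshold."""
    p = np.asarray(p, dtype=float)
    y = _check_two_classes(y)
    pos = p >= threshold
    tp = np.sum(pos & (y == 1))
    fn = np.sum(~pos & (y == 1))
    tn = np.sum(~pos & (y == 0))
    fp = np.sum(pos & (y == 0))
    return float(tp / (tp + fn)), float(tn / (tn + fp))


@dataclass(frozen=True)
class CalibrationPlotData:
    """Numbers behind a calibration plot: decile table, smooth, slope line."""

    mean_predicted: tuple[float, ...]
    observed_fraction: tuple[float, ...]
    group_sizes: tuple[int, ...]
    smooth_x: tuple[float, ...]
    smooth_y: tuple[float, ...]
    slope: float
    slope_intercept: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_predicted": self.mean_predicted,
                "observed_fraction": self.observed_fraction,
                "n": self.group_sizes,
            }
        )


def calibration_plot_data(p, y, n_groups: int = 10, smooth_frac: float = 0.75
                          ) -> CalibrationPlotData:
    """Observed vs predicted risk across quantile groups of predicted risk.

    Patients are sorted by predicted probability (stable, so ties keep input
    order) and split into ``n_groups`` groups whose sizes differ by at most
    one; each group contributes its mean prediction and observed event
    fraction.  A lowess smooth of outcome on prediction and the
    calibration-slope line are included for plotting.
    """
    p = np.asarray(p, dtype=float)
    y = _check_two_classes(y)
    if p.size < n_groups:
        raise ValueError(f"need at least {n_groups} patients for {n_groups} groups")
    order = np.argsort(p, kind="stable")
    groups = np.array_split(order, n_groups)
    mean_pred = tuple(float(p[g].mean()) for g in groups)
    obs = tuple(float(y[g].mean()) for g in groups)
    sizes = tuple(int(g.size) for g in groups)

    # delta: skip near-duplicate abscissae (linear interpolation inside
    # 1% of the range) — standard lowess speedup, visually identical
    smooth = lowess(y, p, frac=smooth_frac, return_sorted=True,
                    delta=0.01 * (p.max() - p.min()))
    # thin to a manageable, strictly plotting-oriented set of points
    keep = np.unique(np.linspace(0, smooth.shape[0] - 1, min(200, smooth.shape[0])).astype(int))
    eps = 1e-12
    lp = _logit(np.clip(p, eps, 1 - eps))
    res = _ml_logit(y, np.column_stack([np.ones(p.size), lp]), context="calibration line")
    return CalibrationPlotData(
        mean_predicted=mean_pred,
        observed_fraction=obs,
        group_sizes=sizes,
        smooth_x=tuple(float(v) for v in smooth[keep, 0]),
        smooth_y=tuple(float(v) for v in smooth[keep, 1]),
        slope=float(res.params[1]),
        slope_intercept=float(res.params[0]),
    )


def pool_metric(values) -> tuple[float, tuple[float, float]]:
    """Median and (25th, 75th) percentile range across imputed datasets."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("no values to pool")
    return float(np.median(v)), tuple(float(x) for x in np.percentile(v, [25, 75]))
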