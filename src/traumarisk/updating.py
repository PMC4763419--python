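"""Model updating: re-estimation fits and the bootstrap linear shrinkage factor.

Updating step of the analysis: each candidate model's original parameters are
re-estimated by maximum-likelihood logistic regression on the local updating
sample (re-estimation updating — the functional form is kept, the
coefficients are refitted).  Because a model refitted on a finite sample is
optimistic, a *linear shrinkage factor* is estimated by bootstrap:

1. refit the model on each of ``n_bootstrap`` resamples drawn with
   replacement (same size as the original sample);
2. use each bootstrap model to compute a linear predictor on the ORIGINAL,
   not bootstrapped, sample;
3. regress the outcome on that linear predictor (logistic, with intercept)
   and collect the slope;
4. the shrinkage factor is the arithmetic mean of the collected slopes.

A slope below 1 means the refitted coefficients are too extreme; multiplying
the non-intercept coefficients by the factor and re-estimating the intercept
(so the mean predicted probability equals the observed event rate) yields the
shrunken model carried forward to validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.special import expit

from .risk_models import ModelSpec, design_matrix, linear_predictor
from .splines import compute_knots

__all__ = [
    "NonConvergenceError",
    "UpdateResult",
    "fit_logit",
    "freeze_spline_knots",
    "bootstrap_shrinkage",
    "apply_shrinkage",
]

logger = logging.getLogger(__name__)

#: Convergence contract for all maximum-likelihood fits.
MAX_ITER = 100
LL_TOL = 1e-8
#: |coefficient| beyond this is treated as (quasi-)separation, never returned.
SEPARATION_BOUND = 50.0


class NonConvergenceError(RuntimeError):
    """Maximum-likelihood fit failed (separation, single-class outcome, ...)."""


def _ml_logit(y: np.ndarray, X: np.ndarray, context: str = "") -> np.ndarray:
    """Newton ML fit with explicit failure on non-convergence or separation."""
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise NonConvergenceError(
            f"outcome has a single class{': ' + context if context else ''}"
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(
                method="newton", maxiter=MAX_ITER, tol=LL_TOL, disp=0
            )
    except Exception as exc:  # statsmodels raises on perfect separation
        raise NonConvergenceError(f"logistic fit failed ({context}): {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise NonConvergenceError(f"logistic fit did not converge ({context})")
    if np.max(np.abs(res.params)) > SEPARATION_BOUND:
        raise NonConvergenceError(
            f"coefficients diverged, likely separation ({context})"
        )
    return res


def freeze_spline_knots(model: ModelSpec, data: pd.DataFrame, n_knots: int = 4,
                        scheme: str = "equal") -> ModelSpec:
    """Compute percentile knots on ``data`` for every unfrozen spline term.

    Knots are computed once, on the model-development sample, and frozen into
    the returned spec; validation and charting must re-use them.
    """
    knots = {}
    for t in model.terms:
        if t.form == "spline" and t.knots is None:
            basis = compute_knots(
                data[t.variable].to_numpy(float), n_knots, scheme, variable=t.variable
            )
            knots[t.variable] = basis.knots
    return model.with_knots(knots) if knots else model


def fit_logit(
    data: pd.DataFrame, model: ModelSpec, outcome: str = "early_death"
) -> ModelSpec:
    """Maximum-likelihood re-estimation of ``model`` on a complete cohort.

    Spline terms without frozen knots get knots from ``data`` first.  Returns
    a new fitted spec (shrinkage factor reset to 1; apply shrinkage
    explicitly).  Raises :class:`NonConvergenceError` on a single-class
    outcome, separation, or failure to converge within the iteration budget.
    """
    model = freeze_spline_knots(model, data)
    X = design_matrix(model, data)
    Xc = np.column_stack([np.ones(len(X)), X])
    res = _ml_logit(data[outcome].to_numpy(float), Xc, context=f"model {model.name!r}")
    se = np.sqrt(np.diag(res.cov_params()))
    fitted = model.with_coefficients(
        res.params[0], res.params[1:], shrinkage_factor=1.0,
        provenance=f"re-estimated by ML on n={len(X)}",
    )
    # standard errors are attached for reporting, not part of the frozen spec
    object.__setattr__(fitted, "standard_errors", tuple(float(s) for s in se))
    return fitted


@dataclass(frozen=True)
class UpdateResult:
    """A re-estimated model plus its bootstrap shrinkage estimate."""

    model: ModelSpec
    shrinkage_factor: float
    bootstrap_slopes: tuple[float, ...]
    n_bootstrap: int
    seed: int
    n_redrawn: int = 0

    def __post_init__(self) -> None:
        assert len(self.bootstrap_slopes) == self.n_bootstrap
        mean = float(np.mean(self.bootstrap_slopes))
        if abs(mean - self.shrinkage_factor) > 1e-12:
            raise ValueError("shrinkage_factor must equal the mean bootstrap slope")


def _lp_slope(y: np.ndarray, lp: np.ndarray, context: str) -> float:
    """Slope of a logistic regression of the outcome on a linear predictor."""
    res = _ml_logit(y, np.column_stack([np.ones(len(lp)), lp]), context=context)
    return float(res.params[1])


def bootstrap_shrinkage(
    data: pd.DataFrame,
    model: ModelSpec,
    n_bootstrap: int = 300,
    seed: int = 0,
    outcome: str = "early_death",
    max_failure_fraction: float = 0.10,
) -> UpdateResult:
    """Re-estimate ``model`` on ``data`` and bootstrap its shrinkage factor.

    Deterministic in ``seed``.  Non-convergent resamples (e.g. separation in
    a small resample) are redrawn and counted; more than
    ``max_failure_fraction * n_bootstrap`` failures aborts with a diagnostic.
    """
    fitted = fit_logit(data, model, outcome)
    y = data[outcome].to_numpy(float)
    X = design_matrix(fitted, data)
    Xc = np.column_stack([np.ones(len(X)), X])
    n = len(X)
    rng = np.random.default_rng(seed)
    max_failures = int(np.ceil(max_failure_fraction * n_bootstrap))

    slopes: list[float] = []
    n_redrawn = 0
    while len(slopes) < n_bootstrap:
        idx = rng.integers(0, n, size=n)
        try:
            boot = _ml_logit(y[idx], Xc[idx], context=f"bootstrap of {model.name!r}")
            lp = Xc @ boot.params  # on the ORIGINAL sample
            slopes.append(_lp_slope(y, lp, context=f"slope for {model.name!r}"))
        except NonConvergenceError:
            n_redrawn += 1
            if n_redrawn > max_failures:
                raise NonConvergenceError(
                    f"{n_redrawn} of the first {len(slopes) + n_redrawn} bootstrap "
                    f"resamples failed to converge for model {model.name!r} "
                    f"(> {max_failure_fraction:.0%} of {n_bootstrap})"
                )
    if n_redrawn:
        logger.info(
            "bootstrap_shrinkage(%s): redrew %d non-convergent resamples",
            model.name, n_redrawn,
        )
    sf = float(np.mean(slopes))
    return UpdateResult(
        model=fitted,
        shrinkage_factor=sf,
        bootstrap_slopes=tuple(slopes),
        n_bootstrap=n_bootstrap,
        seed=seed,
        n_redrawn=n_redrawn,
    )


def apply_shrinkage(
    model: ModelSpec,
    factor: float,
    data: pd.DataFrame | None = None,
    literal: bool = False,
    outcome: str = "early_death",
) -> ModelSpec:
    """Multiply the model's slopes by ``factor`` and fix the intercept.

    Default behaviour multiplies the non-intercept coefficients by ``factor``
    and re-estimates the intercept on ``data`` so the mean predicted
    probability equals the observed event rate (uniform shrinkage with
    re-calibrated intercept; this is the maximum-likelihood intercept given
    the shrunken slopes as an offset).  ``literal=True`` instead multiplies
    every coefficient including the intercept and needs no data.
    """
    if factor <= 0:
        raise ValueError("shrinkage factor must be > 0")
    if not model.is_fitted:
        raise ValueError("cannot shrink an unfitted model")
    slopes = factor * np.asarray(model.coefficients)
    if literal:
        return model.with_coefficients(
            factor * model.intercept, slopes, shrinkage_factor=factor
        )
    if data is None:
        raise ValueError("intercept re-estimation requires the updating data")
    offset = design_matrix(model, data) @ slopes
    ybar = data[outcome].to_numpy(float).mean()
    if not 0 < ybar < 1:
        raise NonConvergenceError("single-class outcome; cannot recalibrate intercept")
    b0 = brentq(lambda a: expit(a + offset).mean() - ybar, -40, 40, xtol=1e-12)
    return model.with_coefficients(b0, slopes, shrinkage_factor=factor)
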