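"""Decision curve analysis: net benefit of model-guided triage.

Clinical scenario: several monitored trauma patients; the clinician may
repeat the survey on everyone (treat-all), on no one (treat-none), or use a
prediction model to choose whom to re-survey.  At a threshold probability
``p_t`` (the predicted risk at which re-survey is triggered) the *net
benefit* of a strategy is

.. math:: NB = TP/n - (FP/n) \\cdot p_t / (1 - p_t)

— true positives per patient, penalised by false positives weighted by the
odds of the threshold.  Treat-none has NB = 0 everywhere; treat-all has
``NB = prevalence - (1 - prevalence) * p_t / (1 - p_t)``, which crosses zero
exactly at ``p_t = prevalence``.  A useful model beats both baselines over
the clinically relevant threshold range.

The model-vs-treat-all gap can be restated as *unnecessary surveys avoided*:
``(NB_model - NB_all) * (1 - p_t) / p_t * 100`` per 100 patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "net_benefit",
    "net_benefit_treat_all",
    "DecisionCurve",
    "decision_curve",
    "net_reduction_per_100",
    "DEFAULT_THRESHOLDS",
]

#: Threshold-probability grid: 0.01 to 0.50 in steps of 0.01.
DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.01, 0.505, 0.01), 2))


def _check_threshold(p_t: float) -> None:
    if not 0 < p_t < 1:
        raise ValueError(f"threshold probability must lie in (0, 1), got {p_t}")


def net_benefit(p, y, p_t: float) -> float:
    """Net benefit of acting on ``p >= p_t`` (ties treated as positive)."""
    _check_threshold(p_t)
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    pos = p >= p_t
    tp = float(np.sum(pos & (y == 1)))
    fp = float(np.sum(pos & (y == 0)))
    return tp / n - (fp / n) * p_t / (1 - p_t)


def net_benefit_treat_all(prevalence: float, p_t: float) -> float:
    """Closed form for the survey-everyone strategy."""
    _check_threshold(p_t)
    return prevalence - (1 - prevalence) * p_t / (1 - p_t)


@dataclass(frozen=True)
class DecisionCurve:
    """Net benefit per threshold probability per strategy."""

    thresholds: tuple[float, ...]
    strategies: tuple[str, ...]  # model names + treat_all + treat_none
    net_benefits: tuple[tuple[float, ...], ...]  # [strategy][threshold]
    prevalence: float

    def as_frame(self) -> pd.DataFrame:
        """Long-format table: threshold × strategy → net benefit."""
        rows = [
            {"threshold": t, "strategy": s, "net_benefit": self.net_benefits[i][j]}
            for i, s in enumerate(self.strategies)
            for j, t in enumerate(self.thresholds)
        ]
        return pd.DataFrame(rows)

    def at(self, strategy: str, p_t: float) -> float:
        i = self.strategies.index(strategy)
        j = int(np.argmin(np.abs(np.asarray(self.thresholds) - p_t)))
        if abs(self.thresholds[j] - p_t) > 1e-9:
            raise KeyError(f"threshold {p_t} not on the curve grid")
        return self.net_benefits[i][j]


def decision_curve(
    predictions: dict[str, np.ndarray],
    y,
    thresholds=DEFAULT_THRESHOLDS,
) -> DecisionCurve:
    """Decision curves for named prediction vectors plus the two baselines.

    ``predictions`` maps strategy name → predicted probabilities on the same
    patients as ``y``.  An empty mapping yields a curve with only
    ``treat_all`` and ``treat_none``.
    """
    y = np.asarray(y, dtype=float)
    prevalence = float(y.mean())
    names = tuple(predictions) + ("treat_all", "treat_none")
    curves = []
    for name in predictions:
        p = np.asarray(predictions[name], dtype=float)
        if p.shape != y.shape:
            raise ValueError(f"predictions for {name!r} do not match the outcomes")
        curves.append(tuple(net_benefit(p, y, t) for t in thresholds))
    curves.append(tuple(net_benefit_treat_all(prevalence, t) for t in thresholds))
    curves.append(tuple(0.0 for _ in thresholds))
    return DecisionCurve(
        thresholds=tuple(float(t) for t in thresholds),
        strategies=names,
        net_benefits=tuple(curves),
        prevalence=prevalence,
    )


def net_reduction_per_100(nb_model: float, nb_all: float, p_t: float
                          ) -> tuple[float, int]:
    """Unnecessary surveys avoided per 100 patients by using the model.

    Returns the real value and its integer truncation.
    """
    _check_threshold(p_t)
    real = (nb_model - nb_all) * (1 - p_t) / p_t * 100
    return float(real), int(real)
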