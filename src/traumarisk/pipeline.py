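"""End-to-end study orchestration: temporal split, update, validate, report.

The study design is a two-step temporal validation.  Patients arriving
before a split date form the *updating sample*: spline knots are computed
and frozen there, every model is re-estimated there, and bootstrap shrinkage
factors are estimated and applied there.  Patients arriving after the split
form the *validation sample*, truncated at a fixed number of events (the
first ``event_cap`` deaths and all patients arriving up to the cap-th
death's arrival — a 200-event stopping rule sized to detect a 0.05 drop in
discrimination).  Each sample is multiply imputed per hospital; models never
see validation-period data before validation, which is asserted by
provenance on every model artefact.

Outputs of :func:`run_study`: serialised model files, a performance table
(AUROCC, calibration slope, sensitivity, specificity — median and IQR
across imputations — plus comparison P-values against the reference model),
a predicted-probability summary per model, a pooled decision-curve table,
calibration-plot tables, and a bedside chart, all as plain-text files plus a
JSON run log recording every design decision in force.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import imputation as imp
from .charting import build_chart, render_chart
from .decision_curves import DEFAULT_THRESHOLDS, decision_curve, net_reduction_per_100
from .performance import (
    auroc,
    calibration_plot_data,
    calibration_slope,
    compare_auroc,
    compare_calibration_slope,
    pool_metric,
    sens_spec,
)
from .risk_models import (
    BUILTIN_MODEL_NAMES,
    ModelSpec,
    builtin_model,
    design_matrix,
    linear_predictor,
    predict_probability,
    save_model,
)
from .updating import apply_shrinkage, bootstrap_shrinkage, freeze_spline_knots

__all__ = ["StudyDesign", "StudyReport", "temporal_split", "select_validation_sample",
           "run_study"]

logger = logging.getLogger(__name__)


class SplitError(ValueError):
    """A temporal split left one side empty."""


@dataclass(frozen=True)
class StudyDesign:
    """All knobs of one study run; the run log records these verbatim."""

    split_date: str = "2014-01-12"
    event_cap: int = 200
    model_roster: tuple[str, ...] = BUILTIN_MODEL_NAMES
    reference_model: str = "basic"
    seed: int = 0
    n_bootstrap: int = 300
    m: int | None = 10            # None -> worst-hospital percentage rule
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    classification_threshold: float = 0.05
    n_boot_compare: int = 200
    chart_cutoff: float = 0.05
    event_cap_granularity: str = "timestamp"  # or "day"

    def __post_init__(self) -> None:
        if self.event_cap < 1:
            raise ValueError("event_cap must be >= 1")
        if self.reference_model not in self.model_roster:
            raise ValueError("reference model must be in the roster")


def temporal_split(cohort: pd.DataFrame, split_date) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition by arrival time: strictly before the split date vs from it on."""
    t = pd.to_datetime(cohort["arrival_time"])
    if t.isna().any():
        raise ValueError("arrival_time must be present for every patient")
    cut = pd.Timestamp(split_date)
    updating = cohort[t < cut].reset_index(drop=True)
    validation = cohort[t >= cut].reset_index(drop=True)
    if len(updating) == 0:
        raise SplitError(f"no patients arrive before {cut:%Y-%m-%d}; updating sample empty")
    if len(validation) == 0:
        raise SplitError(f"no patients arrive on/after {cut:%Y-%m-%d}; validation sample empty")
    return updating, validation


def select_validation_sample(
    cohort: pd.DataFrame, event_cap: int = 200, granularity: str = "timestamp"
) -> pd.DataFrame:
    """First ``event_cap`` consecutive events and all patients up to that point.

    The cohort is sorted by arrival; every patient arriving up to (and
    including) the arrival of the cap-th death is kept.  With
    ``granularity="day"`` the cutoff extends to the end of that calendar
    day.  If fewer than ``event_cap`` events exist the full cohort is
    returned and the shortfall logged.
    """
    out = cohort.sort_values("arrival_time", kind="stable").reset_index(drop=True)
    deaths = out.index[out["early_death"].to_numpy(bool)]
    if len(deaths) < event_cap:
        logger.warning(
            "validation period has %d events, fewer than the %d-event cap; "
            "using all of them", len(deaths), event_cap,
        )
        return out
    cutoff = out.loc[deaths[event_cap - 1], "arrival_time"]
    if granularity == "day":
        cutoff = pd.Timestamp(cutoff).normalize() + pd.Timedelta(days=1) - pd.Timedelta(seconds=1)
    elif granularity != "timestamp":
        raise ValueError(f"unknown granularity {granularity!r}")
    return out[out["arrival_time"] <= cutoff].reset_index(drop=True)


def _impute_sample(cohort: pd.DataFrame, design: StudyDesign, which: str
                   ) -> tuple[list[pd.DataFrame], int]:
    fracs = imp.incomplete_fractions(cohort)
    m = design.m if design.m is not None else imp.choose_m(fracs)
    if m == 0 or not cohort[list(imp.MISSABLE_FIELDS)].isna().any().any():
        return [cohort], 0
    seed = [design.seed, {"updating": 11, "validation": 13}[which]]
    result = imp.impute(cohort, m=max(m, 2), seed=seed)
    return list(result.datasets), result.m


def _pooled_model(
    name: str,
    updating_sets: list[pd.DataFrame],
    knot_source: pd.DataFrame,
    design: StudyDesign,
) -> tuple[ModelSpec, dict]:
    """Fit + shrink one model across the imputed updating datasets.

    Coefficients and bootstrap shrinkage factors are estimated per imputed
    dataset and averaged; the averaged factor is applied to the averaged
    slopes with the intercept re-estimated on the stacked updating data.
    """
    structure = freeze_spline_knots(builtin_model(name), knot_source)
    coefs, intercepts, sfs = [], [], []
    for d, data in enumerate(updating_sets):
        res = bootstrap_shrinkage(
            data, structure, n_bootstrap=design.n_bootstrap,
            seed=[design.seed, 17, hash_name(name), d],
        )
        coefs.append(res.model.coefficients)
        intercepts.append(res.model.intercept)
        sfs.append(res.shrinkage_factor)
    pooled = structure.with_coefficients(
        float(np.mean(intercepts)), np.mean(np.asarray(coefs), axis=0),
        provenance=f"fitted on updating period only; pooled over "
                   f"{len(updating_sets)} imputed dataset(s)",
    )
    sf = float(np.mean(sfs))
    stacked = pd.concat(updating_sets, ignore_index=True)
    final = apply_shrinkage(pooled, sf, data=stacked)
    final = ModelSpec(
        name=final.name, terms=final.terms, intercept=final.intercept,
        coefficients=final.coefficients, shrinkage_factor=final.shrinkage_factor,
        provenance=pooled.provenance + f"; uniform shrinkage {sf:.4f} applied",
    )
    info = {"shrinkage_factor": sf, "per_dataset_sf": sfs}
    return final, info


def hash_name(name: str) -> int:
    """Deterministic small integer from a model name (Python's hash is salted)."""
    return sum((i + 1) * ord(c) for i, c in enumerate(name)) % 9973


@dataclass
class StudyReport:
    """Everything a study run produces, in memory."""

    design: StudyDesign
    models: dict[str, ModelSpec]
    shrinkage: dict[str, float]
    performance: pd.DataFrame
    predicted_probabilities: pd.DataFrame
    decision_curve_table: pd.DataFrame
    calibration: dict[str, pd.DataFrame]
    chart_grid: pd.DataFrame
    log: dict = field(default_factory=dict)


def run_study(cohort: pd.DataFrame, design: StudyDesign, out_dir=None) -> StudyReport:
    """Run the full two-step temporal validation study on a cohort.

    Deterministic given ``design.seed``.  If ``out_dir`` is given, all
    tables, model files, the chart (CSV + PNG) and the run log are written
    there.
    """
    updating_raw, validation_period = temporal_split(cohort, design.split_date)
    validation_raw = select_validation_sample(
        validation_period, design.event_cap, design.event_cap_granularity
    )

    updating_sets, m_upd = _impute_sample(updating_raw, design, "updating")
    validation_sets, m_val = _impute_sample(validation_raw, design, "validation")

    # knots are frozen from the observed (non-missing) updating values only
    knot_source = updating_raw.dropna(subset=["sbp", "hr", "gcs"])

    models: dict[str, ModelSpec] = {}
    shrinkage: dict[str, float] = {}
    for name in design.model_roster:
        final, info = _pooled_model(name, updating_sets, knot_source, design)
        models[name] = final
        shrinkage[name] = info["shrinkage_factor"]
        logger.info("model %s: shrinkage factor %.4f", name, info["shrinkage_factor"])

    # ---- validation ----
    y_sets = [d["early_death"].to_numpy(float) for d in validation_sets]
    lp_sets = {
        name: [np.asarray(linear_predictor(models[name], d)) for d in validation_sets]
        for name in models
    }
    p_sets = {name: [predict_probability(lp) for lp in lp_sets[name]]
              for name in models}

    ref = design.reference_model
    perf_rows = []
    prob_rows = []
    calibration: dict[str, pd.DataFrame] = {}
    for name in models:
        aurocs = [auroc(p, y) for p, y in zip(p_sets[name], y_sets)]
        slopes = [calibration_slope(lp, y) for lp, y in zip(lp_sets[name], y_sets)]
        ss = [
            sens_spec(p, y, design.classification_threshold)
            for p, y in zip(p_sets[name], y_sets)
        ]
        row = {"model": name, "shrinkage_factor": shrinkage[name]}
        for key, vals in (
            ("auroc", aurocs),
            ("calibration_slope", slopes),
            ("sensitivity", [s for s, _ in ss]),
            ("specificity", [s for _, s in ss]),
        ):
            med, (q1, q3) = pool_metric(vals)
            row[key] = med
            row[f"{key}_q1"] = q1
            row[f"{key}_q3"] = q3
        if name != ref:
            p_auc = [
                compare_auroc(p_sets[ref][d], p_sets[name][d], y_sets[d])
                for d in range(len(y_sets))
            ]
            p_cs = [
                compare_calibration_slope(
                    lp_sets[ref][d], lp_sets[name][d], y_sets[d],
                    n_boot=design.n_boot_compare, seed=[design.seed, 29, d],
                )
                for d in range(len(y_sets))
            ]
            for key, vals in (("p_auroc_vs_ref", p_auc), ("p_cs_vs_ref", p_cs)):
                med, (q1, q3), sig = imp.pool_pvalues(vals)
                row[key] = med
                row[f"{key}_q1"] = q1
                row[f"{key}_q3"] = q3
                row[f"{key}_significant"] = sig
        perf_rows.append(row)

        med_p, (p_q1, p_q3) = pool_metric([np.median(p) for p in p_sets[name]])
        q1s, _ = pool_metric([np.percentile(p, 25) for p in p_sets[name]])
        q3s, _ = pool_metric([np.percentile(p, 75) for p in p_sets[name]])
        prob_rows.append(
            {"model": name, "median_p": med_p, "p_q1": q1s, "p_q3": q3s}
        )

        # calibration plot data, pooled over imputations by stacking
        p_all = np.concatenate(p_sets[name])
        y_all = np.concatenate(y_sets)
        calibration[name] = calibration_plot_data(p_all, y_all).as_frame()

    performance = pd.DataFrame(perf_rows)
    predicted = pd.DataFrame(prob_rows)

    # ---- decision curves, pooled by median across imputed datasets ----
    curves = []
    for d in range(len(y_sets)):
        dc = decision_curve(
            {name: p_sets[name][d] for name in models}, y_sets[d], design.thresholds
        )
        curves.append(dc.as_frame().assign(imputation=d + 1))
    dc_all = pd.concat(curves, ignore_index=True)
    dc_table = (
        dc_all.groupby(["threshold", "strategy"], as_index=False)["net_benefit"]
        .median()
        .sort_values(["strategy", "threshold"], kind="stable")
        .reset_index(drop=True)
    )

    # ---- bedside chart from the reference (two-predictor) model ----
    chart = build_chart(models[ref], cutoff=design.chart_cutoff)
    chart_frame = render_chart(chart)

    nb_model = float(
        dc_table.query("strategy == @ref and abs(threshold - 0.05) < 1e-9")["net_benefit"].iloc[0]
    )
    nb_all = float(
        dc_table.query("strategy == 'treat_all' and abs(threshold - 0.05) < 1e-9")["net_benefit"].iloc[0]
    )
    reduction_real, reduction_int = net_reduction_per_100(nb_model, nb_all, 0.05)

    log = {
        "design": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(design).items()},
        "n_updating": int(len(updating_raw)),
        "n_validation": int(len(validation_raw)),
        "events_updating": int(updating_raw["early_death"].sum()),
        "events_validation": int(validation_raw["early_death"].sum()),
        "m_updating": m_upd,
        "m_validation": m_val,
        "event_rate_validation": float(validation_raw["early_death"].mean()),
        "shrinkage_factors": shrinkage,
        "net_benefit_ref_at_0.05": nb_model,
        "net_benefit_treat_all_at_0.05": nb_all,
        "net_reduction_per_100_at_0.05": {"real": reduction_real, "int": reduction_int},
        "knot_policy": "computed on observed updating-period values, frozen",
        "shrinkage_policy": "per imputed dataset, averaged; intercept re-estimated",
    }

    report = StudyReport(
        design=design,
        models=models,
        shrinkage=shrinkage,
        performance=performance,
        predicted_probabilities=predicted,
        decision_curve_table=dc_table,
        calibration=calibration,
        chart_grid=chart_frame,
        log=log,
    )
    if out_dir is not None:
        _write_report(report, chart, out_dir)
    return report


def _write_report(report: StudyReport, chart, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    (out / "models").mkdir(parents=True, exist_ok=True)
    for name, model in report.models.items():
        save_model(model, out / "models" / f"{name}.yaml")
    report.performance.to_csv(out / "performance.csv", index=False)
    report.predicted_probabilities.to_csv(out / "predicted_probabilities.csv", index=False)
    report.decision_curve_table.to_csv(out / "decision_curve.csv", index=False)
    for name, frame in report.calibration.items():
        frame.to_csv(out / f"calibration_{name}.csv", index=False)
    render_chart(chart, image_path=out / "chart.png", grid_path=out / "chart.csv")
    with open(out / "run_log.json", "w") as fh:
        json.dump(report.log, fh, indent=2)
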