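"""Synthetic multi-hospital trauma cohorts.

Real registry data on adult trauma admissions are not publicly deposited, so
every downstream stage of this package (imputation, model updating, temporal
validation, decision curves, charting) is exercised on synthetic cohorts that
emulate the published sample characteristics of a three-hospital urban Indian
trauma registry: the marginal medians/IQRs of age, systolic blood pressure
(SBP), heart rate (HR), Glasgow coma scale (GCS) and pre-admission delay, the
proportions male / transferred / by injury mechanism, the per-variable
missingness fractions, and a ~6-7 % 24-hour mortality.

Marginal families (documented design choices — only medians and IQRs are
published, not families):

* Continuous vitals, age and delay are drawn from *two-piece log-normal*
  distributions: ``x = med * exp(sigma_lo * z)`` for ``z < 0`` and
  ``med * exp(sigma_hi * z)`` otherwise, with ``z`` standard normal and the
  two sigmas chosen so the 25th/75th percentiles match the published
  quartiles exactly.  This reproduces median and IQR by construction and
  gives realistic right skew (e.g. for delay).
* GCS is a two-component mixture: a point mass at 15 (mildly injured
  majority) plus a discrete low-GCS tail, with weights reproducing the
  published median 15 and IQR 9-15.
* SBP, HR and GCS are correlated through a Gaussian copula (the two-piece
  log-normal is a monotone map of its latent normal, so the copula is exact).

The 24-hour mortality outcome is drawn from a logistic model in splined SBP
and linear GCS with *known* coefficients shipped in
``data/generating_model.yaml`` — the generating truth every recovery and
calibration test checks against.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .risk_models import ModelSpec, TermDef, linear_predictor

__all__ = [
    "CohortSpec",
    "ConfigurationError",
    "default_spec",
    "generating_truth_model",
    "generate_cohort",
    "impose_missingness",
    "write_cohort",
    "read_cohort",
    "COHORT_COLUMNS",
    "MISSABLE_FIELDS",
]

#: Canonical column order of a cohort frame.
COHORT_COLUMNS = [
    "hospital_id",
    "arrival_time",
    "age",
    "male",
    "mechanism",
    "delay_h",
    "transferred",
    "sbp",
    "hr",
    "gcs",
    "early_death",
]

#: Only these vitals may be masked; demographics and the outcome are always
#: observed (their published missingness is 0 %).
MISSABLE_FIELDS = ("sbp", "hr", "gcs", "delay_h")

MECHANISMS = ("fall", "railway", "road_traffic", "assault", "burn", "other")

_Z75 = norm.ppf(0.75)


class ConfigurationError(ValueError):
    """Invalid cohort specification (negative n, rates out of range, ...)."""


@dataclass(frozen=True)
class TwoPieceLogNormal:
    """Right-skewed continuous marginal pinned to a median and quartiles."""

    median: float
    q1: float
    q3: float

    def from_normal(self, z: np.ndarray) -> np.ndarray:
        sigma_lo = np.log(self.median / self.q1) / _Z75
        sigma_hi = np.log(self.q3 / self.median) / _Z75
        return self.median * np.exp(np.where(z < 0, sigma_lo, sigma_hi) * z)


#: Discrete GCS tail distribution over 3..14 (conditional on GCS < 15),
#: bimodal-ish with mass at deep coma and near-normal values; combined with
#: the point mass at 15 it reproduces median 15 and IQR 9-15.
_GCS_TAIL_VALUES = np.arange(3, 15)
_GCS_TAIL_WEIGHTS = np.array(
    [0.06, 0.03, 0.03, 0.04, 0.04, 0.05, 0.03, 0.03, 0.03, 0.03, 0.04, 0.04]
)


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one synthetic cohort, seed included."""

    n_per_hospital: dict[str, int]
    seed: int
    arrival_start: str = "2013-10-01"
    arrival_end: str = "2014-07-23"
    # marginal targets: median, q1, q3
    age: tuple[float, float, float] = (35, 25, 46)
    sbp: tuple[float, float, float] = (120, 110, 130)
    hr: tuple[float, float, float] = (89, 80, 98)
    delay_h: tuple[float, float, float] = (7, 2, 26)
    p_male: float = 0.80
    p_transferred: float = 0.71
    p_gcs15: float = 0.55
    mechanism_probs: dict[str, float] = field(
        default_factory=lambda: {
            "fall": 0.26,
            "railway": 0.06,
            "road_traffic": 0.46,
            "assault": 0.11,
            "burn": 0.07,
            "other": 0.04,
        }
    )
    # hypotensive ("shock") mixture component of the SBP marginal: a small
    # fraction of patients whose SBP is drawn low, giving the realistic
    # hypotensive tail a pure median/IQR emulation lacks (and populating the
    # SBP < 60 band used by banded external models)
    p_shock: float = 0.05
    shock_mean: float = 72.0
    shock_sd: float = 14.0
    # latent-normal (copula) correlations among the vitals
    corr_sbp_hr: float = -0.20
    corr_sbp_gcs: float = 0.30
    corr_hr_gcs: float = -0.10
    # true outcome model: logistic in splined SBP + linear GCS
    event_model: ModelSpec | None = None

    def __post_init__(self) -> None:
        if not self.n_per_hospital or any(n < 1 for n in self.n_per_hospital.values()):
            raise ConfigurationError("n_per_hospital must be positive counts")
        for p in (self.p_male, self.p_transferred, self.p_gcs15):
            if not 0 <= p <= 1:
                raise ConfigurationError(f"proportion {p} outside [0, 1]")
        if abs(sum(self.mechanism_probs.values()) - 1) > 1e-9:
            raise ConfigurationError("mechanism probabilities must sum to 1")
        if set(self.mechanism_probs) != set(MECHANISMS):
            raise ConfigurationError(f"mechanisms must be exactly {MECHANISMS}")

    @property
    def n_total(self) -> int:
        return sum(self.n_per_hospital.values())


def _load_generating_config() -> dict:
    ref = importlib.resources.files("traumarisk.data") / "generating_model.yaml"
    return yaml.safe_load(ref.read_text())


def generating_truth_model() -> ModelSpec:
    """The data-generating outcome model shipped with the package.

    A logistic model in a 4-knot restricted cubic spline of SBP plus linear
    GCS, with fixed coefficients chosen so the synthetic 24-h mortality is
    about 6-7 %.  Because the generator draws outcomes from exactly this
    model, it is the "oracle" model against which parameter recovery,
    calibration-slope and decision-curve optimality tests are run.
    """
    cfg = _load_generating_config()["event_model"]
    spec = ModelSpec(
        name="generating_truth",
        terms=(
            TermDef("sbp", "spline", knots=tuple(cfg["sbp_knots"])),
            TermDef("gcs", "linear"),
        ),
        provenance="synthetic data-generating model shipped with the package",
    )
    coefs = list(cfg["sbp_coefficients"]) + [cfg["gcs_coefficient"]]
    return spec.with_coefficients(cfg["intercept"], coefs)


def default_spec(
    sample: str = "full", seed: int = 0, event_model: ModelSpec | None = None
) -> CohortSpec:
    """Cohort spec mirroring the published sample characteristics.

    ``sample`` selects the emulated period: ``updating`` (n=1629, Oct 2013 -
    Jan 11 2014), ``validation`` (n=2811, Jan 12 - Jul 23 2014) or ``full``
    (both periods, n=4440).  Hospital shares default to 40/30/30 %.
    """
    cfg = _load_generating_config()
    try:
        s = cfg["samples"][sample]
    except KeyError:
        raise ConfigurationError(f"unknown sample {sample!r}") from None
    n = s["n_total"]
    shares = cfg["hospital_shares"]
    n_per = {h: int(round(n * w)) for h, w in shares.items()}
    # keep the exact total despite rounding
    first = next(iter(n_per))
    n_per[first] += n - sum(n_per.values())
    return CohortSpec(
        n_per_hospital=n_per,
        seed=seed,
        arrival_start=s["arrival_start"],
        arrival_end=s["arrival_end"],
        age=tuple(s["age"]),
        sbp=tuple(s["sbp"]),
        hr=tuple(s["hr"]),
        delay_h=tuple(s["delay_h"]),
        p_male=s["p_male"],
        p_transferred=s["p_transferred"],
        mechanism_probs=dict(s["mechanism_probs"]),
        event_model=event_model or generating_truth_model(),
    )


def _copula_matrix(spec: CohortSpec) -> np.ndarray:
    c = np.array(
        [
            [1.0, spec.corr_sbp_hr, spec.corr_sbp_gcs],
            [spec.corr_sbp_hr, 1.0, spec.corr_hr_gcs],
            [spec.corr_sbp_gcs, spec.corr_hr_gcs, 1.0],
        ]
    )
    if np.min(np.linalg.eigvalsh(c)) <= 0:
        raise ConfigurationError("vital-sign correlation matrix is not positive definite")
    return c


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one complete cohort (no missing values) from ``spec``.

    Deterministic: the same spec and seed give a byte-identical frame.
    """
    rng = np.random.default_rng(spec.seed)
    model = spec.event_model or generating_truth_model()

    frames = []
    for hospital, n in spec.n_per_hospital.items():
        z = rng.multivariate_normal(np.zeros(3), _copula_matrix(spec), size=n)
        sbp = TwoPieceLogNormal(*spec.sbp).from_normal(z[:, 0])
        # hypotensive tail: a small shock fraction keeps the same latent
        # normal (so low SBP goes with low GCS) but is centred far lower
        shock = rng.random(n) < spec.p_shock
        sbp = np.where(shock, spec.shock_mean + spec.shock_sd * z[:, 0], sbp)
        hr = TwoPieceLogNormal(*spec.hr).from_normal(z[:, 1])
        # GCS through the copula: low latent normal -> low GCS
        u = norm.cdf(z[:, 2])
        tail_cdf = np.cumsum(_GCS_TAIL_WEIGHTS) / _GCS_TAIL_WEIGHTS.sum()
        p_tail = 1.0 - spec.p_gcs15
        gcs = np.where(
            u >= p_tail,
            15,
            _GCS_TAIL_VALUES[np.searchsorted(tail_cdf, np.minimum(u / p_tail, 1.0 - 1e-12))],
        ).astype(float)

        age = np.clip(np.round(TwoPieceLogNormal(*spec.age).from_normal(rng.standard_normal(n))), 15, None)
        delay = TwoPieceLogNormal(*spec.delay_h).from_normal(rng.standard_normal(n))
        male = rng.random(n) < spec.p_male
        transferred = rng.random(n) < spec.p_transferred
        mech = rng.choice(
            list(spec.mechanism_probs), p=list(spec.mechanism_probs.values()), size=n
        )
        start = pd.Timestamp(spec.arrival_start)
        end = pd.Timestamp(spec.arrival_end) + pd.Timedelta(days=1)
        seconds = rng.integers(0, int((end - start).total_seconds()), size=n)
        arrival = start + pd.to_timedelta(seconds, unit="s")

        frame = pd.DataFrame(
            {
                "hospital_id": hospital,
                "arrival_time": arrival,
                "age": age,
                "male": male,
                "mechanism": mech,
                "delay_h": np.round(delay, 2),
                "transferred": transferred,
                "sbp": np.round(np.clip(sbp, 0, 300), 1),
                "hr": np.round(np.clip(hr, 0, 250), 1),
                "gcs": gcs,
            }
        )
        lp = linear_predictor(model, frame)
        frame["early_death"] = rng.random(n) < expit(lp)
        frames.append(frame)

    cohort = pd.concat(frames, ignore_index=True)
    return cohort[COHORT_COLUMNS]


def _mar_weights(cohort: pd.DataFrame) -> np.ndarray:
    """Log-odds offsets for MAR missingness, from always-observed fields only."""
    hospitals = {h: i for i, h in enumerate(sorted(cohort["hospital_id"].unique()))}
    h_eff = cohort["hospital_id"].map(lambda h: (hospitals[h] - 1) * 0.5).to_numpy(float)
    t_eff = np.where(cohort["transferred"].to_numpy(bool), 0.6, 0.0)
    m_eff = np.where(cohort["mechanism"].to_numpy() == "road_traffic", 0.3, 0.0)
    return h_eff + t_eff + m_eff


def impose_missingness(
    cohort: pd.DataFrame,
    rates: dict[str, float],
    mechanism: str = "MCAR",
    seed: int = 0,
) -> pd.DataFrame:
    """Mask vitals at the requested per-variable rates; values are never altered.

    ``mechanism`` is ``MCAR`` (uniform) or ``MAR`` (missingness probability a
    logistic function of always-observed fields: hospital, transfer status,
    injury mechanism — calibrated so the expected overall fraction equals the
    requested rate).  The outcome and demographics cannot be masked.
    """
    if mechanism not in ("MCAR", "MAR"):
        raise ConfigurationError(f"unknown missingness mechanism {mechanism!r}")
    out = cohort.copy()
    rng = np.random.default_rng(seed)
    offsets = _mar_weights(cohort) if mechanism == "MAR" else None
    for var, rate in rates.items():
        if var not in MISSABLE_FIELDS:
            raise ConfigurationError(
                f"field {var!r} is always observed and cannot be masked "
                f"(missable fields: {MISSABLE_FIELDS})"
            )
        if not 0 <= rate < 1:
            raise ConfigurationError(f"missingness rate for {var!r} outside [0, 1)")
        if rate == 0:
            continue
        if mechanism == "MCAR":
            mask = rng.random(len(out)) < rate
        else:
            alpha = brentq(
                lambda a: expit(a + offsets).mean() - rate, -30, 30, xtol=1e-12
            )
            mask = rng.random(len(out)) < expit(alpha + offsets)
        out.loc[mask, var] = np.nan
    return out


# ---------------------------------------------------------------------------
# Delimited-text I/O (RFC-4180 CSV, header row, ISO-8601 timestamps,
# empty field = missing)
# ---------------------------------------------------------------------------

def write_cohort(cohort: pd.DataFrame, path) -> None:
    out = cohort.copy()
    out["arrival_time"] = pd.to_datetime(out["arrival_time"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    out.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["arrival_time"])
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file lacks required columns: {missing}")
    for b in ("male", "transferred", "early_death"):
        df[b] = df[b].astype(bool)
    return df[COHORT_COLUMNS]
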