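"""Declarative risk-model registry and probability prediction.

Six bedside models for early (24-hour) trauma mortality are compared in this
package:

``basic``
    SBP through a 4-knot restricted cubic spline + linear GCS.
``basic_hr``
    The basic model plus heart rate, also splined.
``kondo``
    Linear GCS, an indicator for age < 60 years, and SBP in three bands
    (< 60 reference, 60–120 inclusive, > 120).  Ships with published
    coefficients.
``perel``
    Cubic polynomials in age and SBP and a quadratic in GCS (the re-estimated
    form without the tranexamic-acid term or random intercept).  Ships with
    published coefficients.
``sbp_only`` / ``gcs_only``
    Single-predictor models (splined SBP; linear GCS).

A model is a :class:`ModelSpec`: an ordered list of :class:`TermDef` (each
expanding a raw variable into one or more design columns), a coefficient per
column plus an intercept, and a multiplicative shrinkage factor.  Models with
spline terms carry frozen knots, so a fitted model is a fully portable
artefact; it round-trips through a versioned YAML model file.

The published coefficients for ``basic``, ``basic_hr`` and the two
single-predictor models cannot be executed directly because their spline
knots were never published; those structures must be (re)fitted on data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.special import expit, logit as _logit

from .splines import SplineBasis, rcs_basis

__all__ = [
    "TermDef",
    "ModelSpec",
    "MissingCovariateError",
    "UnfittedModelError",
    "builtin_model",
    "BUILTIN_MODEL_NAMES",
    "design_matrix",
    "linear_predictor",
    "predict_probability",
    "logit",
    "save_model",
    "load_model",
]

MODEL_FILE_FORMAT_VERSION = 1


class MissingCovariateError(ValueError):
    """A required covariate is missing: prediction never silently imputes."""


class UnfittedModelError(ValueError):
    """The model structure has no coefficients (or no frozen knots) yet."""


@dataclass(frozen=True)
class TermDef:
    """One model term: how a raw variable enters the design matrix.

    form
        ``linear`` — one column, the raw value.
        ``spline`` — restricted cubic spline columns; ``knots`` must be
        frozen before the term can be evaluated.
        ``polynomial`` — columns x, x^2, ..., x^degree.
        ``indicator`` — one 0/1 column for ``x <op> threshold``.
        ``category_set`` — indicator columns for ordered bands defined by
        ``cutpoints``; the lowest band is the reference and contributes no
        column.  Band convention: x < c1 (reference), c1 <= x <= c2, then
        strictly above each further cutpoint.
    """

    variable: str
    form: str = "linear"
    knots: tuple[float, ...] | None = None
    degree: int = 1
    op: str = "<"
    threshold: float | None = None
    cutpoints: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.form not in ("linear", "spline", "polynomial", "indicator", "category_set"):
            raise ValueError(f"unknown term form {self.form!r}")
        if self.form == "category_set":
            cp = self.cutpoints or ()
            if len(cp) < 1 or any(b <= a for a, b in zip(cp, cp[1:])):
                raise ValueError("category_set needs ordered cutpoints")
        if self.form == "indicator" and self.threshold is None:
            raise ValueError("indicator term needs a threshold")

    def column_names(self) -> list[str]:
        v = self.variable
        if self.form == "linear":
            return [v]
        if self.form == "spline":
            k = len(self.knots) if self.knots else 4
            return [v] + [f"{v}:sbf{j}" for j in range(1, k - 1)]
        if self.form == "polynomial":
            return [v] + [f"{v}^{d}" for d in range(2, self.degree + 1)]
        if self.form == "indicator":
            return [f"{v}{self.op}{self.threshold:g}"]
        cp = self.cutpoints
        names = []
        for i in range(len(cp)):
            if i + 1 < len(cp):
                names.append(f"{v}:[{cp[i]:g},{cp[i + 1]:g}]")
            else:
                names.append(f"{v}:>{cp[i]:g}")
        return names

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Expand raw values into this term's design columns (n × n_cols)."""
        x = np.asarray(x, dtype=float)
        if self.form == "linear":
            return x[:, None]
        if self.form == "spline":
            if self.knots is None:
                raise UnfittedModelError(
                    f"spline term on {self.variable!r} has no frozen knots"
                )
            return rcs_basis(x, SplineBasis(self.knots, variable=self.variable))
        if self.form == "polynomial":
            return np.column_stack([x**d for d in range(1, self.degree + 1)])
        if self.form == "indicator":
            ops = {"<": np.less, "<=": np.less_equal, ">": np.greater, ">=": np.greater_equal}
            return ops[self.op](x, self.threshold).astype(float)[:, None]
        cp = self.cutpoints
        cols = []
        for i in range(len(cp)):
            if i + 1 < len(cp):
                cols.append((x >= cp[i]) & (x <= cp[i + 1]))
            else:
                cols.append(x > cp[i])
        return np.column_stack(cols).astype(float)


@dataclass(frozen=True)
class ModelSpec:
    """A named risk model: structure, coefficients and shrinkage factor."""

    name: str
    terms: tuple[TermDef, ...]
    intercept: float | None = None
    coefficients: tuple[float, ...] | None = None
    shrinkage_factor: float = 1.0
    provenance: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.shrinkage_factor <= 0:
            raise ValueError("shrinkage_factor must be > 0")
        if self.coefficients is not None:
            n_cols = len(self.column_names())
            if len(self.coefficients) != n_cols:
                raise ValueError(
                    f"model {self.name!r}: {len(self.coefficients)} coefficients "
                    f"for {n_cols} design columns"
                )
            if self.intercept is None:
                raise ValueError("coefficients given without an intercept")

    @property
    def is_fitted(self) -> bool:
        return self.coefficients is not None

    @property
    def variables(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.terms:
            seen.setdefault(t.variable, None)
        return tuple(seen)

    def column_names(self) -> list[str]:
        names: list[str] = []
        for t in self.terms:
            names.extend(t.column_names())
        return names

    def with_coefficients(
        self, intercept: float, coefficients, shrinkage_factor: float | None = None, **kw
    ) -> "ModelSpec":
        sf = self.shrinkage_factor if shrinkage_factor is None else shrinkage_factor
        return replace(
            self,
            intercept=float(intercept),
            coefficients=tuple(float(c) for c in coefficients),
            shrinkage_factor=sf,
            **kw,
        )

    def with_knots(self, knots_by_variable: dict[str, tuple[float, ...]]) -> "ModelSpec":
        """Freeze spline knots (computed on the development sample) into the terms."""
        terms = tuple(
            replace(t, knots=tuple(knots_by_variable[t.variable]))
            if t.form == "spline" and t.variable in knots_by_variable
            else t
            for t in self.terms
        )
        return replace(self, terms=terms)


# ---------------------------------------------------------------------------
# Built-in registry
# ---------------------------------------------------------------------------

#: Published coefficients (after shrinkage) for the two external models.
#: Order matches TermDef expansion order below.
_KONDO_COEFS = {
    "intercept": 1.919,
    "gcs": -0.254,
    "age<60": -0.225,
    "sbp:[60,120]": -2.067,
    "sbp:>120": -2.511,
}
_PEREL_COEFS = {
    "intercept": 3.678,
    "age": -0.067,
    "age^2": 0.002,
    "age^3": -1.3e-5,
    "sbp": 0.019,
    "sbp^2": -0.001,
    "sbp^3": 2.3e-6,
    "gcs": -0.679,
    "gcs^2": 0.024,
}

BUILTIN_MODEL_NAMES = ("basic", "basic_hr", "kondo", "perel", "sbp_only", "gcs_only")


def builtin_model(name: str) -> ModelSpec:
    """Return a built-in model structure by name.

    ``kondo`` and ``perel`` come with their published coefficients and can
    predict immediately; the published values are treated as fixtures to be
    re-estimated on local data before serious use.  ``basic``, ``basic_hr``,
    ``sbp_only`` and ``gcs_only`` are structure-only (their spline knots were
    never published) and must be fitted.
    """
    if name == "basic":
        return ModelSpec(
            name,
            terms=(TermDef("sbp", "spline"), TermDef("gcs", "linear")),
            provenance="structure only; splined SBP + linear GCS, fit before use",
        )
    if name == "basic_hr":
        return ModelSpec(
            name,
            terms=(
                TermDef("sbp", "spline"),
                TermDef("hr", "spline"),
                TermDef("gcs", "linear"),
            ),
            provenance="structure only; splined SBP and HR + linear GCS",
        )
    if name == "kondo":
        terms = (
            TermDef("gcs", "linear"),
            TermDef("age", "indicator", op="<", threshold=60),
            TermDef("sbp", "category_set", cutpoints=(60.0, 120.0)),
        )
        spec = ModelSpec(name, terms, provenance="published coefficients (fixture)")
        order = spec.column_names()
        return spec.with_coefficients(
            _KONDO_COEFS["intercept"], [_KONDO_COEFS[c] for c in order]
        )
    if name == "perel":
        terms = (
            TermDef("age", "polynomial", degree=3),
            TermDef("sbp", "polynomial", degree=3),
            TermDef("gcs", "polynomial", degree=2),
        )
        spec = ModelSpec(
            name,
            terms,
            provenance="published coefficients (fixture); re-estimated form "
            "without tranexamic-acid term or random intercept",
        )
        order = spec.column_names()
        return spec.with_coefficients(
            _PEREL_COEFS["intercept"], [_PEREL_COEFS[c] for c in order]
        )
    if name == "sbp_only":
        return ModelSpec(
            name,
            terms=(TermDef("sbp", "spline"),),
            provenance="structure only; splined SBP, fit before use",
        )
    if name == "gcs_only":
        return ModelSpec(
            name,
            terms=(TermDef("gcs", "linear"),),
            provenance="structure only; linear GCS, fit before use",
        )
    raise KeyError(f"unknown model {name!r}; built-ins are {BUILTIN_MODEL_NAMES}")


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def _extract_columns(model: ModelSpec, record) -> dict[str, np.ndarray]:
    """Pull the model's variables out of a record/dict/Series/DataFrame."""
    out: dict[str, np.ndarray] = {}
    for v in model.variables:
        try:
            col = record[v]
        except (KeyError, IndexError, TypeError) as exc:
            raise MissingCovariateError(
                f"model {model.name!r} requires variable {v!r}"
            ) from exc
        arr = np.atleast_1d(np.asarray(col, dtype=float))
        if np.any(~np.isfinite(arr)):
            raise MissingCovariateError(
                f"model {model.name!r}: variable {v!r} has missing values; "
                "predictions on incomplete records are not silently imputed"
            )
        out[v] = arr
    return out


def design_matrix(model: ModelSpec, data) -> np.ndarray:
    """Design matrix (without intercept column) for a cohort or single record."""
    cols = _extract_columns(model, data)
    n = max(a.size for a in cols.values()) if cols else 1
    blocks = [t.evaluate(np.broadcast_to(cols[t.variable], (n,))) for t in model.terms]
    return np.hstack(blocks)


def linear_predictor(model: ModelSpec, record) -> np.ndarray | float:
    """Linear predictor (log-odds): intercept + sum of coefficient × basis value.

    Uses the coefficients as stored; shrinkage is applied only by explicitly
    transforming the model (see :func:`traumarisk.updating.apply_shrinkage`),
    never implicitly here.
    """
    if not model.is_fitted:
        raise UnfittedModelError(f"model {model.name!r} has no coefficients")
    X = design_matrix(model, record)
    lp = model.intercept + X @ np.asarray(model.coefficients)
    scalar = np.isscalar(record.get(model.variables[0])) if hasattr(record, "get") else False
    return float(lp[0]) if (scalar and lp.size == 1) else lp


def predict_probability(lp) -> np.ndarray | float:
    """Inverse-logit: p = 1 / (1 + exp(-lp)); strictly increasing in lp."""
    lp = np.asarray(lp, dtype=float)
    if np.any(~np.isfinite(lp)):
        raise ValueError("linear predictor must be finite")
    p = expit(lp)
    return float(p) if p.ndim == 0 else p


def logit(p) -> np.ndarray | float:
    """log(p / (1 - p)), the inverse of :func:`predict_probability` on (0, 1)."""
    out = _logit(np.asarray(p, dtype=float))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Serialisation: versioned plain-text model files
# ---------------------------------------------------------------------------

def _term_to_dict(t: TermDef) -> dict:
    d: dict = {"variable": t.variable, "form": t.form}
    if t.form == "spline" and t.knots is not None:
        d["knots"] = [float(k) for k in t.knots]
    if t.form == "polynomial":
        d["degree"] = t.degree
    if t.form == "indicator":
        d["op"] = t.op
        d["threshold"] = float(t.threshold)
    if t.form == "category_set":
        d["cutpoints"] = [float(c) for c in t.cutpoints]
    return d


def _term_from_dict(d: dict) -> TermDef:
    return TermDef(
        variable=d["variable"],
        form=d["form"],
        knots=tuple(d["knots"]) if d.get("knots") is not None else None,
        degree=int(d.get("degree", 1)),
        op=d.get("op", "<"),
        threshold=d.get("threshold"),
        cutpoints=tuple(d["cutpoints"]) if d.get("cutpoints") is not None else None,
    )


def model_to_dict(model: ModelSpec) -> dict:
    d: dict = {
        "format_version": MODEL_FILE_FORMAT_VERSION,
        "name": model.name,
        "provenance": model.provenance,
        "shrinkage_factor": float(model.shrinkage_factor),
        "terms": [_term_to_dict(t) for t in model.terms],
    }
    if model.is_fitted:
        d["intercept"] = float(model.intercept)
        d["coefficients"] = {
            c: float(b) for c, b in zip(model.column_names(), model.coefficients)
        }
    return d


def model_from_dict(d: dict) -> ModelSpec:
    if d.get("format_version") != MODEL_FILE_FORMAT_VERSION:
        raise ValueError(f"unsupported model file version {d.get('format_version')!r}")
    spec = ModelSpec(
        name=d["name"],
        terms=tuple(_term_from_dict(t) for t in d["terms"]),
        provenance=d.get("provenance", ""),
        shrinkage_factor=float(d.get("shrinkage_factor", 1.0)),
    )
    if "coefficients" in d:
        order = spec.column_names()
        spec = spec.with_coefficients(
            d["intercept"], [d["coefficients"][c] for c in order]
        )
    return spec


def save_model(model: ModelSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_model(path) -> ModelSpec:
    if isinstance(path, io.IOBase):
        return model_from_dict(yaml.safe_load(path))
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))
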