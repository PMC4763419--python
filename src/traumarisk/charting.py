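"""Colour-coded bedside risk charts over an SBP × GCS grid.

A two-predictor model can be tabulated once and used at the bedside without
any calculation: rows are GCS values 3-15, columns are SBP bins, and each
cell holds the predicted probability of early mortality plus a triage colour
band.  The binary variant flags cells at or above a single cutoff (default
predicted probability 0.05) for a repeated survey.

The chart is strictly a cache of the model: every cell probability is
computed through the model's own linear predictor, never re-derived.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .risk_models import ModelSpec, linear_predictor, predict_probability

__all__ = ["RiskChart", "build_chart", "render_chart", "parse_chart_grid",
           "DEFAULT_SBP_BINS", "DEFAULT_BANDS"]

#: 10-mmHg SBP bins from 50 to 220.
DEFAULT_SBP_BINS = tuple(float(v) for v in range(50, 221, 10))
#: Probability band edges: < 0.05 green, 0.05-0.20 yellow, >= 0.20 red.
DEFAULT_BANDS = (0.05, 0.20)
_BAND_COLOURS = ("green", "yellow", "red", "darkred", "black")

GCS_AXIS = tuple(range(3, 16))


@dataclass(frozen=True)
class RiskChart:
    """Predicted probability and triage category per (SBP bin, GCS) cell."""

    sbp_edges: tuple[float, ...]       # bin edges, len = n_bins + 1
    gcs_axis: tuple[int, ...]
    probabilities: tuple[tuple[float, ...], ...]  # [gcs][sbp_bin]
    cutoff: float
    bands: tuple[float, ...]
    model_name: str = ""

    @property
    def sbp_midpoints(self) -> tuple[float, ...]:
        e = self.sbp_edges
        return tuple((a + b) / 2 for a, b in zip(e, e[1:]))

    def category(self, prob: float) -> str:
        """Colour band of a probability: a pure function of the band edges."""
        return _BAND_COLOURS[int(np.searchsorted(self.bands, prob, side="right"))]

    def flagged(self, prob: float) -> bool:
        """Binary triage: flag for repeated survey iff prob >= cutoff."""
        return prob >= self.cutoff


def build_chart(
    model: ModelSpec,
    sbp_bins: tuple[float, ...] = DEFAULT_SBP_BINS,
    cutoff: float = 0.05,
    bands: tuple[float, ...] = DEFAULT_BANDS,
) -> RiskChart:
    """Evaluate a two-covariate (SBP, GCS) model over the chart grid.

    Models needing any other covariate are rejected: the bedside chart is
    only defined for two-predictor models.
    """
    extra = set(model.variables) - {"sbp", "gcs"}
    if extra:
        raise ValueError(
            f"chart requires a model in SBP and GCS only; {model.name!r} also "
            f"needs {sorted(extra)}"
        )
    if len(sbp_bins) < 2 or any(b <= a for a, b in zip(sbp_bins, sbp_bins[1:])):
        raise ValueError("sbp_bins must be at least two increasing edges")
    mids = [(a + b) / 2 for a, b in zip(sbp_bins, sbp_bins[1:])]
    # cell-by-cell scalar evaluation: the chart must equal per-record
    # prediction bit-for-bit (it is a cache, not a reimplementation)
    rows = [
        tuple(
            predict_probability(linear_predictor(model, {"sbp": float(m), "gcs": float(g)}))
            for m in mids
        )
        for g in GCS_AXIS
    ]
    return RiskChart(
        sbp_edges=tuple(float(e) for e in sbp_bins),
        gcs_axis=GCS_AXIS,
        probabilities=tuple(rows),
        cutoff=cutoff,
        bands=tuple(bands),
        model_name=model.name,
    )


def chart_grid_frame(chart: RiskChart) -> pd.DataFrame:
    """Text-table form: rows = GCS, columns = SBP bins, cells = prob|category."""
    cols = [f"{a:g}-{b:g}" for a, b in zip(chart.sbp_edges, chart.sbp_edges[1:])]
    data = {
        "gcs": list(chart.gcs_axis),
    }
    for j, c in enumerate(cols):
        data[c] = [
            f"{chart.probabilities[i][j]:.6f}|{chart.category(chart.probabilities[i][j])}"
            for i in range(len(chart.gcs_axis))
        ]
    return pd.DataFrame(data)


def render_chart(chart: RiskChart, image_path=None, grid_path=None):
    """Write the chart as an image (PNG/SVG by extension) and/or a text grid.

    The text grid round-trips losslessly through :func:`parse_chart_grid`.
    Returns the grid frame.
    """
    frame = chart_grid_frame(chart)
    if grid_path is not None:
        frame.to_csv(grid_path, index=False)
    if image_path is not None:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        from matplotlib.colors import BoundaryNorm, ListedColormap

        probs = np.array(chart.probabilities)
        edges = [0.0, *chart.bands, 1.0]
        cmap = ListedColormap(_BAND_COLOURS[: len(edges) - 1])
        norm = BoundaryNorm(edges, cmap.N)
        fig, ax = plt.subplots(figsize=(9, 5))
        x = np.asarray(chart.sbp_edges)
        ybins = np.arange(chart.gcs_axis[0] - 0.5, chart.gcs_axis[-1] + 1.5)
        ax.pcolormesh(x, ybins, probs, cmap=cmap, norm=norm, edgecolors="white")
        for i, g in enumerate(chart.gcs_axis):
            for j in range(len(chart.sbp_midpoints)):
                ax.text(
                    chart.sbp_midpoints[j], g, f"{100 * probs[i, j]:.0f}",
                    ha="center", va="center", fontsize=6,
                )
        ax.set_xlabel("Systolic blood pressure (mmHg)")
        ax.set_ylabel("Glasgow coma scale")
        ax.set_title(
            f"Predicted probability of early mortality (%) — {chart.model_name}"
        )
        fig.tight_layout()
        fig.savefig(image_path, dpi=150)
        plt.close(fig)
    return frame


def parse_chart_grid(path_or_frame) -> tuple[np.ndarray, np.ndarray]:
    """Read a rendered text grid back: (probability matrix, category matrix)."""
    frame = (
        path_or_frame
        if isinstance(path_or_frame, pd.DataFrame)
        else pd.read_csv(path_or_frame)
    )
    cells = frame.drop(columns="gcs")
    probs = cells.map(lambda s: float(s.split("|")[0])).to_numpy()
    cats = cells.map(lambda s: s.split("|")[1]).to_numpy()
    return probs, cats
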