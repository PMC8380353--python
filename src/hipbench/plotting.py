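"""Caterpillar plots of difference-in-failure against the benchmark.

One horizontal 95% CI per comparator construct, sorted ascending by the
point difference, coloured by noninferiority band, with vertical lines
at zero and at the 20%/100% relative-risk margins.  Differences are
shown in percentage points.  Bands with no constructs are omitted from
the legend.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import matplotlib

matplotlib.use("Agg")  # headless rendering; set before pyplot import
import matplotlib.pyplot as plt
import pandas as pd

from .benchmark import BenchmarkReport, ClassificationBand

log = logging.getLogger(__name__)

__all__ = ["PlotSpec", "PlotResult", "DEFAULT_BAND_COLOURS", "plot_caterpillar"]

#: Okabe-Ito palette: colour-blind safe defaults, worst bands warmest.
DEFAULT_BAND_COLOURS: Mapping[ClassificationBand, str] = {
    ClassificationBand.noninferior_20: "#009E73",
    ClassificationBand.noninferior_100: "#56B4E9",
    ClassificationBand.inconclusive: "#999999",
    ClassificationBand.inferior_20: "#E69F00",
    ClassificationBand.inferior_100: "#D55E00",
}

_BAND_LABELS = {
    ClassificationBand.noninferior_20: "Noninferior (20% margin)",
    ClassificationBand.noninferior_100: "Noninferior (100% margin)",
    ClassificationBand.inconclusive: "Inconclusive",
    ClassificationBand.inferior_20: "Inferior (20% margin)",
    ClassificationBand.inferior_100: "Inferior (100% margin)",
}


@dataclass
class PlotSpec:
    """What to draw: a report, a palette, margin lines, and where to save."""

    report: BenchmarkReport
    band_colours: Mapping[ClassificationBand, str] = field(
        default_factory=lambda: dict(DEFAULT_BAND_COLOURS)
    )
    show_margins: bool = True
    output_path: Optional[Union[str, Path]] = None


@dataclass
class PlotResult:
    """Rendered figure plus the exact data behind the drawn intervals."""

    figure: "plt.Figure"
    ax: "plt.Axes"
    data: pd.DataFrame  # columns: construct_label, diff_pp, lo_pp, hi_pp, band, n_at_risk


def plot_caterpillar(spec: PlotSpec) -> PlotResult:
    """Draw the difference-in-failure caterpillar plot for one report.

    Returns the figure together with the plotted interval data (in
    percentage points, ascending-diff order) so callers and tests can
    verify the rendered values without pixel inspection.  If
    ``output_path`` is set the figure is also written there.
    """
    report = spec.report
    rows = [
        {
            "construct_label": c.comparator.construct.label,
            "diff_pp": 100.0 * c.diff,
            "lo_pp": 100.0 * c.ci_low,
            "hi_pp": 100.0 * c.ci_high,
            "band": c.band.value,
            "n_at_risk": c.comparator.n_at_risk,
        }
        for c in report.comparisons
    ]
    data = pd.DataFrame(
        rows, columns=["construct_label", "diff_pp", "lo_pp", "hi_pp", "band", "n_at_risk"]
    )

    n = len(data)
    fig, ax = plt.subplots(figsize=(8.0, max(2.5, 0.45 * n + 1.5)))
    if n == 0:
        log.warning(
            "report %s at %gy has no comparators; legend-only figure",
            report.stratum,
            report.horizon_years,
        )

    seen_bands: list[ClassificationBand] = []
    for i, row in data.iterrows():
        band = ClassificationBand(row["band"])
        colour = spec.band_colours.get(band, "#000000")
        label = None
        if band not in seen_bands:
            seen_bands.append(band)
            label = _BAND_LABELS[band]
        ax.plot([row["lo_pp"], row["hi_pp"]], [i, i], color=colour, lw=2, label=label)
        ax.plot([row["diff_pp"]], [i], marker="o", ms=5, color=colour)
        ax.annotate(
            f"n={int(row['n_at_risk'])}",
            xy=(row["hi_pp"], i),
            xytext=(4, 0),
            textcoords="offset points",
            va="center",
            fontsize=7,
            color="#444444",
        )

    ax.axvline(0.0, color="black", lw=0.8)
    if spec.show_margins:
        ax.axvline(100.0 * report.margins.delta_20, color="#555555", lw=0.8, ls="--")
        ax.axvline(100.0 * report.margins.delta_100, color="#555555", lw=0.8, ls=":")

    ax.set_yticks(range(n))
    ax.set_yticklabels(data["construct_label"].tolist(), fontsize=8)
    ax.invert_yaxis()  # smallest difference at the top
    ax.set_xlabel("Difference in net failure vs reference (percentage points)")
    ref_label = (
        report.reference.construct.label if report.reference.construct else "reference"
    )
    ax.set_title(
        f"{report.stratum} procedures, {report.horizon_years:g} years\n"
        f"reference: {ref_label} "
        f"({100 * report.reference.failure:.2f}%, n at risk {report.reference.n_at_risk})",
        fontsize=10,
    )
    if seen_bands:
        ax.legend(fontsize=8, loc="lower right")
    fig.tight_layout()

    if spec.output_path is not None:
        out = Path(spec.output_path)
        out.parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(out, dpi=150)
        log.info("wrote %s", out)
    return PlotResult(figure=fig, ax=ax, data=data)
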