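"""Noninferiority benchmarking against a dynamic best-practice reference.

For each stratum (all procedures, female, male) and each horizon (3, 5, 7
and 10 years by default) the reference construct is the one with the
lowest net failure among constructs with at least 1000 procedures still
at risk at the horizon.  Every other construct with at least 500 at risk
is compared to it:

    diff    = F_comp(t) - F_ref(t)
    SE_diff = sqrt(SE_comp^2 + SE_ref^2)        (pooled Greenwood SE)
    95% CI  = diff +/- z_0.975 * SE_diff
    Wald z  = diff / SE_diff  (two-sided p against diff = 0)

Noninferiority margins are stated as relative risks of 20% and 100% (a
doubling) of the reference's cumulative failure and applied on the
absolute-difference scale: delta_20 = 0.2 * F_ref(t), delta_100 =
1.0 * F_ref(t).  Each comparison falls in exactly one of five bands:

    inferior_100     lower CI bound above delta_100
    inferior_20      lower CI bound above delta_20 (but not delta_100)
    noninferior_20   upper CI bound below delta_20
    noninferior_100  upper CI bound below delta_100 (but not delta_20)
    inconclusive     everything else

Classification is CI-versus-margin; the Wald test against zero is
reported alongside but does not drive the bands.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .registry import (
    DAYS_PER_YEAR,
    Bearing,
    Construct,
    Gender,
    HipbenchError,
    ProcedureRecord,
    RegistryError,
)
from .survival import SurvivalEstimate, km_failure_from_arrays

log = logging.getLogger(__name__)

__all__ = [
    "ClassificationBand",
    "MarginPair",
    "BenchmarkComparison",
    "BenchmarkReport",
    "classify",
    "compare",
    "select_reference",
    "run_benchmarking",
    "report_to_frame",
    "write_reports",
    "NoEligibleReferenceError",
]

DEFAULT_HORIZONS: Tuple[float, ...] = (3.0, 5.0, 7.0, 10.0)
DEFAULT_STRATA: Tuple[str, ...] = ("all", "female", "male")


class NoEligibleReferenceError(HipbenchError):
    """No construct meets the at-risk threshold required of a reference."""


class ClassificationBand(str, Enum):
    inferior_100 = "inferior_100"
    inferior_20 = "inferior_20"
    inconclusive = "inconclusive"
    noninferior_100 = "noninferior_100"
    noninferior_20 = "noninferior_20"


@dataclass(frozen=True)
class MarginPair:
    """Noninferiority margins on the absolute failure-difference scale.

    ``delta_20`` is 20% of the reference failure (the usual clinical-trial
    margin); ``delta_100`` is 100% — a doubling of the reference's
    cumulative failure.  By construction ``delta_100 = 5 * delta_20``.
    """

    delta_20: float
    delta_100: float

    def __post_init__(self) -> None:
        if self.delta_20 < 0 or self.delta_100 < 0:
            raise ValueError("margins must be nonnegative")
        if not math.isclose(self.delta_100, 5.0 * self.delta_20, rel_tol=1e-12, abs_tol=0.0):
            raise ValueError(
                f"delta_100 ({self.delta_100}) must equal 5 x delta_20 ({self.delta_20})"
            )

    @classmethod
    def from_reference_failure(cls, reference_failure: float) -> "MarginPair":
        d20 = 0.2 * reference_failure
        return cls(delta_20=d20, delta_100=5.0 * d20)


@dataclass(frozen=True)
class BenchmarkComparison:
    """One comparator-versus-reference contrast at a fixed horizon."""

    comparator: SurvivalEstimate
    reference: SurvivalEstimate
    diff: float
    se_diff: float
    ci_low: float
    ci_high: float
    wald_z: float
    wald_p: float
    band: Optional[ClassificationBand] = None
    margins: Optional[MarginPair] = None
    degenerate: bool = False  # zero pooled SE: CI collapses to a point


@dataclass(frozen=True)
class BenchmarkReport:
    """All comparisons for one (stratum, horizon) cell.

    ``comparisons`` are sorted ascending by difference (caterpillar
    order); ``excluded`` lists constructs below the comparator at-risk
    threshold together with their at-risk counts.
    """

    stratum: str
    horizon_years: float
    reference: SurvivalEstimate
    comparisons: Tuple[BenchmarkComparison, ...]
    excluded: Tuple[Tuple[Construct, int], ...]
    margins: MarginPair
    degenerate_reference: bool = False  # reference failure is exactly 0


def classify(ci_low: float, ci_high: float, margins: MarginPair) -> ClassificationBand:
    """Assign the five-band label from the difference CI and the margins.

    Rules in priority order (the stricter noninferior label wins):
    lower bound above delta_100 -> inferior_100; lower bound above
    delta_20 -> inferior_20; upper bound below delta_20 ->
    noninferior_20; upper bound below delta_100 -> noninferior_100;
    otherwise inconclusive.
    """
    if ci_low > ci_high:
        raise ValueError(f"ci_low ({ci_low}) exceeds ci_high ({ci_high})")
    if ci_low > margins.delta_100:
        return ClassificationBand.inferior_100
    if ci_low > margins.delta_20:
        return ClassificationBand.inferior_20
    if ci_high < margins.delta_20:
        return ClassificationBand.noninferior_20
    if ci_high < margins.delta_100:
        return ClassificationBand.noninferior_100
    return ClassificationBand.inconclusive


def compare(
    comparator: SurvivalEstimate,
    reference: SurvivalEstimate,
    confidence: float = 0.95,
) -> BenchmarkComparison:
    """Difference in net failure with pooled Greenwood SE and Wald test.

    The returned comparison has no band; apply :func:`classify_comparison`
    (or :func:`classify`) with the stratum's margins to label it.
    """
    if comparator.horizon_years != reference.horizon_years:
        raise ValueError(
            f"horizon mismatch: comparator at {comparator.horizon_years} y, "
            f"reference at {reference.horizon_years} y"
        )
    diff = comparator.failure - reference.failure
    se_diff = math.sqrt(comparator.se**2 + reference.se**2)
    z_crit = stats.norm.ppf(0.5 + confidence / 2.0)
    degenerate = se_diff == 0.0
    if degenerate:
        wald_z = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
        log.warning(
            "degenerate comparison (zero pooled SE) for %s vs %s",
            comparator.construct.label if comparator.construct else "<comparator>",
            reference.construct.label if reference.construct else "<reference>",
        )
    else:
        wald_z = diff / se_diff
    wald_p = float(2.0 * stats.norm.sf(abs(wald_z))) if math.isfinite(wald_z) else 0.0
    if wald_z == 0.0:
        wald_p = 1.0
    return BenchmarkComparison(
        comparator=comparator,
        reference=reference,
        diff=diff,
        se_diff=se_diff,
        ci_low=diff - z_crit * se_diff,
        ci_high=diff + z_crit * se_diff,
        wald_z=wald_z,
        wald_p=wald_p,
        degenerate=degenerate,
    )


def classify_comparison(comparison: BenchmarkComparison, margins: MarginPair) -> BenchmarkComparison:
    """Return a copy of ``comparison`` with its band and margins filled in."""
    band = classify(comparison.ci_low, comparison.ci_high, margins)
    return dataclasses.replace(comparison, band=band, margins=margins)


def select_reference(
    estimates: Sequence[SurvivalEstimate],
    min_at_risk: int = 1000,
    context: str = "",
) -> SurvivalEstimate:
    """Pick the best-practice reference: lowest failure with enough at risk.

    Eligibility requires ``n_at_risk >= min_at_risk``.  Ties on failure
    are broken by the larger at-risk count (the more precise estimate),
    then by lexicographic construct label; the result is therefore
    invariant to input order.
    """
    eligible = [e for e in estimates if e.n_at_risk >= min_at_risk]
    if not eligible:
        where = f" ({context})" if context else ""
        raise NoEligibleReferenceError(
            f"no construct has >= {min_at_risk} procedures at risk{where}"
        )
    def key(e: SurvivalEstimate):
        label = e.construct.label if e.construct is not None else ""
        return (e.failure, -e.n_at_risk, label)
    return min(eligible, key=key)


def _times_table(records: Sequence[ProcedureRecord], extraction_date: date) -> pd.DataFrame:
    """Vectorised time-to-event derivation; one row per record.

    Mirrors :func:`hipbench.registry.derive_time_to_event` exactly (the
    test suite asserts the equivalence).
    """
    if not records:
        return pd.DataFrame(
            columns=["stem", "cup", "bearing", "gender", "time_years", "event"]
        )
    ext = pd.Timestamp(extraction_date)
    primary = pd.to_datetime([r.primary_date for r in records])
    revision = pd.to_datetime([r.revision_date or pd.NaT for r in records])
    death = pd.to_datetime([r.death_date or pd.NaT for r in records])
    if (primary > ext).any():
        bad = int(np.argmax(primary > ext))
        raise RegistryError(
            f"procedure {records[bad].procedure_id!r}: primary_date after extraction date"
        )
    close = death.fillna(ext)
    close = close.where(close <= ext, ext)
    event = revision.notna() & (revision <= close)
    end = revision.where(event, close)
    time_years = (end - primary).days.astype(float) / DAYS_PER_YEAR
    n_rev_after_death = int((revision.notna() & death.notna() & (revision > death)).sum())
    if n_rev_after_death:
        log.warning(
            "%d record(s) have a revision dated after death; censored at death",
            n_rev_after_death,
        )
    return pd.DataFrame(
        {
            "stem": [r.stem_brand for r in records],
            "cup": [r.cup_brand for r in records],
            "bearing": [r.bearing.value for r in records],
            "gender": [r.gender.value if r.gender is not None else None for r in records],
            "time_years": np.asarray(time_years),
            "event": np.asarray(event),
        }
    )


def run_benchmarking(
    records: Sequence[ProcedureRecord],
    extraction_date: date,
    horizons: Sequence[float] = DEFAULT_HORIZONS,
    strata: Sequence[str] = DEFAULT_STRATA,
    reference_threshold: int = 1000,
    comparator_threshold: int = 500,
    confidence: float = 0.95,
) -> list[BenchmarkReport]:
    """Run the full benchmarking analysis over strata and horizons.

    ``records`` are assumed to have passed the bearing-couple inclusion
    filter.  A (stratum, horizon) cell with no eligible reference is
    omitted with a logged warning rather than failing the batch.  The
    output is deterministic and invariant to record order.
    """
    table = _times_table(records, extraction_date)
    reports: list[BenchmarkReport] = []
    valid_strata = {"all", *(g.value for g in Gender)}
    for stratum in strata:
        if stratum not in valid_strata:
            raise ValueError(f"unknown stratum {stratum!r}; expected one of {sorted(valid_strata)}")
        if stratum == "all":
            sub = table
        else:
            sub = table[table["gender"] == stratum]
            n_missing = int(table["gender"].isna().sum())
            if n_missing:
                log.info(
                    "stratum %r: %d record(s) without gender excluded", stratum, n_missing
                )
        if sub.empty:
            log.warning("stratum %r: no records; skipped", stratum)
            continue
        grouped = list(sub.groupby(["stem", "cup", "bearing"], sort=True))
        for horizon in horizons:
            estimates = []
            for (stem, cup, bearing), g in grouped:
                construct = Construct(stem, cup, Bearing(bearing))
                est = km_failure_from_arrays(
                    g["time_years"].to_numpy(),
                    g["event"].to_numpy(),
                    horizon,
                    confidence,
                    construct=construct,
                )
                estimates.append(est)
            try:
                reference = select_reference(
                    estimates, reference_threshold, context=f"stratum={stratum}, t={horizon:g}y"
                )
            except NoEligibleReferenceError as exc:
                log.warning("skipping report: %s", exc)
                continue
            margins = MarginPair.from_reference_failure(reference.failure)
            if reference.failure == 0.0:
                log.warning(
                    "degenerate reference (zero failure) in stratum %r at %gy: "
                    "margins collapse to 0",
                    stratum,
                    horizon,
                )
            comparisons = []
            excluded = []
            for est in estimates:
                if est is reference:
                    continue
                if est.n_at_risk < comparator_threshold:
                    excluded.append((est.construct, est.n_at_risk))
                    continue
                comparisons.append(classify_comparison(compare(est, reference, confidence), margins))
            comparisons.sort(key=lambda c: (c.diff, c.comparator.construct.label))
            reports.append(
                BenchmarkReport(
                    stratum=stratum,
                    horizon_years=float(horizon),
                    reference=reference,
                    comparisons=tuple(comparisons),
                    excluded=tuple(excluded),
                    margins=margins,
                    degenerate_reference=reference.failure == 0.0,
                )
            )
            log.info(
                "stratum=%s t=%gy: reference %s (failure %.4f, %d at risk), "
                "%d comparator(s), %d below threshold",
                stratum,
                horizon,
                reference.construct.label if reference.construct else "<unset>",
                reference.failure,
                reference.n_at_risk,
                len(comparisons),
                len(excluded),
            )
    return reports


def report_to_frame(report: BenchmarkReport) -> pd.DataFrame:
    """Tabulate a report, one row per comparator (caterpillar order)."""
    rows = []
    for c in report.comparisons:
        rows.append(
            {
                "construct_label": c.comparator.construct.label,
                "n_at_risk": c.comparator.n_at_risk,
                "failure": c.comparator.failure,
                "se": c.comparator.se,
                "ci_low": c.comparator.ci_low,
                "ci_high": c.comparator.ci_high,
                "diff": c.diff,
                "diff_ci_low": c.ci_low,
                "diff_ci_high": c.ci_high,
                "wald_z": c.wald_z,
                "wald_p": c.wald_p,
                "band": c.band.value if c.band else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "construct_label",
            "n_at_risk",
            "failure",
            "se",
            "ci_low",
            "ci_high",
            "diff",
            "diff_ci_low",
            "diff_ci_high",
            "wald_z",
            "wald_p",
            "band",
        ],
    )


def _report_key(report: BenchmarkReport) -> str:
    return f"{report.stratum}_{report.horizon_years:g}y"


def write_reports(reports: Iterable[BenchmarkReport], out_dir: Union[str, Path]) -> list[Path]:
    """Write one CSV per report plus a JSON summary of band counts.

    Returns the paths written.  Output is byte-deterministic for
    identical inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    summary: dict[str, dict] = {}
    for report in reports:
        key = _report_key(report)
        csv_path = out_dir / f"benchmark_{key}.csv"
        report_to_frame(report).to_csv(csv_path, index=False)
        paths.append(csv_path)
        band_counts = {b.value: 0 for b in ClassificationBand}
        for c in report.comparisons:
            band_counts[c.band.value] += 1
        summary[key] = {
            "stratum": report.stratum,
            "horizon_years": report.horizon_years,
            "reference": report.reference.construct.label
            if report.reference.construct
            else None,
            "reference_failure_pct": 100.0 * report.reference.failure,
            "reference_n_at_risk": report.reference.n_at_risk,
            "delta_20_pct": 100.0 * report.margins.delta_20,
            "delta_100_pct": 100.0 * report.margins.delta_100,
            "n_comparators": len(report.comparisons),
            "n_excluded": len(report.excluded),
            "band_counts": band_counts,
        }
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    paths.append(summary_path)
    return paths
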