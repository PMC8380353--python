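"""Reference selection, pooled-SE comparison, and five-band classification."""

from __future__ import annotations

import dataclasses
import itertools
import math
from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hipbench import (
    Bearing,
    ClassificationBand,
    Gender,
    Construct,
    MarginPair,
    NoEligibleReferenceError,
    SurvivalEstimate,
    classify,
    classify_comparison,
    compare,
    run_benchmarking,
    select_reference,
)
from hipbench.benchmark import report_to_frame

from conftest import make_record


def make_estimate(
    failure=0.03,
    se=0.005,
    n_at_risk=1500,
    horizon=3.0,
    label=("StemA", "CupA", Bearing.MP),
    n=2000,
):
    z = 1.959963984540054
    return SurvivalEstimate(
        horizon_years=horizon,
        failure=failure,
        se=se,
        ci_low=max(0.0, failure - z * se),
        ci_high=min(1.0, failure + z * se),
        n_at_risk=n_at_risk,
        n=n,
        n_events=int(round(failure * n)),
        construct=Construct(*label),
    )


class TestClassify:
    # Margins from a reference failing at 3.79%: delta_20 = 0.758 pp,
    # delta_100 = 3.79 pp.  CIs below are in proportions.
    MARGINS = MarginPair.from_reference_failure(0.0379)

    @pytest.mark.parametrize(
        "ci,expected",
        [
            ((0.040, 0.060), ClassificationBand.inferior_100),
            ((0.010, 0.030), ClassificationBand.inferior_20),
            ((-0.005, 0.005), ClassificationBand.noninferior_20),
            ((0.000, 0.020), ClassificationBand.noninferior_100),
            ((0.005, 0.050), ClassificationBand.inconclusive),
        ],
    )
    def test_rule_examples(self, ci, expected):
        assert classify(ci[0], ci[1], self.MARGINS) is expected

    def test_margin_pair_scaling(self):
        assert self.MARGINS.delta_20 == pytest.approx(0.00758)
        assert self.MARGINS.delta_100 == 5 * self.MARGINS.delta_20
        with pytest.raises(ValueError):
            MarginPair(0.01, 0.03)

    @given(
        a=st.floats(-0.2, 0.3), b=st.floats(-0.2, 0.3),
        f_ref=st.floats(0.0, 0.2),
    )
    @settings(max_examples=500, derandomize=True)
    def test_exactly_one_band_fires(self, a, b, f_ref):
        lo, hi = min(a, b), max(a, b)
        margins = MarginPair.from_reference_failure(f_ref)
        band = classify(lo, hi, margins)
        # independent re-derivation of the five mutually exclusive regions
        regions = {
            ClassificationBand.inferior_100: lo > margins.delta_100,
            ClassificationBand.inferior_20: margins.delta_20 < lo <= margins.delta_100,
            ClassificationBand.noninferior_20: hi < margins.delta_20 and lo <= margins.delta_20,
            ClassificationBand.noninferior_100: (
                margins.delta_20 <= hi < margins.delta_100 and lo <= margins.delta_20
            ),
            ClassificationBand.inconclusive: lo <= margins.delta_20 and hi >= margins.delta_100,
        }
        assert sum(regions.values()) == 1
        assert regions[band]

    @given(
        lo=st.floats(-0.1, 0.1), width=st.floats(0, 0.2),
        bump=st.floats(0, 0.1), f_ref=st.floats(0.001, 0.2),
    )
    @settings(max_examples=300, derandomize=True)
    def test_monotone_in_interval_endpoints(self, lo, width, bump, f_ref):
        """Enlarging ci_high never strengthens a noninferior label;
        lowering ci_low never strengthens an inferior label."""
        margins = MarginPair.from_reference_failure(f_ref)
        noninf_rank = {
            ClassificationBand.noninferior_20: 2,
            ClassificationBand.noninferior_100: 1,
        }
        inf_rank = {
            ClassificationBand.inferior_100: 2,
            ClassificationBand.inferior_20: 1,
        }
        hi = lo + width
        base = classify(lo, hi, margins)
        raised_hi = classify(lo, hi + bump, margins)
        assert noninf_rank.get(raised_hi, 0) <= noninf_rank.get(base, 0)
        lowered_lo = classify(lo - bump, hi, margins)
        assert inf_rank.get(lowered_lo, 0) <= inf_rank.get(base, 0)


class TestCompare:
    def test_self_comparison_is_null(self):
        ref = make_estimate()
        c = compare(ref, ref)
        assert c.diff == 0.0
        assert c.wald_z == 0.0
        assert c.wald_p == 1.0

    def test_closed_form_difference(self):
        comp = make_estimate(failure=0.05, se=0.01, label=("StemB", "CupB", Bearing.CP))
        ref = make_estimate(failure=0.03, se=0.01)
        c = compare(comp, ref)
        assert c.diff == pytest.approx(0.02, abs=1e-15)
        assert c.se_diff == pytest.approx(math.sqrt(2) * 0.01, abs=1e-12)
        assert c.ci_low == pytest.approx(-0.007718, abs=5e-7)
        assert c.ci_high == pytest.approx(0.047718, abs=5e-7)
        assert c.se_diff**2 == pytest.approx(comp.se**2 + ref.se**2, abs=1e-12)

    def test_zero_variance_is_degenerate_and_flagged(self):
        comp = make_estimate(failure=0.01, se=0.0, label=("StemB", "CupB", Bearing.CP))
        ref = make_estimate(failure=0.0, se=0.0)
        c = compare(comp, ref)
        assert c.degenerate
        assert c.ci_low == c.ci_high == pytest.approx(0.01)
        assert c.wald_p == 0.0

    def test_mismatched_horizons_raise(self):
        with pytest.raises(ValueError, match="horizon"):
            compare(make_estimate(horizon=3.0), make_estimate(horizon=5.0))

    def test_band_agrees_with_reclassification(self):
        comp = make_estimate(failure=0.06, se=0.008, label=("StemB", "CupB", Bearing.CP))
        ref = make_estimate(failure=0.03, se=0.004)
        margins = MarginPair.from_reference_failure(ref.failure)
        c = classify_comparison(compare(comp, ref), margins)
        assert c.band is classify(c.ci_low, c.ci_high, margins)


class TestSelectReference:
    def test_single_eligible_construct(self):
        est = make_estimate()
        assert select_reference([est]) is est

    def test_argmin_of_failure(self):
        ests = [
            make_estimate(failure=f, label=(f"S{i}", f"C{i}", Bearing.MP))
            for i, f in enumerate([0.012, 0.008, 0.020])
        ]
        assert select_reference(ests).failure == 0.008

    def test_threshold_excludes_small_constructs(self):
        small = make_estimate(failure=0.001, n_at_risk=999)
        big = make_estimate(failure=0.02, n_at_risk=1000, label=("S", "C", Bearing.CP))
        assert select_reference([small, big]) is big
        with pytest.raises(NoEligibleReferenceError, match="1000"):
            select_reference([small])

    def test_tie_breaks_by_at_risk_then_label_order_invariant(self):
        a = make_estimate(failure=0.01, n_at_risk=1500, label=("A", "A", Bearing.MP))
        b = make_estimate(failure=0.01, n_at_risk=1100, label=("B", "B", Bearing.MP))
        c = make_estimate(failure=0.01, n_at_risk=1100, label=("C", "C", Bearing.MP))
        for perm in itertools.permutations([a, b, c]):
            assert select_reference(list(perm)) is a
        for perm in itertools.permutations([b, c]):
            assert select_reference(list(perm)) is b  # label tie-break


def build_registry(arms, accrual_days=1, horizon=3.0, seed=0):
    """Synthetic registry without the simulator: deterministic small arms.

    ``arms`` maps construct tuples to (n, n_failed_by_horizon).
    """
    rng = np.random.default_rng(seed)
    start = date(2010, 1, 1)
    records = []
    for (stem, cup, bearing), (n, n_fail) in arms.items():
        for i in range(n):
            fail = i < n_fail
            gender = None if i % 10 == 9 else (Gender.female if i % 2 else Gender.male)
            records.append(
                make_record(
                    pid=f"{stem}-{i}",
                    gender=gender,
                    stem=stem,
                    cup=cup,
                    bearing=bearing,
                    primary=start + timedelta(days=int(rng.integers(0, accrual_days))),
                    revision=start + timedelta(days=200 + i % 300) if fail else None,
                )
            )
    return records


class TestRunBenchmarking:
    EXTRACTION = date(2022, 1, 1)

    def test_single_dominant_construct_yields_empty_comparisons(self):
        arms = {("A", "A", Bearing.MP): (1500, 15), ("B", "B", Bearing.CP): (100, 5)}
        reports = run_benchmarking(
            build_registry(arms), self.EXTRACTION, horizons=[3.0], strata=["all"]
        )
        (report,) = reports
        assert report.reference.construct.label == "A/A MP"
        assert report.comparisons == ()
        assert [c.label for c, _ in report.excluded] == ["B/B CP"]

    def test_thresholds_reference_exclusion_and_sort_order(self):
        arms = {
            ("A", "A", Bearing.MP): (2000, 20),   # reference: 1% failure
            ("B", "B", Bearing.MP): (800, 40),    # 5%
            ("C", "C", Bearing.CP): (700, 14),    # 2%
            ("D", "D", Bearing.CC): (499, 2),     # below comparator threshold
        }
        (report,) = run_benchmarking(
            build_registry(arms), self.EXTRACTION, horizons=[3.0], strata=["all"]
        )
        labels = [c.comparator.construct.label for c in report.comparisons]
        assert labels == ["C/C CP", "B/B MP"]  # ascending diff
        assert all(c.comparator.n_at_risk >= 500 for c in report.comparisons)
        assert report.reference.n_at_risk >= 1000
        assert all(
            c.comparator.construct != report.reference.construct
            for c in report.comparisons
        )
        diffs = [c.diff for c in report.comparisons]
        assert diffs == sorted(diffs)
        assert all(c.band is not None for c in report.comparisons)

    def test_no_eligible_reference_skips_cell_not_batch(self, caplog):
        arms = {("A", "A", Bearing.MP): (900, 5)}
        with caplog.at_level("WARNING"):
            reports = run_benchmarking(
                build_registry(arms), self.EXTRACTION, horizons=[3.0], strata=["all"]
            )
        assert reports == []
        assert "at risk" in caplog.text

    def test_deterministic_under_record_permutation(self):
        arms = {
            ("A", "A", Bearing.MP): (1200, 12),
            ("B", "B", Bearing.MP): (600, 18),
        }
        records = build_registry(arms)
        rng = np.random.default_rng(7)
        shuffled = [records[i] for i in rng.permutation(len(records))]
        r1 = run_benchmarking(records, self.EXTRACTION, horizons=[3.0], strata=["all"])
        r2 = run_benchmarking(shuffled, self.EXTRACTION, horizons=[3.0], strata=["all"])
        assert r1 == r2

    def test_gender_strata_are_independent_and_drop_missing(self):
        arms = {
            ("A", "A", Bearing.MP): (3000, 30),
            ("B", "B", Bearing.MP): (2400, 72),
        }
        reports = run_benchmarking(
            build_registry(arms), self.EXTRACTION, horizons=[3.0],
            strata=["all", "female", "male"],
        )
        assert [r.stratum for r in reports] == ["all", "female", "male"]
        n_all = reports[0].reference.n + sum(
            c.comparator.n for c in reports[0].comparisons
        )
        n_gendered = sum(
            r.reference.n + sum(c.comparator.n for c in r.comparisons)
            for r in reports[1:]
        )
        assert n_gendered < n_all  # missing-gender records only count in "all"

    def test_report_frame_has_contract_columns(self):
        arms = {
            ("A", "A", Bearing.MP): (1200, 12),
            ("B", "B", Bearing.MP): (600, 18),
        }
        (report,) = run_benchmarking(
            build_registry(arms), self.EXTRACTION, horizons=[3.0], strata=["all"]
        )
        frame = report_to_frame(report)
        assert list(frame.columns) == [
            "construct_label", "n_at_risk", "failure", "se", "ci_low", "ci_high",
            "diff", "diff_ci_low", "diff_ci_high", "wald_z", "wald_p", "band",
        ]
        assert len(frame) == len(report.comparisons)
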