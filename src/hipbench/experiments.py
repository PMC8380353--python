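"""Simulation experiments: classification calibration and power.

Runs the full pipeline (simulate -> estimate -> select reference ->
compare -> classify) on many independently seeded two-arm registries and
tallies the band assigned to the comparator arm.  Used to check that,
under equal true failure, false inferiority calls are rare, and that a
construct with a genuinely elevated hazard is flagged inferior with high
probability.
"""

from __future__ import annotations

import math
from collections import Counter
from datetime import date, timedelta
from typing import Optional

import numpy as np

from .benchmark import ClassificationBand, run_benchmarking
from .registry import Bearing, Construct
from .simulate import ConstructSpec, SyntheticRegistryConfig, simulate_registry

__all__ = ["two_arm_band_counts", "INFERIOR_BANDS"]

INFERIOR_BANDS = frozenset(
    {ClassificationBand.inferior_20, ClassificationBand.inferior_100}
)

_REF = Construct("RefStem", "RefCup", Bearing.MP)
_COMP = Construct("TestStem", "TestCup", Bearing.MP)


def two_arm_band_counts(
    n_replicates: int,
    relative_risk: float,
    seed: int,
    true_reference_failure: float = 0.04,
    horizon_years: float = 10.0,
    n_per_arm: int = 2000,
    death_hazard: float = 0.0,
    complete_follow_up: bool = True,
) -> Counter:
    """Band tally for the comparator arm over replicated registries.

    Each replicate simulates two constructs of ``n_per_arm`` procedures:
    a reference arm whose constant hazard yields
    ``true_reference_failure`` at ``horizon_years``, and a comparator arm
    at ``relative_risk`` times that hazard.  With ``complete_follow_up``
    the accrual window collapses so every procedure is observed past the
    horizon (no administrative censoring before t).  The benchmarking
    pipeline is run per replicate with its usual thresholds and the band
    of the single reported comparison is counted.

    Replicate r uses seed ``seed * 1_000_003 + r`` (kept below 2^31).
    """
    hazard = -math.log(1.0 - true_reference_failure) / horizon_years
    start = date(2000, 1, 1)
    if complete_follow_up:
        extraction = start + timedelta(days=int(math.ceil(horizon_years * 365.25)) + 3)
        accrual_end = start + timedelta(days=1)
    else:
        extraction = start + timedelta(days=int(math.ceil(2 * horizon_years * 365.25)))
        accrual_end = extraction
    catalogue = (
        ConstructSpec(_REF, n_per_arm, hazard, 1.0, is_reference=True),
        ConstructSpec(_COMP, n_per_arm, hazard, relative_risk),
    )
    counts: Counter = Counter()
    for r in range(n_replicates):
        cfg = SyntheticRegistryConfig(
            catalogue=catalogue,
            accrual_start=start,
            accrual_end=accrual_end,
            extraction_date=extraction,
            death_hazard=death_hazard,
            seed=(seed * 1_000_003 + r) % (2**31),
        )
        records = simulate_registry(cfg)
        reports = run_benchmarking(
            records,
            extraction_date=extraction,
            horizons=[horizon_years],
            strata=["all"],
        )
        if not reports or not reports[0].comparisons:
            counts["no_comparison"] += 1
            continue
        (comparison,) = reports[0].comparisons
        counts[comparison.band] += 1
    return counts
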