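# Methods

## Model and estimand

The unit of analysis is the THR *construct*: the (stem brand, cup brand,
bearing couple) triple. For each construct we estimate **net failure**
F(t) = 1 − S(t), the cumulative probability of first revision by t years
after the primary operation, with S the Kaplan-Meier product limit over the
construct's procedures. Death and the registry extraction date censor;
death is *not* treated as a competing risk, so F(t) is the revision
probability in a hypothetical population without mortality. Net failure is
the registry convention for implant comparison: it isolates implant
performance from cohort mortality, at the price of overstating the absolute
real-world revision probability in elderly cohorts. Only first revisions
count; MP, CP and CC bearings are included and metal-on-metal and other
hard-on-hard bearings are excluded before analysis.

Variance is Greenwood's estimator; SE[F] = SE[S]. Confidence intervals are
untransformed Wald intervals on the failure scale, clipped to [0, 1]. A
log(−log) transform would behave better near 0, but the classification
scheme reasons about symmetric CI widths on the difference scale (the
at-risk thresholds below are chosen to give ±1.5 % and ±2.5 % widths), so
the plain Wald form is used consistently for arms and differences.

## Benchmarking

Within each stratum (all procedures; females; males — strata are fully
independent analyses) and at each horizon t ∈ {3, 5, 7, 10} years:

* **Reference**: the construct with the lowest F(t) among those with at
  least 1000 procedures at risk at t. Ties break toward the larger risk set
  (the more precise estimate), then lexicographic label, making selection
  order-invariant. "At risk at t" means follow-up time ≥ t; the same ≥
  convention feeds both the 1000 and the 500 thresholds.
* **Comparisons**: every other construct with ≥ 500 at risk is compared:
  diff = F_comp − F_ref, SE by pooling the two Greenwood SEs in quadrature,
  95 % Wald CI, and a two-sided Wald z = diff/SE against zero. The pooled
  SE ignores the (nonnegative) covariance induced by selecting the
  reference as the observed minimum; the null-calibration study below shows
  the resulting false-inferiority rate stays well inside its nominal bound.
* **Margins**: stated as relative risks of 20 % and 100 % of the
  reference's failure and applied as absolute differences δ₂₀ = 0.2·F_ref(t)
  and δ₁₀₀ = 1.0·F_ref(t) (a doubling), so margins shrink and grow with the
  benchmark itself. If F_ref(t) = 0 both margins collapse to 0; the report
  flags this degenerate case rather than suppressing it.
* **Bands** (mutually exclusive, exhaustive, in priority order): CI lower
  bound above δ₁₀₀ → inferior at 100 %; above δ₂₀ → inferior at 20 %; CI
  upper bound below δ₂₀ → noninferior at 20 %; below δ₁₀₀ → noninferior at
  100 %; otherwise inconclusive. Classification is CI-versus-margin; the
  Wald p-value is reported but does not drive the band. No multiplicity
  adjustment is applied — each contrast answers its own clinical question.

A (stratum, horizon) cell with no eligible reference is skipped with a
warning rather than failing the batch, since late horizons routinely lose
eligibility in gender strata. The reference is excluded from its own
comparison list.

## Time-to-event derivation

Dates are held at day resolution; years = days / 365.25. The observation
window closes at min(death, extraction). A revision on or before the close
is the event at its own date; otherwise the record is censored at the
close. A revision dated after death — a data error — censors at death with
a warning. When events and censorings share a timestamp, events are
processed first (the censored subject remains in the risk set at that
time); time comparisons are exact floating-point after the day/365.25
conversion, with no fuzzing.

## Synthetic registry generator

The generator emulates the censoring structure of a national registry:

* primary dates uniform over an accrual window (default 1999-01-01 to
  2020-06-01, extraction 2020-06-01), giving staggered administrative
  censoring;
* latent revision times exponential with hazard h·RR, where h is a base
  hazard and RR the construct's true relative risk (constant hazards give
  closed-form truths F(t) = 1 − exp(−h·RR·t) for oracle tests);
* latent death times exponential and independent (default 0.025 / y,
  a realistic mortality for a THR cohort of mean age around 70);
* gender Bernoulli per construct (demo fractions 0.35–0.65, cemented
  constructs skewed female as registries observe);
* the registry records whichever of revision, death, extraction came
  first, at day resolution (latent years rounded to the nearest day).

The demo catalogue uses a base hazard of 0.004 / y — a true 10-year net
failure of 3.9 %, the scale reported for well-performing contemporary
constructs — with relative risks 1.0–2.2 across eight included constructs,
one metal-on-metal arm (exercises the bearing filter) and two rarely used
constructs (exercise sub-threshold exclusion). `long_tail_catalogue`
generates registry-shaped catalogues (e.g. 1035 constructs of which ~328
are used exactly once) with Zipf-weighted usage for stress-testing
exclusion logic at scale.

Randomness is a single integer seed split per construct via a CRC of the
construct label, so adding a construct never perturbs the draws of the
others, and identical seeds give byte-identical registries.

What the generator does **not** emulate — and hence what passing tests do
not establish about real registries: non-constant (e.g. early-failure)
hazard shapes beyond the piecewise hooks, informative censoring, case-mix
confounding (age, indication, ASA), surgeon/hospital clustering, and
revision under-linkage. Classification accuracy on synthetic data is
therefore evidence about the *statistical machinery*, not about any real
construct.

## Simulation studies

Calibration and power use two-arm registries (reference and comparator,
n = 2000 per arm, complete follow-up to the 10-year horizon, reference true
failure 4 %), running the full pipeline per replicate with its usual
thresholds:

* **Null (RR = 1)**: the fraction of replicates classified inferior at
  either margin stays below 2.5 % plus three binomial SEs (measured ≈0.2 %
  over 500 replicates — conservative because inferiority needs the whole CI
  above δ₂₀, not just a significant difference).
* **Power (RR = 3)**: ≥ 95 % of replicates are flagged inferior (measured
  100 % over 200 replicates).
* **Margin equipoise (RR = 1.2)**: the true excess failure sits almost
  exactly on δ₂₀, so decisive 20 %-level calls in either direction are rare.
  At this n the CI width (~2.5 pp) is smaller than δ₁₀₀ − δ₂₀ (~3.2 pp), so
  the geometry forces nearly every replicate into the noninferior-at-100 %
  band; the strictly inconclusive band requires smaller risk sets.

Problem sizes throughout (≤ 5000 subjects per arm, hundreds of replicates)
were chosen so that every closed-form or oracle comparison has Monte-Carlo
error far below the assertion tolerance while the full suite runs in a
couple of minutes.

## Numerical and degenerate-case choices

* Empty input to an estimator is a hard error; a horizon beyond the last
  observed time returns the estimate carried forward from the last event
  time with `n_at_risk = 0` and a flag.
* If the risk set is exhausted by events (r = d), S hits 0 and the
  Greenwood SE is defined as 0 (degenerate, as is SE when F = 0; a
  zero-failure construct may still serve as reference, flagged).
* A zero pooled SE makes the difference CI a point; the comparison is
  flagged degenerate, with Wald z of 0 (diff = 0) or ±∞.
* Comparisons sort by (diff, comparator label) so caterpillar order is
  total and deterministic under record permutation.

## Known limitations

No age stratification (registry risk sets are too small once gender×age is
crossed), no case-mix adjustment, no competing-risks cumulative incidence,
no multiple-revision linkage — the design compares crude net failure, so
between-construct differences partly reflect differences in the patients
selected for each construct, not implant quality alone.
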