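# Synthetic demonstration registry: a national-registry-shaped cohort of
# primary total hip replacements accruing over ~21 years.  All hazards are
# per year; the true reference construct fails at ~3.9% by 10 years.
seed: 20210821
accrual_start: 1999-01-01
accrual_end: 2020-06-01
extraction_date: 2020-06-01
death_hazard: 0.025
base_hazard: 0.004
constructs:
  - {stem: MS30, cup: Fitmore, bearing: MP, n: 4000, relative_risk: 1.0,
     reference: true, female_fraction: 0.60}
  - {stem: ExeterV40, cup: Trident, bearing: MP, n: 6000, relative_risk: 1.05,
     female_fraction: 0.55}
  - {stem: ExeterV40, cup: Trident, bearing: CC, n: 2500, relative_risk: 1.10,
     female_fraction: 0.45}
  - {stem: Corail, cup: Pinnacle, bearing: CP, n: 5000, relative_risk: 1.20,
     female_fraction: 0.40}
  - {stem: Accolade, cup: Trident, bearing: CC, n: 1800, relative_risk: 1.40,
     female_fraction: 0.35}
  - {stem: ExeterV40, cup: Tritanium, bearing: MP, n: 1500, relative_risk: 2.20,
     female_fraction: 0.50}
  - {stem: Summit, cup: Duraloc, bearing: MP, n: 900, relative_risk: 1.60,
     female_fraction: 0.50}
  - {stem: CLS, cup: Morscher, bearing: CP, n: 1200, relative_risk: 1.15,
     female_fraction: 0.45}
  # Excluded by the bearing filter (hard-on-hard):
  - {stem: ASR, cup: ASR, bearing: MoM, n: 600, relative_risk: 3.00,
     female_fraction: 0.30}
  # Rarely used constructs, below the comparator threshold:
  - {stem: Spectron, cup: Reflection, bearing: MP, n: 120, relative_risk: 1.30,
     female_fraction: 0.65}
  - {stem: Lubinus, cup: IPLink, bearing: MP, n: 40, relative_risk: 1.50,
     female_fraction: 0.55}
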