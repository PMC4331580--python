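# Methods

## System and scope

`fesip` models the bookkeeping layer of an anoxic soil-slurry SIP
incubation: sealed serum vials (5 ml slurry, 20 ml headspace, 25 °C)
containing paddy soil from a non-fertilized (NF) or long-term N-fertilized
(N) field, amended with ferrihydrite (FER, Fe₅HO₈·4H₂O, 140 μmol Fe g⁻¹ dry
soil), goethite (GOE, α-FeOOH, same dose) or nothing (CTR), and fed
[U-¹³C]acetate (99 atom %) in three pulses of 3.3 μmol g⁻¹ at days 0, 1.5
and 3 over a 4-day incubation. The package does not model microbial growth
kinetics, Fe mineral transformations, or sequence processing; its inputs
are measured time courses, gradient fraction tables and genus count tables.

## Electron balance

Electrons available from the substrate are computed from acetate drawdown
alone under the complete-oxidation stoichiometry (8 e⁻ per acetate); this
is the field convention when no other volatile fatty acids accumulate.
Electrons delivered to iron equal the Fe(II) formed (1 e⁻ per Fe). Two
deliberate consequences:

* The percentage to Fe is a ratio of two *measured* quantities. When
  reproducing a reported table, the measured electron production is carried
  as given rather than recomputed from rounded acetate values, since
  re-deriving it from printed intermediates propagates their rounding.
* A percentage above 100 is possible (indigenous electron donors) and is
  reported with a warning flag, never clamped.

Because the complete-oxidation convention attributes all consumed carbon to
CO₂ while short SIP incubations in fact assimilate most of it into biomass,
the electron balance and the ¹³C recovery are *independent* summaries that
need not be numerically consistent with each other — a high electron
fraction to Fe can coexist with a low carbon recovery. The package keeps
both bookkeepings separate on purpose.

Reported values follow the table convention: round-half-away-from-zero, two
significant figures for electron percentages, integer percent for
recoveries. Rounding is done in decimal arithmetic so that values exact in
decimal round by policy rather than by binary representation.

## Carbonate system

Dissolved inorganic ¹³C is estimated from headspace ¹³CO₂ and slurry pH:
ideal-gas partial pressure (R = 0.082057 L atm mol⁻¹ K⁻¹), Henry's law, and
the two carbonic-acid dissociations. Defaults are 25 °C freshwater
constants — K_H = 0.0339 mol L⁻¹ atm⁻¹, pK₁ = 6.35, pK₂ = 10.33 — with the
effective liquid volume set to the slurry pore-water volume (5 ml) and the
gas volume to the 20-ml headspace. All six constants are configurable: the
constants and effective volumes appropriate to a particular slurry are
rarely reported, so the defaults are a documented choice, validated against
an independent numerical equilibrium solver (to 6 significant figures)
rather than against any particular published dissolved/gaseous ratio. The
function is exactly homogeneous of degree 1 in the gas amount, which also
supplies the phase-partition ratio used by the generator.

## Gradient model and labeling call

Profiles are normalized to the treatment maximum (the standard display
convention for density-resolved qPCR data). Windows default to: light
1.782 ± 0.004 g ml⁻¹, heavy 1.791–1.806, sequencing selection 1.791–1.801;
all overridable. Fractions from labeled and unlabeled runs are paired by
nearest buoyant density within 0.003 g ml⁻¹ — not by fraction index —
because measured BDs wobble between centrifuge runs.

The labeling statistic is the difference in heavy-window mass share
(labeled − unlabeled); the default call threshold of 0.15 is a package
decision (the qualitative literature criterion, "considerably higher heavy
signal", has no standard numeric form). At the default noise model the
threshold gives a false-positive rate well under 5% and near-certain
detection of a 0.6 label shift; both rates are recomputed, not assumed, by
the test suite and acceptance script.

## Community statistics

With three fraction-samples per treatment as the unit of replication, the
assimilator screen uses a one-sided exact permutation test on the
difference of group means (all C(6,3) = 20 assignments enumerated; the
identity assignment is counted, so the smallest attainable p is 1/20).
Normal-theory tests are avoided because n = 3 makes their assumptions
untestable. No multiple-testing correction is applied by default — the
conventional screen is per-genus at α = 0.05 — but a Benjamini–Hochberg
toggle is provided. Fold changes with a zero control mean fall back to a
pseudo-count of half the minimum nonzero relative abundance and are flagged.
Fold changes are computed from fraction-level mean relative abundances, not
pooled counts.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions of the emulated design.

**Microcosms.** Acetate decays first-order between pulses (default rate
2.0 d⁻¹ under FER, 1.0 otherwise — free parameters, not mechanistic
claims). A fraction `f_fe` of the theoretical electron production goes to
Fe(III) (Fe(II) = 8·a·f_fe), a fraction `f_meth` of consumed acetate is
cleaved to CH₄ + CO₂, the Fe pathway adds 2 CO₂ per dissimilated acetate,
and the remainder (1 − f_fe − f_meth of substrate carbon) is the
assimilated pool, reported in the ground truth. Per-treatment defaults:
f_fe mirrors the measured electron partition (0.74/0.84 FER, 0.14/0.31 GOE,
0.046/0.11 CTR for NF/N); f_meth (0.22/0.16 FER, 0.36/0.27 GOE, 0.40/0.30
CTR) was set so the noiseless CH₄ totals show the observed suppression
scale (~33% by FER, ~8% by GOE). Background mineralization of soil organic
carbon runs at natural abundance (1.1 atom %): 0.4 μmol CH₄ d⁻¹ and 30 μmol
CO₂ d⁻¹ per vial, sized so gas atom %¹³C lands near the observed ~80%
(CH₄) and ~20–30% (CO₂). Produced CO₂ partitions between headspace and pore
water through the same carbonate system the analysis uses, closing the
loop. Per-gram ↔ per-vial conversion uses a soil dry mass of 3.0 g per
vial, a derived default (the ratio of per-vial to per-gram Fe(II)
increments), logged on every run.

Gaussian measurement noise is added last (sd: Fe(II) 1.5 μmol g⁻¹, acetate
0.15 μmol g⁻¹, gases 0.3 μmol, atom % 1.0 point), with physical clipping
(Fe(II) ≤ total Fe, non-negative pools). Total extractable Fe is constant
by construction.

**Gradients.** Two-Gaussian mixtures over a 14-fraction grid spanning
1.77–1.82 g ml⁻¹ (fraction 1 heaviest): light band at 1.782, heavy at
1.7985, sd 0.004 g ml⁻¹. Under ¹³C a proportion `label_shift` (default
0.6) of the bacterial signal moves to the heavy band; archaeal profiles
never shift, emulating the absence of archaeal labeling in short acetate
SIP incubations. Noise is multiplicative lognormal per fraction (sd 0.2 in
log space) plus a small BD jitter (sd 0.0005 g ml⁻¹) that exercises the
nearest-BD pairing. The analytic heavy-window mass of the mixture (an
error-function integral) serves as the oracle for the discrete profiles.

**Taxon tables.** Counts are multinomial at depth 3990 per sample (the
rarefaction convention for this kind of data) over baseline genus
proportions, with designated assimilator genera multiplied by
per-amendment enrichment factors in labeled samples (e.g. *Geobacter*
baseline 2.4%, FER enrichment 13×, GOE 4.7×). The unassigned remainder is
an explicit "other" pool that absorbs enrichment, so a configured factor is
also the realized expected fold change as long as named genera total ≤ 100%
(otherwise proportions are renormalized and the realized factors recorded
in the ground truth).

All randomness flows through one seeded `numpy` generator; identical seeds
give byte-identical outputs.

## What the generator does not emulate

Real fraction profiles have asymmetric bands, RNA carryover between
fractions and GC-content-dependent buoyant density; real count tables have
overdispersion beyond multinomial, compositional correlations between
genera, and classification error; real time courses have autocorrelated
instrument drift. Passing closed-loop tests therefore demonstrates that the
analysis chain is *self-consistent and correctly implemented at realistic
signal-to-noise*, not that it is robust to every artifact of real data.
The stoichiometric core also cannot reproduce one observed pattern — CO₂
suppression by Fe amendment — since more oxidation produces more CO₂ under
this bookkeeping; treatment CO₂ contrasts should not be read off the
generator.

## Numerical choices and degenerate inputs

* Zero denominators (electron production, control means, added label) raise
  a dedicated undefined-ratio error rather than returning inf/NaN.
* All-zero gradient profiles are degenerate and refuse normalization.
* Permutation p-values use a relative tie tolerance of 1e-12 so float
  jitter cannot split exact ties; identical pooled values give p = 1.
* Exact enumeration is used up to 20 000 group assignments; beyond that a
  seeded Monte-Carlo fallback (10⁴ draws, identity included) takes over.
* Heavy/light window membership is closed (boundary BDs count as inside);
  heavy takes precedence if windows are configured to overlap.

## Problem sizes

The stochastic summaries are computed at 50 seeds (closed-loop recoveries),
200 seeds (shift-detection rates) and 1000 simulated null genera
(permutation calibration) — sizes at which the Monte-Carlo standard errors
are comfortably below the decision margins they inform.
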