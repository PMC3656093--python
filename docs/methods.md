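# Methods

This note documents the statistical procedures screenkit implements, the
synthetic data model used to validate them, and the numerical and design
choices made where more than one defensible option existed.

## Normalization and plate-pattern correction

Raw luminescence is normalized per plate against the intraplate controls:
`activity(x) = 100·(x − m_n)/(m_n − m_p)`, with `m_n`, `m_p` the *medians*
of the neutral and positive control wells. Medians (not means) make the
anchors robust to a single failed control well. The transform is linear, so
it is invariant to positive affine rescaling of the raw signal (gain or
offset drift of the reader), and per plate the neutral-well median maps to
exactly 0 and the positive-well median to exactly −100. Inhibition is kept
*signed* (negative) internally so inhibitors and activators remain
distinguishable; QC output reports the positive-control level as
|activity| = 100.

Pattern correction targets additive positional bias (edge effects, dispenser
gradients) that repeats across the plates of one replicate run. For every
well position, the median of that position's compound-well activities across
plates estimates the positional bias; subtracting it re-centred on the grand
median of the positional medians preserves plate-level medians. Control
wells are never modified, and the correction is exactly idempotent. It
requires at least 3 plates sharing a layout; with fewer it is skipped with a
warning. This is deliberately the *minimal* positional-median algorithm — no
B-score/median-polish or loess surface — and is validated by
inject-and-recover simulation: a noiseless injected row gradient is removed
to machine precision, and on a gradient-free screen the maximal spurious
correction stays below one well-noise SD (30-plate configuration).

Assay quality uses the standard Z'-factor from the raw control means/SDs,
`Z' = 1 − 3(σ_p + σ_n)/|μ_p − μ_n|`, flagged robust above 0.5. Note the
deliberate asymmetry: Z' uses means/SDs, normalization uses medians; both
sets of statistics are carried in `ControlStats`.

## Hit calling

Preliminary hits require concordant inhibition: corrected activity below
`μ_neutral − k·σ_neutral` in *both* replicates, with the neutral statistics
pooled over all plates of the screen and `k = 2` by default (the operational
reading of a 95% confidence band; `k = Φ⁻¹(0.975) ≈ 1.96` gives the exact
Gaussian 2.5% tail and is what the calibration suite uses). Under a null of
independent Gaussian replicates with thresholds at the true 2.5% point, the
both-replicate hit probability is 0.025² = 6.25×10⁻⁴, which the test suite
confirms by Monte Carlo at n = 10⁵.

One caveat worth knowing: when thresholds are *estimated* from neutral
controls, they are slightly anti-conservative, because each plate's neutral
wells are re-centred by their own median during normalization — the neutral
activity spread understates the compound activity spread (which additionally
carries the plate-anchor estimation error). The effect is small but visible
at the 10⁻⁴ scale; the calibration analysis therefore states the null in
terms of true-quantile thresholds.

Frequent hitters are filtered on assay history alone: promiscuous ⇔ tested
in > 50 assays AND hit ratio > 0.25, both inequalities strict (51 assays
with 13 hits qualifies; 50 assays never does; a ratio of exactly 0.25 does
not). Compounds with no history are never promiscuous. Final hits are
preliminary hits minus the promiscuous overlap, and the accounting identity
`final + overlap = preliminary` is enforced.

An excess-hit test is provided as a one-sided exact binomial upper tail with
a *user-supplied* null both-replicate tail probability. No particular null
is privileged because none is uniquely implied by the screen design; the
test is a clean primitive, not a reproduction of any specific historical
p-value.

## Dose-response model

The four-parameter logistic is parameterized as

    y(x) = L − h / (1 + (α/x)^β)

with L the top plateau, h the span, α the relative IC50 and β the Hill
slope. This form is chosen because y(α) = L − h/2 identically: α *is* the
halfway point between the plateaus, so "relative IC50" needs no
post-processing. Fitting is `scipy.optimize.curve_fit` (trust-region
reflective, α bounded positive) with fixed starting values: L₀ = maximum
response at the smallest concentration, h₀ = mean response at the smallest
concentration minus the minimum response at the largest, α₀ = 4 µM, β₀ = 2.
Fixed starting points keep fits deterministic and reproducible.

Fallback ("plateau not observed") triggers when the optimizer fails, when
|β̂| < 0.2 (essentially flat), or when α̂ falls outside
[0.1·min dose, 10·max dose]. The fallback smooths response against
log-concentration with lowess (span 0.45, chosen so that the smoothed
midpoint crossing of a clean sigmoid stays within 5% of the parametric α on
an 8-dose design) and reports the interpolated concentration at the midpoint
of the smoothed extremes, scanning from low to high concentration; if the
midpoint is never crossed inside the tested range the IC50 is undefined and
flagged. Flatness of the smooth is judged at relative tolerance 1e-8 to
absorb float fuzz in the smoother.

Percent maximum inhibition is computed from the observed dose extremes,
`100·(ȳ_low − ȳ_high)/ȳ_low`. With finite plateaus this lands slightly
below the true span h (e.g. a 90.2-span curve with α = 5 µM on the 50 →
0.39 µM ladder reads ≈ 89.3%), which is a property of the metric, not a bug.

IC50 confidence intervals use a percentile bootstrap over residual
resampling (default 1,000 resamples, seeded); the CI is declared unstable
and withheld if more than half the refits fail. Coverage is checked by
simulation at 5% CV noise. A viability gate interpolates the parallel
viability series at the IC50 on the log-concentration axis and flags the
compound toxic below 70% of untreated by default — a viability drop confined
to doses above the IC50 does not trip the gate.

## Enrichment

Compound-set enrichment ranks all screened compounds by corrected activity
ascending (most inhibitory = rank 1, mid-ranks for ties) and tests each
annotation term's members against non-members with a two-sided Wilcoxon
rank-sum test — exact enumeration when both groups have ≤ 20 members and no
ties, the normal approximation with tie correction otherwise. The enrichment
score is `(mean rank of non-members − mean rank of members)/N`, positive for
inhibition-enriched sets and antisymmetric under activity negation. Terms
with fewer than 3 screened members (configurable) are excluded, as are
degenerate terms covering the whole library. Significance is Bonferroni at
`0.05 / #sets tested` — the most literal reading of a fixed
number-of-hypotheses line.

Class enrichment among hits is the upper-tail hypergeometric probability
P(X ≥ k) for k class members among n hits, K in the library of N, evaluated
via `hypergeom.logsf` so tails far below 10⁻¹⁶ remain representable. It is
verified against brute-force combinatorial summation on every configuration
with N ≤ 30.

Trinarization for display divides corrected activity by the neutral-control
SD, so the neutral band (−1, 1) means "within one control SD"; the band is
open — exactly ±1 classifies as active — because the active classes are the
ones reported. The SD scaling is a declared convention: the band could be
defined on any dimensionless scale, and one control SD is the same unit the
hit threshold is built from.

## Synthetic screen generator

The generator emulates a duplicate pilot screen: 1,982 compounds at 9.4 µM
on 16×24 plates (six per replicate), one neutral-control column and one
positive-control column per plate, identical compound placement across
replicates, and

    raw = neutral_mean · (1 − effect) · (1 + positional bias) · noise

with a mean-1 multiplicative lognormal noise model (luminescence is positive
and right-skewed; a Gaussian option exists for calibration studies that
assume symmetric tails). The positional bias is an additive separable
row+column gradient — exactly the artifact the pattern correction claims to
remove, hence easy to assert on.

Default parameters and why:

| parameter | default | rationale |
|---|---|---|
| `neutral_mean` | 10,000 counts | typical plate-reader scale; arbitrary units |
| `neutral_cv` | 0.07 | control-well variability; puts per-plate Z' at ≈ 0.78 with spread 0.63–0.85 |
| `positive_effect` | 0.98 | near-complete inhibition by the positive control (≈ 50-fold) |
| `frac_true_inhibitors` | 0.04 | a ~4% genuine-inhibitor rate, matching a pilot screen of bioactives |
| `inhibitor_effect_range` | (0.30, 0.99) | inhibitors span moderate to complete suppression |
| `background_effect_sd` | 0.06 | reproducible low-level bioactivity of a real library |
| `replicate_noise_cv` | 0.015 | run-to-run repeatability of a compound well; sets r² ≈ 0.94 |
| `plate_gradient_amplitude` | 0.02 | mild positional bias, ±2% of signal |
| dose design | 8 doses, 2-fold from 50 µM | standard confirmatory titration (50 → 0.39 µM) |

Two separate noise scales are a deliberate modelling choice: control columns
sit on the plate edge and empirically run noisier than interior compound
wells, and a single shared CV cannot simultaneously produce Z'-factors near
0.8 (which require σ_control/separation ≈ 0.07) and replicate concordance
r² ≈ 0.94 at a 4% hit rate (which requires compound-well noise well below
the spread of true activities). The split parameterization reproduces both
operating characteristics at once; the calibration suite verifies, over 100
seeds, that ≥ 90% of plates land in the Z' band [0.63, 0.85] and every
seed's r² lies in [0.85, 0.99].

What the generator does *not* emulate — and hence what passing tests do not
establish about real screens: compound chemistry (effects are
phenomenological signal suppressions, not binding models), heavy-tailed
interference artifacts (autofluorescence, quenchers), evaporation fronts or
time-drift within a run, dispense failures, and correlations between a
compound's primary-screen effect and its dose-response parameters beyond the
span. Dose-titration truth for inhibitors draws IC50 log-uniformly from
1–20 µM and Hill slopes from 0.8–2.5, with the span tied to the compound's
screen effect.

Ground truth (true effects, inhibitor status, dose parameters, planted
frequent-hitter status) is written alongside the data and never consumed by
analysis stages. All outputs are byte-identical under a fixed (config, seed).

## Validation problem sizes

The automated suites use: 100 seeds × 6-plate screens for simulator
calibration; 10⁵ compounds for null hit-rate calibration; 1,000 simulated
titrations at 5% CV for 4PL recovery (plus 40 series × 199 resamples for
bootstrap coverage); 1,000 null simulations for rank-test uniformity (KS at
α = 0.01); exhaustive enumeration for the hypergeometric (all N ≤ 30) and
the rank-sum oracle (all C(10,3) placements). These sizes keep the full
suite around a minute while leaving Monte-Carlo margins well clear of the
asserted bounds.

## Known limitations

* Control-anchored hit thresholds are mildly anti-conservative (see above);
  a plate-median-free anchor (e.g. leave-one-out controls) would remove this
  at the cost of complexity.
* The pattern correction estimates positional bias from compound wells only,
  so a bias aligned with the control columns is corrected for compounds but
  not reflected in QC statistics.
* The smoothing fallback reports a point IC50 without an uncertainty
  interval; only converged parametric fits get bootstrap CIs.
* The rank-sum exact path requires tie-free data; with ties it falls back to
  the tie-corrected normal approximation even for small sets.
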