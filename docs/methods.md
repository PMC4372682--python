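# Methods

## Scope and data model

`cagscore` operates on peak-called fragment-analysis exports, never raw
electropherogram signal: the unit of input is a tab-delimited peak table
(sample, tissue, fragment size in bp, peak height), and the unit of
analysis is a `RepeatTrace` — a sparse map from integer CAG repeat length
to peak height for one sample × tissue, with an optional constitutive-
allele annotation. Peak *height* (not area) is the intensity measure
throughout.

Fragment sizes are converted to repeat counts by an explicit linear
calibration anchored on a control DNA of known repeat length, at 3 bp per
repeat unit: `cag = anchor_cag + round((size − anchor_size)/3)`, nearest
integer with half-repeat ties rounding up (toward the longer repeat). The
calibration is always supplied by the user — genotyping runs include sizing
controls, and how a given installation's bins map to repeat counts is not
recoverable from a peak table alone. Rows of one trace that round to the
same repeat count have their heights summed, so total height is conserved.

## Instability scoring

The main allele is the tallest peak (ties toward the smaller repeat).
Peaks below a relative threshold τ of the main-allele height are excluded;
τ defaults to 0.20 and "below" is strict, so a peak at exactly 20% is
retained. The main allele is always retained, as it defines the cutoff.

Retained heights are normalised to weights summing to one, and the
instability index is the weight-by-ΔCAG sum relative to the main allele.
The normalisation runs over the *retained* peaks: this makes the weights a
proper distribution, makes the index equal the sum of its expansion
(ΔCAG > 0) and contraction (ΔCAG < 0) components exactly, and gives the
index its interpretation as the mean repeat-length change of the retained
signal mass. Consequences worth knowing: the index is invariant to
rescaling all heights, equivariant under shifting all repeat lengths, and
the retained set shrinks monotonically as τ grows.

### Pattern metrics

*Distance to longest*: (largest retained repeat) − (constitutive repeat),
floored at 0. Background correction is the same relative threshold τ,
exposed as a parameter since other laboratories may use a different value.

*Distance between modes*: mode detection is not standardised in the
literature, so the rule here is explicit and deterministic. A retained
repeat is a mode candidate when no retained peak strictly within
`min_separation` repeats (default 5) is taller, height ties breaking
toward the smaller repeat; candidates are therefore pairwise at least
`min_separation` apart. The two tallest candidates are reported as the
constitutive and somatically expanded modes; the metric is absent for
unimodal profiles (the tail and striatum patterns). Liver-type bimodal
ladders yield the separation of the constitutive and expanded populations.

The constitutive repeat defaults to the same animal's tail-trace main
allele; when no tail trace is available the trace's own main allele is
used and a warning logged.

## Transmissions

The signed transmission change is offspring minus parental constitutive
repeat. Expansion bias is the percentage of transmissions with a positive
change; unchanged transmissions count in the denominator by default (they
are transmissions that did not expand), with a switch to restrict the
denominator to length-changing events since published denominators are not
always explicit. Summaries use the sample (n−1) SD, matching the
mean ± SD reporting convention.

## Weight and histology traits

Weight traits use three anchor ages — 25, 98 and 169 days (configurable,
since cohort weighing grids are approximate) — with linear interpolation
between weekly weighings. IW/MW/FW are the anchored weights; EWG, FWG and
WG are endpoint differences divided by the window length in days
(73, 71 and 144 days for the default anchors), not regression slopes:
endpoint rates are the standard growth-trait definitions for such cohorts
and reproduce published group values from group-mean endpoints exactly.
A weighing record that does not span an anchor raises an error naming the
missing endpoint rather than extrapolating.

The inclusion fraction is 100 × inclusions / EM48-positive nuclei per
section; the per-mouse value is the unweighted mean over (typically three)
consecutive sections, likewise for DARPP-32 intensity (8-bit scale,
0–255). Group effects are expressed as percent change relative to a
reference group mean.

## Group statistics

`compare_groups` is two-sided and unpaired throughout. With
`method="auto"` each group is screened with Shapiro–Wilk at α = 0.05; the
pooled-variance t test is used when both groups pass, the Mann–Whitney U
test otherwise, and the decision (with both screen p-values) is recorded
in the result and the run log. Constant groups, for which Shapiro–Wilk is
undefined, are treated as failing the screen. No multiple-testing
correction is applied by default (a Bonferroni helper exists).

Sample-size estimation defaults to the closed-form normal approximation
with pooled SD √((sd₁² + sd₂²)/2) and ceiling, floored at n = 2; it is the
conventional quick estimate and reproduces published whole-animal counts.
The noncentral-t option (via statsmodels) solves the exact power equation
and typically returns one more animal per group. Monte-Carlo helpers
(`empirical_power`, `type_i_error_rate`) verify both the power at a
returned n and the t test's null calibration by vectorised simulation.

## Synthetic data

The generator exists so every stage can be exercised and validated without
raw traces, which are not publicly deposited for this kind of study.

**Traces.** A tissue profile specifies the true repeat-length distribution:
tail is a point mass at the constitutive repeat; striatum adds a broad
one-sided expansion tail (discretised gamma over ΔCAG ≥ 1 with the given
mean and SD, weight `expanded_fraction`); liver adds a distinct expanded
mode at a fixed offset (discretised gaussian of width `expansion_sd`).
PCR stutter is modelled as geometric decay on the contraction side only —
the dominant artifact direction for CAG amplification — so each allele
contributes a ladder `mass × decay^k` at k repeats below itself. Peak
heights then receive i.i.d. multiplicative lognormal noise of unit mean
and the profile's CV. Default profiles are calibrated so scored indices
fall near the values reported for 5-month heterozygous knock-in animals
(liver ≈ 12, striatum ≈ 8, tail ≈ 0, in CAG units) — realism targets for
the generator, not evidence about real data. The liver default spreads the
expanded mode (SD 2.5 repeats) rather than concentrating it: a
single-peak expanded mode carrying most of the mass would out-top the
constitutive peak and flip the main-allele call, which contradicts the
strongly positive liver indices the bimodal pattern produces in practice.

`true_index` computes the noise-free expectation of the scored statistic —
the same thresholding and weighted sum applied to the expected heights,
via an independent explicit loop — and is the recovery target for
simulation tests. A caveat the test suite makes explicit: because the 20%
cutoff is a discontinuity, multiplicative measurement noise biases the
scored index by O(cv²) wherever peak mass sits near the cutoff (at
CV 0.1, about −1.5% for the default striatum profile and +2% for liver).
The noiseless recovery is exact to 1e-6; the noisy mean therefore sits a
small, systematic distance from `true_index` that exceeds pure sampling
error once enough traces are averaged. This is a property of
threshold-based instability indices generally, not of the generator.

**Cohorts.** Mouse records are generated over the full genotype ×
chromosome-background × sex grid (default five per cell, mirroring the
ten-per-genotype, sex-matched design such studies use). Weight
trajectories are linear in age with background- and sex-specific
intercepts and slopes set to the published wild-type group means
(e.g. males on the host background: 9.22 g at day 25, 0.133 g/day),
mouse-level normal effects on both (SD 1.8 g and 0.014 g/day), weekly
weighings from day 21 to 175, and 0.3 g measurement noise. Histology
readouts are drawn per mouse from the published group normals (DARPP-32
for all genotypes; inclusion percentages for mutants only, realised as
binomial section counts over ~80–120 EM48-positive nuclei). Mutant
constitutive repeats are uniform over the transmitted 133–149 range.
What the generator does *not* emulate: age dependence, CAG-length
dependence of phenotypes within a cohort, litter effects and
non-normal trait distributions — so passing recovery tests show the
pipeline arithmetic is right, not that real cohorts meet these
distributional assumptions.

**Transmissions.** Each event expands with probability `p_expand`
(default 0.74, the observed paternal bias scale) and contracts otherwise;
magnitudes are a discretised half-normal (scale 3 repeats) floored at one
repeat. This reproduces a bias percentage, not the empirical joint
distribution of change sizes.

All generators take explicit integer seeds; identical seeds give identical
outputs and there is no global RNG state.

## Numerical and degenerate-input choices

- Ties: main allele and mode ties break toward the smaller repeat;
  half-repeat sizing ties round toward the longer repeat. Both are
  documented determinism choices, not field conventions.
- Traces must contain a positive-height peak; all-zero traces, empty row
  sets, mixed-tissue row sets, non-positive repeat counts, negative
  heights and zero-cell histology denominators are errors, reported with
  file line numbers where applicable.
- Equality tolerances in results: weight normalisation and index
  additivity hold to 1e-9 (floating-point summation only); the brute-force
  oracle agreement is asserted at 1e-12 on traces of ≤ 10 peaks.
- Problem sizes in the shipped checks are chosen for seconds-scale
  runtime: 300 random traces for the oracle sweep, 200 traces per tissue
  for recovery, 10,000 replicates for the Monte-Carlo power and type-I
  checks, 500 simulated transmissions, 8 simulated mice per tissue (the
  per-group size typical of such instability cohorts).

## Known limitations

- No stutter correction is applied on the contraction side, so
  contraction indices fold PCR artifact and true contraction together —
  as does the published scoring this implements.
- The threshold-induced noise bias described above means cross-laboratory
  comparisons of indices are only meaningful at a shared threshold and
  comparable noise levels.
- Mode detection assumes at most two biologically meaningful populations;
  tri-modal ladders report the two tallest.
- The sample-size formula assumes normality and equal group sizes; for
  skewed traits (inclusion counts near 0 or 100%) it is only a first
  approximation.
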