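# Methods

## Scope and model

`karyobias` analyses chromosome-specific segregation-error frequencies
after a single error-prone mitosis in diploid cells. The genome is
treated as 23 distinguishable chromosome types (autosomes 1–22 plus X in
a 46,XX karyotype; homologues are indistinguishable in binned
copy-number data), so a chromosome-blind error process assigns each
error to a given type with probability p₀ = 1/23 — the 4.34% null line —
and a cohort of N pooled events gives per-type counts
k_c ~ Binomial(N, p₀) under that null.

The package's organizing hypothesis, which the simulator encodes and the
analysis stages measure, is that mis-segregation probability increases
with a chromosome's radial position in the interphase nucleus.

## Statistical primitives (`stats`)

- **Two-sided binomial test**: exact, minimum-likelihood convention —
  p = Σ P(i) over all outcomes whose point probability is ≤ that of the
  observed count, with relative tolerance 1e-12 on point-probability
  ties. The convention matters in the tails of skewed binomials; the
  central (doubled one-sided) convention would give different p-values,
  and we fix minlike throughout and state it here.
- **Bonferroni**: threshold α/m with m = 23; a test is significant iff
  p < α/m (0.05/23 ≈ 0.0022). p-values are stored at full double
  precision; rounding to two significant figures happens only in report
  formatting.
- **Fisher's exact test** (two-sided, hypergeometric tail summation) and
  **Pearson correlation** (t-transform p with n−2 df) delegate to scipy;
  tests validate both against independent exact-fraction enumeration and
  permutation oracles.
- **Ratio t-test**: a paired comparison of two within-nucleus distances,
  implemented as a one-sample t-test of log(d₁/d₂) against 0. The log
  base does not affect t or p. Degenerate zero-variance input returns
  t = 0, p = 1 when all ratios are 1.

## Synthetic cohorts (`simulate`)

The generator defines the study conditions; its defaults are fixed, not
tuned per experiment.

- **Genome**: chromosome lengths and centromere positions follow the
  human karyotype at a 1-Mb-style grid (≈3,000 bins genome-wide at full
  scale). A proportional `scale` parameter shrinks every chromosome
  (scale 0.2 ≈ 600 bins) for desk-scale cohort work; relative sizes, arm
  ratios and position structure are preserved. Mean radial position
  rises linearly with chromosome size (range 0.30–0.80), with the
  nucleolus-associated acrocentrics 14, 15, 21, 22 shifted 0.18 toward
  the centre; true LAD fraction is an affine function of radial
  position. These choices reproduce the qualitative structure of human
  nuclei — big chromosomes peripheral, acrocentrics central — without
  claiming quantitative fidelity for any one cell line.
- **Error process**: a cell is an error cell with probability
  `p_error_cell` = 0.8; it then receives k ~ zero-truncated Poisson(λ)
  events, λ solved (fixed-point) so the truncated mean is 5.5 events per
  aneuploid cell. Each event's chromosome is drawn with probability
  ∝ exp(β·r_c), where r_c ~ Beta(mean = radial_mean, concentration 8) is
  the cell's radial draw — the minimal one-parameter monotone link, with
  β = 0 exactly uniform (which also models position randomization by a
  monopolar-spindle washout). Default β = 3 gives ~4.5-fold weight range
  across the radial span, enough for clear rank recovery at ~2,400
  events without degenerate landscapes. Events are whole-chromosome with
  probability `p_whole` = 0.8, else arm-anchored partials with a uniform
  breakpoint (telomere-anchored contiguous ranges); direction is a fair
  coin, and a loss that would push any bin below zero copies flips to a
  gain. One daughter per division is emitted (G1-sorted design);
  `p_whole` and the micronucleus entrapment probability `p_mn` = 0.3 are
  exposed defaults, not empirical claims.
- **Sequencing noise**: per-bin counts are gamma-Poisson (negative
  binomial) with mean reads·copies_b/Σcopies and size (dispersion) 20;
  800,000 reads per cell at full scale, 160,000 at scale 0.2 (same
  per-bin depth ≈ 260 for two copies). Micronucleus read sets cover only
  the entrapped segment at ~100 reads per bin, so total MN reads scale
  with segment size as DNA content does.
- **Lamina track**: each chromosome's 100-kb-style bins (10 per analysis
  bin) are laid out as alternating LAD / inter-LAD runs (~20-bin LAD
  runs, exact rounded bin count per chromosome), with log₂(OE) drawn
  from N(+1, 0.4) in LADs and N(−1, 0.4) outside — well separated, as
  lamina DamID contrasts are.
- **Geometry batteries**: labelled fixtures constructed from closed-form
  polygon geometry (regular 64-gon nuclei), with all sampled points kept
  a safe margin away from the 2/3-shell and pole-plane decision
  boundaries so the ground truth is exact; anaphase-outcome cells place
  segregating masses, lagging/bridge/misaligned anomalies and poles in
  regions separable by construction, then apply a random rigid motion.

**What the simulator does not emulate**: GC/mappability bias,
replication timing, read-level artefacts, chromothripsis within
micronuclei, 3D nuclear structure beyond one radial coordinate, z-motion
of tracked kinetochores. Passing tests therefore demonstrate the
correctness and calibration of the algorithms under the stated noise
model, not robustness to every artefact of real libraries or images.

## Copy-number calling (`cnv`)

Per-cell normalization estimates the per-copy depth as the median of
count/baseline over bins (robust to aneuploidy affecting a minority of
bins). Segmentation is an HMM over integer copy states 0..`max_copies`
(default 4), negative-binomial emissions with mean depth·state and
shared size parameter, a self-transition of 0.999 with the remainder
spread uniformly, uniform initial distribution, Viterbi-decoded per
chromosome. The zero state uses an emission mean floor of 0.05× the
per-copy depth to avoid zero-likelihood degeneracy.

Event extraction takes maximal runs of constant non-zero deviation from
the per-bin baseline; runs shorter than `min_bins` = 5 are discarded as
noise; an event covering ≥ 90% of its chromosome (`f_whole` = 0.9) is
whole, otherwise partial with the arm assigned by centromere overlap.
Baseline ploidy is per-bin, so constitutive segmental trisomies (e.g. a
q-arm at three copies) are part of the reference, not called as events.

Two consequences worth knowing:

- **Merging/cancellation**: events that coincide on one chromosome are
  not separable in a copy profile — two same-direction whole-chromosome
  events appear as a single two-copy step, and a gain plus a loss cancel
  entirely. At 5.5 events per aneuploid cell the profile-visible
  alteration rate is therefore systematically below the underlying event
  rate (≈4.6 vs ≈5.4 in a 400-cell measurement). Calling accuracy is
  evaluated against profile-level truth (the same extraction applied to
  noiseless truth profiles), which handles merging consistently on both
  sides.
- **Evidence vs persistence trade-off**: the 0.999 self-transition costs
  ~8.3 log units per state switch. With the sequencing-noise emission
  (size 20) this is what suppresses false blips; on noise-free data the
  correct emission model is near-Poisson (a very large size parameter),
  and short true segments then always win. The noiseless validation runs
  use size 1e6 and `max_copies` = 8 (truth profiles can exceed 4 copies
  when whole-chromosome gains stack).

Viterbi correctness is established against exhaustive path enumeration
on all instances with ≤ 8 bins and ≤ 4 states.

## Landscapes (`landscape`)

The y-axis is the **event share**: each event contributes once and the
denominator is the cohort's total event count, which is the reading
under which the 1/23 null line is exact. (A per-cell-fraction reading
would imply a ~22% null at 5.5 events/cell; the two readings coincide
only approximately, and we implement event shares.) Gains and losses are
pooled for testing — the null concerns which chromosome errs, not the
direction — with the four category counts (lost, gained, partially
lost/gained) retained for reporting. The X chromosome counts as one of
23 types in a 46,XX genome; a 24-type configuration covers XY.

Landscape comparisons are Pearson correlations over per-chromosome
shares, with an explicit exclusion list for chromosomes not quantified
in one condition. FISH-style error frequencies (positive/total
mis-segregating chromosomes) carry exact Clopper–Pearson 95% intervals.

## Micronucleus content (`mn`)

Single-MN presence: a chromosome is present when ≥ 10% of its bins have
at least one read (`min_frac` configurable; the fraction-of-bins rule is
our declared operationalization of a presence heatmap). Samples under 50
reads are excluded as sorter debris and counted in the QC report. A
consequence of the threshold is a detection floor: entrapped fragments
spanning < 10% of their chromosome are invisible, which depresses raw
presence counts by several percent (chromosome-dependent) while leaving
the detected composition within total-variation distance ~0.02 of the
event-share distribution at ~5,000 MN. Against the detection-aware truth
(entrapped events with span ≥ `min_frac`), recovery is exact at the
default MN depth.

Bulk percentages divide each chromosome's summed reads by its bin count
and rescale to 100%. Constitutive trisomic segments are corrected by
dividing the chromosome's MN share by the matched bulk-nuclei
observed/expected ratio, holding corrected chromosomes fixed and
rescaling the rest to 100% — with a diploid nuclei profile the
correction is the identity. Enrichment is log₂(MN share / nuclei share)
against the matched primary-nuclei bulk profile (a uniform-expectation
baseline is available as an option); a chromosome never seen in
micronuclei maps to −∞ and is excluded from correlations.

## Nuclear position (`position`)

Radial distance is 2D: probe centroid to nucleus centre of mass,
normalized by the equivalent radius √(area/π); both absolute (μm) and
relative values are reported. LAD calling is by sign of log₂(OE) with
run filtering: candidate runs shorter than `min_run` = 3 bins (300 kb)
are removed, then sub-`min_run` gaps strictly between surviving runs are
bridged (chromosome-end gaps are not). A threshold rule was chosen over
a two-state HMM for transparency; the threshold and run length are
configurable, and LAD% is monotone in the threshold by construction.

## Mitotic geometry (`geometry`)

All rules operate on 2D maximum-intensity-projection coordinates and are
invariant under rigid motions and pole relabelling.

- **Shells**: the hand-drawn nuclear outline is scaled about its
  centroid by 2/3; central = inside or touching the scaled boundary
  (a small relative tolerance makes "touching" robust to floating-point
  ties). Scaling about the centroid approximates "three equally spaced
  concentric areas" for convex-ish outlines; for a circle it reduces
  exactly to a radius threshold at 2/3 R.
- **Polar**: scalar projection onto the pole–pole axis outside the
  closed [pole1, pole2] segment; pole-coincident points are non-polar
  (boundary convention; measure-zero either way).
- **Elongation peak**: last frame whose two preceding steps both
  increase pole separation and together exceed 1 μm (the "sum" rule,
  default). The sentence defining the rule admits a per-step reading
  (each step > 1 μm); both are implemented and results carry the rule
  identifier.
- **Alignment time**: minutes from NEBD until the kinetochore first
  stays within 1.5 μm of the equatorial plane (perpendicular bisector of
  the pole axis) for ≥ 3 consecutive frames; transient crossings do not
  count; a track that never settles returns an explicit unaligned
  result. The 1.5-μm half-width and 3-frame persistence are our declared
  numeric criterion.
- **Outcomes** (per cell, two poles required; multipolar cells are
  excluded upstream with a logged count): bridge = a pair with both
  kinetochores within 1.5 μm of the midplane and > 1 μm apart;
  lagging = exactly one kinetochore of a pair at the midplane;
  misaligned = a pair with both kinetochores within 1.5 μm of a pole;
  no error otherwise. Precedence bridge → lagging → misaligned.
- **Expected vs observed**: expected polar-misalignment percentage is
  the polar fraction at NEBD; observed is the polar fraction among
  chromosomes unaligned at metaphase start; significance by two-sided
  Fisher on the polar × unaligned 2×2.

## Numerical and design notes

- Event counting is per observed daughter nucleus: a reciprocal
  gain/loss pair across sister cells would count once, matching the
  one-daughter emission of the simulator.
- All genomic intervals are 0-based half-open; all tables are TSV/CSV
  with headers; run configs are YAML with a mandatory seed and rejection
  of unknown keys; per-stage RNGs derive deterministically from the run
  seed, so stages reproduce in isolation and full runs are byte-stable
  (verified by manifest checksums).
- Validation problem sizes: cohort work uses the scale-0.2 genome
  (~600 bins) at matched per-bin depth; per-cell oracle tests run at
  full scale. The familywise-error check combines an exact enumeration
  of the per-test rejection probability (union bound ≤ α,
  deterministic) with a simulated cohort battery judged by a binomial
  consistency envelope — a raw Monte-Carlo point estimate of a quantity
  whose true value is ≈0.042 would spuriously exceed 0.05 in ~5% of
  batteries of 200.

## Known limitations

- No GC or mappability correction; real shallow-WGS counts need one
  upstream of the caller.
- Breakpoints are bin-resolution; no sub-bin refinement, no subclone or
  quality-score model.
- The position-effect form exp(β·r) is a modelling choice constrained
  only by monotonicity; β is not identified separately from the radial
  spread by landscape data alone.
- 2D geometry throughout; kinetochores moving in z are outside the
  model, as is spot detection from pixel data.
- The LAD threshold rule inherits its definition from processed
  log₂(OE) input; raw DamID processing (GATC mapping, normalization) is
  out of scope.
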