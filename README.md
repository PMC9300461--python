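# karyobias

Chromosome mis-segregation is not uniform: when a mitosis goes wrong,
some chromosomes end up gained, lost or trapped in micronuclei far more
often than others, and how often tracks where each chromosome sits in
the interphase nucleus. `karyobias` implements the full analysis chain
for quantifying that bias from single-cell sequencing and live-imaging
data, together with a synthetic-cohort simulator so every stage can be
exercised and validated without any external download.

It is written for researchers studying chromosomal instability,
aneuploidy and micronucleation who work with shallow single-cell
whole-genome sequencing (binned read counts), micronucleus sorting
(MN-seq), DamID-style lamina-contact tracks, FISH centroid measurements
and kinetochore/centrosome tracking.

## What it computes

**Aneuploidy landscapes.** Per-cell binned read counts are segmented by
a negative-binomial-emission hidden Markov model (Viterbi decoding over
integer copy states 0..max); deviations from the baseline karyotype
become whole- or arm-level gain/loss events. Pooling N events over a
cohort gives each chromosome c a share 100·k_c/N, tested against the
uniform null

&nbsp;&nbsp;&nbsp;&nbsp;k_c ~ Binomial(N, p₀), p₀ = 1/23 (null line 100/23 ≈ 4.34%),

with an exact two-sided (minimum-likelihood) binomial test and
Bonferroni correction over the m = 23 chromosome types
(α/m = 0.05/23 ≈ 0.0022).

**Micronucleus content.** Per-micronucleus chromosome presence calls
(fraction of bins covered ≥ 10%), bin-count-normalized bulk percentages,
correction of constitutive segmental trisomies against a matched
bulk-nuclei profile, and per-chromosome log₂(MN share / nuclei share)
enrichment.

**Nuclear position.** LAD calling from log₂(observed/expected) lamina
tracks at 100-kb bins (sign threshold + run filtering), per-chromosome
LAD percentages, probe radial distances normalized by the nucleus
equivalent radius √(area/π), and Pearson correlation of either measure
with error shares.

**Mitotic geometry.** The live-imaging classification rules: central vs
peripheral by the three-concentric-shell rule (central = inside or
touching the 2/3-scaled nuclear outline), polar = projecting outside the
closed pole–pole segment, spindle-elongation peak (last 2-frame run of
increasing pole separation totalling > 1 μm), alignment time to the
metaphase plate, anaphase outcomes (no error / lagging / bridge /
misaligned), and the expected-vs-observed polar-misalignment comparison
with Fisher's exact test.

**Simulator.** Cohorts with position-dependent mis-segregation: each
cell draws per-chromosome radial positions r_c ~ Beta around the
chromosome's mean; an error cell receives k ~ zero-truncated
Poisson(λ) events (λ calibrated so the mean is ≈ 5.5 per aneuploid
cell) with chromosome weights ∝ exp(β·r_c); β = 0 recovers the
uniform null (and models chromosome-position randomization). Read
counts, micronuclei, lamina tracks and geometry fixtures all carry an
exact ground-truth ledger.

## Worked example

```bash
python analysis/01_simulate_cohort.py 1
python analysis/02_call_copy_number.py
python analysis/03_aneuploidy_landscape.py
python analysis/04_micronucleus_content.py
python analysis/05_nuclear_position.py
python analysis/06_mitotic_geometry.py 1
```

prints (seed 1):

```
simulated 200 cells (156 aneuploid), 821 true events (5.26 per aneuploid cell), 250 micronuclei -> results/cohort
154/200 cells aneuploid, 638 called events (4.14/aneuploid cell); event F1 vs truth = 0.973
N=638 events; null line 4.35%; threshold 0.0022; high: ['1', '2', '3']; low: ['21', '22']
250 micronuclei (0 empty excluded); log2 enrichment vs landscape shares: r=0.861, p=1.3e-07
LAD% vs error share over 23 chromosomes: r=0.924, p=3.3e-10
shell/polar accuracy 1.000 (n=1000); outcome accuracy 1.000 (n=200); misaligned-vs-not Fisher p = 1.8e-05
```

Reading the output: the caller recovers the simulated events with
F1 = 0.97; the large, peripheral chromosomes (1–3) mis-segregate
significantly more often than the 4.35% uniform expectation and the
small, centrally located ones (21, 22) significantly less; micronucleus
enrichment and LAD density both correlate strongly with the error
shares, as the position-dependent model predicts; and the geometric
classifiers are exact on labelled fixtures. The called events per
aneuploid cell (4.14) sit below the simulated 5.26 because events that
coincide on one chromosome merge or cancel in the copy profile.

The same stages are available as a CLI (`karyobias
simulate|call|landscape|mn|position|run`) for use on real data in the
standard shapes: BED bin grid, cells×bins TSV count matrix, MN count
TSV, lamina-track TSV, track/centroid CSV.

## Layout

- `src/karyobias/` — library: `stats`, `genome`, `simulate`, `cnv`,
  `landscape`, `mn`, `position`, `geometry`, `io`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers (the worked example above).
- `tests/` — pytest suite with brute-force oracles (exhaustive binomial
  and hypergeometric enumeration, exhaustive Viterbi path scoring,
  permutation nulls) and property tests.
- `docs/methods.md` — model and algorithm documentation.
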