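"""Copy-number caller: normalization, Viterbi vs enumeration, events."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from karyobias.cnv import (
    EventCall,
    HMMParams,
    ZeroCoverageError,
    call_cohort,
    classify_cells,
    evaluate_calls,
    extract_events,
    normalize_cell,
    viterbi_profile,
)
from karyobias.genome import ChromosomeSpec, GenomeSpec
from karyobias.simulate import (
    ErrorModel,
    SequencingModel,
    simulate_cell_errors,
    simulate_cohort,
)


def single_chrom_genome(n_bins, centromere=None):
    return GenomeSpec(
        chromosomes=(
            ChromosomeSpec("A", n_bins=n_bins,
                           centromere_bin=centromere or n_bins // 2),
        )
    )


def viterbi_oracle(counts, depth, params):
    """Best path by exhaustive scoring of all (max_copies+1)^T paths,
    with emission and transition log-probabilities computed directly."""
    n_states = params.max_copies + 1
    mus = [depth * (params.state0_floor if s == 0 else s) for s in range(n_states)]
    size = params.dispersion

    def emis(s, c):
        mu = mus[s]
        return sps.nbinom.logpmf(round(c), size, size / (size + mu))

    log_stay = np.log(params.self_transition)
    log_switch = np.log((1 - params.self_transition) / (n_states - 1))
    best, best_score = None, -np.inf
    for path in itertools.product(range(n_states), repeat=len(counts)):
        score = -np.log(n_states) + emis(path[0], counts[0])
        for t in range(1, len(counts)):
            score += log_stay if path[t] == path[t - 1] else log_switch
            score += emis(path[t], counts[t])
        if score > best_score:
            best, best_score = path, score
    return np.array(best)


class TestNormalize:
    def test_constant_counts_map_to_baseline(self):
        baseline = np.full(100, 2)
        rates, depth = normalize_cell(np.full(100, 84.0), baseline)
        assert depth == pytest.approx(42.0)
        assert np.allclose(rates, 2.0)

    def test_minority_trisomy_keeps_diploid_anchor(self):
        """A trisomic chromosome covering <10% of bins does not shift
        the median-based per-copy depth."""
        baseline = np.full(100, 2)
        counts = np.full(100, 80.0)
        counts[:8] = 120.0  # 3 copies at depth 40
        _, depth = normalize_cell(counts, baseline)
        assert depth == pytest.approx(40.0)

    def test_zero_coverage_rejected(self):
        with pytest.raises(ZeroCoverageError):
            normalize_cell(np.zeros(10), np.full(10, 2))


class TestViterbi:
    def test_noiseless_integer_rates_recovered(self):
        genome = single_chrom_genome(12)
        params = HMMParams(max_copies=4, dispersion=50.0)
        depth = 100.0
        truth = np.array([2, 2, 2, 3, 3, 3, 3, 1, 1, 2, 2, 2])
        counts = truth * depth
        path = viterbi_profile(counts, depth, genome, params)
        assert np.array_equal(path, truth)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        """Viterbi equals brute-force best path on random instances with
        <= 8 bins and <= 4 states."""
        rng = np.random.default_rng(seed)
        n_bins = int(rng.integers(2, 9))
        max_copies = int(rng.integers(1, 4))
        params = HMMParams(
            max_copies=max_copies,
            self_transition=float(rng.uniform(0.6, 0.999)),
            dispersion=float(rng.uniform(5, 50)),
        )
        depth = float(rng.uniform(20, 80))
        counts = rng.integers(0, int(depth * (max_copies + 1)), size=n_bins)
        genome = single_chrom_genome(n_bins)
        got = viterbi_profile(counts.astype(float), depth, genome, params)
        want = viterbi_oracle(counts, depth, params)
        assert np.array_equal(got, want)

    def test_single_gain_recovered_at_depth(self, demo_genome, rng):
        """A whole-chromosome gain at realistic depth is recovered on
        >= 99% of bins."""
        profile = demo_genome.baseline_profile().copy()
        profile[demo_genome.chrom_slices()["7"]] = 3
        from karyobias.simulate import render_read_counts

        seq = SequencingModel(reads_per_cell=160_000)
        counts = render_read_counts(profile, seq, rng)
        rates, depth = normalize_cell(counts, demo_genome.baseline_profile())
        called = viterbi_profile(counts, depth, demo_genome, HMMParams())
        assert (called == profile).mean() >= 0.99


class TestExtractEvents:
    def test_whole_gain(self, toy_genome):
        baseline = toy_genome.baseline_profile()
        profile = baseline.copy()
        profile[toy_genome.chrom_slices()["A"]] = 3
        (event,) = extract_events(profile, baseline, toy_genome)
        assert (event.chrom, event.extent, event.direction) == ("A", "whole", "gain")
        assert (event.copies_from, event.copies_to) == (2, 3)

    def test_partial_q_arm_loss(self):
        genome = single_chrom_genome(20, centromere=8)
        baseline = genome.baseline_profile()
        profile = baseline.copy()
        profile[12:20] = 1  # 40% of bins, entirely q
        (event,) = extract_events(profile, baseline, genome)
        assert (event.extent, event.arm, event.direction) == ("partial", "q", "loss")
        assert (event.start_bin, event.end_bin) == (12, 20)

    def test_short_blip_filtered(self, toy_genome):
        baseline = toy_genome.baseline_profile()
        profile = baseline.copy()
        profile[2:5] = 3  # 3 bins < default min_bins=5
        assert extract_events(profile, baseline, toy_genome) == []

    def test_truth_replay_commutes(self, demo_genome, rng):
        """Extracting events from a noiseless truth profile reproduces the
        simulator's ledger, up to merging/splitting of overlapping
        same-chromosome events."""
        params = HMMParams(min_bins=1)
        baseline = demo_genome.baseline_profile()
        for _ in range(20):
            cell = simulate_cell_errors(demo_genome, ErrorModel(), rng)
            extracted = extract_events(
                cell.profile, baseline, demo_genome, params=params
            )
            # bin-by-bin deviation mass is identical
            dev_truth = cell.profile - baseline
            dev_extracted = np.zeros_like(dev_truth)
            slices = demo_genome.chrom_slices()
            for e in extracted:
                sl = slices[e.chrom]
                dev_extracted[sl.start + e.start_bin : sl.start + e.end_bin] += (
                    e.copies_to - e.copies_from
                )
            assert np.array_equal(dev_truth, dev_extracted)
            # and chromosomes hit coincide exactly
            assert {e.chrom for e in extracted} == {e.chrom for e in cell.events}

    def test_event_call_validation(self):
        with pytest.raises(ValueError):
            EventCall("c", "A", "whole", "spanning", "gain", 5, 5, 2, 3)
        with pytest.raises(ValueError):
            EventCall("c", "A", "whole", "spanning", "gain", 0, 5, 2, 2)


class TestClassifyCells:
    def test_flags_and_summary(self):
        ev = EventCall("c1", "A", "whole", "spanning", "gain", 0, 10, 2, 3)
        flags, summary = classify_cells({"c0": [], "c1": [ev]})
        assert flags.set_index("cell_id")["status"].to_dict() == {
            "c0": "euploid", "c1": "aneuploid"
        }
        assert summary["n_aneuploid"] == 1
        assert summary["mean_events_per_aneuploid_cell"] == 1.0

    def test_called_event_rate_matches_profile_truth(self, demo_genome, rng):
        """The caller's mean events per aneuploid cell equals the rate of
        profile-visible alterations in the truth.

        Coincident events on one chromosome merge (two gains) or cancel
        (a gain plus a loss) in the copy profile, so the profile-level
        rate sits below the underlying event-ledger rate of ~5.5; the
        caller must agree with what the profile can show.
        """
        import pandas as pd

        baseline = demo_genome.baseline_profile()
        depth = 100
        cells = [
            simulate_cell_errors(demo_genome, ErrorModel(), rng, f"c{i}")
            for i in range(60)
        ]
        counts = pd.DataFrame(
            np.vstack([c.profile * depth for c in cells]),
            index=[c.cell_id for c in cells],
        )
        params = HMMParams(dispersion=1e6)
        _, called = call_cohort(counts, demo_genome, params)
        _, called_summary = classify_cells(called)
        truth_extracted = {
            c.cell_id: extract_events(
                c.profile, baseline, demo_genome, c.cell_id, params
            )
            for c in cells
        }
        _, truth_summary = classify_cells(truth_extracted)
        assert called_summary["mean_events_per_aneuploid_cell"] == pytest.approx(
            truth_summary["mean_events_per_aneuploid_cell"], abs=1e-12
        )


class TestEndToEndCalling:
    def test_noiseless_calls_are_exact(self, demo_genome, rng):
        """On noiseless counts (counts = profile x depth) event recovery
        is exact: precision = recall = 1.

        Noise-free data has no overdispersion, so the emission size
        parameter is set large (near-Poisson); the wide default emission
        tuned for sequencing noise would let the 0.999 self-transition
        absorb short true segments.
        """
        import pandas as pd

        depth = 100
        cells = [
            simulate_cell_errors(demo_genome, ErrorModel(), rng, f"c{i}")
            for i in range(30)
        ]
        counts = pd.DataFrame(
            np.vstack([c.profile * depth for c in cells]),
            index=[c.cell_id for c in cells],
        )
        params = HMMParams(dispersion=1e6)
        _, called = call_cohort(counts, demo_genome, params)
        truth_profiles = {c.cell_id: c.profile for c in cells}
        metrics = evaluate_calls(truth_profiles, called, demo_genome, params)
        assert metrics["precision"] == 1.0 and metrics["recall"] == 1.0

    def test_noisy_cohort_f1(self, demo_genome):
        """Event-level F1 >= 0.95 with NB noise at default depth."""
        rng = np.random.default_rng(77)
        cohort = simulate_cohort(
            demo_genome, ErrorModel(),
            SequencingModel(reads_per_cell=160_000),
            n_cells=100, rng=rng, with_micronuclei=False,
        )
        _, called = call_cohort(cohort.counts, demo_genome)
        truth_profiles = {c.cell_id: c.profile for c in cohort.truth.cells}
        metrics = evaluate_calls(truth_profiles, called, demo_genome)
        assert metrics["f1"] >= 0.95
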