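"""Simulator: event statistics, noise models, truth-ledger consistency."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from karyobias.genome import human_genome
from karyobias.simulate import (
    ErrorModel,
    SequencingModel,
    calibrate_lambda,
    make_geometry_battery,
    make_lam_track,
    make_outcome_battery,
    render_read_counts,
    replay_events,
    simulate_cell_errors,
    simulate_cohort,
    spawn_micronuclei,
)


def _collect_events(genome, model, rng, n_events_min):
    events = []
    while len(events) < n_events_min:
        events.extend(simulate_cell_errors(genome, model, rng).events)
    return events


class TestErrorProcess:
    def test_lambda_calibration_closed_form(self):
        lam = calibrate_lambda(5.5)
        assert lam / (1 - np.exp(-lam)) == pytest.approx(5.5, abs=1e-10)

    def test_uniform_shares_under_null(self, demo_genome, rng):
        """With the position effect off, per-chromosome event shares stay
        inside the exact binomial 99% envelope around 1/23."""
        events = _collect_events(demo_genome, ErrorModel(beta=0.0), rng, 10_000)
        n = len(events)
        counts = pd.Series([e.chrom for e in events]).value_counts()
        lo = sps.binom.ppf(0.005, n, 1 / 23)
        hi = sps.binom.ppf(0.995, n, 1 / 23)
        outside = sum(
            not lo <= counts.get(c.name, 0) <= hi
            for c in demo_genome.chromosomes
        )
        # 23 envelopes at 99% each: allow a single chance excursion
        assert outside <= 1

    def test_position_effect_ranks_chromosomes(self, demo_genome, rng):
        """With beta>0 the realized event share tracks mean radial
        position (Spearman >= 0.8 at 10,000 events)."""
        events = _collect_events(demo_genome, ErrorModel(beta=3.0), rng, 10_000)
        counts = pd.Series([e.chrom for e in events]).value_counts()
        shares = np.array(
            [counts.get(c.name, 0) for c in demo_genome.chromosomes], float
        )
        rho = sps.spearmanr(demo_genome.radial_means(), shares).statistic
        assert rho >= 0.8

    def test_mean_events_per_aneuploid_cell(self, demo_genome, rng):
        """Realized event count per aneuploid cell ~5.5 at 1,000 cells."""
        model = ErrorModel()
        cells = [
            simulate_cell_errors(demo_genome, model, rng) for _ in range(1000)
        ]
        per_cell = [len(c.events) for c in cells if c.events]
        assert np.mean(per_cell) == pytest.approx(5.5, abs=0.3)

    def test_profiles_never_negative(self, demo_genome, rng):
        model = ErrorModel(p_whole=0.5, lambda_events=12.0)
        for _ in range(50):
            cell = simulate_cell_errors(demo_genome, model, rng)
            assert cell.profile.min() >= 0

    def test_truth_ledger_replays_to_profile(self, demo_genome, rng):
        for _ in range(30):
            cell = simulate_cell_errors(demo_genome, ErrorModel(), rng)
            assert np.array_equal(
                replay_events(demo_genome, cell.events), cell.profile
            )


class TestReadRendering:
    def test_uniform_profile_uniform_means(self, demo_genome, rng):
        seq = SequencingModel(reads_per_cell=200_000)
        profile = demo_genome.baseline_profile()
        counts = render_read_counts(profile, seq, rng)
        assert counts.sum() == pytest.approx(200_000, rel=0.05)
        assert counts.mean() == pytest.approx(200_000 / profile.size, rel=0.05)

    def test_large_dispersion_is_poisson_limit(self, rng):
        """At huge NB size the variance/mean ratio approaches 1."""
        seq = SequencingModel(reads_per_cell=1, dispersion=1e9)
        profile = np.ones(10_000)
        counts = render_read_counts(profile, seq, rng, total_reads=1_000_000)
        ratio = counts.var() / counts.mean()
        assert 0.9 <= ratio <= 1.1

    def test_trisomic_chromosome_scales_by_half(self, demo_genome, rng):
        profile = demo_genome.baseline_profile().copy()
        sl = demo_genome.chrom_slices()["5"]
        profile[sl] = 3
        counts = render_read_counts(
            profile, SequencingModel(reads_per_cell=2_000_000), rng
        )
        diploid = np.ones(profile.size, bool)
        diploid[sl] = False
        # ~36 bins with NB size 20: the chromosome mean carries ~4% SE
        assert counts[sl].mean() / counts[diploid].mean() == pytest.approx(
            1.5, rel=0.12
        )

    def test_zero_profile_rejected(self, rng):
        with pytest.raises(ValueError):
            render_read_counts(np.zeros(10), SequencingModel(), rng)


class TestMicronuclei:
    def test_pmn_extremes(self, demo_genome, rng):
        model_hit = ErrorModel(p_mn=1.0, p_error_cell=1.0)
        cell = simulate_cell_errors(demo_genome, model_hit, rng)
        seq = SequencingModel()
        assert spawn_micronuclei(
            cell, demo_genome, ErrorModel(p_mn=0.0), seq, rng
        ) == []
        mns = spawn_micronuclei(cell, demo_genome, model_hit, seq, rng)
        assert len(mns) == len(cell.events)

    def test_mn_reads_confined_to_event_range(self, demo_genome, rng):
        model = ErrorModel(p_mn=1.0, p_error_cell=1.0)
        cell = simulate_cell_errors(demo_genome, model, rng)
        slices = demo_genome.chrom_slices()
        for ev_idx, counts in spawn_micronuclei(
            cell, demo_genome, model, SequencingModel(), rng
        ):
            e = cell.events[ev_idx]
            sl = slices[e.chrom]
            mask = np.zeros(demo_genome.n_bins, bool)
            mask[sl.start + e.start_bin : sl.start + e.end_bin] = True
            assert counts[~mask].sum() == 0
            assert counts[mask].sum() > 0


class TestLamTrack:
    def test_exact_fraction_and_components(self, demo_genome, rng):
        track = make_lam_track(demo_genome, rng)
        for spec in demo_genome.chromosomes:
            sub = track[track["chrom"] == spec.name]
            frac = sub["is_lad_true"].mean()
            assert frac == pytest.approx(spec.lad_fraction_true, abs=0.51 / len(sub))
        lads = track[track["is_lad_true"]]["log2oe"]
        inters = track[~track["is_lad_true"]]["log2oe"]
        assert lads.mean() > 0.5 and inters.mean() < -0.5

    def test_fixed_seed_reproducible(self, demo_genome):
        t1 = make_lam_track(demo_genome, np.random.default_rng(5))
        t2 = make_lam_track(demo_genome, np.random.default_rng(5))
        pd.testing.assert_frame_equal(t1, t2)


class TestCohortReproducibility:
    def test_identical_seed_identical_outputs(self, demo_genome):
        kw = dict(n_cells=20)
        c1 = simulate_cohort(
            demo_genome, ErrorModel(), SequencingModel(reads_per_cell=50_000),
            rng=np.random.default_rng(11), **kw
        )
        c2 = simulate_cohort(
            demo_genome, ErrorModel(), SequencingModel(reads_per_cell=50_000),
            rng=np.random.default_rng(11), **kw
        )
        pd.testing.assert_frame_equal(c1.counts, c2.counts)
        assert c1.truth.event_table().equals(c2.truth.event_table())
        assert len(c1.micronuclei) == len(c2.micronuclei)

    def test_mn_ledger_maps_to_events(self, demo_genome, rng):
        cohort = simulate_cohort(
            demo_genome, ErrorModel(p_mn=0.5), SequencingModel(),
            n_cells=30, rng=rng, render_counts=False,
        )
        for cell_idx, ev_idx in cohort.truth.mn_event_index:
            assert ev_idx < len(cohort.truth.cells[cell_idx].events)


class TestGeometryFixtures:
    def test_battery_classes_well_formed(self, rng):
        battery = make_geometry_battery(rng, n_points=100)
        assert set(battery["points"]["true_class"]) <= {"cen", "pol", "NPP"}
        assert battery["poles"].shape == (2, 2)

    def test_outcome_battery_anomaly_counts(self, rng):
        cells = make_outcome_battery(rng, n_cells=40)
        for cell in cells:
            kts = cell["kinetochores"]
            sizes = kts.groupby("pair_id").size()
            assert (sizes <= 2).all()
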