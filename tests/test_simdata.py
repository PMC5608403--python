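"""Generator contracts: traces, composition, rendering identities."""

import numpy as np
import pandas as pd
import pytest

from cyclemap import simdata
from cyclemap.simdata import (
    ConfigurationError, PanelError, ProteinProfileSet, SimConfig,
    SnapshotConfig, TraceModel, sample_trace, simulate_cohort,
    snapshot_population,
)


class TestSimConfig:
    def test_composition_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_cells=10, composition={"CDK2inc": 0.5, "CDK2low": 0.4})

    def test_negative_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_cells=10, composition={"CDK2inc": 1.2, "CDK2low": -0.2})

    def test_unknown_fate_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_cells=10, composition={"weird": 1.0})

    def test_non_integer_frame_count_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_cells=10, frame_interval=11.0)

    def test_default_grid(self):
        cfg = SimConfig(n_cells=10)
        assert cfg.n_frames == 120
        assert np.allclose(np.diff(cfg.times), 0.2)


class TestSampleTrace:
    def test_low_is_constant(self):
        m = TraceModel("CDK2low", low_level=0.3)
        t = np.arange(0, 10, 0.2)
        assert np.allclose(sample_trace(m, t), 0.3)

    def test_emerge_crossing_time(self):
        # 0.3 + 0.25 * (t - 5) reaches 0.5 at t = 5.8 h
        m = TraceModel("CDK2emerge", low_level=0.3, rise_rate=0.25,
                       emerge_delay=5.0)
        t = np.arange(0, 20, 0.01)
        a = sample_trace(m, t)
        crossing = t[np.argmax(a >= 0.5)]
        assert crossing == pytest.approx(5.8, abs=0.02)

    def test_inc_closed_form(self):
        m = TraceModel("CDK2inc", birth_activity=0.6, rise_rate=0.09)
        a = sample_trace(m, np.array([0.0, 16.0]))
        assert a[-1] == pytest.approx(2.04)

    def test_emerge_delay_below_three_hours_rejected(self):
        with pytest.raises(ConfigurationError):
            TraceModel("CDK2emerge", emerge_delay=2.0)

    def test_inc_stays_above_half_pre_noise(self):
        m = TraceModel("CDK2inc", birth_activity=0.55, rise_rate=0.06)
        assert (sample_trace(m, np.arange(0, 23, 0.2)) >= 0.5).all()


class TestSimulateCohort:
    def test_degenerate_composition_all_divide(self):
        cfg = SimConfig(n_cells=50, composition={"CDK2inc": 1.0}, seed=2)
        cohort = simulate_cohort(cfg)
        assert (cohort.lineages.fate == "CDK2inc").all()
        assert (cohort.lineages.anaphase_frame >= 1).all()

    def test_determinism(self):
        cfg = SimConfig(n_cells=30, seed=5)
        a = simulate_cohort(cfg)
        b = simulate_cohort(SimConfig(n_cells=30, seed=5))
        pd.testing.assert_frame_equal(a.cells, b.cells)
        np.testing.assert_array_equal(a.activity, b.activity)

    def test_composition_recovery(self):
        cfg = SimConfig(n_cells=4000, seed=9)
        cohort = simulate_cohort(cfg)
        frac = cohort.lineages.fate.value_counts(normalize=True)
        for fate, p in simdata.DEFAULT_COMPOSITION.items():
            se = np.sqrt(p * (1 - p) / cfg.n_cells)
            assert abs(frac.get(fate, 0.0) - p) < 4 * se + 1e-9, fate

    def test_daughter_masses_within_band(self, small_cohort):
        frac = small_cohort.lineages.daughter_frac.dropna()
        assert ((frac >= 0.45) & (frac <= 0.55)).all()

    def test_prolonged_quiescent_truth_invariant(self, small_cohort):
        cells = small_cohort.cells
        pq = cells[cells.fate == "prolonged_quiescent"]
        for rec in pq.itertuples():
            assert rec.division_frame == -1
            a = small_cohort.activity[rec.cell_id]
            assert np.nanmax(a) < 0.6


class TestRenderer:
    def test_mass_conservation_across_frames(self, small_cohort, small_renderer):
        ren = small_renderer
        mask0 = ren.true_mask(0)
        h2b0, _ = ren.render_frame(0, noisy=False)
        hN, _ = ren.render_frame(small_cohort.n_frames - 1, noisy=False)
        maskN = ren.true_mask(small_cohort.n_frames - 1)
        bg = small_cohort.config.background_level
        for rec in small_cohort.cells.itertuples():
            if rec.birth_frame == 0 and rec.end_frame == small_cohort.n_frames:
                m0 = (h2b0[mask0 == rec.cell_id + 1] - bg).sum()
                mN = (hN[maskN == rec.cell_id + 1] - bg).sum()
                assert mN == pytest.approx(m0, rel=1e-3)

    def test_daughters_sum_to_mother(self, small_cohort, small_renderer):
        ren = small_renderer
        cells = small_cohort.cells
        for rec in cells[cells.division_frame >= 0].itertuples():
            daughters = cells[cells.mother_id == rec.cell_id]
            if len(daughters) != 2:
                continue
            md = ren.h2b_mass[daughters.cell_id.to_numpy()]
            assert md.sum() == pytest.approx(ren.h2b_mass[rec.cell_id], rel=0.01)
            for f in md / ren.h2b_mass[rec.cell_id]:
                assert 0.45 <= f <= 0.55

    def test_construction_identity_single_cell(self):
        # ring mean / nuclear mean equals the configured activity exactly
        cfg = SimConfig(n_cells=1, composition={"prolonged_quiescent": 1.0},
                        noise_sd=0.0, trace_noise_sd=0.0, crowding=0.0, seed=4)
        cohort = simulate_cohort(cfg)
        cohort.activity[:] = 1.0
        ren = simdata.MovieRenderer(cohort)
        _, sensor = ren.render_frame(0, noisy=False)
        pl = ren.pixels[0]
        bg = cfg.background_level
        nuc = sensor.ravel()[pl.nucleus].mean() - bg
        ring = sensor.ravel()[pl.ring] - bg
        top = np.sort(ring)[-int(np.ceil(0.5 * ring.size)):].mean()
        assert top / nuc == pytest.approx(1.0, abs=0.01)

    def test_movie_determinism(self, small_cohort):
        a = simdata.MovieRenderer(small_cohort).render_frame(7)
        b = simdata.MovieRenderer(small_cohort).render_frame(7)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestProteinProfiles:
    def test_group1_proteins_at_baseline_in_quiescence(self):
        p = ProteinProfileSet()
        t = np.linspace(0, 24, 49)
        for protein in ("CyclinA2", "CyclinB1"):
            np.testing.assert_allclose(
                p.expected(protein, "CDK2low", t), ProteinProfileSet.BASELINE)

    def test_all_profiles_nonnegative(self):
        p = ProteinProfileSet()
        t = np.linspace(0, 24, 97)
        for protein in ProteinProfileSet.PROTEINS:
            for fate in simdata.FATES:
                assert (np.asarray(
                    p.expected(protein, fate, t, emerge_delay=6.0)) >= 0).all()

    def test_edu_marks_s_phase_window(self):
        p = ProteinProfileSet()
        lo, hi = simdata.S_PHASE_WINDOW
        assert p.expected("EdU", "CDK2inc", (lo + hi) / 2) > 100
        assert p.expected("EdU", "CDK2inc", lo - 1) < 10
        assert p.expected("EdU", "CDK2inc", hi + 1) < 10
        assert p.expected("EdU", "CDK2low", 12.0) < 10

    def test_quiescent_cyclin_d1_exceeds_cycling_levels(self):
        p = ProteinProfileSet()
        assert p.expected("CyclinD1", "CDK2low", 2.0) > \
            p.expected("CyclinD1", "CDK2inc", 2.0)

    def test_unknown_protein_raises(self):
        with pytest.raises(PanelError):
            ProteinProfileSet().expected("Nonexistin", "CDK2inc", 1.0)


class TestEndpointIF:
    def test_zero_jitter_matches_unshifted(self, small_cohort, small_renderer):
        from dataclasses import replace

        cfg0 = replace(small_cohort.config, jitter_shift=(0, 0))
        cohort0 = simdata.GroundTruthCohort(
            cfg0, small_cohort.cells, small_cohort.lineages,
            small_cohort.activity, small_cohort.models)
        stack, channels, shift, _ = simdata.render_endpoint_if(
            cohort0, ["p21"], renderer=small_renderer)
        assert shift == (0, 0)
        assert channels == ["Hoechst", "p21"]

    def test_unknown_panel_protein(self, small_cohort, small_renderer):
        with pytest.raises(PanelError):
            simdata.render_endpoint_if(small_cohort, ["NotAProtein"],
                                       renderer=small_renderer)

    def test_cdk2low_cyclin_a2_at_baseline(self):
        cfg = SimConfig(n_cells=20, composition={"CDK2low": 1.0}, seed=6)
        cohort = simulate_cohort(cfg)
        truth = cohort.endpoint_truth(["CyclinA2"])
        np.testing.assert_allclose(truth["CyclinA2"],
                                   ProteinProfileSet.BASELINE)


class TestSnapshotPopulation:
    def test_all_g0_population(self):
        cfg = SnapshotConfig(n_cells=300, phase_fractions={"G0": 1.0},
                             noise_log_sd=0.0, seed=1)
        rec, phases = snapshot_population(cfg)
        assert (phases == "G0").all()
        assert (rec.edu < 100).all()
        assert (rec.prb < 100).all()  # hypo-phosphorylated Rb only

    def test_all_mitotic_population(self):
        cfg = SnapshotConfig(n_cells=300, phase_fractions={"M": 1.0},
                             noise_log_sd=0.0, seed=1)
        rec, phases = snapshot_population(cfg)
        assert (rec.phh3 > 100).all()
        assert np.allclose(rec.dna / cfg.dna_2n, 2.0, atol=0.15)

    def test_fraction_validation(self):
        with pytest.raises(ConfigurationError):
            SnapshotConfig(phase_fractions={"G0": 0.5})
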