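"""Snapshot phase gating: DNA normalization, density-valley gates, phase calls."""

import numpy as np
import pandas as pd
import pytest

from cyclemap.gating import (
    GateError, GateSet, NormalizationError, UNASSIGNED, call_phase,
    call_phases, fit_bimodal_gate, fit_gates, normalize_dna,
    phase_histograms,
)
from cyclemap.simdata import SnapshotConfig, snapshot_population


class TestNormalizeDNA:
    def test_single_population_mode_at_one(self):
        rng = np.random.default_rng(0)
        v = rng.normal(5000, 150, 2000)
        scaled, scale = normalize_dna(v)
        assert scale == pytest.approx(5000, rel=0.03)
        assert np.median(scaled) == pytest.approx(1.0, abs=0.05)

    def test_mixture_second_mode_near_two(self):
        rng = np.random.default_rng(1)
        v = np.concatenate([rng.normal(3000, 90, 3000),
                            rng.normal(6000, 180, 1000)])
        scaled, _ = normalize_dna(v)
        hi = scaled[scaled > 1.5]
        assert np.median(hi) == pytest.approx(2.0, abs=0.1)

    def test_constant_input_scales_to_one(self):
        scaled, scale = normalize_dna(np.full(500, 4200.0))
        assert np.allclose(scaled, 1.0)

    def test_too_few_cells(self):
        with pytest.raises(NormalizationError):
            normalize_dna(np.ones(20) * 100)


class TestBimodalGate:
    def test_threshold_between_log_modes(self):
        # equal-weight symmetric mixture: the density valley sits at the
        # midpoint of the modes, 2.0, by symmetry
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(1.0, 0.1, 2000),
                            rng.normal(3.0, 0.1, 2000)])
        thr = fit_bimodal_gate(x)
        assert thr == pytest.approx(2.0, abs=0.2)

    def test_unimodal_raises(self):
        rng = np.random.default_rng(3)
        with pytest.raises(GateError):
            fit_bimodal_gate(rng.normal(2.0, 0.2, 2000))

    @pytest.mark.parametrize("w", [0.2, 0.5, 0.8])
    def test_weight_sweep_keeps_threshold_between_modes(self, w):
        rng = np.random.default_rng(4)
        n = 3000
        x = np.concatenate([rng.normal(1.0, 0.1, int(w * n)),
                            rng.normal(3.0, 0.1, n - int(w * n))])
        thr = fit_bimodal_gate(x)
        assert 1.3 < thr < 2.7


class TestCallPhase:
    GATES = GateSet(edu_neg_max=100.0, edu_high_min=1000.0,
                    prb_threshold=200.0, phh3_threshold=100.0,
                    dna_scale=1000.0)

    @pytest.mark.parametrize("record,expected", [
        ({"dna": 1000, "edu": 30, "prb": 50, "phh3": 20}, "G0"),
        ({"dna": 1000, "edu": 30, "prb": 800, "phh3": 20}, "G1"),
        ({"dna": 2000, "edu": 30, "prb": 800, "phh3": 500}, "M"),
        ({"dna": 2000, "edu": 30, "prb": 800, "phh3": 20}, "G2"),
        ({"dna": 1050, "edu": 300, "prb": 800, "phh3": 20}, "earlyS"),
        ({"dna": 1500, "edu": 3000, "prb": 800, "phh3": 20}, "S"),
        ({"dna": 1900, "edu": 300, "prb": 800, "phh3": 20}, "lateS"),
        ({"dna": 1450, "edu": 300, "prb": 800, "phh3": 20}, UNASSIGNED),
    ])
    def test_decision_tree(self, record, expected):
        assert call_phase(record, self.GATES) == expected

    def test_missing_prb_downgrades(self):
        assert call_phase({"dna": 1000, "edu": 30, "prb": np.nan},
                          self.GATES) == "G0/G1"

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(5)
        recs = pd.DataFrame({
            "dna": rng.uniform(800, 2200, 200),
            "edu": rng.choice([30.0, 300.0, 3000.0], 200),
            "prb": rng.choice([50.0, 800.0], 200),
            "phh3": rng.choice([20.0, 500.0], 200),
        })
        vec = call_phases(recs, self.GATES)
        for i in range(len(recs)):
            assert vec.iloc[i] == call_phase(recs.iloc[i], self.GATES)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        recs = pd.DataFrame({
            "dna": rng.uniform(800, 2200, 100),
            "edu": rng.choice([30.0, 300.0, 3000.0], 100),
            "prb": rng.choice([50.0, 800.0], 100),
            "phh3": rng.choice([20.0, 500.0], 100),
        })
        perm = rng.permutation(100)
        a = call_phases(recs, self.GATES).to_numpy()
        b = call_phases(recs.iloc[perm].reset_index(drop=True),
                        self.GATES).to_numpy()
        np.testing.assert_array_equal(a[perm], b)


class TestEndToEndGating:
    def test_noiseless_population_fully_recovered(self):
        cfg = SnapshotConfig(n_cells=3000, noise_log_sd=0.0, seed=7)
        records, truth = snapshot_population(cfg)
        gates = fit_gates(records)
        phases = call_phases(records, gates)
        acc = (phases.to_numpy() == truth.to_numpy()).mean()
        assert acc == 1.0

    def test_noisy_population_above_95_percent(self):
        cfg = SnapshotConfig(n_cells=3000, noise_log_sd=0.05, seed=8)
        records, truth = snapshot_population(cfg)
        gates = fit_gates(records)
        phases = call_phases(records, gates)
        called = phases != UNASSIGNED
        acc = (phases[called].to_numpy() == truth[called].to_numpy()).mean()
        assert acc >= 0.95


class TestPhaseHistograms:
    def test_p21_shifted_up_in_g0(self):
        cfg = SnapshotConfig(n_cells=4000, poi="p21", seed=9)
        records, truth = snapshot_population(cfg)
        out = phase_histograms(records, truth)
        g0 = out["G0"]
        g1 = out["G1"]
        mean_g0 = np.sum(g0["centers"] * g0["density"]) / g0["density"].sum()
        mean_g1 = np.sum(g1["centers"] * g1["density"]) / g1["density"].sum()
        assert mean_g0 > mean_g1

    def test_single_phase_input(self):
        records = pd.DataFrame({"poi": np.random.default_rng(0).normal(10, 1, 50)})
        phases = pd.Series(["G1"] * 50)
        with pytest.warns(UserWarning):
            out = phase_histograms(records, phases)
        assert out["G1"]["n"] == 50
        assert out["unassigned_fraction"] == 0.0
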