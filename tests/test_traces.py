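"""Fate classification rules, R-point detection, ensemble alignment."""

import numpy as np
import pandas as pd
import pytest

from cyclemap.simdata import SimConfig, TraceModel, sample_trace, simulate_cohort
from cyclemap.traces import (
    ClassifierParams, RPointParams, align_ensemble, classify_trace,
    classify_traces, detect_rpoint,
)

T = np.arange(0, 24, 0.2)
CP = ClassifierParams()


class TestClassifyTrace:
    def test_constant_high_is_inc(self):
        assert classify_trace(T, np.full_like(T, 0.8), 0.0, CP) == "CDK2inc"

    def test_constant_low_is_low(self):
        assert classify_trace(T, np.full_like(T, 0.3), 0.0, CP) == "CDK2low"

    def test_low_then_rise_is_emerge(self):
        a = np.where(T < 4.0, 0.3, 0.3 + 0.2 * (T - 4.0))
        assert classify_trace(T, a, 0.0, CP) == "CDK2emerge"

    def test_prolonged_quiescent_nondividing(self):
        a = np.full_like(T, 0.45)
        a[60] = 0.55  # still below the 0.6 prolonged threshold
        assert classify_trace(T, a, None, CP) == "prolonged_quiescent"

    def test_nondividing_emerge(self):
        a = np.where(T < 10.0, 0.3, 0.3 + 0.25 * (T - 10.0))
        assert classify_trace(T, a, None, CP) == "nondividing_emerge"

    def test_single_dip_unclassified_under_strict_rule(self):
        a = np.full_like(T, 0.8)
        a[5] = 0.49  # one dip at 1 h post-anaphase
        assert classify_trace(T, a, 0.0, CP) == "unclassified"

    def test_early_rise_not_emerge(self):
        # crosses 0.5 already at 1 h: fails the 3 h low-dwell requirement
        a = np.where(T < 1.0, 0.3, 0.8)
        assert classify_trace(T, a, 0.0, CP) == "unclassified"

    def test_short_trace_unclassified(self):
        assert classify_trace(T[:2], np.array([0.3, 0.4]), 0.0, CP) == \
            "unclassified"

    def test_grace_period_variant(self):
        a = np.full_like(T, 0.8)
        a[5] = 0.49
        relaxed = ClassifierParams(grace_period=2.0)
        assert classify_trace(T, a, 0.0, relaxed) == "CDK2inc"

    def test_partition_single_label(self):
        rng = np.random.default_rng(0)
        labels = {"CDK2inc", "CDK2low", "CDK2emerge", "prolonged_quiescent",
                  "nondividing_emerge", "unclassified"}
        for _ in range(50):
            a = np.clip(rng.normal(0.5, 0.3, T.size), 0, None)
            ana = 0.0 if rng.random() < 0.5 else None
            assert classify_trace(T, a, ana, CP) in labels


def oracle_classify(times, activity, anaphase_time, p: ClassifierParams):
    """Literal transcription of the classification predicates."""
    ts, As = [], []
    for t, a in zip(times, activity):
        if np.isfinite(a):
            ts.append(t)
            As.append(a)
    if len(As) < p.rise_confirm:
        return "unclassified"

    def confirmed(seq):
        run = 0
        for x in seq:
            run = run + 1 if x >= p.inc_threshold else 0
            if run >= p.rise_confirm:
                return True
        return False

    if anaphase_time is None:
        if max(As) < p.prolonged_threshold:
            return "prolonged_quiescent"
        if confirmed(As):
            return "nondividing_emerge"
        return "unclassified"
    post = [(t, a) for t, a in zip(ts, As) if t >= anaphase_time]
    if len(post) < p.rise_confirm:
        return "unclassified"
    vals = [a for _, a in post]
    if all(a >= p.inc_threshold for a in vals):
        return "CDK2inc"
    if all(a < p.inc_threshold for a in vals):
        return "CDK2low"
    first_above = next(t for t, a in post if a >= p.inc_threshold)
    if first_above - anaphase_time >= p.emerge_min_low:
        run, start_t = 0, None
        for t, a in post:
            run = run + 1 if a >= p.inc_threshold else 0
            if run == p.rise_confirm:
                start_t = post[[x for x, _ in post].index(t) - p.rise_confirm + 1][0]
                break
        if start_t is not None and start_t - anaphase_time >= p.emerge_min_low:
            return "CDK2emerge"
    return "unclassified"


class TestOracleEquality:
    def test_matches_brute_force_on_random_traces(self):
        rng = np.random.default_rng(42)
        for i in range(1000):
            kind = rng.integers(4)
            if kind == 0:
                a = np.full(T.size, rng.uniform(0.1, 1.2))
            elif kind == 1:
                base = rng.uniform(0.2, 0.45)
                onset = rng.uniform(0, 20)
                a = np.where(T < onset, base,
                             base + rng.uniform(0.05, 0.4) * (T - onset))
            elif kind == 2:
                a = np.clip(rng.normal(0.5, 0.25, T.size), 0, None)
            else:
                a = np.clip(rng.uniform(0.2, 0.8)
                            + rng.normal(0, 0.1, T.size), 0, None)
            ana = None if rng.random() < 0.3 else float(rng.uniform(0, 4))
            got = classify_trace(T, a, ana, CP)
            want = oracle_classify(T, a, ana, CP)
            assert got == want, (i, kind, ana)


class TestRPoint:
    def test_changepoint_recovered(self):
        a = np.where(T < 6.0, 0.3, 0.3 + 0.25 * (T - 6.0))
        r = detect_rpoint(T, a, 0.0)
        assert r == pytest.approx(6.0, abs=0.4)  # within 2 frames

    def test_flat_trace_has_no_rpoint(self):
        assert detect_rpoint(T, np.full_like(T, 0.3), 0.0) is None

    def test_shift_equivariance(self):
        a = np.where(T < 6.0, 0.3, 0.3 + 0.25 * (T - 6.0))
        r0 = detect_rpoint(T, a, 0.0)
        r1 = detect_rpoint(T + 3.0, a, 3.0)
        assert r1 == pytest.approx(r0 + 3.0, abs=1e-9)

    def test_recovery_on_noisy_emerge_traces(self):
        errors = []
        for seed in range(1, 51):
            rng = np.random.default_rng(seed)
            delay = rng.uniform(3.5, 10.0)
            m = TraceModel("CDK2emerge", low_level=0.3,
                           rise_rate=rng.uniform(0.15, 0.3),
                           emerge_delay=delay, noise_sd=0.05)
            a = sample_trace(m, T, rng)
            r = detect_rpoint(T, a, 0.0)
            assert r is not None
            errors.append(abs(r - delay))
        assert np.median(errors) <= 0.8


class TestAlignEnsemble:
    def _table(self):
        rows = []
        for cid, ana in ((1, 12.0), (2, 6.0)):
            for t in T:
                rows.append((cid, t, 0.7))
        df = pd.DataFrame(rows, columns=["cell_id", "time_h", "cdk2_activity"])
        return df

    def test_anchor_at_zero(self):
        ens = align_ensemble(self._table(), {1: 12.0, 2: 6.0})
        t1 = ens.aligned[ens.aligned.cell_id == 1].time_h
        assert t1.min() == pytest.approx(-12.0)
        assert t1.max() == pytest.approx(11.8)

    def test_endpoint_x_is_time_to_fixation(self):
        ens = align_ensemble(self._table(), {1: 12.0, 2: 6.0}, movie_length=24.0)
        assert ens.endpoint_x[1] == pytest.approx(12.0)
        assert ens.endpoint_x[2] == pytest.approx(18.0)

    def test_missing_anchor_excluded(self):
        ens = align_ensemble(self._table(), {1: 12.0, 2: np.nan})
        assert ens.excluded == [2]
        assert set(ens.aligned.cell_id) == {1}


class TestEndToEndAlignment:
    def test_noiseless_cohort_endpoint_x_matches_truth(self):
        cfg = SimConfig(n_cells=40, seed=13, trace_noise_sd=0.0)
        cohort = simulate_cohort(cfg)
        lin = cohort.lineages
        ana = {int(r.lineage_id): float(r.division_time)
               for r in lin.itertuples() if np.isfinite(r.division_time)}
        df = pd.DataFrame({
            "cell_id": list(ana.keys()),
            "time_h": [12.0] * len(ana),
            "cdk2_activity": [0.7] * len(ana),
        })
        ens = align_ensemble(df, ana, movie_length=cfg.duration)
        for cid, at in ana.items():
            assert ens.endpoint_x[cid] == pytest.approx(24.0 - at)


class TestClassifyTraces:
    def test_batch_matches_single(self):
        rows = []
        for t in T:
            rows.append((1, t, 0.8))
            rows.append((2, t, 0.3))
        df = pd.DataFrame(rows, columns=["cell_id", "time_h", "cdk2_activity"])
        fates = classify_traces(df, {1: 0.0, 2: 0.0}, CP)
        assert fates[1] == "CDK2inc" and fates[2] == "CDK2low"
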