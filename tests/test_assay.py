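"""Gating, thresholding, scoring and statistics of the assay chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from nanofield import (AssayError, GateSet, auto_gates, best_voltage,
                       compare_groups, derive_pi_thresholds, gate_events,
                       generate_events, overall_get,
                       permeabilization_fraction, PopulationModel,
                       viability_mts)
from nanofield.assay import _holm_sidak


@pytest.fixture(scope="module")
def population():
    return PopulationModel()


@pytest.fixture(scope="module")
def sham_and_thresholds(population):
    sham = generate_events(population.with_fractions(0.0, 0.02), 10_000, seed=7)
    gates = auto_gates(sham)
    gated = gate_events(sham, gates)
    return sham, gates, gated, derive_pi_thresholds(gated)


class TestGating:
    def test_gated_fraction_matches_design(self, population):
        # 20% debris + 10% doublets -> ~70% should survive both gates
        from dataclasses import replace
        m = replace(population, fractions={
            "debris": 0.2, "live": 0.65, "permeabilized": 0.0,
            "dead": 0.05, "doublet": 0.1})
        ev = generate_events(m, 10_000, seed=11)
        g = gate_events(ev, auto_gates(ev))
        se = np.sqrt(0.7 * 0.3 / 10_000)
        assert abs(len(g) / len(ev) - 0.7) < 3 * se + 0.01

    def test_gating_idempotent(self, sham_and_thresholds):
        sham, gates, gated, _ = sham_and_thresholds
        again = gate_events(gated, gates)
        pd.testing.assert_frame_equal(again, gated)

    def test_clean_singlet_table_passes_unchanged(self):
        ev = pd.DataFrame({"fsc_a": [10.0, 11.0], "fsc_h": [10.0, 11.0],
                           "ssc_a": [5.0, 6.0], "fl": [1.0, 2.0]})
        gates = GateSet(scatter_gate=((0, 0), (100, 0), (100, 100), (0, 100)),
                        singlet_k=1.0)
        pd.testing.assert_frame_equal(gate_events(ev, gates), ev)

    def test_event_on_polygon_vertex_retained(self):
        ev = pd.DataFrame({"fsc_a": [1.0], "fsc_h": [1.0],
                           "ssc_a": [1.0], "fl": [1.0]})
        gates = GateSet(scatter_gate=((1.0, 1.0), (5.0, 1.0), (5.0, 5.0),
                                      (1.0, 5.0)))
        assert len(gate_events(ev, gates)) == 1

    def test_empty_input_gives_empty_output(self):
        ev = pd.DataFrame({c: pd.Series(dtype=float)
                           for c in ("fsc_a", "fsc_h", "ssc_a", "fl")})
        gates = GateSet(scatter_gate=((0, 0), (1, 0), (1, 1), (0, 1)))
        assert len(gate_events(ev, gates)) == 0

    def test_gates_exclude_true_debris_and_doublets(self, population):
        ev = generate_events(population.with_fractions(0.1, 0.05), 20_000,
                             seed=3)
        g = gate_events(ev, auto_gates(ev))
        kept = set(g["true_class"].unique())
        assert "debris" not in kept
        assert "doublet" not in kept


class TestThresholds:
    def test_few_live_events_above_t_low(self, sham_and_thresholds):
        _, _, gated, (t_low, _) = sham_and_thresholds
        live = gated[gated["true_class"] == "live"]
        assert (live["fl"] >= t_low).mean() < 0.01

    def test_log_shift_equivariance(self, sham_and_thresholds):
        sham, gates, gated, (t_low, t_high) = sham_and_thresholds
        shifted = gated.copy()
        shifted["fl"] = shifted["fl"] * 100.0
        s_low, s_high = derive_pi_thresholds(shifted)
        assert s_low == pytest.approx(100 * t_low, rel=1e-9)
        assert s_high == pytest.approx(100 * t_high, rel=1e-9)

    def test_unimodal_sham_uses_fallback(self, population):
        sham = generate_events(population.with_fractions(0.0, 0.0), 5_000,
                               seed=5)
        t_low, t_high = derive_pi_thresholds(sham)
        assert t_high == pytest.approx(30.0 * t_low)

    def test_empty_sham_rejected(self):
        empty = pd.DataFrame({c: pd.Series(dtype=float)
                              for c in ("fsc_a", "fsc_h", "ssc_a", "fl")})
        with pytest.raises(AssayError, match="empty"):
            derive_pi_thresholds(empty)


class TestPartition:
    def test_partition_sums_to_hundred(self, population, sham_and_thresholds):
        *_, thresholds = sham_and_thresholds
        ev = generate_events(population.with_fractions(0.3, 0.05), 10_000,
                             seed=21)
        res = permeabilization_fraction(gate_events(ev, auto_gates(ev)),
                                        thresholds)
        assert res.a1_pct + res.a2_pct + res.a3_pct == pytest.approx(100.0)

    def test_recovers_true_permeabilized_fraction(self, population,
                                                  sham_and_thresholds):
        *_, thresholds = sham_and_thresholds
        ev = generate_events(population.with_fractions(0.30, 0.05), 10_000,
                             seed=42)
        g = gate_events(ev, auto_gates(ev))
        res = permeabilization_fraction(g, thresholds)
        truth = 100 * (g["true_class"] == "permeabilized").mean()
        se = 100 * np.sqrt(0.3 * 0.7 / len(g))
        assert abs(res.a2_pct - truth) < 3 * se + 1.0

    def test_all_below_threshold_is_all_a1(self):
        ev = pd.DataFrame({"fsc_a": [1, 1], "fsc_h": [1, 1],
                           "ssc_a": [1, 1], "fl": [0.1, 0.2]})
        res = permeabilization_fraction(ev, (1.0, 10.0))
        assert (res.a1_pct, res.a2_pct, res.a3_pct) == (100.0, 0.0, 0.0)

    def test_event_exactly_at_t_low_counts_as_a2(self):
        ev = pd.DataFrame({"fsc_a": [1], "fsc_h": [1], "ssc_a": [1],
                           "fl": [1.0]})
        res = permeabilization_fraction(ev, (1.0, 10.0))
        assert res.a2_pct == 100.0


class TestScores:
    def test_viability_normalization(self):
        assert viability_mts(1.0, 1.0) == 100.0
        assert viability_mts(1.04, 1.0) == pytest.approx(104.0)
        assert viability_mts(0.0, 1.0) == 0.0
        with pytest.raises(AssayError):
            viability_mts(1.0, 0.0)

    def test_overall_get_examples(self):
        assert overall_get(40.0, 80.0) == pytest.approx(32.0)
        assert overall_get(0.0, 55.0) == 0.0
        assert overall_get(100.0, 100.0) == 100.0
        with pytest.raises(AssayError):
            overall_get(-1.0, 50.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0, 100), st.floats(0, 110), st.floats(0.1, 3.0))
    def test_overall_get_commutative_and_homogeneous(self, a, b, k):
        assert overall_get(a, b) == pytest.approx(overall_get(b, a))
        assert overall_get(k * a, b) == pytest.approx(k * overall_get(a, b))

    def test_best_voltage_rules(self):
        assert best_voltage([(0, 0.0), (200, 30.0), (250, 46.0),
                             (275, 45.0)]) == 250
        assert best_voltage([(0, 1.0), (100, 2.0), (200, 3.0)]) == 200
        assert best_voltage([(100, 5.0), (50, 5.0)]) == 50  # tie -> lower V
        with pytest.raises(AssayError):
            best_voltage([])


class TestStatistics:
    def test_identical_groups_not_significant(self):
        rep = compare_groups({"ctrl": [1.0, 2.0, 3.0],
                              "trt": [1.0, 2.0, 3.0]})
        assert rep["anova_F"] == 0.0
        assert rep["anova_p"] == 1.0
        assert not rep["comparisons"]["trt"]["significant"]

    def test_holm_sidak_stepdown_values(self):
        adj = _holm_sidak(np.array([0.01, 0.02, 0.2]))
        assert adj == pytest.approx([0.029701, 0.0396, 0.2])

    def test_holm_sidak_monotone_nondecreasing_in_order(self):
        raw = np.array([0.04, 0.011, 0.04, 0.3])
        adj = _holm_sidak(raw)
        order = np.argsort(raw, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_single_replicate_group_rejected(self):
        with pytest.raises(AssayError, match="replicates"):
            compare_groups({"a": [1.0, 2.0], "b": [1.0]})

    def test_familywise_error_controlled_under_null(self):
        # 10,000 simulated null experiments, 4 groups x 3 replicates;
        # vectorised pooled t-tests + the same step-down adjustment
        rng = np.random.default_rng(2024)
        n_rep, k, n = 10_000, 4, 3
        data = rng.normal(size=(n_rep, k, n))
        ctrl = data[:, 0]
        raws = np.empty((n_rep, k - 1))
        for j in range(1, k):
            t, p = stats.ttest_ind(ctrl, data[:, j], axis=1, equal_var=True)
            raws[:, j - 1] = p
        # vectorised step-down Sidak, checked against the scalar routine
        order = np.argsort(raws, axis=1)
        sorted_p = np.take_along_axis(raws, order, axis=1)
        m = k - 1
        exps = m - np.arange(m)
        adj_sorted = np.maximum.accumulate(1 - (1 - sorted_p) ** exps, axis=1)
        adj = np.take_along_axis(adj_sorted, np.argsort(order, axis=1), axis=1)
        for row in range(5):
            assert adj[row] == pytest.approx(_holm_sidak(raws[row]))
        fwer = (adj < 0.05).any(axis=1).mean()
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert fwer <= 0.05 + 3 * se
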