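"""Field metrics on solved scenarios: profiles, membrane increase, thinning
ratio, decay and asymmetry measures."""

import math

import numpy as np
import pytest

from nanofield import (MetricsError, NanoparticleSpec, PlacementMode,
                       ScenarioSpec, asymmetry_index, decay_length,
                       embedded_thinning_ratio, evaluation_line_profile,
                       full_width_half_excess, membrane_field_increase,
                       solve_scenario)
from nanofield.metrics import FieldProfile

from conftest import center_field, profile_of


def flat_profile(value=100.0, n=41):
    x = np.linspace(-200, 200, n)
    return FieldProfile(arc_position_nm=x, field_V_per_cm=np.full(n, value),
                        scenario="synthetic-flat", line="synthetic")


class TestProfiles:
    def test_baseline_profile_nearly_flat(self, solved):
        # no-NP solve sampled on the same line an NP scenario would use
        prof = evaluation_line_profile(solved["gold_disc_r10"].baseline)
        cv = prof.field_V_per_cm.std() / prof.field_V_per_cm.mean()
        # the background tangential field varies as sin(theta) along the
        # line (~2% over +-200 nm at the 45 deg station); nothing NP-like
        assert cv < 0.02

    def test_profile_positions_centred_and_increasing(self, gap_results):
        for res in gap_results.values():
            prof = profile_of(res)
            assert np.all(np.diff(prof.arc_position_nm) > 0)
            n = len(prof.arc_position_nm)
            assert prof.arc_position_nm[n // 2] == 0.0

    def test_silica_beats_gold_beneath_centre_both_radii(self, gap_results):
        for tag in ("r10", "r50"):
            si = center_field(gap_results[f"silica_disc_{tag}"])
            au = center_field(gap_results[f"gold_disc_{tag}"])
            assert si > au

    def test_silica_peak_grows_and_broadens_with_size(self, gap_results):
        p10 = profile_of(gap_results["silica_disc_r10"])
        p50 = profile_of(gap_results["silica_disc_r50"])
        assert p50.field_V_per_cm.max() > p10.field_V_per_cm.max()
        assert (full_width_half_excess(p50) > full_width_half_excess(p10))

    def test_capsule_profile_asymmetric(self, gap_results):
        prof = profile_of(gap_results["gold_capsule"])
        assert asymmetry_index(prof) > 0.01

    def test_embedded_scenario_has_no_gap_line(self, embedded_result):
        with pytest.raises(MetricsError, match="embedded"):
            evaluation_line_profile(embedded_result.solution)


class TestMembraneIncrease:
    def test_identity_is_zero(self, solved):
        res = solved["gold_disc_r10"]
        assert membrane_field_increase(res.solution, res.solution) == 0.0

    def test_all_gap_scenarios_negligible(self, gap_results):
        # conductive NPs slightly *shield* the membrane beneath them
        # (negative change), insulating ones slightly enhance it; either
        # way the effect never reaches 0.3% of the baseline field
        for label, res in gap_results.items():
            inc = res.report["membrane_increase_pct"]
            assert abs(inc) <= 0.3, label

    def test_rejects_embedded_mode(self, embedded_result):
        with pytest.raises(MetricsError, match="gap"):
            membrane_field_increase(embedded_result.solution,
                                    embedded_result.baseline)

    def test_drive_invariance_to_machine_precision(self, builtin):
        from nanofield import assemble_and_solve, default_materials
        from nanofield.metrics import matched_baseline_mesh
        spec = builtin["gold_disc_r10"]
        from nanofield import build_geometry, generate_mesh
        mesh = generate_mesh(build_geometry(spec))
        mesh0 = matched_baseline_mesh(mesh)
        mats = default_materials("gold")
        incs = []
        for drive in (8.0, 16.0):
            s = assemble_and_solve(mesh, mats, drive)
            b = assemble_and_solve(mesh0, mats, drive)
            incs.append(membrane_field_increase(s, b))
        assert abs(incs[1] - incs[0]) < 1e-10


class TestThinningRatio:
    def test_embedded_ratio_exceeds_series_resistor_bound(self, embedded_result):
        ratio = embedded_thinning_ratio(embedded_result.solution,
                                        embedded_result.baseline)
        # 1D series-resistor oracle: 5 nm vs 3 nm in a fixed-current column
        assert ratio > 100 * 5 / 3
        # and the 2D correction is small: the NP surface potential is pinned
        # by the locally flat exterior potential
        assert ratio < 175.0

    def test_shallow_embedding_continuity_with_gap_result(self):
        np_spec = NanoparticleSpec(placement_mode=PlacementMode.EMBEDDED,
                                   embed_depth=0.1e-9)
        res = solve_scenario(ScenarioSpec(label="shallow",
                                          nanoparticle=np_spec))
        ratio = embedded_thinning_ratio(res.solution, res.baseline)
        assert 99.0 < ratio <= 100.5

    def test_rejects_gap_mode(self, gap_results):
        res = gap_results["gold_disc_r50"]
        with pytest.raises(MetricsError, match="embedded"):
            embedded_thinning_ratio(res.solution, res.baseline)


class TestDecay:
    def test_silica_excess_decays_within_five_radii(self, gap_results):
        for tag, radius_nm in (("r10", 10.0), ("r50", 50.0)):
            prof = profile_of(gap_results[f"silica_disc_{tag}"])
            dl = decay_length(prof)
            assert dl is not None
            assert dl < 5 * radius_nm

    def test_silica_excess_monotone_to_plateau(self, gap_results):
        prof = profile_of(gap_results["silica_disc_r10"])
        y = prof.field_V_per_cm
        ipk = int(np.argmax(y))
        ripple = 0.01 * y[ipk]
        right = y[ipk:]
        assert np.all(np.diff(right) <= ripple)
        left = y[:ipk + 1][::-1]
        assert np.all(np.diff(left) <= ripple)

    def test_flat_profile_returns_undefined_marker(self):
        assert decay_length(flat_profile()) is None
        assert full_width_half_excess(flat_profile()) is None


class TestReports:
    def test_reports_complete_for_all_np_scenarios(self, solved):
        for label, res in solved.items():
            if label == "baseline":
                assert res.report is None
                continue
            rep = res.report
            assert rep["scenario"] == label
            assert np.isfinite(rep["baseline_max_membrane_field"])
            assert np.isfinite(rep["with_np_max_membrane_field"])
            if label.endswith("embedded"):
                assert rep["thinning_ratio_pct"] == pytest.approx(
                    rep["thinning_increase_pct"] + 100.0)
            else:
                assert np.isfinite(rep["gap_peak_field"])

    def test_membrane_fields_at_expected_scale(self, solved):
        # 8 V across 80 um induces TMV ~ 1.3 V at the 45 deg station, i.e.
        # a membrane field of ~2.7e6 V/cm -- orders above the gap fields
        rep = solved["gold_disc_r50"].report
        assert 1e6 < rep["baseline_max_membrane_field"] < 1e7
        assert rep["gap_peak_field"] < 0.01 * rep["baseline_max_membrane_field"]
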