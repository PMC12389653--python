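"""Conduction solver: exact solutions, conservation laws, conditioning
treatments, point queries, submodeling."""

import math

import numpy as np
import pytest

from nanofield import (MaterialProps, SolverError, assemble_and_solve,
                       build_geometry, default_materials, extract_submodel,
                       generate_mesh, solve_submodel,
                       treat_conductor_as_equipotential)
from nanofield.geometry import REGION_ID
from nanofield.metrics import matched_baseline_mesh, membrane_field_station

TH0 = math.pi / 4


@pytest.fixture(scope="module")
def uniform_solution(solved):
    """The baseline mesh solved with one conductivity everywhere: the exact
    solution is the parallel-plate slab field U/W."""
    mesh = solved["baseline"].mesh
    mat = MaterialProps(name="uniform", conductivity=1.5)
    mats = {k: mat for k in ("exterior", "membrane", "cytoplasm")}
    return assemble_and_solve(mesh, mats, drive=8.0)


class TestExactness:
    def test_uniform_medium_gives_slab_field(self, uniform_solution):
        geom = uniform_solution.mesh.geom
        E0 = uniform_solution.drive / geom.width
        mag = np.hypot(*uniform_solution.field_vectors.T)
        assert np.abs(mag - E0).max() / E0 < 1e-9

    def test_wall_midheight_field_is_axial(self, uniform_solution):
        geom = uniform_solution.mesh.geom
        E0 = uniform_solution.drive / geom.width
        E = uniform_solution.field_at([[0.0, geom.height / 4]])[0]
        assert E[0] == pytest.approx(E0, rel=1e-9)
        assert abs(E[1]) < 1e-9 * E0

    def test_linearity_in_drive(self, solved):
        mesh = solved["baseline"].mesh
        mats = default_materials()
        s1 = assemble_and_solve(mesh, mats, drive=8.0)
        s2 = assemble_and_solve(mesh, mats, drive=16.0)
        assert np.allclose(s2.potentials, 2 * s1.potentials, rtol=1e-12,
                           atol=1e-15 * 8.0)

    def test_point_query_deterministic(self, solved):
        sol = solved["gold_disc_r10"].solution
        p = [[1e-6, 2e-6]]
        a = sol.field_at(p)
        b = sol.field_at(p)
        assert np.array_equal(a, b)

    def test_point_outside_domain_raises(self, solved):
        sol = solved["baseline"].solution
        with pytest.raises(SolverError, match="outside"):
            sol.field_at([[1.0, 1.0]])


class TestConservation:
    @pytest.mark.parametrize("label", ["baseline", "gold_disc_r50",
                                       "gold_capsule",
                                       "gold_disc_r50_embedded"])
    def test_current_in_equals_current_out(self, solved, label):
        sol = solved[label].solution
        i_in = sol.electrode_current("left")
        i_out = sol.electrode_current("right")
        assert abs(i_in + i_out) / max(abs(i_in), abs(i_out)) < 1e-6

    def test_discrete_maximum_principle(self, solved):
        for res in solved.values():
            sol = res.solution
            lo, hi = -sol.drive / 2, sol.drive / 2
            tol = 1e-6 * sol.drive
            assert sol.potentials.min() >= lo - tol
            assert sol.potentials.max() <= hi + tol

    def test_missing_conductivity_raises(self, solved):
        mesh = solved["gold_disc_r10"].mesh
        mats = default_materials()
        mats.pop("nanoparticle")
        with pytest.raises(SolverError, match="nanoparticle"):
            assemble_and_solve(mesh, mats, drive=8.0)


class TestEquipotentialTreatment:
    def test_matches_full_contrast_on_gap_metrics(self, solved):
        res = solved["gold_disc_r50"]
        eq = treat_conductor_as_equipotential(res.mesh,
                                              default_materials("gold"), 8.0)
        geom = res.mesh.geom
        clear = geom.min_np_membrane_distance()
        n = np.array([math.cos(TH0), math.sin(TH0)])
        pt = [(geom.R + clear / 2) * n]
        full_field = np.hypot(*res.solution.field_at(pt)[0])
        eq_field = np.hypot(*eq.field_at(pt)[0])
        assert abs(eq_field - full_field) / full_field < 1e-3
        wm = membrane_field_station(res.solution, TH0)
        we = membrane_field_station(eq, TH0)
        assert abs(we - wm) / wm < 1e-3

    def test_np_interior_field_is_zero(self, solved):
        res = solved["gold_disc_r10"]
        eq = treat_conductor_as_equipotential(res.mesh,
                                              default_materials("gold"), 8.0)
        inside = eq.mesh.region == REGION_ID["nanoparticle"]
        mag = np.hypot(*eq.field_vectors[inside].T)
        # identically zero up to floating-point cancellation of the shared
        # nodal value against shape-function gradients ~ 1/h
        assert mag.max() <= 1e-9 * 8.0 / eq.mesh.geom.width

    def test_silica_flagged_conductive_is_an_error(self, solved):
        res = solved["silica_disc_r10"]
        with pytest.raises(SolverError, match="not strongly conductive"):
            treat_conductor_as_equipotential(res.mesh,
                                             default_materials("silica"), 8.0)


class TestSubmodeling:
    def test_baseline_submodel_reproduces_global_membrane_field(self, builtin,
                                                                solved):
        # window around the r10 NP, but with the NP removed on both sides:
        # the submodel driven by the global baseline must reproduce the
        # global membrane field in-window
        geom = build_geometry(builtin["gold_disc_r10"])
        sub = extract_submodel(geom)
        sub_mesh = matched_baseline_mesh(generate_mesh(sub))
        glob = solved["gold_disc_r10"]
        base_sol = glob.baseline
        sub_sol = solve_submodel(sub_mesh, base_sol)
        for dth in (-5e-3, 0.0, 5e-3):
            a = membrane_field_station(sub_sol, TH0 + dth)
            b = membrane_field_station(base_sol, TH0 + dth)
            assert abs(a - b) / b < 5e-3

    def test_two_stage_agrees_with_single_stage_np_solve(self, builtin, solved):
        # with the NP present in the window, Dirichlet data from the global
        # NP solve must reproduce the single-mesh gap metrics within 1%
        geom = build_geometry(builtin["gold_disc_r10"])
        sub_mesh = generate_mesh(extract_submodel(geom))
        glob = solved["gold_disc_r10"].solution
        sub_sol = solve_submodel(sub_mesh, glob)
        a = membrane_field_station(sub_sol, TH0)
        b = membrane_field_station(glob, TH0)
        assert abs(a - b) / b < 1e-2

    def test_submodel_requires_window_mesh(self, solved):
        res = solved["gold_disc_r10"]
        with pytest.raises(SolverError, match="window"):
            solve_submodel(res.mesh, res.solution)
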