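"""Implicit-system assembly, oracle equivalence and coupled propagation."""

import numpy as np
import pytest

from emistrand.geometry import (build_strand, membrane_areas, StrandLayout,
                                Spacings, DIR)
from emistrand.channels import ChannelDistribution, assign_gna
from emistrand.ionic import reduced_test_model, StimulusProtocol
from emistrand.solver import PhysicalParameters, assemble, run
from emistrand.fixtures import (DenseReference, make_fixture,
                                tiny_cell_geometry, convergence_suite)
from emistrand.analysis import cell_center_probe, conduction_velocity


PAD = (4e-4, 4e-4, 4e-4)


class TestAssembly:
    def test_parameters_validated(self):
        with pytest.raises(ValueError):
            PhysicalParameters(sigma_e=-1.0)
        with pytest.raises(ValueError):
            PhysicalParameters(rg_factors={0: 0.0})

    def test_unknown_count_matches_layout(self, tiny_two_cell_mesh):
        mesh = tiny_two_cell_mesh
        system = assemble(mesh, PhysicalParameters(), 0.02)
        lab = mesh.label
        n_e = int(((lab == 0) | (lab == DIR) | (lab == 3)).sum())
        n_i = int(((lab == 2) | (lab == 3)).sum())
        n_d = len(mesh.discs)
        assert system.n_unknowns == n_e + n_i + 2 * n_d

    def test_dirichlet_rows_exact_zero(self, tiny_two_cell_mesh):
        system = assemble(tiny_two_cell_mesh, PhysicalParameters(), 0.02)
        rng = np.random.default_rng(3)
        v_star = rng.normal(-70, 10, len(tiny_two_cell_mesh.membrane))
        w_star = rng.normal(0, 1, len(tiny_two_cell_mesh.discs))
        _, _, x = system.implicit_step(v_star, w_star)
        assert np.all(x[system.dirichlet] == 0.0)

    def test_quiescent_state_is_fixed_point(self, tiny_cell_mesh):
        """Uniform v*, zero w: the solve returns u_e = 0, v = v* exactly."""
        system = assemble(tiny_cell_mesh, PhysicalParameters(), 0.02)
        v_star = np.full(len(tiny_cell_mesh.membrane), -80.0)
        w_star = np.zeros(len(tiny_cell_mesh.discs))
        v, w, x = system.implicit_step(v_star, w_star, refine=True)
        assert np.allclose(v, -80.0, atol=1e-9)
        assert np.allclose(x[system.idx_e[tiny_cell_mesh.label == 0]], 0.0,
                           atol=1e-9)


class TestDenseOracle:
    @pytest.mark.parametrize("fixture", ["single_cuboid", "tiny_two_cell"])
    def test_sparse_matches_dense(self, fixture):
        mesh = make_fixture(fixture)
        params = PhysicalParameters(rg_factors={0: 3.0} if len(mesh.discs) else {})
        system = assemble(mesh, params, 0.02)
        dense = DenseReference(mesh, params, 0.02)
        rng = np.random.default_rng(0)
        v_star = rng.normal(-80, 5, len(mesh.membrane))
        w_star = rng.normal(0, 1, len(mesh.discs))
        v1, w1, x1 = system.implicit_step(v_star, w_star, refine=True)
        v2, w2, x2 = dense.implicit_step(v_star, w_star)
        assert np.abs(x1 - x2).max() < 1e-10
        assert np.abs(v1 - v2).max() < 1e-10
        if len(w1):
            assert np.abs(w1 - w2).max() < 1e-10

    def test_zero_input_gives_zero_fields(self, tiny_cell_mesh):
        dense = DenseReference(tiny_cell_mesh, PhysicalParameters(), 0.02)
        v, w, x = dense.implicit_step(np.zeros(len(tiny_cell_mesh.membrane)),
                                      np.zeros(0))
        assert np.abs(x).max() < 1e-14

    def test_passive_trajectory_matches_dense(self, tiny_two_cell_mesh):
        """Linear membrane (I_ion = v/R_m): sparse and dense paths agree."""
        mesh = tiny_two_cell_mesh
        params = PhysicalParameters()
        dt, rm, cm = 0.05, 10.0, params.cm
        system = assemble(mesh, params, dt)
        dense = DenseReference(mesh, params, dt)
        rng = np.random.default_rng(5)
        v_a = rng.normal(-40, 20, len(mesh.membrane))
        v_b = v_a.copy()
        w_a = np.zeros(len(mesh.discs))
        w_b = w_a.copy()
        for _ in range(10):
            v_a = v_a * (1 - dt / (rm * cm))       # explicit ionic half-step
            v_b = v_b * (1 - dt / (rm * cm))
            v_a, w_a, _ = system.implicit_step(v_a, w_a, refine=True)
            v_b, w_b, _ = dense.implicit_step(v_b, w_b)
            assert np.abs(v_a - v_b).max() < 1e-6


class TestCoupledRun:
    def test_resting_run_stays_at_rest(self, tiny_two_cell_mesh, reduced_model):
        mesh = tiny_two_cell_mesh
        quad = membrane_areas(mesh)
        fld = assign_gna(mesh, quad, ChannelDistribution(p=0.0),
                         reduced_model.gbar_na)
        res = run(mesh, PhysicalParameters(), reduced_model, fld, None,
                  0.02, 10.0, quadrature=quad)
        assert np.abs(res.final_state.v - reduced_model.v_rest).max() < 0.5
        assert not np.isfinite(res.activation).any()

    def test_stimulated_neighbour_activates(self, tiny_two_cell_mesh,
                                            reduced_model):
        mesh = tiny_two_cell_mesh
        quad = membrane_areas(mesh)
        fld = assign_gna(mesh, quad, ChannelDistribution(p=0.0),
                         reduced_model.gbar_na)
        res = run(mesh, PhysicalParameters(), reduced_model, fld,
                  StimulusProtocol(cells=(0,)), 0.02, 10.0, quadrature=quad)
        t0 = res.activation[cell_center_probe(mesh, 0)]
        t1 = res.activation[cell_center_probe(mesh, 1)]
        assert np.isfinite(t0) and np.isfinite(t1)
        assert 0 < t1 - t0 < 5.0

    def test_closed_junction_blocks_at_micron_distance(self, tiny_two_cell_mesh,
                                                       reduced_model):
        """Zero disc conductance, micron-scale cleft: no ephaptic rescue."""
        mesh = tiny_two_cell_mesh
        quad = membrane_areas(mesh)
        fld = assign_gna(mesh, quad, ChannelDistribution(p=0.0),
                         reduced_model.gbar_na)
        params = PhysicalParameters(rg_factors={0: np.inf})
        res = run(mesh, params, reduced_model, fld,
                  StimulusProtocol(cells=(0,)), 0.02, 25.0, quadrature=quad)
        act1 = res.activation[mesh.membrane.cell == 1]
        assert not np.isfinite(act1).any()

    def test_determinism(self, tiny_two_cell_mesh, reduced_model):
        mesh = tiny_two_cell_mesh
        quad = membrane_areas(mesh)
        fld = assign_gna(mesh, quad, ChannelDistribution(p=0.0),
                         reduced_model.gbar_na)

        def once():
            return run(mesh, PhysicalParameters(), reduced_model, fld,
                       StimulusProtocol(cells=(0,)), 0.02, 3.0, quadrature=quad)
        a, b = once(), once()
        assert np.array_equal(a.final_state.v, b.final_state.v)
        assert np.array_equal(a.activation, b.activation,  equal_nan=True)

    def test_symmetric_reduction_matches_full_domain(self, reduced_model):
        geo = tiny_cell_geometry()
        acts = []
        for sym in ((), ("y", "z")):
            mesh = build_strand(geo, StrandLayout(2, PAD),
                                Spacings.from_um(2, 2, 2), symmetry=sym)
            quad = membrane_areas(mesh)
            fld = assign_gna(mesh, quad,
                             ChannelDistribution(p=1.0, region="horizontal_ends"),
                             reduced_model.gbar_na)
            res = run(mesh, PhysicalParameters(), reduced_model, fld,
                      StimulusProtocol(cells=(0,)), 0.02, 6.0, quadrature=quad)
            acts.append([res.activation[cell_center_probe(mesh, k)]
                         for k in range(2)])
        assert np.allclose(acts[0], acts[1], atol=1e-9)

    def test_y_z_mirror_symmetry_of_fields(self, tiny_two_cell_mesh,
                                           reduced_model):
        """Symmetric stimulation keeps the potential mirror-symmetric."""
        mesh = tiny_two_cell_mesh
        quad = membrane_areas(mesh)
        fld = assign_gna(mesh, quad, ChannelDistribution(p=0.0),
                         reduced_model.gbar_na)
        res = run(mesh, PhysicalParameters(), reduced_model, fld,
                  StimulusProtocol(cells=(0,)), 0.02, 1.5, quadrature=quad)
        v = np.full(mesh.shape, np.nan)
        v.reshape(-1)[mesh.membrane.flat] = res.final_state.v
        for axis in (1, 2):
            flipped = np.flip(v, axis=axis)
            both = np.isfinite(v) & np.isfinite(flipped)
            assert both.any()
            assert np.abs(v[both] - flipped[both]).max() < 1e-8


class TestConvergence:
    def test_dt_refinement_first_order_and_spatial_monotone(self):
        report = convergence_suite(dts=(0.08, 0.04, 0.02),
                                   spacings_um=(2.0, 1.0))
        acts = np.asarray(report.activation_by_dt)
        assert np.all(np.isfinite(acts))
        errs = np.abs(np.diff(acts))
        assert errs[1] < errs[0]            # converging as dt shrinks
        cvs = np.asarray(report.cv_by_spacing)
        assert np.all(np.isfinite(cvs))
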