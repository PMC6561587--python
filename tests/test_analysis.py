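"""Measurement pipeline on constructed traces and small runs."""

import numpy as np
import pytest

from emistrand import analysis
from emistrand.geometry import membrane_areas
from emistrand.channels import ChannelDistribution, assign_gna
from emistrand.ionic import StimulusProtocol
from emistrand.solver import PhysicalParameters, run


class TestActivationTimes:
    def test_linear_ramp_crossing(self):
        t = np.arange(0, 20.0, 1.0)
        v = -80.0 + 10.0 * t
        out = analysis.activation_times(t, v)
        assert np.isclose(out[0], 8.0)

    def test_flat_trace_never_crosses(self):
        t = np.arange(10.0)
        assert np.isnan(analysis.activation_times(t, np.full(10, -80.0))[0])

    def test_offset_pair_recovers_delay(self):
        t = np.arange(0, 10, 0.05)
        up = lambda t0: -80 + 120 / (1 + np.exp(-(t - t0) / 0.2))
        ta, tb = analysis.activation_times(t, np.vstack([up(3.0), up(3.37)]))
        assert abs((tb - ta) - 0.37) < 0.01

    def test_first_crossing_only(self):
        t = np.arange(0, 20, 0.1)
        v = -50 * np.cos(t)  # upward crossings at pi/2, 5pi/2, ...
        out = analysis.activation_times(t, v, threshold=0.0)
        assert abs(out[0] - np.pi / 2) < 0.05


class TestConductionVelocity:
    def test_arithmetic(self, tiny_two_cell_mesh):
        mesh = tiny_two_cell_mesh
        act = np.full(len(mesh.membrane), np.nan)
        ia = analysis.cell_center_probe(mesh, 0)
        ib = analysis.cell_center_probe(mesh, 1)
        act[ia], act[ib] = 1.0, 1.0 + 0.48
        cv = analysis.conduction_velocity(act, mesh, 0, 1)
        dist_um = (mesh.cell_center_x(1) - mesh.cell_center_x(0)) * 1e4
        assert np.isclose(cv.speed, dist_um * 1e-4 / 0.48 * 1000)
        assert not cv.blocked

    def test_blocked_when_downstream_silent(self, tiny_two_cell_mesh):
        mesh = tiny_two_cell_mesh
        act = np.full(len(mesh.membrane), np.nan)
        act[analysis.cell_center_probe(mesh, 0)] = 1.0
        cv = analysis.conduction_velocity(act, mesh, 0, 1)
        assert cv.blocked and np.isnan(cv.speed)

    def test_reversed_propagation_flagged(self, tiny_two_cell_mesh):
        mesh = tiny_two_cell_mesh
        act = np.full(len(mesh.membrane), np.nan)
        act[analysis.cell_center_probe(mesh, 0)] = 2.0
        act[analysis.cell_center_probe(mesh, 1)] = 1.0
        cv = analysis.conduction_velocity(act, mesh, 0, 1)
        assert cv.reversed and cv.speed > 0


class TestGapDelay:
    def test_identical_flanks_zero_delay(self, tiny_two_cell_mesh):
        mesh = tiny_two_cell_mesh
        ia, ib = analysis.disc_flank_probes(mesh, 0)
        act = np.full(len(mesh.membrane), np.nan)
        act[ia] = act[ib] = 4.2
        assert analysis.gap_delay(act, mesh, 0) == 0.0

    def test_constructed_offset(self, tiny_two_cell_mesh):
        mesh = tiny_two_cell_mesh
        ia, ib = analysis.disc_flank_probes(mesh, 0)
        act = np.full(len(mesh.membrane), np.nan)
        act[ia], act[ib] = 2.0, 3.2
        assert np.isclose(analysis.gap_delay(act, mesh, 0), 1.2)

    def test_block_reported_as_infinite(self, tiny_two_cell_mesh):
        mesh = tiny_two_cell_mesh
        ia, _ = analysis.disc_flank_probes(mesh, 0)
        act = np.full(len(mesh.membrane), np.nan)
        act[ia] = 2.0
        assert analysis.gap_delay(act, mesh, 0) == np.inf

    def test_flank_probes_bracket_the_disc(self, tiny_two_cell_mesh):
        mesh = tiny_two_cell_mesh
        ia, ib = analysis.disc_flank_probes(mesh, 0)
        xd = mesh.xs[mesh.discs.ijk[0, 0]]
        xa = mesh.xs[mesh.membrane.ijk[ia, 0]]
        xb = mesh.xs[mesh.membrane.ijk[ib, 0]]
        assert xa < xd < xb
        assert mesh.membrane.cell[ia] == 0 and mesh.membrane.cell[ib] == 1


class TestUpstrokeVelocity:
    def test_linear_ramp(self):
        t = np.arange(0, 5, 0.1)
        dvdt, mx = analysis.upstroke_velocity(t, -80 + 10 * t)
        assert np.allclose(dvdt, 10.0)
        assert np.isclose(mx, 10.0)

    def test_sine_max_matches_amplitude_times_frequency(self):
        t = np.arange(0, 10, 0.01)
        a, w = 30.0, 2.0
        _, mx = analysis.upstroke_velocity(t, a * np.sin(w * t))
        assert abs(mx - a * w) / (a * w) < 0.01


class TestIntegratedIna:
    def test_zero_current_integrates_to_zero(self, tiny_two_cell_mesh,
                                             reduced_model):
        mesh = tiny_two_cell_mesh
        quad = membrane_areas(mesh)
        fld = assign_gna(mesh, quad, ChannelDistribution(p=0.0), 1e-12)
        res = run(mesh, PhysicalParameters(), reduced_model, fld, None,
                  0.05, 0.5, quadrature=quad, record_ina=True)
        trace, q = analysis.integrated_ina(res, 0)
        assert np.abs(trace).max() < 1e-6
        assert abs(q) < 1e-6

    def test_uniform_density_times_area(self, tiny_cell_mesh, tiny_quad):
        """A constant nodal density integrates to density times A_c."""
        from emistrand.solver import SimulationResult, EmiState
        ina = np.ones(len(tiny_cell_mesh.membrane))
        per_cell = np.zeros(1)
        np.add.at(per_cell, tiny_cell_mesh.membrane.cell, ina * tiny_quad.areas)
        a_c = tiny_quad.cell_area(tiny_cell_mesh, 0)
        assert np.isclose(per_cell[0], a_c)


class TestCleftFit:
    def test_exact_inverse_law(self):
        d = np.array([0.16, 0.08, 0.04, 0.01, 0.005])
        a = analysis.cleft_extremum_fit(d, -0.15 / d)
        assert np.isclose(a, -0.15)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(11)
        d = np.array([0.16, 0.08, 0.04, 0.02, 0.01, 0.005])
        y = -0.15 / d * (1 + rng.normal(0, 0.05, d.size))
        a = analysis.cleft_extremum_fit(d, y)
        assert abs(a - (-0.15)) / 0.15 < 0.10

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            analysis.cleft_extremum_fit(np.array([0.1]), np.array([-1.0]))


def test_metrics_pure_functions_of_saved_data(tmp_path, tiny_two_cell_mesh,
                                              reduced_model):
    """Re-running the analysis on saved output reproduces it bit-for-bit."""
    import h5py
    mesh = tiny_two_cell_mesh
    quad = membrane_areas(mesh)
    fld = assign_gna(mesh, quad, ChannelDistribution(p=0.0),
                     reduced_model.gbar_na)
    res = run(mesh, PhysicalParameters(), reduced_model, fld,
              StimulusProtocol(cells=(0,)), 0.02, 4.0, quadrature=quad,
              probes=[], record_ina=True)
    path = tmp_path / "out.h5"
    res.save(str(path))
    with h5py.File(path) as f:
        act = f["activation"][...]
    cv1 = analysis.conduction_velocity(res.activation, mesh, 0, 1)
    cv2 = analysis.conduction_velocity(act, mesh, 0, 1)
    assert cv1 == cv2
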