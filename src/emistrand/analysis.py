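"""Measurements of conduction from recorded simulation data.

All metrics are pure functions of recorded traces or activation maps:
activation times (first upward crossing of 0 mV, linearly interpolated),
conduction velocity between cell centres, activation-time delay across a
gap junction, upstroke velocity dv/dt, whole-cell integrated sodium current
and the 1/d fit of the junctional-cleft extracellular potential extremum.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .geometry import Mesh
from .solver import SimulationResult


def activation_times(times: np.ndarray, v: np.ndarray,
                     threshold: float = 0.0) -> np.ndarray:
    """First upward-crossing time of ``threshold`` per trace (NaN if never).

    ``v`` has shape (n_times,) for one trace or (n_traces, n_times); crossings
    are located by linear interpolation between the bracketing samples.
    """
    times = np.asarray(times, dtype=float)
    v = np.atleast_2d(np.asarray(v, dtype=float))
    below = v[:, :-1] < threshold
    above = v[:, 1:] >= threshold
    out = np.full(v.shape[0], np.nan)
    for i in range(v.shape[0]):
        hits = np.flatnonzero(below[i] & above[i])
        if hits.size:
            j = hits[0]
            frac = (threshold - v[i, j]) / (v[i, j + 1] - v[i, j])
            out[i] = times[j] + frac * (times[j + 1] - times[j])
    return out if out.size > 1 else out[:1]


def cell_center_probe(mesh: Mesh, k: int) -> int:
    """Membrane-set index of the node probing cell k's centre.

    The membrane node closest (in x) to the cell's x-midpoint, breaking ties
    towards the middle of the cross-section, is used; the membrane potential
    is defined only on the membrane, so the "cell centre" is probed at the
    nearest membrane node of the mid-cell plane.
    """
    mem = mesh.membrane
    sel = np.flatnonzero(mem.cell == k)
    if sel.size == 0:
        raise ValueError(f"cell {k} has no membrane nodes")
    xc = mesh.cell_center_x(k)
    x = mesh.xs[mem.ijk[sel, 0]]
    y = mesh.ys[mem.ijk[sel, 1]]
    z = mesh.zs[mem.ijk[sel, 2]]
    ymid, zmid = mesh.cross_center
    span = mesh.xs[-1] - mesh.xs[0]
    score = np.abs(x - xc) + 1e-4 * (np.abs(z - zmid) + np.abs(y - ymid)) / max(span, 1e-30)
    return int(sel[np.argmin(score)])


def disc_flank_probes(mesh: Mesh, disc_index: int) -> tuple[int, int]:
    """Membrane-set indices of the last node before / first node after a disc."""
    mem = mesh.membrane
    for k, name in ((disc_index, "before"), (disc_index + 1, "after")):
        if not (0 <= k < mesh.n_cells):
            raise ValueError(f"disc {disc_index} has no cell {name} it")
    x = mesh.xs[mem.ijk[:, 0]]
    y = mesh.ys[mem.ijk[:, 1]]
    z = mesh.zs[mem.ijk[:, 2]]
    ymid, zmid = mesh.cross_center
    out = []
    for k, sign in ((disc_index, +1), (disc_index + 1, -1)):
        sel = np.flatnonzero(mem.cell == k)
        xa = x[sel] * sign
        best = xa.max()
        cand = sel[np.abs(xa - best) < 1e-12]
        dist = np.abs(y[cand] - ymid) + np.abs(z[cand] - zmid)
        out.append(int(cand[np.argmin(dist)]))
    return out[0], out[1]


@dataclass(frozen=True)
class ConductionVelocity:
    """Wavefront speed between two cell centres (cm/s)."""

    speed: float            # cm/s, NaN when blocked
    blocked: bool
    reversed: bool          # activation order opposite to cell order
    t_a: float
    t_b: float
    distance: float         # cm


def conduction_velocity(activation: np.ndarray, mesh: Mesh,
                        cell_a: int, cell_b: int) -> ConductionVelocity:
    """Centre-to-centre distance over activation-time difference.

    ``activation`` is the per-membrane-node activation map of a run.  Times
    are read at the two cell-centre probes; a missing activation marks the
    propagation as blocked.
    """
    ia = cell_center_probe(mesh, cell_a)
    ib = cell_center_probe(mesh, cell_b)
    ta, tb = float(activation[ia]), float(activation[ib])
    dist = abs(mesh.cell_center_x(cell_b) - mesh.cell_center_x(cell_a))
    if np.isnan(ta) or np.isnan(tb):
        return ConductionVelocity(np.nan, True, False, ta, tb, dist)
    dt = tb - ta
    rev = dt < 0
    if dt == 0:
        return ConductionVelocity(np.inf, False, False, ta, tb, dist)
    return ConductionVelocity(abs(dist / dt) * 1000.0, False, rev, ta, tb, dist)


def gap_delay(activation: np.ndarray, mesh: Mesh, disc_index: int) -> float:
    """Activation-time difference across a disc (ms); inf when blocked."""
    ia, ib = disc_flank_probes(mesh, disc_index)
    ta, tb = float(activation[ia]), float(activation[ib])
    if np.isnan(ta):
        raise ValueError(f"upstream flank of disc {disc_index} never activated")
    if np.isnan(tb):
        return float("inf")
    return tb - ta


def upstroke_velocity(times: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, float]:
    """dv/dt series (centred differences) and its maximum (mV/ms)."""
    times = np.asarray(times, dtype=float)
    v = np.asarray(v, dtype=float)
    dvdt = np.gradient(v, times)
    return dvdt, float(dvdt.max())


def integrated_ina(result: SimulationResult, cell: int,
                   window: tuple[float, float] | None = None
                   ) -> tuple[np.ndarray, float]:
    """Whole-cell sodium current trace (µA) and its time integral (nC).

    The trace is the quadrature sum of the nodal current densities recorded
    during the run; the integral is trapezoidal over ``window`` (default: the
    whole recording).
    """
    if result.ina_cell is None:
        raise ValueError("run was recorded without per-cell I_Na (record_ina=True)")
    trace = result.ina_cell[:, cell]
    t = result.times
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        t, trace_w = t[sel], trace[sel]
    else:
        trace_w = trace
    return trace, float(np.trapezoid(trace_w, t))


def cleft_extremum_fit(distances: np.ndarray, min_ue: np.ndarray) -> float:
    """Least-squares slope ``a`` of min(u_e) ~ a / d through the origin.

    ``distances`` and the returned coefficient share length units (a in
    mV * length-unit); at least two points are required.
    """
    d = np.asarray(distances, dtype=float)
    y = np.asarray(min_ue, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two distances to fit the 1/d law")
    x = 1.0 / d
    return float((x @ y) / (x @ x))
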