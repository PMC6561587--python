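"""Assembly and time stepping of the coupled cell-based conduction model.

The model couples a Laplace problem for the extracellular potential u_e, one
Laplace problem per cell for the intracellular potential u_i, a capacitive
membrane with ionic currents carrying v = u_i - u_e on every membrane node,
and resistive-capacitive intercalated discs carrying w = u_i(left) -
u_i(right) with passive gap-junction current I_gap = w / R_g.  The outer x/y
boundary of the bath is grounded (u_e = 0); the z faces are insulated.

Discretisation: node-centred finite volumes on the classified lattice.  Every
lattice edge joining two sites that carry the same potential field receives a
conductance sigma * A / h, where A is the edge's transverse cross-section
clipped to the region occupied by that field (computed from the octant map,
so surface-tangential conduction through half and quarter control volumes is
included).  Membrane nodes carry both an intracellular and an extracellular
trace, coupled through the exposed control-volume surface area; disc nodes
carry the two intracellular traces of the abutting cells.  Because each edge
conductance and each interface coupling appears with opposite signs in
exactly two rows, discrete charge is conserved per cell to solver round-off.

Time integration is a two-step operator splitting: the nonlinear membrane
ODEs advance by forward-Euler substeps (the spatial coupling current set to
zero), then a single backward-Euler step of the linear spatial problem
updates u_e, u_i, v and w simultaneously (the ionic current set to zero).
The implicit operator is constant in time and factorised once per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import Mesh, MembraneQuadrature, EXT, DIR, INT, MEM, DISC, _oct_index
from .channels import ConductanceField
from .ionic import IonicModel, StimulusProtocol, ode_substeps


@dataclass(frozen=True)
class PhysicalParameters:
    """Conductivities, capacitances and gap-junction resistance.

    Units: sigma in mS/cm, capacitances in µF/cm^2, r_gap in kOhm cm^2.
    ``rg_factors`` multiplies r_gap per disc index (``np.inf`` closes the
    junction entirely).
    """

    sigma_i: float = 4.0
    sigma_e: float = 20.0
    cm: float = 1.0
    c_disc: float = 0.5
    r_gap: float = 0.0045
    rg_factors: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("sigma_i", "sigma_e", "cm", "c_disc", "r_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for k, f in self.rg_factors.items():
            if not (f > 0):
                raise ValueError(f"gap-junction factor for disc {k} must be > 0 (may be inf)")

    def disc_conductance(self, disc_index: int) -> float:
        """Gap-junction conductance 1/(R_g * factor) in mS/cm^2."""
        f = self.rg_factors.get(disc_index, 1.0)
        return 0.0 if np.isinf(f) else 1.0 / (self.r_gap * f)


@dataclass
class EmiState:
    """Dynamic state: membrane potential, disc potential, ionic state, time."""

    v: np.ndarray           # (n_mem,) mV
    w: np.ndarray           # (n_disc,) mV
    s: np.ndarray           # (n_states, n_mem)
    t: float = 0.0
    solution: np.ndarray | None = None  # last full potential vector


class EmiSystem:
    """Factorised implicit operator plus the index maps to read fields back."""

    def __init__(self, mesh: Mesh, params: PhysicalParameters, dt: float):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.mesh = mesh
        self.params = params
        self.dt = dt
        self._build_indices()
        self._assemble()

    # -- unknown layout -----------------------------------------------------
    def _build_indices(self) -> None:
        mesh = self.mesh
        lab = mesh.label
        shape = mesh.shape
        self.idx_e = np.full(shape, -1, dtype=np.int64)
        self.idx_i = np.full(shape, -1, dtype=np.int64)
        self.idx_d1 = np.full(shape, -1, dtype=np.int64)
        self.idx_d2 = np.full(shape, -1, dtype=np.int64)
        n = 0
        e_sites = (lab == EXT) | (lab == DIR) | (lab == MEM)
        ne = int(e_sites.sum())
        self.idx_e[e_sites] = np.arange(n, n + ne)
        n += ne
        i_sites = (lab == INT) | (lab == MEM)
        ni = int(i_sites.sum())
        self.idx_i[i_sites] = np.arange(n, n + ni)
        n += ni
        d_sites = lab == DISC
        nd = int(d_sites.sum())
        self.idx_d1[d_sites] = np.arange(n, n + nd)
        n += nd
        self.idx_d2[d_sites] = np.arange(n, n + nd)
        n += nd
        self.n_unknowns = n
        self.dirichlet = self.idx_e[lab == DIR]
        if self.dirichlet.size == 0 and ne > 0:
            raise ValueError("no grounded boundary nodes: the extracellular "
                             "problem would be singular")
        mem, dsc = mesh.membrane, mesh.discs
        self.mem_e = self.idx_e.reshape(-1)[mem.flat]
        self.mem_i = self.idx_i.reshape(-1)[mem.flat]
        self.disc_1 = self.idx_d1.reshape(-1)[dsc.flat]
        self.disc_2 = self.idx_d2.reshape(-1)[dsc.flat]

    # -- operator -----------------------------------------------------------
    def _edges(self):
        """Yield (p_slot, q_slot, conductance) arrays per axis/quadrant/field."""
        mesh = self.mesh
        lab = mesh.label
        cid = mesh.cell_id
        halves = [mesh.half_steps(a) for a in range(3)]
        for axis in range(3):
            coords = (mesh.xs, mesh.ys, mesh.zs)[axis]
            d = np.diff(coords)
            nline = len(coords)
            t1, t2 = [a for a in range(3) if a != axis]
            sl_p = [slice(None)] * 3
            sl_q = [slice(None)] * 3
            sl_p[axis] = slice(0, nline - 1)
            sl_q[axis] = slice(1, nline)
            sl_p, sl_q = tuple(sl_p), tuple(sl_q)
            for q1 in (0, 1):
                for q2 in (0, 1):
                    o = _oct_index(axis, 1, t1, q1, t2, q2)
                    region = mesh.octants[o][sl_p]  # band region of each pair
                    h1 = halves[t1][q1] * 0.5
                    h2 = halves[t2][q2] * 0.5
                    area = _outer_on_axes(h1, h2, t1, t2, region.shape, axis, d)
                    yield axis, sl_p, sl_q, region, area["trans"], area["len"]

    def _assemble(self) -> None:
        mesh = self.mesh
        par = self.params
        lab = mesh.label
        cid = mesh.cell_id
        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        vals: list[np.ndarray] = []

        def add(r, c, v):
            rows.append(r)
            cols.append(c)
            vals.append(v)

        def add_edges(p_idx, q_idx, g):
            add(p_idx, p_idx, g)
            add(p_idx, q_idx, -g)
            add(q_idx, q_idx, g)
            add(q_idx, p_idx, -g)

        flat = lambda a: a.reshape(-1)
        for axis, sl_p, sl_q, region, a_trans, h_len in self._edges():
            reg = flat(region)
            at = flat(a_trans)
            hl = flat(h_len)
            lab_p, lab_q = flat(lab[sl_p]), flat(lab[sl_q])
            cid_p, cid_q = flat(cid[sl_p]), flat(cid[sl_q])
            ie_p, ie_q = flat(self.idx_e[sl_p]), flat(self.idx_e[sl_q])
            ii_p, ii_q = flat(self.idx_i[sl_p]), flat(self.idx_i[sl_q])
            d1_p, d1_q = flat(self.idx_d1[sl_p]), flat(self.idx_d1[sl_q])
            d2_p, d2_q = flat(self.idx_d2[sl_p]), flat(self.idx_d2[sl_q])

            # extracellular edges
            m = (reg == -1) & (ie_p >= 0) & (ie_q >= 0) & (at > 0)
            if m.any():
                g = par.sigma_e * at[m] / hl[m]
                add_edges(ie_p[m], ie_q[m], g)

            # intracellular edges of cell reg
            mc = reg >= 0
            if mc.any():
                slot_p = _intra_slot(lab_p, cid_p, ii_p, d1_p, d2_p, reg)
                slot_q = _intra_slot(lab_q, cid_q, ii_q, d1_q, d2_q, reg)
                ok = mc & (slot_p >= 0) & (slot_q >= 0) & (at > 0)
                bad = mc & (at > 0) & ((slot_p < 0) | (slot_q < 0))
                if bad.any():
                    raise AssertionError("intracellular edge without matching unknown slot")
                g = par.sigma_i * at[ok] / hl[ok]
                add_edges(slot_p[ok], slot_q[ok], g)

        # membrane capacitive coupling
        mem = mesh.membrane
        kappa = par.cm * mem.area_fv / self.dt
        add(self.mem_i, self.mem_i, kappa)
        add(self.mem_i, self.mem_e, -kappa)
        add(self.mem_e, self.mem_e, kappa)
        add(self.mem_e, self.mem_i, -kappa)

        # intercalated discs: capacitance + gap-junction conductance
        dsc = mesh.discs
        kc = par.c_disc * dsc.area_fv / self.dt
        gg = np.array([par.disc_conductance(int(k)) for k in dsc.left_cell])
        gam = gg * dsc.area_fv
        add(self.disc_1, self.disc_1, kc + gam)
        add(self.disc_1, self.disc_2, -(kc + gam))
        add(self.disc_2, self.disc_2, kc + gam)
        add(self.disc_2, self.disc_1, -(kc + gam))

        n = self.n_unknowns
        a = sp.coo_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows).astype(np.int64),
              np.concatenate(cols).astype(np.int64))),
            shape=(n, n)).tocsr()
        # grounded boundary rows -> identity
        keep = np.ones(n)
        keep[self.dirichlet] = 0.0
        a = sp.diags(keep) @ a + sp.diags(1.0 - keep)
        a = a.tocsc()
        try:
            self.lu = splu(a)
        except RuntimeError as err:  # pragma: no cover - diagnostic path
            raise RuntimeError(f"implicit operator is singular: {err}") from err
        self.kappa_m = kappa
        self.kc_disc = kc
        self.gamma_disc = gam
        self.matrix = a

    # -- solve --------------------------------------------------------------
    def _rhs(self, v_star: np.ndarray, w_star: np.ndarray) -> np.ndarray:
        b = np.zeros(self.n_unknowns)
        np.add.at(b, self.mem_i, self.kappa_m * v_star)
        np.add.at(b, self.mem_e, -self.kappa_m * v_star)
        np.add.at(b, self.disc_1, self.kc_disc * w_star)
        np.add.at(b, self.disc_2, -self.kc_disc * w_star)
        b[self.dirichlet] = 0.0
        return b

    def implicit_step(self, v_star: np.ndarray, w_star: np.ndarray,
                      refine: bool = False):
        """One backward-Euler solve; returns (v, w, solution vector).

        With ``refine`` one step of iterative refinement is applied: the
        operator mixes bulk-conductance and interface-capacitance scales, and
        the refined residual keeps the per-cell charge balance at round-off
        (used whenever conservation is being monitored).
        """
        b = self._rhs(v_star, w_star)
        x = self.lu.solve(b)
        if refine:
            r = b - self.matrix @ x
            x += self.lu.solve(r)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError("linear solve produced non-finite potentials")
        v = x[self.mem_i] - x[self.mem_e]
        w = x[self.disc_1] - x[self.disc_2]
        return v, w, x

    def charge_balance(self, x: np.ndarray, v_star: np.ndarray,
                       w_star: np.ndarray) -> float:
        """Max over cells of |net intracellular current| / gross |current|.

        The net current is the sum of the discrete flux-balance residuals over
        every row carrying the cell's intracellular potential — the exact
        Kirchhoff sum of transmembrane and disc currents.  The gross current
        normalising it is floored at the charging current of a uniform 1 mV
        step, the smallest physiologically meaningful scale, so quiescent
        cells (where net and gross are both round-off) stay well-posed.
        """
        mesh = self.mesh
        b = self._rhs(v_star, w_star)
        r = b - self.matrix @ x
        v = x[self.mem_i] - x[self.mem_e]
        w = x[self.disc_1] - x[self.disc_2]
        i_mem = self.kappa_m * (v - v_star)                      # µA out of cell
        i_disc = self.kc_disc * (w - w_star) + self.gamma_disc * w
        lab, cid = mesh.label, mesh.cell_id
        worst = 0.0
        for k in range(mesh.n_cells):
            in_cell = mesh.membrane.cell == k
            rows = [self.mem_i[in_cell],
                    self.idx_i[(lab == INT) & (cid == k)],
                    self.disc_1[mesh.discs.left_cell == k],
                    self.disc_2[mesh.discs.left_cell == k - 1]]
            net = sum(r[idx].sum() for idx in rows if idx.size)
            mag = np.abs(i_mem[in_cell]).sum()
            mag += np.abs(i_disc[mesh.discs.left_cell == k]).sum()
            mag += np.abs(i_disc[mesh.discs.left_cell == k - 1]).sum()
            floor = 1e-3 * self.kappa_m[in_cell].sum()
            worst = max(worst, abs(net) / max(mag, floor))
        return worst

    # -- field access -------------------------------------------------------
    def u_e_at(self, x: np.ndarray, mem_index: int) -> float:
        return float(x[self.mem_e[mem_index]])

    def u_i_at(self, x: np.ndarray, mem_index: int) -> float:
        return float(x[self.mem_i[mem_index]])

    def extracellular_values(self, x: np.ndarray) -> np.ndarray:
        sel = np.flatnonzero(self.idx_e.reshape(-1) >= 0)
        return x[self.idx_e.reshape(-1)[sel]]


def _intra_slot(lab, cid, ii, d1, d2, reg):
    """Unknown index carrying cell ``reg``'s potential at each site (-1 if none)."""
    out = np.full(lab.shape, -1, dtype=np.int64)
    m = ((lab == INT) | (lab == MEM)) & (cid == reg)
    out[m] = ii[m]
    md = lab == DISC
    m1 = md & (cid == reg)
    out[m1] = d1[m1]
    m2 = md & (cid + 1 == reg)
    out[m2] = d2[m2]
    return out


def _outer_on_axes(h1, h2, t1, t2, shape, axis, d):
    """Broadcast transverse half-areas and edge lengths to the pair-array shape."""
    tshape = [1, 1, 1]
    a1 = h1.reshape([-1 if i == t1 else 1 for i in range(3)])
    a2 = h2.reshape([-1 if i == t2 else 1 for i in range(3)])
    hl = d.reshape([-1 if i == axis else 1 for i in range(3)])
    trans = np.broadcast_to(a1 * a2, shape)
    length = np.broadcast_to(hl, shape)
    return {"trans": trans, "len": length}


def assemble(mesh: Mesh, params: PhysicalParameters, dt: float,
             quadrature: MembraneQuadrature | None = None) -> EmiSystem:
    """Build and factorise the implicit operator for a mesh and time step.

    The capacitive and flux coupling areas come from the finite-volume
    decomposition of the lattice (exact discrete charge conservation); the
    membrane quadrature weights serve the channel-distribution and analysis
    integrals and are not needed here.
    """
    return EmiSystem(mesh, params, dt)


# ---------------------------------------------------------------------------
# simulation driver


@dataclass
class Probe:
    """A membrane node probed every record interval."""

    name: str
    mem_index: int


@dataclass
class SimulationResult:
    """Recorded traces and summary fields of one run.

    ``activation`` holds the first 0 mV upward-crossing time of every
    membrane node (NaN if never reached), tracked at full time resolution
    during the run.  ``traces`` maps probe name -> dict with keys ``v``,
    ``u_e``, ``u_i`` (mV, at ``times``).
    """

    times: np.ndarray
    traces: dict[str, dict[str, np.ndarray]]
    activation: np.ndarray
    mesh: Mesh
    final_state: EmiState
    ina_cell: np.ndarray | None = None      # (n_times, n_cells) µA
    max_abs_ue: float = 0.0
    balance_max: float | None = None
    meta: dict = field(default_factory=dict)

    def activation_time_at(self, mem_index: int) -> float:
        return float(self.activation[mem_index])

    def save(self, path: str) -> None:
        """Write traces and activation map to an HDF5 container."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("times", data=self.times)
            f.create_dataset("activation", data=self.activation)
            f.attrs["max_abs_ue"] = self.max_abs_ue
            for name, tr in self.traces.items():
                g = f.create_group(f"traces/{name}")
                for key, arr in tr.items():
                    g.create_dataset(key, data=arr)
            if self.ina_cell is not None:
                f.create_dataset("ina_cell", data=self.ina_cell)


def run(mesh: Mesh, params: PhysicalParameters, model: IonicModel,
        conductance: ConductanceField, stim: StimulusProtocol | None,
        dt: float, t_end: float, *,
        quadrature: MembraneQuadrature | None = None,
        dt_ode: float | None = None,
        probes: list[Probe] | None = None,
        record_dt: float | None = None,
        record_ina: bool = False,
        stim_mask: np.ndarray | None = None,
        initial_v: float | None = None,
        check_balance: bool = False,
        stop_when=None,
        system: EmiSystem | None = None) -> SimulationResult:
    """Advance the coupled system from rest and record probes and activation.

    ``dt_ode`` defaults to min(0.001 ms, dt).  ``stim_mask`` optionally
    restricts the stimulus to a subset of membrane nodes (otherwise all
    membrane nodes of the protocol's cells are stimulated).  ``initial_v``
    overrides the resting potential on all membrane nodes (gating states stay
    at rest), used by premature-trigger protocols.  ``stop_when`` is an
    optional callback (state, activation) -> bool checked at record times.
    """
    mem = mesh.membrane
    n_mem = len(mem)
    if dt_ode is None:
        dt_ode = min(0.001, dt)
    v, s = model.initial_state(n_mem)
    if initial_v is not None:
        v[:] = float(initial_v)
    w = np.zeros(len(mesh.discs))
    if system is None:
        system = assemble(mesh, params, dt, quadrature)
    elif system.mesh is not mesh or system.dt != dt:
        raise ValueError("supplied system was assembled for a different mesh "
                         "or time step")

    if stim is not None and stim_mask is None:
        stim_mask = np.isin(mem.cell, np.asarray(stim.cells))
    g_na = conductance.g_na

    probes = probes or []
    record_dt = record_dt or dt
    every = max(1, int(round(record_dt / dt)))
    n_steps = int(round(t_end / dt))

    times = []
    tr: dict[str, dict[str, list]] = {p.name: {"v": [], "u_e": [], "u_i": []}
                                      for p in probes}
    ina_cell: list[np.ndarray] = []
    activation = np.full(n_mem, np.nan)
    max_abs_ue = 0.0
    balance_max = 0.0
    state = EmiState(v=v, w=w, s=s, t=0.0)

    if quadrature is None and record_ina:
        from .geometry import membrane_areas
        quadrature = membrane_areas(mesh)

    def record(x):
        times.append(state.t)
        for p in probes:
            tr[p.name]["v"].append(state.v[p.mem_index])
            if x is not None:
                tr[p.name]["u_e"].append(system.u_e_at(x, p.mem_index))
                tr[p.name]["u_i"].append(system.u_i_at(x, p.mem_index))
            else:
                tr[p.name]["u_e"].append(0.0)
                tr[p.name]["u_i"].append(state.v[p.mem_index])
        if record_ina:
            ina = model.i_na(state.v, state.s, g_na) * quadrature.areas
            per_cell = np.zeros(mesh.n_cells)
            np.add.at(per_cell, mem.cell, ina)
            ina_cell.append(per_cell)

    record(None)
    for n in range(n_steps):
        t0 = state.t
        i_stim = 0.0
        if stim is not None and stim_mask is not None:
            amp = stim.current_density(t0, params.cm)
            if amp != 0.0:
                i_stim = np.where(stim_mask, amp, 0.0)
        v_star, s_new = ode_substeps(model, state.v, state.s, g_na,
                                     dt, dt_ode, params.cm, i_stim, t0)
        v_new, w_new, x = system.implicit_step(v_star, state.w,
                                               refine=check_balance)
        if check_balance:
            balance_max = max(balance_max,
                              system.charge_balance(x, v_star, state.w))
        crossed = (v_new >= 0.0) & (state.v < 0.0) & np.isnan(activation)
        if crossed.any():
            frac = (0.0 - state.v[crossed]) / (v_new[crossed] - state.v[crossed])
            activation[crossed] = t0 + dt * frac
        max_abs_ue = max(max_abs_ue, float(np.abs(system.extracellular_values(x)).max()))
        state = EmiState(v=v_new, w=w_new, s=s_new, t=t0 + dt, solution=x)
        if (n + 1) % every == 0:
            record(x)
            if stop_when is not None and stop_when(state, activation):
                break

    return SimulationResult(
        times=np.asarray(times),
        traces={k: {kk: np.asarray(vv) for kk, vv in d.items()} for k, d in tr.items()},
        activation=activation,
        mesh=mesh,
        final_state=state,
        ina_cell=np.asarray(ina_cell) if record_ina else None,
        max_abs_ue=max_abs_ue,
        balance_max=balance_max if check_balance else None,
        meta={"dt": dt, "dt_ode": dt_ode, "t_end": t_end,
              "model": model.name, "n_cells": mesh.n_cells},
    )
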