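"""Named in-silico protocols: scaled-down reproductions of the study designs.

Each protocol builds its strand or two-cell cleft domain, runs the solver and
reduces the output to the quantities of interest (conduction velocity versus
channel localisation, gap-junction delay versus coupling resistance,
conduction velocity versus cell length, junctional-cleft potentials versus
cell distance, sodium-current dynamics versus cell distance).  Default
problem sizes are desk-scale: strands of 4-7 cells at 2 µm lateral
resolution instead of 10-20 cells at 1 µm; every result dictionary records
the scale actually used.
"""

from __future__ import annotations

import numpy as np

from .geometry import (CellGeometry, StrandLayout, Spacings, Mesh, UM,
                       build_strand, membrane_areas)
from .channels import ChannelDistribution, assign_gna, rescale_for_cell_length
from .ionic import IonicModel, StimulusProtocol, grandi_epicardial
from .solver import PhysicalParameters, Probe, assemble, run
from . import analysis


def _snap_even(x: float) -> float:
    return 2.0 * np.floor(x / 2.0)


def scaled_cell_geometry(body_length_um: float = 100.0) -> CellGeometry:
    """Reference cell with the bump footprint snapped to a 2 µm lattice."""
    lo = float(body_length_um)
    sn_len = 14.0 if lo + 4.0 >= 20.0 else max(lo + 4.0 - 6.0, 0.0)
    sn_len = min(sn_len, lo)
    sn_x0 = _snap_even((lo - sn_len) / 2.0)
    return CellGeometry.from_um((lo, 18, 18), (2, 14, 14), (sn_len, 2, 14),
                                sn_x0=sn_x0)


def strand_mesh(n_cells: int, body_length_um: float = 100.0,
                dx_um: float = 2.0, dy_um: float = 2.0, dz_um: float = 2.0) -> Mesh:
    geo = scaled_cell_geometry(body_length_um)
    return build_strand(geo, StrandLayout(n_cells), Spacings.from_um(dx_um, dy_um, dz_um))


def _strand_cv(mesh, model, dist: ChannelDistribution, params, stim,
               dt, t_end, cell_a, cell_b, extra_margin=0.3, system=None,
               quad=None):
    quad = quad if quad is not None else membrane_areas(mesh)
    fld = assign_gna(mesh, quad, dist, model.gbar_na)
    stop = _margin_stop(mesh, cell_b, extra_margin)
    res = run(mesh, params, model, fld, stim, dt, t_end, quadrature=quad,
              record_dt=10 * dt, stop_when=stop, system=system)
    return analysis.conduction_velocity(res.activation, mesh, cell_a, cell_b), res


def _margin_stop(mesh: Mesh, cell: int, margin_ms: float):
    """Stop a short time after the watched cell's centre activates."""
    probe = analysis.cell_center_probe(mesh, cell)

    def stop(state, activation):
        return np.isfinite(activation[probe]) and state.t > activation[probe] + margin_ms
    return stop


# ---------------------------------------------------------------------------
# protocols


def cv_vs_localization(ps=(0.0, 0.25, 0.5, 0.75, 1.0), *, n_cells: int = 7,
                       model: IonicModel | None = None, dt: float = 0.01,
                       t_end: float = 10.0, sigma_e: float = 20.0,
                       cell_a: int | None = None, cell_b: int | None = None,
                       body_length_um: float = 100.0) -> dict:
    """Conduction velocity for increasing end-localised channel fractions.

    Sweeps the fraction p of sodium channels moved to the lateral cap faces
    and measures CV between two interior cell centres.
    """
    model = model or grandi_epicardial()
    mesh = strand_mesh(n_cells, body_length_um)
    params = PhysicalParameters(sigma_e=sigma_e)
    stim = StimulusProtocol(cells=(0, 1))
    if cell_a is None:
        cell_a = max(2, n_cells // 3) if n_cells >= 4 else 0
    if cell_b is None:
        cell_b = n_cells - 2 if n_cells >= 4 else n_cells - 1
    cell_a, cell_b = min(cell_a, n_cells - 1), min(cell_b, n_cells - 1)
    out = {"p": [], "cv": [], "blocked": [],
           "scale": {"n_cells": n_cells, "dx_um": 2.0, "dt": dt,
                     "model": model.name, "sigma_e": sigma_e,
                     "cells": (cell_a, cell_b)}}
    quad = membrane_areas(mesh)
    system = assemble(mesh, params, dt)  # shared: independent of the channel field
    for p in ps:
        dist = ChannelDistribution(p=float(p), region="horizontal_ends")
        cv, _ = _strand_cv(mesh, model, dist, params, stim, dt, t_end,
                           cell_a, cell_b, system=system, quad=quad)
        out["p"].append(float(p))
        out["cv"].append(cv.speed)
        out["blocked"].append(cv.blocked)
    return out


def delay_vs_rg(factors=(1, 10, 30, 70), *, n_cells: int = 6,
                target_disc: int | None = None,
                model: IonicModel | None = None, dt: float = 0.01,
                t_end: float = 50.0, distributions=("U", "NU"),
                tiny: bool = False) -> dict:
    """Gap-junction delay versus coupling resistance for U and NU channels.

    Multiplies the resistance of one disc by each factor and measures the
    activation delay between the flanking membrane nodes; ``inf`` marks
    block.  ``tiny`` switches to the miniature test cells for second-scale
    qualitative runs.
    """
    model = model or grandi_epicardial()
    if tiny:
        from .fixtures import tiny_cell_geometry
        mesh = build_strand(tiny_cell_geometry(), StrandLayout(n_cells),
                            Spacings.from_um(2, 2, 2))
    else:
        mesh = strand_mesh(n_cells)
    disc = target_disc if target_disc is not None else n_cells // 2 - 1
    quad = membrane_areas(mesh)
    stim = StimulusProtocol(cells=(0, 1))
    out = {"factor": list(map(float, factors)),
           "scale": {"n_cells": n_cells, "disc": disc, "dt": dt,
                     "model": model.name, "tiny": tiny}}
    for name in distributions:
        p = 0.0 if name == "U" else 1.0
        dist = ChannelDistribution(p=p, region="horizontal_ends")
        fld = assign_gna(mesh, quad, dist, model.gbar_na)
        delays = []
        for f in factors:
            params = PhysicalParameters(rg_factors={disc: float(f)})
            stop = _margin_stop(mesh, disc + 1, 1.0)
            res = run(mesh, params, model, fld, stim, dt, t_end,
                      quadrature=quad, record_dt=10 * dt, stop_when=stop)
            delays.append(analysis.gap_delay(res.activation, mesh, disc))
        out[f"delay_{name}"] = delays
    return out


def cv_vs_cell_length(lengths_um=(54.0, 104.0, 154.0, 204.0), *,
                      n_cells: int = 5, model: IonicModel | None = None,
                      dt: float = 0.01, t_end: float = 20.0,
                      distributions=("U", "NU"),
                      cell_a: int | None = None,
                      cell_b: int | None = None) -> dict:
    """Conduction velocity versus cell length at fixed channels per cell.

    Only the body length varies; the conductance density is rescaled with
    the reference cell's membrane area so every cell carries the default
    cell's channel count.  Lengths are total cell lengths (body + caps).
    The first two cells are stimulated and the velocity is measured between
    two downstream cells, avoiding the unloaded last cell; the factorised
    operator is shared between distributions at each length.
    """
    model = model or grandi_epicardial()
    ref_mesh = strand_mesh(1)
    ref_quad = membrane_areas(ref_mesh)
    a_c_default = ref_quad.cell_area(ref_mesh, 0)
    if cell_a is None:
        cell_a = 2
    if cell_b is None:
        cell_b = max(cell_a + 1, n_cells - 2)
    out = {"length_um": list(map(float, lengths_um)),
           "scale": {"n_cells": n_cells, "dt": dt, "model": model.name,
                     "a_c_default_cm2": a_c_default,
                     "cells": (cell_a, cell_b)}}
    stim = StimulusProtocol(cells=(0, 1))
    params = PhysicalParameters()
    cvs = {name: [] for name in distributions}
    for length in lengths_um:
        body = float(length) - 4.0
        mesh = strand_mesh(n_cells, body_length_um=body)
        quad = membrane_areas(mesh)
        system = assemble(mesh, params, dt)
        for name in distributions:
            p = 0.0 if name == "U" else 1.0
            base = ChannelDistribution(p=p, region="horizontal_ends")
            dist = rescale_for_cell_length(base, a_c_default,
                                           quad.cell_area(mesh, 0))
            cv, _ = _strand_cv(mesh, model, dist, params, stim, dt, t_end,
                               cell_a, cell_b, system=system, quad=quad)
            cvs[name].append(cv.speed)
    for name in distributions:
        out[f"cv_{name}"] = cvs[name]
    return out


# ---------------------------------------------------------------------------
# junctional-cleft (ephaptic) protocols


def cleft_geometry(d_nm: float) -> CellGeometry:
    """Reduced two-cell geometry: body 100x12x12 µm, caps (d/2)x4x4 µm."""
    d_um = float(d_nm) * 1e-3
    return CellGeometry.from_um((100, 12, 12), (d_um / 2, 4, 4), (4, 2, 4),
                                sn_x0=48.0)


def cleft_mesh(d_nm: float, *, dx_bulk_um: float = 4.0, dy_um: float = 1.0,
               dz_um: float = 1.0) -> Mesh:
    """Two-cell mesh with the junctional cleft resolved at Δx = d/4.

    The fine spacing is applied across the junctional cleft (the two abutting
    caps plus the extracellular gap between the cell bodies), growing
    geometrically (ratio <= 2) into the bulk spacing elsewhere; the free
    outer cap of each cell is meshed with a single interval.  The mirror
    symmetry of the domain in y and z is exploited: only the upper quarter
    of the cross-section is meshed, with insulated cut planes.
    """
    geo = cleft_geometry(d_nm)
    layout = StrandLayout(2)
    lw = geo.size_we[0]
    cl = geo.cell_length
    px = layout.padding[0]
    fine = lw / 2.0  # d/4 in cm
    windows = [
        (px, px + lw, lw),                            # outer cap, cell 1
        (px + cl - lw, px + cl + lw, fine),           # junctional cleft
        (px + 2 * cl - lw, px + 2 * cl, lw),          # outer cap, cell 2
    ]
    sp = Spacings(dx_bulk_um * UM, dy_um * UM, dz_um * UM,
                  refine_x=[(a, b, h) for (a, b, h) in windows])
    return build_strand(geo, layout, sp, symmetry=("y", "z"))


def _cleft_probe(mesh: Mesh) -> int:
    """Membrane node of cell 2 facing the cleft, centre of the end annulus.

    The probed point sits just downstream of the intercalated disc, on the
    x-normal end face of the second cell's body.
    """
    mem = mesh.membrane
    geo = mesh.geometry
    x_target = mesh.cell_x0[1] + geo.size_we[0]  # body start of cell 2
    sel = np.flatnonzero((mem.cell == 1)
                         & (np.abs(mesh.xs[mem.ijk[:, 0]] - x_target) < 1e-10)
                         & (mem.exposed[:, 0]))
    if sel.size == 0:
        raise ValueError("no membrane node on the downstream cleft face")
    y = mesh.ys[mem.ijk[sel, 1]]
    z = mesh.zs[mem.ijk[sel, 2]]
    # nearest the cap: the inner annulus ring just after the disc
    ymid, zmid = mesh.cross_center
    score = np.abs(y - ymid) + np.abs(z - zmid)
    return int(sel[np.argmin(score)])


def _first_half_mask(mesh: Mesh) -> np.ndarray:
    """Membrane nodes of cell 1 with x below the cell midpoint."""
    mem = mesh.membrane
    xmid = mesh.cell_center_x(0)
    return (mem.cell == 0) & (mesh.xs[mem.ijk[:, 0]] < xmid)


def ephaptic_closed_junction(d_list_nm=(160.0, 80.0, 40.0, 20.0, 10.0, 5.0), *,
                             sigma_e: float = 20.0, distribution: str = "NU",
                             model: IonicModel | None = None,
                             dt: float = 0.01, t_end: float = 15.0,
                             dz_um: float = 1.0,
                             stop_margin: float | None = None) -> dict:
    """Cleft potentials across a fully closed gap junction versus distance.

    Two cells, zero gap-junction conductance, the first half of the first
    cell stimulated; records the minimum extracellular potential, the peak
    membrane and intracellular potentials just downstream of the closed
    disc, and whether the second cell fired.
    """
    model = model or grandi_epicardial()
    out = {"d_nm": list(map(float, d_list_nm)), "min_ue": [], "max_v": [],
           "max_ui": [], "propagated": [],
           "scale": {"dt": dt, "sigma_e": sigma_e, "dz_um": dz_um,
                     "distribution": distribution, "model": model.name}}
    for d in d_list_nm:
        rec = _cleft_run(float(d), sigma_e, distribution, model, dt, t_end,
                         np.inf, dz_um=dz_um, stop_margin=stop_margin)
        out["min_ue"].append(rec["min_ue"])
        out["max_v"].append(rec["max_v"])
        out["max_ui"].append(rec["max_ui"])
        out["propagated"].append(rec["propagated"])
    return out


def _cleft_run(d_nm: float, sigma_e: float, distribution: str,
               model: IonicModel, dt: float, t_end: float,
               rg_factor: float, *, dz_um: float = 1.0,
               record_ina: bool = False,
               stop_margin: float | None = None) -> dict:
    mesh = cleft_mesh(d_nm, dz_um=dz_um)
    quad = membrane_areas(mesh)
    p = 0.0 if distribution == "U" else 1.0
    dist = ChannelDistribution(p=p, region="vertical_ends")
    fld = assign_gna(mesh, quad, dist, model.gbar_na)
    params = PhysicalParameters(sigma_e=sigma_e, rg_factors={0: rg_factor})
    stim = StimulusProtocol(cells=(0,))
    probe_down = _cleft_probe(mesh)
    up_mem = mesh.membrane
    # matching upstream probe: end annulus of cell 1
    x_up = mesh.cell_x0[0] + mesh.geometry.cell_length - mesh.geometry.size_we[0]
    sel = np.flatnonzero((up_mem.cell == 0)
                         & (np.abs(mesh.xs[up_mem.ijk[:, 0]] - x_up) < 1e-10)
                         & (up_mem.exposed[:, 1]))
    probe_up = int(sel[0]) if sel.size else probe_down
    stop = None
    if stop_margin is not None:
        def stop(state, activation):
            t_up = activation[probe_up]
            t_dn = activation[probe_down]
            if np.isfinite(t_dn) and state.t > t_dn + stop_margin:
                return True
            return np.isfinite(t_up) and state.t > t_up + stop_margin
    res = run(mesh, params, model, fld, stim, dt, t_end,
              quadrature=quad, stim_mask=_first_half_mask(mesh),
              probes=[Probe("down", probe_down), Probe("up", probe_up)],
              record_dt=dt, record_ina=record_ina, stop_when=stop)
    tr = res.traces["down"]
    fired = bool(np.isfinite(res.activation[mesh.membrane.cell == 1]).any())
    return {
        "mesh": mesh, "result": res,
        "min_ue": float(np.min(tr["u_e"])),
        "max_v": float(np.max(tr["v"])),
        "max_ui": float(np.max(tr["u_i"])),
        "propagated": fired,
        "times": res.times, "trace_down": tr, "trace_up": res.traces["up"],
    }


def ina_dynamics_vs_distance(d_list_nm=(160.0, 10.0, 5.0), *,
                             model: IonicModel | None = None,
                             distributions=("U", "NU"), dt: float = 0.01,
                             t_end: float = 15.0, dz_um: float = 1.0,
                             stop_margin: float | None = None) -> dict:
    """Sodium-current dynamics in the two-cell cleft with open gap junctions.

    Same domain as the closed-junction protocol but with the default
    gap-junction resistance; records downstream activation, the potentials
    at the cleft probe and the integrated whole-cell sodium influx of the
    second cell.
    """
    model = model or grandi_epicardial()
    out = {"d_nm": list(map(float, d_list_nm)),
           "scale": {"dt": dt, "dz_um": dz_um, "model": model.name}}
    for name in distributions:
        act, influx, min_ue, ui_at_act = [], [], [], []
        for d in d_list_nm:
            rec = _cleft_run(float(d), 20.0, name, model, dt, t_end, 1.0,
                             dz_um=dz_um, record_ina=True,
                             stop_margin=stop_margin)
            res = rec["result"]
            mesh = rec["mesh"]
            t_act = analysis.activation_times(res.times, rec["trace_down"]["v"])[0]
            act.append(float(t_act))
            _, q = analysis.integrated_ina(res, 1)
            influx.append(q)
            min_ue.append(rec["min_ue"])
            tr = rec["trace_down"]
            if np.isfinite(t_act):
                idx = int(np.searchsorted(res.times, t_act))
                idx = min(idx, len(tr["u_i"]) - 1)
                ui_at_act.append(float(tr["u_i"][idx]))
            else:
                ui_at_act.append(float("nan"))
        out[f"activation_{name}"] = act
        out[f"influx_{name}"] = influx
        out[f"min_ue_{name}"] = min_ue
        out[f"ui_at_activation_{name}"] = ui_at_act
    return out
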