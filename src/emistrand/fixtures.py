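"""Tiny deterministic fixtures and independent brute-force oracles.

The fixtures are small strands (a few thousand lattice nodes) that exercise
every node class in seconds.  The dense reference solver re-derives the
discrete equations with plain Python loops and dense linear algebra — it
shares the classified mesh data but none of the production assembly code —
and serves as the oracle for the sparse implicit step.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .geometry import (CellGeometry, StrandLayout, Spacings, Mesh, build_strand,
                       membrane_areas, EXT, DIR, INT, MEM, DISC)
from .solver import PhysicalParameters


def tiny_cell_geometry() -> CellGeometry:
    """Shrunken five-box cell (body 20x8x8 µm) for fast tests."""
    return CellGeometry.from_um((20, 8, 8), (2, 4, 4), (4, 2, 4))


def single_cuboid_geometry() -> CellGeometry:
    """Degenerate cell: plain cuboid body, no caps or bumps."""
    return CellGeometry.from_um((20, 8, 8), (0, 0, 0), (0, 0, 0))


def make_fixture(name: str) -> Mesh:
    """Named tiny meshes used across the test suite and the CLI."""
    pad = (4e-4, 4e-4, 4e-4)
    if name == "single_cuboid":
        return build_strand(single_cuboid_geometry(), StrandLayout(1, pad),
                            Spacings.from_um(2, 2, 2))
    if name == "tiny_cell":
        return build_strand(tiny_cell_geometry(), StrandLayout(1, pad),
                            Spacings.from_um(2, 2, 2))
    if name == "tiny_two_cell":
        return build_strand(tiny_cell_geometry(), StrandLayout(2, pad),
                            Spacings.from_um(2, 2, 2))
    if name == "tiny_strand3":
        return build_strand(tiny_cell_geometry(), StrandLayout(3, pad),
                            Spacings.from_um(2, 2, 2))
    raise KeyError(f"unknown fixture {name!r}")


# ---------------------------------------------------------------------------
# dense reference solver (independent assembly path)


class DenseReference:
    """Loop-based dense assembly of the implicit system for tiny meshes.

    Unknown layout mirrors the production solver (extracellular block, then
    intracellular, then the two disc blocks) so solution vectors are directly
    comparable, but every conductance, area and row is rebuilt here from the
    octant map with explicit loops and dense storage.
    """

    def __init__(self, mesh: Mesh, params: PhysicalParameters, dt: float):
        if mesh.n_nodes > 40000:
            raise ValueError("dense reference is meant for tiny fixtures")
        self.mesh = mesh
        self.params = params
        self.dt = dt
        self._index()
        self._assemble()

    def _index(self):
        mesh = self.mesh
        lab = mesh.label
        nx, ny, nz = mesh.shape
        self.idx_e = {}
        self.idx_i = {}
        self.idx_d1 = {}
        self.idx_d2 = {}
        n = 0
        for node in np.ndindex(nx, ny, nz):
            if lab[node] in (EXT, DIR, MEM):
                self.idx_e[node] = n
                n += 1
        for node in np.ndindex(nx, ny, nz):
            if lab[node] in (INT, MEM):
                self.idx_i[node] = n
                n += 1
        discs = [tuple(t) for t in np.argwhere(lab == DISC)]
        for node in discs:
            self.idx_d1[node] = n
            n += 1
        for node in discs:
            self.idx_d2[node] = n
            n += 1
        self.n = n

    def _octant(self, node, ox, oy, oz):
        o = 4 * ox + 2 * oy + oz
        return int(self.mesh.octants[o][node])

    def _half(self, axis, i, side):
        c = (self.mesh.xs, self.mesh.ys, self.mesh.zs)[axis]
        if side == 0:
            return c[i] - c[i - 1] if i > 0 else 0.0
        return c[i + 1] - c[i] if i + 1 < len(c) else 0.0

    def _intra_slot(self, node, cell):
        lab = self.mesh.label[node]
        cid = int(self.mesh.cell_id[node])
        if lab in (INT, MEM) and cid == cell:
            return self.idx_i[node]
        if lab == DISC and cid == cell:
            return self.idx_d1[node]
        if lab == DISC and cid + 1 == cell:
            return self.idx_d2[node]
        return None

    def _e_slot(self, node):
        return self.idx_e.get(node)

    def _assemble(self):
        mesh, par = self.mesh, self.params
        nx, ny, nz = mesh.shape
        a = np.zeros((self.n, self.n))
        for axis in range(3):
            for node in np.ndindex(nx, ny, nz):
                nb = list(node)
                nb[axis] += 1
                if nb[axis] >= mesh.shape[axis]:
                    continue
                nb = tuple(nb)
                h = self._half(axis, node[axis], 1)
                t1, t2 = [ax for ax in range(3) if ax != axis]
                for q1 in (0, 1):
                    for q2 in (0, 1):
                        side = [0, 0, 0]
                        side[axis] = 1
                        side[t1] = q1
                        side[t2] = q2
                        reg = self._octant(node, *side)
                        if reg == -2:
                            continue
                        area = (self._half(t1, node[t1], q1) / 2
                                * self._half(t2, node[t2], q2) / 2)
                        if area <= 0:
                            continue
                        if reg == -1:
                            sp_, sq_ = self._e_slot(node), self._e_slot(nb)
                            if sp_ is None or sq_ is None:
                                continue
                            g = par.sigma_e * area / h
                        else:
                            sp_ = self._intra_slot(node, reg)
                            sq_ = self._intra_slot(nb, reg)
                            if sp_ is None or sq_ is None:
                                continue
                            g = par.sigma_i * area / h
                        a[sp_, sp_] += g
                        a[sp_, sq_] -= g
                        a[sq_, sq_] += g
                        a[sq_, sp_] -= g

        # membrane capacitive coupling through the exposed area
        self.mem_rows = []
        mem = mesh.membrane
        for idx in range(len(mem)):
            node = tuple(mem.ijk[idx])
            cell = int(mem.cell[idx])
            area = self._exposed_area(node, cell)
            kappa = par.cm * area / self.dt
            ii, ie = self.idx_i[node], self.idx_e[node]
            a[ii, ii] += kappa
            a[ii, ie] -= kappa
            a[ie, ie] += kappa
            a[ie, ii] -= kappa
            self.mem_rows.append((ii, ie, kappa))

        self.disc_rows = []
        for node, d1 in self.idx_d1.items():
            d2 = self.idx_d2[node]
            left = int(mesh.cell_id[node])
            area = self._disc_area(node, left)
            kc = par.c_disc * area / self.dt
            gam = par.disc_conductance(left) * area
            a[d1, d1] += kc + gam
            a[d1, d2] -= kc + gam
            a[d2, d2] += kc + gam
            a[d2, d1] -= kc + gam
            self.disc_rows.append((d1, d2, kc))

        for node, ie in self.idx_e.items():
            if mesh.label[node] == DIR:
                a[ie, :] = 0.0
                a[ie, ie] = 1.0
        self.matrix = a

    def _exposed_area(self, node, cell):
        total = 0.0
        for axis in range(3):
            t1, t2 = [ax for ax in range(3) if ax != axis]
            for far_side in (0, 1):
                for q1 in (0, 1):
                    for q2 in (0, 1):
                        side_far = [0, 0, 0]
                        side_far[axis] = far_side
                        side_far[t1], side_far[t2] = q1, q2
                        side_near = list(side_far)
                        side_near[axis] = 1 - far_side
                        if (self._octant(node, *side_far) == -1
                                and self._octant(node, *side_near) == cell):
                            total += (self._half(t1, node[t1], q1) / 2
                                      * self._half(t2, node[t2], q2) / 2)
        return total

    def _disc_area(self, node, left):
        total = 0.0
        for q1 in (0, 1):
            for q2 in (0, 1):
                if (self._octant(node, 0, q1, q2) == left
                        and self._octant(node, 1, q1, q2) == left + 1):
                    total += (self._half(1, node[1], q1) / 2
                              * self._half(2, node[2], q2) / 2)
        return total

    def implicit_step(self, v_star: np.ndarray, w_star: np.ndarray):
        """Dense solve mirroring the production implicit step."""
        b = np.zeros(self.n)
        for (ii, ie, kappa), vs in zip(self.mem_rows, v_star):
            b[ii] += kappa * vs
            b[ie] -= kappa * vs
        for (d1, d2, kc), ws in zip(self.disc_rows, w_star):
            b[d1] += kc * ws
            b[d2] -= kc * ws
        x = np.linalg.solve(self.matrix, b)
        v = np.array([x[ii] - x[ie] for (ii, ie, _) in self.mem_rows])
        w = np.array([x[d1] - x[d2] for (d1, d2, _) in self.disc_rows])
        return v, w, x


def dense_reference_solve(mesh: Mesh, params: PhysicalParameters, dt: float,
                          v_star: np.ndarray, w_star: np.ndarray):
    """One implicit step through the independent dense path."""
    return DenseReference(mesh, params, dt).implicit_step(v_star, w_star)


# ---------------------------------------------------------------------------
# refinement ladders


@dataclass
class ConvergenceReport:
    dts: list[float]
    activation_by_dt: list[float]
    observed_order: float
    spacings: list[float]
    cv_by_spacing: list[float]


def convergence_suite(model=None, dts=(0.04, 0.02, 0.01),
                      spacings_um=(2.0, 1.0)) -> ConvergenceReport:
    """Δt and Δx refinement ladders on a tiny three-cell strand.

    Reports the activation time of the last cell's centre per time step (with
    the observed order from successive differences) and the conduction
    velocity per spatial resolution at fixed Δt.
    """
    from .ionic import reduced_test_model, StimulusProtocol
    from .channels import ChannelDistribution, assign_gna
    from .solver import run
    from .analysis import conduction_velocity, cell_center_probe

    model = model or reduced_test_model()
    stim = StimulusProtocol(cells=(0,))

    def activation_last(mesh, dt):
        quad = membrane_areas(mesh)
        field = assign_gna(mesh, quad, ChannelDistribution(p=0.0), model.gbar_na)
        res = run(mesh, PhysicalParameters(), model, field, stim, dt, 12.0,
                  quadrature=quad)
        return res

    mesh = make_fixture("tiny_strand3")
    acts = []
    for dt in dts:
        res = activation_last(mesh, dt)
        acts.append(float(res.activation[cell_center_probe(mesh, 2)]))
    errs = np.abs(np.diff(acts))
    order = float(np.log2(errs[0] / errs[1])) if len(errs) >= 2 and errs[1] > 0 else np.nan

    cvs = []
    geo = tiny_cell_geometry()
    for h in spacings_um:
        m = build_strand(geo, StrandLayout(3, (4e-4, 4e-4, 4e-4)),
                         Spacings.from_um(h, min(h, 2), min(h, 2)))
        res = activation_last(m, 0.02)
        cvs.append(conduction_velocity(res.activation, m, 0, 2).speed)
    return ConvergenceReport(list(dts), acts, order, list(spacings_um), cvs)
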