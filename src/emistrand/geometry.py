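"""Strand-of-cells computational domain: lattice construction and node classification.

Each cardiomyocyte is a composition of five axis-aligned cuboids: a main body
``O`` flanked in x by two junctional end caps ``W`` (west) and ``E`` (east) with a
smaller cross-section, and two lateral bumps ``S``/``N`` sitting on the y-sides of
the body.  Cells are chained along x into a strand; the shared face where the
``E`` cap of one cell abuts the ``W`` cap of the next is the intercalated disc.
The strand is embedded in an extracellular bath bounded by a box with grounded
(Dirichlet) x/y faces and insulated (Neumann) z faces.

All lengths are stored in cm; the public constructors accept µm for convenience
(``UM`` converts).  The lattice is node-centered and every material interface
lies exactly on a lattice plane, so each node belongs to exactly one of five
classes: extracellular, grounded boundary, intracellular of one cell, membrane
of one cell, or intercalated disc between two adjacent cells.

Classification is performed by sampling the eight octants around every node
(at quarter-spacing offsets, which by construction never touch an interface):
a node whose octants are all extracellular is extracellular, all inside one
cell is intracellular, a mix of one cell and bath is membrane, and a mix of
two cells is a disc node.  The octant map is also the single source of truth
for the finite-volume face areas used by the solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np

UM = 1e-4  # cm per micrometre
NM = 1e-7  # cm per nanometre

# node classes
EXT = 0  # extracellular interior
DIR = 1  # extracellular node on a grounded (Dirichlet) outer face
INT = 2  # intracellular interior
MEM = 3  # membrane node (carries v and ionic state)
DISC = 4  # intercalated-disc node (carries w)

# octant region codes: -2 outside domain, -1 extracellular, k >= 0 cell index
_OUTSIDE = -2
_BATH = -1

_REL_TOL = 1e-9


class GeometryError(ValueError):
    """Raised when a requested geometry cannot be represented on the lattice."""


@dataclass(frozen=True)
class CellGeometry:
    """Dimensions (cm) of the five cuboids composing one cell.

    ``size_o``/``size_we``/``size_sn`` are (x, y, z) extents of the main body,
    the west/east junctional caps and the south/north lateral bumps.  The caps
    are centred on the body's y-z face; the bumps sit on the body's y-sides,
    centred along x and z.  Zero extents degenerate gracefully (a cell with
    zero-size caps and bumps is a plain cuboid).
    """

    size_o: tuple[float, float, float]
    size_we: tuple[float, float, float]
    size_sn: tuple[float, float, float]
    sn_x0: float | None = None  # bump-footprint offset from the body x-start; None = centred

    @classmethod
    def default(cls) -> "CellGeometry":
        """Reference cell: body 100x18x18 µm, caps 2x14x14 µm, bumps 14x2x14 µm."""
        return cls.from_um((100, 18, 18), (2, 14, 14), (14, 2, 14))

    @classmethod
    def from_um(cls, size_o, size_we, size_sn, sn_x0=None) -> "CellGeometry":
        to_cm = lambda t: tuple(float(v) * UM for v in t)
        return cls(to_cm(size_o), to_cm(size_we), to_cm(size_sn),
                   None if sn_x0 is None else float(sn_x0) * UM)

    def __post_init__(self):
        for name, s in (("O", self.size_o), ("WE", self.size_we), ("SN", self.size_sn)):
            if any(v < 0 for v in s):
                raise GeometryError(f"negative extent in size_{name}: {s}")
        if any(v <= 0 for v in self.size_o):
            raise GeometryError("main body must have positive extents")
        if self.size_we[1] > self.size_o[1] or self.size_we[2] > self.size_o[2]:
            raise GeometryError("cap cross-section must fit within the body y-z face")
        if self.size_sn[0] > self.size_o[0] or self.size_sn[2] > self.size_o[2]:
            raise GeometryError("bump footprint must fit on the body")

    @property
    def cell_length(self) -> float:
        """Total intracellular x-extent: west cap + body + east cap."""
        return self.size_we[0] * 2 + self.size_o[0]

    def with_body_length(self, length_o_cm: float) -> "CellGeometry":
        """Vary the body length, shrinking the bump footprint for short cells.

        For cells shorter than 20 µm total, the bump x-extent is reduced to the
        cell length minus 6 µm so the bumps still fit on the body.
        """
        lo = float(length_o_cm)
        if lo <= 0:
            raise GeometryError("body length must be positive")
        sn = self.size_sn
        cell_len = lo + 2 * self.size_we[0]
        if cell_len < 20 * UM or sn[0] > lo:
            sn = (max(cell_len - 6 * UM, 0.0), sn[1], sn[2])
            if sn[0] <= 0:
                sn = (0.0, 0.0, 0.0)
        return replace(self, size_o=(lo, self.size_o[1], self.size_o[2]), size_sn=sn)

    def boxes(self, x0: float, y0: float, z0: float) -> dict[str, tuple]:
        """Cuboids of a cell whose body's min corner sits at (x0+Lw, y0, z0).

        Returns name -> (lo, hi) corner pairs in cm; zero-volume parts omitted.
        ``x0`` is the x where the west cap begins; ``y0``/``z0`` locate the min
        corner of the body (bumps extend below y0 and above y0 + body height).
        """
        lo_x, lo_y, lo_z = self.size_o
        lw, wy, wz = self.size_we
        sx, sy, sz = self.size_sn
        out: dict[str, tuple] = {}
        bx0 = x0 + lw
        out["O"] = ((bx0, y0, z0), (bx0 + lo_x, y0 + lo_y, z0 + lo_z))
        if lw > 0 and wy > 0 and wz > 0:
            cy = y0 + (lo_y - wy) / 2
            cz = z0 + (lo_z - wz) / 2
            out["W"] = ((x0, cy, cz), (x0 + lw, cy + wy, cz + wz))
            out["E"] = ((bx0 + lo_x, cy, cz), (bx0 + lo_x + lw, cy + wy, cz + wz))
        if sx > 0 and sy > 0 and sz > 0:
            fx = bx0 + ((lo_x - sx) / 2 if self.sn_x0 is None else self.sn_x0)
            if fx < bx0 - 1e-12 or fx + sx > bx0 + lo_x + 1e-12:
                raise GeometryError("bump footprint does not fit on the body in x")
            fz = z0 + (lo_z - sz) / 2
            out["S"] = ((fx, y0 - sy, fz), (fx + sx, y0, fz + sz))
            out["N"] = ((fx, y0 + lo_y, fz), (fx + sx, y0 + lo_y + sy, fz + sz))
        return out


@dataclass(frozen=True)
class StrandLayout:
    """Arrangement of cells in a single row along x inside the bath box.

    ``padding`` is the minimal bath thickness around the strand, per axis (cm);
    defaults are 10 µm in x and y and 4 µm in z.
    """

    n_cells: int = 1
    padding: tuple[float, float, float] = (10 * UM, 10 * UM, 4 * UM)

    def __post_init__(self):
        if self.n_cells < 1:
            raise GeometryError("need at least one cell")
        if any(p <= 0 for p in self.padding):
            raise GeometryError("padding must be positive on every axis")


@dataclass
class Spacings:
    """Target lattice spacings (cm) with optional graded refinement windows in x.

    ``refine_x`` is a list of ``(x_lo, x_hi, dx_fine)`` windows (cm, absolute
    domain coordinates) meshed at ``dx_fine``; outside a window the spacing
    grows geometrically (ratio <= ``ratio``) until it reaches ``dx``.
    """

    dx: float
    dy: float
    dz: float
    refine_x: list[tuple[float, float, float]] = field(default_factory=list)
    ratio: float = 2.0

    @classmethod
    def from_um(cls, dx, dy, dz, refine_x=(), ratio=2.0) -> "Spacings":
        return cls(dx * UM, dy * UM, dz * UM,
                   [(a * UM, b * UM, h * UM) for (a, b, h) in refine_x], ratio)


@dataclass
class MembraneSet:
    """Flat arrays describing all membrane nodes (one entry per node)."""

    ijk: np.ndarray          # (n, 3) int lattice indices
    flat: np.ndarray         # (n,) flattened lattice index
    cell: np.ndarray         # (n,) owning cell
    exposed: np.ndarray      # (n, 6) bool, exposure towards -x,+x,-y,+y,-z,+z
    area_fv: np.ndarray      # (n,) exposed control-volume surface area (cm^2)

    def __len__(self):
        return len(self.cell)


@dataclass
class DiscSet:
    """Flat arrays describing all intercalated-disc nodes."""

    ijk: np.ndarray
    flat: np.ndarray
    left_cell: np.ndarray    # disc joins left_cell and left_cell + 1
    area_fv: np.ndarray      # shared-face area of the node's control volume

    def __len__(self):
        return len(self.left_cell)


@dataclass
class Mesh:
    """Classified lattice for a strand of cells in a bath."""

    xs: np.ndarray
    ys: np.ndarray
    zs: np.ndarray
    label: np.ndarray            # (nx, ny, nz) int8 node class
    cell_id: np.ndarray          # (nx, ny, nz) int16; cell for INT/MEM, left cell for DISC
    octants: np.ndarray          # (8, nx, ny, nz) int16 octant region codes
    geometry: CellGeometry
    layout: StrandLayout
    cell_x0: np.ndarray          # (n_cells,) west-cap start x of each cell (cm)
    cross_center: tuple[float, float] = (0.0, 0.0)  # physical (y, z) strand axis
    symmetry: tuple[str, ...] = ()  # mirror planes the lattice was cut on

    @property
    def shape(self):
        return self.label.shape

    @property
    def n_cells(self) -> int:
        return self.layout.n_cells

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.shape))

    def __post_init__(self):
        self._build_sets()

    # -- spacing helpers ---------------------------------------------------
    def half_steps(self, axis: int) -> tuple[np.ndarray, np.ndarray]:
        """(h_minus, h_plus) per node along an axis; 0 beyond the boundary."""
        c = (self.xs, self.ys, self.zs)[axis]
        d = np.diff(c)
        hm = np.concatenate(([0.0], d))
        hp = np.concatenate((d, [0.0]))
        return hm, hp

    def mean_spacing(self, axis: int) -> np.ndarray:
        """Control-volume extent per node along an axis (h-/2 + h+/2)."""
        hm, hp = self.half_steps(axis)
        return 0.5 * (hm + hp)

    def cell_x_span(self, k: int) -> tuple[float, float]:
        x0 = float(self.cell_x0[k])
        return x0, x0 + self.geometry.cell_length

    def cell_center_x(self, k: int) -> float:
        a, b = self.cell_x_span(k)
        return 0.5 * (a + b)

    # -- classification-derived sets ---------------------------------------
    def _build_sets(self) -> None:
        oc = self.octants
        # octant index o = 4*ox + 2*oy + oz with o* in {0 (minus), 1 (plus)}
        mem = np.argwhere(self.label == MEM)
        exposed, area = self._exposure(mem)
        flat = np.ravel_multi_index(mem.T, self.shape)
        self.membrane = MembraneSet(
            ijk=mem, flat=flat, cell=self.cell_id[tuple(mem.T)].astype(np.int32),
            exposed=exposed, area_fv=area)
        dsc = np.argwhere(self.label == DISC)
        dflat = np.ravel_multi_index(dsc.T, self.shape)
        darea = self._disc_area(dsc)
        self.discs = DiscSet(ijk=dsc, flat=dflat,
                             left_cell=self.cell_id[tuple(dsc.T)].astype(np.int32),
                             area_fv=darea)

    def _exposure(self, ijk: np.ndarray):
        """Exposure flags and exposed control-volume area for membrane nodes.

        A quadrant of the ±a face of a node's control volume is exposed when
        the octant on the far side (along a) is bath while the near octant is
        the node's cell; its area is the product of the two transverse
        half-spacings of that quadrant.
        """
        n = len(ijk)
        exposed = np.zeros((n, 6), dtype=bool)
        area = np.zeros(n)
        cells = self.cell_id[tuple(ijk.T)]
        halves = [self.half_steps(a) for a in range(3)]
        oc = self.octants[:, ijk[:, 0], ijk[:, 1], ijk[:, 2]]  # (8, n)
        for axis in range(3):
            t1, t2 = [a for a in range(3) if a != axis]
            for side in (0, 1):  # 0: -axis, 1: +axis
                face_area = np.zeros(n)
                for q1 in (0, 1):
                    for q2 in (0, 1):
                        o_far = _oct_index(axis, side, t1, q1, t2, q2)
                        o_near = _oct_index(axis, 1 - side, t1, q1, t2, q2)
                        far = oc[o_far]
                        near = oc[o_near]
                        hit = (far == _BATH) & (near == cells)
                        h1 = halves[t1][q1][ijk[:, t1]] * 0.5
                        h2 = halves[t2][q2][ijk[:, t2]] * 0.5
                        face_area += np.where(hit, h1 * h2, 0.0)
                exposed[:, 2 * axis + side] |= face_area > 0
                area += face_area
        return exposed, area

    def _disc_area(self, ijk: np.ndarray) -> np.ndarray:
        """Shared-face area of each disc node's control volume (x-normal)."""
        n = len(ijk)
        area = np.zeros(n)
        left = self.cell_id[tuple(ijk.T)]
        halves = [self.half_steps(a) for a in range(3)]
        oc = self.octants[:, ijk[:, 0], ijk[:, 1], ijk[:, 2]]
        axis = 0
        t1, t2 = 1, 2
        for q1 in (0, 1):
            for q2 in (0, 1):
                o_w = _oct_index(axis, 0, t1, q1, t2, q2)
                o_e = _oct_index(axis, 1, t1, q1, t2, q2)
                hit = (oc[o_w] == left) & (oc[o_e] == left + 1)
                h1 = halves[t1][q1][ijk[:, t1]] * 0.5
                h2 = halves[t2][q2][ijk[:, t2]] * 0.5
                area += np.where(hit, h1 * h2, 0.0)
        return area


def _oct_index(a1: int, s1: int, a2: int, s2: int, a3: int, s3: int) -> int:
    """Octant flat index from (axis, side) pairs; axes must cover {0,1,2}."""
    side = [0, 0, 0]
    side[a1], side[a2], side[a3] = s1, s2, s3
    return 4 * side[0] + 2 * side[1] + side[2]


# ---------------------------------------------------------------------------
# lattice construction


def _is_multiple(value: float, h: float) -> bool:
    r = value / h
    return abs(r - round(r)) < 1e-6


def _uniform_axis(lo: float, hi: float, planes: list[float], h: float,
                  axis_name: str) -> np.ndarray:
    """Uniform coordinates lo..hi at spacing h; all planes must land on nodes."""
    for p in planes:
        if p < lo - 1e-12 or p > hi + 1e-12:
            continue
        if not _is_multiple(p - lo, h):
            raise GeometryError(
                f"plane at {p / UM:.6g} um on axis {axis_name} is not a multiple "
                f"of the spacing {h / UM:.6g} um")
    if not _is_multiple(hi - lo, h):
        raise GeometryError(f"axis {axis_name} extent is not a multiple of the spacing")
    n = round((hi - lo) / h)
    return np.linspace(lo, hi, n + 1)


def _graded_increments(length: float, h_left: float, h_right: float,
                       h_max: float, ratio: float) -> list[float]:
    """Increments spanning ``length``: geometric growth from both ends, uniform middle.

    The middle block is stretched (by at most ``ratio``) so the increments sum
    exactly to ``length``.
    """
    if length <= 0:
        return []
    if min(h_left, h_right) >= length - _REL_TOL * length:
        return [length]
    left: list[float] = []
    right: list[float] = []
    rem = length
    hl, hr = min(h_left, h_max), min(h_right, h_max)
    # alternate growth on the smaller side while room remains
    while rem > (hl + hr) and (hl < h_max or hr < h_max):
        if hl <= hr and hl < h_max:
            step = min(hl, rem / 2)
            left.append(step)
            rem -= step
            hl = min(hl * ratio, h_max)
        elif hr < h_max:
            step = min(hr, rem / 2)
            right.append(step)
            rem -= step
            hr = min(hr * ratio, h_max)
        else:
            break
    n_mid = max(1, int(np.ceil(rem / h_max - 1e-9)))
    mid = [rem / n_mid] * n_mid
    return left + mid + right[::-1]


def _graded_axis(length: float, planes: list[float], h: float,
                 refine: list[tuple[float, float, float]], ratio: float) -> np.ndarray:
    """x-axis coordinates honouring required planes and refinement windows."""
    req = sorted({0.0, length, *planes})
    merged: list[float] = [req[0]]
    for p in req[1:]:
        if p - merged[-1] > _REL_TOL * max(length, 1e-30):
            merged.append(p)
    coords = [0.0]
    for a, b in zip(merged[:-1], merged[1:]):
        seg = b - a
        mid = 0.5 * (a + b)
        h_here = h
        for (lo, hi, hf) in refine:
            if lo - _REL_TOL <= mid <= hi + _REL_TOL:
                h_here = min(h_here, hf)
        # spacing requested at each end by the neighbouring segment
        def _end_h(x):
            he = h
            for (lo, hi, hf) in refine:
                if lo - _REL_TOL <= x <= hi + _REL_TOL:
                    he = min(he, hf)
            return he
        if h_here < h:  # inside a refinement window: uniform fine spacing
            if not _is_multiple(seg, h_here):
                raise GeometryError(
                    f"refined segment [{a / UM:.6g}, {b / UM:.6g}] um is not a "
                    f"multiple of dx_fine on axis x")
            n = round(seg / h_here)
            inc = [seg / n] * n
        else:
            hl = _end_h(a - _REL_TOL * length)
            hr = _end_h(b + _REL_TOL * length)
            if hl >= h and hr >= h:
                if not _is_multiple(seg, h):
                    raise GeometryError(
                        f"segment [{a / UM:.6g}, {b / UM:.6g}] um is not a multiple "
                        f"of dx on axis x")
                n = round(seg / h)
                inc = [seg / n] * n
            else:
                inc = _graded_increments(seg, hl, hr, h, ratio)
        for d in inc:
            coords.append(coords[-1] + d)
        coords[-1] = b  # kill accumulated round-off at required planes
    return np.asarray(coords)


def build_strand(geometry: CellGeometry, layout: StrandLayout,
                 spacings: Spacings, symmetry: tuple[str, ...] = ()) -> Mesh:
    """Mesh a strand of cells inside its bath box and classify every node.

    ``symmetry`` may contain ``"y"`` and/or ``"z"`` to mesh only the upper
    half of the mirror-symmetric cross-section, with the cut plane treated
    as an insulated (zero-flux) boundary.  Fields, activation times and
    conduction metrics are identical to the full domain for symmetric
    stimulation; per-cell areas and integrated currents halve per cut.
    """
    px, py, pz = layout.padding
    cl = geometry.cell_length
    n = layout.n_cells
    lx = 2 * px + n * cl
    ly = 2 * py + geometry.size_o[1] + 2 * geometry.size_sn[1]
    lz = 2 * pz + geometry.size_o[2]
    for ax in symmetry:
        if ax not in ("y", "z"):
            raise GeometryError(f"symmetry axis must be 'y' or 'z', got {ax!r}")

    cell_x0 = np.array([px + k * cl for k in range(n)])
    y0 = py + geometry.size_sn[1]
    z0 = pz

    boxes: list[tuple[int, tuple, tuple]] = []  # (cell, lo, hi)
    xplanes: set[float] = {0.0, lx}
    yplanes: set[float] = {0.0, ly}
    zplanes: set[float] = {0.0, lz}
    for k in range(n):
        for _, (lo, hi) in geometry.boxes(cell_x0[k], y0, z0).items():
            boxes.append((k, lo, hi))
            xplanes.update((lo[0], hi[0]))
            yplanes.update((lo[1], hi[1]))
            zplanes.update((lo[2], hi[2]))

    xs = _graded_axis(lx, sorted(xplanes), spacings.dx, spacings.refine_x, spacings.ratio)
    y_lo = ly / 2 if "y" in symmetry else 0.0
    z_lo = lz / 2 if "z" in symmetry else 0.0
    ys = _uniform_axis(y_lo, ly, sorted(yplanes), spacings.dy, "y")
    zs = _uniform_axis(z_lo, lz, sorted(zplanes), spacings.dz, "z")

    nx, ny, nz = len(xs), len(ys), len(zs)
    octants = np.full((8, nx, ny, nz), _BATH, dtype=np.int16)

    dx = np.diff(xs)
    dy = np.diff(ys)
    dz = np.diff(zs)

    def samples(c, d, side):
        """Quarter-offset octant sample coordinates; NaN where out of domain."""
        out = np.full(len(c), np.nan)
        if side == 0:
            out[1:] = c[1:] - d / 4
        else:
            out[:-1] = c[:-1] + d / 4
        return out

    sx = [samples(xs, dx, s) for s in (0, 1)]
    sy = [samples(ys, dy, s) for s in (0, 1)]
    sz = [samples(zs, dz, s) for s in (0, 1)]

    for ox in (0, 1):
        for oy in (0, 1):
            for oz in (0, 1):
                o = 4 * ox + 2 * oy + oz
                pxs, pys, pzs = sx[ox], sy[oy], sz[oz]
                octants[o][np.isnan(pxs), :, :] = _OUTSIDE
                octants[o][:, np.isnan(pys), :] = _OUTSIDE
                octants[o][:, :, np.isnan(pzs)] = _OUTSIDE
                for cell, lo, hi in boxes:
                    ix = np.nonzero((pxs > lo[0]) & (pxs < hi[0]))[0]
                    iy = np.nonzero((pys > lo[1]) & (pys < hi[1]))[0]
                    iz = np.nonzero((pzs > lo[2]) & (pzs < hi[2]))[0]
                    if len(ix) and len(iy) and len(iz):
                        octants[o][np.ix_(ix, iy, iz)] = cell

    valid = octants >= _BATH
    big = np.where(valid, octants, np.int16(-1))
    maxc = big.max(axis=0)
    small = np.where(octants >= 0, octants, np.int16(32000))
    minc = small.min(axis=0)
    has_bath = ((octants == _BATH)).any(axis=0)
    has_cell = maxc >= 0

    label = np.zeros((nx, ny, nz), dtype=np.int8)
    cell_id = np.full((nx, ny, nz), -1, dtype=np.int16)
    label[~has_cell] = EXT
    intra = has_cell & (minc == maxc) & ~has_bath
    memb = has_cell & (minc == maxc) & has_bath
    disc = has_cell & (minc < maxc) & (minc < 32000)
    if np.any(disc & (maxc - np.where(minc < 32000, minc, maxc) > 1)):
        raise GeometryError("non-adjacent cells share a node")
    label[intra] = INT
    label[memb] = MEM
    label[disc] = DISC
    cell_id[intra | memb] = maxc[intra | memb]
    cell_id[disc] = minc[disc]

    # grounded outer boundary on x and y faces, insulated z faces; symmetry
    # cut planes are insulated as well
    ext = label == EXT
    dirich = np.zeros_like(ext)
    dirich[0, :, :] = True
    dirich[-1, :, :] = True
    if "y" not in symmetry:
        dirich[:, 0, :] = True
    dirich[:, -1, :] = True
    label[ext & dirich] = DIR

    return Mesh(xs=xs, ys=ys, zs=zs, label=label, cell_id=cell_id,
                octants=octants, geometry=geometry, layout=layout,
                cell_x0=cell_x0, cross_center=(ly / 2, lz / 2),
                symmetry=tuple(symmetry))


# ---------------------------------------------------------------------------
# membrane quadrature (trapezoidal-style area weights per membrane node)


@dataclass
class MembraneQuadrature:
    """Per-node area weights over membrane and disc nodes.

    ``areas`` follows the seven-case rule: nodes interior to a single flat
    membrane plane weigh the product of the two in-plane spacings, nodes on
    the intersection of two planes the arithmetic mean of the two products,
    and corner nodes one third of the sum of the three products.  Graded
    spacings use the mean local spacing at the node.
    """

    areas: np.ndarray        # (n_mem,) weights aligned with mesh.membrane
    disc_areas: np.ndarray   # (n_disc,) weights aligned with mesh.discs

    def cell_area(self, mesh: Mesh, k: int) -> float:
        """A_c: quadrature area of cell k's membrane (discs excluded)."""
        return float(self.areas[mesh.membrane.cell == k].sum())

    def region_area(self, mesh: Mesh, mask: np.ndarray, k: int | None = None) -> float:
        sel = mask if k is None else (mask & (mesh.membrane.cell == k))
        return float(self.areas[sel].sum())


def membrane_areas(mesh: Mesh) -> MembraneQuadrature:
    """Area weights for every membrane and disc node from the plane-case rule."""
    mem = mesh.membrane
    hbar = [mesh.mean_spacing(a) for a in range(3)]
    prods = []
    for axis in range(3):
        t1, t2 = [a for a in range(3) if a != axis]
        prods.append(hbar[t1][mem.ijk[:, t1]] * hbar[t2][mem.ijk[:, t2]])
    prods = np.stack(prods, axis=1)  # (n, 3): products for x-, y-, z-normal planes
    on_plane = np.stack([mem.exposed[:, 2 * a] | mem.exposed[:, 2 * a + 1]
                         for a in range(3)], axis=1)
    n_planes = on_plane.sum(axis=1)
    if np.any(n_planes == 0):
        raise GeometryError("membrane node not on any interface plane")
    areas = (prods * on_plane).sum(axis=1) / n_planes

    dsc = mesh.discs
    disc_areas = (hbar[1][dsc.ijk[:, 1]] * hbar[2][dsc.ijk[:, 2]]
                  if len(dsc) else np.zeros(0))
    return MembraneQuadrature(areas=areas, disc_areas=disc_areas)


# ---------------------------------------------------------------------------
# junctional membrane regions


def junction_region(mesh: Mesh, mode: str) -> np.ndarray:
    """Membrane-node mask for the high-density sodium-channel region.

    ``horizontal_ends``: the lateral (x-parallel) faces of the west/east caps.
    ``vertical_ends``: x-normal membrane faces within the cap windows at both
    cell ends (the exposed end annulus of the body and any free cap end face).
    Disc nodes never belong to the region (they carry no ionic current).
    """
    if mode not in ("horizontal_ends", "vertical_ends"):
        raise ValueError(f"unknown junction region mode: {mode!r}")
    geo = mesh.geometry
    lw = geo.size_we[0]
    if lw <= 0 or geo.size_we[1] <= 0 or geo.size_we[2] <= 0:
        if mode == "horizontal_ends":
            raise GeometryError("horizontal_ends requires non-degenerate caps")
    mem = mesh.membrane
    x = mesh.xs[mem.ijk[:, 0]]
    mask = np.zeros(len(mem), dtype=bool)
    tol = _REL_TOL + 1e-12
    for k in range(mesh.n_cells):
        x0, x1 = mesh.cell_x_span(k)
        win = lw if lw > 0 else 0.0
        in_cell = mem.cell == k
        in_west = in_cell & (x <= x0 + win + tol)
        in_east = in_cell & (x >= x1 - win - tol)
        if mode == "horizontal_ends":
            lateral = mem.exposed[:, 2:].any(axis=1)
            # restrict to nodes on the cap boxes themselves
            bxs = geo.boxes(mesh.cell_x0[k], _cell_y0(mesh), mesh.layout.padding[2])
            on_cap = np.zeros(len(mem), dtype=bool)
            for name in ("W", "E"):
                if name in bxs:
                    lo, hi = bxs[name]
                    on_cap |= _in_closed_box(mesh, mem.ijk, lo, hi)
            mask |= (in_west | in_east) & lateral & on_cap
        else:
            xnormal = mem.exposed[:, 0] | mem.exposed[:, 1]
            mask |= (in_west | in_east) & xnormal
    if mode == "vertical_ends":
        for k in range(mesh.n_cells):
            if not mask[mesh.membrane.cell == k].any():
                raise GeometryError(
                    f"cell {k}: no vertical end membrane (end faces coincide "
                    "with intercalated discs)")
    return mask


def _cell_y0(mesh: Mesh) -> float:
    return mesh.layout.padding[1] + mesh.geometry.size_sn[1]


def _in_closed_box(mesh: Mesh, ijk: np.ndarray, lo, hi) -> np.ndarray:
    tol = 1e-12
    x = mesh.xs[ijk[:, 0]]
    y = mesh.ys[ijk[:, 1]]
    z = mesh.zs[ijk[:, 2]]
    return ((x >= lo[0] - tol) & (x <= hi[0] + tol) &
            (y >= lo[1] - tol) & (y <= hi[1] + tol) &
            (z >= lo[2] - tol) & (z <= hi[2] + tol))
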