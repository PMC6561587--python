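"""Lattice construction, node classification and membrane quadrature."""

import numpy as np
import pytest

from emistrand.geometry import (CellGeometry, StrandLayout, Spacings, UM, NM,
                                build_strand, membrane_areas, junction_region,
                                GeometryError, EXT, DIR, INT, MEM, DISC)
from emistrand.fixtures import tiny_cell_geometry, single_cuboid_geometry


def _analytic_area_default_um2():
    """Exact surface area of the composed default cell by face bookkeeping."""
    body = 4 * (100 * 18) + 2 * (18 * 18)       # lateral + end faces
    body -= 2 * (14 * 14)                        # cap attachment holes
    body -= 2 * (14 * 14)                        # bump footprints
    caps = 2 * (4 * 14 * 2 + 14 * 14)            # lateral tube + free end
    bumps = 2 * (4 * 14 * 2 + 14 * 14)           # lateral sides + outer face
    return body + caps + bumps


class TestBuildStrand:
    def test_default_cell_box_extents(self):
        mesh = build_strand(CellGeometry.default(), StrandLayout(1),
                            Spacings.from_um(1, 1, 2))
        assert np.isclose(mesh.xs[-1] - mesh.xs[0], 124 * UM)
        assert np.isclose(mesh.ys[-1] - mesh.ys[0], 42 * UM)
        assert np.isclose(mesh.zs[-1] - mesh.zs[0], 26 * UM)
        x0, x1 = mesh.cell_x_span(0)
        assert np.isclose(x1 - x0, 104 * UM)

    def test_degenerate_single_cuboid_membrane_is_box_surface(self):
        geo = single_cuboid_geometry()
        mesh = build_strand(geo, StrandLayout(1, (4e-4, 4e-4, 4e-4)),
                            Spacings.from_um(2, 2, 2))
        mem = mesh.membrane
        x = mesh.xs[mem.ijk[:, 0]]
        y = mesh.ys[mem.ijk[:, 1]]
        z = mesh.zs[mem.ijk[:, 2]]
        lo = np.array([4e-4, 4e-4, 4e-4])
        hi = lo + np.array([20 * UM, 8 * UM, 8 * UM])
        on_surf = ((np.isclose(x, lo[0]) | np.isclose(x, hi[0]))
                   | (np.isclose(y, lo[1]) | np.isclose(y, hi[1]))
                   | (np.isclose(z, lo[2]) | np.isclose(z, hi[2])))
        inside = ((x >= lo[0] - 1e-12) & (x <= hi[0] + 1e-12)
                  & (y >= lo[1] - 1e-12) & (y <= hi[1] + 1e-12)
                  & (z >= lo[2] - 1e-12) & (z <= hi[2] + 1e-12))
        assert np.all(on_surf & inside)
        # count must equal the number of surface lattice nodes of the box
        n_expect = 11 * 5 * 5 - 9 * 3 * 3
        assert len(mem) == n_expect

    def test_nm_cleft_contains_interior_extracellular_planes(self):
        from emistrand.experiments import cleft_mesh
        mesh = cleft_mesh(5.0)
        geo = mesh.geometry
        a = mesh.cell_x0[0] + geo.cell_length - geo.size_we[0]
        b = mesh.cell_x0[1] + geo.size_we[0]
        inner = (mesh.xs > a + 1e-12) & (mesh.xs < b - 1e-12)
        # Δx = d/4 puts three lattice planes strictly inside the cleft
        assert inner.sum() == 3
        labs = mesh.label[inner]
        assert (labs == EXT).any()

    def test_unrepresentable_geometry_rejected_with_axis(self):
        with pytest.raises(GeometryError, match="axis x"):
            build_strand(CellGeometry.default(), StrandLayout(1),
                         Spacings.from_um(2, 1, 2))  # bump planes at odd x
        with pytest.raises(GeometryError, match="axis z"):
            build_strand(CellGeometry.default(), StrandLayout(1),
                         Spacings.from_um(1, 1, 4))

    def test_classification_partitions_all_nodes(self, tiny_two_cell_mesh):
        lab = tiny_two_cell_mesh.label
        assert set(np.unique(lab)) <= {EXT, DIR, INT, MEM, DISC}
        # every membrane node belongs to one cell; discs to a left cell
        mem = tiny_two_cell_mesh.membrane
        assert np.all((mem.cell >= 0) & (mem.cell < 2))
        assert np.all(tiny_two_cell_mesh.discs.left_cell == 0)

    def test_two_cells_share_disc_plane(self, tiny_two_cell_mesh):
        mesh = tiny_two_cell_mesh
        xj = mesh.cell_x_span(0)[1]
        xd = mesh.xs[mesh.discs.ijk[:, 0]]
        assert np.allclose(xd, xj)
        assert len(mesh.discs) > 0

    def test_mirror_symmetry_class_counts(self):
        """Reflecting the layout in y/z leaves the class census unchanged."""
        geo = tiny_cell_geometry()
        mesh = build_strand(geo, StrandLayout(1, (4e-4, 4e-4, 4e-4)),
                            Spacings.from_um(2, 2, 2))
        for axis in (1, 2):
            flipped = np.flip(mesh.label, axis=axis)
            assert np.array_equal(np.sort(flipped.ravel()),
                                  np.sort(mesh.label.ravel()))
            # reflection maps the classified lattice onto itself exactly
            assert np.array_equal(flipped, mesh.label)


class TestMembraneAreas:
    def test_plane_interior_and_corner_weights(self, single_cuboid_mesh):
        quad = membrane_areas(single_cuboid_mesh)
        mesh = single_cuboid_mesh
        mem = mesh.membrane
        n_planes = (np.stack([mem.exposed[:, 2 * a] | mem.exposed[:, 2 * a + 1]
                              for a in range(3)], axis=1)).sum(axis=1)
        interior = n_planes == 1
        corner = n_planes == 3
        h = 2 * UM
        assert np.allclose(quad.areas[interior], h * h)
        assert np.allclose(quad.areas[corner], (3 * h * h) / 3)

    def test_corner_weight_mixed_spacings(self):
        geo = single_cuboid_geometry()
        mesh = build_strand(geo, StrandLayout(1, (4e-4, 4e-4, 4e-4)),
                            Spacings.from_um(1, 1, 2))
        quad = membrane_areas(mesh)
        mem = mesh.membrane
        n_planes = (np.stack([mem.exposed[:, 2 * a] | mem.exposed[:, 2 * a + 1]
                              for a in range(3)], axis=1)).sum(axis=1)
        corner = n_planes == 3
        expect = (1 * 1 + 1 * 2 + 1 * 2) / 3 * UM * UM
        assert np.allclose(quad.areas[corner], expect)

    def test_total_area_matches_analytic_composition(self, default_cell_mesh):
        quad = membrane_areas(default_cell_mesh)
        a_c = quad.cell_area(default_cell_mesh, 0) / UM ** 2
        exact = _analytic_area_default_um2()
        assert abs(a_c - exact) / exact < 0.02

    def test_flat_face_area_within_boundary_band(self, single_cuboid_mesh):
        """Σ A_i over one flat face is exact up to the half-cell edge band."""
        mesh = single_cuboid_mesh
        quad = membrane_areas(mesh)
        mem = mesh.membrane
        top = mem.exposed[:, 5]  # +z face of the box
        face = quad.areas[top].sum() / UM ** 2
        exact = 20 * 8
        # node-sum rule counts (m1+1)(m2+1) weights for an m1 x m2 face:
        # the excess is exactly the one-node boundary band (m1+m2+1) h^2
        band = (10 + 4 + 1) * 2 * 2
        assert abs(face - exact) <= band + 1e-9


class TestJunctionRegion:
    def test_horizontal_ends_area_matches_cap_faces(self, default_cell_mesh):
        quad = membrane_areas(default_cell_mesh)
        mask = junction_region(default_cell_mesh, "horizontal_ends")
        a_j = quad.areas[mask].sum() / UM ** 2
        exact = 2 * (4 * 14 * 2)  # two caps, four lateral faces each
        # the node-sum quadrature adds a one-node band around each 2x14 face
        # and the cap edge rings belong to the region by convention
        assert exact <= a_j <= 2.0 * exact

    def test_vertical_ends_on_degenerate_cell(self, single_cuboid_mesh):
        quad = membrane_areas(single_cuboid_mesh)
        mask = junction_region(single_cuboid_mesh, "vertical_ends")
        mem = single_cuboid_mesh.membrane
        assert np.all(mem.exposed[mask, 0] | mem.exposed[mask, 1])
        a_j = quad.areas[mask].sum() / UM ** 2
        exact = 2 * 8 * 8
        band = 2 * (4 + 4 + 1) * 2 * 2  # one-node band per 8x8 end face
        assert abs(a_j - exact) <= band + 1e-9

    def test_vertical_ends_excludes_disc_nodes(self, tiny_two_cell_mesh):
        mask = junction_region(tiny_two_cell_mesh, "vertical_ends")
        # masks index membrane nodes only; discs are a separate set
        assert mask.shape == (len(tiny_two_cell_mesh.membrane),)
        assert mask.any()

    def test_unknown_mode_rejected(self, tiny_cell_mesh):
        with pytest.raises(ValueError):
            junction_region(tiny_cell_mesh, "sideways")
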