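"""Sodium-channel conductance fields with exactly conserved whole-cell totals.

A fraction ``p`` of each cell's sodium channels is moved from the bulk
membrane to a junctional region at the cell ends.  The junctional density is
raised by ``p * A_c / A_j`` so that the total conductance

    G_Na = sum_i g_Na(i) * A_i

is identical for every ``p`` (the uniform total ``A_c * gbar``).  Areas are
the quadrature weights of :func:`emistrand.geometry.membrane_areas`, so the
identity holds to round-off by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .geometry import Mesh, MembraneQuadrature, junction_region, GeometryError


@dataclass(frozen=True)
class ChannelDistribution:
    """Placement of sodium channels on the membrane.

    p
        Fraction of channels moved to the junctional region (0 = uniform).
    region
        ``"horizontal_ends"`` (lateral cap faces) or ``"vertical_ends"``
        (x-normal end faces); ignored when ``p == 0``.
    gbar
        Uniform-case conductance density (mS/cm^2); ``None`` means take the
        default of the active ionic model.
    area_override
        Replacement membrane area A_c* (cm^2) used in place of the actual
        cell area when fixing the channel count across cell lengths.
    """

    p: float = 0.0
    region: str = "horizontal_ends"
    gbar: float | None = None
    area_override: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"fraction p must lie in [0, 1], got {self.p}")
        if self.gbar is not None and self.gbar <= 0:
            raise ValueError("gbar must be positive")
        if self.area_override is not None and self.area_override <= 0:
            raise ValueError("area_override must be positive")


@dataclass
class ConductanceField:
    """Per-membrane-node sodium conductance density (mS/cm^2)."""

    g_na: np.ndarray          # aligned with mesh.membrane
    gbar: float
    distribution: ChannelDistribution

    def total_per_cell(self, mesh: Mesh, quad: MembraneQuadrature) -> np.ndarray:
        """G_Na per cell by quadrature (mS)."""
        out = np.zeros(mesh.n_cells)
        np.add.at(out, mesh.membrane.cell, self.g_na * quad.areas)
        return out


def assign_gna(mesh: Mesh, quad: MembraneQuadrature,
               dist: ChannelDistribution, default_gbar: float | None = None
               ) -> ConductanceField:
    """Realise a channel distribution as a nodal conductance-density field.

    The junctional region is resolved per cell; nodes on the region boundary
    belong to the junctional part.  With an ``area_override`` A_c*, the bulk
    density is scaled by A_c*/A_c and the junctional surcharge uses A_c*, so
    the per-cell total equals A_c* * gbar (channel count held fixed).
    """
    gbar = dist.gbar if dist.gbar is not None else default_gbar
    if gbar is None or gbar <= 0:
        raise ValueError("no positive gbar available (set dist.gbar or pass the model default)")
    mem = mesh.membrane
    g = np.empty(len(mem))
    if dist.p == 0.0:
        jmask = np.zeros(len(mem), dtype=bool)
    else:
        jmask = junction_region(mesh, dist.region)
    for k in range(mesh.n_cells):
        in_cell = mem.cell == k
        a_c = quad.areas[in_cell].sum()
        a_star = dist.area_override if dist.area_override is not None else a_c
        scale = a_star / a_c
        g_r = (1.0 - dist.p) * scale * gbar
        g[in_cell] = g_r
        if dist.p > 0.0:
            sel = in_cell & jmask
            a_j = quad.areas[sel].sum()
            if a_j <= 0:
                raise GeometryError(
                    f"cell {k}: junctional region has zero area but p = {dist.p}")
            g[sel] = g_r + dist.p * (a_star / a_j) * gbar
    return ConductanceField(g_na=g, gbar=float(gbar), distribution=dist)


def rescale_for_cell_length(dist: ChannelDistribution, a_c_default: float,
                            a_c_actual: float) -> ChannelDistribution:
    """Distribution holding the per-cell channel count at the default-cell value.

    ``a_c_default`` is the membrane area A_c* of the reference cell and
    ``a_c_actual`` the area of the mesh the distribution will be applied to;
    both in cm^2.  Returns a distribution whose total conductance equals
    ``A_c* * gbar`` regardless of the actual cell area.
    """
    if a_c_default <= 0 or a_c_actual <= 0:
        raise ValueError("membrane areas must be positive")
    from dataclasses import replace
    return replace(dist, area_override=a_c_default)
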