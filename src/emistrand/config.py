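"""Run configuration: YAML documents with explicit units, validated and defaulted.

A configuration document describes one simulation: cell geometry and strand
layout (µm), lattice spacings with optional graded x-refinement windows,
time steps (ms), physical parameters, the ionic model, the sodium-channel
distribution, the stimulus protocol, per-disc gap-junction resistance
factors and the probes to record.  An empty document yields the reference
defaults (100x18x18 µm body, 1 µm lateral spacing, 2 µm axial, Δt = 0.001 ms,
sigma_i = 4 mS/cm, sigma_e = 20 mS/cm, C_m = 1 µF/cm^2, C_disc = 0.5 µF/cm^2,
R_g = 0.0045 kOhm cm^2, uniform channels, 80 A/F for 1 ms on the first two
cells).  All lengths are given in µm in the document and stored in cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import numpy as np
import yaml

from .geometry import CellGeometry, StrandLayout, Spacings, Mesh, UM, build_strand, membrane_areas
from .channels import ChannelDistribution, assign_gna
from .ionic import StimulusProtocol, get_model
from .solver import PhysicalParameters, Probe, SimulationResult, run
from . import analysis


class ConfigError(ValueError):
    """Raised for malformed, unknown or dimensionally inconsistent entries."""


def _take(d: dict, section: str, known: dict) -> dict:
    """Pop a section, reject unknown keys, merge with defaults."""
    raw = d.pop(section, {}) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"section {section!r} must be a mapping")
    unknown = set(raw) - set(known)
    if unknown:
        raise ConfigError(f"unknown keys in {section!r}: {sorted(unknown)}")
    out = dict(known)
    out.update(raw)
    return out


@dataclass
class RunConfig:
    """Fully validated, unit-normalised description of one simulation."""

    geometry: CellGeometry
    layout: StrandLayout
    spacings: Spacings
    symmetry: tuple[str, ...]
    dt: float
    dt_ode: float
    t_end: float
    record_dt: float
    params: PhysicalParameters
    model_name: str
    distribution: ChannelDistribution
    stimulus: StimulusProtocol
    probe_cells: tuple[int, ...]
    record_ina: bool

    def build_mesh(self) -> Mesh:
        return build_strand(self.geometry, self.layout, self.spacings,
                            symmetry=self.symmetry)

    def execute(self, check_balance: bool = False) -> SimulationResult:
        mesh = self.build_mesh()
        quad = membrane_areas(mesh)
        model = get_model(self.model_name)
        fld = assign_gna(mesh, quad, self.distribution, model.gbar_na)
        probes = [Probe(f"cell{c}", analysis.cell_center_probe(mesh, c))
                  for c in self.probe_cells]
        return run(mesh, self.params, model, fld, self.stimulus,
                   self.dt, self.t_end, quadrature=quad, dt_ode=self.dt_ode,
                   probes=probes, record_dt=self.record_dt,
                   record_ina=self.record_ina, check_balance=check_balance)

    def to_yaml(self) -> str:
        geo = self.geometry
        doc = {
            "geometry": {
                "size_o_um": [v / UM for v in geo.size_o],
                "size_we_um": [v / UM for v in geo.size_we],
                "size_sn_um": [v / UM for v in geo.size_sn],
                "sn_x0_um": None if geo.sn_x0 is None else geo.sn_x0 / UM,
            },
            "layout": {"n_cells": self.layout.n_cells,
                       "padding_um": [p / UM for p in self.layout.padding]},
            "spacings": {"dx_um": self.spacings.dx / UM,
                         "dy_um": self.spacings.dy / UM,
                         "dz_um": self.spacings.dz / UM,
                         "refine_x_um": [[a / UM, b / UM, h / UM]
                                         for (a, b, h) in self.spacings.refine_x],
                         "symmetry": list(self.symmetry)},
            "time": {"dt_ms": self.dt, "dt_ode_ms": self.dt_ode,
                     "t_end_ms": self.t_end, "record_dt_ms": self.record_dt},
            "parameters": {"sigma_i": self.params.sigma_i,
                           "sigma_e": self.params.sigma_e,
                           "cm": self.params.cm, "c_disc": self.params.c_disc,
                           "r_gap": self.params.r_gap,
                           "rg_factors": {int(k): (None if np.isinf(v) else float(v))
                                          for k, v in self.params.rg_factors.items()}},
            "model": self.model_name,
            "distribution": {"p": self.distribution.p,
                             "region": self.distribution.region},
            "stimulus": {"amplitude": self.stimulus.amplitude,
                         "duration_ms": self.stimulus.duration,
                         "onset_ms": self.stimulus.onset,
                         "cells": list(self.stimulus.cells)},
            "probes": {"cells": list(self.probe_cells)},
            "output": {"record_ina": self.record_ina},
        }
        return yaml.safe_dump(doc, sort_keys=False)


def load_validate(text: str) -> RunConfig:
    """Parse and validate a configuration document; empty text gives defaults."""
    doc = yaml.safe_load(text) or {}
    if not isinstance(doc, dict):
        raise ConfigError("configuration must be a mapping")

    g = _take(doc, "geometry", {"size_o_um": [100.0, 18.0, 18.0],
                                "size_we_um": [2.0, 14.0, 14.0],
                                "size_sn_um": [14.0, 2.0, 14.0],
                                "sn_x0_um": None})
    lay = _take(doc, "layout", {"n_cells": 2, "padding_um": [10.0, 10.0, 4.0]})
    sp = _take(doc, "spacings", {"dx_um": 1.0, "dy_um": 1.0, "dz_um": 2.0,
                                 "refine_x_um": [], "symmetry": []})
    tm = _take(doc, "time", {"dt_ms": 0.001, "dt_ode_ms": None,
                             "t_end_ms": 10.0, "record_dt_ms": None})
    pr = _take(doc, "parameters", {"sigma_i": 4.0, "sigma_e": 20.0, "cm": 1.0,
                                   "c_disc": 0.5, "r_gap": 0.0045,
                                   "rg_factors": {}})
    model_name = doc.pop("model", "grandi_epicardial")
    di = _take(doc, "distribution", {"p": 0.0, "region": "horizontal_ends"})
    st = _take(doc, "stimulus", {"amplitude": 80.0, "duration_ms": 1.0,
                                 "onset_ms": 0.0, "cells": [0, 1]})
    pb = _take(doc, "probes", {"cells": []})
    out = _take(doc, "output", {"record_ina": False})
    if doc:
        raise ConfigError(f"unknown top-level sections: {sorted(doc)}")

    for key in ("sigma_i", "sigma_e", "cm", "c_disc", "r_gap"):
        if not (float(pr[key]) > 0):
            raise ConfigError(f"parameter {key} must be positive, got {pr[key]}")

    try:
        geometry = CellGeometry.from_um(g["size_o_um"], g["size_we_um"],
                                        g["size_sn_um"], g["sn_x0_um"])
        layout = StrandLayout(int(lay["n_cells"]),
                              tuple(float(p) * UM for p in lay["padding_um"]))
        spacings = Spacings.from_um(float(sp["dx_um"]), float(sp["dy_um"]),
                                    float(sp["dz_um"]),
                                    [tuple(map(float, w)) for w in sp["refine_x_um"]])
    except (ValueError, TypeError) as err:
        raise ConfigError(str(err)) from err

    dt = float(tm["dt_ms"])
    if dt <= 0:
        raise ConfigError("dt_ms must be positive")
    dt_ode = tm["dt_ode_ms"]
    dt_ode = min(0.001, dt) if dt_ode is None else float(dt_ode)
    record_dt = tm["record_dt_ms"]
    record_dt = dt if record_dt is None else float(record_dt)

    rg = {}
    for k, v in (pr["rg_factors"] or {}).items():
        rg[int(k)] = np.inf if v is None else float(v)
    params = PhysicalParameters(sigma_i=float(pr["sigma_i"]),
                                sigma_e=float(pr["sigma_e"]),
                                cm=float(pr["cm"]), c_disc=float(pr["c_disc"]),
                                r_gap=float(pr["r_gap"]), rg_factors=rg)
    get_model(model_name)  # validates the name
    dist = ChannelDistribution(p=float(di["p"]), region=str(di["region"]))
    stim = StimulusProtocol(amplitude=float(st["amplitude"]),
                            duration=float(st["duration_ms"]),
                            onset=float(st["onset_ms"]),
                            cells=tuple(int(c) for c in st["cells"]))
    return RunConfig(geometry=geometry, layout=layout, spacings=spacings,
                     symmetry=tuple(sp["symmetry"]), dt=dt, dt_ode=dt_ode,
                     t_end=float(tm["t_end_ms"]), record_dt=record_dt,
                     params=params, model_name=str(model_name),
                     distribution=dist, stimulus=stim,
                     probe_cells=tuple(int(c) for c in pb["cells"]),
                     record_ina=bool(out["record_ina"]))


# ---------------------------------------------------------------------------
# exports


def export_vtk(mesh: Mesh, path: str, fields: dict | None = None) -> None:
    """Write the classified lattice as a legacy ASCII VTK rectilinear grid.

    ``fields`` maps names to arrays over the full lattice (mesh.shape); the
    node-class array is always included.
    """
    nx, ny, nz = mesh.shape
    fields = dict(fields or {})
    fields["node_class"] = mesh.label.astype(float)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("emistrand lattice (lengths in cm)\n")
        f.write("ASCII\nDATASET RECTILINEAR_GRID\n")
        f.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        for name, coords in (("X", mesh.xs), ("Y", mesh.ys), ("Z", mesh.zs)):
            f.write(f"{name}_COORDINATES {len(coords)} double\n")
            f.write(" ".join(f"{c:.9g}" for c in coords) + "\n")
        f.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in fields.items():
            if arr.shape != mesh.shape:
                raise ValueError(f"field {name!r} has shape {arr.shape}, "
                                 f"expected {mesh.shape}")
            f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            # VTK expects x fastest; our arrays are (x, y, z) C-ordered
            flat = np.transpose(arr, (2, 1, 0)).reshape(-1)
            f.write("\n".join(f"{v:.9g}" for v in flat) + "\n")


def membrane_field_to_lattice(mesh: Mesh, values: np.ndarray,
                              fill: float = np.nan) -> np.ndarray:
    """Scatter a per-membrane-node array onto the full lattice for export."""
    out = np.full(mesh.shape, fill)
    out.reshape(-1)[mesh.membrane.flat] = values
    return out
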