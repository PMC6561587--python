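"""Pluggable membrane kinetics evaluated per membrane node.

A model supplies the transmembrane current density I_ion(v, s) (µA/cm^2,
positive outward) and the state derivatives ds/dt = F(v, s), both vectorised
over nodes.  The fast sodium current is separately retrievable and scales
linearly with the per-node conductance density supplied by the channel
distribution.  State lives only on membrane nodes; intercalated discs carry
no ionic current.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np


class IonicModel:
    """Contract for membrane kinetics models.

    Subclasses define ``state_names``, ``gbar_na`` (default sodium
    conductance density, mS/cm^2), ``v_rest`` (mV) and the vectorised
    evaluation methods below.
    """

    name: str = "base"
    state_names: tuple[str, ...] = ()
    gbar_na: float = 0.0
    v_rest: float = 0.0

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def initial_state(self, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
        """Resting (v, s) arrays of shapes (n,) and (n_states, n)."""
        raise NotImplementedError

    def rates(self, v: np.ndarray, s: np.ndarray, g_na) -> tuple[np.ndarray, np.ndarray]:
        """(I_ion, ds/dt); I_ion in µA/cm^2 positive outward, ds/dt in 1/ms."""
        raise NotImplementedError

    def i_na(self, v: np.ndarray, s: np.ndarray, g_na) -> np.ndarray:
        """Fast sodium current density alone (µA/cm^2, negative inward)."""
        raise NotImplementedError


@dataclass(frozen=True)
class StimulusProtocol:
    """External stimulus applied to all membrane nodes of selected cells.

    ``amplitude`` is in A/F; multiplied by C_m (µF/cm^2) it yields an inward
    current density in µA/cm^2.  Default: 80 A/F for 1 ms from t = 0 on the
    first two cells.
    """

    amplitude: float = 80.0
    duration: float = 1.0
    onset: float = 0.0
    cells: tuple[int, ...] = (0, 1)

    def active(self, t: float) -> bool:
        return self.onset <= t < self.onset + self.duration

    def current_density(self, t: float, cm: float) -> float:
        """Inward stimulus current density (µA/cm^2) at time t."""
        return self.amplitude * cm if self.active(t) else 0.0


def ode_substeps(model: IonicModel, v: np.ndarray, s: np.ndarray, g_na,
                 dt: float, dt_star: float, cm: float,
                 i_stim: np.ndarray | float = 0.0,
                 t: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Advance the membrane ODEs by m = dt/dt_star forward-Euler substeps.

    Integrates dv/dt = -(I_ion - I_stim)/C_m together with ds/dt = F(v, s);
    the spatial coupling current is handled by the implicit PDE step and is
    zero here.  ``dt_star`` should be min(0.001 ms, dt); ``i_stim`` is an
    inward current density (µA/cm^2) added on stimulated nodes.
    """
    m = max(1, int(round(dt / dt_star)))
    h = dt / m
    v = v.copy()
    s = s.copy()
    for _ in range(m):
        i_ion, ds = model.rates(v, s, g_na)
        v += h * (-(i_ion - i_stim) / cm)
        s += h * ds
    if not np.all(np.isfinite(v)):
        bad = int(np.flatnonzero(~np.isfinite(v))[0])
        raise FloatingPointError(
            f"membrane potential became non-finite at node {bad}, t = {t + dt:.4f} ms")
    return v, s


def grandi_epicardial() -> IonicModel:
    """Epicardial human-ventricular membrane model (gating-level port)."""
    from .grandi import GrandiEpicardial
    return GrandiEpicardial()

def reduced_test_model() -> IonicModel:
    """Small excitable surrogate (fast sodium + rectifier) for quick runs."""
    from .reduced import ReducedModel
    return ReducedModel()

def get_model(name: str) -> IonicModel:
    """Model registry used by the configuration layer."""
    try:
        return {"grandi_epicardial": grandi_epicardial,
                "reduced": reduced_test_model}[name]()
    except KeyError:
        raise ValueError(f"unknown ionic model {name!r}") from None
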