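"""Reduced excitable membrane model for fast tests and convergence studies.

Four gating states: the fast sodium current uses the same (m, h, j)
formulation as the full ventricular model, paired with an inward-rectifier
K+ current that pins the resting potential near E_K and a single slow
delayed-rectifier-like gate that repolarises the action potential.  The
model produces regenerative upstrokes (dv/dt max well above 50 mV/ms) and
propagating waves in the tissue solver at a small fraction of the cost of
the full model.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from . import IonicModel

_R, _FRDY, _T = 8314.0, 96485.0, 310.0
_FoRT = _FRDY / (_R * _T)
_NAO, _NAI = 140.0, 10.0
_KO, _KI = 5.4, 135.0


class ReducedModel(IonicModel):

    name = "reduced"
    state_names = ("m", "h", "j", "x")
    gbar_na = 23.0   # mS/cm^2
    g_k1 = 0.35
    g_x = 0.3
    g_leak = 0.0006

    def __init__(self):
        self.e_na = np.log(_NAO / _NAI) / _FoRT
        self.e_k = np.log(_KO / _KI) / _FoRT
        self.v_rest = brentq(self._rest_current, -95.0, -60.0, xtol=1e-10)

    def _gates_inf_tau(self, v):
        v = np.asarray(v, dtype=float)
        inf, tau = {}, {}
        inf["m"] = 1.0 / (1 + np.exp(-(56.86 + v) / 9.03)) ** 2
        tau["m"] = (0.1292 * np.exp(-(((v + 45.79) / 15.54) ** 2))
                    + 0.06487 * np.exp(-(((v - 4.823) / 51.12) ** 2)))
        low = v < -40
        ah = np.where(low, 0.057 * np.exp(-(v + 80) / 6.8), 0.0)
        bh = np.where(low, 2.7 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.3485 * v),
                      0.77 / (0.13 * (1 + np.exp(-(v + 10.66) / 11.1))))
        inf["h"] = 1.0 / (1 + np.exp((v + 71.55) / 7.43)) ** 2
        tau["h"] = 1.0 / (ah + bh)
        with np.errstate(over="ignore"):
            aj = np.where(
                low,
                (-2.5428e4 * np.exp(0.2444 * v) - 6.948e-6 * np.exp(-0.04391 * v))
                * (v + 37.78) / (1 + np.exp(0.311 * (v + 79.23))),
                0.0)
            bj = np.where(
                low,
                0.02424 * np.exp(-0.01052 * v) / (1 + np.exp(-0.1378 * (v + 40.14))),
                0.6 * np.exp(0.057 * v) / (1 + np.exp(-0.1 * (v + 32))))
        inf["j"] = inf["h"]
        tau["j"] = 1.0 / (aj + bj)
        inf["x"] = 1.0 / (1 + np.exp(-(v + 10.0) / 10.0))
        tau["x"] = np.full_like(np.asarray(v, dtype=float), 300.0)
        return inf, tau

    def _currents(self, v, s, g_na):
        m, h, j, x = s
        i_na = g_na * m ** 3 * h * j * (v - self.e_na)
        dvk = v - self.e_k
        aki = 1.02 / (1 + np.exp(0.2385 * (dvk - 59.215)))
        with np.errstate(over="ignore"):
            bki = ((0.49124 * np.exp(0.08032 * (dvk + 5.476))
                    + np.exp(0.06175 * (dvk - 594.31)))
                   / (1 + np.exp(-0.5143 * (dvk + 4.753))))
        i_k1 = self.g_k1 * aki / (aki + bki) * dvk
        i_x = self.g_x * x * dvk
        i_leak = self.g_leak * (v - self.e_na)
        return i_na + i_k1 + i_x + i_leak, i_na

    def _rest_current(self, v):
        v = np.float64(v)
        inf, _ = self._gates_inf_tau(v)
        s = np.array([inf[n] for n in self.state_names])
        total, _ = self._currents(v, s, self.gbar_na)
        return float(total)

    def initial_state(self, n_nodes: int):
        v = np.full(n_nodes, self.v_rest)
        inf, _ = self._gates_inf_tau(np.float64(self.v_rest))
        s0 = np.array([float(inf[n]) for n in self.state_names])
        return v, np.repeat(s0[:, None], n_nodes, axis=1)

    def rates(self, v, s, g_na):
        total, _ = self._currents(v, s, g_na)
        inf, tau = self._gates_inf_tau(v)
        ds = np.empty_like(s)
        for i, name in enumerate(self.state_names):
            ds[i] = (inf[name] - s[i]) / tau[name]
        return total, ds

    def i_na(self, v, s, g_na):
        return g_na * s[0] ** 3 * s[1] * s[2] * (v - self.e_na)
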