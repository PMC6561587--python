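"""Gating-level port of the Grandi et al. epicardial human ventricular model.

The port keeps the full complement of sarcolemmal currents (fast and
background Na+, Na+/K+ pump, rapid/slow/plateau/transient-outward/inward-
rectifier K+, Ca2+-activated and background Cl-, L-type Ca2+ with GHK flux,
Na+/Ca2+ exchange, sarcolemmal Ca2+ pump and background Ca2+) and all thirteen
gating variables, but holds the intracellular and subcompartment ion
concentrations fixed at their resting values.  Over the 10-50 ms windows
relevant for conduction — the action-potential foot, upstroke and early
plateau — concentration excursions have a negligible effect on the currents,
while clamping removes the slow-drift bookkeeping of the full model.  The
resting potential is determined at construction by solving I_ion(v, s_inf(v))
= 0, so a resting membrane is an exact equilibrium of the port.

Currents are densities in µA/cm^2 with the convention that a specific
membrane capacitance of 1 µF/cm^2 makes them numerically equal to A/F.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from . import IonicModel

# physical constants
_R = 8314.0        # J / (kmol K)
_FRDY = 96485.0    # C / mol
_T = 310.0         # K
_FoRT = _FRDY / (_R * _T)

# fixed extracellular / clamped intracellular concentrations (mM)
_NAO, _KO, _CAO = 140.0, 5.4, 1.8
_CLI, _CLO = 15.0, 150.0
_KI = 120.0
_NAJ = _NASL = 9.136
_CAJ, _CASL = 1.737e-4, 1.031e-4

# membrane fractions
_FJUNC, _FSL = 0.11, 0.89
_FJUNC_CAL, _FSL_CAL = 0.9, 0.1

_STATE = ("m", "h", "j", "d", "f", "fcaBj", "fcaBsl",
          "xtos", "ytos", "xtof", "ytof", "xkr", "xks")


def _ghk(v, z, ci, co, perm):
    """GHK flux density for valence z; finite limit at v = 0."""
    vv = np.where(np.abs(v) < 1e-6, 1e-6, v)
    a = z * vv * _FoRT
    return perm * z * vv * _FRDY * _FoRT * (ci * np.exp(a) - co) / (np.exp(a) - 1.0)


class GrandiEpicardial(IonicModel):

    name = "grandi_epicardial"
    state_names = _STATE
    gbar_na = 23.0  # mS/cm^2

    # conductances / maximal rates
    g_nab = 0.597e-3
    ibar_nak = 1.8
    g_ks = 0.0035
    g_kp = 0.002
    g_to_slow = 0.0156   # epicardial split
    g_to_fast = 0.1144
    g_k1 = 0.35
    g_clca = 0.0548
    g_clb = 9e-3
    p_ca = 2.7e-4        # cm/s (0.5 * 5.4e-4)
    p_k = 1.35e-7
    p_na = 0.75e-8
    ibar_ncx = 4.5
    ibar_pca = 0.0673
    g_cab = 5.513e-4

    def __init__(self):
        self.e_na_junc = np.log(_NAO / _NAJ) / _FoRT
        self.e_na_sl = np.log(_NAO / _NASL) / _FoRT
        self.e_k = np.log(_KO / _KI) / _FoRT
        self.e_ca_junc = np.log(_CAO / _CAJ) / (2 * _FoRT)
        self.e_ca_sl = np.log(_CAO / _CASL) / (2 * _FoRT)
        self.e_cl = np.log(_CLI / _CLO) / _FoRT
        self.e_ks = np.log((_KO + 0.01833 * _NAO) / (_KI + 0.01833 * _NAJ)) / _FoRT
        self.v_rest = self._find_rest()

    # -- gate kinetics ------------------------------------------------------
    def _gates_inf_tau(self, v):
        v = np.asarray(v, dtype=float)
        inf = {}
        tau = {}
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

        vv = np.where(np.abs(v + 5.0) < 1e-6, -5.0 + 1e-6, v)
        inf["d"] = 1.0 / (1 + np.exp(-(vv + 5) / 6.0))
        tau["d"] = inf["d"] * (1 - np.exp(-(vv + 5) / 6.0)) / (0.035 * (vv + 5))
        inf["f"] = (1.0 / (1 + np.exp((v + 35) / 9.0))
                    + 0.6 / (1 + np.exp((50 - v) / 20.0)))
        tau["f"] = 1.0 / (0.0197 * np.exp(-((0.0337 * (v + 14.5)) ** 2)) + 0.02)

        inf["xtos"] = 1.0 / (1 + np.exp(-(v - 19.0) / 13.0))
        tau["xtos"] = 9.0 / (1 + np.exp((v + 3.0) / 15.0)) + 0.5
        inf["ytos"] = 1.0 / (1 + np.exp((v + 19.5) / 5.0))
        tau["ytos"] = 800.0 / (1 + np.exp((v + 60.0) / 10.0)) + 30.0
        inf["xtof"] = inf["xtos"]
        tau["xtof"] = 8.5 * np.exp(-(((v + 45) / 50.0) ** 2)) + 0.5
        inf["ytof"] = inf["ytos"]
        tau["ytof"] = 85.0 * np.exp(-((v + 40.0) ** 2) / 220.0) + 7.0

        inf["xkr"] = 1.0 / (1 + np.exp(-(v + 10) / 5.0))
        tau["xkr"] = (550.0 / (1 + np.exp((-22 - v) / 9.0))
                      * 6.0 / (1 + np.exp((v + 11) / 9.0))
                      + 230.0 / (1 + np.exp((v + 40) / 20.0)))
        inf["xks"] = 1.0 / (1 + np.exp(-(v + 3.8) / 14.25))
        tau["xks"] = 990.1 / (1 + np.exp(-(v + 2.436) / 14.12))
        return inf, tau

    @staticmethod
    def _fcab_inf(ca):
        return 1.7 * ca / (1.7 * ca + 11.9e-3)

    # -- currents -----------------------------------------------------------
    def _currents(self, v, s, g_na):
        m, h, j, d, f, fcaBj, fcaBsl, xtos, ytos, xtof, ytof, xkr, xks = s
        i_na = g_na * m ** 3 * h * j * (
            _FJUNC * (v - self.e_na_junc) + _FSL * (v - self.e_na_sl))
        e_na = _FJUNC * self.e_na_junc + _FSL * self.e_na_sl
        i_nab = self.g_nab * (v - e_na)

        sigma = (np.exp(_NAO / 67.3) - 1) / 7.0
        fnak = 1.0 / (1 + 0.1245 * np.exp(-0.1 * v * _FoRT)
                      + 0.0365 * sigma * np.exp(-v * _FoRT))
        i_nak = (self.ibar_nak * fnak * _KO
                 / (1 + (11.0 / _NAJ) ** 4) / (_KO + 1.5))

        gkr = 0.035 * np.sqrt(_KO / 5.4)
        rkr = 1.0 / (1 + np.exp((v + 74) / 24.0))
        i_kr = gkr * xkr * rkr * (v - self.e_k)
        i_ks = self.g_ks * xks ** 2 * (v - self.e_ks)
        i_kp = self.g_kp * (v - self.e_k) / (1 + np.exp(7.488 - v / 5.98))
        i_to = (self.g_to_slow * xtos * ytos
                + self.g_to_fast * xtof * ytof) * (v - self.e_k)

        dvk = v - self.e_k
        aki = 1.02 / (1 + np.exp(0.2385 * (dvk - 59.215)))
        with np.errstate(over="ignore"):
            bki = ((0.49124 * np.exp(0.08032 * (dvk + 5.476))
                    + np.exp(0.06175 * (dvk - 594.31)))
                   / (1 + np.exp(-0.5143 * (dvk + 4.753))))
        i_k1 = self.g_k1 * np.sqrt(_KO / 5.4) * aki / (aki + bki) * dvk

        i_clca = self.g_clca * (v - self.e_cl) * (
            _FJUNC / (1 + 0.1 / _CAJ) + _FSL / (1 + 0.1 / _CASL))
        i_clb = self.g_clb * (v - self.e_cl)

        open_cal = d * f
        i_ca = 0.45 * open_cal * (
            _FJUNC_CAL * (1 - fcaBj) * _ghk(v, 2, 0.341 * _CAJ, 0.341 * _CAO, self.p_ca)
            + _FSL_CAL * (1 - fcaBsl) * _ghk(v, 2, 0.341 * _CASL, 0.341 * _CAO, self.p_ca))
        fca_mix = _FJUNC_CAL * (1 - fcaBj) + _FSL_CAL * (1 - fcaBsl)
        i_cak = 0.45 * open_cal * fca_mix * _ghk(v, 1, 0.75 * _KI, 0.75 * _KO, self.p_k)
        i_cana = 0.45 * open_cal * fca_mix * _ghk(v, 1, 0.75 * _NAJ, 0.75 * _NAO, self.p_na)

        i_ncx = self._ncx(v)
        i_pca = (self.ibar_pca
                 * (_FJUNC * _CAJ ** 1.6 / (0.5e-3 ** 1.6 + _CAJ ** 1.6)
                    + _FSL * _CASL ** 1.6 / (0.5e-3 ** 1.6 + _CASL ** 1.6)))
        e_ca = _FJUNC * self.e_ca_junc + _FSL * self.e_ca_sl
        i_cab = self.g_cab * (v - e_ca)

        total = (i_na + i_nab + i_nak + i_kr + i_ks + i_kp + i_to + i_k1
                 + i_clca + i_clb + i_ca + i_cak + i_cana + i_ncx + i_pca + i_cab)
        return total, i_na

    def _ncx(self, v):
        nu, ksat = 0.27, 0.32
        km_cai, km_cao, km_nai, km_nao = 3.59e-3, 1.3, 12.29, 87.5
        out = 0.0
        for frac, na_i, ca_i in ((_FJUNC, _NAJ, _CAJ), (_FSL, _NASL, _CASL)):
            ka = 1.0 / (1 + (0.15e-3 / ca_i) ** 2)
            s1 = np.exp(nu * v * _FoRT) * na_i ** 3 * _CAO
            s2 = np.exp((nu - 1) * v * _FoRT) * _NAO ** 3 * ca_i
            s3 = (km_cai * _NAO ** 3 * (1 + (na_i / km_nai) ** 3)
                  + km_nao ** 3 * ca_i * (1 + ca_i / km_cai)
                  + km_cao * na_i ** 3 + na_i ** 3 * _CAO + _NAO ** 3 * ca_i)
            out = out + (frac * self.ibar_ncx * ka * (s1 - s2)
                         / (s3 * (1 + ksat * np.exp((nu - 1) * v * _FoRT))))
        return out

    # -- contract -----------------------------------------------------------
    def _steady_state(self, v):
        inf, _ = self._gates_inf_tau(v)
        vals = [inf[n] for n in ("m", "h", "j", "d", "f")]
        vals += [np.full_like(np.asarray(v, dtype=float), self._fcab_inf(_CAJ)),
                 np.full_like(np.asarray(v, dtype=float), self._fcab_inf(_CASL))]
        vals += [inf[n] for n in ("xtos", "ytos", "xtof", "ytof", "xkr", "xks")]
        return np.array([np.broadcast_to(x, np.shape(v)) if np.shape(v) else x
                         for x in vals])

    def _find_rest(self) -> float:
        def f(v):
            s = self._steady_state(np.float64(v))
            total, _ = self._currents(np.float64(v), s, self.gbar_na)
            return float(total)
        return brentq(f, -95.0, -60.0, xtol=1e-10)

    def initial_state(self, n_nodes: int):
        v = np.full(n_nodes, self.v_rest)
        s0 = self._steady_state(np.float64(self.v_rest))
        s = np.repeat(np.asarray(s0, dtype=float)[:, None], n_nodes, axis=1)
        return v, s

    def rates(self, v, s, g_na):
        total, _ = self._currents(v, s, g_na)
        inf, tau = self._gates_inf_tau(v)
        ds = np.empty_like(s)
        for i, name in enumerate(_STATE):
            if name == "fcaBj":
                ds[i] = 1.7 * _CAJ * (1 - s[i]) - 11.9e-3 * s[i]
            elif name == "fcaBsl":
                ds[i] = 1.7 * _CASL * (1 - s[i]) - 11.9e-3 * s[i]
            else:
                ds[i] = (inf[name] - s[i]) / tau[name]
        return total, ds

    def i_na(self, v, s, g_na):
        m, h, j = s[0], s[1], s[2]
        return g_na * m ** 3 * h * j * (
            _FJUNC * (v - self.e_na_junc) + _FSL * (v - self.e_na_sl))
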