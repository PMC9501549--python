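"""Full reaction-network right-hand side and stiff integration.

Couples the nine-state Ca²⁺–CaM module to its five binding targets
(AC1, AC8, PDE1, PP2B's CaNA subunit, CaMKII), CaMKII T286
autophosphorylation and its dephosphorylation by PP1/PP2A, cAMP
production (CaM-bound AC1/AC8 plus CaM-independent AC*) and hydrolysis
(PDE1, PDE4B/D with their PKA-phosphorylated forms), the I-1/PP1 switch,
and PKA in either full (four-state) or reduced (algebraic Hill) mode.

Only fully loaded CaM₄ binds targets.  Free pools (AC1, PP1, I-1, ...)
are eliminated algebraically through their conservation laws, so every
total pool is conserved by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .cam import CAM4, CAM_STATE_NAMES, cam_fluxes, equilibrate_cam
from .parameters import ParameterSet
from .pka import pka_reduced
from .stimulus import StimulusProtocol, calcium_trace

__all__ = ["SPECIES", "NetworkState", "SimulationResult", "network_rhs",
           "integrate", "observables", "initial_state", "conserved_pools"]

SPECIES = CAM_STATE_NAMES + (
    "CaMAC1", "CaMAC8", "CaMPDE1", "CaMCaNA",
    "CaMCaMKII", "CaMCaMKIIP", "CaMKIIP",
    "cAMP", "PDE4BP", "PDE4DP", "I1P", "I1PP1",
    "R2C2", "R2C2cAMP2", "R2C2cAMP4", "PKAc",
)
_IDX = {name: i for i, name in enumerate(SPECIES)}
N_SPECIES = len(SPECIES)

#: species bound to CaM₄ (count toward the CaM pool and toward "total CaM₄")
CAM_BOUND = ("CaMAC1", "CaMAC8", "CaMPDE1", "CaMCaNA", "CaMCaMKII", "CaMCaMKIIP")

NetworkState = np.ndarray  # concentration vector in SPECIES order, µM


def initial_state(p: ParameterSet) -> NetworkState:
    """Rest initial conditions: complexes at zero, CaM equilibrated at basal Ca²⁺."""
    y0 = np.zeros(N_SPECIES)
    y0[:9] = equilibrate_cam(p.Ca_basal, p)
    y0[_IDX["R2C2"]] = p.R2C2_T
    return y0


def _hill(x: float, k: float, n: float) -> float:
    if x <= 0.0:
        return 0.0
    xn = x**n
    return xn / (xn + k**n)


def _make_rhs(p: ParameterSet, mode: str, orientation: str):
    """Compile the network right-hand side into a closure of scalar arithmetic.

    The nine-state CaM block is unrolled (index = 3·c_load + n_load); the
    solver spends essentially all its time here, so the hot path avoids any
    attribute lookups and array temporaries beyond the output vector.
    """
    # CaM lobe rates with statistical factors
    onN0, onN1 = 2.0 * p.kon_NT, p.kon_NR
    offN1, offN2 = p.koff_NT, 2.0 * p.koff_NR
    onC0, onC1 = 2.0 * p.kon_CT, p.kon_CR
    offC1, offC2 = p.koff_CT, 2.0 * p.koff_CR
    kc1f, kc1b, kc2f, kc2b, kc3f, kc3b = p.kc1f, p.kc1b, p.kc2f, p.kc2b, p.kc3f, p.kc3b
    kc4f, kc4b1, Kd1, n1, kc4b2, Kd2, n2 = p.kc4f, p.kc4b1, p.Kd1, p.n1, p.kc4b2, p.Kd2, p.n2
    kc5f, kc5b1, kc5b2 = p.kc5f, p.kc5b1, p.kc5b2
    K1, n_canb = p.K1, p.n_canb
    AC1_T, AC8_T, ACstar_T, PDE1_T = p.AC1_T, p.AC8_T, p.ACstar_T, p.PDE1_T
    PP2B_T, CaMKII_T, PP1_T, PP2A_T, I1_T = p.PP2B_T, p.CaMKII_T, p.PP1_T, p.PP2A_T, p.I1_T
    PDE4B_T, PDE4D_T = p.PDE4B_T, p.PDE4D_T
    kcat1, kcat2, kcat3 = p.kcat1, p.kcat2, p.kcat3
    kcat4, Km4, k10 = p.kcat4, p.Km4, p.k10
    kcat5, kcat6, Km5 = p.kcat5, p.kcat6, p.Km5
    kcat7, kcat8, Km7 = p.kcat7, p.kcat8, p.Km7
    kcat9, kcat10, Km9 = p.kcat9, p.kcat10, p.Km9
    kcat11, Km11, kcat12, Km12, kcat13, Km13 = (p.kcat11, p.Km11, p.kcat12,
                                                p.Km12, p.kcat13, p.Km13)
    kcat14, kcat15, Km15, kcat16, Km16 = p.kcat14, p.kcat15, p.Km15, p.kcat16, p.Km16
    k17f, k17b, k18f, k18b = p.k17f, p.k17b, p.k18f, p.k18b
    if orientation == "release_slow":
        krel, kreb = p.k19b, p.k19f
    elif orientation == "release_fast":
        krel, kreb = p.k19f, p.k19b
    else:
        raise ValueError(f"unknown k19 orientation: {orientation!r}")
    kon_ip, koff_ip = p.kon_i1pp1, p.koff_i1pp1
    pka_max, pka_ic50, pka_n = p.pka_max, p.pka_ic50, p.pka_n
    full = mode == "full_pka"
    if not full and mode != "reduced_pka":
        raise ValueError(f"unknown mode: {mode!r}")

    def rhs(t: float, y: np.ndarray, Ca: float) -> np.ndarray:
        (s0, s1, s2, s3, s4, s5, s6, s7, s8,
         cam_ac1, cam_ac8, cam_pde1, cam_cana, cam_k2, cam_k2p, k2p_free,
         camp, pde4bp, pde4dp, i1p, i1pp1, R, R2, R4, pkac_dyn) = y

        dy = np.empty(25)
        aN0, aN1 = onN0 * Ca, onN1 * Ca
        aC0, aC1 = onC0 * Ca, onC1 * Ca
        # N-lobe transitions within each C-row
        fn0 = aN0 * s0 - offN1 * s1
        fn1 = aN1 * s1 - offN2 * s2
        fn2 = aN0 * s3 - offN1 * s4
        fn3 = aN1 * s4 - offN2 * s5
        fn4 = aN0 * s6 - offN1 * s7
        fn5 = aN1 * s7 - offN2 * s8
        # C-lobe transitions within each N-column
        fc0 = aC0 * s0 - offC1 * s3
        fc1 = aC1 * s3 - offC2 * s6
        fc2 = aC0 * s1 - offC1 * s4
        fc3 = aC1 * s4 - offC2 * s7
        fc4 = aC0 * s2 - offC1 * s5
        fc5 = aC1 * s5 - offC2 * s8

        dy[0] = -fn0 - fc0
        dy[1] = fn0 - fn1 - fc2
        dy[2] = fn1 - fc4
        dy[3] = -fn2 + fc0 - fc1
        dy[4] = fn2 - fn3 + fc2 - fc3
        dy[5] = fn3 + fc4 - fc5
        dy[6] = -fn4 + fc1
        dy[7] = fn4 - fn5 + fc3
        dy[8] = fn5 + fc5

        cam4 = s8 if s8 > 0.0 else 0.0
        # reversible CaM4 + target binding
        f_ac1 = kc1f * cam4 * (AC1_T - cam_ac1) - kc1b * cam_ac1
        f_ac8 = kc2f * cam4 * (AC8_T - cam_ac8) - kc2b * cam_ac8
        f_pde1 = kc3f * cam4 * (PDE1_T - cam_pde1) - kc3b * cam_pde1
        # PP2B: only Ca-loaded CaNB (fast pre-equilibrium on K1) presents
        # CaNA; the off-rate blends the high-/low-Ca limits (Hill weights)
        cana_avail = (PP2B_T - cam_cana) * _hill(Ca, K1, n_canb)
        koff_cana = kc4b1 * _hill(Ca, Kd1, n1) + kc4b2 * (1.0 - _hill(Ca, Kd2, n2))
        f_cana = kc4f * cam4 * cana_avail - koff_cana * cam_cana
        k2_free = CaMKII_T - cam_k2 - cam_k2p - k2p_free
        f_k2 = kc5f * cam4 * k2_free - kc5b1 * cam_k2
        f_k2p = kc5f * cam4 * k2p_free - kc5b2 * cam_k2p

        dy[8] -= f_ac1 + f_ac8 + f_pde1 + f_cana + f_k2 + f_k2p
        dy[9] = f_ac1
        dy[10] = f_ac8
        dy[11] = f_pde1
        dy[12] = f_cana

        # T286 flux needs an occupied neighbouring subunit (mean-field
        # probability = CaM-bound fraction of the holoenzyme pool)
        phos = kcat14 * cam_k2 * (cam_k2 + cam_k2p) / CaMKII_T
        pp1_active = PP1_T - i1pp1
        s_phos = cam_k2p + k2p_free
        if s_phos > 0.0:
            dep_tot = (kcat15 * pp1_active * s_phos / (Km15 + s_phos)
                       + kcat16 * PP2A_T * s_phos / (Km16 + s_phos))
            dep_bound = dep_tot * cam_k2p / s_phos
            dep_free = dep_tot * k2p_free / s_phos
        else:
            dep_bound = dep_free = 0.0
        dy[13] = f_k2 - phos + dep_bound
        dy[14] = f_k2p + phos - dep_bound
        dy[15] = -f_k2p - dep_free

        # cAMP production and hydrolysis
        c = camp if camp > 0.0 else 0.0
        prod = kcat1 * cam_ac1 + kcat2 * cam_ac8 + kcat3 * ACstar_T
        hyd = ((kcat5 * (PDE1_T - cam_pde1) + kcat6 * cam_pde1) * c / (Km5 + c)
               + (kcat7 * (PDE4B_T - pde4bp) + kcat8 * pde4bp) * c / (Km7 + c)
               + (kcat9 * (PDE4D_T - pde4dp) + kcat10 * pde4dp) * c / (Km9 + c))
        dcamp = prod - hyd

        if full:
            c2 = c * c
            f1 = k17f * R * c2 - k17b * R2
            f2 = k18f * R2 * c2 - k18b * R4
            rel = krel * R4
            reb = kreb * 0.5 * pkac_dyn * pkac_dyn * pkac_dyn
            dy[21] = -f1
            dy[22] = f1 - f2
            dy[23] = f2 - rel + reb
            dy[24] = 2.0 * (rel - reb)
            dcamp -= 2.0 * f1 + 2.0 * f2
            pkac = pkac_dyn
        else:
            dy[21] = dy[22] = dy[23] = dy[24] = 0.0
            pkac = pka_max / (1.0 + (pka_ic50 / c) ** pka_n) if c > 0.0 else 0.0
        dy[16] = dcamp

        # PKA substrates: PDE4B/D and I-1
        pde4b = PDE4B_T - pde4bp
        pde4d = PDE4D_T - pde4dp
        dy[17] = kcat4 * pkac * pde4b / (Km4 + pde4b) - k10 * pde4bp
        dy[18] = kcat4 * pkac * pde4d / (Km4 + pde4d) - k10 * pde4dp

        i1_free = I1_T - i1p - i1pp1
        if i1_free < 0.0:
            i1_free = 0.0
        phos_i1 = kcat11 * pkac * i1_free / (Km11 + i1_free)
        # PP2A/PP2B dephosphorylate phospho-I-1 whether free or PP1-bound;
        # the complexed route releases PP1
        ip = i1p if i1p > 0.0 else 0.0
        ipc = i1pp1 if i1pp1 > 0.0 else 0.0
        s_i1 = ip + ipc
        if s_i1 > 0.0:
            dep_tot = (kcat12 * PP2A_T * s_i1 / (Km12 + s_i1)
                       + kcat13 * cam_cana * s_i1 / (Km13 + s_i1))
            dep_free_i1 = dep_tot * ip / s_i1
            dep_cplx_i1 = dep_tot * ipc / s_i1
        else:
            dep_free_i1 = dep_cplx_i1 = 0.0
        bind = kon_ip * ip * (pp1_active if pp1_active > 0.0 else 0.0) - koff_ip * i1pp1
        dy[19] = phos_i1 - dep_free_i1 - bind
        dy[20] = bind - dep_cplx_i1
        return dy

    return rhs


def _rhs(t: float, y: np.ndarray, Ca: float, p: ParameterSet, mode: str,
         orientation: str) -> np.ndarray:
    return _make_rhs(p, mode, orientation)(t, y, Ca)


# ----------------------------------------------------------------------
# Compiled fast path.  The kernel below is an exact transliteration of the
# closure returned by `_make_rhs`; the test suite asserts equality of the
# two on random states.  Constants are packed into a flat vector so the
# kernel compiles once per process and is reused for every parameter set.

def _pack(p: ParameterSet, mode: str, orientation: str) -> np.ndarray:
    if orientation == "release_slow":
        krel, kreb = p.k19b, p.k19f
    elif orientation == "release_fast":
        krel, kreb = p.k19f, p.k19b
    else:
        raise ValueError(f"unknown k19 orientation: {orientation!r}")
    if mode not in ("full_pka", "reduced_pka"):
        raise ValueError(f"unknown mode: {mode!r}")
    return np.array([
        2.0 * p.kon_NT, p.kon_NR, p.koff_NT, 2.0 * p.koff_NR,
        2.0 * p.kon_CT, p.kon_CR, p.koff_CT, 2.0 * p.koff_CR,
        p.kc1f, p.kc1b, p.kc2f, p.kc2b, p.kc3f, p.kc3b,
        p.kc4f, p.kc4b1, p.Kd1, p.n1, p.kc4b2, p.Kd2, p.n2,
        p.kc5f, p.kc5b1, p.kc5b2,
        p.K1, p.n_canb,
        p.AC1_T, p.AC8_T, p.ACstar_T, p.PDE1_T, p.PP2B_T, p.CaMKII_T,
        p.PP1_T, p.PP2A_T, p.I1_T, p.PDE4B_T, p.PDE4D_T,
        p.kcat1, p.kcat2, p.kcat3, p.kcat4, p.Km4, p.k10,
        p.kcat5, p.kcat6, p.Km5, p.kcat7, p.kcat8, p.Km7,
        p.kcat9, p.kcat10, p.Km9,
        p.kcat11, p.Km11, p.kcat12, p.Km12, p.kcat13, p.Km13,
        p.kcat14, p.kcat15, p.Km15, p.kcat16, p.Km16,
        p.k17f, p.k17b, p.k18f, p.k18b, krel, kreb,
        p.kon_i1pp1, p.koff_i1pp1, p.pka_max, p.pka_ic50, p.pka_n,
        1.0 if mode == "full_pka" else 0.0,
    ])


def _kernel(t, y, Ca, k):
    (s0, s1, s2, s3, s4, s5, s6, s7, s8,
     cam_ac1, cam_ac8, cam_pde1, cam_cana, cam_k2, cam_k2p, k2p_free,
     camp, pde4bp, pde4dp, i1p, i1pp1, R, R2, R4, pkac_dyn) = y

    dy = np.empty(25)
    aN0 = k[0] * Ca
    aN1 = k[1] * Ca
    aC0 = k[4] * Ca
    aC1 = k[5] * Ca
    fn0 = aN0 * s0 - k[2] * s1
    fn1 = aN1 * s1 - k[3] * s2
    fn2 = aN0 * s3 - k[2] * s4
    fn3 = aN1 * s4 - k[3] * s5
    fn4 = aN0 * s6 - k[2] * s7
    fn5 = aN1 * s7 - k[3] * s8
    fc0 = aC0 * s0 - k[6] * s3
    fc1 = aC1 * s3 - k[7] * s6
    fc2 = aC0 * s1 - k[6] * s4
    fc3 = aC1 * s4 - k[7] * s7
    fc4 = aC0 * s2 - k[6] * s5
    fc5 = aC1 * s5 - k[7] * s8
    dy[0] = -fn0 - fc0
    dy[1] = fn0 - fn1 - fc2
    dy[2] = fn1 - fc4
    dy[3] = -fn2 + fc0 - fc1
    dy[4] = fn2 - fn3 + fc2 - fc3
    dy[5] = fn3 + fc4 - fc5
    dy[6] = -fn4 + fc1
    dy[7] = fn4 - fn5 + fc3
    dy[8] = fn5 + fc5

    cam4 = s8 if s8 > 0.0 else 0.0
    f_ac1 = k[8] * cam4 * (k[26] - cam_ac1) - k[9] * cam_ac1
    f_ac8 = k[10] * cam4 * (k[27] - cam_ac8) - k[11] * cam_ac8
    f_pde1 = k[12] * cam4 * (k[29] - cam_pde1) - k[13] * cam_pde1
    if Ca > 0.0:
        h_gate = Ca ** k[25] / (Ca ** k[25] + k[24] ** k[25])
        h1 = Ca ** k[17] / (Ca ** k[17] + k[16] ** k[17])
        h2 = Ca ** k[20] / (Ca ** k[20] + k[19] ** k[20])
    else:
        h_gate = h1 = h2 = 0.0
    cana_avail = (k[30] - cam_cana) * h_gate
    koff_cana = k[15] * h1 + k[18] * (1.0 - h2)
    f_cana = k[14] * cam4 * cana_avail - koff_cana * cam_cana
    k2_free = k[31] - cam_k2 - cam_k2p - k2p_free
    f_k2 = k[21] * cam4 * k2_free - k[22] * cam_k2
    f_k2p = k[21] * cam4 * k2p_free - k[23] * cam_k2p

    dy[8] -= f_ac1 + f_ac8 + f_pde1 + f_cana + f_k2 + f_k2p
    dy[9] = f_ac1
    dy[10] = f_ac8
    dy[11] = f_pde1
    dy[12] = f_cana

    phos = k[58] * cam_k2 * (cam_k2 + cam_k2p) / k[31]
    pp1_active = k[32] - i1pp1
    s_phos = cam_k2p + k2p_free
    if s_phos > 0.0:
        dep_tot = (k[59] * pp1_active * s_phos / (k[60] + s_phos)
                   + k[61] * k[33] * s_phos / (k[62] + s_phos))
        dep_bound = dep_tot * cam_k2p / s_phos
        dep_free = dep_tot * k2p_free / s_phos
    else:
        dep_bound = 0.0
        dep_free = 0.0
    dy[13] = f_k2 - phos + dep_bound
    dy[14] = f_k2p + phos - dep_bound
    dy[15] = -f_k2p - dep_free

    c = camp if camp > 0.0 else 0.0
    prod = k[37] * cam_ac1 + k[38] * cam_ac8 + k[39] * k[28]
    hyd = ((k[43] * (k[29] - cam_pde1) + k[44] * cam_pde1) * c / (k[45] + c)
           + (k[46] * (k[35] - pde4bp) + k[47] * pde4bp) * c / (k[48] + c)
           + (k[49] * (k[36] - pde4dp) + k[50] * pde4dp) * c / (k[51] + c))
    dcamp = prod - hyd

    if k[74] > 0.5:
        c2 = c * c
        f1 = k[63] * R * c2 - k[64] * R2
        f2 = k[65] * R2 * c2 - k[66] * R4
        rel = k[67] * R4
        reb = k[68] * 0.5 * pkac_dyn * pkac_dyn * pkac_dyn
        dy[21] = -f1
        dy[22] = f1 - f2
        dy[23] = f2 - rel + reb
        dy[24] = 2.0 * (rel - reb)
        dcamp -= 2.0 * f1 + 2.0 * f2
        pkac = pkac_dyn
    else:
        dy[21] = 0.0
        dy[22] = 0.0
        dy[23] = 0.0
        dy[24] = 0.0
        pkac = k[71] / (1.0 + (k[72] / c) ** k[73]) if c > 0.0 else 0.0
    dy[16] = dcamp

    pde4b = k[35] - pde4bp
    pde4d = k[36] - pde4dp
    dy[17] = k[40] * pkac * pde4b / (k[41] + pde4b) - k[42] * pde4bp
    dy[18] = k[40] * pkac * pde4d / (k[41] + pde4d) - k[42] * pde4dp

    i1_free = k[34] - i1p - i1pp1
    if i1_free < 0.0:
        i1_free = 0.0
    phos_i1 = k[52] * pkac * i1_free / (k[53] + i1_free)
    ip = i1p if i1p > 0.0 else 0.0
    ipc = i1pp1 if i1pp1 > 0.0 else 0.0
    s_i1 = ip + ipc
    if s_i1 > 0.0:
        dep_tot = (k[54] * k[33] * s_i1 / (k[55] + s_i1)
                   + k[56] * cam_cana * s_i1 / (k[57] + s_i1))
        dep_free_i1 = dep_tot * ip / s_i1
        dep_cplx_i1 = dep_tot * ipc / s_i1
    else:
        dep_free_i1 = 0.0
        dep_cplx_i1 = 0.0
    bind = k[69] * ip * (pp1_active if pp1_active > 0.0 else 0.0) - k[70] * i1pp1
    dy[19] = phos_i1 - dep_free_i1 - bind
    dy[20] = bind - dep_cplx_i1
    return dy


try:  # compiled kernel; the pure-Python closure remains the reference
    from numba import njit as _njit

    _kernel_fast = _njit(cache=True, fastmath=False)(_kernel)
except ImportError:  # pragma: no cover
    _kernel_fast = _kernel


def network_rhs(t: float, s: NetworkState, p: ParameterSet,
                proto: StimulusProtocol, mode: str = "reduced_pka",
                orientation: str = "release_slow") -> np.ndarray:
    """Time derivatives (µM/s) of the full network state at time ``t``."""
    s = np.asarray(s, dtype=float)
    if np.any(np.isnan(s)):
        bad = SPECIES[int(np.flatnonzero(np.isnan(s))[0])]
        raise ValueError(f"NaN state for species {bad} at t={t}")
    return _rhs(t, s, float(calcium_trace(proto, t)), p, mode, orientation)


@dataclass(frozen=True)
class SimulationResult:
    """Trajectory plus derived observables of one simulation run."""

    t: np.ndarray                 # s
    y: np.ndarray                 # (N_SPECIES, nt), µM
    protocol: StimulusProtocol
    params: ParameterSet
    mode: str

    def series(self, name: str) -> np.ndarray:
        """Raw or derived concentration series.

        Derived names: ``CaM4_total`` (free plus protein-bound CaM₄),
        ``pT286`` (all T286-phosphorylated subunits), ``PP1_active``.
        """
        if name == "CaM4_total":
            return self.y[CAM4] + sum(self.y[_IDX[n]] for n in CAM_BOUND)
        if name == "pT286":
            return self.y[_IDX["CaMCaMKIIP"]] + self.y[_IDX["CaMKIIP"]]
        if name == "PP1_active":
            return self.params.PP1_T - self.y[_IDX["I1PP1"]]
        return self.y[_IDX[name]]

    @property
    def train_window(self) -> np.ndarray:
        return self.t <= self.protocol.train_end + 1e-12

    def to_frame(self):
        """Tidy trajectory (time, species, value)."""
        import pandas as pd
        return pd.DataFrame(self.y.T, columns=list(SPECIES)).assign(
            time=self.t
        ).melt(id_vars="time", var_name="species", value_name="value")


def integrate(p: ParameterSet, proto: StimulusProtocol,
              mode: str = "reduced_pka", t_end: float | None = None,
              rtol: float = 1e-8, atol: float = 1e-12,
              orientation: str = "release_slow",
              output_dt: float = 1e-3) -> SimulationResult:
    """Integrate from rest through the pulse train plus follow-up.

    The trace is integrated segment-by-segment between pulse onsets (the
    input is smooth inside a segment and jumps by ``A`` at each pulse), with
    a stiff solver at tight tolerances and dense millisecond output.
    """
    if mode not in ("full_pka", "reduced_pka"):
        raise ValueError(f"unknown mode: {mode!r}")
    t_end = proto.total_duration if t_end is None else float(t_end)
    if t_end < proto.train_end:
        raise ValueError("t_end must cover the stimulation train")

    pulse_times = [float(t) for t in proto.pulse_times if t < t_end]
    edges = ([0.0] if (not pulse_times or pulse_times[0] > 0.0) else []) \
        + pulse_times + [t_end]
    gaps = np.diff(edges)
    max_step = max(0.5 * gaps.min(), 1e-4)

    y0 = initial_state(p)
    K = _pack(p, mode, orientation)
    core = lambda t, y, ca: _kernel_fast(t, y, ca, K)
    # running summated pulse amplitude S: Ca(t) = Ca_basal + S·exp(-(t-t0)/tau)
    S = 0.0
    tau = proto.tau
    ca_basal = proto.Ca_basal
    exp = np.exp
    t_out: list[np.ndarray] = []
    y_out: list[np.ndarray] = []

    for k in range(len(edges) - 1):
        t0, t1 = edges[k], edges[k + 1]
        if k > 0:
            S *= exp(-(t0 - edges[k - 1]) / tau)
        if t0 in pulse_times:
            S += proto.amplitude

        def rhs(t, y, t0=t0, S=S):
            return core(t, y, ca_basal + S * exp(-(t - t0) / tau))

        # output at (t0, t1] on the millisecond grid, plus t0 for the first
        # segment and always the exact segment end (it seeds the next one)
        pts = np.arange(np.ceil(t0 / output_dt) * output_dt, t1, output_dt)
        pts = pts[(pts > t0 + 1e-15) & (pts < t1 - 1e-15)]
        head = [t0] if k == 0 else []
        pts = np.unique(np.concatenate((head, pts, [t1])))
        sol = solve_ivp(rhs, (t0, t1), y0, method="LSODA", rtol=rtol, atol=atol,
                        max_step=max_step, t_eval=pts)
        if not sol.success:
            raise RuntimeError(
                f"solver failed in segment [{t0}, {t1}]: {sol.message}; "
                f"last good state at t={sol.t[-1] if len(sol.t) else t0}")
        t_out.append(sol.t)
        y_out.append(sol.y)
        y0 = sol.y[:, -1].copy()

    t = np.concatenate(t_out)
    y = np.concatenate(y_out, axis=1)
    if y.min() < -1e-6:
        i, j = np.unravel_index(np.argmin(y), y.shape)
        raise RuntimeError(
            f"negative concentration beyond solver tolerance: "
            f"{SPECIES[i]}={y[i, j]:.3e} µM at t={t[j]:.4f} s")
    return SimulationResult(t=t, y=np.maximum(y, 0.0), protocol=proto,
                            params=p, mode=mode)


def observables(r: SimulationResult, which: str, summary: str = "time_average") -> float:
    """Scalar summary of an output series over the train window.

    ``which``: ``CaM4_total``, ``cAMP`` or ``I1PP1``;
    ``summary``: ``end_of_train``, ``time_average`` or ``peak``.
    """
    if which not in ("CaM4_total", "cAMP", "I1PP1"):
        raise ValueError(f"unknown observable: {which!r}")
    series = r.series(which)
    w = r.train_window
    ts, vs = r.t[w], series[w]
    if summary == "end_of_train":
        return float(vs[-1])
    if summary == "peak":
        return float(vs.max())
    if summary == "time_average":
        return float(np.trapezoid(vs, ts) / (ts[-1] - ts[0]))
    raise ValueError(f"unknown summary: {summary!r}")


def conserved_pools(r: SimulationResult) -> dict[str, np.ndarray]:
    """Time series of every conserved total (µM), for invariant checks."""
    y, p = r.y, r.params
    g = lambda n: y[_IDX[n]]
    return {
        "CaM_T": y[:9].sum(axis=0) + sum(g(n) for n in CAM_BOUND),
        "CaMKII_T": (p.CaMKII_T - g("CaMCaMKII") - g("CaMCaMKIIP") - g("CaMKIIP"))
        + g("CaMCaMKII") + g("CaMCaMKIIP") + g("CaMKIIP"),
        "AC1_T": (p.AC1_T - g("CaMAC1")) + g("CaMAC1"),
        "AC8_T": (p.AC8_T - g("CaMAC8")) + g("CaMAC8"),
        "PDE1_T": (p.PDE1_T - g("CaMPDE1")) + g("CaMPDE1"),
        "PP2B_T": (p.PP2B_T - g("CaMCaNA")) + g("CaMCaNA"),
        "PP1_T": (p.PP1_T - g("I1PP1")) + g("I1PP1"),
        "I1_T": (p.I1_T - g("I1P") - g("I1PP1")) + g("I1P") + g("I1PP1"),
        "PDE4B_T": (p.PDE4B_T - g("PDE4BP")) + g("PDE4BP"),
        "PDE4D_T": (p.PDE4D_T - g("PDE4DP")) + g("PDE4DP"),
        "R2C2_T": g("R2C2") + g("R2C2cAMP2") + g("R2C2cAMP4") + g("PKAc") / 2.0,
    }
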