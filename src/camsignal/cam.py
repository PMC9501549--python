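"""Nine-state Ca²⁺–calmodulin binding submodel.

The N- and C-lobes fill independently, each as a three-state chain
(0, 1 or 2 Ca²⁺ bound).  The first ion on a lobe binds at the tense-state
rate and the second at the relaxed-state rate, with statistical factors of
two on the first association and the last dissociation:

    lobe₀ --2·kon_T·Ca-->  lobe₁ --kon_R·Ca-->  lobe₂
    lobe₀ <--koff_T------  lobe₁ <--2·koff_R--  lobe₂

The nine joint states are the tensor product of the two chains; only the
fully loaded state (CaM₄) binds targets.

State ordering (index = 3*c + n, c = C-lobe load, n = N-lobe load):
CaM₀, CaM₁N, CaM₂N, CaM₁C, CaM₁C1N, CaM₁C2N, CaM₂C, CaM₂C1N, CaM₄.
"""

from __future__ import annotations

import numpy as np

from .parameters import ParameterSet

__all__ = ["CAM_STATE_NAMES", "CAM4", "cam_fluxes", "equilibrate_cam",
           "lobe_occupancy"]

CAM_STATE_NAMES = (
    "CaM0", "CaM1N", "CaM2N",
    "CaM1C", "CaM1C1N", "CaM1C2N",
    "CaM2C", "CaM2C1N", "CaM4",
)
#: index of fully loaded calmodulin in the 9-vector
CAM4 = 8


def _lobe_rates(p: ParameterSet, lobe: str) -> tuple[float, float, float, float]:
    if lobe == "N":
        return p.kon_NT, p.koff_NT, p.kon_NR, p.koff_NR
    return p.kon_CT, p.koff_CT, p.kon_CR, p.koff_CR


def lobe_occupancy(Ca: float, p: ParameterSet, lobe: str) -> np.ndarray:
    """Closed-form equilibrium occupancy (0/1/2 ions) of one lobe at clamped Ca²⁺."""
    kon_t, koff_t, kon_r, koff_r = _lobe_rates(p, lobe)
    w1 = 2.0 * kon_t * Ca / koff_t
    w2 = w1 * kon_r * Ca / (2.0 * koff_r)
    w = np.array([1.0, w1, w2])
    return w / w.sum()


def cam_fluxes(s: np.ndarray, Ca: float, p: ParameterSet) -> np.ndarray:
    """Mass-action time derivatives (µM/s) of the nine free CaM states.

    ``s`` is the 9-vector in `CAM_STATE_NAMES` order.  Derivatives sum to
    zero: target binding is handled by the network layer, not here.
    """
    s = np.asarray(s, dtype=float)
    if s.shape != (9,):
        raise ValueError("expected a 9-state CaM vector")
    if np.any(s < 0):
        raise ValueError("negative CaM state concentration")
    g = s.reshape(3, 3)      # [c_load, n_load]
    ds = np.zeros((3, 3))

    for axis, lobe in ((1, "N"), (0, "C")):
        kon_t, koff_t, kon_r, koff_r = _lobe_rates(p, lobe)
        up0 = 2.0 * kon_t * Ca   # 0 -> 1
        up1 = kon_r * Ca         # 1 -> 2
        dn1 = koff_t             # 1 -> 0
        dn2 = 2.0 * koff_r       # 2 -> 1
        x = g if axis == 1 else g.T
        d = np.zeros_like(x)
        f01 = up0 * x[:, 0] - dn1 * x[:, 1]
        f12 = up1 * x[:, 1] - dn2 * x[:, 2]
        d[:, 0] -= f01
        d[:, 1] += f01 - f12
        d[:, 2] += f12
        ds += d if axis == 1 else d.T

    return ds.reshape(9)


def equilibrate_cam(Ca: float, p: ParameterSet, total: float | None = None) -> np.ndarray:
    """Steady state of the lone 9-state model at clamped Ca²⁺ (µM 9-vector).

    The equilibrium factorizes over the independent lobes, so the
    distribution is the outer product of the two closed-form lobe
    occupancies scaled to ``total`` (default: the full CaM pool).
    """
    if Ca < 0:
        raise ValueError("Ca must be >= 0")
    total = p.CaM_T if total is None else total
    occ = np.outer(lobe_occupancy(Ca, p, "C"), lobe_occupancy(Ca, p, "N"))
    state = total * occ.reshape(9)
    # defensive residual check against the dynamic right-hand side
    resid = np.abs(cam_fluxes(state, Ca, p)).max()
    scale = max(total, 1.0) * max(p.koff_NT, p.koff_CT)
    if resid > 1e-9 * scale:
        raise RuntimeError(f"CaM equilibration residual too large: {resid:.3e} µM/s")
    return state
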