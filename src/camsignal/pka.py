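"""PKA activation: full four-state model and its Hill reduction.

The holoenzyme R₂C₂ binds cAMP in two double-steps and then releases two
catalytic subunits:

    R₂C₂ + 2 cAMP ⇌ R₂C₂cAMP₂        (k17f, k17b)
    R₂C₂cAMP₂ + 2 cAMP ⇌ R₂C₂cAMP₄   (k18f, k18b)
    R₂C₂cAMP₄ ⇌ R₂cAMP₄ + 2 PKAc     (release step, see below)

The printed units of the release pair are mutually inconsistent (a
second-order constant labelled as the release direction), so both
orientations are implemented behind ``orientation``:

* ``"release_slow"`` (default, selected by the steady-state oracle):
  first-order release at ``k19b`` (s⁻¹) with termolecular rebinding at
  ``k19f`` (µM⁻²s⁻¹) acting on [R₂cAMP₄]·[PKAc]², where the stripped
  regulatory complex is bookkept as [PKAc]/2.
* ``"release_fast"``: the constants as labelled (release at ``k19f``,
  rebinding at ``k19b``), which overshoots the catalytic pool ten-fold.

The reduced model is the Hill dose–response
``PKAc = PKA_max / (1 + (IC50/cAMP)^n)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, curve_fit

from .parameters import ParameterSet

__all__ = [
    "PKAFit", "pka_full_rhs", "pka_steady_state", "pka_dose_response",
    "fit_hill", "pka_reduced", "select_orientation",
]

ORIENTATIONS = ("release_slow", "release_fast")


def _release_rates(p: ParameterSet, orientation: str) -> tuple[float, float]:
    """(release s⁻¹, rebinding µM⁻²s⁻¹) for the requested orientation."""
    if orientation == "release_slow":
        return p.k19b, p.k19f
    if orientation == "release_fast":
        return p.k19f, p.k19b
    raise ValueError(f"unknown k19 orientation: {orientation!r}")


def pka_full_rhs(s, cAMP: float, p: ParameterSet,
                 orientation: str = "release_slow") -> np.ndarray:
    """Derivatives of [R₂C₂, R₂C₂cAMP₂, R₂C₂cAMP₄, PKAc] at clamped cAMP.

    The fifth returned entry is the net cAMP consumption flux (µM/s) for
    callers that treat cAMP dynamically.
    """
    R, R2, R4, P = np.asarray(s, dtype=float)
    if min(R, R2, R4, P) < -1e-12:
        raise ValueError("negative PKA sub-state")
    krel, kreb = _release_rates(p, orientation)
    f1 = p.k17f * R * cAMP**2 - p.k17b * R2
    f2 = p.k18f * R2 * cAMP**2 - p.k18b * R4
    rel = krel * R4
    reb = kreb * (P / 2.0) * P**2
    return np.array([-f1, f1 - f2, f2 - rel + reb, 2.0 * (rel - reb),
                     2.0 * f1 + 2.0 * f2])


def pka_steady_state(cAMP: float, p: ParameterSet,
                     orientation: str = "release_slow",
                     method: str = "algebraic") -> float:
    """Steady-state PKAc (µM) at clamped cAMP.

    ``method="algebraic"`` solves the equilibrium by root-finding;
    ``method="integrate"`` runs the ODEs until ‖ds/dt‖∞ < 1e-10 µM/s.
    The two agree to well below 1e-8 (asserted in the test suite).
    """
    if cAMP <= 0.0:
        return 0.0
    krel, kreb = _release_rates(p, orientation)
    if method == "algebraic":
        c2 = cAMP**2

        def excess(P: float) -> float:
            R4 = kreb * P**3 / (2.0 * krel)
            R2 = R4 * p.k18b / (p.k18f * c2)
            R = R2 * p.k17b / (p.k17f * c2)
            return R + R2 + R4 + P / 2.0 - p.R2C2_T

        return brentq(excess, 0.0, 2.0 * p.R2C2_T, xtol=1e-14, rtol=1e-14)
    if method == "integrate":
        y0 = [p.R2C2_T, 0.0, 0.0, 0.0]
        t = 0.0
        for _ in range(60):
            sol = solve_ivp(lambda t, y: pka_full_rhs(y, cAMP, p, orientation)[:4],
                            (t, t + 50000.0), y0, method="LSODA",
                            rtol=1e-12, atol=1e-14)
            y0, t = sol.y[:, -1], sol.t[-1]
            if np.abs(pka_full_rhs(y0, cAMP, p, orientation)[:4]).max() < 1e-10:
                return float(y0[3])
        raise RuntimeError(f"PKA steady state did not converge at cAMP={cAMP}")
    raise ValueError(f"unknown method: {method!r}")


def pka_dose_response(p: ParameterSet, grid=None,
                      orientation: str = "release_slow"):
    """Steady-state PKAc over a clamped cAMP grid (default 101 points on [0, 10])."""
    grid = np.linspace(0.0, 10.0, 101) if grid is None else np.asarray(grid, float)
    if grid.min() < 0 or grid.max() > 10 + 1e-9:
        raise ValueError("cAMP grid must lie within [0, 10] µM")
    resp = np.array([pka_steady_state(c, p, orientation) for c in grid])
    if np.any(np.diff(resp) < -1e-12):
        raise RuntimeError("dose-response is not monotone non-decreasing")
    return grid, resp


@dataclass(frozen=True)
class PKAFit:
    """Hill reduction of the PKA dose–response."""

    PKA_max: float
    IC50: float
    n_hill: float
    r_squared: float
    grid: np.ndarray = field(repr=False)
    response: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.PKA_max <= 0 or self.IC50 <= 0:
            raise ValueError("PKA_max and IC50 must be positive")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")


def pka_reduced(cAMP, fit: PKAFit | None = None, *, PKA_max: float | None = None,
                IC50: float | None = None, n_hill: float | None = None):
    """Reduced-model PKAc; accepts a fit or explicit Hill constants.

    Returns 0 at cAMP = 0 (the limit of the Hill form).
    """
    if fit is not None:
        PKA_max, IC50, n_hill = fit.PKA_max, fit.IC50, fit.n_hill
    c = np.asarray(cAMP, dtype=float)
    with np.errstate(divide="ignore"):
        out = PKA_max / (1.0 + (IC50 / np.where(c > 0, c, np.inf)) ** n_hill)
    out = np.where(c > 0, out, 0.0)
    return out if out.ndim else float(out)


def fit_hill(grid, response) -> PKAFit:
    """Fit the Hill reduction to a dose–response curve.

    PKA_max is pinned to the maximum response, IC50 to the interpolated
    half-maximum; only the Hill exponent is free (least squares).
    """
    grid = np.asarray(grid, float)
    response = np.asarray(response, float)
    if len(grid) < 10:
        raise ValueError("need at least 10 grid points")
    if np.any(np.diff(response) < -1e-9 * max(response.max(), 1e-30)):
        raise ValueError("response must be monotone non-decreasing")
    pka_max = float(response.max())
    ic50 = float(np.interp(pka_max / 2.0, response, grid))

    pos = grid > 0

    def model(c, n):
        return pka_max / (1.0 + (ic50 / c) ** n)

    (n_hill,), _ = curve_fit(model, grid[pos], response[pos], p0=[2.0], maxfev=20000)
    pred = model(grid[pos], n_hill)
    ss_res = float(np.sum((response[pos] - pred) ** 2))
    ss_tot = float(np.sum((response[pos] - response[pos].mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return PKAFit(PKA_max=pka_max, IC50=ic50, n_hill=float(n_hill),
                  r_squared=r2, grid=grid, response=response)


def select_orientation(p: ParameterSet, target_pka_max: float = 0.2170) -> str:
    """Pick the k19 orientation whose saturating PKAc best matches ``target_pka_max``."""
    errs = {o: abs(pka_steady_state(10.0, p, o) - target_pka_max)
            for o in ORIENTATIONS}
    return min(errs, key=errs.get)
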