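"""Fit the membrane-conductance sigmoid to observed g_oxz(ψ_xyl) data.

The fit runs the full two-compartment forward model at each data point's
ψ_xyl, compares predicted and observed OXZ conductance on a log scale
(g_oxz spans more than an order of magnitude, and the log loss weights the
decline and the plateau comparably), and minimizes by bounded least squares
with a seeded multi-start to escape the sigmoid's local minima.

κ_max and κ_min are constrained to a configured interval representing the
protoplast-derived bounds on plasma-membrane conductance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import model as mdl
from .model import (BoundaryConditions, LeafNetwork, MembraneLaw,
                    ScenarioSpec, T_LEAF_DEFAULT)
from . import thermo

__all__ = ["FitResult", "fit_membrane_law", "DEFAULT_KAPPA_BOUNDS"]

logger = logging.getLogger(__name__)

#: Allowed interval for κ_max and κ_min (mol m⁻² s⁻¹ MPa⁻¹ per membrane
#: area) — the protoplast-derived bracket the sigmoid must respect.
DEFAULT_KAPPA_BOUNDS = (1e-6, 1e-2)

#: Relative spread of κ_max/κ_min below which the fitted sigmoid is flat and
#: its midpoint/slope are unidentifiable.
_FLAT_SPREAD = 1.5


@dataclass(frozen=True)
class FitResult:
    """Outcome of a membrane-law fit.

    ``half_widths`` are approximate 1-σ confidence half-widths from the
    Jacobian-based covariance (linearization around the optimum); treat
    them as indicative, not exact.
    """

    law: MembraneLaw
    loss: float
    half_widths: dict
    converged: bool
    identifiable: bool
    n_points: int
    loss_trace: tuple

    def to_dict(self) -> dict:
        return {
            "kappa_max": self.law.kappa_max, "kappa_min": self.law.kappa_min,
            "psi_50": self.law.psi_50, "slope": self.law.slope,
            "loss": self.loss, "converged": self.converged,
            "identifiable": self.identifiable, "n_points": self.n_points,
        }


def _predict_log_goxz(params: np.ndarray, psi: np.ndarray, net: LeafNetwork,
                      scen: ScenarioSpec | None, vpd: float, gs: float,
                      t_leaf: float) -> np.ndarray:
    lkmax, lkmin, psi50, slope = params
    kmax, kmin = 10.0 ** lkmax, 10.0 ** lkmin
    if kmax <= kmin:
        kmax = kmin * (1 + 1e-9)
    law = MembraneLaw(kappa_max=kmax, kappa_min=kmin, psi_50=psi50, slope=slope)
    air = thermo.air_state_from_vpd(vpd, t_leaf)
    out = np.empty_like(psi)
    for i, p in enumerate(psi):
        bc = BoundaryConditions(psi_xyl=float(p), air=air, gs_ad=gs / 2, gs_ab=gs / 2)
        out[i] = np.log(mdl.solve_steady_state(net, law, scen, bc).g_oxz)
    return out


def fit_membrane_law(data: pd.DataFrame,
                     net: LeafNetwork = mdl.DEFAULT_NETWORK,
                     scen: ScenarioSpec | None = None,
                     vpd: float = 3.8,
                     gs: float = mdl.GS_DEFAULT,
                     t_leaf: float = T_LEAF_DEFAULT,
                     kappa_bounds: tuple[float, float] = DEFAULT_KAPPA_BOUNDS,
                     n_starts: int = 5,
                     seed: int = 0) -> FitResult:
    """Fit (κ_max, κ_min, ψ50, slope) to observed g_oxz(ψ_xyl).

    Parameters
    ----------
    data:
        Table with columns ``psi_xyl`` (MPa), ``g_oxz`` (mmol m⁻² s⁻¹) and
        optionally ``se`` (standard error of g_oxz, used as relative
        weights on the log scale).
    kappa_bounds:
        Interval constraining both κ_max and κ_min.
    n_starts, seed:
        Seeded multi-start count; ties broken by lowest loss, then lowest
        κ_max.

    Requires at least 4 points spanning at least 1 MPa of ψ_xyl.
    """
    psi = data["psi_xyl"].to_numpy(float)
    gobs = data["g_oxz"].to_numpy(float)
    keep = np.isfinite(psi) & np.isfinite(gobs) & (gobs > 0)
    psi, gobs = psi[keep], gobs[keep]
    if len(psi) < 4 or np.ptp(psi) < 1.0:
        raise ValueError("need >= 4 points spanning >= 1 MPa of psi_xyl")
    logg = np.log(gobs)
    if "se" in data.columns:
        se = data["se"].to_numpy(float)[keep]
        wt = 1.0 / np.clip(se / gobs, 1e-3, np.inf)   # relative SE on log scale
        wt /= wt.mean()
    else:
        wt = np.ones_like(logg)

    # order-invariance: evaluate on a sorted copy
    order = np.argsort(psi)
    psi, logg, wt = psi[order], logg[order], wt[order]

    lk_lo, lk_hi = np.log10(kappa_bounds[0]), np.log10(kappa_bounds[1])
    lower = np.array([lk_lo, lk_lo, -2.5, 0.02])
    upper = np.array([lk_hi, lk_hi, 0.5, 1.0])

    trace: list[float] = []

    def residuals(params):
        try:
            pred = _predict_log_goxz(params, psi, net, scen, vpd, gs, t_leaf)
        except Exception:
            return np.full_like(logg, 1e3)
        res = wt * (pred - logg)
        loss = float(res @ res)
        if not trace or loss < trace[-1]:
            trace.append(loss)
        return res

    rng = np.random.default_rng(seed)
    starts = [np.array([lk_hi - 0.5, lk_lo + 0.5, -0.5, 0.2])]
    for _ in range(n_starts - 1):
        starts.append(lower + (upper - lower) * rng.random(4))
        starts[-1][0] = max(starts[-1][0], starts[-1][1])  # κ_max >= κ_min

    best = None
    for x0 in starts:
        try:
            sol = least_squares(residuals, x0, bounds=(lower, upper),
                                method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        key = (sol.cost, sol.x[0])
        if best is None or key < best[0]:
            best = (key, sol)
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    sol = best[1]
    converged = bool(sol.status > 0)
    if not converged:
        logger.warning("membrane-law fit did not converge; returning best-so-far")

    lkmax, lkmin, psi50, slope = sol.x
    kmax, kmin = 10.0 ** lkmax, 10.0 ** lkmin
    if kmax <= kmin:
        kmax = kmin * (1 + 1e-9)
    law = MembraneLaw(kappa_max=kmax, kappa_min=kmin, psi_50=psi50, slope=slope)

    identifiable = kmax / kmin > _FLAT_SPREAD
    if not identifiable:
        logger.warning("flat sigmoid (kappa_max ~= kappa_min): psi_50 and "
                       "slope are unidentifiable")

    # Jacobian-based covariance; approximate confidence half-widths
    half = {k: float("nan") for k in ("kappa_max", "kappa_min", "psi_50", "slope")}
    try:
        J = sol.jac
        dof = max(len(psi) - len(sol.x), 1)
        s2 = 2 * sol.cost / dof
        cov = s2 * np.linalg.inv(J.T @ J)
        sd = np.sqrt(np.diag(cov))
        half = {
            "kappa_max": float(kmax * np.log(10) * sd[0]),
            "kappa_min": float(kmin * np.log(10) * sd[1]),
            "psi_50": float(sd[2]),
            "slope": float(sd[3]),
        }
    except np.linalg.LinAlgError:
        logger.warning("singular Jacobian; confidence half-widths unavailable")

    return FitResult(law=law, loss=float(2 * sol.cost), half_widths=half,
                     converged=converged, identifiable=identifiable,
                     n_points=len(psi), loss_trace=tuple(trace))
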