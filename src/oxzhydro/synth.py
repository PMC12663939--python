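"""Synthetic measurement campaigns and synthetic FRET images with known
ground truth.

The campaign generator emulates the study design the analytics are built
for: 37 plants / 87 measurements with xylem water potential (ψ_xyl ∈
[−2, 0] MPa) and vapor pressure deficit (VPD ∈ [2.66, 4.82] kPa) varied
independently (uniform, uncorrelated draws).  Each record is produced by
forward-solving the two-compartment transport model under the preferred
uniform-membrane scenario with the shipped membrane law and a stomatal
closure schedule near the turgor loss point, then adding instrument-style
noise (multiplicative lognormal on fluxes, additive Gaussian on ψ
readings, clipped to preserve ψ_ssc ≤ ψ_xyl).

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning: stream 0 draws the design
(ψ_xyl, VPD), stream 1 the noise, stream 2 image pixel noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import model as mdl
from . import thermo
from .imaging import CalibrationCurve, DEFAULT_CALIBRATION, FretImage
from .model import (BoundaryConditions, LeafNetwork, MembraneLaw,
                    ScenarioSpec, gs_closure_schedule)

__all__ = [
    "CampaignDesign",
    "NoiseModel",
    "CellSpec",
    "generate_campaign",
    "generate_fret_image",
]

#: Leaf temperature used for the synthetic campaign (°C).  The upper end of
#: the VPD range (4.82 kPa) requires e_sat(T_leaf) above 4.82 kPa, so the
#: campaign is simulated at a warm greenhouse leaf temperature.
T_LEAF_C_CAMPAIGN = 33.0

#: Light-saturated assimilation (µmol m⁻² s⁻¹) and the stomatal conductance
#: at half-saturation (mmol m⁻² s⁻¹) for the synthetic A(g_s) response.
A_MAX = 40.0
GS_HALF = 100.0


@dataclass(frozen=True)
class CampaignDesign:
    """Design of a synthetic campaign (defaults follow the study layout)."""

    n_plants: int = 37
    n_measurements: int = 87
    psi_xyl_range: tuple[float, float] = (-2.0, 0.0)
    vpd_range: tuple[float, float] = (2.66, 4.82)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_measurements < self.n_plants:
            raise ValueError("need at least one measurement per plant")
        if not (self.psi_xyl_range[0] < self.psi_xyl_range[1]
                and self.vpd_range[0] < self.vpd_range[1]):
            raise ValueError("ranges must be ordered (low, high)")


@dataclass(frozen=True)
class NoiseModel:
    """Instrument-style noise: additive Gaussian on ψ readings (MPa),
    multiplicative lognormal on fluxes and assimilation (relative sd)."""

    psi_sd: float = 0.15
    flux_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.psi_sd < 0 or self.flux_cv < 0:
            raise ValueError("noise dispersions must be non-negative")


def generate_campaign(design: CampaignDesign = CampaignDesign(),
                      noise: NoiseModel = NoiseModel(),
                      law: MembraneLaw = mdl.DEFAULT_LAW,
                      net: LeafNetwork = mdl.DEFAULT_NETWORK,
                      scen: ScenarioSpec | None = None,
                      gs_schedule=gs_closure_schedule) -> pd.DataFrame:
    """Simulate a measurement campaign and return it as a campaign table.

    Output columns follow the campaign CSV schema, with the noise-free
    forward-model values appended as ``true_*`` columns (extra columns, so
    the analytics ignore them).  Measurements are assigned to plants
    round-robin across up to three "days", so every plant carries at least
    one record.
    """
    ss = np.random.SeedSequence(design.seed)
    rng_design, rng_noise, _ = [np.random.default_rng(s) for s in ss.spawn(3)]

    n = design.n_measurements
    psi_xyl = rng_design.uniform(*design.psi_xyl_range, size=n)
    vpd = rng_design.uniform(*design.vpd_range, size=n)

    t_leaf = T_LEAF_C_CAMPAIGN + 273.15
    plant_ids = [f"P{(i % design.n_plants) + 1:02d}" for i in range(n)]
    days = [(i // design.n_plants) + 1 for i in range(n)]

    rows = []
    for i in range(n):
        air = thermo.air_state_from_vpd(float(vpd[i]), t_leaf)
        gs_tot = float(gs_schedule(psi_xyl[i]))
        bc = BoundaryConditions(psi_xyl=float(psi_xyl[i]), air=air,
                                gs_ad=gs_tot / 2, gs_ab=gs_tot / 2)
        sol = mdl.solve_steady_state(net, law, scen, bc)
        a_true = A_MAX * gs_tot / (gs_tot + GS_HALF)

        e_ad = sol.E_ad * _lognormal(rng_noise, noise.flux_cv)
        e_ab = sol.E_ab * _lognormal(rng_noise, noise.flux_cv)
        a_obs = a_true * _lognormal(rng_noise, noise.flux_cv)
        psi_xyl_obs = min(psi_xyl[i] + rng_noise.normal(0.0, noise.psi_sd), 0.0)
        psi_ssc_obs = sol.psi_ssc_ad + rng_noise.normal(0.0, noise.psi_sd)
        # preserve the physical ordering psi_ssc <= psi_xyl under noise
        psi_ssc_obs = min(psi_ssc_obs, psi_xyl_obs - 1e-3)

        rows.append({
            "plant_id": plant_ids[i], "day": days[i],
            "E_ad": e_ad, "E_ab": e_ab, "A": a_obs,
            "T_leaf_C": T_LEAF_C_CAMPAIGN, "VPD_kPa": vpd[i],
            "psi_xyl_MPa": psi_xyl_obs, "psi_ssc_MPa": psi_ssc_obs,
            "P_kPa": thermo.CONSTANTS.atm_pressure,
            # noise-free ground truth
            "true_psi_xyl": psi_xyl[i], "true_psi_ssc": sol.psi_ssc_ad,
            "true_E_ad": sol.E_ad, "true_E_ab": sol.E_ab, "true_A": a_true,
            "true_gs_input": gs_tot, "true_g_oxz": sol.g_oxz,
            "true_h_ssc": sol.h_ssc_ad,
        })
    return pd.DataFrame(rows)


def _lognormal(rng: np.random.Generator, cv: float) -> float:
    """Unit-median multiplicative noise with relative sd ≈ cv."""
    if cv == 0:
        return 1.0
    return float(np.exp(rng.normal(0.0, math.sqrt(math.log(1.0 + cv ** 2)))))


@dataclass(frozen=True)
class CellSpec:
    """One rendered cell: center (row, col), radius in px, turgid flag."""

    center: tuple[float, float]
    radius: float
    turgid: bool = True


@dataclass(frozen=True)
class PsiFieldSpec:
    """Parameters of the ground-truth ψ field (MPa).

    kind: ``"uniform"`` (mean), ``"gaussian"`` (mean, sd) or ``"bimodal"``
    (mean, mean2, sd, weight of the first component).
    """

    kind: str = "gaussian"
    mean: float = -6.0
    sd: float = 1.0
    mean2: float = -11.0
    weight: float = 0.6

    def sample(self, rng: np.random.Generator, shape) -> np.ndarray:
        if self.kind == "uniform":
            return np.full(shape, self.mean)
        if self.kind == "gaussian":
            return rng.normal(self.mean, self.sd, size=shape)
        if self.kind == "bimodal":
            pick = rng.random(shape) < self.weight
            return np.where(pick, rng.normal(self.mean, self.sd, size=shape),
                            rng.normal(self.mean2, self.sd, size=shape))
        raise ValueError(f"unknown psi field kind {self.kind!r}")


def _default_cells(shape, rng: np.random.Generator, n_cells: int,
                   turgid: bool) -> list[CellSpec]:
    """Place non-overlapping cells on a jittered grid."""
    h, w = shape
    cells: list[CellSpec] = []
    n_side = math.ceil(math.sqrt(n_cells))
    pitch_r, pitch_c = h / (n_side + 1), w / (n_side + 1)
    for k in range(n_cells):
        r0 = (k // n_side + 1) * pitch_r + rng.uniform(-2, 2)
        c0 = (k % n_side + 1) * pitch_c + rng.uniform(-2, 2)
        radius = min(pitch_r, pitch_c) * 0.33 * rng.uniform(0.9, 1.1)
        cells.append(CellSpec((r0, c0), radius, turgid))
    return cells


def generate_fret_image(shape: tuple[int, int] = (256, 256),
                        cells: Sequence[CellSpec] | None = None,
                        n_cells: int = 25,
                        turgid: bool = True,
                        psi_field: PsiFieldSpec = PsiFieldSpec(),
                        calibration: CalibrationCurve = DEFAULT_CALIBRATION,
                        zeta_noise: float = 0.0,
                        seed: int = 0):
    """Render a synthetic FRET image with known ground truth.

    The autofluorescence channel shows bright cells — smooth disks when
    turgid, shrunken six-lobed (faceted) outlines when not — over a dim
    background with dark elliptical substomatal-cavity regions.  The ζ map
    is ``calibration(ψ_field)`` plus optional pixel noise.

    Returns ``(FretImage, truth)`` where ``truth`` holds the ψ field, the
    wall mask (pixels outside cells, where the reporter sits) and the
    ground-truth histogram mode over that mask.
    """
    ss = np.random.SeedSequence(seed)
    _, _, rng = [np.random.default_rng(s) for s in ss.spawn(3)]

    h, w = shape
    if cells is None:
        cells = _default_cells(shape, rng, n_cells, turgid)
    yy, xx = np.mgrid[0:h, 0:w]

    cell_mask = np.zeros(shape, bool)
    labels = np.zeros(shape, int)
    for i, cell in enumerate(cells, start=1):
        r0, c0 = cell.center
        if not (0 <= r0 < h and 0 <= c0 < w):
            raise ValueError(f"cell {i} center outside the frame")
        dy, dx = yy - r0, xx - c0
        rr = np.hypot(dy, dx)
        theta = np.arctan2(dy, dx)
        if cell.turgid:
            boundary = cell.radius
        else:
            phase = rng.uniform(0, 2 * math.pi)
            boundary = 0.72 * cell.radius * (1 + 0.20 * np.sin(6 * theta + phase))
        inside = rr <= boundary
        if np.any(inside & cell_mask):
            import warnings
            warnings.warn(f"cell {i} overlaps a previously rendered cell")
        labels[inside] = i
        cell_mask |= inside

    auto = 0.08 + 0.02 * rng.standard_normal(shape)
    auto[cell_mask] = 0.85 + 0.05 * rng.standard_normal(np.sum(cell_mask))
    # dark elliptical SSC regions in the background
    ssc_mask = np.zeros(shape, bool)
    for _ in range(max(len(cells) // 5, 1)):
        r0, c0 = rng.uniform(0, h), rng.uniform(0, w)
        a_ax, b_ax = rng.uniform(4, 8), rng.uniform(7, 14)
        ang = rng.uniform(0, math.pi)
        dy, dx = yy - r0, xx - c0
        u = dy * math.cos(ang) + dx * math.sin(ang)
        v = -dy * math.sin(ang) + dx * math.cos(ang)
        ell = (u / a_ax) ** 2 + (v / b_ax) ** 2 <= 1
        ssc_mask |= ell & ~cell_mask
    auto[ssc_mask] = 0.02
    auto = np.clip(auto, 0, 1)

    psi_true = psi_field.sample(rng, shape)
    zeta = np.asarray(calibration.zeta(psi_true), float)
    if zeta_noise > 0:
        zeta = zeta + rng.normal(0.0, zeta_noise, size=shape)

    img = FretImage(zeta_map=zeta, autofluorescence=auto,
                    metadata={"turgid": turgid, "seed": seed,
                              "psi_field": psi_field.kind})
    wall_mask = ~cell_mask
    from .imaging import psi_histogram
    _, true_mode = psi_histogram(psi_true, mask=wall_mask)
    truth = {"psi_field": psi_true, "wall_mask": wall_mask,
             "cell_labels": labels, "mode_MPa": true_mode,
             "n_cells": len(cells)}
    return img, truth
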