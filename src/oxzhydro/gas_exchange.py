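"""Per-measurement conductance analytics for gas-exchange + nanoreporter
campaigns.

Given transpiration per surface, assimilation, leaf temperature, VPD and the
nanoreporter-measured water potentials upstream (ψ_xyl, from a both-sides
taped region) and downstream (ψ_ssc, untaped region) of the outside-xylem
zone, this module computes:

* the effective OXZ conductance       g_oxz = (E_ad + E_ab)/(w_xyl − w_ssc)
* the corrected stomatal conductance  g_s = E·(1 − (w_i + w_a)/2)/(w_i − w_a)
  with the measured w_i = w_ssc in place of saturation
* the conventional (Gaastra) estimate g_s_sat = E/(w_sat(T_l) − w_a)
* the nonstomatal-control phenotypes δw, δg_s, δiWUE and the resistance
  ratio g_s/g_oxz

plus binned summaries over the campaign's ψ_xyl and VPD ranges.

Records with a physically impossible driving force (w_xyl ≤ w_ssc, or
w_i ≤ w_a) are *flagged*: their metrics become missing values and a warning
is logged, but the batch never fails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from . import thermo
from .thermo import CONSTANTS

__all__ = [
    "MeasurementRecord",
    "CAMPAIGN_COLUMNS",
    "PSI_XYL_BIN_EDGES",
    "VPD_BIN_EDGES",
    "oxz_conductance",
    "stomatal_conductance_corrected",
    "stomatal_conductance_gaastra",
    "derive_metrics",
    "delta_metrics",
    "bin_summarize",
    "read_campaign",
]

logger = logging.getLogger(__name__)

#: Required input columns, in order (extra columns are preserved).
CAMPAIGN_COLUMNS = [
    "plant_id", "day", "E_ad", "E_ab", "A", "T_leaf_C", "VPD_kPa",
    "psi_xyl_MPa", "psi_ssc_MPa", "P_kPa",
]

#: Campaign binning edges (MPa / kPa) for the summary tables.
PSI_XYL_BIN_EDGES = (0.0, -0.4, -0.8, -1.2, -1.6, -2.0)
VPD_BIN_EDGES = (2.66, 3.25, 3.75, 4.25, 4.82)

#: Metric columns produced by :func:`derive_metrics`.
METRIC_COLUMNS = [
    "w_sat", "w_a", "w_xyl", "w_ssc", "g_oxz", "g_s", "g_s_sat",
    "delta_w", "delta_gs", "delta_iwue", "ratio_gs_goxz",
]


@dataclass(frozen=True)
class MeasurementRecord:
    """One gas-exchange + nanoreporter observation.

    E_ad/E_ab in mmol m⁻² s⁻¹, A in µmol m⁻² s⁻¹, temperatures in K,
    VPD and P in kPa, water potentials in MPa.
    """

    plant_id: str
    E_ad: float
    E_ab: float
    A: float
    T_leaf: float
    vpd: float
    psi_xyl: float
    psi_ssc: float
    P: float = CONSTANTS.atm_pressure
    day: int = 1

    def __post_init__(self) -> None:
        if self.E_ad < 0 or self.E_ab < 0:
            raise ValueError("transpiration rates must be non-negative")
        if self.vpd <= 0:
            raise ValueError("VPD must be positive")

    def to_row(self) -> dict:
        return {
            "plant_id": self.plant_id, "day": self.day,
            "E_ad": self.E_ad, "E_ab": self.E_ab, "A": self.A,
            "T_leaf_C": self.T_leaf - 273.15, "VPD_kPa": self.vpd,
            "psi_xyl_MPa": self.psi_xyl, "psi_ssc_MPa": self.psi_ssc,
            "P_kPa": self.P,
        }


def oxz_conductance(e_ad, e_ab, w_xyl, w_ssc_ad):
    """Effective outside-xylem-zone conductance, mmol m⁻² s⁻¹.

    g_oxz = (E_ad + E_ab)/(w_xyl − w_ssc_ad).  Non-positive driving forces
    yield NaN (flagged record), never an exception.
    """
    e = np.asarray(e_ad, float) + np.asarray(e_ab, float)
    drive = np.asarray(w_xyl, float) - np.asarray(w_ssc_ad, float)
    out = np.where(drive > 0, e / np.where(drive > 0, drive, np.nan), np.nan)
    n_bad = int(np.sum(~(drive > 0)))
    if n_bad:
        logger.warning("%d record(s) flagged: w_xyl <= w_ssc", n_bad)
    return out if out.ndim else float(out)


def stomatal_conductance_corrected(e, w_i, w_a, mass_flow_correction: bool = True):
    """Stomatal conductance from the measured interior mole fraction w_i.

    g_s = E·(1 − (w_i + w_a)/2)/(w_i − w_a); with
    ``mass_flow_correction=False`` the bulk-flow factor is dropped,
    g_s = E/(w_i − w_a).
    """
    e = np.asarray(e, float)
    wi = np.asarray(w_i, float)
    wa = np.asarray(w_a, float)
    drive = wi - wa
    corr = 1.0 - (wi + wa) / 2.0 if mass_flow_correction else 1.0
    out = np.where(drive > 0, e * corr / np.where(drive > 0, drive, np.nan), np.nan)
    n_bad = int(np.sum(~(drive > 0)))
    if n_bad:
        logger.warning("%d record(s) flagged: w_i <= w_a", n_bad)
    return out if out.ndim else float(out)


def stomatal_conductance_gaastra(e, w_sat_leaf, w_a):
    """Conventional stomatal-conductance estimate assuming a saturated
    interior: g_s_sat = E/(w_sat(T_l) − w_a) (no bulk-flow factor)."""
    e = np.asarray(e, float)
    drive = np.asarray(w_sat_leaf, float) - np.asarray(w_a, float)
    out = np.where(drive > 0, e / np.where(drive > 0, drive, np.nan), np.nan)
    return out if out.ndim else float(out)


def derive_metrics(df: pd.DataFrame, mass_flow_correction: bool = True,
                   iwue_convention: Literal["flux", "conductance"] = "flux",
                   ) -> pd.DataFrame:
    """Compute all derived conductances and δ-phenotypes for a campaign table.

    Parameters
    ----------
    df:
        Campaign table with the :data:`CAMPAIGN_COLUMNS` schema.
    mass_flow_correction:
        Apply the (1 − (w_i+w_a)/2) bulk-flow factor in g_s (default).  With
        the factor disabled, δg_s equals δw identically.
    iwue_convention:
        ``"flux"`` (default): iWUE = A/E and iWUE_sat = A/E_sat with
        E_sat = g_s·(w_sat − w_a), the transpiration a saturated interior
        would sustain at the same corrected g_s.  ``"conductance"``:
        iWUE = A/g_s against A/g_s_sat.

    Returns a copy of ``df`` with the :data:`METRIC_COLUMNS` appended.
    """
    missing = [c for c in CAMPAIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"campaign table missing column(s): {missing}")
    out = df.copy()
    t_leaf = out["T_leaf_C"].to_numpy(float) + 273.15
    p = out["P_kPa"].to_numpy(float)
    vpd = out["VPD_kPa"].to_numpy(float)

    w_sat = thermo.saturation_mole_fraction(t_leaf, p)
    w_a = (thermo.saturation_vapor_pressure(t_leaf) - vpd) / p
    if np.any(w_a < 0):
        raise ValueError("VPD exceeds e_sat(T_leaf) for some record(s)")
    w_xyl = w_sat * thermo.psi_to_h(
        np.minimum(out["psi_xyl_MPa"].to_numpy(float), 0.0), t_leaf)
    w_ssc = w_sat * thermo.psi_to_h(
        np.minimum(out["psi_ssc_MPa"].to_numpy(float), 0.0), t_leaf)

    e_ad = out["E_ad"].to_numpy(float)
    e_ab = out["E_ab"].to_numpy(float)
    e = e_ad + e_ab

    g_oxz = oxz_conductance(e_ad, e_ab, w_xyl, w_ssc)
    g_s = stomatal_conductance_corrected(e, w_ssc, w_a, mass_flow_correction)
    g_s_sat = stomatal_conductance_gaastra(e, w_sat, w_a)

    delta_w = (w_sat - w_ssc) / (w_sat - w_a)
    delta_gs = (g_s - g_s_sat) / g_s
    if iwue_convention == "flux":
        e_sat = g_s * (w_sat - w_a)
        delta_iwue = 1.0 - e / e_sat          # = (iWUE − iWUE_sat)/iWUE
    elif iwue_convention == "conductance":
        # iWUE = A/g_s vs A/g_s_sat; undersaturation makes g_s > g_s_sat,
        # so the deficit is 1 - g_s_sat/g_s (positive, like the flux form)
        delta_iwue = 1.0 - g_s_sat / g_s
    else:
        raise ValueError(f"unknown iwue_convention {iwue_convention!r}")

    out["w_sat"] = w_sat
    out["w_a"] = w_a
    out["w_xyl"] = w_xyl
    out["w_ssc"] = w_ssc
    out["g_oxz"] = g_oxz
    out["g_s"] = g_s
    out["g_s_sat"] = g_s_sat
    out["delta_w"] = delta_w
    out["delta_gs"] = delta_gs
    out["delta_iwue"] = delta_iwue
    out["ratio_gs_goxz"] = g_s / g_oxz
    return out


def delta_metrics(record: MeasurementRecord, **kwargs) -> pd.Series:
    """Derived metrics for a single :class:`MeasurementRecord`."""
    df = derive_metrics(pd.DataFrame([record.to_row()]), **kwargs)
    return df.iloc[0]


def bin_summarize(metrics: pd.DataFrame,
                  axis: Literal["psi_xyl", "vpd"] = "psi_xyl") -> pd.DataFrame:
    """Binned means and standard errors of every derived metric.

    Bins follow the campaign presentation (ψ_xyl: 0 to −0.4, …, −1.6 to −2
    MPa; VPD: 2.66–3.25, …, 4.25–4.82 kPa); a record on a shared edge goes
    to the lower-stress bin.  Empty bins appear with n = 0 and missing means.
    """
    if axis == "psi_xyl":
        # bin on stress = −ψ so that ψ = −0.4 lands in the 0 to −0.4 bin
        values = -metrics["psi_xyl_MPa"].to_numpy(float)
        edges = [-e for e in PSI_XYL_BIN_EDGES]
        labels = [f"{hi} to {lo}" for hi, lo in
                  zip(PSI_XYL_BIN_EDGES[:-1], PSI_XYL_BIN_EDGES[1:])]
    elif axis == "vpd":
        values = metrics["VPD_kPa"].to_numpy(float)
        edges = list(VPD_BIN_EDGES)
        labels = [f"{lo} to {hi}" for lo, hi in
                  zip(VPD_BIN_EDGES[:-1], VPD_BIN_EDGES[1:])]
    else:
        raise ValueError(f"unknown binning axis {axis!r}")

    cat = pd.cut(values, bins=edges, labels=labels, right=True,
                 include_lowest=True)
    rows = []
    cols = [c for c in METRIC_COLUMNS if c in metrics.columns]
    for label, (lo, hi) in zip(labels, zip(edges[:-1], edges[1:])):
        sub = metrics.loc[np.asarray(cat == label)]
        row = {"bin": label, "bin_low": lo, "bin_high": hi, "n": len(sub)}
        for c in cols:
            x = sub[c].dropna()
            row[f"{c}_mean"] = x.mean() if len(x) else np.nan
            row[f"{c}_se"] = (x.std(ddof=1) / np.sqrt(len(x))
                              if len(x) > 1 else (0.0 if len(x) == 1 else np.nan))
        rows.append(row)
    return pd.DataFrame(rows)


def read_campaign(path) -> pd.DataFrame:
    """Read a campaign CSV, validating the required column schema."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in CAMPAIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df
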