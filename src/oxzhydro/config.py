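"""TOML configuration for model runs, fits and the pipeline.

Sections (all optional; defaults are the shipped study conditions):

```toml
[constants]          # R, Vw, P_atm, psi_tlp
[network]            # n_layers, thickness, xylem_position, k_cc, k_vap, a_int
[membrane_law]       # kappa_max, kappa_min, psi_50, slope
[scenario]           # kind, air_layer_thickness, bs_area_per_leaf_area
[boundary]           # psi_xyl, vpd, t_leaf_C, gs_ad, gs_ab, pressure
[campaign]           # n_plants, n_measurements, psi_xyl_range, vpd_range, seed
[noise]              # psi_sd, flux_cv
[fit]                # kappa_bounds, n_starts
[calibration]        # zeta_wet, zeta_dry, psi_50, slope, psi_range
```

Unknown sections or keys are rejected with their location, so typos fail
loudly instead of silently reverting to defaults.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .imaging import CalibrationCurve
from .model import LeafNetwork, MembraneLaw, ScenarioSpec
from .synth import CampaignDesign, NoiseModel
from .thermo import PhysicalConstants

__all__ = ["PipelineConfig", "load_config"]

_KNOWN_KEYS = {
    "constants": {"R", "Vw", "P_atm", "psi_tlp"},
    "network": {"n_layers", "thickness", "xylem_position", "k_cc", "k_vap", "a_int"},
    "membrane_law": {"kappa_max", "kappa_min", "psi_50", "slope"},
    "scenario": {"kind", "air_layer_thickness", "bs_area_per_leaf_area"},
    "boundary": {"psi_xyl", "vpd", "t_leaf_C", "gs_ad", "gs_ab", "pressure"},
    "campaign": {"n_plants", "n_measurements", "psi_xyl_range", "vpd_range", "seed"},
    "noise": {"psi_sd", "flux_cv"},
    "fit": {"kappa_bounds", "n_starts"},
    "calibration": {"zeta_wet", "zeta_dry", "psi_50", "slope", "psi_range"},
}


@dataclass
class PipelineConfig:
    """Validated configuration bundle for model runs and the pipeline."""

    constants: PhysicalConstants
    network: LeafNetwork
    membrane_law: MembraneLaw
    scenario: ScenarioSpec
    boundary: dict
    campaign: CampaignDesign
    noise: NoiseModel
    fit: dict
    calibration: CalibrationCurve
    source: dict = field(default_factory=dict)


def _check_keys(raw: dict, path) -> None:
    for section, content in raw.items():
        if section not in _KNOWN_KEYS:
            raise ValueError(f"{path}: unknown section [{section}]")
        if not isinstance(content, dict):
            raise ValueError(f"{path}: [{section}] must be a table")
        for key in content:
            if key not in _KNOWN_KEYS[section]:
                raise ValueError(f"{path}: unknown key {key!r} in [{section}]")


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load and validate a TOML config; with no path, return the defaults."""
    raw: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        _check_keys(raw, path)

    c = raw.get("constants", {})
    constants = PhysicalConstants(
        gas_constant=c.get("R", 8.314),
        molar_volume_water=c.get("Vw", 1.805e-5),
        atm_pressure=c.get("P_atm", 101.325),
        turgor_loss_point=c.get("psi_tlp", -2.0),
    )
    from . import model as mdl
    net_defaults = mdl.DEFAULT_NETWORK
    n = raw.get("network", {})
    network = LeafNetwork(
        n_layers=n.get("n_layers", net_defaults.n_layers),
        thickness=n.get("thickness", net_defaults.thickness),
        xylem_position=n.get("xylem_position", net_defaults.xylem_position),
        k_cc=n.get("k_cc", net_defaults.k_cc),
        k_vap=n.get("k_vap", net_defaults.k_vap),
        a_int=n.get("a_int", net_defaults.a_int),
    )
    m = raw.get("membrane_law", {})
    law_defaults = mdl.DEFAULT_LAW
    law = MembraneLaw(
        kappa_max=m.get("kappa_max", law_defaults.kappa_max),
        kappa_min=m.get("kappa_min", law_defaults.kappa_min),
        psi_50=m.get("psi_50", law_defaults.psi_50),
        slope=m.get("slope", law_defaults.slope),
    )
    s = raw.get("scenario", {})
    scenario = ScenarioSpec(
        kind=s.get("kind", "uniform_membrane"),
        air_layer_thickness=s.get("air_layer_thickness", 200e-9),
        bs_area_per_leaf_area=s.get("bs_area_per_leaf_area", 2.0),
    )
    b = dict(raw.get("boundary", {}))
    b.setdefault("psi_xyl", -0.85)
    b.setdefault("vpd", 3.8)
    b.setdefault("t_leaf_C", mdl.T_LEAF_DEFAULT - 273.15)
    b.setdefault("gs_ad", mdl.GS_DEFAULT / 2)
    b.setdefault("gs_ab", mdl.GS_DEFAULT / 2)
    b.setdefault("pressure", constants.atm_pressure)

    g = raw.get("campaign", {})
    campaign = CampaignDesign(
        n_plants=g.get("n_plants", 37),
        n_measurements=g.get("n_measurements", 87),
        psi_xyl_range=tuple(g.get("psi_xyl_range", (-2.0, 0.0))),
        vpd_range=tuple(g.get("vpd_range", (2.66, 4.82))),
        seed=g.get("seed", 0),
    )
    z = raw.get("noise", {})
    noise = NoiseModel(psi_sd=z.get("psi_sd", 0.15), flux_cv=z.get("flux_cv", 0.05))

    f = dict(raw.get("fit", {}))
    f.setdefault("kappa_bounds", (1e-6, 1e-2))
    f.setdefault("n_starts", 5)

    k = raw.get("calibration", {})
    calibration = CalibrationCurve(
        zeta_wet=k.get("zeta_wet", 0.20), zeta_dry=k.get("zeta_dry", 0.70),
        psi_50=k.get("psi_50", -8.0), slope=k.get("slope", 3.0),
        psi_range=tuple(k.get("psi_range", (-20.0, 0.0))),
    )
    return PipelineConfig(constants=constants, network=network,
                          membrane_law=law, scenario=scenario, boundary=b,
                          campaign=campaign, noise=noise, fit=f,
                          calibration=calibration, source=raw)
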