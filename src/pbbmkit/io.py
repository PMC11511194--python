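"""File I/O for the standard CSV/JSON dialects of the pipeline.

Concentration columns carry explicit unit suffixes: in vitro data in
ug/mL on a minute time base, plasma data in ng/mL on an hour time base.
Configs are JSON; YAML is accepted and normalized to the same structures.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dissolution import DissolutionParameters, VesselConfig
from .particles import ParticleDistribution
from .pk import CTProfile, DispositionParameters, PopulationSpec
from .solubility import (
    DrugProperties,
    MediumSpec,
    SolubilityMeasurement,
    SolubilityParameters,
)
from .transfer import PrecipitationParameters, TransferConfig

__all__ = [
    "load_config",
    "dump_json",
    "read_solubility_csv",
    "read_dissolution_csv",
    "read_transfer_csv",
    "read_ct_csv",
    "write_ct_csv",
    "drug_from_config",
    "distribution_from_config",
    "vessel_from_config",
    "transfer_config_from_config",
    "disposition_from_config",
    "sol_params_from_config",
    "sol_params_to_config",
    "precip_from_config",
    "dis_params_from_config",
]


def load_config(path) -> dict:
    """Load a JSON or YAML config file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def dump_json(obj, path):
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# CSV dialects


def read_solubility_csv(path) -> list[SolubilityMeasurement]:
    """medium_name,pH,bile_salt_mM,volume_mL,solubility_ug_per_mL[,sd]"""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        medium = MediumSpec(
            name=str(row["medium_name"]), pH=float(row["pH"]),
            bile_salt=float(row["bile_salt_mM"]), volume=float(row["volume_mL"]),
        )
        sd = float(row["sd"]) / 1000.0 if "sd" in df.columns and pd.notna(row.get("sd")) else None
        out.append(SolubilityMeasurement(
            medium=medium,
            observed=float(row["solubility_ug_per_mL"]) / 1000.0,
            replicate_sd=sd if sd else None,
        ))
    return out


def read_dissolution_csv(path):
    """time_min,percent_dissolved -> (times, percents)"""
    df = pd.read_csv(path)
    return df["time_min"].to_numpy(float), df["percent_dissolved"].to_numpy(float)


def read_transfer_csv(path) -> pd.DataFrame:
    """time_min,chamber,concentration_ug_per_mL (long format)"""
    df = pd.read_csv(path)
    need = {"time_min", "chamber", "concentration_ug_per_mL"}
    if not need <= set(df.columns):
        raise ValueError(f"transfer CSV needs columns {sorted(need)}")
    return df


def read_ct_csv(path, dose: float = np.nan) -> CTProfile:
    """time_h,concentration_ng_per_mL[,sd]"""
    df = pd.read_csv(path)
    return CTProfile(times=df["time_h"].to_numpy(float),
                     concentration=df["concentration_ng_per_mL"].to_numpy(float),
                     dose=dose)


def write_ct_csv(profile: CTProfile, path):
    pd.DataFrame({
        "time_h": profile.times,
        "concentration_ng_per_mL": profile.concentration,
    }).to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# config constructors


def drug_from_config(cfg: dict) -> DrugProperties:
    return DrugProperties(
        name=cfg["name"], mw=cfg["mw"],
        pkas=tuple((p["value"], p["type"]) for p in cfg.get("pkas", [])),
        logp=cfg.get("logp", 0.0), density=cfg.get("density", 1.2),
    )


def distribution_from_config(cfg: dict) -> ParticleDistribution:
    return ParticleDistribution(
        kind=cfg["kind"], d10=cfg.get("d10"), d50=cfg.get("d50"),
        d90=cfg.get("d90"), mean_diameter=cfg.get("mean_diameter"),
        n_bins=cfg.get("n_bins", 20),
    )


def _medium_from_config(cfg: dict) -> MediumSpec:
    return MediumSpec(name=cfg["name"], pH=cfg["pH"],
                      bile_salt=cfg.get("bile_salt_mM", 0.0),
                      volume=cfg.get("volume_mL", 500.0))


def vessel_from_config(cfg: dict) -> VesselConfig:
    return VesselConfig(
        medium=_medium_from_config(cfg["medium"]),
        dose=cfg["dose_mg"],
        duration=cfg.get("duration_min", 120.0),
        paddle_rpm=cfg.get("paddle_rpm", 75.0),
    )


def transfer_config_from_config(cfg: dict) -> TransferConfig:
    kwargs = {}
    if "gastric_medium" in cfg:
        kwargs["gastric_medium"] = _medium_from_config(cfg["gastric_medium"])
    if "intestinal_medium" in cfg:
        kwargs["intestinal_medium"] = _medium_from_config(cfg["intestinal_medium"])
    for src, dst in (("emptying_half_life_min", "emptying_half_life"),
                     ("duration_min", "duration")):
        if src in cfg:
            kwargs[dst] = cfg[src]
    return TransferConfig(**kwargs)


def sol_params_from_config(cfg: dict) -> SolubilityParameters:
    return SolubilityParameters(
        s_o=cfg["s_o_mg_per_mL"], s_oscalar=dict(cfg.get("s_oscalar", {})),
        sf=cfg.get("sf", 1.0),
        km_w_unionized=cfg.get("km_w_unionized", 0.0),
        km_w_ionized=cfg.get("km_w_ionized", 0.0),
        s_bound_excip=cfg.get("s_bound_excip_mg_per_mL", 0.0),
    )


def sol_params_to_config(params: SolubilityParameters) -> dict:
    return {
        "s_o_mg_per_mL": params.s_o,
        "s_oscalar": dict(params.s_oscalar),
        "sf": params.sf,
        "km_w_unionized": params.km_w_unionized,
        "km_w_ionized": params.km_w_ionized,
        "s_bound_excip_mg_per_mL": params.s_bound_excip,
    }


def dis_params_from_config(cfg: dict) -> DissolutionParameters:
    return DissolutionParameters(
        dlm_scalar=cfg.get("dlm_scalar", 1.0),
        d_eff=cfg.get("d_eff_cm2_per_s"),
        h_eff_cap=cfg.get("h_eff_cap_um", 30.0),
    )


def precip_from_config(cfg: dict) -> PrecipitationParameters:
    return PrecipitationParameters(
        csc=cfg.get("csc", 1.001), prc=cfg.get("prc_per_h", 1e-4),
        precip_particle_radius=cfg.get("precip_particle_radius_um", 1.0),
        redissolution=cfg.get("redissolution", True),
    )


def disposition_from_config(cfg: dict) -> DispositionParameters:
    return DispositionParameters(
        n_compartments=cfg.get("n_compartments", 1),
        vc=cfg["vc_L"], cl=cfg["cl_L_per_h"],
        vp=cfg.get("vp_L"), q=cfg.get("q_L_per_h"),
        kp_scalar=cfg.get("kp_scalar", 1.0),
        q_h=cfg.get("q_h_L_per_h", 90.0),
        f_u=cfg.get("f_u", 1.0),
        well_stirred=cfg.get("well_stirred", True),
    )


def population_from_config(cfg: dict) -> PopulationSpec:
    if "seed" not in cfg:
        raise ValueError("population spec requires an explicit seed")
    return PopulationSpec(
        n_trials=cfg.get("n_trials", 10),
        n_subjects=cfg.get("n_subjects", 10),
        variability=dict(cfg.get("variability", {})),
        seed=cfg["seed"],
    )
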