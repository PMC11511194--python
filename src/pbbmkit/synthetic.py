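"""Synthetic input generation from known ground truth.

Every file format the pipeline consumes (equilibrium solubilities,
vessel dissolution profiles, two-stage transfer profiles, observed
concentration-time data) can be generated here from a fully specified
:class:`GroundTruth`, noise-free or with seeded noise, so that each
calibration stage is testable as a round trip without any external data.

Three bundled archetypes mirror the behavioral classes of weakly basic,
poorly soluble drugs:

* ``rivaroxaban_like`` — pH-insensitive solubility (high pKa), no
  precipitation, food effect driven by bile and permeability;
* ``ticagrelor_like`` — strongly bile-sensitive solubility, high
  intestinal solubility, no food effect;
* ``pb201_like`` — steeply pH-dependent solubility, precipitates on
  gastric-to-intestinal transfer. This is a synthetic archetype: its
  parameters are chosen so supersaturation actually develops in the
  idealized two-chamber apparatus, not to reproduce any measured
  compound.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .absorption import (
    PermeabilityInput,
    papp_to_peff,
    physiology_preset,
    simulate_gi_absorption,
)
from .dissolution import DissolutionParameters, simulate_vessel
from .particles import ParticleDistribution, discretize
from .pk import CTProfile, DispositionParameters, simulate_pk
from .solubility import (
    BUILTIN_MEDIA,
    DrugProperties,
    SolubilityParameters,
    builtin_medium,
    total_solubility,
)
from .transfer import (
    PrecipitationParameters,
    TransferConfig,
    simulate_two_stage_transfer,
)

__all__ = [
    "GroundTruth",
    "NoiseSpec",
    "rivaroxaban_like",
    "ticagrelor_like",
    "pb201_like",
    "gen_solubility_data",
    "gen_dissolution_profiles",
    "gen_transfer_profile",
    "gen_ct_observations",
    "simulate_truth_ct",
]

#: generic PAMPA->human Peff calibration line (Papp cm/s, Peff 1e-4 cm/s);
#: three decades lying close to a log-log trend of slope ~0.7
DEFAULT_PEFF_CALIBRATION = (
    (1e-6, 0.25),
    (1e-5, 1.3),
    (1e-4, 6.5),
)


@dataclass
class GroundTruth:
    """A fully specified scenario: drug, formulation, kinetics, disposition."""

    drug: DrugProperties
    sol: SolubilityParameters
    dist: ParticleDistribution
    dis: DissolutionParameters
    precip: PrecipitationParameters
    disp: DispositionParameters
    dose_mg: float
    papp: dict = field(default_factory=dict)  # source -> cm/s
    peff_calibration: tuple = DEFAULT_PEFF_CALIBRATION
    physiology_overrides: dict = field(default_factory=dict)
    variability: dict = field(default_factory=lambda: {
        "cl": 30.0, "gastric_emptying_half_life": 30.0, "bile": 25.0,
    })

    def bins(self, dose: float | None = None):
        return discretize(self.dist, dose or self.dose_mg, self.drug.density)

    def peff_for_state(self, state: str) -> float:
        source = "pampa_fassif" if state == "fasted" else "pampa_fessif"
        papp = self.papp.get(source)
        if papp is None:
            raise KeyError(f"ground truth has no Papp for source {source!r}")
        cal = papp_to_peff(PermeabilityInput(
            source=source, papp=papp, calibration_set=self.peff_calibration,
        ))
        return cal.peff


@dataclass(frozen=True)
class NoiseSpec:
    kind: str  # "multiplicative_lognormal" | "additive_gaussian"
    cv_or_sd: float  # CV% (multiplicative) or SD in data units (additive)
    seed: int

    def __post_init__(self):
        if self.kind not in ("multiplicative_lognormal", "additive_gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.cv_or_sd == 0:
            return values.copy()
        if self.kind == "multiplicative_lognormal":
            sigma = np.sqrt(np.log(1.0 + (self.cv_or_sd / 100.0) ** 2))
            return values * np.exp(sigma * rng.standard_normal(values.shape))
        return np.maximum(values + self.cv_or_sd * rng.standard_normal(values.shape), 0.0)


# ---------------------------------------------------------------------------
# bundled archetypes


def _soscalar_for(s_o, km_u, km_i, si, targets):
    """Per-medium Soscalar values that place STot exactly at ``targets``."""
    out = {}
    for name, stot in targets.items():
        med = BUILTIN_MEDIA[name]
        bs = med.bile_salt / med.water_conc
        si_term = si * (1.0 + bs * km_i)
        out[name] = (stot - si_term) / (s_o * (1.0 + bs * km_u))
    return out


def rivaroxaban_like() -> GroundTruth:
    """pH-insensitive weak base; no precipitation; 20 mg immediate release.

    Solubility scalars are set so the FaSSGF/FaSSIF equilibrium
    solubilities are 7.50 and 6.17 ug/mL.
    """
    drug = DrugProperties("rivaroxaban-like", mw=435.9,
                         pkas=((13.6, "base"),), logp=1.90)
    s_o, km_u, km_i = 5.0e-3, 3000.0, 300.0
    sol = SolubilityParameters(
        s_o=s_o, sf=1.0, km_w_unionized=km_u, km_w_ionized=km_i,
        s_oscalar=_soscalar_for(s_o, km_u, km_i, 0.0,
                                {"FaSSGF": 7.50e-3, "FaSSIF": 6.17e-3,
                                 "FeSSIF": 8.90e-3}),
    )
    return GroundTruth(
        drug=drug,
        sol=sol,
        dist=ParticleDistribution("lognormal", d10=3.809, d50=7.955, d90=15.532),
        dis=DissolutionParameters(dlm_scalar=1.0),
        precip=PrecipitationParameters.minimal(),
        disp=DispositionParameters(n_compartments=1, vc=50.0, cl=6.0),
        dose_mg=20.0,
        papp={"pampa_fassif": 5.0e-5, "pampa_fessif": 2.0e-5, "caco2": 3.0e-5},
    )


def ticagrelor_like() -> GroundTruth:
    """Bile-sensitive weak base with high intestinal solubility; 90 mg dose.

    Uses the measured FaSSIF/FeSSIF PAMPA permeabilities of ticagrelor
    (9.02e-5 and 1.43e-5 cm/s).
    """
    drug = DrugProperties("ticagrelor-like", mw=522.6,
                         pkas=((2.82, "base"), (0.98, "base")), logp=3.521)
    sol = SolubilityParameters(
        s_o=1.0e-2, sf=1.0, km_w_unionized=2.0e4, km_w_ionized=2.0e3,
        s_oscalar={"FaSSGF": 1.0, "FaSSIF": 1.0, "FeSSIF": 1.0},
    )
    return GroundTruth(
        drug=drug,
        sol=sol,
        dist=ParticleDistribution("lognormal", d10=3.045, d50=6.926, d90=13.605),
        dis=DissolutionParameters(dlm_scalar=1.0),
        precip=PrecipitationParameters.minimal(),
        disp=DispositionParameters(n_compartments=2, vc=30.0, vp=58.0,
                                   q=10.0, cl=14.0),
        dose_mg=90.0,
        papp={"pampa_fassif": 9.02e-5, "pampa_fessif": 1.43e-5, "caco2": 5.0e-5},
    )


def pb201_like() -> GroundTruth:
    """Steeply pH-dependent weak base that precipitates on transfer; 50 mg.

    Synthetic archetype: gastric solubility ~12 ug/mL versus intestinal
    ~2 ug/mL, so the intestinal chamber supersaturates several-fold after
    transfer and first-order precipitation (CSC 1.5, PRC 2/h) is clearly
    expressed. Only a volume-average particle diameter (1.697 um) is
    carried, so a monodispersed description is used.
    """
    drug = DrugProperties("pb201-like", mw=408.0,
                         pkas=((10.41, "base"),), logp=2.102)
    sol = SolubilityParameters(
        s_o=2.4e-7, sf=5.0e4, km_w_unionized=1000.0, km_w_ionized=100.0,
        s_oscalar={"FaSSGF": 1.0, "FaSSIF": 1.0, "FeSSIF": 1.0},
    )
    return GroundTruth(
        drug=drug,
        sol=sol,
        dist=ParticleDistribution("monodispersed", mean_diameter=1.697),
        dis=DissolutionParameters(dlm_scalar=1.0),
        precip=PrecipitationParameters(csc=1.5, prc=2.0),
        disp=DispositionParameters(n_compartments=1, vc=120.0, cl=20.0),
        dose_mg=50.0,
        papp={"pampa_fassif": 3.0e-5, "pampa_fessif": 1.5e-5, "caco2": 2.0e-5},
    )


FIXTURES = {
    "rivaroxaban_like": rivaroxaban_like,
    "ticagrelor_like": ticagrelor_like,
    "pb201_like": pb201_like,
}


# ---------------------------------------------------------------------------
# generators


def gen_solubility_data(truth: GroundTruth, media,
                        noise: NoiseSpec | None = None,
                        n_replicates: int = 3):
    """Equilibrium solubility measurements per medium.

    Returns ``(summary, replicates)`` DataFrames; the summary carries the
    replicate mean and SD in the standard solubility CSV dialect.
    """
    media = list(media)
    if not media:
        raise ValueError("media list must not be empty")
    rng = np.random.default_rng(noise.seed if noise else 0)
    rows, reps = [], []
    for med in media:
        if isinstance(med, str):
            med = builtin_medium(med)
        stot = total_solubility(truth.sol, truth.drug, med)
        values = np.full(n_replicates, stot)
        if noise:
            values = noise.apply(values, rng)
        for r, v in enumerate(values):
            reps.append({"medium_name": med.name, "replicate": r,
                         "solubility_ug_per_mL": v * 1000.0})
        rows.append({
            "medium_name": med.name,
            "pH": med.pH,
            "bile_salt_mM": med.bile_salt,
            "volume_mL": med.volume,
            "solubility_ug_per_mL": float(values.mean()) * 1000.0,
            "sd": float(values.std(ddof=1)) * 1000.0 if n_replicates > 1 else 0.0,
        })
    return pd.DataFrame(rows), pd.DataFrame(reps)


def gen_dissolution_profiles(truth: GroundTruth, vessels,
                             noise: NoiseSpec | None = None):
    """Simulated per-vessel dissolution profiles on the 1-min sampling grid."""
    rng = np.random.default_rng(noise.seed if noise else 0)
    out = []
    for vessel in vessels:
        bins = truth.bins(vessel.dose)
        prof = simulate_vessel(bins, vessel, truth.sol, truth.dis, truth.drug)
        pct = prof.percent_dissolved.copy()
        if noise:
            pct = np.clip(noise.apply(pct, rng), 0.0, None)
        out.append(pd.DataFrame({"time_min": prof.times,
                                 "percent_dissolved": pct}))
    return out


def gen_transfer_profile(truth: GroundTruth, config: TransferConfig,
                         noise: NoiseSpec | None = None,
                         dose: float | None = None,
                         predissolved_mg: float = 0.0) -> pd.DataFrame:
    """Two-chamber transfer concentration series (both chambers, long format)."""
    solid_dose = truth.dose_mg if dose is None else dose
    bins = truth.bins(solid_dose) if solid_dose > 0 else []
    result = simulate_two_stage_transfer(
        config, bins, truth.sol, truth.dis, truth.precip, truth.drug,
        predissolved_mg=predissolved_mg,
    )
    rng = np.random.default_rng(noise.seed if noise else 0)
    frames = []
    for chamber, conc in (("gastric", result.gastric_concentration),
                          ("intestinal", result.intestinal_concentration)):
        c = conc * 1000.0  # mg/mL -> ug/mL
        if noise:
            c = noise.apply(c, rng)
        frames.append(pd.DataFrame({
            "time_min": result.times,
            "chamber": chamber,
            "concentration_ug_per_mL": c,
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_truth_ct(truth: GroundTruth, state: str = "fasted",
                      sampling_times_h=None,
                      duration_h: float = 24.0,
                      n_bins: int | None = None,
                      physiology_overrides: dict | None = None) -> CTProfile:
    """Deterministic concentration-time profile for a ground-truth scenario."""
    sampling = (np.asarray(sampling_times_h, dtype=float)
                if sampling_times_h is not None
                else np.arange(0.25, duration_h + 1e-9, 0.25))
    overrides = dict(truth.physiology_overrides)
    overrides.update(physiology_overrides or {})
    phys = physiology_preset(state, overrides)
    dist = truth.dist if n_bins is None else replace(truth.dist, n_bins=n_bins)
    bins = discretize(dist, truth.dose_mg, truth.drug.density)
    absorption = simulate_gi_absorption(
        truth.drug, bins, truth.sol, truth.dis, truth.precip, phys,
        peff=truth.peff_for_state(state), duration_h=max(duration_h, sampling[-1]),
    )
    return simulate_pk(absorption, truth.disp, sampling)


def gen_ct_observations(truth: GroundTruth, sampling_times_h,
                        noise: NoiseSpec | None, n_subjects: int,
                        seed: int, state: str = "fasted",
                        n_bins: int | None = None):
    """Observed-like concentration-time data from the population model.

    Inter-individual variability follows ``truth.variability``;
    observation noise is applied on top of each subject's profile.
    Returns ``(subjects, mean)`` DataFrames. When only disposition
    parameters vary, the GI absorption simulation is shared across
    subjects.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    sampling = np.asarray(sampling_times_h, dtype=float)
    disp_keys = {"cl", "vc", "vp", "q", "kp_scalar"}
    var = {k: v for k, v in truth.variability.items() if v > 0}
    absorption_varies = bool(set(var) - disp_keys)
    overrides = dict(truth.physiology_overrides)
    phys = physiology_preset(state, overrides)
    dist = truth.dist if n_bins is None else replace(truth.dist, n_bins=n_bins)
    bins = discretize(dist, truth.dose_mg, truth.drug.density)
    peff = truth.peff_for_state(state)
    duration = float(sampling[-1])
    shared_absorption = None
    if not absorption_varies:
        shared_absorption = simulate_gi_absorption(
            truth.drug, bins, truth.sol, truth.dis, truth.precip, phys,
            peff=peff, duration_h=duration,
        )

    rng = np.random.default_rng(seed)
    sigmas = {k: np.sqrt(np.log(1.0 + (cv / 100.0) ** 2)) for k, cv in var.items()}
    rows = []
    for s in range(n_subjects):
        draws = {k: float(np.exp(sig * rng.standard_normal()))
                 for k, sig in sigmas.items()}
        disp = truth.disp
        disp_kw = {k: getattr(truth.disp, k) * draws[k]
                   for k in draws if k in disp_keys}
        if disp_kw:
            disp = replace(truth.disp, **disp_kw)
        absorption = shared_absorption
        if absorption is None:
            ov = dict(overrides)
            if "gastric_emptying_half_life" in draws:
                ov["gastric_emptying_half_life"] = (
                    phys.gastric_emptying_half_life
                    * draws["gastric_emptying_half_life"]
                )
            if "bile" in draws:
                for comp in phys.compartments:
                    if comp.absorbing:
                        ov[f"{comp.name}.bile_salt"] = comp.bile_salt * draws["bile"]
            subj_phys = physiology_preset(state, ov)
            absorption = simulate_gi_absorption(
                truth.drug, bins, truth.sol, truth.dis, truth.precip,
                subj_phys, peff=peff, duration_h=duration,
            )
        conc = simulate_pk(absorption, disp, sampling).concentration
        if noise:
            conc = noise.apply(conc, rng)
        for t, c in zip(sampling, conc):
            rows.append({"subject": s, "time_h": t,
                         "concentration_ng_per_mL": c})
    subjects = pd.DataFrame(rows)
    mean = (subjects.groupby("time_h", as_index=False)["concentration_ng_per_mL"]
            .mean())
    return subjects, mean
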