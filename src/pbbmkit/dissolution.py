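"""Diffusion layer model (DLM) dissolution and USP-2 vessel simulation.

Per size bin of N identical spherical particles, the dissolution rate is
the amended Wang-Flanagan form::

    DR(t) = N * DLM_scalar * D_eff / h_eff(t) * 4*pi*a(t)*(a(t) + h_eff(t))
            * (S_surface - C_bulk(t))

with particle radius ``a(t)``, effective diffusion layer thickness
``h_eff(t) = min(a(t), h_cap)`` (cap default 30 um), effective diffusivity
``D_eff`` and the solubility/bulk concentration difference as driving
force. ``S_surface`` defaults to the total solubility STot of the bulk
medium (no particle-surface microclimate pH model).

The vessel simulator integrates per-bin solid mass plus the dissolved
amount with an adaptive stiff-capable solver; solid + dissolved equals the
dose identically in the right-hand side, so mass is conserved to solver
tolerance. Internal units: mg, mL, min, um (lengths in the rate law
converted to cm).
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np
from scipy.integrate import solve_ivp

from .particles import ParticleBin, ParticleDistribution, discretize
from .solubility import DrugProperties, MediumSpec, SolubilityParameters, total_solubility

__all__ = [
    "DissolutionParameters",
    "VesselConfig",
    "DissolutionProfile",
    "default_d_eff",
    "dissolution_rate",
    "simulate_vessel",
    "fit_dissolution",
    "DissolutionFitResult",
]

#: radius below which a particle is treated as fully depleted, um
DEPLETION_RADIUS_UM = 1e-3


def default_d_eff(mw: float) -> float:
    """Effective diffusivity (cm^2/s) from molecular weight.

    Uses the empirical small-molecule correlation D = 9.9e-5 * MW**-0.453.
    """
    if mw <= 0:
        raise ValueError("mw must be positive")
    return 9.9e-5 * mw ** -0.453


@dataclass
class DissolutionParameters:
    """Tunable constants of the diffusion layer model."""

    dlm_scalar: float = 1.0
    d_eff: float | None = None  # cm^2/s; None -> MW correlation at use time
    h_eff_cap: float = 30.0  # um

    def __post_init__(self):
        if self.dlm_scalar <= 0:
            raise ValueError("dlm_scalar must be positive")
        if self.d_eff is not None and self.d_eff <= 0:
            raise ValueError("d_eff must be positive")
        if self.h_eff_cap <= 0:
            raise ValueError("h_eff_cap must be positive")

    def resolve_d_eff(self, drug: DrugProperties) -> float:
        return self.d_eff if self.d_eff is not None else default_d_eff(drug.mw)


@dataclass
class VesselConfig:
    """A USP-2-style dissolution vessel run."""

    medium: MediumSpec
    dose: float  # mg
    duration: float = 120.0  # min
    paddle_rpm: float = 75.0  # metadata only; the rate law has no rpm term
    output_step: float = 1.0  # min, matching per-minute fiber-optic sampling
    rtol: float = 1e-8
    atol: float = 1e-12  # mg

    def __post_init__(self):
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class DissolutionProfile:
    times: np.ndarray  # min
    percent_dissolved: np.ndarray  # % of dose
    bulk_concentration: np.ndarray  # mg/mL
    surface_concentration: float  # mg/mL (S_surface used)
    dose: float  # mg
    dissolved_mg: np.ndarray = None
    solid_mg: np.ndarray = None


def _radius_from_mass(mass_mg, count, density):
    """Radius (um) of identical spheres holding ``mass_mg`` in ``count`` particles."""
    mass = np.maximum(mass_mg, 0.0)
    vol_um3 = mass / (density * 1000.0) * 1e12
    with np.errstate(divide="ignore", invalid="ignore"):
        a3 = np.where(count > 0, vol_um3 / (count * 4.0 / 3.0 * np.pi), 0.0)
    return np.cbrt(a3)


def _flux_mg_min(radius_um, count, s_surface, c_bulk, dlm, d_eff_cm2_s, h_cap_um):
    """Signed DLM flux (mg/min, positive = dissolving) for one or more bins."""
    a_um = np.asarray(radius_um, dtype=float)
    a_cm = a_um * 1e-4
    h_cm = np.minimum(a_um, h_cap_um) * 1e-4
    d_cm2_min = d_eff_cm2_s * 60.0
    with np.errstate(divide="ignore", invalid="ignore"):
        geom = np.where(
            a_um > DEPLETION_RADIUS_UM,
            4.0 * np.pi * a_cm * (a_cm + h_cm) / h_cm,
            0.0,
        )
    return np.asarray(count) * dlm * d_cm2_min * geom * (s_surface - c_bulk)


def dissolution_rate(bin: ParticleBin, s_surface: float, c_bulk: float,
                     params: DissolutionParameters,
                     drug: DrugProperties | None = None,
                     d_eff: float | None = None) -> float:
    """DLM dissolution rate (mg/min) of one particle bin.

    Positive when dissolving (S_surface > C_bulk); the signed value is
    returned as-is, growth handling is the caller's concern. Zero for a
    fully depleted bin.
    """
    if s_surface < 0:
        raise ValueError("s_surface must be >= 0")
    if d_eff is None:
        if drug is None and params.d_eff is None:
            raise ValueError("need drug (for the MW correlation) or explicit d_eff")
        d_eff = params.resolve_d_eff(drug) if params.d_eff is None else params.d_eff
    return float(
        _flux_mg_min(bin.radius, bin.count, s_surface, c_bulk,
                     params.dlm_scalar, d_eff, params.h_eff_cap)
    )


def simulate_vessel(bins, vessel: VesselConfig,
                    sol_params: SolubilityParameters,
                    dis_params: DissolutionParameters,
                    drug: DrugProperties,
                    s_surface: float | None = None) -> DissolutionProfile:
    """Simulate dissolution of particle ``bins`` in a closed stirred vessel.

    ``s_surface`` defaults to the medium's total solubility. Negative
    driving force (bulk above the surface concentration) is clamped to
    zero: particle growth is disabled outside the precipitation module.
    """
    stot = total_solubility(sol_params, drug, vessel.medium)
    s_surf = stot if s_surface is None else s_surface
    v = vessel.medium.volume
    counts = np.array([b.count for b in bins])
    density = drug.density
    d_eff = dis_params.resolve_d_eff(drug)
    m0 = np.array(
        [b.count * 4.0 / 3.0 * np.pi * b.radius**3 * 1e-12 * density * 1000.0
         for b in bins]
    )
    solid0 = float(m0.sum())
    if solid0 > vessel.dose * (1 + 1e-9):
        raise ValueError("bin solid mass exceeds the vessel dose")
    dissolved0 = vessel.dose - solid0  # pre-dissolved remainder, usually 0

    # smooth taper near bin depletion: the raw rate law is non-Lipschitz
    # at m -> 0 (flux ~ m**1/3), which stalls adaptive steps; the taper
    # leaves a ~1e-5 relative mass residual per bin
    m_tap = 1e-5 * np.maximum(m0, 1e-30)

    def rhs(t, y):
        masses, dissolved = y[:-1], y[-1]
        c_bulk = dissolved / v
        radii = _radius_from_mass(masses, counts, density)
        flux = _flux_mg_min(radii, counts, s_surf, c_bulk,
                            dis_params.dlm_scalar, d_eff, dis_params.h_eff_cap)
        mc = np.maximum(masses, 0.0)
        flux *= mc**2 / (mc**2 + m_tap**2)
        flux = np.maximum(flux, 0.0)  # no growth
        flux[masses <= 0.0] = 0.0
        return np.concatenate([-flux, [flux.sum()]])

    t_eval = np.arange(0.0, vessel.duration + 1e-9, vessel.output_step)
    sol = solve_ivp(rhs, (0.0, vessel.duration), np.concatenate([m0, [dissolved0]]),
                    method="LSODA", t_eval=t_eval,
                    rtol=vessel.rtol, atol=vessel.atol)
    if not sol.success:
        raise RuntimeError(
            f"vessel integration failed: {sol.message} "
            f"(dose={vessel.dose} mg, medium={vessel.medium.name}, STot={stot:.4g})"
        )
    dissolved = sol.y[-1]
    solid = sol.y[:-1].sum(axis=0)
    return DissolutionProfile(
        times=sol.t,
        percent_dissolved=dissolved / vessel.dose * 100.0,
        bulk_concentration=dissolved / v,
        surface_concentration=s_surf,
        dose=vessel.dose,
        dissolved_mg=dissolved,
        solid_mg=solid,
    )


# ---------------------------------------------------------------------------
# parameter estimation


@dataclass
class DissolutionFitResult:
    params: DissolutionParameters  # averaged across profiles
    per_profile: list  # list of dicts {dlm_scalar, sf?, sse, n_points}
    sf_override: float | None  # refit SF, if requested
    sensitivity: dict  # param -> {0.5x: SSE, 1x: SSE, 2x: SSE} on profile 0
    report: str = ""


def fit_dissolution(profiles, vessels, dist: ParticleDistribution,
                    sol_params: SolubilityParameters,
                    drug: DrugProperties,
                    base_params: DissolutionParameters | None = None,
                    refit_sf: bool = False,
                    dlm_bounds=(1e-3, 1e3),
                    sf_bounds=(1.0, 1e3)) -> DissolutionFitResult:
    """Fit DLM_scalar (optionally also SF) to measured vessel profiles.

    Each profile is fit independently and the per-profile estimates are
    averaged into the returned parameter set, mirroring the practice of
    feeding averaged per-medium estimates into the in vivo model. The
    sensitivity table reports SSE under +/-2-fold perturbation of each
    fitted parameter around the averaged optimum.
    """
    base = base_params or DissolutionParameters()
    if len(profiles) != len(vessels):
        raise ValueError("profiles and vessels must pair one-to-one")
    per_profile = []
    import dataclasses as _dc

    for prof, vessel in zip(profiles, vessels):
        times = np.asarray(prof.times, dtype=float)
        obs = np.asarray(prof.percent_dissolved, dtype=float)
        if len(times) < 4:
            raise ValueError("dissolution profiles need at least 4 points")

        def residual(p, _times=times, _obs=obs, _vessel=vessel):
            dp = _dc.replace(base, dlm_scalar=p["dlm_scalar"].value)
            sp = sol_params
            if refit_sf:
                sp = _dc.replace(sol_params, sf=p["sf"].value)
            v = _dc.replace(_vessel, duration=float(_times[-1]),
                            output_step=max(float(np.min(np.diff(_times))), 1e-3))
            sim = simulate_vessel(discretize(dist, v.dose, drug.density),
                                  v, sp, dp, drug)
            pred = np.interp(_times, sim.times, sim.percent_dissolved)
            return pred - _obs

        p = lmfit.Parameters()
        p.add("dlm_scalar", value=base.dlm_scalar,
              min=dlm_bounds[0], max=dlm_bounds[1])
        if refit_sf:
            p.add("sf", value=max(sol_params.sf, 1.0 + 1e-6),
                  min=sf_bounds[0], max=sf_bounds[1])
        res = lmfit.minimize(residual, p, method="least_squares")
        entry = {
            "dlm_scalar": float(res.params["dlm_scalar"].value),
            "sse": float(res.chisqr),
            "n_points": len(times),
        }
        if refit_sf:
            entry["sf"] = float(res.params["sf"].value)
        per_profile.append(entry)

    avg_dlm = float(np.mean([e["dlm_scalar"] for e in per_profile]))
    sf_override = (float(np.mean([e["sf"] for e in per_profile]))
                   if refit_sf else None)
    import dataclasses as dc
    fitted = dc.replace(base, dlm_scalar=avg_dlm)

    # +/- 2-fold sensitivity of the first profile's SSE
    sensitivity = {}
    prof0, vessel0 = profiles[0], vessels[0]
    times0 = np.asarray(prof0.times, dtype=float)
    obs0 = np.asarray(prof0.percent_dissolved, dtype=float)

    def sse_at(dlm):
        dp = dc.replace(fitted, dlm_scalar=dlm)
        sp = sol_params if sf_override is None else dc.replace(sol_params, sf=sf_override)
        v = dc.replace(vessel0, duration=float(times0[-1]))
        sim = simulate_vessel(discretize(dist, v.dose, drug.density), v, sp, dp, drug)
        pred = np.interp(times0, sim.times, sim.percent_dissolved)
        return float(np.sum((pred - obs0) ** 2))

    sensitivity["dlm_scalar"] = {
        "0.5x": sse_at(avg_dlm * 0.5),
        "1x": sse_at(avg_dlm),
        "2x": sse_at(avg_dlm * 2.0),
    }
    lines = [f"dissolution fit over {len(profiles)} profile(s):"]
    for i, e in enumerate(per_profile):
        lines.append(f"  profile {i}: DLM_scalar={e['dlm_scalar']:.4g}"
                     + (f", SF={e['sf']:.4g}" if "sf" in e else "")
                     + f", SSE={e['sse']:.4g}")
    lines.append(f"  averaged DLM_scalar = {avg_dlm:.4g}")
    if sf_override is not None:
        lines.append(f"  averaged SF override = {sf_override:.4g}")
    return DissolutionFitResult(
        params=fitted,
        per_profile=per_profile,
        sf_override=sf_override,
        sensitivity=sensitivity,
        report="\n".join(lines),
    )
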