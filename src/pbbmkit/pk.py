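"""Compartmental disposition, PK metrics, fitting and population simulation.

Systemic disposition is a 1- or 2-compartment linear model fed by the
portal absorption flux after well-stirred hepatic first-pass extraction
(E_h = CL/Q_h, so F_h = 1 - CL/Q_h with CL interpreted as hepatic blood
clearance). Distribution volumes are multiplied by a global ``kp_scalar``
— the single tissue-partitioning knob retained from full-PBPK practice,
where it is tuned against an observed concentration-time profile.

PK metrics use the linear-up/log-down trapezoid with terminal log-linear
extrapolation to infinity. Population simulation draws lognormal
inter-individual variability per subject, reports per-trial mean profiles
and the 5th-95th percentile band across trial means (the 10-trials x
10-subjects reporting convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator

__all__ = [
    "DispositionParameters",
    "CTProfile",
    "PopulationSpec",
    "PopulationResult",
    "first_order_input",
    "simulate_pk",
    "pk_metrics",
    "fit_disposition",
    "population_simulate",
]


@dataclass
class DispositionParameters:
    n_compartments: int = 1
    vc: float = 50.0  # L, central volume
    cl: float = 5.0  # L/h, systemic (hepatic) clearance
    vp: float | None = None  # L, peripheral volume
    q: float | None = None  # L/h, inter-compartment clearance
    kp_scalar: float = 1.0  # multiplies distribution volumes
    q_h: float = 90.0  # L/h, hepatic blood flow
    f_u: float = 1.0  # unbound fraction (0, 1]
    well_stirred: bool = True  # apply hepatic first-pass E_h = cl/q_h

    def __post_init__(self):
        if self.n_compartments not in (1, 2):
            raise ValueError("n_compartments must be 1 or 2")
        if min(self.vc, self.cl, self.kp_scalar, self.q_h) <= 0:
            raise ValueError("volumes, clearances and kp_scalar must be positive")
        if not (0 < self.f_u <= 1):
            raise ValueError("f_u must be in (0, 1]")
        if self.n_compartments == 2:
            if not self.vp or not self.q or self.vp <= 0 or self.q <= 0:
                raise ValueError("2-compartment model needs vp > 0 and q > 0")
        if self.well_stirred and self.cl >= self.q_h:
            raise ValueError("well-stirred first-pass needs cl < q_h")

    @property
    def f_hepatic(self) -> float:
        return 1.0 - self.cl / self.q_h if self.well_stirred else 1.0

    @property
    def vss(self) -> float:
        return self.kp_scalar * (self.vc + (self.vp or 0.0))


@dataclass
class CTProfile:
    times: np.ndarray  # h
    concentration: np.ndarray  # ng/mL
    dose: float  # mg

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concentration < -1e-9):
            raise ValueError("concentrations must be >= 0")
        self.concentration = np.maximum(self.concentration, 0.0)

    @property
    def metrics(self) -> dict:
        return pk_metrics(self)


@dataclass
class PopulationSpec:
    n_trials: int = 10
    n_subjects: int = 10
    variability: dict = field(default_factory=lambda: {"cl": 30.0})  # param -> CV%
    seed: int = 0

    def __post_init__(self):
        if self.n_trials < 1 or self.n_subjects < 1:
            raise ValueError("n_trials and n_subjects must be >= 1")
        if any(cv < 0 for cv in self.variability.values()):
            raise ValueError("CVs must be >= 0")


def first_order_input(dose_mg: float, ka_per_h: float, fa: float = 1.0):
    """Portal flux callable for first-order absorption (for tests/oracles)."""
    if dose_mg <= 0 or ka_per_h <= 0:
        raise ValueError("dose and ka must be positive")
    return lambda t: fa * dose_mg * ka_per_h * np.exp(-ka_per_h * np.asarray(t))


def simulate_pk(absorption, disp: DispositionParameters,
                sampling_times, rtol: float = 1e-9,
                atol: float = 1e-12) -> CTProfile:
    """Simulate the plasma concentration-time profile (ng/mL).

    ``absorption`` is an ``AbsorptionResult`` (its cumulative absorbed
    curve is differentiated with a monotone spline to give the portal
    flux in mg/h) or a callable ``flux(t_h) -> mg/h``. The systemic input
    is ``F_h * flux`` with the well-stirred hepatic extraction.
    """
    t = np.asarray(sampling_times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("sampling times must be strictly increasing")
    if callable(absorption):
        flux = absorption
        dose = None
        t_max_avail = np.inf
    else:
        if len(absorption.times) < 2:
            raise ValueError("absorption result too short")
        interp = PchipInterpolator(absorption.times, absorption.absorbed)
        dflux = interp.derivative()
        flux = lambda tt: np.maximum(dflux(np.clip(tt, absorption.times[0],
                                                   absorption.times[-1])), 0.0)
        dose = absorption.dose
        t_max_avail = absorption.times[-1]
    if t[-1] > t_max_avail + 1e-9:
        raise ValueError(
            f"sampling extends to {t[-1]} h but absorption only covers "
            f"{t_max_avail} h"
        )
    fh = disp.f_hepatic
    vc = disp.vc * disp.kp_scalar

    if disp.n_compartments == 1:
        def rhs(tt, y):
            return [fh * float(flux(tt)) - disp.cl * y[0] / vc]
        y0 = [0.0]
    else:
        vp = disp.vp * disp.kp_scalar

        def rhs(tt, y):
            cc, cp = y[0] / vc, y[1] / vp
            return [fh * float(flux(tt)) - disp.cl * cc - disp.q * (cc - cp),
                    disp.q * (cc - cp)]
        y0 = [0.0, 0.0]

    t0 = min(0.0, t[0])
    sol = solve_ivp(rhs, (t0, t[-1]), y0, t_eval=t, method="LSODA",
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"PK integration failed: {sol.message}")
    conc_ng_ml = np.maximum(sol.y[0], 0.0) / vc * 1000.0  # mg/L -> ng/mL
    return CTProfile(times=t, concentration=conc_ng_ml,
                     dose=dose if dose is not None else np.nan)


def pk_metrics(profile: CTProfile) -> dict:
    """AUC (linear-up/log-down), Cmax, Tmax, and AUC extrapolated to infinity.

    The terminal slope is a log-linear fit of the last >= 3 positive
    concentrations; the extrapolated fraction ``auc_extrap_fraction`` is
    reported so sparse tails are auditable.
    """
    t, c = profile.times, profile.concentration
    if len(t) < 3:
        raise ValueError("need at least 3 points for PK metrics")
    auc = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if c2 < c1 and c1 > 0 and c2 > 0:
            auc += (c1 - c2) * dt / np.log(c1 / c2)
        else:
            auc += 0.5 * (c1 + c2) * dt
    imax = int(np.argmax(c))
    cmax, tmax = float(c[imax]), float(t[imax])

    pos = np.nonzero(c > 0)[0]
    tail = pos[pos >= imax][-3:]
    lam_z, auc_inf, extrap = np.nan, np.nan, np.nan
    if len(tail) >= 3:
        slope, _ = np.polyfit(t[tail], np.log(c[tail]), 1)
        if slope < 0:
            lam_z = -slope
            auc_inf = auc + c[pos[-1]] / lam_z
            extrap = (auc_inf - auc) / auc_inf
    return {
        "auc_0_t": float(auc),
        "auc_inf": float(auc_inf),
        "cmax": cmax,
        "tmax": tmax,
        "lambda_z": float(lam_z),
        "auc_extrap_fraction": float(extrap),
    }


# ---------------------------------------------------------------------------
# fitting


@dataclass
class DispositionFitResult:
    params: DispositionParameters
    sse: float
    free: tuple
    at_bounds: list
    report: str = ""


_DISP_BOUNDS = {
    "vc": (1e-2, 1e4), "vp": (1e-2, 1e4), "q": (1e-3, 1e3),
    "cl": (1e-3, 1e3), "kp_scalar": (1e-2, 1e2),
}


def fit_disposition(observed: CTProfile, absorption,
                    base: DispositionParameters,
                    free=("cl", "vc"),
                    bounds: dict | None = None,
                    n_starts: int = 4, seed: int = 0) -> DispositionFitResult:
    """Weighted least squares (1/yhat weights) fit of disposition parameters.

    ``kp_scalar`` and any volume cannot both be freed — they scale the
    profile identically (an identifiability guard, not a numerical
    limitation). Needs at least ``len(free) + 2`` observed points.
    """
    free = tuple(free)
    if "kp_scalar" in free and ("vc" in free or "vp" in free):
        raise ValueError(
            "kp_scalar and a distribution volume cannot both be free: "
            "they are scale-confounded"
        )
    if len(observed.times) < len(free) + 2:
        raise ValueError("need at least n_free + 2 observed points")
    bounds = {**_DISP_BOUNDS, **(bounds or {})}

    def residual(p):
        kw = {name: p[name].value for name in free}
        try:
            disp = replace(base, **kw)
        except ValueError:
            return np.full(len(observed.times), 1e6)
        pred = simulate_pk(absorption, disp, observed.times).concentration
        w = 1.0 / np.maximum(pred, 1e-6)
        return w * (pred - observed.concentration)

    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(n_starts, 1)):
        p = lmfit.Parameters()
        for name in free:
            lo, hi = bounds[name]
            base_val = getattr(base, name) or np.sqrt(lo * hi)
            init = base_val if start == 0 else float(
                np.exp(rng.uniform(np.log(lo), np.log(hi)))
            )
            p.add(name, value=min(max(init, lo), hi), min=lo, max=hi)
        try:
            res = lmfit.minimize(residual, p, method="least_squares")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("disposition fit failed in every start")
    kw = {name: float(best.params[name].value) for name in free}
    fitted = replace(base, **kw)
    at_bounds = [
        name for name in free
        if min(kw[name] - bounds[name][0], bounds[name][1] - kw[name])
        < 1e-6 * (bounds[name][1] - bounds[name][0])
    ]
    lines = [f"disposition fit ({len(observed.times)} points):"]
    for name in free:
        lines.append(f"  {name} = {kw[name]:.5g}"
                     + ("  [at bound]" if name in at_bounds else ""))
    return DispositionFitResult(
        params=fitted, sse=float(best.chisqr), free=free,
        at_bounds=at_bounds, report="\n".join(lines),
    )


# ---------------------------------------------------------------------------
# population simulation


@dataclass
class PopulationResult:
    times: np.ndarray  # h
    mean: np.ndarray  # ng/mL, mean of trial means
    lower: np.ndarray  # 5th percentile across trial means
    upper: np.ndarray  # 95th percentile across trial means
    trial_means: np.ndarray  # (n_trials, n_times)
    degenerate_band: bool


def population_simulate(profile_fn, base_params: dict,
                        pop: PopulationSpec, sampling_times) -> PopulationResult:
    """Monte-Carlo population simulation with lognormal variability.

    ``profile_fn(params: dict) -> concentrations`` evaluates one subject;
    ``base_params`` holds the population-typical values and
    ``pop.variability`` maps parameter names to CV%. Each subject draws
    ``p = p_typ * exp(sigma * Z)`` with ``sigma = sqrt(ln(1 + CV^2))``.
    The 90% band is the 5th-95th percentile across per-trial means.
    """
    t = np.asarray(sampling_times, dtype=float)
    rng = np.random.default_rng(pop.seed)
    degenerate = (all(cv == 0 for cv in pop.variability.values())
                  and pop.n_subjects * pop.n_trials > 1)
    if degenerate:
        warnings.warn("all CVs are zero: confidence band is degenerate",
                      stacklevel=2)
    unknown = set(pop.variability) - set(base_params)
    if unknown:
        raise KeyError(f"variability on unknown parameters: {sorted(unknown)}")
    sigmas = {k: np.sqrt(np.log(1.0 + (cv / 100.0) ** 2))
              for k, cv in pop.variability.items()}
    trial_means = np.empty((pop.n_trials, len(t)))
    for trial in range(pop.n_trials):
        subj = np.empty((pop.n_subjects, len(t)))
        for s in range(pop.n_subjects):
            params = dict(base_params)
            for k, sig in sigmas.items():
                params[k] = base_params[k] * np.exp(sig * rng.standard_normal())
            subj[s] = np.asarray(profile_fn(params), dtype=float)
        trial_means[trial] = subj.mean(axis=0)
    return PopulationResult(
        times=t,
        mean=trial_means.mean(axis=0),
        lower=np.percentile(trial_means, 5, axis=0),
        upper=np.percentile(trial_means, 95, axis=0),
        trial_means=trial_means,
        degenerate_band=degenerate,
    )
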