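"""Biorelevant solubility model for ionizable, poorly soluble drugs.

The total solubility of a drug in an aqueous or biorelevant medium is
modeled as the sum of an un-ionized term, an ionized term, and an
excipient-bound term, each of the first two enhanced by bile-micelle
solubilization::

    STot = So * Soscalar * (1 + [BS]/C_H2O * Km:w,u)
         + Si * (1 + [BS]/C_H2O * Km:w,i)
         + Sbound

where ``So`` is the intrinsic (un-ionized) solubility, ``Soscalar`` a
per-medium multiplier capturing medium-specific solubilization beyond the
bile term, ``Si`` the ionized aqueous solubility derived from the
Henderson-Hasselbalch ratio and capped by the salt limiting solubility
factor ``SF`` (So + Si <= So*SF), ``[BS]`` the bile-salt concentration,
``C_H2O`` the molar concentration of water, and ``Km:w`` the micelle/water
partition coefficients of the un-ionized and ionized species.

Calibration (:func:`fit_solubility`) is weighted least squares in
log-concentration space, since equilibrium solubilities of weak bases span
orders of magnitude between gastric and intestinal pH.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np

__all__ = [
    "DrugProperties",
    "MediumSpec",
    "SolubilityParameters",
    "SolubilityMeasurement",
    "FitPlan",
    "SolubilityFitResult",
    "BUILTIN_MEDIA",
    "builtin_medium",
    "ionization_fractions",
    "total_solubility",
    "fit_solubility",
]

#: molar concentration of water, mM
WATER_CONC_MM = 55_500.0


@dataclass(frozen=True)
class DrugProperties:
    """Physicochemical identity of the API.

    ``pkas`` is a list of ``(value, kind)`` pairs with kind ``"base"`` or
    ``"acid"``; an empty list means a neutral molecule.
    """

    name: str
    mw: float  # g/mol
    pkas: tuple = ()
    logp: float = 0.0
    density: float = 1.2  # g/cm^3, true density of the solid

    def __post_init__(self):
        if not np.isfinite(self.mw) or self.mw <= 0:
            raise ValueError(f"mw must be positive, got {self.mw}")
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        object.__setattr__(self, "pkas", tuple(tuple(p) for p in self.pkas))
        for value, kind in self.pkas:
            if kind not in ("base", "acid"):
                raise ValueError(f"pKa kind must be 'base' or 'acid', got {kind!r}")
            if not (0.0 <= value <= 14.0):
                warnings.warn(
                    f"pKa {value} outside [0, 14] for {self.name}; tolerated",
                    stacklevel=2,
                )


@dataclass(frozen=True)
class MediumSpec:
    """An aqueous or biorelevant dissolution medium."""

    name: str
    pH: float
    bile_salt: float = 0.0  # mM
    volume: float = 500.0  # mL
    water_conc: float = WATER_CONC_MM  # mM

    def __post_init__(self):
        if not (0.0 < self.pH < 14.0):
            raise ValueError(f"pH must be in (0, 14), got {self.pH}")
        if self.bile_salt < 0:
            raise ValueError("bile_salt must be >= 0")
        if self.volume <= 0:
            raise ValueError("volume must be positive")


# Standard published recipes for the fasted/fed simulated GI fluids; all
# overridable by constructing MediumSpec directly or via a JSON media table.
BUILTIN_MEDIA = {
    "FaSSGF": MediumSpec("FaSSGF", pH=1.6, bile_salt=0.08, volume=300.0),
    "FaSSIF": MediumSpec("FaSSIF", pH=6.5, bile_salt=3.0, volume=500.0),
    "FeSSIF": MediumSpec("FeSSIF", pH=5.0, bile_salt=15.0, volume=900.0),
}


def builtin_medium(name: str, **overrides) -> MediumSpec:
    """Return a copy of a built-in medium, optionally with fields replaced."""
    try:
        base = BUILTIN_MEDIA[name]
    except KeyError:
        raise KeyError(
            f"unknown medium {name!r}; built-ins: {sorted(BUILTIN_MEDIA)}"
        ) from None
    return replace(base, **overrides) if overrides else base


@dataclass
class SolubilityParameters:
    """Calibrated constants of the biorelevant solubility model.

    ``s_oscalar`` maps medium name -> multiplier; media absent from the map
    use 1.0 (or raise, in strict mode).
    """

    s_o: float  # mg/mL, intrinsic solubility
    s_oscalar: dict = field(default_factory=dict)
    sf: float = 1.0  # salt limiting solubility factor, >= 1
    km_w_unionized: float = 0.0
    km_w_ionized: float = 0.0
    s_bound_excip: float = 0.0  # mg/mL

    def __post_init__(self):
        if self.s_o <= 0:
            raise ValueError("s_o must be positive")
        if self.sf < 1.0:
            raise ValueError("sf must be >= 1")
        if self.km_w_unionized < 0 or self.km_w_ionized < 0:
            raise ValueError("Km:w coefficients must be >= 0")
        for name, value in self.s_oscalar.items():
            if value <= 0:
                raise ValueError(f"s_oscalar[{name!r}] must be positive")


@dataclass(frozen=True)
class SolubilityMeasurement:
    """One equilibrium solubility observation in a given medium."""

    medium: MediumSpec
    observed: float  # mg/mL
    replicate_sd: float | None = None  # mg/mL

    def __post_init__(self):
        if self.observed <= 0:
            raise ValueError("observed solubility must be positive")


def ionization_fractions(pH: float, drug: DrugProperties) -> tuple[float, float]:
    """Henderson-Hasselbalch fractions (f_unionized, f_ionized) at ``pH``.

    Basic and acidic groups contribute independently; successive pKa values
    of the same kind are treated as cumulative protonation/deprotonation
    steps. A drug with no pKa entries is fully un-ionized.
    """
    if not np.isfinite(pH):
        raise ValueError(f"pH must be finite, got {pH}")
    base_pkas = sorted((v for v, k in drug.pkas if k == "base"), reverse=True)
    acid_pkas = sorted(v for v, k in drug.pkas if k == "acid")
    ratio = 0.0  # total ionized / un-ionized
    log_term = 0.0
    for pka in base_pkas:
        log_term += pka - pH
        ratio += 10.0 ** min(log_term, 300.0)
    log_term = 0.0
    for pka in acid_pkas:
        log_term += pH - pka
        ratio += 10.0 ** min(log_term, 300.0)
    f_un = 1.0 / (1.0 + ratio)
    return f_un, 1.0 - f_un


def ionized_solubility(params: SolubilityParameters, drug: DrugProperties,
                       pH: float) -> float:
    """Ionized aqueous solubility Si, salt-limited.

    Si = So * f_ionized/f_unionized, capped so that So + Si <= So * SF.
    The cap keeps Si finite at low pH, where the Henderson-Hasselbalch
    ratio for a weak base diverges; the precipitating counter-ion then
    limits total aqueous solubility to SF-fold the intrinsic value.
    """
    f_un, f_ion = ionization_fractions(pH, drug)
    cap = params.s_o * (params.sf - 1.0)
    if f_un <= 0.0:
        return cap
    return min(params.s_o * f_ion / f_un, cap)


def total_solubility(params: SolubilityParameters, drug: DrugProperties,
                     medium: MediumSpec, strict: bool = False) -> float:
    """Total solubility STot (mg/mL) of ``drug`` in ``medium``."""
    if medium.name in params.s_oscalar:
        sos = params.s_oscalar[medium.name]
    elif strict:
        raise KeyError(
            f"no Soscalar calibrated for medium {medium.name!r} (strict mode)"
        )
    else:
        sos = 1.0
    bs_ratio = medium.bile_salt / medium.water_conc
    s_i = ionized_solubility(params, drug, medium.pH)
    return (
        params.s_o * sos * (1.0 + bs_ratio * params.km_w_unionized)
        + s_i * (1.0 + bs_ratio * params.km_w_ionized)
        + params.s_bound_excip
    )


# ---------------------------------------------------------------------------
# calibration


@dataclass
class FitPlan:
    """Which solubility parameters are free and how the fit is run.

    ``free`` names from {"s_o", "sf", "km_w_unionized", "km_w_ionized"} plus
    per-medium scalars as ``"s_oscalar:<medium name>"``. ``fixed`` supplies
    values for parameters not freed (s_o is mandatory one way or the other).
    ``exclude_media`` implements the outlier-exclusion mechanism (e.g.
    dropping an aqueous pH 1.0 point the model family cannot capture).
    ``tie_km_ratio`` ties Km:w,ionized = Km:w,unionized / 10 when the data
    cannot separate the two coefficients.
    """

    free: tuple = ("s_o",)
    fixed: dict = field(default_factory=dict)
    bounds: dict = field(default_factory=dict)
    exclude_media: tuple = ()
    tie_km_ratio: bool = False
    n_starts: int = 5
    seed: int = 0
    strict_soscalar: bool = False

    _DEFAULT_BOUNDS = {
        "s_o": (1e-9, 1e3),
        "sf": (1.0, 1e4),
        "km_w_unionized": (0.0, 1e7),
        "km_w_ionized": (0.0, 1e7),
        "s_oscalar": (1e-3, 1e3),
    }

    def bounds_for(self, name: str) -> tuple[float, float]:
        if name in self.bounds:
            return self.bounds[name]
        key = "s_oscalar" if name.startswith("s_oscalar:") else name
        return self._DEFAULT_BOUNDS[key]


@dataclass
class SolubilityFitResult:
    params: SolubilityParameters
    residuals: np.ndarray  # log-space residuals, excluded points omitted
    sse: float
    n_used: int
    at_bounds: list
    unidentifiable: list
    excluded: list
    report: str = ""


def _build_params(values: dict, plan: FitPlan) -> SolubilityParameters:
    scalars = {}
    scalar_fixed = plan.fixed.get("s_oscalar", {})
    scalars.update(scalar_fixed)
    for name, v in values.items():
        if name.startswith("s_oscalar:"):
            scalars[name.split(":", 1)[1]] = v
    kw = {k: v for k, v in values.items() if not k.startswith("s_oscalar:")}
    for key in ("s_o", "sf", "km_w_unionized", "km_w_ionized", "s_bound_excip"):
        if key not in kw and key in plan.fixed:
            kw[key] = plan.fixed[key]
    if plan.tie_km_ratio and "km_w_ionized" not in kw:
        kw["km_w_ionized"] = kw.get("km_w_unionized", 0.0) / 10.0
    kw.setdefault("sf", 1.0)
    kw.setdefault("km_w_unionized", 0.0)
    kw.setdefault("km_w_ionized", 0.0)
    return SolubilityParameters(s_oscalar=scalars, **kw)


def fit_solubility(measurements, drug: DrugProperties,
                   plan: FitPlan | None = None) -> SolubilityFitResult:
    """Calibrate the solubility model to equilibrium measurements.

    Weighted least squares on ``log(predicted) - log(observed)``;
    measurements with a replicate SD are weighted by the inverse relative
    SD. Runs ``plan.n_starts`` seeded multi-starts and keeps the best.

    Raises ``ValueError`` when the design is under-identified (more free
    parameters than usable points, or micelle coefficients freed without
    at least two bile-containing media).
    """
    plan = plan or FitPlan()
    used = [m for m in measurements if m.medium.name not in plan.exclude_media]
    excluded = [m.medium.name for m in measurements if m not in used]
    if not used:
        raise ValueError("no usable measurements after exclusions")

    free = list(plan.free)
    if plan.tie_km_ratio and "km_w_ionized" in free:
        free.remove("km_w_ionized")
    if "s_o" not in free and "s_o" not in plan.fixed:
        raise ValueError("s_o must be free or supplied in plan.fixed")
    n_bile = sum(1 for m in used if m.medium.bile_salt > 0)
    unidentifiable = []
    for km in ("km_w_unionized", "km_w_ionized"):
        if km in free and n_bile < 2:
            unidentifiable.append(km)
    if len(free) > len(used):
        # Per-medium scalars paired one-to-one with their medium stay
        # identifiable; anything beyond that is flagged.
        n_scalars = sum(1 for f in free if f.startswith("s_oscalar:"))
        if len(free) - n_scalars > max(0, len(used) - n_scalars):
            unidentifiable.extend(
                f for f in free if not f.startswith("s_oscalar:")
            )
    if unidentifiable and len(unidentifiable) == len(free):
        raise ValueError(
            f"under-identified fit: cannot estimate {sorted(set(unidentifiable))} "
            "from the supplied design"
        )

    obs = np.array([m.observed for m in used])
    weights = np.ones(len(used))
    for i, m in enumerate(used):
        if m.replicate_sd and m.replicate_sd > 0:
            weights[i] = 1.0 / max(m.replicate_sd / m.observed, 1e-3)
    weights /= weights.max()

    def residual(lm_params):
        values = {name: lm_params[_safe(name)].value for name in free}
        try:
            sp = _build_params(values, plan)
        except ValueError:
            return np.full(len(used), 1e6)
        pred = np.array(
            [total_solubility(sp, drug, m.medium, strict=plan.strict_soscalar)
             for m in used]
        )
        pred = np.maximum(pred, 1e-300)
        return weights * (np.log(pred) - np.log(obs))

    def _safe(name):  # lmfit parameter names cannot contain ':'
        return name.replace(":", "__").replace(" ", "_")

    rng = np.random.default_rng(plan.seed)
    best = None
    for start in range(max(plan.n_starts, 1)):
        lm = lmfit.Parameters()
        for name in free:
            lo, hi = plan.bounds_for(name)
            if start == 0:
                init = np.sqrt(max(lo, 1e-12) * hi) if lo > 0 else 0.1 * hi
                if name.startswith("s_oscalar:"):
                    init = 1.0
                if name == "sf":
                    init = 2.0
                if name == "s_o":
                    init = float(np.median(obs))
            else:
                lo_ = max(lo, 1e-9)
                init = float(np.exp(rng.uniform(np.log(lo_), np.log(max(hi, lo_ * 10)))))
            lm.add(_safe(name), value=min(max(init, lo), hi), min=lo, max=hi)
        try:
            res = lmfit.minimize(residual, lm, method="least_squares")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("solubility fit failed in every start")

    values = {name: best.params[_safe(name)].value for name in free}
    fitted = _build_params(values, plan)
    resid = residual(best.params)
    at_bounds = []
    for name in free:
        lo, hi = plan.bounds_for(name)
        v = values[name]
        span = max(hi - lo, 1e-12)
        if min(v - lo, hi - v) < 1e-6 * span:
            at_bounds.append(name)
    lines = [f"solubility fit: {len(used)} points, SSE(log)={np.sum(resid**2):.3e}"]
    for name in free:
        lines.append(f"  {name} = {values[name]:.6g}"
                     + ("  [at bound]" if name in at_bounds else ""))
    if plan.tie_km_ratio:
        lines.append("  km_w_ionized tied to km_w_unionized/10")
    if excluded:
        lines.append(f"  excluded media: {excluded}")
    if unidentifiable:
        lines.append(f"  flagged unidentifiable: {sorted(set(unidentifiable))}")
    return SolubilityFitResult(
        params=fitted,
        residuals=resid,
        sse=float(np.sum(resid**2)),
        n_used=len(used),
        at_bounds=at_bounds,
        unidentifiable=sorted(set(unidentifiable)),
        excluded=excluded,
        report="\n".join(lines),
    )
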