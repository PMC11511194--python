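"""Food-effect ratios, predicted/observed diagnostics and acceptance flags.

Predictive performance is judged by the predicted-to-observed AUC and Cmax
ratios against the conventional 0.5-2.0-fold acceptance boundary and the
stricter 0.80-1.25-fold band, plus the fraction of observed points falling
inside the simulated 90% confidence band. The food effect itself is the
fed/fasted ratio of exposure metrics; ratios within 0.8-1.25 for both AUC
and Cmax are classified as "none".

To avoid grid-density bias, ratio comparisons restrict the predicted
profile to the observed sampling times and apply the same trapezoid rule
to both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pk import CTProfile, pk_metrics

__all__ = [
    "RatioReport",
    "predicted_observed_ratios",
    "food_effect",
    "ci_coverage",
]

TWOFOLD = (0.5, 2.0)
BIOEQUIVALENCE_BAND = (0.8, 1.25)


@dataclass
class RatioReport:
    auc_ratio: float
    cmax_ratio: float
    auc_inf_ratio: float
    within_2fold: dict  # metric -> bool
    within_1p25fold: dict


def _restrict(predicted: CTProfile, observed: CTProfile) -> CTProfile:
    conc = np.interp(observed.times, predicted.times, predicted.concentration)
    return CTProfile(times=observed.times, concentration=conc,
                     dose=predicted.dose)


def _inside(ratio: float, band: tuple) -> bool:
    return band[0] < ratio < band[1]  # strictly inside


def predicted_observed_ratios(predicted: CTProfile,
                              observed: CTProfile) -> RatioReport:
    """Predicted/observed AUC and Cmax ratios with acceptance flags.

    AUC uses the observed timepoints for both profiles (the predicted
    curve is linearly interpolated onto them). Both AUC(0-t) and
    AUC(0-inf) ratios are reported since acceptance conventions differ.
    """
    pred_r = _restrict(predicted, observed)
    mp, mo = pk_metrics(pred_r), pk_metrics(observed)
    for key in ("auc_0_t", "cmax"):
        if mo[key] == 0:
            raise ValueError(f"observed {key} is zero; ratio undefined")
    auc_ratio = mp["auc_0_t"] / mo["auc_0_t"]
    cmax_ratio = mp["cmax"] / mo["cmax"]
    auc_inf_ratio = (mp["auc_inf"] / mo["auc_inf"]
                     if np.isfinite(mp["auc_inf"]) and np.isfinite(mo["auc_inf"])
                     and mo["auc_inf"] > 0 else np.nan)
    return RatioReport(
        auc_ratio=auc_ratio,
        cmax_ratio=cmax_ratio,
        auc_inf_ratio=auc_inf_ratio,
        within_2fold={"auc": _inside(auc_ratio, TWOFOLD),
                      "cmax": _inside(cmax_ratio, TWOFOLD)},
        within_1p25fold={"auc": _inside(auc_ratio, BIOEQUIVALENCE_BAND),
                         "cmax": _inside(cmax_ratio, BIOEQUIVALENCE_BAND)},
    )


def food_effect(fed: CTProfile, fasted: CTProfile,
                dose_normalized: bool = False) -> dict:
    """Fed/fasted exposure ratios and a food-effect classification.

    Classification: "none" when both ratios lie in [0.8, 1.25],
    "positive" when both exceed it, "negative" when both fall below,
    otherwise "mixed".
    """
    if not dose_normalized and np.isfinite(fed.dose) and np.isfinite(fasted.dose):
        if abs(fed.dose - fasted.dose) > 1e-9 * max(fed.dose, fasted.dose):
            raise ValueError(
                "fed and fasted doses differ; pass dose_normalized=True "
                "to compare dose-normalized exposure"
            )
    mf, mfa = pk_metrics(fed), pk_metrics(fasted)
    scale = 1.0
    if dose_normalized:
        scale = fasted.dose / fed.dose
    fe_auc = mf["auc_0_t"] / mfa["auc_0_t"] * scale
    fe_cmax = mf["cmax"] / mfa["cmax"] * scale
    lo, hi = BIOEQUIVALENCE_BAND

    def cls(r):
        if lo <= r <= hi:
            return "none"
        return "positive" if r > hi else "negative"

    c_auc, c_cmax = cls(fe_auc), cls(fe_cmax)
    classification = c_auc if c_auc == c_cmax else "mixed"
    return {
        "fe_auc": fe_auc,
        "fe_cmax": fe_cmax,
        "classification": classification,
        "per_metric": {"auc": c_auc, "cmax": c_cmax},
    }


def ci_coverage(observed_times, observed_conc, band_times,
                lower, upper) -> float:
    """Fraction of observed points inside a [lower, upper] band.

    The band is interpolated linearly onto the observation times.
    """
    t_obs = np.asarray(observed_times, dtype=float)
    c_obs = np.asarray(observed_conc, dtype=float)
    if len(t_obs) == 0:
        raise ValueError("no observations supplied")
    lo = np.interp(t_obs, np.asarray(band_times, float), np.asarray(lower, float))
    hi = np.interp(t_obs, np.asarray(band_times, float), np.asarray(upper, float))
    inside = (c_obs >= lo) & (c_obs <= hi)
    return float(inside.mean())
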