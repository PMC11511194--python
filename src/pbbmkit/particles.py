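"""Particle size distributions and their discretization into size bins.

Laser-diffraction sizing reports volume-weighted quantiles D(0.1), D(0.5),
D(0.9). For milled APIs these are well described by a lognormal volume
distribution; :func:`lognormal_from_quantiles` recovers (geometric mean,
geometric SD) by least squares on the three log-quantiles. A monodispersed
description (one representative diameter) is used when only a mean size is
available.

:func:`discretize` converts a distribution plus a dose into discrete
particle bins (radius + particle count) for the population-balance
dissolution model; bins are equal-volume-fraction slices between the 0.5th
and 99.5th volume percentile, so the summed bin volume reproduces the dose
exactly by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

__all__ = [
    "ParticleDistribution",
    "ParticleBin",
    "LognormalFit",
    "lognormal_from_quantiles",
    "discretize",
]

#: standard normal quantile at p = 0.9 (and -z at p = 0.1)
_Z90 = 1.2815515655446004


@dataclass(frozen=True)
class ParticleDistribution:
    kind: str  # "lognormal" | "monodispersed"
    d10: float | None = None  # um
    d50: float | None = None
    d90: float | None = None
    mean_diameter: float | None = None  # um, monodispersed
    n_bins: int = 20

    def __post_init__(self):
        if self.kind == "lognormal":
            if not (self.d10 and self.d50 and self.d90):
                raise ValueError("lognormal distribution needs d10, d50, d90")
            if not (0 < self.d10 < self.d50 < self.d90):
                raise ValueError("quantiles must satisfy 0 < d10 < d50 < d90")
        elif self.kind == "monodispersed":
            if not self.mean_diameter or self.mean_diameter <= 0:
                raise ValueError("monodispersed distribution needs mean_diameter > 0")
        else:
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")


@dataclass
class ParticleBin:
    """A cohort of identical spherical particles."""

    radius: float  # um, current radius a(t)
    count: float  # number of particles
    initial_radius: float  # um

    def __post_init__(self):
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if not (0 <= self.radius <= self.initial_radius * (1 + 1e-12)):
            raise ValueError("radius must be within [0, initial_radius]")


class LognormalFit(NamedTuple):
    geo_mean: float  # um
    geo_sd: float  # unitless, exp(sigma_log)
    residual: float  # RMS of log-quantile misfit


def lognormal_from_quantiles(d10: float, d50: float, d90: float) -> LognormalFit:
    """Least-squares lognormal fit to volume quantiles at z = -1.2816, 0, +1.2816.

    With symmetric z-scores the normal equations give mu = mean of the three
    log-quantiles and sigma = (log d90 - log d10) / (2 * 1.2816); the RMS
    residual is zero iff d50 = sqrt(d10 * d90).
    """
    if not (0 < d10 < d50 < d90):
        raise ValueError("quantiles must satisfy 0 < d10 < d50 < d90")
    logs = np.log([d10, d50, d90])
    z = np.array([-_Z90, 0.0, _Z90])
    mu = logs.mean()
    sigma = float(z @ logs / (z @ z))
    resid = float(np.sqrt(np.mean((mu + sigma * z - logs) ** 2)))
    geo_sd = float(np.exp(sigma))
    if geo_sd < 1.05:
        warnings.warn(
            "near-equal size quantiles: distribution is effectively "
            "monodisperse (geometric SD < 1.05)",
            stacklevel=2,
        )
    return LognormalFit(float(np.exp(mu)), geo_sd, resid)


def _sphere_volume_um3(radius_um: float) -> float:
    return 4.0 / 3.0 * np.pi * radius_um**3


def discretize(dist: ParticleDistribution, dose: float,
               density: float) -> list[ParticleBin]:
    """Split ``dose`` mg of solid of ``density`` g/cm^3 into particle bins.

    Lognormal distributions are sliced into ``n_bins`` equal volume-fraction
    bins between the 0.5th and 99.5th percentile; each bin's representative
    diameter is the volume-median within the slice. Total solid volume
    equals dose/density exactly.
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    total_volume_um3 = dose / (density * 1000.0) * 1e12  # mg / (mg/cm3) -> cm3 -> um3

    if dist.kind == "monodispersed":
        radius = dist.mean_diameter / 2.0
        count = total_volume_um3 / _sphere_volume_um3(radius)
        return [ParticleBin(radius=radius, count=count, initial_radius=radius)]

    fit = lognormal_from_quantiles(dist.d10, dist.d50, dist.d90)
    mu, sigma = np.log(fit.geo_mean), np.log(fit.geo_sd)
    n = dist.n_bins
    p_edges = np.linspace(0.005, 0.995, n + 1)
    p_mid = 0.5 * (p_edges[:-1] + p_edges[1:])
    diam = np.exp(mu + sigma * stats.norm.ppf(p_mid))
    frac = np.full(n, 1.0 / n)
    bins = []
    for d_um, f in zip(diam, frac):
        radius = d_um / 2.0
        count = f * total_volume_um3 / _sphere_volume_um3(radius)
        bins.append(ParticleBin(radius=radius, count=count, initial_radius=radius))
    return bins


def bins_solid_mass(bins, radii_um, density: float) -> float:
    """Total solid mass (mg) of ``bins`` evaluated at radii ``radii_um``."""
    vol_um3 = sum(
        b.count * _sphere_volume_um3(max(a, 0.0)) for b, a in zip(bins, radii_um)
    )
    return vol_um3 * 1e-12 * density * 1000.0
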