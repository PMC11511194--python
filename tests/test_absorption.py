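"""GI physiology presets, permeability calibration, absorption simulation."""

import dataclasses

import numpy as np
import pytest

from pbbmkit.absorption import (
    PermeabilityInput,
    papp_to_peff,
    physiology_preset,
    simulate_gi_absorption,
)
from pbbmkit.particles import ParticleDistribution, discretize
from pbbmkit.solubility import SolubilityParameters, total_solubility
from pbbmkit.transfer import PrecipitationParameters


class TestPhysiologyPresets:
    def test_fasted_gastric_emptying_anchor(self):
        phys = physiology_preset("fasted")
        assert phys.gastric_emptying_half_life == 15.0
        assert phys.compartments[0].pH == 1.6

    def test_fed_preset_documented_differences(self):
        fasted = physiology_preset("fasted")
        fed = physiology_preset("fed")
        assert fed.gastric_emptying_half_life == 60.0
        assert fed.gastric_ph_initial == 5.0
        # fed gastric pH relaxes toward the fasted value
        assert fed.gastric_ph(0.0) == pytest.approx(5.0)
        assert fed.gastric_ph(60.0) == pytest.approx(1.6 + 3.4 / 2)
        si_fasted = [c.bile_salt for c in fasted.compartments if c.absorbing]
        si_fed = [c.bile_salt for c in fed.compartments if c.absorbing]
        assert set(si_fasted) == {3.0} and set(si_fed) == {15.0}
        # non-prandial fields coincide
        for cf, cd in zip(fasted.compartments[1:-1], fed.compartments[1:-1]):
            assert cf.radius == cd.radius and cf.mrt == cd.mrt

    def test_override_bile_to_zero_removes_solubilization(self, riva):
        phys = physiology_preset("fasted",
                                 {"jejunum1.bile_salt": 0.0})
        comp = [c for c in phys.compartments if c.name == "jejunum1"][0]
        assert comp.bile_salt == 0.0
        assert phys.provenance["jejunum1.bile_salt"] == "user override"

    def test_unknown_override_rejected(self):
        with pytest.raises(KeyError):
            physiology_preset("fasted", {"pancreas.volume": 10.0})
        with pytest.raises(KeyError):
            physiology_preset("fasted", {"stomach.color": "red"})


class TestPappToPeff:
    CAL = ((1e-6, 0.1), (1e-5, 1.0), (1e-4, 10.0))  # exact log-log line

    def test_exact_interpolation_on_a_line(self):
        cal = papp_to_peff(PermeabilityInput("pampa_fassif", 3e-5, self.CAL))
        assert cal.slope == pytest.approx(1.0, abs=1e-12)
        assert cal.r_squared == pytest.approx(1.0)
        assert cal.peff == pytest.approx(3.0, rel=1e-9)

    def test_identity_calibration(self):
        cal_set = ((1e-5, 1e-5), (1e-4, 1e-4), (1e-3, 1e-3))
        cal = papp_to_peff(PermeabilityInput("caco2", 5e-5, cal_set))
        assert cal.peff == pytest.approx(5e-5, rel=1e-9)

    def test_fassif_exceeds_fessif_for_measured_papp(self):
        fassif = papp_to_peff(PermeabilityInput("pampa_fassif", 9.02e-5, self.CAL))
        fessif = papp_to_peff(PermeabilityInput("pampa_fessif", 1.43e-5, self.CAL))
        assert fassif.peff > fessif.peff

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            PermeabilityInput("caco2", 1e-5, ((1e-6, 0.1), (1e-5, 1.0)))
        dec = papp_to_peff(PermeabilityInput(
            "caco2", 1e-5, ((1e-6, 1.0), (1e-5, 0.5), (1e-4, 0.2))))
        assert dec.nonmonotone_warning


def _mini_scenario(riva, n_bins=3, dose=5.0):
    dist = dataclasses.replace(riva.dist, n_bins=n_bins)
    return discretize(dist, dose, riva.drug.density)


class TestGIAbsorption:
    def test_zero_permeability_zero_fraction_absorbed(self, riva, fasted_physiology):
        res = simulate_gi_absorption(
            riva.drug, _mini_scenario(riva), riva.sol, riva.dis, riva.precip,
            fasted_physiology, peff=1e-9, duration_h=12.0)
        assert res.fa < 1e-6

    def test_unlimited_solubility_high_peff_complete_absorption(self, riva, fasted_physiology):
        sol = SolubilityParameters(s_o=10.0)  # effectively unlimited
        res = simulate_gi_absorption(
            riva.drug, _mini_scenario(riva), sol, riva.dis, riva.precip,
            fasted_physiology, peff=50.0, duration_h=24.0)
        assert res.fa > 0.99

    def test_mass_balance(self, riva_absorption):
        assert riva_absorption.mass_balance_error < 1e-6

    def test_fa_monotone_in_peff_and_solubility(self, riva, fasted_physiology):
        bins = _mini_scenario(riva)
        fas = [
            simulate_gi_absorption(riva.drug, bins, riva.sol, riva.dis,
                                   riva.precip, fasted_physiology,
                                   peff=p, duration_h=12.0).fa
            for p in (0.5, 2.0, 8.0)
        ]
        assert fas[0] < fas[1] < fas[2]
        sols = []
        for scale in (0.5, 1.0, 2.0):
            sol = dataclasses.replace(riva.sol, s_o=riva.sol.s_o * scale)
            sols.append(simulate_gi_absorption(
                riva.drug, bins, sol, riva.dis, riva.precip,
                fasted_physiology, peff=2.0, duration_h=12.0).fa)
        assert sols[0] < sols[1] < sols[2]

    def test_fa_decreases_with_particle_size(self, riva, fasted_physiology):
        fas = []
        for d50_scale in (1.0, 4.0):
            dist = ParticleDistribution(
                "lognormal", d10=riva.dist.d10 * d50_scale,
                d50=riva.dist.d50 * d50_scale, d90=riva.dist.d90 * d50_scale,
                n_bins=3)
            bins = discretize(dist, 5.0, riva.drug.density)
            fas.append(simulate_gi_absorption(
                riva.drug, bins, riva.sol, riva.dis, riva.precip,
                fasted_physiology, peff=2.0, duration_h=12.0).fa)
        assert fas[1] < fas[0]

    def test_minimal_precipitation_equals_disabled(self, riva, fasted_physiology):
        bins = _mini_scenario(riva)
        kwargs = dict(peff=riva.peff_for_state("fasted"), duration_h=12.0)
        minimal = simulate_gi_absorption(
            riva.drug, bins, riva.sol, riva.dis,
            PrecipitationParameters.minimal(), fasted_physiology, **kwargs)
        disabled = simulate_gi_absorption(
            riva.drug, bins, riva.sol, riva.dis,
            PrecipitationParameters(csc=1e9, prc=1e-4), fasted_physiology,
            **kwargs)
        assert abs(minimal.fa - disabled.fa) / disabled.fa < 1e-3
        assert np.abs(minimal.absorbed - disabled.absorbed).max() \
            < 1e-3 * disabled.absorbed[-1]

    def test_permeability_swap_orders_fed_vs_fasted(self, tica, fasted_physiology):
        # solubility effects off (same physiology); only Papp differs
        bins = discretize(dataclasses.replace(tica.dist, n_bins=3), 10.0,
                          tica.drug.density)
        fa_fassif = simulate_gi_absorption(
            tica.drug, bins, tica.sol, tica.dis, tica.precip,
            fasted_physiology, peff=tica.peff_for_state("fasted"),
            duration_h=12.0).fa
        fa_fessif = simulate_gi_absorption(
            tica.drug, bins, tica.sol, tica.dis, tica.precip,
            fasted_physiology, peff=tica.peff_for_state("fed"),
            duration_h=12.0).fa
        assert fa_fessif <= fa_fassif

    def test_agrees_with_independent_euler_integrator(self, riva, fasted_physiology):
        """One-bin scenario versus a brute-force explicit reimplementation."""
        from pbbmkit.dissolution import default_d_eff

        dist = ParticleDistribution("monodispersed", mean_diameter=5.0)
        bins = discretize(dist, 5.0, riva.drug.density)
        peff = 2.0
        res = simulate_gi_absorption(
            riva.drug, bins, riva.sol, riva.dis,
            PrecipitationParameters(csc=1e9, prc=1e-4),
            fasted_physiology, peff=peff, duration_h=6.0)

        # independent forward-Euler reimplementation of the model equations
        comps = fasted_physiology.compartments
        nc = len(comps)
        from pbbmkit.solubility import MediumSpec

        stot = np.array([
            total_solubility(riva.sol, riva.drug,
                             MediumSpec(name=c.medium_family, pH=c.pH,
                                        bile_salt=c.bile_salt, volume=c.volume))
            for c in comps
        ])
        k = np.array([1.0 / c.mrt for c in comps])
        vol = np.array([c.volume for c in comps])
        ka = np.array([2.0 * peff * 1e-4 / c.radius * 60.0 if c.absorbing else 0.0
                       for c in comps])
        d_eff = default_d_eff(riva.drug.mw)
        rho = riva.drug.density
        n0 = bins[0].count
        m_part = 5.0 / n0  # mg per particle initially
        counts = np.zeros(nc)
        counts[0] = n0
        solid = np.zeros(nc)
        solid[0] = 5.0
        diss = np.zeros(nc)
        absorbed = 0.0
        dt = 0.02  # min
        m_tap = 1e-5 * 5.0
        for _ in range(int(6.0 * 60.0 / dt)):
            with np.errstate(divide="ignore", invalid="ignore"):
                vol_um3 = np.where(counts > 0, solid / (rho * 1000.0) * 1e12 / counts, 0.0)
            a_um = np.cbrt(vol_um3 * 3.0 / (4.0 * np.pi))
            a_cm = a_um * 1e-4
            h_cm = np.minimum(a_um, 30.0) * 1e-4
            with np.errstate(divide="ignore", invalid="ignore"):
                geom = np.where(a_um > 1e-3, 4 * np.pi * a_cm * (a_cm + h_cm) / h_cm, 0.0)
            flux = counts * (d_eff * 60.0) * geom * (stot - diss / vol)
            flux *= solid**2 / (solid**2 + m_tap**2)
            flux = np.clip(flux, 0.0, None)
            dcounts = -k * counts
            dcounts[1:] += k[:-1] * counts[:-1]
            dsolid = -flux - k * solid
            dsolid[1:] += k[:-1] * solid[:-1]
            ddiss = flux - k * diss - ka * diss
            ddiss[1:] += k[:-1] * diss[:-1]
            absorbed += (ka * diss).sum() * dt
            counts += dcounts * dt
            solid += dsolid * dt
            diss += ddiss * dt
        fa_euler = absorbed / 5.0
        assert res.fa == pytest.approx(fa_euler, rel=0.005)
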