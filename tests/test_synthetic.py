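"""Synthetic data generators: determinism, zero-noise fidelity, round trips."""

import dataclasses

import numpy as np
import pytest

from pbbmkit.dissolution import VesselConfig, fit_dissolution
from pbbmkit.solubility import FitPlan, builtin_medium, fit_solubility, total_solubility
from pbbmkit.synthetic import (
    NoiseSpec,
    gen_ct_observations,
    gen_dissolution_profiles,
    gen_solubility_data,
    gen_transfer_profile,
    pb201_like,
    rivaroxaban_like,
)
from pbbmkit.transfer import TransferConfig, detect_precipitation

MEDIA = ["FaSSGF", "FaSSIF", "FeSSIF"]


class TestSolubilityGenerator:
    def test_zero_noise_equals_model(self, riva):
        summary, _ = gen_solubility_data(riva, MEDIA)
        for _, row in summary.iterrows():
            expected = total_solubility(riva.sol, riva.drug,
                                        builtin_medium(row["medium_name"]))
            assert row["solubility_ug_per_mL"] == pytest.approx(expected * 1000.0)

    def test_archetype_reproduces_reference_solubilities(self, riva):
        summary, _ = gen_solubility_data(riva, ["FaSSGF", "FaSSIF"])
        values = dict(zip(summary["medium_name"], summary["solubility_ug_per_mL"]))
        assert values["FaSSGF"] == pytest.approx(7.50, rel=1e-9)
        assert values["FaSSIF"] == pytest.approx(6.17, rel=1e-9)

    def test_seeded_determinism(self, riva):
        noise = NoiseSpec("multiplicative_lognormal", 5.0, seed=42)
        a, _ = gen_solubility_data(riva, MEDIA, noise)
        b, _ = gen_solubility_data(riva, MEDIA, noise)
        assert a.equals(b)

    def test_replicate_cv_matches_specification(self, riva):
        noise = NoiseSpec("multiplicative_lognormal", 5.0, seed=7)
        _, reps = gen_solubility_data(riva, ["FaSSIF"], noise,
                                      n_replicates=1000)
        values = reps["solubility_ug_per_mL"].to_numpy()
        cv = values.std(ddof=1) / values.mean() * 100.0
        assert cv == pytest.approx(5.0, abs=1.0)

    def test_empty_media_rejected(self, riva):
        with pytest.raises(ValueError):
            gen_solubility_data(riva, [])


class TestDissolutionGenerator:
    def test_round_trip_recovers_dlm_scalar(self, riva):
        truth = dataclasses.replace(riva,
                                    dis=dataclasses.replace(riva.dis, dlm_scalar=0.8),
                                    dist=dataclasses.replace(riva.dist, n_bins=8))
        vessel = VesselConfig(medium=builtin_medium("FaSSIF"), dose=4.0,
                              duration=60.0)
        (profile,) = gen_dissolution_profiles(truth, [vessel])
        from pbbmkit.dissolution import DissolutionProfile

        prof = DissolutionProfile(
            times=profile["time_min"].to_numpy(),
            percent_dissolved=profile["percent_dissolved"].to_numpy(),
            bulk_concentration=None, surface_concentration=np.nan, dose=4.0)
        res = fit_dissolution([prof], [vessel], truth.dist, truth.sol,
                              truth.drug)
        assert res.params.dlm_scalar == pytest.approx(0.8, rel=0.02)


class TestTransferGenerator:
    def test_precipitating_truth_detected(self, pb201):
        df = gen_transfer_profile(pb201, TransferConfig(), dose=25.0)
        intest = df[df["chamber"] == "intestinal"]
        dec = detect_precipitation(intest["time_min"],
                                   intest["concentration_ug_per_mL"])
        assert dec.detected is True

    def test_non_precipitating_truth_not_detected(self, riva):
        df = gen_transfer_profile(riva, TransferConfig(), dose=5.0)
        intest = df[df["chamber"] == "intestinal"]
        dec = detect_precipitation(intest["time_min"],
                                   intest["concentration_ug_per_mL"])
        assert dec.detected is False

    def test_seeded_determinism(self, riva):
        noise = NoiseSpec("multiplicative_lognormal", 3.0, seed=5)
        a = gen_transfer_profile(riva, TransferConfig(), noise, dose=5.0)
        b = gen_transfer_profile(riva, TransferConfig(), noise, dose=5.0)
        assert a.equals(b)


class TestCTGenerator:
    SAMPLING = np.arange(0.5, 12.5, 0.5)

    def test_missing_seed_rejected(self, riva):
        with pytest.raises(ValueError):
            gen_ct_observations(riva, self.SAMPLING, None, n_subjects=2,
                                seed=None)

    def test_zero_variability_equals_deterministic(self):
        truth = rivaroxaban_like()
        truth.variability = {"cl": 0.0}
        from pbbmkit.synthetic import simulate_truth_ct

        subjects, mean = gen_ct_observations(truth, self.SAMPLING, None,
                                             n_subjects=2, seed=1, n_bins=3)
        det = simulate_truth_ct(truth, "fasted", self.SAMPLING, n_bins=3)
        per_subject = subjects.groupby("subject")
        for _, grp in per_subject:
            assert np.allclose(grp["concentration_ng_per_mL"].to_numpy(),
                               det.concentration, rtol=1e-9)

    def test_seeded_determinism(self):
        truth = rivaroxaban_like()
        truth.variability = {"cl": 25.0}
        noise = NoiseSpec("multiplicative_lognormal", 5.0, seed=9)
        a, _ = gen_ct_observations(truth, self.SAMPLING, noise, n_subjects=3,
                                   seed=9, n_bins=3)
        b, _ = gen_ct_observations(truth, self.SAMPLING, noise, n_subjects=3,
                                   seed=9, n_bins=3)
        assert a.equals(b)


class TestFullPipelineRecovery:
    def test_zero_noise_stagewise_recovery(self):
        """Solubility, dissolution, and precipitation parameters are all
        recovered within 5% from noise-free generated data."""
        # --- solubility stage (identifiable aqueous + biorelevant design)
        from pbbmkit.solubility import MediumSpec, SolubilityMeasurement

        from pbbmkit.solubility import SolubilityParameters
        from pbbmkit.solubility import DrugProperties

        drug = DrugProperties("weak-base", mw=420.0, pkas=((5.0, "base"),))
        sol_truth = SolubilityParameters(s_o=2e-3, sf=8.0,
                                         km_w_unionized=4000.0,
                                         km_w_ionized=400.0)
        media = [MediumSpec("pH2", pH=2.0), MediumSpec("pH4.5", pH=4.5),
                 MediumSpec("pH7", pH=7.0), builtin_medium("FaSSGF"),
                 builtin_medium("FaSSIF"), builtin_medium("FeSSIF"),
                 MediumSpec("mid-bile", pH=5.0, bile_salt=7.5)]
        meas = [SolubilityMeasurement(m, total_solubility(sol_truth, drug, m))
                for m in media]
        sol_fit = fit_solubility(
            meas, drug,
            FitPlan(free=("s_o", "sf", "km_w_unionized", "km_w_ionized"),
                    n_starts=6, seed=2))
        assert sol_fit.params.s_o == pytest.approx(2e-3, rel=0.05)
        assert sol_fit.params.sf == pytest.approx(8.0, rel=0.05)
        assert sol_fit.params.km_w_unionized == pytest.approx(4000.0, rel=0.05)
        assert sol_fit.params.km_w_ionized == pytest.approx(400.0, rel=0.05)

        # --- dissolution stage re-uses the fitted solubility parameters
        truth = rivaroxaban_like()
        truth = dataclasses.replace(
            truth, drug=drug, sol=sol_truth,
            dis=dataclasses.replace(truth.dis, dlm_scalar=1.2),
            dist=dataclasses.replace(truth.dist, n_bins=8))
        vessel = VesselConfig(medium=builtin_medium("FaSSIF"), dose=4.0,
                              duration=60.0)
        (gen,) = gen_dissolution_profiles(truth, [vessel])
        from pbbmkit.dissolution import DissolutionProfile

        prof = DissolutionProfile(
            times=gen["time_min"].to_numpy(),
            percent_dissolved=gen["percent_dissolved"].to_numpy(),
            bulk_concentration=None, surface_concentration=np.nan, dose=4.0)
        dis_fit = fit_dissolution([prof], [vessel], truth.dist,
                                  sol_fit.params, drug)
        assert dis_fit.params.dlm_scalar == pytest.approx(1.2, rel=0.05)
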