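"""PK simulation: random-effect layers, ODE model, residual error, full trial."""

import numpy as np
import pandas as pd
import pytest

from rifpk import nca
from rifpk.config import default_config
from rifpk.pipeline import simulate_stage
from rifpk.pk_model import (
    DoseRegimen,
    IndividualParams,
    StructuralParams,
    VariabilityParams,
    apply_ruv,
    bioavailability,
    draw_random_effects,
    individualize,
    simulate_profile,
    simulate_trial,
)
from rifpk.trial_design import ConfigurationError


def one_compartment_oral(t, dose, f, ka, ke, v):
    """Closed-form linear one-compartment oral solution (single dose)."""
    t = np.asarray(t, dtype=float)
    return f * dose * ka / (v * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))


def linear_params(ka=1.2, v=87.2, ke=0.12, km=1e6):
    """Parameters in the linear limit: KM far above any concentration, no
    induction. The Michaelis-Menten linearization error is ~C_max/KM, so KM is
    set orders of magnitude above C_max to probe the solver itself."""
    return IndividualParams(
        subject_id=1, occasion=1, ka=ka, v=v, vmax=ke * km * v, km=km,
        kenz=0.01, emax_ind=0.0, ec50_ind=0.07, f=1.0)


class TestRandomEffects:
    def test_degenerate_variances_give_zeros(self):
        var = VariabilityParams(iiv={"ka": 0.0, "v": 0.0}, iov={"ka": 0.0},
                                ruv_prop_sd=0.1)
        eta, kappa = draw_random_effects(var, 50, 2, seed=1)
        assert (eta.to_numpy() == 0).all()
        assert (kappa["ka"] == 0).all()

    def test_sample_variance_matches_configured(self):
        var = VariabilityParams(iiv={"v": 0.09}, iov={}, ruv_prop_sd=0.1)
        eta, _ = draw_random_effects(var, 100_000, 2, seed=2)
        s2 = eta["v"].var(ddof=1)
        se = 0.09 * np.sqrt(2.0 / (100_000 - 1))  # SE of a normal sample variance
        assert abs(s2 - 0.09) < 3 * se

    def test_determinism(self):
        var = VariabilityParams()
        a = draw_random_effects(var, 100, 2, seed=3)
        b = draw_random_effects(var, 100, 2, seed=3)
        pd.testing.assert_frame_equal(a[0], b[0])
        for p in a[1]:
            np.testing.assert_array_equal(a[1][p], b[1][p])

    def test_negative_variance_rejected(self):
        with pytest.raises(ConfigurationError, match="ka"):
            VariabilityParams(iiv={"ka": -0.1}).validate()


class TestIndividualize:
    def _subject(self, ffm, dose=450.0):
        return pd.Series({"ID": 1, "FFM": ffm, "DOSE": dose})

    def test_identity_at_reference(self):
        pop = StructuralParams()
        ind = individualize(pop, self._subject(pop.ffm_ref), {}, {}, occasion=1)
        assert ind.ka == pytest.approx(pop.ka)
        assert ind.v == pytest.approx(pop.v)
        assert ind.vmax == pytest.approx(pop.vmax)
        assert ind.f == pytest.approx(pop.f_ref)  # reference dose

    def test_log_normal_construction(self):
        pop = StructuralParams()
        ind = individualize(pop, self._subject(pop.ffm_ref),
                            {"v": np.log(2.0)}, {}, occasion=1)
        assert ind.v == pytest.approx(2.0 * pop.v)

    def test_allometric_linear_limit(self):
        pop = StructuralParams(ffm_exponents={"v": 1.0})
        ind = individualize(pop, self._subject(2.0 * pop.ffm_ref), {}, {}, 1)
        assert ind.v == pytest.approx(2.0 * pop.v)

    def test_missing_ffm_rejected(self):
        with pytest.raises(ValueError, match="FFM"):
            individualize(StructuralParams(),
                          pd.Series({"ID": 1, "FFM": np.nan, "DOSE": 450.0}),
                          {}, {}, 1)

    def test_bioavailability_monotone_in_dose(self):
        pop = StructuralParams()
        doses = np.arange(450.0, 2701.0, 150.0)
        f = [bioavailability(pop, d) for d in doses]
        assert np.all(np.diff(f) >= 0)
        assert 0 < min(f) and max(f) <= 1.5


class TestSimulateProfile:
    def test_zero_dose_gives_zero_concentration(self):
        conc = simulate_profile(linear_params(), DoseRegimen(0.0, n_doses=3),
                                [1.0, 25.0, 49.0])
        np.testing.assert_array_equal(conc, 0.0)

    def test_linear_limit_matches_closed_form(self):
        ind = linear_params()
        times = np.array([0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0])
        conc = simulate_profile(ind, DoseRegimen(1200.0, n_doses=1), times)
        ke = ind.vmax / (ind.km * ind.v)
        expected = one_compartment_oral(times, 1200.0, ind.f, ind.ka, ke, ind.v)
        np.testing.assert_allclose(conc, expected, rtol=1e-4)

    def test_linear_limit_auc_inf_is_fd_km_over_vmax(self):
        ind = linear_params(ke=0.25)
        # integrate the solver output far beyond 7 half-lives
        times = np.unique(np.concatenate([
            np.linspace(0.0, 24.0, 200), np.geomspace(24.0, 72.0, 60)]))
        regimen = DoseRegimen(1200.0, n_doses=1, interval_h=72.0)
        conc = simulate_profile(ind, regimen, times[times > 0])
        auc = np.trapezoid(np.concatenate([[0.0], conc]), times)
        expected = ind.f * 1200.0 * ind.km / ind.vmax  # F*D/CL, CL = VMAX/KM
        assert auc == pytest.approx(expected, rel=5e-3)

    def test_nonnegative_everywhere(self):
        conc = simulate_profile(
            IndividualParams(1, 1, ka=1.7, v=87.2, vmax=175.0, km=35.0,
                             kenz=0.0132, emax_ind=1.16, ec50_ind=0.07, f=1.4),
            DoseRegimen(2700.0, n_doses=14), np.linspace(0.5, 336.0, 200))
        assert (conc >= 0).all()


class TestResidualError:
    def test_zero_sds_identity(self):
        var = VariabilityParams(ruv_prop_sd=0.0, ruv_add_sd=0.0)
        dv = apply_ruv([0.0, 1.0, 10.0], var, seed=1)
        np.testing.assert_array_equal(dv, [0.0, 1.0, 10.0])

    def test_floor_at_zero(self):
        var = VariabilityParams(ruv_prop_sd=0.0, ruv_add_sd=5.0)
        dv = apply_ruv(np.zeros(10_000), var, seed=2)
        assert (dv >= 0).all()
        assert (dv == 0).any()  # truncation active

    def test_proportional_cv_recovered(self):
        var = VariabilityParams(ruv_prop_sd=0.1, ruv_add_sd=0.0)
        dv = apply_ruv(np.full(100_000, 10.0), var, seed=3)
        cv = dv.std() / dv.mean()
        assert cv == pytest.approx(0.10, abs=0.002)


def _novar(prop=0.1):
    return VariabilityParams(iiv={}, iov={}, ruv_prop_sd=prop, ruv_add_sd=0.0)


class TestSimulateTrial:
    def test_row_counts_small_design(self, small_run):
        design, sim = small_run
        assert len(sim.observations) == 264
        assert len(sim.rich) == 480
        assert sim.observations.groupby(["ID", "OCC"]).size().eq(11).all()
        assert sim.rich.groupby(["ID", "OCC"]).size().eq(20).all()

    def test_reproducibility(self, small_cfg):
        a = simulate_stage(small_cfg)[1]
        b = simulate_stage(small_cfg)[1]
        pd.testing.assert_frame_equal(a.observations, b.observations)
        pd.testing.assert_frame_equal(a.rich, b.rich)

    def test_nonnegativity(self, small_run):
        _, sim = small_run
        assert (sim.observations[["DV_TRUE", "DV"]] >= 0).all().all()
        assert (sim.rich[["DV_TRUE", "DV"]] >= 0).all().all()

    def _deterministic_sim(self, n=4):
        cfg = default_config(13).model_copy(deep=True)
        cfg.design.n_subjects = n
        cfg.model.iiv = {}
        cfg.model.iov = {}
        return simulate_stage(cfg)

    def test_predose_sample_is_preceding_trough(self):
        """TAD=0 matches an independent constant-parameter integration of the
        whole regimen evaluated just before the occasion's dose."""
        design, sim = self._deterministic_sim(n=2)
        pars = sim.individual_params
        for sid in design.subjects["ID"]:
            row = pars[(pars["ID"] == sid) & (pars["OCC"] == 1)].iloc[0]
            ind = IndividualParams(
                subject_id=sid, occasion=1, ka=row["KA"], v=row["V"],
                vmax=row["VMAX"], km=row["KM"], kenz=row["KENZ"],
                emax_ind=1.16, ec50_ind=0.07, f=row["F"])
            dose = float(design.subjects.set_index("ID").loc[sid, "DOSE"])
            ref = simulate_profile(ind, DoseRegimen(dose, n_doses=14), [144.0])
            obs = sim.observations
            got = obs[(obs["ID"] == sid) & (obs["OCC"] == 1)
                      & (obs["TAD"] == 0.0)]["DV_TRUE"].iloc[0]
            assert got == pytest.approx(ref[0], rel=1e-6)
            assert got > 0  # a true trough, not an artificial zero

    def test_autoinduction_lowers_day14_exposure(self):
        _, sim = self._deterministic_sim(n=6)
        aucs = nca.derive_aucs(sim)
        piv = aucs.pivot(index="ID", columns="OCC", values="AUC0_24")
        assert (piv[2] <= piv[1]).all()

    def test_auc_nondecreasing_in_dose(self):
        cfg = default_config(17).model_copy(deep=True)
        cfg.design.n_subjects = 6
        cfg.model.iiv = {}
        cfg.model.iov = {}
        design, sim = simulate_stage(cfg)
        # same covariates for everyone, ascending doses
        subjects = design.subjects.copy()
        for col in ("WT", "FFM", "HT", "AGE", "SEX", "HIV", "RACE", "BMI"):
            subjects[col] = subjects[col].iloc[0]
        subjects["DOSE"] = [450.0, 900.0, 1350.0, 1800.0, 2250.0, 2700.0]
        from rifpk.trial_design import build_design
        design2 = build_design(subjects)
        sim2 = simulate_trial(design2, StructuralParams(), _novar(), seed=1)
        aucs = nca.derive_aucs(sim2).pivot(index="ID", columns="OCC",
                                           values="AUC0_24")
        for occ in (1, 2):
            assert (np.diff(aucs[occ].to_numpy()) >= 0).all()
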