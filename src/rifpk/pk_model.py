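"""Nonlinear mixed-effects simulation of rifampicin plasma concentrations.

Structural model: one-compartment disposition with first-order oral
absorption, Michaelis-Menten (saturable) elimination, autoinduction of
elimination through a hypothetical enzyme-turnover compartment, and
dose-dependent bioavailability:

    dAg/dt  = -ka * Ag
    dAc/dt  =  ka * Ag - ENZ * VMAX * C / (KM + C),     C = Ac / V
    dENZ/dt =  kENZ * (1 + EMAX_ind * C / (EC50_ind + C)) - kENZ * ENZ

with ENZ(0) = 1 (baseline enzyme pool, production stimulated by drug
concentration) and each once-daily dose entering the gut compartment as a
bolus of F(dose) * dose. Central volume and VMAX scale allometrically with
fat-free mass. Random effects: log-normal inter-individual variability (IIV,
eta) and inter-occasion variability (IOV, kappa) on configured parameters,
plus combined proportional + additive residual error truncated at zero.

Default parameter values are documented calibration defaults patterned on
the published rifampicin autoinduction model class; every value is
configuration, not code (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .trial_design import TrialDesign, ConfigurationError

__all__ = [
    "StructuralParams",
    "VariabilityParams",
    "IndividualParams",
    "SimulationResult",
    "RICH_TIMES_H",
    "DEFAULT_SOLVER_OPTS",
    "draw_random_effects",
    "individualize",
    "bioavailability",
    "simulate_profile",
    "apply_ruv",
    "simulate_trial",
]

# 20-point rich grid per occasion spanning absorption and elimination phases.
RICH_TIMES_H = (0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0,
                5.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0, 18.0, 21.0, 24.0)

DEFAULT_SOLVER_OPTS = {"method": "LSODA", "rtol": 1e-8, "atol": 1e-10}


@dataclass(frozen=True)
class StructuralParams:
    """Population (typical-value) structural parameters."""

    ka: float = 1.7            # 1/h, first-order absorption
    v: float = 87.2            # L, central volume at reference FFM
    vmax: float = 175.0        # mg/h, maximal elimination at baseline enzyme
    km: float = 35.0           # mg/L, Michaelis constant
    kenz: float = 0.0132       # 1/h, enzyme-pool turnover (t1/2 ~ 2.2 days)
    emax_ind: float = 1.16     # max fold-stimulation of enzyme production
    ec50_ind: float = 0.07     # mg/L, concentration of half-max stimulation
    f_ref: float = 1.0         # relative bioavailability at the reference dose
    f_emax: float = 0.5        # max fractional F increase above the reference
    f_ed50: float = 67.0       # mg above reference dose giving half-max increase
    f_dose_ref: float = 450.0  # mg, reference dose of the F sub-model
    ffm_ref: float = 45.0      # kg, reference fat-free mass
    ffm_exponents: dict = field(
        default_factory=lambda: {"v": 1.0, "vmax": 0.75})

    def validate(self) -> None:
        for name in ("ka", "v", "vmax", "km", "kenz", "ec50_ind",
                     "f_ref", "f_ed50", "f_dose_ref", "ffm_ref"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"structural parameter {name} must be > 0")
        if self.emax_ind < 0 or self.f_emax < 0:
            raise ConfigurationError("Emax-type parameters must be >= 0")
        if self.f_ref * (1.0 + self.f_emax) > 1.5:
            raise ConfigurationError("F(dose) must stay within (0, 1.5]")


@dataclass(frozen=True)
class VariabilityParams:
    """Log-scale variances of the random-effect layers and residual-error SDs."""

    iiv: dict = field(default_factory=lambda: {"ka": 0.09, "v": 0.02, "vmax": 0.04})
    iov: dict = field(default_factory=lambda: {"ka": 0.04, "f": 0.02})
    ruv_prop_sd: float = 0.10  # fraction
    ruv_add_sd: float = 0.05   # mg/L

    def validate(self, require_ruv: bool = True) -> None:
        for layer_name, layer in (("IIV", self.iiv), ("IOV", self.iov)):
            for pname, var in layer.items():
                if var < 0:
                    raise ConfigurationError(
                        f"{layer_name} variance for {pname} must be >= 0")
        if self.ruv_prop_sd < 0 or self.ruv_add_sd < 0:
            raise ConfigurationError("residual-error SDs must be >= 0")
        if require_ruv and self.ruv_prop_sd == 0 and self.ruv_add_sd == 0:
            raise ConfigurationError(
                "at least one of proportional/additive residual error must be > 0")


@dataclass(frozen=True)
class IndividualParams:
    """Realized parameters for one subject-occasion."""

    subject_id: int
    occasion: int
    ka: float
    v: float
    vmax: float
    km: float
    kenz: float
    emax_ind: float
    ec50_ind: float
    f: float  # realized bioavailability fraction applied to each dose

    def validate(self) -> None:
        for name in ("ka", "v", "vmax", "km", "kenz", "ec50_ind", "f"):
            if getattr(self, name) <= 0:
                raise ValueError(f"realized parameter {name} must be > 0")


@dataclass(frozen=True)
class DoseRegimen:
    """Once-daily repeated oral dosing."""

    dose_mg: float
    n_doses: int = 14
    interval_h: float = 24.0


@dataclass(frozen=True)
class SimulationResult:
    observations: pd.DataFrame  # nominal-schedule rows, with RUV
    rich: pd.DataFrame          # 20-point rich grid per occasion, error-free DV_TRUE
    individual_params: pd.DataFrame
    seed: int


def draw_random_effects(var: VariabilityParams, n_subjects: int,
                        n_occasions: int, seed: int):
    """Draw eta (IIV, per subject) and kappa (IOV, per subject-occasion).

    Returns ``(eta, kappa)``: eta is a DataFrame (one row per subject, one
    column per IIV parameter); kappa is a dict parameter -> array of shape
    (n_subjects, n_occasions).
    """
    var.validate()
    rng = np.random.default_rng(seed)
    eta = pd.DataFrame(
        {p: rng.normal(0.0, np.sqrt(w2), size=n_subjects)
         for p, w2 in sorted(var.iiv.items())},
        index=np.arange(n_subjects))
    kappa = {p: rng.normal(0.0, np.sqrt(p2), size=(n_subjects, n_occasions))
             for p, p2 in sorted(var.iov.items())}
    return eta, kappa


def bioavailability(pop: StructuralParams, dose_mg: float) -> float:
    """Structural F(dose): saturable increase above the reference dose."""
    excess = max(dose_mg - pop.f_dose_ref, 0.0)
    return pop.f_ref * (1.0 + pop.f_emax * excess / (pop.f_ed50 + excess))


def individualize(pop: StructuralParams, subject: pd.Series,
                  eta: dict | pd.Series, kappa: dict | pd.Series,
                  occasion: int) -> IndividualParams:
    """Realize one subject-occasion's parameters.

    Each parameter is population value x FFM-scaling factor (where
    configured) x exp(eta + kappa); bioavailability additionally carries the
    structural dose dependence.
    """
    ffm = subject.get("FFM", np.nan)
    if not np.isfinite(ffm):
        raise ValueError(f"subject {subject.get('ID')} is missing FFM")

    def effect(name: str) -> float:
        return float(np.exp(dict(eta).get(name, 0.0) + dict(kappa).get(name, 0.0)))

    def scale(name: str) -> float:
        exp = pop.ffm_exponents.get(name, 0.0)
        return float((ffm / pop.ffm_ref) ** exp)

    ind = IndividualParams(
        subject_id=int(subject["ID"]), occasion=occasion,
        ka=pop.ka * scale("ka") * effect("ka"),
        v=pop.v * scale("v") * effect("v"),
        vmax=pop.vmax * scale("vmax") * effect("vmax"),
        km=pop.km, kenz=pop.kenz,
        emax_ind=pop.emax_ind, ec50_ind=pop.ec50_ind,
        f=bioavailability(pop, float(subject["DOSE"])) * effect("f"),
    )
    ind.validate()
    return ind


def _rhs(t, y, p: IndividualParams):
    ag, ac, enz = y
    c = max(ac, 0.0) / p.v
    elim = enz * p.vmax * c / (p.km + c)
    stim = 1.0 + p.emax_ind * c / (p.ec50_ind + c)
    return (-p.ka * ag,
            p.ka * ag - elim,
            p.kenz * stim - p.kenz * enz)


def _integrate_intervals(params_by_interval, dose_mg, interval_h,
                         eval_times, solver_opts):
    """Piecewise integration over dosing intervals with a gut bolus at each start.

    ``eval_times`` exactly at a dose time are evaluated *before* that dose's
    bolus, i.e. they are the trough of the preceding interval. Returns
    concentrations (mg/L) aligned with ``eval_times``.
    """
    opts = dict(DEFAULT_SOLVER_OPTS)
    opts.update(solver_opts or {})
    eval_times = np.asarray(eval_times, dtype=float)
    out = np.full(eval_times.shape, np.nan)
    out[eval_times == 0.0] = 0.0  # before any drug
    y = np.array([0.0, 0.0, 1.0])
    n = len(params_by_interval)
    for s, p in enumerate(params_by_interval):
        t0, t1 = s * interval_h, (s + 1) * interval_h
        y = y.copy()
        y[0] += p.f * dose_mg
        sel = (eval_times > t0) & (eval_times <= t1)
        ts = np.unique(np.concatenate([eval_times[sel], [t1]]))
        sol = solve_ivp(_rhs, (t0, t1), y, t_eval=ts, args=(p,), **opts)
        if not sol.success:
            raise RuntimeError(
                f"ODE solver failed in interval {s}: {sol.message}; params={p}")
        if sel.any():
            conc = np.maximum(sol.y[1], 0.0) / p.v
            lookup = dict(zip(sol.t, conc))
            out[sel] = [lookup[t] for t in eval_times[sel]]
        y = sol.y[:, -1]
    if np.isnan(out).any():
        bad = eval_times[np.isnan(out)]
        raise ValueError(f"evaluation times outside the dosing horizon: {bad}")
    return out


def simulate_profile(ind: IndividualParams, regimen: DoseRegimen,
                     eval_times, solver_opts: dict | None = None) -> np.ndarray:
    """Error-free concentration series for one parameter set under a regimen."""
    ind.validate()
    if regimen.dose_mg == 0.0:
        return np.zeros(len(np.asarray(eval_times)))
    return _integrate_intervals([ind] * regimen.n_doses, regimen.dose_mg,
                                regimen.interval_h, eval_times, solver_opts)


def apply_ruv(dv_true, var: VariabilityParams, seed: int) -> np.ndarray:
    """Perturb with combined proportional + additive error, truncated at 0 mg/L."""
    var.validate(require_ruv=False)
    rng = np.random.default_rng(seed)
    dv_true = np.asarray(dv_true, dtype=float)
    eps_p = rng.normal(0.0, var.ruv_prop_sd, size=dv_true.shape)
    eps_a = rng.normal(0.0, var.ruv_add_sd, size=dv_true.shape)
    return np.maximum(dv_true * (1.0 + eps_p) + eps_a, 0.0)


def simulate_trial(design: TrialDesign, pop: StructuralParams,
                   var: VariabilityParams, seed: int,
                   rich_times_h=RICH_TIMES_H,
                   solver_opts: dict | None = None) -> SimulationResult:
    """Simulate the full trial: all subjects, both occasions, both grids.

    IOV is re-drawn per occasion; occasion 1 parameters govern treatment week
    1 (dosing days 1-7), occasion 2 week 2. The nominal-schedule table gets
    residual error applied; the rich table keeps error-free concentrations for
    downstream noncompartmental analysis (configurable there).
    """
    pop.validate()
    var.validate()
    subjects = design.subjects
    n = len(subjects)
    occ_ids = sorted(design.occasion_days)
    eta, kappa = draw_random_effects(var, n, len(occ_ids), seed)

    # per-occasion dose-time index: occasion day d means the dose given at
    # t = (d-1)*24 h, sampled over the following 24 h
    dose_idx = {occ: (design.occasion_days[occ] - 1) for occ in occ_ids}
    # week boundary: intervals before the occasion-2 week use occasion-1 IOV
    switch_interval = dose_idx[occ_ids[-1]] - 6 if len(occ_ids) > 1 else design.n_days

    obs_rows, rich_rows, par_rows = [], [], []
    for i, (_, subj) in enumerate(subjects.iterrows()):
        dose = float(subj["DOSE"])
        inds = {}
        for j, occ in enumerate(occ_ids):
            ind = individualize(
                pop, subj, eta.iloc[i],
                {p: k[i, j] for p, k in kappa.items()}, occ)
            inds[occ] = ind
            par_rows.append({"ID": ind.subject_id, "OCC": occ, "KA": ind.ka,
                             "V": ind.v, "VMAX": ind.vmax, "KM": ind.km,
                             "KENZ": ind.kenz, "F": ind.f})
        params_by_interval = [
            inds[occ_ids[0]] if s < switch_interval else inds[occ_ids[-1]]
            for s in range(design.n_days)]

        eval_map = []  # (occ, tad, abs_time, grid)
        for occ in occ_ids:
            t_dose = dose_idx[occ] * 24.0
            for tad in design.nominal_times_h:
                eval_map.append((occ, tad, t_dose + tad, "obs"))
            for tad in rich_times_h:
                eval_map.append((occ, tad, t_dose + tad, "rich"))
        abs_times = np.array([m[2] for m in eval_map])
        order = np.argsort(abs_times, kind="stable")
        conc = np.empty(len(abs_times))
        conc[order] = _integrate_intervals(
            params_by_interval, dose, 24.0, abs_times[order], solver_opts)

        for (occ, tad, t_abs, grid), c in zip(eval_map, conc):
            row = {"ID": int(subj["ID"]), "OCC": occ, "TAD": tad,
                   "TIME": t_abs, "DOSE": dose, "DV_TRUE": c}
            (obs_rows if grid == "obs" else rich_rows).append(row)

    obs = pd.DataFrame(obs_rows)
    rich = pd.DataFrame(rich_rows)
    obs["DV"] = apply_ruv(obs["DV_TRUE"].to_numpy(), var,
                          np.random.SeedSequence([seed, 1]).generate_state(1)[0])
    rich["DV"] = apply_ruv(rich["DV_TRUE"].to_numpy(), var,
                           np.random.SeedSequence([seed, 2]).generate_state(1)[0])
    covars = subjects[["ID", "WT", "FFM", "HT", "AGE", "SEX", "HIV", "RACE", "BMI"]]
    obs = obs.merge(covars, on="ID", how="left")
    return SimulationResult(observations=obs, rich=rich,
                            individual_params=pd.DataFrame(par_rows), seed=seed)
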