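"""Virtual phase-2 trial population and dosing/sampling design.

Generates the study population for a once-daily oral rifampicin dose-ranging
trial: 83 subjects with correlated covariates (bodyweight, fat-free mass,
height, age, sex, HIV co-infection, race), weight-based doses of 10-40 mg/kg
rounded to the 150-mg tablet strength, and a two-occasion (treatment days 7
and 14) sampling schedule of 11 nominal times after dose.

Covariates are sampled parametrically: continuous covariates from truncated
normal distributions, binary covariates from Bernoulli distributions, and
(WT, FFM) jointly from a sex-conditional correlated bivariate truncated
normal so that the known WT-FFM-sex dependence is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TruncatedNormal",
    "SexConditionalBody",
    "CovariateDistribution",
    "TrialDesign",
    "DesignError",
    "ConfigurationError",
    "DOSE_GROUPS_MG_KG",
    "PRINTED_DOSES_MG",
    "PRINTED_DOSE_COUNTS",
    "NOMINAL_TIMES_H",
    "OCCASION_DAYS",
    "sample_covariates",
    "compute_bmi",
    "round_to_150",
    "assign_doses",
    "build_design",
]


class ConfigurationError(ValueError):
    """Invalid distribution or design configuration."""


class DesignError(ValueError):
    """Trial-design construction failure."""


DOSE_GROUPS_MG_KG = (10, 20, 25, 30, 35, 40)

# Realized mg-dose allocation of the emulated phase-2 trial: 14 dose levels
# assigned to 83 subjects in total.
PRINTED_DOSES_MG = (450, 600, 900, 1050, 1200, 1350, 1500, 1650,
                    1800, 1950, 2250, 2400, 2550, 2700)
PRINTED_DOSE_COUNTS = (8, 9, 1, 7, 8, 3, 17, 2, 13, 5, 3, 4, 1, 2)

NOMINAL_TIMES_H = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0)
OCCASION_DAYS = {1: 7, 2: 14}

SUBJECT_COLUMNS = ["ID", "WT", "FFM", "HT", "AGE", "SEX", "HIV", "RACE",
                   "BMI", "DOSEGRP", "DOSE"]


@dataclass(frozen=True)
class TruncatedNormal:
    """Truncated normal marginal: mean/SD on the untruncated scale, hard bounds."""

    mean: float
    sd: float
    lower: float
    upper: float

    def validate(self, name: str) -> None:
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ConfigurationError(f"{name}: truncation bounds must be finite")
        if not self.lower < self.upper:
            raise ConfigurationError(f"{name}: lower bound must be < upper bound")
        if self.sd < 0:
            raise ConfigurationError(f"{name}: SD must be >= 0")
        if self.sd == 0 and not (self.lower <= self.mean <= self.upper):
            raise ConfigurationError(f"{name}: degenerate mean outside bounds")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, float(self.mean))
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                                   size=n, random_state=rng)


@dataclass(frozen=True)
class SexConditionalBody:
    """Joint (WT, FFM) model for one sex: correlated bivariate truncated normal."""

    wt: TruncatedNormal
    ffm: TruncatedNormal
    corr: float

    def validate(self, name: str) -> None:
        self.wt.validate(f"{name}.WT")
        self.ffm.validate(f"{name}.FFM")
        if not -1.0 < self.corr < 1.0:
            raise ConfigurationError(
                f"{name}: WT-FFM correlation must lie in (-1, 1) for a "
                "positive-definite structure")

    def sample(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Rejection sampling inside the truncation box with FFM < WT enforced."""
        if self.wt.sd == 0 and self.ffm.sd == 0:
            return np.full(n, self.wt.mean), np.full(n, self.ffm.mean)
        cov = np.array([[self.wt.sd**2, self.corr * self.wt.sd * self.ffm.sd],
                        [self.corr * self.wt.sd * self.ffm.sd, self.ffm.sd**2]])
        mean = np.array([self.wt.mean, self.ffm.mean])
        out_wt = np.empty(n)
        out_ffm = np.empty(n)
        filled = 0
        for _ in range(1000):
            draw = rng.multivariate_normal(mean, cov, size=max(2 * (n - filled), 16),
                                           method="cholesky")
            ok = ((draw[:, 0] >= self.wt.lower) & (draw[:, 0] <= self.wt.upper)
                  & (draw[:, 1] >= self.ffm.lower) & (draw[:, 1] <= self.ffm.upper)
                  & (draw[:, 1] < draw[:, 0]))
            keep = draw[ok]
            take = min(len(keep), n - filled)
            out_wt[filled:filled + take] = keep[:take, 0]
            out_ffm[filled:filled + take] = keep[:take, 1]
            filled += take
            if filled == n:
                return out_wt, out_ffm
        raise ConfigurationError(
            "WT/FFM rejection sampling failed to fill the requested sample; "
            "truncation box too small for the configured distribution")


@dataclass(frozen=True)
class CovariateDistribution:
    """Parametric covariate distribution of the emulated trial population.

    Defaults describe an adult, predominantly male and African, tuberculosis
    phase-2 population; every value is overridable through configuration.
    """

    ht: TruncatedNormal = TruncatedNormal(166.0, 8.0, 145.0, 190.0)
    age: TruncatedNormal = TruncatedNormal(34.0, 11.0, 18.0, 65.0)
    p_male: float = 0.6
    p_hiv: float = 0.2
    p_race_other: float = 0.1
    body_male: SexConditionalBody = SexConditionalBody(
        wt=TruncatedNormal(56.0, 8.0, 38.0, 90.0),
        ffm=TruncatedNormal(46.0, 5.5, 30.0, 70.0),
        corr=0.9,
    )
    body_female: SexConditionalBody = SexConditionalBody(
        wt=TruncatedNormal(52.0, 9.0, 35.0, 90.0),
        ffm=TruncatedNormal(36.0, 4.5, 25.0, 60.0),
        corr=0.9,
    )

    def validate(self) -> None:
        self.ht.validate("HT")
        self.age.validate("AGE")
        for pname, p in (("SEX", self.p_male), ("HIV", self.p_hiv),
                         ("RACE", self.p_race_other)):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{pname}: probability must be in [0, 1]")
        self.body_male.validate("male body")
        self.body_female.validate("female body")


def compute_bmi(wt_kg: float, ht_cm: float) -> float:
    """Body mass index WT/(HT/100)^2 in kg/m^2."""
    wt = np.asarray(wt_kg, dtype=float)
    ht = np.asarray(ht_cm, dtype=float)
    if np.any(wt <= 0) or np.any(ht <= 0):
        raise ValueError("WT and HT must be strictly positive")
    out = wt / (ht / 100.0) ** 2
    return float(out) if out.ndim == 0 else out


def sample_covariates(dist: CovariateDistribution, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` subjects from the parametric covariate distribution.

    SEX is drawn first; (WT, FFM) come from the sex-conditional correlated
    model, preserving both the marginal truncation bounds and the WT-FFM
    correlation. BMI is derived from WT and HT. Doses are left unset.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    dist.validate()
    rng = np.random.default_rng(seed)
    sex = (rng.random(n) < dist.p_male).astype(int)  # 1 = male
    wt = np.empty(n)
    ffm = np.empty(n)
    for code, body in ((1, dist.body_male), (0, dist.body_female)):
        mask = sex == code
        if mask.any():
            wt[mask], ffm[mask] = body.sample(int(mask.sum()), rng)
    ht = dist.ht.sample(n, rng)
    age = dist.age.sample(n, rng)
    hiv = (rng.random(n) < dist.p_hiv).astype(int)
    race = (rng.random(n) < dist.p_race_other).astype(int)
    return pd.DataFrame({
        "ID": np.arange(1, n + 1),
        "WT": wt, "FFM": ffm, "HT": ht, "AGE": age,
        "SEX": sex, "HIV": hiv, "RACE": race,
        "BMI": compute_bmi(wt, ht),
        "DOSEGRP": np.nan, "DOSE": np.nan,
    })


def round_to_150(dose_mg, mode: str = "nearest"):
    """Round a raw mg dose to the 150-mg tablet increment.

    ``nearest`` rounds to the closest multiple (ties upward); ``up`` always
    rounds up. The result is never below one tablet (150 mg).
    """
    x = np.asarray(dose_mg, dtype=float)
    if np.any(x <= 0):
        raise ValueError("dose must be strictly positive")
    if mode == "nearest":
        rounded = 150.0 * np.floor(x / 150.0 + 0.5)
    elif mode == "up":
        rounded = 150.0 * np.ceil(x / 150.0)
    else:
        raise ValueError(f"unknown rounding mode {mode!r}")
    rounded = np.maximum(rounded, 150.0)
    return float(rounded) if rounded.ndim == 0 else rounded


def assign_doses(subjects: pd.DataFrame, dose_groups=DOSE_GROUPS_MG_KG,
                 mode: str = "random", seed: int = 0,
                 rounding: str = "nearest") -> pd.DataFrame:
    """Assign mg/kg dose groups and realized mg doses.

    ``random`` draws each subject's dose group uniformly and converts it to a
    tablet-rounded mg dose from the subject's weight. ``fixed_printed``
    reproduces the realized allocation of the emulated trial exactly: the 14
    listed mg doses with their subject counts, randomly permuted over the 83
    subjects.
    """
    out = subjects.copy()
    rng = np.random.default_rng(seed)
    if mode == "random":
        grp = rng.choice(np.asarray(dose_groups, dtype=float), size=len(out))
        out["DOSEGRP"] = grp
        out["DOSE"] = round_to_150(grp * out["WT"].to_numpy(), mode=rounding)
    elif mode == "fixed_printed":
        if len(out) != sum(PRINTED_DOSE_COUNTS):
            raise DesignError(
                f"fixed_printed allocation requires exactly "
                f"{sum(PRINTED_DOSE_COUNTS)} subjects, got {len(out)}")
        doses = np.repeat(PRINTED_DOSES_MG, PRINTED_DOSE_COUNTS).astype(float)
        rng.shuffle(doses)
        out["DOSE"] = doses
        groups = np.asarray(dose_groups, dtype=float)
        mgkg = doses / out["WT"].to_numpy()
        out["DOSEGRP"] = groups[np.argmin(np.abs(mgkg[:, None] - groups), axis=1)]
    else:
        raise ValueError(f"unknown dose allocation mode {mode!r}")
    return out


@dataclass(frozen=True)
class TrialDesign:
    """Subjects plus the dosing regimen and nominal sampling schedule."""

    subjects: pd.DataFrame
    occasion_days: dict = field(default_factory=lambda: dict(OCCASION_DAYS))
    nominal_times_h: tuple = NOMINAL_TIMES_H
    n_days: int = 14

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_planned_observations(self) -> int:
        return self.n_subjects * len(self.occasion_days) * len(self.nominal_times_h)


def build_design(subjects: pd.DataFrame,
                 occasion_days: dict | None = None,
                 nominal_times_h=NOMINAL_TIMES_H,
                 n_days: int = 14) -> TrialDesign:
    """Assemble a validated :class:`TrialDesign`."""
    if subjects["ID"].duplicated().any():
        raise DesignError("duplicate subject IDs in design")
    if subjects[["WT", "FFM", "HT", "AGE", "DOSE"]].isna().any().any():
        raise DesignError("subjects must be fully populated (incl. doses)")
    if (subjects["FFM"] >= subjects["WT"]).any():
        raise DesignError("FFM must be strictly below WT for every subject")
    occ = dict(OCCASION_DAYS) if occasion_days is None else dict(occasion_days)
    if any(day * 24 > n_days * 24 for day in occ.values()):
        raise DesignError("sampling occasion beyond the dosing horizon")
    times = tuple(float(t) for t in nominal_times_h)
    if sorted(set(times)) != list(times):
        raise DesignError("nominal times must be strictly increasing")
    return TrialDesign(subjects=subjects.reset_index(drop=True),
                       occasion_days=occ, nominal_times_h=times, n_days=n_days)
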