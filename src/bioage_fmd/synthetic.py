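"""Synthetic reference populations and trial cohorts.

Every downstream stage (KDM fitting, Gompertz survival, the lifecourse
simulation, trial statistics) is exercised on data generated here, with the
statistical structure the analysis assumes:

* a reference population (an NHANES-like analogue) whose seven clinical
  markers are linear in age plus independent Gaussian noise, with
  Gompertz-distributed mortality right-censored at a fixed follow-up horizon
  and survey sampling weights >= 1;
* paired baseline/follow-up trial cohorts in which an intervention shifts the
  markers and body weight, with a configurable fraction of "non-responders"
  whose marker effects are sign-flipped.

Marker noises are treated as independent across markers (the joint covariance
is not modelled); an optional per-person latent aging deviation shifts all
markers coherently when a correlated structure is wanted.  All generators are
deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gompertz import GompertzModel
from .kdm import DEFAULT_MARKERS, KDMParameters, kdm_bioage

__all__ = [
    "MarkerGenerativeModel",
    "TrialCohortSpec",
    "CAUSES",
    "REFERENCE_COLUMNS",
    "sample_gompertz_event_time",
    "generate_reference_population",
    "generate_trial_cohort",
    "simulate_survival_records",
]

#: Cause codes used for cause-specific mortality.
CAUSES = ("heart", "cancer", "cerebrovascular", "diabetes", "other")

#: Fixed column order for reference-cohort CSV output.
REFERENCE_COLUMNS = (
    "person_id",
    "age",
    *DEFAULT_MARKERS,
    "weight_kg",
    "sampling_weight",
    "time",
    "event",
    "cause",
)

# Default marker lines: intercept at age 0, slope per year, noise sd.  Chosen
# to give mid-life marker values in realistic clinical ranges (albumin g/dL,
# ALP U/L, creatinine mg/dL, CRP mg/L, HbA1c %, SBP mmHg, cholesterol mg/dL)
# with age trends of the sign seen in adult cross-sections.
_DEFAULT_LINES = {
    #                    intercept  slope    noise sd
    "albumin": (4.6, -0.008, 0.25),
    "alkaline_phosphatase": (55.0, 0.45, 18.0),
    "creatinine": (0.75, 0.004, 0.15),
    "crp": (0.5, 0.045, 1.5),
    "hba1c": (4.8, 0.012, 0.45),
    "systolic_bp": (95.0, 0.55, 11.0),
    "total_cholesterol": (150.0, 0.90, 30.0),
}


@dataclass(frozen=True)
class MarkerGenerativeModel:
    """Linear-in-age generative model for the biomarker panel.

    intercepts/slopes/noise_sds are in marker units (per year for slopes);
    ``age_range`` spans the reference population; ``bioage_sd`` optionally
    adds a per-person latent aging deviation shifting every marker coherently
    (0 disables it); ``weight_mean``/``weight_sd`` generate body weight in kg.
    """

    markers: tuple = DEFAULT_MARKERS
    intercepts: tuple = tuple(_DEFAULT_LINES[m][0] for m in DEFAULT_MARKERS)
    slopes: tuple = tuple(_DEFAULT_LINES[m][1] for m in DEFAULT_MARKERS)
    noise_sds: tuple = tuple(_DEFAULT_LINES[m][2] for m in DEFAULT_MARKERS)
    age_range: tuple = (30.0, 90.0)
    bioage_sd: float = 0.0
    weight_mean: float = 78.0
    weight_sd: float = 14.0

    def __post_init__(self):
        m = len(self.markers)
        for name in ("intercepts", "slopes", "noise_sds"):
            if len(getattr(self, name)) != m:
                raise ValueError(f"{name} must have one entry per marker")
        if any(sd <= 0 for sd in self.noise_sds):
            raise ValueError("noise standard deviations must be strictly positive")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age range lower bound must be below upper bound")

    def with_noise(self, scale: float) -> "MarkerGenerativeModel":
        """Copy with every noise sd multiplied by `scale` (floored at 1e-12)."""
        return MarkerGenerativeModel(
            markers=self.markers,
            intercepts=self.intercepts,
            slopes=self.slopes,
            noise_sds=tuple(max(sd * scale, 1e-12) for sd in self.noise_sds),
            age_range=self.age_range,
            bioage_sd=self.bioage_sd,
            weight_mean=self.weight_mean,
            weight_sd=self.weight_sd,
        )


@dataclass(frozen=True)
class TrialCohortSpec:
    """Configuration of a paired baseline/follow-up trial cohort.

    ``effects`` maps marker name -> signed intervention shift (marker units)
    applied baseline -> follow-up for responders; non-responders (a seeded
    fraction) get the shifts sign-flipped.  Weight change is N(mean, sd) kg.
    """

    n: int = 52
    effects: dict = field(default_factory=dict)
    weight_change_mean: float = -1.5
    weight_change_sd: float = 1.5
    nonresponder_fraction: float = 0.0
    followup_noise_scale: float = 0.3
    age_range: tuple | None = (30.0, 70.0)
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("sample size must be >= 2")
        if not 0 <= self.nonresponder_fraction <= 1:
            raise ValueError("nonresponder fraction must be in [0, 1]")


def sample_gompertz_event_time(hazard_scale, gamma: float, u) -> float:
    """Invert the Gompertz survival function: the t with s(t) = u.

    t = (1/gamma) * ln(1 - (gamma/lambda) * ln u).  Vectorised over
    ``hazard_scale`` and ``u``.  For gamma < 0 the survival plateaus at
    exp(lambda/gamma) > 0; draws of u below the plateau never die and return
    +inf (callers censor them at the horizon).
    """
    lam = np.asarray(hazard_scale, dtype=float)
    u_arr = np.asarray(u, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("hazard scale must be > 0")
    if gamma == 0:
        raise ValueError("gamma must be nonzero")
    if np.any((u_arr <= 0) | (u_arr >= 1)):
        raise ValueError("u must lie in (0, 1)")
    arg = 1.0 - (gamma / lam) * np.log(u_arr)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(arg > 0, np.log(np.maximum(arg, 1e-300)) / gamma, np.inf)
    return float(t) if np.isscalar(u) and np.isscalar(hazard_scale) else t


def generate_reference_population(
    model: MarkerGenerativeModel,
    gompertz: GompertzModel,
    kdm_truth: KDMParameters | None = None,
    n: int = 5000,
    censor_horizon: float = 23.0,
    seed: int = 0,
    cause_probs: dict | None = None,
) -> pd.DataFrame:
    """Generate an NHANES-like reference cohort with mortality follow-up.

    Ages are uniform on the model's age range; marker j is
    intercept_j + slope_j * age + N(0, noise_sd_j); event times follow the
    Gompertz law with each person's hazard scale from `gompertz` (biological
    age taken from `kdm_truth` scoring if given, else equal to chronological
    age), censored at `censor_horizon`.  Sampling weights are drawn log-normal
    and clipped so that the 548.5-divisor rounding rule spans roughly 6-1000.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if censor_horizon <= 0:
        raise ValueError("censor horizon must be > 0")
    rng = np.random.default_rng(seed)
    age = rng.uniform(*model.age_range, size=n)
    dev = rng.normal(0.0, model.bioage_sd, size=n) if model.bioage_sd > 0 else np.zeros(n)
    x = np.empty((n, len(model.markers)))
    for j, (b0, b1, sd) in enumerate(zip(model.intercepts, model.slopes, model.noise_sds)):
        x[:, j] = b0 + b1 * (age + dev) + rng.normal(0.0, sd, size=n)
    cohort = pd.DataFrame(x, columns=list(model.markers))
    cohort.insert(0, "age", age)
    cohort.insert(0, "person_id", np.arange(n))
    cohort["weight_kg"] = np.maximum(rng.normal(model.weight_mean, model.weight_sd, n), 35.0)
    # log-normal sampling weights, clipped to the 6..1000 range after /548.5
    sw = rng.lognormal(mean=np.log(548.5 * 144), sigma=0.9, size=n)
    cohort["sampling_weight"] = np.clip(sw, 548.5 * 6, 548.5 * 1000)

    if kdm_truth is not None:
        bioage = kdm_bioage(cohort, age, kdm_truth)
    else:
        bioage = age + dev
    extra = set(gompertz.betas) - {"age", "bioage"}
    if extra:
        raise ValueError(f"reference generator cannot supply covariates: {sorted(extra)}")
    lam = np.exp(
        gompertz.const
        + gompertz.betas.get("age", 0.0) * age
        + gompertz.betas.get("bioage", 0.0) * bioage
    )
    u = rng.uniform(1e-12, 1.0, size=n)
    t_event = sample_gompertz_event_time(lam, gompertz.gamma, u)
    event = (t_event <= censor_horizon).astype(int)
    cohort["time"] = np.where(event == 1, t_event, censor_horizon)
    cohort["event"] = event

    probs = cause_probs or {"heart": 0.30, "cancer": 0.25, "cerebrovascular": 0.10,
                            "diabetes": 0.05, "other": 0.30}
    names = list(probs)
    p = np.asarray([probs[c] for c in names], dtype=float)
    p = p / p.sum()
    draws = rng.choice(names, size=n, p=p)
    cohort["cause"] = np.where(event == 1, draws, "")
    return cohort[list(REFERENCE_COLUMNS)]


def generate_trial_cohort(
    reference_model: MarkerGenerativeModel, spec: TrialCohortSpec
) -> pd.DataFrame:
    """Generate a paired baseline/follow-up trial cohort.

    Baseline panels come from the reference model; follow-up panels are the
    baseline shifted by the configured intervention effects plus re-draw noise
    scaled by ``followup_noise_scale``.  Returns a wide table with
    ``<marker>_baseline`` / ``<marker>_followup`` columns plus age, baseline
    weight, weight change, baseline BMI / fasting glucose (for risk-factor
    filters), and the non-responder construction flag.
    """
    rng = np.random.default_rng(spec.seed)
    model = reference_model
    n = spec.n
    lo, hi = spec.age_range if spec.age_range is not None else model.age_range
    age = rng.uniform(lo, hi, size=n)
    nonresp = np.zeros(n, dtype=bool)
    n_flip = int(round(spec.nonresponder_fraction * n))
    nonresp[rng.choice(n, size=n_flip, replace=False)] = True

    out = {"person_id": np.arange(n), "age": age}
    for j, name in enumerate(model.markers):
        b0, b1, sd = model.intercepts[j], model.slopes[j], model.noise_sds[j]
        base = b0 + b1 * age + rng.normal(0.0, sd, size=n)
        eff = spec.effects.get(name, 0.0)
        shift = np.where(nonresp, -eff, eff)
        fu = base + shift + rng.normal(0.0, sd * spec.followup_noise_scale, size=n)
        out[f"{name}_baseline"] = base
        out[f"{name}_followup"] = fu
    out["weight_baseline"] = np.maximum(
        rng.normal(model.weight_mean, model.weight_sd, n), 35.0
    )
    out["weight_change"] = rng.normal(spec.weight_change_mean, spec.weight_change_sd, n)
    out["bmi_baseline"] = np.maximum(rng.normal(26.0, 4.0, n), 16.0)
    out["fasting_glucose_baseline"] = np.maximum(rng.normal(95.0, 12.0, n), 55.0)
    out["nonresponder_constructed"] = nonresp.astype(int)
    return pd.DataFrame(out)


def simulate_survival_records(
    n: int,
    gompertz: GompertzModel,
    censor_horizon: float = 23.0,
    age_range: tuple = (30.0, 90.0),
    bioage_sd: float = 5.0,
    weight_mean: float = 78.0,
    weight_sd: float = 14.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate survival records with separately identified age and bioage.

    Chronological age is uniform on `age_range`; biological age is
    age + N(0, bioage_sd) so the two covariates are not collinear; weight is
    N(weight_mean, weight_sd).  Event times follow the Gompertz law of
    `gompertz` with right censoring at `censor_horizon`.  Used for
    parameter-recovery checks.
    """
    rng = np.random.default_rng(seed)
    age = rng.uniform(*age_range, size=n)
    bioage = age + rng.normal(0.0, bioage_sd, size=n)
    weight = rng.normal(weight_mean, weight_sd, size=n)
    lin = (
        gompertz.const
        + gompertz.betas.get("age", 0.0) * age
        + gompertz.betas.get("bioage", 0.0) * bioage
        + gompertz.betas.get("weight", 0.0) * weight
    )
    lam = np.exp(lin)
    u = rng.uniform(1e-12, 1.0, size=n)
    t_event = sample_gompertz_event_time(lam, gompertz.gamma, u)
    event = (t_event <= censor_horizon).astype(int)
    return pd.DataFrame(
        {
            "time": np.where(event == 1, t_event, censor_horizon),
            "event": event,
            "cause": np.where(event == 1, "all", ""),
            "age": age,
            "bioage": bioage,
            "weight": weight,
        }
    )
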