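"""Klemera-Doubal (KDM) biological age estimation.

The KDM estimator combines m biomarker regression lines with chronological
age into a single "biological age" -- the age whose average biomarker profile
a person most resembles.  Each biomarker x_j is modelled as linear in age in a
reference population,

    x_j = q_j + k_j * age + eps_j,    eps_j ~ (0, s_j^2),

and the corrected estimator for a person with panel {x_j} and chronological
age CA is the precision-weighted combination

    BA_EC = [ sum_j (x_j - q_j) * k_j / s_j^2  +  CA / s_BA^2 ]
            / [ sum_j (k_j / s_j)^2  +  1 / s_BA^2 ],

where s_BA^2 is the variance of the deviation R_BA = BA_E - CA of the
uncorrected estimator (the CA-free weighted mean of per-marker implied ages)
over the reference population.  A person lying exactly on every regression
line gets BA_EC = CA.

`KDM` is a model class in the statsmodels style: construct from a reference
cohort, call :meth:`KDM.fit` to obtain a :class:`KDMResults` carrying the
fitted :class:`KDMParameters`, then score new panels with
:meth:`KDMResults.predict`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_MARKERS",
    "KDMParameters",
    "BioAgeEstimate",
    "KDM",
    "KDMResults",
    "fit_kdm_parameters",
    "kdm_bioage",
    "weight_adjusted_change",
    "classify_responders",
]

#: The seven clinical-chemistry markers scored by default.
DEFAULT_MARKERS = (
    "albumin",
    "alkaline_phosphatase",
    "creatinine",
    "crp",
    "hba1c",
    "systolic_bp",
    "total_cholesterol",
)

# Floor applied to residual scales fitted from (near-)noiseless cohorts so the
# scoring equation stays defined; slopes/intercepts are unaffected.
_SCALE_FLOOR = 1e-8


class DegenerateMarkerError(ValueError):
    """A marker has no variation (or no age dependence) in the reference cohort."""


@dataclass(frozen=True)
class KDMParameters:
    """Fitted reference-population parameters for KDM scoring.

    Parameters
    ----------
    markers : tuple of str
        Marker names, fixed order.
    k : ndarray
        Per-marker slope of marker on age (marker units per year).
    q : ndarray
        Per-marker intercept (marker units).
    s : ndarray
        Per-marker residual root-mean-square error (marker units).
    s_ba2 : float
        Variance (years^2) of the deviation R_BA = BA_E - CA.
    """

    markers: tuple
    k: np.ndarray
    q: np.ndarray
    s: np.ndarray
    s_ba2: float
    log_crp: bool = False

    def __post_init__(self):
        k = np.asarray(self.k, dtype=float)
        q = np.asarray(self.q, dtype=float)
        s = np.asarray(self.s, dtype=float)
        object.__setattr__(self, "markers", tuple(self.markers))
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "s", s)
        m = len(self.markers)
        if m < 1 or k.shape != (m,) or q.shape != (m,) or s.shape != (m,):
            raise ValueError("markers, k, q, s must have matching length >= 1")
        if np.any(s <= 0):
            raise ValueError("all residual scales s_j must be > 0")
        if self.s_ba2 <= 0:
            raise ValueError("s_BA^2 must be > 0")
        if np.any(k == 0):
            raise ValueError("no slope k_j may be exactly 0")

    @property
    def m(self) -> int:
        return len(self.markers)

    def to_json(self) -> str:
        payload = {
            "markers": {
                name: {"k": float(k), "q": float(q), "s": float(s)}
                for name, k, q, s in zip(self.markers, self.k, self.q, self.s)
            },
            "s_ba2": float(self.s_ba2),
            "log_crp": bool(self.log_crp),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "KDMParameters":
        payload = json.loads(text)
        names = tuple(payload["markers"])
        per = payload["markers"]
        return cls(
            markers=names,
            k=np.array([per[n]["k"] for n in names]),
            q=np.array([per[n]["q"] for n in names]),
            s=np.array([per[n]["s"] for n in names]),
            s_ba2=float(payload["s_ba2"]),
            log_crp=bool(payload.get("log_crp", False)),
        )


@dataclass(frozen=True)
class BioAgeEstimate:
    """A scored person: biological age, chronological age, and their gap."""

    ba_ec: float
    ca: float

    @property
    def delta(self) -> float:
        return self.ba_ec - self.ca


def _panel_matrix(panel, markers):
    """Extract an (n, m) marker matrix, raising on missing markers."""
    if isinstance(panel, pd.DataFrame):
        missing = [c for c in markers if c not in panel.columns]
        if missing:
            raise ValueError(f"missing markers: {missing}")
        if panel[list(markers)].isna().any().any():
            bad = [c for c in markers if panel[c].isna().any()]
            raise ValueError(f"missing markers: {bad}")
        return panel[list(markers)].to_numpy(dtype=float)
    if isinstance(panel, dict):
        missing = [c for c in markers if c not in panel or panel[c] is None]
        if missing:
            raise ValueError(f"missing markers: {missing}")
        return np.array([[float(panel[c]) for c in markers]])
    arr = np.atleast_2d(np.asarray(panel, dtype=float))
    if arr.shape[1] != len(markers):
        raise ValueError(f"panel has {arr.shape[1]} values, expected {len(markers)}")
    if np.isnan(arr).any():
        raise ValueError("missing markers: panel contains NaN")
    return arr


def _apply_log_crp(x: np.ndarray, markers, log_crp: bool) -> np.ndarray:
    if log_crp and "crp" in markers:
        x = x.copy()
        j = list(markers).index("crp")
        x[:, j] = np.log(x[:, j])
    return x


def kdm_bioage(panel, ca, params: KDMParameters):
    """Score KDM biological age for one person or a whole cohort.

    Parameters
    ----------
    panel : dict, DataFrame or array
        Marker values; a DataFrame scores every row.
    ca : float or array
        Chronological age(s) in years, > 0.
    params : KDMParameters

    Returns
    -------
    BioAgeEstimate or ndarray
        A single estimate for scalar input, else the vector of BA_EC values.
    """
    x = _panel_matrix(panel, params.markers)
    x = _apply_log_crp(x, params.markers, params.log_crp)
    ca_arr = np.atleast_1d(np.asarray(ca, dtype=float))
    if np.any(ca_arr <= 0):
        raise ValueError("chronological age must be > 0")
    if x.shape[0] == 1 and ca_arr.shape[0] > 1:
        x = np.broadcast_to(x, (ca_arr.shape[0], x.shape[1]))
    num = (x - params.q) @ (params.k / params.s**2) + ca_arr / params.s_ba2
    den = np.sum((params.k / params.s) ** 2) + 1.0 / params.s_ba2
    ba = num / den
    if np.isscalar(ca) and ba.shape[0] == 1:
        return BioAgeEstimate(ba_ec=float(ba[0]), ca=float(ca))
    return ba


def fit_kdm_parameters(
    cohort: pd.DataFrame,
    markers=DEFAULT_MARKERS,
    age_col: str = "age",
    log_crp: bool = False,
    s_ba2_override: float | None = None,
) -> KDMParameters:
    """Fit per-marker regression lines and s_BA^2 on a reference cohort.

    Each marker is regressed on age by OLS (x_j = q_j + k_j*age); s_j is the
    residual RMSE.  s_BA^2 is the empirical variance of BA_E - CA where BA_E
    is the CA-free estimator, unless ``s_ba2_override`` supplies a fixed value.
    """
    markers = tuple(markers)
    cols = [age_col, *markers]
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks columns: {missing}")
    data = cohort[cols].dropna()
    if len(data) < 30:
        raise ValueError("need at least 30 complete records to fit KDM parameters")
    age = data[age_col].to_numpy(dtype=float)
    x = data[list(markers)].to_numpy(dtype=float)
    x = _apply_log_crp(x, markers, log_crp)

    k = np.empty(len(markers))
    q = np.empty(len(markers))
    s = np.empty(len(markers))
    design = np.column_stack([np.ones_like(age), age])
    for j, name in enumerate(markers):
        if np.ptp(x[:, j]) == 0:
            raise DegenerateMarkerError(f"marker {name!r} is constant in the cohort")
        coef, *_ = np.linalg.lstsq(design, x[:, j], rcond=None)
        q[j], k[j] = coef
        if k[j] == 0:
            raise DegenerateMarkerError(f"marker {name!r} has no age dependence")
        resid = x[:, j] - design @ coef
        s[j] = max(np.sqrt(np.mean(resid**2)), _SCALE_FLOOR)

    if s_ba2_override is not None:
        s_ba2 = float(s_ba2_override)
    else:
        # CA-free estimator BA_E; its deviation from CA defines s_BA^2
        ba_e = (x - q) @ (k / s**2) / np.sum((k / s) ** 2)
        s_ba2 = max(float(np.var(ba_e - age)), _SCALE_FLOOR)
    return KDMParameters(markers=markers, k=k, q=q, s=s, s_ba2=s_ba2, log_crp=log_crp)


class KDM:
    """KDM biological-age model bound to a reference cohort.

    Parameters
    ----------
    cohort : DataFrame
        Reference population with an age column and one column per marker.
    markers : sequence of str, optional
        Marker columns to use (default: the seven-marker clinical panel).
    age_col : str
        Name of the chronological-age column.
    log_crp : bool
        Score C-reactive protein on the natural-log scale.
    """

    def __init__(self, cohort, markers=DEFAULT_MARKERS, age_col="age", log_crp=False):
        self.cohort = cohort
        self.markers = tuple(markers)
        self.age_col = age_col
        self.log_crp = log_crp

    @classmethod
    def from_dataframe(cls, cohort, **kwargs) -> "KDM":
        return cls(cohort, **kwargs)

    def fit(self, s_ba2_override: float | None = None) -> "KDMResults":
        params = fit_kdm_parameters(
            self.cohort,
            markers=self.markers,
            age_col=self.age_col,
            log_crp=self.log_crp,
            s_ba2_override=s_ba2_override,
        )
        return KDMResults(self, params)


class KDMResults:
    """Fitted KDM reference parameters with scoring and reporting helpers."""

    def __init__(self, model: KDM, params: KDMParameters):
        self.model = model
        self.params = params

    def predict(self, panel, ca):
        """Score biological age for new panels; see :func:`kdm_bioage`."""
        return kdm_bioage(panel, ca, self.params)

    def score_cohort(self, cohort: pd.DataFrame, age_col: str | None = None) -> pd.Series:
        age_col = age_col or self.model.age_col
        ba = kdm_bioage(cohort, cohort[age_col].to_numpy(), self.params)
        return pd.Series(ba, index=cohort.index, name="bioage")

    def summary(self) -> str:
        p = self.params
        lines = [
            "KDM biological age -- reference fit",
            f"  markers: {p.m}   s_BA^2: {p.s_ba2:.4f} yr^2",
            f"  {'marker':<22}{'k (slope)':>12}{'q (icept)':>12}{'s (rmse)':>12}",
        ]
        for name, k, q, s in zip(p.markers, p.k, p.q, p.s):
            lines.append(f"  {name:<22}{k:>12.5f}{q:>12.4f}{s:>12.4f}")
        return "\n".join(lines)

    def __repr__(self):
        return f"<KDMResults: m={self.params.m}, s_BA^2={self.params.s_ba2:.3f}>"


def weight_adjusted_change(
    followup_bioage,
    weight_change,
    mode: str = "followup",
):
    """Residualize biological age on weight change.

    mode="followup": regress follow-up biological age on weight change and
    return residual + cohort mean -- "follow-up biological age assuming no
    change in weight".  mode="change": same construction applied to the
    change in biological age regressed on change in weight (the caller passes
    the per-person bioage change as the first argument).

    Returns
    -------
    ndarray
        Per-person adjusted values, same length as the inputs.
    """
    y = np.asarray(followup_bioage, dtype=float)
    w = np.asarray(weight_change, dtype=float)
    if y.shape != w.shape or y.ndim != 1:
        raise ValueError("inputs must be aligned 1-d vectors")
    if len(y) < 3:
        raise ValueError("need at least 3 persons")
    if mode not in ("followup", "change"):
        raise ValueError(f"unknown mode {mode!r}")
    if np.ptp(w) == 0:
        raise ValueError("all weight changes identical: regression undefined")
    design = np.column_stack([np.ones_like(w), w])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return resid + y.mean()


def classify_responders(baseline, followup) -> np.ndarray:
    """Flag persons whose biological age increased (non-responders).

    flag = 1 iff follow-up BA_EC strictly exceeds baseline BA_EC; exact ties
    count as responders (flag 0).
    """
    b = np.asarray(
        [e.ba_ec if isinstance(e, BioAgeEstimate) else e for e in np.atleast_1d(baseline)],
        dtype=float,
    )
    f = np.asarray(
        [e.ba_ec if isinstance(e, BioAgeEstimate) else e for e in np.atleast_1d(followup)],
        dtype=float,
    )
    if b.shape != f.shape:
        raise ValueError("baseline and follow-up cohorts are unmatched")
    return (f > b).astype(int)
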