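"""Synthetic EHR-like cohorts with known latent trajectory classes.

The generator emulates the structure of routinely collected in-hospital
blood tests after spine trauma: a handful of markers observed irregularly
over the first 21 days of stay, front-loaded sampling (labs are drawn most
densely right after admission), multi-class non-linear mean trajectories on
a latent scale, subject-level random effects, non-Gaussian marginal shapes
via inverse link transforms, and injected zeros/outliers to exercise the
data-cleaning stage.  Outcome labels (in-hospital death; motor-complete
injury for the external cohort) are Bernoulli draws whose log-odds depend on
the true class memberships and age, so downstream classifiers have a planted,
recoverable signal.

Ground truth (class labels, random effects) is returned separately from the
subject/lab tables and is never consumed by the analysis stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .basis import TimeBasis
from .links import BetaLink, LinearLink
from .trajectory import RE_DIMS

__all__ = [
    "MarkerTruth",
    "GroupConfig",
    "CohortConfig",
    "ExternalShift",
    "simulate_cohort",
    "simulate_external_cohort",
    "default_cohort_config",
]

GROUPS = ("SCI_Fracture", "SCI_noFracture", "Spine_Trauma")

_ETHNICITIES = ["WHITE", "BLACK", "HISPANIC", "ASIAN", "OTHER"]
_ETH_PROBS = [0.80, 0.06, 0.05, 0.03, 0.06]
_INSURANCE = ["Medicare", "Medicaid", "Other"]
_INS_PROBS = [0.38, 0.08, 0.54]


@dataclass
class MarkerTruth:
    """Generative truth for one marker.

    ``mean_coeffs`` lives on the latent (link) scale; observed values are
    ``link.inverse(latent + noise)``.  ``class_probs_by_group`` optionally
    overrides the marginal class probabilities per cohort group, which is
    what makes group membership (and hence the SCI-detection task)
    learnable from trajectory classes.
    """

    marker_name: str
    class_probs: np.ndarray
    mean_coeffs: np.ndarray  # (n_classes, basis dim), latent scale
    basis: TimeBasis
    link: object
    re_sd: tuple = (0.0, 0.0)  # (intercept sd, slope sd per day)
    resid_sd: float = 1.0
    outlier_rate: float = 0.0
    zero_rate: float = 0.0
    class_probs_by_group: dict | None = None

    def __post_init__(self):
        self.class_probs = np.asarray(self.class_probs, dtype=float)
        self.mean_coeffs = np.asarray(self.mean_coeffs, dtype=float)
        if abs(self.class_probs.sum() - 1.0) > 1e-12:
            raise ValueError(f"{self.marker_name}: class_probs must sum to 1")
        if self.mean_coeffs.shape != (self.n_classes, self.basis.n_columns):
            raise ValueError(f"{self.marker_name}: mean_coeffs shape mismatch")
        if self.resid_sd <= 0:
            raise ValueError(f"{self.marker_name}: resid_sd must be > 0")
        for r, name in [(self.outlier_rate, "outlier_rate"), (self.zero_rate, "zero_rate")]:
            if not 0 <= r <= 1:
                raise ValueError(f"{self.marker_name}: {name} must be in [0,1]")
        if any(s < 0 for s in self.re_sd):
            raise ValueError(f"{self.marker_name}: re_sd must be nonnegative")

    @property
    def n_classes(self) -> int:
        return len(self.class_probs)

    def probs_for_group(self, group: str) -> np.ndarray:
        if self.class_probs_by_group and group in self.class_probs_by_group:
            p = np.asarray(self.class_probs_by_group[group], dtype=float)
            if abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(f"{self.marker_name}: group probs must sum to 1")
            return p
        return self.class_probs


@dataclass
class GroupConfig:
    n_subjects: int
    age_mean: float
    age_sd: float
    male_prob: float
    los_meanlog: float  # length-of-stay ~ LogNormal(meanlog, sdlog), days
    los_sdlog: float

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("group size must be >= 1")


@dataclass
class CohortConfig:
    groups: dict  # name -> GroupConfig
    markers: list
    lab_intensity: float = 2.5  # expected labs/day at admission
    lab_decay: float = 0.12  # exponential decay per day
    mortality_coefs: dict = field(default_factory=dict)
    severity_coefs: dict = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self):
        if self.lab_intensity <= 0:
            raise ValueError("sampling intensity must be > 0")


@dataclass
class ExternalShift:
    """Distribution shift applied to the external cohort."""

    mean_shift: float = 0.0  # additive, latent scale, all classes/markers
    intensity_scale: float = 1.0

    def __post_init__(self):
        if not np.isfinite(self.mean_shift) or not np.isfinite(self.intensity_scale):
            raise ValueError("shift magnitudes must be finite")


def _truncated_normal(rng, mean, sd, lower, size):
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _outcome_logit(coefs: dict, age: float, classes: dict) -> float:
    """coefs: {'intercept': c, 'age': per-sd-of-15y coef,
    ('marker', class_index): c, ...}"""
    logit = coefs.get("intercept", 0.0)
    logit += coefs.get("age", 0.0) * (age - 60.0) / 15.0
    for key, c in coefs.items():
        if isinstance(key, tuple):
            marker, cls = key
            if classes.get(marker) == cls:
                logit += c
    return logit


def _sample_times(rng, los, intensity, decay):
    horizon = min(float(los), 22.0)
    times = []
    day = 0
    while day < horizon:
        lam = intensity * np.exp(-decay * day)
        k = rng.poisson(lam)
        if k:
            tt = day + rng.uniform(0.0, 1.0, size=k)
            times.extend(tt[tt <= horizon])
        day += 1
    return np.sort(np.array(times))


def simulate_cohort(config: CohortConfig, *, rng_seed: int | None = None,
                    _severity_all: bool = False,
                    _shift: ExternalShift | None = None):
    """Draw a cohort; returns ``(subjects, labs, truth)`` DataFrames.

    ``subjects``: one row per subject with group, demographics, length of
    stay and outcome labels.  ``labs``: long format (subject_id, day,
    marker, value).  ``truth``: per subject and marker, the true class and
    random effects — for evaluation only, never an analysis input.

    Identical seeds give identical tables.
    """
    seed = config.rng_seed if rng_seed is None else rng_seed
    shift = _shift or ExternalShift()
    rng = np.random.default_rng(seed)
    subj_rows, lab_rows, truth_rows = [], [], []
    sid_counter = 0
    for group in GROUPS:
        if group not in config.groups:
            continue
        gc = config.groups[group]
        ages = _truncated_normal(rng, gc.age_mean, gc.age_sd, 15.0, gc.n_subjects)
        for j in range(gc.n_subjects):
            sid = f"S{sid_counter:05d}"
            sid_counter += 1
            age = float(ages[j])
            gender = "M" if rng.random() < gc.male_prob else "F"
            ethnicity = _ETHNICITIES[rng.choice(len(_ETHNICITIES), p=_ETH_PROBS)]
            insurance = _INSURANCE[rng.choice(len(_INSURANCE), p=_INS_PROBS)]
            los = float(np.exp(rng.normal(gc.los_meanlog, gc.los_sdlog)))
            los = max(los, 0.25)
            classes = {}
            for mk in config.markers:
                g = int(rng.choice(mk.n_classes, p=mk.probs_for_group(group)))
                classes[mk.marker_name] = g + 1
                b0 = rng.normal(0.0, mk.re_sd[0]) if mk.re_sd[0] > 0 else 0.0
                b1 = (rng.normal(0.0, mk.re_sd[1])
                      if len(mk.re_sd) > 1 and mk.re_sd[1] > 0 else 0.0)
                times = _sample_times(rng, los, config.lab_intensity * shift.intensity_scale,
                                      config.lab_decay)
                truth_rows.append({"subject_id": sid, "marker": mk.marker_name,
                                   "true_class": g + 1, "b_intercept": b0, "b_slope": b1})
                if times.size == 0:
                    continue
                latent = (mk.basis.design(times) @ mk.mean_coeffs[g]
                          + b0 + b1 * times + shift.mean_shift
                          + rng.normal(0.0, mk.resid_sd, size=times.size))
                try:
                    values = np.asarray(mk.link.inverse(latent), dtype=float)
                except ValueError as exc:
                    raise ValueError(
                        f"marker {mk.marker_name!r}: link not invertible over "
                        f"the sampled latent range ({exc})") from exc
                for t, v in zip(times, values):
                    lab_rows.append({"subject_id": sid, "day": float(t),
                                     "marker": mk.marker_name, "value": float(v)})
            mort_logit = _outcome_logit(config.mortality_coefs, age, classes)
            died = bool(rng.random() < 1.0 / (1.0 + np.exp(-mort_logit)))
            row = {"subject_id": sid, "group": group, "age": age, "gender": gender,
                   "ethnicity": ethnicity, "insurance": insurance,
                   "length_of_stay": los, "died_in_hospital": died}
            if _severity_all:
                sev_logit = _outcome_logit(config.severity_coefs, age, classes)
                row["severity_motor_complete"] = bool(
                    rng.random() < 1.0 / (1.0 + np.exp(-sev_logit)))
            else:
                row["severity_motor_complete"] = pd.NA
            subj_rows.append(row)
    subjects = pd.DataFrame(subj_rows)
    labs = pd.DataFrame(lab_rows, columns=["subject_id", "day", "marker", "value"])
    truth = pd.DataFrame(truth_rows)
    labs = _inject_artifacts(labs, config.markers, rng)
    return subjects, labs, truth


def _inject_artifacts(labs: pd.DataFrame, markers, rng) -> pd.DataFrame:
    """Replace a random fraction of values by zeros / extreme outliers.

    Outliers are placed symmetrically above/below at >= 5 sample sd from the
    marker mean; zeros are injected regardless of plausibility so the zero
    filter has work to do.
    """
    if labs.empty:
        return labs
    values = labs["value"].to_numpy().copy()
    for mk in markers:
        if mk.zero_rate == 0 and mk.outlier_rate == 0:
            continue
        idx = np.flatnonzero((labs["marker"] == mk.marker_name).to_numpy())
        if idx.size == 0:
            continue
        mean = values[idx].mean()
        sd = values[idx].std(ddof=1) if idx.size > 1 else 1.0
        sd = sd if sd > 0 else 1.0
        u = rng.random(idx.size)
        zero_mask = u < mk.zero_rate
        out_mask = (~zero_mask) & (u < mk.zero_rate + mk.outlier_rate)
        values[idx[zero_mask]] = 0.0
        k = int(out_mask.sum())
        if k:
            sign = rng.choice([-1.0, 1.0], size=k)
            dist = 5.0 + rng.exponential(1.0, size=k)
            values[idx[out_mask]] = mean + sign * dist * sd
    labs = labs.copy()
    labs["value"] = values
    return labs


def simulate_external_cohort(config: CohortConfig, shift: ExternalShift | None = None,
                             n_subjects: int = 137, rng_seed: int | None = None):
    """External validation cohort: SCI subjects only, severity label present
    for everyone, same generative model with optional latent-scale mean
    shift and rescaled sampling intensity."""
    shift = shift or ExternalShift()
    n_frac = config.groups.get("SCI_Fracture")
    n_nofrac = config.groups.get("SCI_noFracture")
    w_frac = (n_frac.n_subjects if n_frac else 0)
    w_nofrac = (n_nofrac.n_subjects if n_nofrac else 0)
    if w_frac + w_nofrac == 0:
        raise ValueError("external cohort needs at least one SCI group in config")
    frac_share = w_frac / (w_frac + w_nofrac)
    n_f = int(round(n_subjects * frac_share))
    groups = {}
    if n_frac and n_f > 0:
        groups["SCI_Fracture"] = replace(n_frac, n_subjects=n_f)
    if n_nofrac and n_subjects - n_f > 0:
        groups["SCI_noFracture"] = replace(n_nofrac, n_subjects=n_subjects - n_f)
    ext = replace(config, groups=groups)
    seed = (config.rng_seed + 10_007) if rng_seed is None else rng_seed
    return simulate_cohort(ext, rng_seed=seed, _severity_all=True, _shift=shift)


# ---------------------------------------------------------------------------
# default desk-scale study conditions


def default_cohort_config(rng_seed: int = 0) -> CohortConfig:
    """Desk-scale cohort: 6 markers, groups of (120, 60, 420) subjects
    (the study cohort imbalance at roughly quarter scale), 2-3 latent
    classes per marker, hematology-style class shapes (similar admission
    levels that diverge over the stay), outcome prevalences near the
    study's (~8-12% mortality, ~30% SCI, ~45% motor complete)."""
    poly2 = TimeBasis("polynomial", 2)
    poly1 = TimeBasis("polynomial", 1)

    hgb = MarkerTruth(
        "hemoglobin",
        class_probs=[0.50, 0.30, 0.20],
        # classes start close and diverge: slow decline / fast early drop / low flat
        mean_coeffs=[[1.1, -0.045, 0.0005],
                     [1.0, -0.38, 0.012],
                     [-0.9, 0.01, 0.0]],
        basis=poly2,
        link=LinearLink(11.0, 2.0),
        re_sd=(0.30, 0.008),
        resid_sd=0.40,
        outlier_rate=0.01,
        zero_rate=0.01,
        class_probs_by_group={
            "Spine_Trauma": [0.62, 0.23, 0.15],
            "SCI_Fracture": [0.28, 0.42, 0.30],
            "SCI_noFracture": [0.38, 0.35, 0.27],
        },
    )
    hct = MarkerTruth(
        "hematocrit",
        class_probs=[0.50, 0.30, 0.20],
        mean_coeffs=[[1.0, -0.04, 0.0004],
                     [0.9, -0.33, 0.010],
                     [-1.0, 0.02, 0.0]],
        basis=poly2,
        link=LinearLink(33.0, 5.0),
        re_sd=(0.30, 0.008),
        resid_sd=0.42,
        outlier_rate=0.01,
        zero_rate=0.01,
        class_probs_by_group={
            "Spine_Trauma": [0.60, 0.25, 0.15],
            "SCI_Fracture": [0.30, 0.40, 0.30],
            "SCI_noFracture": [0.40, 0.33, 0.27],
        },
    )
    wbc = MarkerTruth(
        "wbc",
        class_probs=[0.60, 0.25, 0.15],
        # mild flat / rising / high early then resolving, on the beta-latent scale
        mean_coeffs=[[0.0, 0.005, 0.0],
                     [-0.1, 0.16, -0.003],
                     [1.6, -0.14, 0.003]],
        basis=poly2,
        link=BetaLink(2.0, 4.0, 0.35, 0.12, 2.0, 30.0),
        re_sd=(0.25, 0.0),
        resid_sd=0.35,
        outlier_rate=0.01,
        zero_rate=0.01,
        class_probs_by_group={
            "Spine_Trauma": [0.68, 0.20, 0.12],
            "SCI_Fracture": [0.42, 0.33, 0.25],
            "SCI_noFracture": [0.50, 0.30, 0.20],
        },
    )
    sodium = MarkerTruth(
        "sodium",
        class_probs=[0.88, 0.12],
        mean_coeffs=[[0.0, 0.005], [0.6, 0.09]],
        basis=poly1,
        link=LinearLink(139.0, 3.0),
        re_sd=(0.25, 0.0),
        resid_sd=0.45,
        outlier_rate=0.01,
        zero_rate=0.01,
    )
    potassium = MarkerTruth(
        "potassium",
        class_probs=[0.85, 0.15],
        mean_coeffs=[[-0.1, 0.002], [0.9, 0.05]],
        basis=poly1,
        link=BetaLink(2.5, 3.5, 0.40, 0.13, 2.5, 7.5),
        re_sd=(0.20, 0.0),
        resid_sd=0.38,
        outlier_rate=0.01,
        zero_rate=0.01,
    )
    glucose = MarkerTruth(
        "glucose",
        class_probs=[0.70, 0.30],
        mean_coeffs=[[-0.3, -0.005], [0.8, -0.03]],
        basis=poly1,
        link=LinearLink(130.0, 35.0),
        re_sd=(0.30, 0.0),
        resid_sd=0.50,
        outlier_rate=0.01,
        zero_rate=0.01,
    )

    groups = {
        "SCI_Fracture": GroupConfig(120, 55.0, 18.0, 0.74, np.log(10.0), 0.55),
        "SCI_noFracture": GroupConfig(60, 57.0, 17.0, 0.70, np.log(8.0), 0.55),
        "Spine_Trauma": GroupConfig(420, 64.0, 19.0, 0.56, np.log(7.0), 0.55),
    }
    # weight concentrated on late-diverging classes (hemoglobin/hematocrit
    # class 2 drop after day ~3, wbc class 2 rises over the stay) so that the
    # predictive value of trajectory membership grows as data accrues
    # weight concentrated on late-diverging classes (hemoglobin/hematocrit
    # class 2 drop after day ~3, wbc class 2 rises over the stay) so that the
    # predictive value of trajectory membership grows as data accrues
    mortality = {
        "intercept": -4.6,
        "age": 0.6,
        ("hemoglobin", 2): 2.0,
        ("hemoglobin", 3): 1.2,
        ("hematocrit", 2): 0.9,
        ("wbc", 2): 1.2,
        ("wbc", 3): 0.8,
        ("sodium", 2): 1.2,
    }
    severity = {
        "intercept": -0.7,
        "age": 0.1,
        ("hemoglobin", 3): 1.2,
        ("hematocrit", 3): 0.8,
        ("wbc", 3): 0.9,
        ("potassium", 2): 0.7,
    }
    return CohortConfig(
        groups=groups,
        markers=[hgb, hct, wbc, sodium, potassium, glucose],
        lab_intensity=2.5,
        lab_decay=0.12,
        mortality_coefs=mortality,
        severity_coefs=severity,
        rng_seed=rng_seed,
    )


def write_cohort(outdir, subjects: pd.DataFrame, labs: pd.DataFrame,
                 truth: pd.DataFrame) -> None:
    """Write subjects.csv, labs.csv and truth.json to ``outdir``."""
    import os

    os.makedirs(outdir, exist_ok=True)
    subjects.to_csv(os.path.join(outdir, "subjects.csv"), index=False)
    labs.to_csv(os.path.join(outdir, "labs.csv"), index=False)
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth.to_dict(orient="records"), fh)
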