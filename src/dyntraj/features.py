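"""Predictor sets for the dynamic-prediction experiments.

For a cutoff day ``t`` in {1, 3, 7, 14, 21} and a frozen set of per-marker
trajectory models, three nested feature sets are assembled per subject:

``ppa``          posterior class-membership probabilities per marker,
                 computed from observations at or before the cutoff only
                 (all G columns per marker are kept; the elastic net
                 tolerates the sum-to-one collinearity);
``ppa_sum``      plus within-window summary statistics (mean, sd, min, max)
                 of the raw marker values;
``ppa_sum_bl``   plus baseline covariates: age, gender, and one-hot
                 ethnicity/insurance (experiment III: age and gender only).

Experiments: I = in-hospital mortality on the modeling cohort; II = SCI
presence (SCI groups vs spine trauma without SCI); III = motor-complete
injury on the external cohort.  Missing numeric entries (sparse early
windows) are imputed downstream with the training-split median so no test
information leaks into imputation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import posterior_matrix, series_from_labs

__all__ = [
    "FeatureMatrix",
    "window_summary",
    "build_feature_matrix",
    "label_outcome",
    "fit_imputer",
    "apply_imputer",
]

CUTOFF_DAYS = (1, 3, 7, 14, 21)
FEATURE_SETS = ("ppa", "ppa_sum", "ppa_sum_bl")
EXPERIMENTS = ("I", "II", "III")


@dataclass
class FeatureMatrix:
    experiment: str
    cutoff_day: float
    feature_set: str
    X: pd.DataFrame  # rows = subjects; may hold NaN until imputation
    y: pd.Series  # binary outcome, aligned with X
    numeric_columns: list = field(default_factory=list)
    categorical_columns: list = field(default_factory=list)

    def __post_init__(self):
        if not self.X.index.equals(self.y.index):
            raise ValueError("X and y must be aligned on subject_id")


def window_summary(series, cutoff_day: float):
    """(mean, sd, min, max, n_obs) over observations at ``t <= cutoff``.

    Sample sd uses the n-1 denominator; a single observation leaves sd
    missing, an empty window leaves all four missing.
    """
    sub = series.truncated(cutoff_day)
    n = len(sub)
    if n == 0:
        return (np.nan, np.nan, np.nan, np.nan, 0)
    v = sub.values
    sd = float(np.std(v, ddof=1)) if n > 1 else np.nan
    return (float(v.mean()), sd, float(v.min()), float(v.max()), n)


def label_outcome(subjects: pd.DataFrame, experiment: str) -> pd.Series:
    """Binary outcome vector for an experiment, indexed by subject_id.

    I: died in hospital.  II: 1 for the SCI groups, 0 for spine trauma
    without SCI.  III: 1 for motor-complete injury (AIS A/B); subjects
    without a severity label are dropped with a warning.
    """
    s = subjects.set_index("subject_id")
    if experiment == "I":
        return s["died_in_hospital"].astype(int)
    if experiment == "II":
        return s["group"].isin(["SCI_Fracture", "SCI_noFracture"]).astype(int)
    if experiment == "III":
        sev = s["severity_motor_complete"]
        missing = sev.isna()
        if missing.any():
            warnings.warn(f"experiment III: dropping {int(missing.sum())} "
                          "subject(s) without a severity label", stacklevel=2)
        return sev[~missing].astype(int)
    raise ValueError(f"unknown experiment {experiment!r}")


def ais_to_motor_complete(grades) -> np.ndarray:
    """AIS A/B -> 1 (motor complete), C/D/E -> 0."""
    arr = np.asarray(grades, dtype=object)
    out = np.empty(arr.shape, dtype=int)
    for i, g in np.ndenumerate(arr):
        gu = str(g).strip().upper()
        if gu not in "ABCDE" or len(gu) != 1:
            raise ValueError(f"unknown AIS grade {g!r}")
        out[i] = 1 if gu in ("A", "B") else 0
    return out


def build_feature_matrix(subjects: pd.DataFrame, models: dict, labs: pd.DataFrame,
                         experiment: str, cutoff_day: float,
                         feature_set: str) -> FeatureMatrix:
    """Assemble one experiment/cutoff/feature-set matrix.

    ``models`` maps marker -> frozen FittedTrajectoryModel.  Subjects with
    no retained events for a marker get the model's prior as their PPA and
    missing summaries (imputed later).
    """
    if experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment!r}")
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}")
    y = label_outcome(subjects, experiment)
    ids = list(y.index)
    blocks = {}
    numeric_cols, categorical_cols = [], []
    for marker in sorted(models):
        model = models[marker]
        series = series_from_labs(labs, marker, ids)
        G = model.n_classes
        ppa = posterior_matrix(series, model, cutoff_day)
        summ = np.empty((len(ids), 4))
        for i, s in enumerate(series):
            summ[i] = window_summary(s, cutoff_day)[:4]
        for g in range(G):
            col = f"{marker}::ppa_class{g + 1}"
            blocks[col] = ppa[:, g]
            numeric_cols.append(col)
        if feature_set in ("ppa_sum", "ppa_sum_bl"):
            for j, stat in enumerate(["mean", "sd", "min", "max"]):
                col = f"{marker}::{stat}"
                blocks[col] = summ[:, j]
                numeric_cols.append(col)
    if feature_set == "ppa_sum_bl":
        s = subjects.set_index("subject_id").loc[ids]
        blocks["age"] = s["age"].to_numpy(dtype=float)
        numeric_cols.append("age")
        blocks["gender_M"] = (s["gender"] == "M").astype(float).to_numpy()
        categorical_cols.append("gender_M")
        if experiment != "III":
            for base in ("ethnicity", "insurance"):
                for level in sorted(s[base].astype(str).unique()):
                    col = f"{base}_{level}"
                    blocks[col] = (s[base].astype(str) == level).astype(float).to_numpy()
                    categorical_cols.append(col)
    X = pd.DataFrame(blocks, index=pd.Index(ids, name="subject_id"))
    return FeatureMatrix(experiment, cutoff_day, feature_set, X, y,
                         numeric_cols, categorical_cols)


def fit_imputer(X_train: pd.DataFrame, numeric_columns, categorical_columns) -> dict:
    """Imputation parameters learned on the training split only:
    column median for numeric features, column mode for categorical
    indicators."""
    params = {}
    for c in numeric_columns:
        med = X_train[c].median()
        params[c] = float(med) if np.isfinite(med) else 0.0
    for c in categorical_columns:
        col = X_train[c].dropna()
        params[c] = float(col.mode().iloc[0]) if len(col) else 0.0
    return params


def apply_imputer(X: pd.DataFrame, params: dict) -> pd.DataFrame:
    out = X.copy()
    for c, v in params.items():
        if c in out.columns:
            out[c] = out[c].fillna(v)
    if out.isna().any().any():
        bad = out.columns[out.isna().any()].tolist()
        raise ValueError(f"columns still missing after imputation: {bad}")
    return out
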