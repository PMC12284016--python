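"""Repeated elastic-net classification harness for dynamic prediction.

Each experiment/cutoff/feature-set cell is run ``n_repeats`` (default 25)
times.  Repeat ``r`` draws one stratified 80/20 train/test split from seed
``base_seed + r`` that is reused across every cutoff and feature set, so
performance curves over cutoffs are comparable within a repeat.  Inside the
training split, hyperparameters (glmnet-style mixing ``alpha`` and penalty
``lambda``) are chosen by stratified 5-fold cross-validation maximizing
Cohen's kappa at probability threshold 0.5, ties resolved toward stronger
regularization (larger lambda, then larger alpha).  The selected pair is
refit on the full training split and scored in-train and out-of-train with
ROC-AUC (primary) and PR-AUC (secondary); 95% CIs over repeats use the
t distribution with ``n_repeats - 1`` df.

The penalized logistic model minimizes

    (1/n) sum_i log(1 + exp(-y_i eta_i)) + lambda [ alpha ||w||_1
                                                   + (1 - alpha)/2 ||w||_2^2 ]

(intercept unpenalized, features standardized with training mean/sd) and is
solved by FISTA proximal gradient — fast enough for the tens of thousands
of fits the repeated grid search needs, and agreeing with off-the-shelf
solvers to ~1e-5 (checked in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, cohen_kappa_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .features import CUTOFF_DAYS, FEATURE_SETS, FeatureMatrix, apply_imputer, fit_imputer

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "default_grids",
    "ElasticNetLogistic",
    "tune_and_fit",
    "roc_auc",
    "pr_auc",
    "run_experiment",
    "variable_importance",
]


def default_grids():
    """The study's hyperparameter grids (10 alphas x 10 lambdas)."""
    alpha = (0.00, 0.11, 0.22, 0.33, 0.44, 0.55, 0.66, 0.77, 0.88, 1.00)
    lam = (0.0001, 0.11, 0.22, 0.33, 0.44, 0.55, 0.66, 0.77, 0.88, 1.00)
    return alpha, lam


@dataclass
class ExperimentConfig:
    experiment: str
    cutoffs: tuple = CUTOFF_DAYS
    feature_sets: tuple = FEATURE_SETS
    n_repeats: int = 25
    train_fraction: float = 0.8
    cv_folds: int = 5
    alpha_grid: tuple = field(default_factory=lambda: default_grids()[0])
    lambda_grid: tuple = field(default_factory=lambda: default_grids()[1])
    base_seed: int = 0


# ---------------------------------------------------------------------------
# elastic-net logistic regression (FISTA)


class ElasticNetLogistic:
    """Penalized logistic regression with glmnet parametrization."""

    def __init__(self, lam: float, alpha: float, max_iter: int = 1000,
                 tol: float = 1e-9):
        self.lam = float(lam)
        self.alpha = float(alpha)
        self.max_iter = max_iter
        self.tol = tol
        self.intercept_ = 0.0
        self.coef_ = None

    def fit(self, X: np.ndarray, y: np.ndarray, warm_start=None,
            design_norm2: float | None = None):
        n, p = X.shape
        Xb = np.hstack([np.ones((n, 1)), X])
        w = np.zeros(p + 1) if warm_start is None else np.asarray(warm_start, dtype=float).copy()
        l1 = self.lam * self.alpha
        l2 = self.lam * (1.0 - self.alpha)
        # Lipschitz bound for the smooth part; the spectral norm of the
        # design is reusable across the hyperparameter grid
        if design_norm2 is None:
            design_norm2 = float(np.linalg.norm(Xb, 2) ** 2)
        L = design_norm2 / (4.0 * n) + l2
        z = w.copy()
        tk = 1.0
        for _ in range(self.max_iter):
            eta = np.clip(Xb @ z, -35, 35)
            mu = 1.0 / (1.0 + np.exp(-eta))
            g = Xb.T @ (mu - y) / n
            g[1:] += l2 * z[1:]
            wn = z - g / L
            wn[1:] = np.sign(wn[1:]) * np.maximum(np.abs(wn[1:]) - l1 / L, 0.0)
            tk1 = (1.0 + np.sqrt(1.0 + 4.0 * tk * tk)) / 2.0
            z = wn + ((tk - 1.0) / tk1) * (wn - w)
            tk = tk1
            if np.max(np.abs(wn - w)) < self.tol * (1.0 + np.max(np.abs(wn))):
                w = wn
                break
            w = wn
        self.intercept_ = float(w[0])
        self.coef_ = w[1:]
        return self

    @property
    def params_(self):
        return np.r_[self.intercept_, self.coef_]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        eta = np.clip(self.intercept_ + X @ self.coef_, -35, 35)
        return 1.0 / (1.0 + np.exp(-eta))


def _standardize_fit(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant columns pass through
    return mean, sd


def tune_and_fit(X: np.ndarray, y: np.ndarray, alpha_grid=None, lambda_grid=None,
                 cv_folds: int = 5, seed: int = 0, max_iter: int = 350):
    """Grid-search (alpha, lambda) by stratified CV kappa, refit on all data.

    Returns ``(model, (alpha, lam), cv_kappa, scaler)`` where ``scaler`` is
    the (mean, sd) standardization learned on the full training data and the
    model's coefficients live on the standardized scale.
    """
    if alpha_grid is None or lambda_grid is None:
        a, l = default_grids()
        alpha_grid = alpha_grid or a
        lambda_grid = lambda_grid or l
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("training outcome has a single class")
    X = np.asarray(X, dtype=float)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    lam_desc = sorted(lambda_grid, reverse=True)  # warm-start path
    kappa_sum = {(a, l): 0.0 for a in alpha_grid for l in lam_desc}
    for tr, te in folds:
        Xtr_raw, ytr = X[tr], y[tr]
        mean, sd = _standardize_fit(Xtr_raw)
        Xtr = (Xtr_raw - mean) / sd
        Xte = (X[te] - mean) / sd
        yte = y[te]
        norm2 = float(np.linalg.norm(
            np.hstack([np.ones((len(tr), 1)), Xtr]), 2) ** 2)
        for a in alpha_grid:
            warm = None
            for lam in lam_desc:
                m = ElasticNetLogistic(lam, a, max_iter=max_iter,
                                       tol=1e-6).fit(
                    Xtr, ytr, warm, design_norm2=norm2)
                warm = m.params_
                pred = (m.predict_proba(Xte) >= 0.5).astype(int)
                kappa_sum[(a, lam)] += cohen_kappa_score(yte, pred)
    best = None
    for a in alpha_grid:
        for lam in lam_desc:
            k = kappa_sum[(a, lam)] / len(folds)
            # ties prefer sparser models: larger lambda, then larger alpha
            key = (k, lam, a)
            if best is None or key > best[0]:
                best = (key, (a, lam))
    (kappa, _, _), (a_best, lam_best) = best
    mean, sd = _standardize_fit(X)
    Xs = (X - mean) / sd
    final = ElasticNetLogistic(lam_best, a_best, max_iter=max(max_iter, 3000)).fit(Xs, y)
    return final, (a_best, lam_best), kappa, (mean, sd)


# ---------------------------------------------------------------------------
# metrics


def roc_auc(scores, labels) -> float:
    """ROC-AUC (Mann-Whitney with half-credit for ties)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC-AUC undefined for single-class labels")
    return float(roc_auc_score(labels, scores))


def pr_auc(scores, labels) -> float:
    """PR-AUC by step-wise interpolation (average precision)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("PR-AUC undefined for single-class labels")
    return float(average_precision_score(labels, scores))


# ---------------------------------------------------------------------------
# experiment harness


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    records: pd.DataFrame  # long: cutoff, feature_set, repeat, split, metric, value
    summary: pd.DataFrame  # mean + 95% CI per cutoff/feature_set/split/metric
    importance: pd.DataFrame  # mean importance per cutoff/feature_set/feature
    split_hashes: dict  # repeat -> hash of train membership (split-reuse audit)


def _split_membership(index, y, train_fraction, seed):
    sss = StratifiedShuffleSplit(n_splits=1, train_size=train_fraction,
                                 random_state=seed)
    tr, te = next(sss.split(np.zeros(len(y)), y))
    return np.sort(tr), np.sort(te)


def run_experiment(config: ExperimentConfig, feature_matrices: dict) -> ExperimentResult:
    """Run the repeated-holdout experiment.

    ``feature_matrices`` maps ``(cutoff, feature_set)`` -> FeatureMatrix
    (all cells must share the same subject roster).  Failures in a single
    cell/repeat are recorded as missing rows rather than aborting.
    """
    cells = [(c, fs) for c in config.cutoffs for fs in config.feature_sets]
    for cell in cells:
        if cell not in feature_matrices:
            raise ValueError(f"missing feature matrix for {cell}")
    ref = feature_matrices[cells[0]]
    index = ref.X.index
    y = ref.y.to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; nothing to train")
    for cell in cells:
        if not feature_matrices[cell].X.index.equals(index):
            raise ValueError(f"feature matrix {cell} has a different roster")
    rec_rows, imp_rows = [], []
    split_hashes = {}
    for r in range(config.n_repeats):
        seed = config.base_seed + r
        tr, te = _split_membership(index, y, config.train_fraction, seed)
        split_hashes[r] = hash(tr.tobytes())
        for cutoff, fs in cells:
            fm = feature_matrices[(cutoff, fs)]
            imp_params = fit_imputer(fm.X.iloc[tr], fm.numeric_columns,
                                     fm.categorical_columns)
            Xtr = apply_imputer(fm.X.iloc[tr], imp_params).to_numpy(dtype=float)
            Xte = apply_imputer(fm.X.iloc[te], imp_params).to_numpy(dtype=float)
            ytr, yte = y[tr], y[te]
            try:
                model, (a, lam), kappa, (mean, sd) = tune_and_fit(
                    Xtr, ytr, config.alpha_grid, config.lambda_grid,
                    config.cv_folds, seed)
            except ValueError as exc:
                rec_rows.append({"cutoff": cutoff, "feature_set": fs, "repeat": r,
                                 "split": "error", "metric": "error",
                                 "value": np.nan, "note": str(exc)})
                continue
            p_tr = model.predict_proba((Xtr - mean) / sd)
            p_te = model.predict_proba((Xte - mean) / sd)
            for split, scores, labels in [("in_train", p_tr, ytr),
                                          ("out_of_train", p_te, yte)]:
                for metric, fn in [("roc_auc", roc_auc), ("pr_auc", pr_auc)]:
                    rec_rows.append({"cutoff": cutoff, "feature_set": fs,
                                     "repeat": r, "split": split, "metric": metric,
                                     "value": fn(scores, labels), "note": ""})
            rec_rows.append({"cutoff": cutoff, "feature_set": fs, "repeat": r,
                             "split": "cv", "metric": "kappa", "value": kappa,
                             "note": f"alpha={a};lambda={lam}"})
            for feat, sc in zip(fm.X.columns, importance_scores(model.coef_)):
                imp_rows.append({"cutoff": cutoff, "feature_set": fs, "repeat": r,
                                 "feature": feat, "importance": sc})
    records = pd.DataFrame(rec_rows)
    summary = summarize_records(records, config.n_repeats)
    imp = pd.DataFrame(imp_rows)
    importance = variable_importance(imp) if not imp.empty else imp
    return ExperimentResult(config, records, summary, importance, split_hashes)


def summarize_records(records: pd.DataFrame, n_repeats: int) -> pd.DataFrame:
    """Mean and 95% t-CI over repeats; a single repeat gets a point CI."""
    metr = records[records["split"].isin(["in_train", "out_of_train"])]
    rows = []
    for (cutoff, fs, split, metric), g in metr.groupby(
            ["cutoff", "feature_set", "split", "metric"]):
        v = g["value"].dropna().to_numpy()
        n = len(v)
        mean = float(v.mean()) if n else np.nan
        if n > 1:
            half = float(stats.t.ppf(0.975, n - 1) * v.std(ddof=1) / np.sqrt(n))
        else:
            half = 0.0
        rows.append({"cutoff": cutoff, "feature_set": fs, "split": split,
                     "metric": metric, "mean": mean, "ci_low": mean - half,
                     "ci_high": mean + half, "n_repeats": n})
    return pd.DataFrame(rows)


def importance_scores(coef) -> np.ndarray:
    """|standardized coefficient| rescaled so the top feature scores 100;
    an all-zero coefficient vector maps to all-zero scores."""
    c = np.abs(np.asarray(coef, dtype=float))
    mx = c.max() if c.size else 0.0
    return c / mx * 100.0 if mx > 0 else np.zeros_like(c)


def variable_importance(imp_records: pd.DataFrame, flag_threshold: float = 40.0
                        ) -> pd.DataFrame:
    """Mean per-repeat importance (|standardized coefficient| rescaled so the
    top feature scores 100); features above the threshold are flagged."""
    out = (imp_records.groupby(["cutoff", "feature_set", "feature"])["importance"]
           .mean().reset_index(name="mean_importance"))
    out["important"] = out["mean_importance"] > flag_threshold
    return out.sort_values(["cutoff", "feature_set", "mean_importance"],
                           ascending=[True, True, False]).reset_index(drop=True)
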