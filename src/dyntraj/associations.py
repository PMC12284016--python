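"""Univariate association of trajectory-class membership with demographics
and stay characteristics.

Continuous covariates use one-way ANOVA by default (with two classes this is
exactly the pooled-variance two-sample t-test, F = t^2); Kruskal-Wallis is
available as an alternative.  Categorical covariates use Fisher's exact test,
with a seeded Monte-Carlo p-value (2000 fixed-margin tables) when the table
is larger than 2x2.  P-values are Benjamini-Hochberg adjusted within a
family (default: all covariates of one marker) and flagged at q < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "test_association",
    "adjust_fdr",
    "fisher_exact_mc",
    "class_covariate_associations",
    "plot_q_heatmap",
]


@dataclass
class AssociationResult:
    marker: str
    covariate: str
    test: str
    statistic: float
    p_value: float
    q_value: float = np.nan
    significant: bool = False
    testable: bool = True
    note: str = ""


def _table_logprob(table: np.ndarray) -> float:
    """Log hypergeometric probability of an r x c table given its margins."""
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return float(gammaln(r + 1).sum() + gammaln(c + 1).sum()
                 - gammaln(n + 1) - gammaln(table + 1).sum())


def fisher_exact_mc(table: np.ndarray, n_replicates: int = 2000,
                    seed: int = 0) -> float:
    """Monte-Carlo Fisher exact p for an r x c table.

    Samples tables with the observed margins by permuting one margin's
    labels, and counts tables at most as probable as the observed one —
    the same simulated p-value R's ``fisher.test`` reports.
    """
    table = np.asarray(table, dtype=int)
    rng = np.random.default_rng(seed)
    obs_lp = _table_logprob(table)
    rows = np.repeat(np.arange(table.shape[0]), table.sum(axis=1))
    cols = np.repeat(np.arange(table.shape[1]), table.sum(axis=0))
    hits = 0
    for _ in range(n_replicates):
        perm = rng.permutation(cols)
        t = np.zeros_like(table)
        np.add.at(t, (rows, perm), 1)
        if _table_logprob(t) <= obs_lp + 1e-9:
            hits += 1
    return (hits + 1) / (n_replicates + 1)


def test_association(class_labels, covariate, kind: str, marker: str = "",
                     covariate_name: str = "", continuous_test: str = "anova",
                     mc_replicates: int = 2000, seed: int = 0) -> AssociationResult:
    """Single class-vs-covariate test (p-value not yet FDR-adjusted).

    ``kind`` is "continuous" or "categorical".  Degenerate covariates
    (a single level or zero variance) are returned as untestable.
    """
    cls = np.asarray(class_labels)
    cov = np.asarray(covariate)
    ok = ~pd.isna(cov)
    cls, cov = cls[ok], cov[ok]
    ulab = np.unique(cls)
    sizes = [np.sum(cls == u) for u in ulab]
    if len(ulab) < 2 or min(sizes) < 2:
        return AssociationResult(marker, covariate_name, "none", np.nan, np.nan,
                                 testable=False, note="fewer than 2 classes with >= 2 members")
    if kind == "continuous":
        groups = [cov[cls == u].astype(float) for u in ulab]
        if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
            return AssociationResult(marker, covariate_name, "none", np.nan, np.nan,
                                     testable=False, note="zero variance")
        if continuous_test == "kruskal":
            stat, p = stats.kruskal(*groups)
            return AssociationResult(marker, covariate_name, "kruskal", float(stat), float(p))
        stat, p = stats.f_oneway(*groups)
        if not np.isfinite(stat):
            return AssociationResult(marker, covariate_name, "anova", np.nan, np.nan,
                                     testable=False, note="degenerate ANOVA")
        return AssociationResult(marker, covariate_name, "anova", float(stat), float(p))
    if kind != "categorical":
        raise ValueError(f"unknown covariate kind {kind!r}")
    tab = pd.crosstab(cls, cov).to_numpy()
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return AssociationResult(marker, covariate_name, "fisher", np.nan, np.nan,
                                 testable=False, note="single level")
    if tab.shape == (2, 2):
        _, p = stats.fisher_exact(tab)
        return AssociationResult(marker, covariate_name, "fisher", np.nan, float(p))
    p = fisher_exact_mc(tab, mc_replicates, seed)
    return AssociationResult(marker, covariate_name, "fisher_mc", np.nan, float(p))


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (running-minimum enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def class_covariate_associations(subjects: pd.DataFrame, map_classes: pd.DataFrame,
                                 covariates=None, family: str = "per_marker",
                                 continuous_test: str = "anova",
                                 q_threshold: float = 0.05, seed: int = 0
                                 ) -> pd.DataFrame:
    """Association battery over markers x covariates.

    ``map_classes``: columns subject_id, marker, map_class.  ``covariates``:
    list of (column, kind) pairs; defaults to the demographic and stay
    variables.  ``family``: "per_marker" adjusts within each marker,
    "global" over the whole grid.
    """
    if covariates is None:
        covariates = [("age", "continuous"), ("gender", "categorical"),
                      ("ethnicity", "categorical"), ("insurance", "categorical"),
                      ("group", "categorical"), ("length_of_stay", "continuous"),
                      ("died_in_hospital", "categorical")]
    s = subjects.set_index("subject_id")
    rows = []
    for mi, (marker, g) in enumerate(map_classes.groupby("marker")):
        cls = g.set_index("subject_id")["map_class"]
        common = cls.index.intersection(s.index)
        for ci, (cov, kind) in enumerate(covariates):
            res = test_association(cls.loc[common].to_numpy(),
                                   s.loc[common, cov].to_numpy(), kind,
                                   marker=marker, covariate_name=cov,
                                   continuous_test=continuous_test,
                                   seed=seed + 1000 * mi + ci)
            rows.append(res)
    df = pd.DataFrame([r.__dict__ for r in rows])
    df["q_value"] = np.nan
    if family == "per_marker":
        for marker, g in df.groupby("marker"):
            ok = g["testable"] & g["p_value"].notna()
            if ok.any():
                df.loc[g.index[ok], "q_value"] = adjust_fdr(g.loc[ok, "p_value"])
    elif family == "global":
        ok = df["testable"] & df["p_value"].notna()
        if ok.any():
            df.loc[ok, "q_value"] = adjust_fdr(df.loc[ok, "p_value"])
    else:
        raise ValueError(f"unknown family {family!r}")
    df["significant"] = df["q_value"] < q_threshold
    return df


def plot_q_heatmap(assoc: pd.DataFrame, q_threshold: float = 0.05, ax=None):
    """Marker x covariate heatmap of q-values; significant cells outlined."""
    import matplotlib.pyplot as plt

    pivot = assoc.pivot_table(index="marker", columns="covariate",
                              values="q_value", aggfunc="first")
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.8 * pivot.shape[1],
                                      1 + 0.5 * pivot.shape[0]))
    im = ax.imshow(pivot.to_numpy(), cmap="viridis_r", vmin=0, vmax=1, aspect="auto")
    ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=45, ha="right")
    ax.set_yticks(range(pivot.shape[0]), pivot.index)
    for i in range(pivot.shape[0]):
        for j in range(pivot.shape[1]):
            q = pivot.iloc[i, j]
            if np.isfinite(q) and q < q_threshold:
                ax.add_patch(plt.Rectangle((j - 0.5, i - 0.5), 1, 1, fill=False,
                                           edgecolor="red", lw=2))
    ax.figure.colorbar(im, ax=ax, label="q value")
    ax.set_title("Trajectory-class associations (BH-adjusted)")
    return ax
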