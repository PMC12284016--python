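"""Shared fixtures.

The heavier fixtures are session-scoped: a desk-scale outcome-linked cohort
with per-marker trajectory models fit at the true specification, and its
posterior-feature matrices over all cutoffs.  Several tests (dynamic
information gain, null control, importance recovery) reuse them.
"""

import warnings

import numpy as np
import pytest

import dyntraj as dt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_linear3_dataset(seed=1, n=300, sigma=1.0):
    """3-class, linear-link simulation with known classes: the standard
    parameter-recovery testbed (5-15 observations per subject)."""
    rng = np.random.default_rng(seed)
    basis = dt.TimeBasis("polynomial", 2)
    beta = np.array([[0.0, 0.30, -0.010],
                     [4.0, -0.20, 0.005],
                     [-4.0, 0.00, 0.020]])
    pi = np.array([0.45, 0.35, 0.20])
    series, classes = [], []
    for i in range(n):
        g = rng.choice(3, p=pi)
        classes.append(g)
        nobs = rng.integers(5, 16)
        t = np.sort(rng.uniform(0, 21, nobs))
        y = basis.design(t) @ beta[g] + rng.normal(0, sigma, nobs)
        series.append(dt.SubjectSeries(i, t, y))
    return series, np.array(classes), beta, pi, basis, sigma


@pytest.fixture(scope="session")
def linear3_dataset():
    return make_linear3_dataset(seed=1)


@pytest.fixture(scope="session")
def outcome_cohort():
    """Default desk-scale cohort, curated, with per-marker models fit at the
    generating specification, plus posterior/summary feature matrices for
    experiment I at every cutoff."""
    cfg = dt.default_cohort_config(7)
    subjects, labs, truth = dt.simulate_cohort(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clean, report, incl = dt.preprocess_labs(labs, top_k=6)
    kept = set(incl.loc[incl["included"], "subject_id"])
    ids = sorted(kept)
    subjects_kept = subjects[subjects["subject_id"].isin(kept)].reset_index(drop=True)
    models = {}
    for mk in cfg.markers:
        series = [s for s in dt.series_from_labs(clean, mk.marker_name, ids)
                  if len(s)]
        spec = dt.TrajectoryModelSpec(mk.marker_name, mk.n_classes, mk.basis,
                                      mk.link.family)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models[mk.marker_name] = dt.fit_trajectory_model(
                series, spec, dt.FitOptions(n_starts=2, max_iter=200, seed=0))
    fms = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for cutoff in (1, 3, 7, 14, 21):
            fms[(cutoff, "ppa")] = dt.build_feature_matrix(
                subjects_kept, models, clean, "I", cutoff, "ppa")
    return {
        "config": cfg, "subjects": subjects_kept, "labs": clean,
        "truth": truth, "models": models, "features": fms,
    }
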