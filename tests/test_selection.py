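import numpy as np
import pandas as pd
import pytest

import dyntraj as dt
from dyntraj.selection import (compute_criteria, criteria_frame,
                               enumerate_lcga_grid, refine_with_gmm,
                               select_shortlist)
from dyntraj.links import LinearLink
from dyntraj.trajectory import responsibilities

from conftest import make_linear3_dataset


def test_grid_sizes():
    assert len(enumerate_lcga_grid([f"m{i}" for i in range(20)])) == 900
    assert len(enumerate_lcga_grid(["m"], (1,), ("linear",), (1,))) == 1
    assert len(enumerate_lcga_grid([f"m{i}" for i in range(6)])) == 270


def test_grid_ordering_deterministic():
    specs = enumerate_lcga_grid(["a", "b"], (1, 2), ("linear", "beta"), (1, 2))
    keys = [(s.marker_name, s.n_classes, s.link_family, s.basis.degree)
            for s in specs]
    assert keys == sorted(keys, key=lambda k: (k[0], k[1],
                                               ("linear", "beta").index(k[2]), k[3]))
    assert all(s.random_effects == "none" for s in specs)


def _fit_small(series, G, seed=0):
    spec = dt.TrajectoryModelSpec("m", G, dt.TimeBasis("polynomial", 2), "linear")
    return dt.fit_trajectory_model(series, spec,
                                   dt.FitOptions(n_starts=2, max_iter=200, seed=seed))


def test_single_class_criteria(linear3_dataset):
    series = linear3_dataset[0][:60]
    model = _fit_small(series, 1)
    crit = compute_criteria(model, series)
    assert crit.entropy == 0.0
    assert np.isclose(crit.icl, crit.bic)
    assert np.allclose(crit.appa_per_class, 1.0)
    assert crit.min_class_size == len(series)


def test_half_half_posteriors_analytic_entropy(linear3_dataset):
    # two identical classes with equal priors: every posterior is exactly 0.5
    series = linear3_dataset[0][:50]
    basis = dt.TimeBasis("polynomial", 1)
    spec = dt.TrajectoryModelSpec("m", 2, basis, "linear")
    beta = np.array([[0.0, 0.1], [0.0, 0.1]])
    model = dt.FittedTrajectoryModel(spec, np.array([0.0]), beta, None, 1.0,
                                     LinearLink(0.0, 1.0), np.nan,
                                     dt.n_parameters(spec), True, len(series))
    model.loglik = dt.marginal_loglik(series, model)
    crit = compute_criteria(model, series)
    n = len(series)
    assert np.isclose(crit.entropy, n * np.log(2))
    assert np.isclose(crit.icl - crit.bic, 2 * n * np.log(2))
    # exact ties MAP-assign everyone to the first class; the emptied class
    # has no assignees so its APPA is recorded as missing
    assert crit.appa_per_class[0] == 0.5
    assert np.isnan(crit.appa_per_class[1])
    assert crit.min_class_size == 0


def test_well_separated_three_class_appa(linear3_dataset):
    series, *_ = linear3_dataset
    model = _fit_small(series, 3)
    crit = compute_criteria(model, series)
    assert np.nanmin(crit.appa_per_class) >= 0.9


def test_icl_at_least_bic(linear3_dataset):
    series, *_ = linear3_dataset
    for G in (1, 2, 3):
        crit = compute_criteria(_fit_small(series[:150], G), series[:150])
        assert crit.icl >= crit.bic - 1e-9


def test_bic_round_trip(linear3_dataset):
    series = linear3_dataset[0][:100]
    model = _fit_small(series, 2)
    crit = compute_criteria(model, series)
    recomputed = -2 * model.loglik + model.n_params * np.log(len(series))
    assert abs(crit.bic - recomputed) < 1e-9


def _row(marker, G, icl, bic, n_params, appa=0.9, size=50, **kw):
    return {"marker": marker, "n_classes": G, "link": "linear", "degree": 2,
            "random_effects": "none", "loglik": -100.0, "n_params": n_params,
            "converged": True, "bic": bic, "icl": icl, "min_appa": appa,
            "appa_per_class": "", "min_class_size": size, "entropy": 1.0,
            "valid": True, **kw}


def test_parsimony_rule_on_near_ties():
    crit = pd.DataFrame([_row("m", 3, 100.0, 95.0, 20),
                         _row("m", 2, 100.0, 95.0, 15)])
    shortlist, _ = select_shortlist(crit)
    assert shortlist["m"][0]["n_params"] == 15  # fewer parameters first


def test_constraints_filter_and_fallback():
    crit = pd.DataFrame([_row("m", 3, 90.0, 85.0, 20, appa=0.5),
                         _row("m", 2, 120.0, 110.0, 15, appa=0.9, size=5)])
    with pytest.warns(UserWarning, match="falling back"):
        shortlist, ranking = select_shortlist(crit)
    assert len(shortlist["m"]) == 1
    assert not ranking["passes_constraints"].any()
    # fallback picks the best-BIC model
    assert shortlist["m"][0]["bic"] == 85.0


def test_icl_window_keeps_near_ties_only():
    crit = pd.DataFrame([_row("m", 2, 100.0, 95.0, 15),
                         _row("m", 3, 104.0, 96.0, 20),
                         _row("m", 4, 120.0, 97.0, 25)])
    shortlist, _ = select_shortlist(crit)
    kept = {r["n_classes"] for r in shortlist["m"]}
    assert kept == {2, 3}


def make_re_dataset(re_sd, seed=0, n=150):
    rng = np.random.default_rng(seed)
    basis = dt.TimeBasis("polynomial", 1)
    series = []
    for i in range(n):
        g = int(rng.random() < 0.4)
        b0 = rng.normal(0, re_sd)
        t = np.sort(rng.uniform(0, 21, 8))
        y = (4.0 if g else 0.0) + 0.08 * t + b0 + rng.normal(0, 0.8, 8)
        series.append(dt.SubjectSeries(i, t, y))
    return series


def test_gmm_refit_beats_lcga_when_random_effects_present():
    series = make_re_dataset(re_sd=1.2, seed=4)
    opts = dt.FitOptions(n_starts=2, max_iter=80, seed=0, tol=1e-5)
    lcga_spec = dt.TrajectoryModelSpec("m", 2, dt.TimeBasis("polynomial", 2),
                                       "linear")
    lcga = dt.fit_trajectory_model(series, lcga_spec, opts)
    crit = compute_criteria(lcga, series)
    cframe = criteria_frame([(lcga_spec, lcga, crit)])
    shortlist, _ = select_shortlist(cframe, min_class_size=10)
    finals, log = refine_with_gmm(shortlist, {"m": series}, "intercept",
                                  opts, {("m", 2, "linear", 2): lcga})
    gmm = finals["m"]
    assert gmm.spec.random_effects == "intercept"
    assert gmm.spec.basis.kind == "natural_spline"
    # GMM nests LCGA: with real random effects it must fit better
    assert gmm.loglik > lcga.loglik
    # intercept variance mapped back to the observed scale (true value 1.44)
    d_observed = gmm.D[0, 0] * gmm.link.scale**2
    assert d_observed > 0.5


def test_gmm_recovers_null_random_effects():
    series = make_re_dataset(re_sd=0.0, seed=6)
    opts = dt.FitOptions(n_starts=2, max_iter=80, seed=0, tol=1e-5)
    spec = dt.TrajectoryModelSpec("m", 2, dt.TimeBasis("polynomial", 1),
                                  "linear", "intercept_slope")
    gmm = dt.fit_trajectory_model(series, spec, opts)
    assert np.all(np.diag(gmm.D) < 0.05 * gmm.sigma2)


def test_refine_survives_bad_cells(linear3_dataset):
    series = linear3_dataset[0][:50]
    shortlist = {"m": [dict(_row("m", 5, 100.0, 95.0, 30))]}  # 5 classes, 50 subjects
    finals, log = refine_with_gmm(shortlist, {"m": series},
                                  options=dt.FitOptions(n_starts=1, max_iter=10))
    assert len(log) == 1  # logged, not raised
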