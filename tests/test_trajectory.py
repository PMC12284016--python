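import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import logsumexp
from sklearn.metrics import adjusted_rand_score

import dyntraj as dt
from dyntraj.links import LinearLink, make_link
from dyntraj.trajectory import RE_DIMS, responsibilities

from conftest import make_linear3_dataset


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_loglik(series, model):
    """Dense-covariance mixture likelihood: explicit per-subject covariance
    assembly, scipy multivariate-normal density, explicit mixture sum and
    Jacobian.  Kept deliberately independent of the package's vectorized
    Woodbury implementation."""
    q = RE_DIMS[model.spec.random_effects]
    pi = model.pi
    total = 0.0
    for s in series:
        h, lj = model.link.transform(s.values)
        B = model.spec.basis.design(s.times)
        n = len(s)
        cov = model.sigma2 * np.eye(n)
        if q:
            Z = np.column_stack([np.ones(n), s.times][:q])
            cov = cov + Z @ model.D @ Z.T
        comps = [np.log(pi[g]) + stats.multivariate_normal.logpdf(
            h, mean=B @ model.beta[g], cov=cov) for g in range(model.n_classes)]
        total += logsumexp(comps) + lj.sum()
    return total


def random_small_model(rng, G, re_kind, link_family="linear"):
    basis = dt.TimeBasis("polynomial", int(rng.integers(1, 3)))
    series = []
    pool = rng.gamma(5, 2, 200) + 1
    for i in range(int(rng.integers(2, 6))):
        n = int(rng.integers(1, 5))
        t = np.sort(rng.uniform(0, 21, n))
        y = rng.choice(pool, n) + rng.normal(0, 0.5, n)
        series.append(dt.SubjectSeries(i, t, y))
    link = make_link(link_family, np.concatenate([s.values for s in series]))
    q = RE_DIMS[re_kind]
    D = None
    if q:
        A = rng.normal(0, 0.5, (q, q))
        D = A @ A.T + 0.1 * np.eye(q)
    pi = rng.dirichlet(np.ones(G) * 3)
    spec = dt.TrajectoryModelSpec("m", G, basis, link_family, re_kind)
    model = dt.FittedTrajectoryModel(
        spec=spec,
        class_logits=np.log(pi[:-1]) - np.log(pi[-1]),
        beta=rng.normal(0, 1, (G, basis.n_columns)),
        D=D, sigma2=float(rng.uniform(0.3, 2.0)), link=link,
        loglik=np.nan, n_params=dt.n_parameters(spec), converged=True,
        n_subjects=len(series))
    return series, model


def test_loglik_equals_iid_normal_closed_form(rng):
    # G=1, no random effects, identity link: plain iid Gaussian likelihood
    basis = dt.TimeBasis("polynomial", 1)
    series = [dt.SubjectSeries(i, np.sort(rng.uniform(0, 21, 4)),
                               rng.normal(0, 1, 4)) for i in range(6)]
    spec = dt.TrajectoryModelSpec("m", 1, basis, "linear")
    beta = np.array([[0.3, -0.05]])
    sigma2 = 1.7
    model = dt.FittedTrajectoryModel(spec, np.empty(0), beta, None, sigma2,
                                     LinearLink(0.0, 1.0), np.nan,
                                     dt.n_parameters(spec), True, len(series))
    expected = sum(stats.norm.logpdf(s.values, basis.design(s.times) @ beta[0],
                                     np.sqrt(sigma2)).sum() for s in series)
    assert np.isclose(dt.marginal_loglik(series, model), expected, atol=1e-10)


def test_degenerate_two_class_mixture_equals_single_class(rng):
    series, m1 = random_small_model(rng, 1, "none")
    spec2 = dt.TrajectoryModelSpec("m", 2, m1.spec.basis, "linear")
    m2 = dt.FittedTrajectoryModel(spec2, np.array([0.0]),
                                  np.vstack([m1.beta, m1.beta]), None,
                                  m1.sigma2, m1.link, np.nan,
                                  dt.n_parameters(spec2), True, m1.n_subjects)
    assert np.isclose(dt.marginal_loglik(series, m2),
                      dt.marginal_loglik(series, m1), atol=1e-10)


@pytest.mark.parametrize("re_kind", ["none", "intercept", "intercept_slope"])
@pytest.mark.parametrize("link_family", ["linear", "beta", "ispline"])
def test_loglik_matches_brute_force(re_kind, link_family, rng):
    for G in (1, 2):
        series, model = random_small_model(rng, G, re_kind, link_family)
        assert np.isclose(dt.marginal_loglik(series, model),
                          brute_force_loglik(series, model), atol=1e-8)


def test_random_intercept_matches_quadrature(rng):
    # G=1, one subject: marginal likelihood is a 1-D integral over the
    # random intercept
    basis = dt.TimeBasis("polynomial", 1)
    t = np.sort(rng.uniform(0, 21, 4))
    y = rng.normal(1.0, 1.0, 4)
    series = [dt.SubjectSeries(0, t, y)]
    spec = dt.TrajectoryModelSpec("m", 1, basis, "linear", "intercept")
    beta = np.array([[0.5, 0.05]])
    sigma2, d2 = 0.8, 1.3
    model = dt.FittedTrajectoryModel(spec, np.empty(0), beta,
                                     np.array([[d2]]), sigma2,
                                     LinearLink(0.0, 1.0), np.nan,
                                     dt.n_parameters(spec), True, 1)
    mu = basis.design(t) @ beta[0]

    def logf(b):
        return (stats.norm.logpdf(y, mu + b, np.sqrt(sigma2)).sum()
                + stats.norm.logpdf(b, 0, np.sqrt(d2)))

    bgrid = np.linspace(-10 * np.sqrt(d2), 10 * np.sqrt(d2), 1001)
    M = max(logf(b) for b in bgrid)
    val, _ = integrate.quad(lambda b: np.exp(logf(b) - M), bgrid[0], bgrid[-1],
                            epsabs=1e-13, epsrel=1e-12, limit=200)
    assert np.isclose(dt.marginal_loglik(series, model), np.log(val) + M,
                      atol=1e-6)


# ---------------------------------------------------------------------------
# fitting


def test_noise_free_fixed_effect_recovery():
    rng = np.random.default_rng(0)
    basis = dt.TimeBasis("polynomial", 2)
    beta_true = np.array([1.5, -0.2, 0.01])
    series = []
    for i in range(40):
        t = np.sort(rng.uniform(0, 21, 6))
        y = basis.design(t) @ beta_true + rng.normal(0, 1e-8, 6)
        series.append(dt.SubjectSeries(i, t, y))
    spec = dt.TrajectoryModelSpec("m", 1, basis, "linear")
    model = dt.fit_trajectory_model(series, spec,
                                    dt.FitOptions(n_starts=1, max_iter=50))
    # map the latent-scale coefficients back to the observed scale
    recovered = model.beta[0] * model.link.scale
    recovered[0] += model.link.loc
    assert np.max(np.abs(recovered - beta_true)) < 1e-3


def test_well_separated_two_class_perfect_recovery():
    rng = np.random.default_rng(5)
    basis = dt.TimeBasis("polynomial", 1)
    truth = []
    series = []
    for i in range(200):
        g = int(rng.random() < 0.4)
        truth.append(g)
        t = np.sort(rng.uniform(0, 21, 8))
        y = (6.0 if g else 0.0) + 0.1 * t + rng.normal(0, 1.0, 8)
        series.append(dt.SubjectSeries(i, t, y))
    spec = dt.TrajectoryModelSpec("m", 2, basis, "linear")
    model = dt.fit_trajectory_model(series, spec, dt.FitOptions(n_starts=2, seed=1))
    R = responsibilities(series, model)
    assert adjusted_rand_score(truth, R.argmax(axis=1)) == 1.0


def test_three_class_recovery_proportions_and_curves(linear3_dataset):
    series, classes, beta_true, pi_true, basis, sigma = linear3_dataset
    spec = dt.TrajectoryModelSpec("m", 3, basis, "linear")
    model = dt.fit_trajectory_model(series, spec,
                                    dt.FitOptions(n_starts=3, max_iter=300, seed=0))
    assert model.converged
    R = responsibilities(series, model)
    ari = adjusted_rand_score(classes, R.argmax(axis=1))
    assert ari >= 0.8
    # match fitted classes to truth by posterior vote, compare curves on a grid
    tgrid = np.linspace(0, 21, 43)
    fitted = model.link.inverse((basis.design(tgrid) @ model.beta.T).T.ravel()).reshape(3, -1)
    for g in range(3):
        members = np.flatnonzero(classes == g)
        fitted_class = np.bincount(R.argmax(axis=1)[members], minlength=3).argmax()
        true_curve = basis.design(tgrid) @ beta_true[g]
        rmse = np.sqrt(np.mean((fitted[fitted_class] - true_curve) ** 2))
        assert rmse < 0.15 * sigma
        est_prop = model.pi[fitted_class]
        assert abs(est_prop - pi_true[g]) < 0.05


def test_seeded_determinism(linear3_dataset):
    series = linear3_dataset[0][:80]
    spec = dt.TrajectoryModelSpec("m", 2, dt.TimeBasis("polynomial", 1), "linear")
    opts = dt.FitOptions(n_starts=2, max_iter=60, seed=9)
    m1 = dt.fit_trajectory_model(series, spec, opts)
    m2 = dt.fit_trajectory_model(series, spec, opts)
    assert np.array_equal(m1.beta, m2.beta)
    assert m1.sigma2 == m2.sigma2
    assert np.array_equal(m1.class_logits, m2.class_logits)


def test_affine_rescaling_shifts_loglik_by_jacobian(linear3_dataset):
    # y -> a*y + c changes the maximized linear-link log-likelihood by
    # exactly -n*log(a)
    series = linear3_dataset[0][:60]
    a, c = 3.7, -12.0
    scaled = [dt.SubjectSeries(s.subject_id, s.times, a * s.values + c)
              for s in series]
    spec = dt.TrajectoryModelSpec("m", 2, dt.TimeBasis("polynomial", 1), "linear")
    opts = dt.FitOptions(n_starts=2, max_iter=150, seed=2)
    m1 = dt.fit_trajectory_model(series, spec, opts)
    m2 = dt.fit_trajectory_model(scaled, spec, opts)
    n = sum(len(s) for s in series)
    assert np.isclose(m2.loglik - m1.loglik, -n * np.log(a), atol=1e-6)


# ---------------------------------------------------------------------------
# posteriors


def test_single_class_posterior_is_one(linear3_dataset):
    series = linear3_dataset[0][:30]
    spec = dt.TrajectoryModelSpec("m", 1, dt.TimeBasis("polynomial", 1), "linear")
    model = dt.fit_trajectory_model(series, spec, dt.FitOptions(n_starts=1))
    for cutoff in (1, 7, 21):
        pa = dt.posterior_probabilities(series[0], model, cutoff)
        assert pa.probabilities.shape == (1,) and pa.probabilities[0] == 1.0
        assert pa.map_class == 1


def test_empty_window_falls_back_to_prior(rng):
    series, model = random_small_model(rng, 2, "none")
    late = dt.SubjectSeries("x", np.array([15.0, 18.0]), np.array([8.0, 9.0]))
    pa = dt.posterior_probabilities(late, model, 1.0)
    assert np.allclose(pa.probabilities, model.pi)


def test_two_class_single_observation_bayes_rule():
    basis = dt.TimeBasis("polynomial", 1)
    spec = dt.TrajectoryModelSpec("m", 2, basis, "linear")
    beta = np.array([[0.0, 0.0], [3.0, 0.0]])
    pi1 = 0.3
    model = dt.FittedTrajectoryModel(
        spec, np.array([np.log(pi1 / (1 - pi1))]), beta, None, 1.0,
        LinearLink(0.0, 1.0), np.nan, dt.n_parameters(spec), True, 10)
    y0, t0 = 1.0, 2.0
    pa = dt.posterior_probabilities(
        dt.SubjectSeries("s", np.array([t0]), np.array([y0])), model, 7.0)
    f1 = pi1 * stats.norm.pdf(y0, 0.0, 1.0)
    f2 = (1 - pi1) * stats.norm.pdf(y0, 3.0, 1.0)
    assert np.isclose(pa.probabilities[0], f1 / (f1 + f2), atol=1e-10)


def test_posterior_normalization_property(outcome_cohort):
    labs = outcome_cohort["labs"]
    for marker, model in outcome_cohort["models"].items():
        series = dt.series_from_labs(labs, marker)[:25]
        for cutoff in (1, 7, 21):
            for s in series:
                pa = dt.posterior_probabilities(s, model, cutoff)
                assert abs(pa.probabilities.sum() - 1.0) < 1e-10
                assert pa.map_class == int(np.argmax(pa.probabilities)) + 1


# ---------------------------------------------------------------------------
# bookkeeping


def test_parameter_counts():
    poly3 = dt.TimeBasis("polynomial", 3)
    lcga = dt.TrajectoryModelSpec("m", 3, poly3, "linear")
    assert dt.n_parameters(lcga) == 17  # 2 + 12 + 0 + 1 + 2
    gmm = dt.TrajectoryModelSpec("m", 2, dt.TimeBasis("natural_spline", 3, (7.0, 14.0)),
                                 "linear", "intercept_slope")
    assert dt.n_parameters(gmm) == 15  # 1 + 8 + 3 + 1 + 2
    # one more class always costs (d+1) + 1 parameters
    for spec in (lcga, gmm):
        bigger = dt.TrajectoryModelSpec(spec.marker_name, spec.n_classes + 1,
                                        spec.basis, spec.link_family,
                                        spec.random_effects)
        assert (dt.n_parameters(bigger) - dt.n_parameters(spec)
                == spec.basis.n_columns + 1)


def test_model_serialization_round_trip(tmp_path, linear3_dataset):
    series = linear3_dataset[0][:40]
    spec = dt.TrajectoryModelSpec("m", 2, dt.TimeBasis("polynomial", 1), "linear")
    model = dt.fit_trajectory_model(series, spec, dt.FitOptions(n_starts=1))
    path = tmp_path / "model.json"
    model.save(path)
    clone = dt.FittedTrajectoryModel.load(path)
    assert np.isclose(dt.marginal_loglik(series, clone), model.loglik, atol=1e-9)
    assert clone.spec == model.spec
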