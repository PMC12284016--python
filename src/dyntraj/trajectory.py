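"""Latent-class trajectory models for longitudinal lab markers.

Model
-----
For subject ``i`` in latent class ``g`` the marker follows a latent Gaussian
process on the link scale:

    H(y_ij) = B(t_ij)' beta_g + Z(t_ij)' b_i + eps_ij,
    b_i ~ N(0, D),   eps_ij ~ N(0, sigma^2),

with class membership an intercept-only multinomial logit (prior ``pi_g``).
``H`` is a monotone link (see :mod:`dyntraj.links`); its Jacobian enters the
observed-data likelihood so that fits with different links are comparable:

    logL = sum_i log sum_g pi_g N(H(y_i); B_i beta_g, Z_i D Z_i' + sigma^2 I)
           + sum_ij log H'(y_ij).

``random_effects='none'`` gives latent class growth analysis (LCGA);
``'intercept'`` / ``'intercept_slope'`` give growth mixture models (GMM).
``D`` is shared across classes.

Estimation is EM over class responsibilities with a closed-form weighted-GLS
M-step for ``(pi, beta)`` and an L-BFGS sub-step for ``(sigma^2, D, link)``
under log/Cholesky parametrizations, multi-started (one k-means start on
per-subject OLS summaries plus random starts).  Classes are canonicalized by
descending MAP-assigned count (ties by fitted level at t=0) so that class
labels — and the feature columns built from them — are stable across refits.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .basis import TimeBasis
from .links import BetaLink, link_from_dict, make_link

__all__ = [
    "SubjectSeries",
    "TrajectoryModelSpec",
    "FittedTrajectoryModel",
    "PosteriorAssignment",
    "FitOptions",
    "fit_trajectory_model",
    "marginal_loglik",
    "posterior_probabilities",
    "responsibilities",
    "n_parameters",
    "series_from_labs",
]

RE_DIMS = {"none": 0, "intercept": 1, "intercept_slope": 2}
_LINK_PARAM_COUNT = {"linear": 2, "ispline": 6, "beta": 4}
_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class SubjectSeries:
    """One subject's observation times (days) and values for one marker."""

    subject_id: object
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) < 0):
            order = np.argsort(self.times, kind="stable")
            self.times = self.times[order]
            self.values = self.values[order]
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values for subject {self.subject_id!r}")

    def truncated(self, cutoff_day: float) -> "SubjectSeries":
        m = self.times <= cutoff_day
        return SubjectSeries(self.subject_id, self.times[m], self.values[m])

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class TrajectoryModelSpec:
    marker_name: str
    n_classes: int
    basis: TimeBasis
    link_family: str
    random_effects: str = "none"

    def __post_init__(self):
        if not (1 <= self.n_classes <= 5):
            raise ValueError("n_classes must be in 1..5")
        if self.random_effects not in RE_DIMS:
            raise ValueError(f"unknown random_effects {self.random_effects!r}")
        if self.link_family not in _LINK_PARAM_COUNT:
            raise ValueError(f"unknown link family {self.link_family!r}")

    @property
    def is_lcga(self) -> bool:
        return self.random_effects == "none"

    def to_dict(self) -> dict:
        return {
            "marker_name": self.marker_name,
            "n_classes": int(self.n_classes),
            "basis": self.basis.to_dict(),
            "link_family": self.link_family,
            "random_effects": self.random_effects,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrajectoryModelSpec":
        return cls(d["marker_name"], d["n_classes"], TimeBasis.from_dict(d["basis"]),
                   d["link_family"], d.get("random_effects", "none"))


def n_parameters(spec: TrajectoryModelSpec) -> int:
    """Free-parameter count.

    Convention: (G-1) class-membership logits + G*(d+1) fixed effects +
    q(q+1)/2 random-effect covariance terms (0 for LCGA) + 1 residual
    variance + link parameters (linear 2, I-spline 6, beta 4).
    """
    G = spec.n_classes
    p = spec.basis.n_columns
    q = RE_DIMS[spec.random_effects]
    return (G - 1) + G * p + q * (q + 1) // 2 + 1 + _LINK_PARAM_COUNT[spec.link_family]


@dataclass
class PosteriorAssignment:
    subject_id: object
    cutoff_day: float
    probabilities: np.ndarray  # length G, sums to 1
    map_class: int  # 1-based; argmax, ties -> lowest index

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)


@dataclass
class FitOptions:
    n_starts: int = 5
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0
    inner_iters: int = 10  # L-BFGS iterations of the variance/link sub-step


@dataclass
class FittedTrajectoryModel:
    spec: TrajectoryModelSpec
    class_logits: np.ndarray  # length G-1, class G is reference
    beta: np.ndarray  # (G, d+1)
    D: np.ndarray | None  # (q, q) shared across classes; None for LCGA
    sigma2: float
    link: object
    loglik: float
    n_params: int
    converged: bool
    n_subjects: int
    notes: str = ""

    @property
    def pi(self) -> np.ndarray:
        z = np.r_[self.class_logits, 0.0]
        z = z - z.max()
        e = np.exp(z)
        return e / e.sum()

    @property
    def n_classes(self) -> int:
        return self.spec.n_classes

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "class_logits": np.asarray(self.class_logits).tolist(),
            "beta": np.asarray(self.beta).tolist(),
            "D": None if self.D is None else np.asarray(self.D).tolist(),
            "sigma2": float(self.sigma2),
            "link": self.link.to_dict(),
            "loglik": float(self.loglik),
            "n_params": int(self.n_params),
            "converged": bool(self.converged),
            "n_subjects": int(self.n_subjects),
            "notes": self.notes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedTrajectoryModel":
        return cls(
            spec=TrajectoryModelSpec.from_dict(d["spec"]),
            class_logits=np.asarray(d["class_logits"], dtype=float),
            beta=np.asarray(d["beta"], dtype=float),
            D=None if d["D"] is None else np.asarray(d["D"], dtype=float),
            sigma2=d["sigma2"],
            link=link_from_dict(d["link"]),
            loglik=d["loglik"],
            n_params=d["n_params"],
            converged=d["converged"],
            n_subjects=d["n_subjects"],
            notes=d.get("notes", ""),
        )

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "FittedTrajectoryModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# stacked data container


class _Stacked:
    """All subjects' observations concatenated, with per-subject precomputes."""

    def __init__(self, series, basis: TimeBasis, re_kind: str):
        if len(series) == 0:
            raise ValueError("no subjects")
        for s in series:
            if len(s) == 0:
                raise ValueError(f"subject {s.subject_id!r} has no observations")
        self.series = series
        self.n_sub = len(series)
        counts = np.array([len(s) for s in series])
        self.counts = counts
        self.starts = np.r_[0, np.cumsum(counts)[:-1]]
        self.t = np.concatenate([s.times for s in series])
        self.y = np.concatenate([s.values for s in series])
        self.N = self.t.size
        self.B = basis.design(self.t)
        self.p = self.B.shape[1]
        q = RE_DIMS[re_kind]
        self.q = q
        if q:
            cols = [np.ones_like(self.t)]
            if q == 2:
                cols.append(self.t)
            self.Z = np.column_stack(cols)
            self.ZtZ = self._segouter(self.Z, self.Z)  # (n, q, q)
            self.BtZ = self._segouter(self.B, self.Z)  # (n, p, q)
        else:
            self.Z = None
        self.BtB = self._segouter(self.B, self.B)  # (n, p, p)

    def _segouter(self, X, Y):
        prod = X[:, :, None] * Y[:, None, :]
        return np.add.reduceat(prod, self.starts, axis=0)

    def segsum(self, x, axis=0):
        return np.add.reduceat(x, self.starts, axis=axis)


def _transform_all(data: _Stacked, link, marker=""):
    if isinstance(link, BetaLink):
        return link.transform(data.y, marker)
    return link.transform(data.y)


def _chol_from_theta(theta, q):
    """Lower Cholesky from unconstrained vector: log-diagonals then
    below-diagonal entries row-major."""
    L = np.zeros((q, q))
    L[np.diag_indices(q)] = np.exp(theta[:q])
    if q > 1:
        idx = np.tril_indices(q, -1)
        L[idx] = theta[q:]
    return L


def _theta_from_D(D):
    q = D.shape[0]
    jitter = 0
    while True:
        try:
            L = np.linalg.cholesky(D + jitter * np.eye(q))
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-10 * max(np.trace(D) / q, 1.0))
    theta = np.log(np.maximum(np.diag(L), 1e-8))
    if q > 1:
        theta = np.r_[theta, L[np.tril_indices(q, -1)]]
    return theta


def _class_loglik_matrix(data: _Stacked, h, beta, D, sigma2):
    """Per-subject, per-class Gaussian log-density of the link-scale data
    (Jacobian excluded).  Shape (n_sub, G)."""
    G = beta.shape[0]
    n = data.n_sub
    if sigma2 <= 0 or not np.isfinite(sigma2):
        raise FloatingPointError("non-positive residual variance")
    if data.q == 0:
        resid = h[:, None] - data.B @ beta.T  # (N, G)
        rss = data.segsum(resid * resid)  # (n, G)
        return -0.5 * (data.counts[:, None] * (_LOG2PI + np.log(sigma2)) + rss / sigma2)
    q = data.q
    Iq = np.eye(q)
    DA = np.einsum("ab,ibc->iac", D, data.ZtZ)  # (n, q, q)
    M = sigma2 * Iq[None] + DA
    # S_i = (sigma^2 I + D A_i)^{-1} D  gives  Sigma_i^{-1} = (I - Z S Z')/sigma^2
    S = np.linalg.solve(M, np.broadcast_to(D, (n, q, q)).copy())
    sign, logdet_small = np.linalg.slogdet(Iq[None] + DA / sigma2)
    if np.any(sign <= 0):
        raise FloatingPointError("covariance not positive definite")
    logdet = data.counts * np.log(sigma2) + logdet_small
    out = np.empty((n, G))
    for g in range(G):
        r = h - data.B @ beta[g]
        rtr = data.segsum(r * r)
        c = data.segsum(data.Z * r[:, None])  # (n, q)
        quad = (rtr - np.einsum("iq,iqr,ir->i", c, S, c)) / sigma2
        out[:, g] = -0.5 * (data.counts * _LOG2PI + logdet + quad)
    return out


def _loglik_from_matrix(L, pi, logjac_total):
    lw = L + np.log(np.maximum(pi, 1e-300))[None, :]
    return float(logsumexp(lw, axis=1).sum() + logjac_total)


def _responsibilities(L, pi):
    lw = L + np.log(np.maximum(pi, 1e-300))[None, :]
    lw = lw - logsumexp(lw, axis=1, keepdims=True)
    return np.exp(lw)


def marginal_loglik(series, model: FittedTrajectoryModel) -> float:
    """Observed-data log-likelihood of ``series`` under ``model``."""
    data = _Stacked(series, model.spec.basis, model.spec.random_effects)
    h, logjac = _transform_all(data, model.link, model.spec.marker_name)
    L = _class_loglik_matrix(data, h, np.asarray(model.beta, dtype=float),
                             model.D, model.sigma2)
    ll = _loglik_from_matrix(L, model.pi, float(np.sum(logjac)))
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite log-likelihood")
    return ll


def responsibilities(series, model: FittedTrajectoryModel) -> np.ndarray:
    """Posterior class probabilities on the full series, shape (n_sub, G)."""
    data = _Stacked(series, model.spec.basis, model.spec.random_effects)
    h, _ = _transform_all(data, model.link, model.spec.marker_name)
    L = _class_loglik_matrix(data, h, np.asarray(model.beta, dtype=float),
                             model.D, model.sigma2)
    return _responsibilities(L, model.pi)


# ---------------------------------------------------------------------------
# fitting


def _initial_responsibilities(data: _Stacked, h, G, mode, rng, seed):
    n = data.n_sub
    if G == 1:
        return np.ones((n, 1))
    if mode == "kmeans":
        feats = np.empty((n, 2))
        for i, (s0, c) in enumerate(zip(data.starts, data.counts)):
            hs = h[s0:s0 + c]
            ts = data.t[s0:s0 + c]
            if c >= 2 and np.ptp(ts) > 0:
                slope, intc = np.polyfit(ts, hs, 1)
                feats[i] = (intc, slope)
            else:
                feats[i] = (hs.mean(), 0.0)
        sd = feats.std(axis=0)
        sd[sd == 0] = 1.0
        feats = (feats - feats.mean(axis=0)) / sd
        km = KMeans(n_clusters=G, n_init=3, random_state=seed)
        labels = km.fit_predict(feats)
    else:
        labels = rng.integers(0, G, size=n)
        # guarantee every class is seeded
        for g in range(G):
            if not np.any(labels == g):
                labels[rng.integers(0, n)] = g
    R = np.full((n, G), 0.05 / max(G - 1, 1))
    R[np.arange(n), labels] = 0.95
    return R / R.sum(axis=1, keepdims=True)


def _mstep_pi_beta(data: _Stacked, h, R, D, sigma2):
    n, G = R.shape
    pi = R.mean(axis=0)
    p = data.p
    beta = np.empty((G, p))
    Bth = data.segsum(data.B * h[:, None])  # (n, p)
    if data.q == 0:
        for g in range(G):
            XtX = np.einsum("i,ipq->pq", R[:, g], data.BtB)
            Xty = np.einsum("i,ip->p", R[:, g], Bth)
            beta[g] = _solve_psd(XtX, Xty)
        return pi, beta
    q = data.q
    Iq = np.eye(q)
    DA = np.einsum("ab,ibc->iac", D, data.ZtZ)
    S = np.linalg.solve(sigma2 * Iq[None] + DA, np.broadcast_to(D, (n, q, q)).copy())
    Zth = data.segsum(data.Z * h[:, None])  # (n, q)
    # B' Sigma^{-1} B = (B'B - B'Z S Z'B)/sigma^2  (sigma^2 cancels in GLS)
    BtZS = np.einsum("ipq,iqr->ipr", data.BtZ, S)
    XtX_i = data.BtB - np.einsum("ipr,iqr->ipq", BtZS, data.BtZ)
    Xty_i = Bth - np.einsum("ipr,ir->ip", BtZS, Zth)
    for g in range(G):
        XtX = np.einsum("i,ipq->pq", R[:, g], XtX_i)
        Xty = np.einsum("i,ip->p", R[:, g], Xty_i)
        beta[g] = _solve_psd(XtX, Xty)
    return pi, beta


def _solve_psd(A, b):
    try:
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * np.trace(A) / A.shape[0]
        return np.linalg.solve(A + jitter * np.eye(A.shape[0]), b)


def _pack_psi(sigma2, D, link, q):
    psi = [np.log(sigma2)]
    if q:
        psi.extend(_theta_from_D(D))
    psi.extend(link.free_params())
    return np.array(psi)


def _unpack_psi(psi, link0, q):
    sigma2 = float(np.exp(np.clip(psi[0], -30, 30)))
    k = 1
    D = None
    if q:
        nD = q * (q + 1) // 2
        L = _chol_from_theta(psi[k:k + nD], q)
        D = L @ L.T
        k += nD
    link = link0.with_free(psi[k:]) if link0.n_free else link0
    return sigma2, D, link


def fit_trajectory_model(series, spec: TrajectoryModelSpec,
                         options: FitOptions | None = None) -> FittedTrajectoryModel:
    """Maximum-likelihood fit by multi-start EM.

    The best start by final log-likelihood is retained.  ``converged`` is
    true iff the relative log-likelihood change fell below ``options.tol``
    and no class prior collapsed below ``1/(10 n_subjects)``.
    """
    opts = options or FitOptions()
    data = _Stacked(series, spec.basis, spec.random_effects)
    n = data.n_sub
    G = spec.n_classes
    if n < 20 * G:
        warnings.warn(
            f"{spec.marker_name}: {n} subjects for {G} classes "
            f"(>= {20 * G} recommended)", stacklevel=2)
    link0 = make_link(spec.link_family, data.y)
    rng = np.random.default_rng(opts.seed)
    q = data.q

    best = None
    notes = []
    for start in range(opts.n_starts):
        mode = "kmeans" if start == 0 else "random"
        try:
            result = _fit_one_start(data, spec, link0, mode, rng, opts, start)
        except (np.linalg.LinAlgError, FloatingPointError, ValueError) as exc:
            notes.append(f"start {start}: failed ({exc})")
            continue
        if result["collapsed"]:
            notes.append(f"start {start}: class prior collapsed")
        if best is None or result["loglik"] > best["loglik"]:
            best = result
    if best is None:
        raise RuntimeError(
            f"all {opts.n_starts} starts failed for {spec.marker_name} "
            f"(G={G}, link={spec.link_family}); diagnostics: {notes}")

    pi, beta, D, sigma2, link = (best["pi"], best["beta"], best["D"],
                                 best["sigma2"], best["link"])
    converged = best["em_converged"] and not best["collapsed"]
    # canonical class order: descending MAP count, ties by fitted level at t=0
    h, logjac = _transform_all(data, link, spec.marker_name)
    L = _class_loglik_matrix(data, h, beta, D, sigma2)
    R = _responsibilities(L, pi)
    order = _canonical_order(R, beta, spec.basis)
    pi, beta, R = pi[order], beta[order], R[:, order]
    logits = np.log(np.maximum(pi[:-1], 1e-300)) - np.log(max(pi[-1], 1e-300))
    ll = _loglik_from_matrix(L[:, order], pi, float(np.sum(logjac)))
    return FittedTrajectoryModel(
        spec=spec, class_logits=logits, beta=beta, D=D, sigma2=sigma2,
        link=link, loglik=ll, n_params=n_parameters(spec), converged=converged,
        n_subjects=n, notes="; ".join(notes))


def _canonical_order(R, beta, basis: TimeBasis):
    G = R.shape[1]
    counts = np.bincount(R.argmax(axis=1), minlength=G)
    level0 = (basis.design(np.array([0.0])) @ beta.T).ravel()
    return np.lexsort((level0, -counts))


def _fit_one_start(data: _Stacked, spec, link0, mode, rng, opts: FitOptions, start):
    G = spec.n_classes
    q = data.q
    link = link0
    h, logjac = _transform_all(data, link, spec.marker_name)
    logjac_total = float(np.sum(logjac))
    var_h = float(np.var(h)) or 1.0
    sigma2 = var_h
    D = None
    if q:
        diag = [0.2 * var_h, 0.02 * var_h][:q]
        D = np.diag(diag)
    R = _initial_responsibilities(data, h, G, mode, rng, opts.seed + start)
    closed_form_var = (q == 0 and link0.n_free == 0)
    floor = 1.0 / (10.0 * data.n_sub)
    prev_ll = -np.inf
    em_converged = False
    collapsed = False
    pi = np.full(G, 1.0 / G)
    beta = np.zeros((G, data.p))
    for it in range(opts.max_iter):
        pi, beta = _mstep_pi_beta(data, h, R, D, sigma2)
        if np.min(pi) < floor:
            collapsed = True
        if closed_form_var:
            resid = h[:, None] - data.B @ beta.T
            rss = data.segsum(resid * resid)
            sigma2 = float(np.sum(R * rss) / data.N)
            sigma2 = max(sigma2, 1e-12 * var_h, 1e-300)
        else:
            psi0 = _pack_psi(sigma2, D, link, q)

            def negll(psi):
                s2, Dm, lk = _unpack_psi(psi, link, q)
                if lk is link:
                    hh, jac_tot = h, logjac_total
                else:
                    try:
                        hh, jac = _transform_all(data, lk, spec.marker_name)
                    except ValueError:
                        return 1e12
                    jac_tot = float(np.sum(jac))
                try:
                    Lm = _class_loglik_matrix(data, hh, beta, Dm, s2)
                except FloatingPointError:
                    return 1e12
                val = _loglik_from_matrix(Lm, pi, jac_tot)
                return 1e12 if not np.isfinite(val) else -val

            res = optimize.minimize(negll, psi0, method="L-BFGS-B",
                                    options={"maxiter": opts.inner_iters})
            psi = res.x if np.isfinite(res.fun) and res.fun < negll(psi0) + 1e-9 else psi0
            sigma2, D, link = _unpack_psi(psi, link, q)
            h, logjac = _transform_all(data, link, spec.marker_name)
            logjac_total = float(np.sum(logjac))
        L = _class_loglik_matrix(data, h, beta, D, sigma2)
        ll = _loglik_from_matrix(L, pi, logjac_total)
        R = _responsibilities(L, pi)
        if np.isfinite(prev_ll):
            rel = abs(ll - prev_ll) / (abs(prev_ll) + 1.0)
            if rel < opts.tol:
                em_converged = True
                prev_ll = ll
                break
        prev_ll = ll
    return {
        "pi": pi, "beta": beta, "D": D, "sigma2": sigma2, "link": link,
        "loglik": prev_ll, "em_converged": em_converged,
        "collapsed": collapsed or bool(np.min(pi) < floor),
    }


# ---------------------------------------------------------------------------
# posterior class membership


def posterior_matrix(series_list, model: FittedTrajectoryModel,
                     cutoff_day: float) -> np.ndarray:
    """Batched :func:`posterior_probabilities`: posterior class-membership
    matrix (n_subjects, G) using observations at ``t <= cutoff`` only.
    Subjects with empty windows get the model's prior row."""
    if not (0.0 < cutoff_day <= 21.0):
        raise ValueError("cutoff_day must be in (0, 21]")
    pi = model.pi
    out = np.tile(pi, (len(series_list), 1))
    truncated, keep_idx = [], []
    for i, s in enumerate(series_list):
        sub = s.truncated(cutoff_day)
        if len(sub) == 0:
            continue
        if isinstance(model.link, BetaLink):
            sub = SubjectSeries(sub.subject_id, sub.times,
                                model.link.clip_to_domain(sub.values))
        truncated.append(sub)
        keep_idx.append(i)
    if truncated:
        data = _Stacked(truncated, model.spec.basis, model.spec.random_effects)
        h, _ = _transform_all(data, model.link, model.spec.marker_name)
        L = _class_loglik_matrix(data, h, np.asarray(model.beta, dtype=float),
                                 model.D, model.sigma2)
        out[np.array(keep_idx)] = _responsibilities(L, pi)
    return out


def posterior_probabilities(series: SubjectSeries, model: FittedTrajectoryModel,
                            cutoff_day: float) -> PosteriorAssignment:
    """Posterior class membership using only observations at ``t <= cutoff``.

    The link Jacobian is identical across classes and cancels.  An empty
    window falls back to the model's prior class probabilities.  Values
    outside a bounded link's domain (possible when applying a frozen model
    to an external cohort) are pulled to the domain edge first.
    """
    if not (0.0 < cutoff_day <= 21.0):
        raise ValueError("cutoff_day must be in (0, 21]")
    sub = series.truncated(cutoff_day)
    pi = model.pi
    if len(sub) == 0:
        probs = pi.copy()
        return PosteriorAssignment(series.subject_id, cutoff_day, probs,
                                   int(np.argmax(probs)) + 1)
    values = sub.values
    if isinstance(model.link, BetaLink):
        values = model.link.clip_to_domain(values)
        sub = SubjectSeries(sub.subject_id, sub.times, values)
    data = _Stacked([sub], model.spec.basis, model.spec.random_effects)
    h, _ = _transform_all(data, model.link, model.spec.marker_name)
    L = _class_loglik_matrix(data, h, np.asarray(model.beta, dtype=float),
                             model.D, model.sigma2)
    probs = _responsibilities(L, pi)[0]
    return PosteriorAssignment(series.subject_id, cutoff_day, probs,
                               int(np.argmax(probs)) + 1)


# ---------------------------------------------------------------------------
# convenience


def series_from_labs(labs, marker: str, subject_ids=None) -> list:
    """Build per-subject series for one marker from a long lab-event table
    (columns: subject_id, day, marker, value).

    ``subject_ids`` fixes the roster and ordering; subjects without events
    for this marker get an empty series.
    """
    sub = labs[labs["marker"] == marker]
    grouped = {sid: g for sid, g in sub.groupby("subject_id")}
    if subject_ids is None:
        subject_ids = sorted(grouped)
    out = []
    for sid in subject_ids:
        g = grouped.get(sid)
        if g is None:
            out.append(SubjectSeries(sid, np.empty(0), np.empty(0)))
        else:
            out.append(SubjectSeries(sid, g["day"].to_numpy(dtype=float),
                                     g["value"].to_numpy(dtype=float)))
    return out
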