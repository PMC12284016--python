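"""Monotone link functions mapping observed marker values to a latent
Gaussian scale.

Three families:

``linear``
    ``H(y) = (y - loc) / scale`` — an empirical standardization for markers
    whose conditional distribution is already close to Gaussian.  ``loc`` and
    ``scale`` are fixed at the pooled sample mean/sd (they are not identified
    jointly with the fixed effects and residual variance; standardization
    selects the canonical point on that ridge) but still count as 2
    parameters in the model-size convention.

``ispline``
    ``H(y) = c0 + sum_m alpha_m^2 I_m(y)`` where ``I_m`` are quadratic
    I-splines (integrals of linear M-splines) with three interior knots at
    the 25/50/75% quantiles of the pooled values.  Squaring the coefficients
    keeps ``H`` nondecreasing without constrained optimization.  Outside the
    data range ``H`` is extended linearly, keeping it monotone everywhere.

``beta``
    Rescale ``y`` into (0, 1) with a small buffer, then
    ``H(y) = (BetaCDF(y*; a, b) - loc) / scale``.  Captures heavily skewed
    or bounded marginals.

Every link reports the log-Jacobian ``log H'(y)`` alongside the transform,
so the model likelihood can live on the observed scale.
"""

from __future__ import annotations

import numpy as np
from scipy import interpolate, optimize, special, stats

__all__ = [
    "LinearLink",
    "ISplineLink",
    "BetaLink",
    "link_transform",
    "make_link",
    "link_from_dict",
    "LINK_FAMILIES",
]

LINK_FAMILIES = ("linear", "ispline", "beta")


class LinkRangeError(ValueError):
    """Observed value outside the link's valid range."""


class LinearLink:
    family = "linear"
    n_params = 2  # loc, scale (fixed at data moments)
    n_free = 0

    def __init__(self, loc: float, scale: float):
        if scale <= 0:
            raise ValueError("linear link scale must be > 0")
        self.loc = float(loc)
        self.scale = float(scale)

    @classmethod
    def from_data(cls, values) -> "LinearLink":
        v = np.asarray(values, dtype=float)
        sd = v.std(ddof=1) if v.size > 1 else 1.0
        return cls(v.mean() if v.size else 0.0, sd if sd > 0 else 1.0)

    def transform(self, y):
        y = np.asarray(y, dtype=float)
        h = (y - self.loc) / self.scale
        return h, np.full_like(h, -np.log(self.scale))

    def inverse(self, h):
        return np.asarray(h, dtype=float) * self.scale + self.loc

    # -- optimizer plumbing (no free parameters) --
    def free_params(self) -> np.ndarray:
        return np.empty(0)

    def with_free(self, theta) -> "LinearLink":
        return self

    def to_dict(self) -> dict:
        return {"family": "linear", "loc": self.loc, "scale": self.scale}


class ISplineLink:
    """Quadratic I-spline link: monotone piecewise-quadratic transform."""

    family = "ispline"
    n_params = 6  # 5 I-spline coefficients + intercept
    n_free = 6

    def __init__(self, interior_knots, bounds, intercept: float, raw_coefs):
        self.interior_knots = np.asarray(interior_knots, dtype=float)
        self.bounds = (float(bounds[0]), float(bounds[1]))
        self.intercept = float(intercept)
        self.raw_coefs = np.asarray(raw_coefs, dtype=float)
        if len(self.interior_knots) != 3:
            raise ValueError("ispline link uses exactly 3 interior knots")
        if len(self.raw_coefs) != 5:
            raise ValueError("ispline link uses exactly 5 coefficients")
        self._build()

    def _build(self):
        lo, hi = self.bounds
        # degree-1 B-splines (hats) on [lo, k1, k2, k3, hi]; their normalized
        # antiderivatives are the quadratic I-splines.
        t = np.r_[lo, lo, self.interior_knots, hi, hi]
        n = len(t) - 2  # 5 basis functions
        self._msplines = []
        self._isplines = []
        for j in range(n):
            c = np.zeros(n)
            c[j] = 1.0
            b = interpolate.BSpline(t, c, 1, extrapolate=False)
            total = b.integrate(lo, hi)
            self._msplines.append((b, total))
            self._isplines.append((b.antiderivative(), total))

    @classmethod
    def from_data(cls, values) -> "ISplineLink":
        v = np.asarray(values, dtype=float)
        lo, hi = float(v.min()), float(v.max())
        if hi <= lo:
            hi = lo + 1.0
        pad = 1e-6 * (hi - lo)
        knots = np.quantile(v, [0.25, 0.5, 0.75])
        knots = np.clip(knots, lo + pad, hi - pad)
        for i in range(1, 3):
            if knots[i] <= knots[i - 1]:
                knots[i] = knots[i - 1] + pad
        # start near a standardized linear map: H spans ~[-2, 2]
        return cls(knots, (lo, hi), -2.0, np.full(5, np.sqrt(4.0 / 5.0)))

    def _eval_basis(self, y):
        lo, hi = self.bounds
        yc = np.clip(y, lo, hi)
        I = np.empty((yc.size, 5))
        M = np.empty((yc.size, 5))
        for j, ((ib, tot), (mb, _)) in enumerate(zip(self._isplines, self._msplines)):
            iv = ib(yc)
            mv = mb(yc)
            iv = np.nan_to_num(iv, nan=0.0)
            mv = np.nan_to_num(mv, nan=0.0)
            # antiderivative of a clamped spline is 0 below lo; above hi it
            # saturates at the total integral
            iv = np.where(yc >= hi, tot, iv)
            I[:, j] = iv / tot
            M[:, j] = mv / tot
        return I, M, yc

    def transform(self, y):
        y = np.atleast_1d(np.asarray(y, dtype=float))
        lo, hi = self.bounds
        w = self.raw_coefs**2
        I, M, yc = self._eval_basis(y)
        h = self.intercept + I @ w
        hp = M @ w
        # linear extension beyond the data range keeps H monotone and finite
        below = y < lo
        above = y > hi
        if below.any() or above.any():
            slope_lo = self._edge_slope(lo)
            slope_hi = self._edge_slope(hi)
            h = np.where(below, h + slope_lo * (y - lo), h)
            h = np.where(above, h + slope_hi * (y - hi), h)
            hp = np.where(below, slope_lo, hp)
            hp = np.where(above, slope_hi, hp)
        floor = 1e-12
        hp = np.maximum(hp, floor)
        return h, np.log(hp)

    def _edge_slope(self, x):
        w = self.raw_coefs**2
        _, M, _ = self._eval_basis(np.array([x]))
        s = float(M[0] @ w)
        wsum = w.sum()
        ref = wsum / (self.bounds[1] - self.bounds[0]) if wsum > 0 else 1.0
        return max(s, 1e-3 * ref, 1e-12)

    def inverse(self, h):
        h = np.atleast_1d(np.asarray(h, dtype=float))
        lo, hi = self.bounds
        h_lo = float(self.transform(np.array([lo]))[0][0])
        h_hi = float(self.transform(np.array([hi]))[0][0])
        out = np.empty_like(h)
        slope_lo = self._edge_slope(lo)
        slope_hi = self._edge_slope(hi)
        for i, v in enumerate(h):
            if v <= h_lo:
                out[i] = lo + (v - h_lo) / slope_lo
            elif v >= h_hi:
                out[i] = hi + (v - h_hi) / slope_hi
            else:
                out[i] = optimize.brentq(
                    lambda x: float(self.transform(np.array([x]))[0][0]) - v, lo, hi
                )
        return out

    def free_params(self) -> np.ndarray:
        return np.r_[self.intercept, self.raw_coefs]

    def with_free(self, theta) -> "ISplineLink":
        theta = np.asarray(theta, dtype=float)
        return ISplineLink(self.interior_knots, self.bounds, theta[0], theta[1:6])

    def to_dict(self) -> dict:
        return {
            "family": "ispline",
            "interior_knots": self.interior_knots.tolist(),
            "bounds": list(self.bounds),
            "intercept": self.intercept,
            "raw_coefs": self.raw_coefs.tolist(),
        }


class BetaLink:
    """Beta-CDF link for skewed/bounded markers."""

    family = "beta"
    n_params = 4  # a, b, loc, scale
    n_free = 4

    def __init__(self, a, b, loc, scale, ymin, ymax, delta_frac=1e-3):
        if a <= 0 or b <= 0 or scale <= 0:
            raise ValueError("beta link requires a, b, scale > 0")
        self.a, self.b = float(a), float(b)
        self.loc, self.scale = float(loc), float(scale)
        self.ymin, self.ymax = float(ymin), float(ymax)
        self.delta = float(delta_frac) * (self.ymax - self.ymin)
        if self.delta <= 0:
            self.delta = 1e-3

    @classmethod
    def from_data(cls, values) -> "BetaLink":
        v = np.asarray(values, dtype=float)
        lo, hi = float(v.min()), float(v.max())
        if hi <= lo:
            hi = lo + 1.0
        return cls(2.0, 2.0, 0.5, 0.25, lo, hi)

    def _rescale(self, y):
        return (y - self.ymin + self.delta) / (self.ymax - self.ymin + 2 * self.delta)

    def transform(self, y, marker: str = ""):
        y = np.atleast_1d(np.asarray(y, dtype=float))
        ystar = self._rescale(y)
        bad = (ystar <= 0) | (ystar >= 1)
        if bad.any():
            who = f" for marker {marker!r}" if marker else ""
            raise LinkRangeError(
                f"value {y[bad][0]:g}{who} outside the beta link's valid range "
                f"({self.ymin - self.delta:g}, {self.ymax + self.delta:g})"
            )
        h = (special.betainc(self.a, self.b, ystar) - self.loc) / self.scale
        logpdf = stats.beta.logpdf(ystar, self.a, self.b)
        logjac = logpdf - np.log(self.ymax - self.ymin + 2 * self.delta) - np.log(self.scale)
        return h, logjac

    def clip_to_domain(self, y):
        """Pull values into the (open) valid range; used when applying a
        frozen model to data outside the range it was fit on."""
        eps = 0.49 * self.delta
        return np.clip(np.asarray(y, dtype=float),
                       self.ymin - self.delta + eps, self.ymax + self.delta - eps)

    def inverse(self, h):
        h = np.atleast_1d(np.asarray(h, dtype=float))
        u = self.scale * h + self.loc
        if np.any(u <= 0) or np.any(u >= 1):
            raise LinkRangeError(
                "latent value maps outside (0,1) under the beta CDF; "
                "the link is not invertible over this latent range"
            )
        ystar = special.betaincinv(self.a, self.b, u)
        return ystar * (self.ymax - self.ymin + 2 * self.delta) + self.ymin - self.delta

    def free_params(self) -> np.ndarray:
        return np.array([np.log(self.a), np.log(self.b), self.loc, np.log(self.scale)])

    def with_free(self, theta) -> "BetaLink":
        theta = np.asarray(theta, dtype=float)
        return BetaLink(np.exp(theta[0]), np.exp(theta[1]), theta[2],
                        np.exp(theta[3]), self.ymin, self.ymax,
                        self.delta / (self.ymax - self.ymin))

    def to_dict(self) -> dict:
        return {
            "family": "beta", "a": self.a, "b": self.b, "loc": self.loc,
            "scale": self.scale, "ymin": self.ymin, "ymax": self.ymax,
            "delta_frac": self.delta / (self.ymax - self.ymin),
        }


def make_link(family: str, values):
    """Initialize a link of the given family from pooled marker values."""
    if family == "linear":
        return LinearLink.from_data(values)
    if family == "ispline":
        return ISplineLink.from_data(values)
    if family == "beta":
        return BetaLink.from_data(values)
    raise ValueError(f"unknown link family {family!r}")


def link_transform(y, link):
    """Functional form of ``link.transform``: returns ``(h, log_jacobian)``."""
    return link.transform(y)


def link_from_dict(d: dict):
    fam = d["family"]
    if fam == "linear":
        return LinearLink(d["loc"], d["scale"])
    if fam == "ispline":
        return ISplineLink(d["interior_knots"], d["bounds"], d["intercept"], d["raw_coefs"])
    if fam == "beta":
        return BetaLink(d["a"], d["b"], d["loc"], d["scale"], d["ymin"], d["ymax"],
                        d.get("delta_frac", 1e-3))
    raise ValueError(f"unknown link family {fam!r}")
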