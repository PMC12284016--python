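"""Time bases for trajectory mean curves.

Two families are supported: raw polynomials ``(1, t, ..., t^d)`` and natural
cubic splines.  Both include an explicit intercept column so that a basis of
"degree" ``d`` always evaluates to a vector of length ``d + 1``.

The natural cubic spline uses the classic truncated-power construction
(linear tail restriction beyond the boundary knots): with knots
``xi_1 < ... < xi_K`` (boundary knots included) the non-intercept columns are
``t`` and ``d_k(t) - d_{K-1}(t)`` for ``k = 1..K-2``, where

    d_k(t) = ((t - xi_k)_+^3 - (t - xi_K)_+^3) / (xi_K - xi_k).

A spline of ``degree`` (degrees of freedom) ``d`` therefore needs ``d - 1``
interior knots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeBasis", "evaluate_basis", "natural_spline_basis"]


@dataclass(frozen=True)
class TimeBasis:
    """Evaluatable time basis on a bounded follow-up window (days)."""

    kind: str  # "polynomial" | "natural_spline"
    degree: int
    knots: tuple = ()  # interior knots, natural_spline only
    boundary: tuple = (0.0, 21.0)

    def __post_init__(self):
        if self.kind not in ("polynomial", "natural_spline"):
            raise ValueError(f"unknown basis kind {self.kind!r}")
        if self.degree < 1:
            raise ValueError("basis degree must be >= 1")
        if self.kind == "natural_spline":
            needed = self.degree - 1
            if len(self.knots) != needed:
                raise ValueError(
                    f"natural spline with df={self.degree} needs {needed} "
                    f"interior knots, got {len(self.knots)}"
                )
        object.__setattr__(self, "knots", tuple(float(k) for k in self.knots))
        object.__setattr__(self, "boundary", tuple(float(b) for b in self.boundary))

    @property
    def n_columns(self) -> int:
        return self.degree + 1

    def design(self, t) -> np.ndarray:
        """Design matrix, shape (len(t), degree + 1), first column = 1."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.kind == "polynomial":
            return np.vander(t, N=self.degree + 1, increasing=True)
        return _ns_design(t, self._all_knots())

    def _all_knots(self) -> np.ndarray:
        lo, hi = self.boundary
        return np.array([lo, *self.knots, hi], dtype=float)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "degree": int(self.degree),
            "knots": list(self.knots),
            "boundary": list(self.boundary),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TimeBasis":
        return cls(d["kind"], d["degree"], tuple(d.get("knots", ())),
                   tuple(d.get("boundary", (0.0, 21.0))))


def _ns_design(t: np.ndarray, knots: np.ndarray) -> np.ndarray:
    K = len(knots)
    if K < 2:
        raise ValueError("natural spline needs at least the two boundary knots")
    cols = [np.ones_like(t), t]
    if K > 2:
        xiK = knots[-1]
        xiKm1 = knots[-2]

        def d_k(k):
            num = np.maximum(t - knots[k], 0.0) ** 3 - np.maximum(t - xiK, 0.0) ** 3
            return num / (xiK - knots[k])

        dKm1 = d_k(K - 2)
        for k in range(K - 2):
            cols.append(d_k(k) - dKm1)
    return np.column_stack(cols)


def evaluate_basis(t, basis: TimeBasis) -> np.ndarray:
    """Evaluate ``basis`` at time(s) ``t``; scalar ``t`` yields a 1-D vector."""
    out = basis.design(t)
    if np.isscalar(t) or np.ndim(t) == 0:
        return out[0]
    return out


def natural_spline_basis(times, df: int, boundary=(0.0, 21.0)) -> TimeBasis:
    """Natural-spline basis with interior knots at quantiles of ``times``.

    For ``df`` degrees of freedom, the ``df - 1`` interior knots sit at the
    ``i / df`` quantiles of the pooled observation times, clipped strictly
    inside the boundary.
    """
    times = np.asarray(times, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    n_int = df - 1
    if n_int == 0:
        return TimeBasis("natural_spline", df, (), boundary)
    qs = np.arange(1, n_int + 1) / (n_int + 1)
    knots = np.quantile(times, qs)
    lo, hi = boundary
    eps = 1e-6 * (hi - lo)
    knots = np.clip(knots, lo + eps, hi - eps)
    # strictly increasing (duplicate quantiles can happen on gridded days)
    for i in range(1, len(knots)):
        if knots[i] <= knots[i - 1]:
            knots[i] = knots[i - 1] + eps
    return TimeBasis("natural_spline", df, tuple(knots), boundary)
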