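"""LCGA candidate grid, information-criterion scoring, and GMM refinement.

Selection rule: rank converged candidates by ICL (BIC as tiebreak) after
dropping models whose minimum per-class APPA falls below 0.7 or whose
smallest MAP-assigned class is under the minimum class size; keep the best
model plus near-ties within 6 ICL units, fewest parameters first.
Survivors are refit as growth mixture models with a natural-spline time
basis of matching degrees of freedom and random effects; the final model
per marker is the best-ICL converged refit, falling back to the LCGA fit
(flagged) when no refit converges.

ICL is the entropy-penalized BIC: ``ICL = BIC + 2 * entropy`` with
``entropy = -sum_i sum_g p_ig log p_ig``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import TimeBasis, natural_spline_basis
from .trajectory import (FitOptions, FittedTrajectoryModel, TrajectoryModelSpec,
                         fit_trajectory_model, responsibilities)

__all__ = [
    "SelectionCriteria",
    "enumerate_lcga_grid",
    "compute_criteria",
    "criteria_frame",
    "select_shortlist",
    "refine_with_gmm",
]

DEFAULT_LINKS = ("linear", "ispline", "beta")
DEFAULT_CLASS_RANGE = (1, 2, 3, 4, 5)
DEFAULT_POLY_DEGREES = (1, 2, 3)


@dataclass
class SelectionCriteria:
    bic: float
    icl: float
    appa_per_class: np.ndarray  # NaN for a class with zero MAP assignees
    min_class_size: int
    entropy: float
    valid: bool = True

    def __post_init__(self):
        self.appa_per_class = np.asarray(self.appa_per_class, dtype=float)


def enumerate_lcga_grid(markers, class_range=DEFAULT_CLASS_RANGE,
                        links=DEFAULT_LINKS, poly_degrees=DEFAULT_POLY_DEGREES,
                        boundary=(0.0, 21.0)):
    """Full Cartesian candidate grid of LCGA specifications, ordered by
    (marker, n_classes, link, degree).  20 markers x 5 classes x 3 links x
    3 degrees gives the canonical 900 specifications."""
    if not len(markers):
        raise ValueError("marker list must be nonempty")
    specs = []
    for m in markers:
        for G in class_range:
            for link in links:
                for d in poly_degrees:
                    specs.append(TrajectoryModelSpec(
                        m, G, TimeBasis("polynomial", d, boundary=boundary),
                        link, "none"))
    return specs


def compute_criteria(model: FittedTrajectoryModel, series) -> SelectionCriteria:
    """BIC / ICL / per-class APPA / smallest class for a fitted model.

    ``BIC = -2 logL + n_params log(n_subjects)``.  APPA for class g is the
    mean posterior probability of g among subjects MAP-assigned to g.
    """
    G = model.n_classes
    if not model.converged:
        return SelectionCriteria(np.nan, np.nan, np.full(G, np.nan), 0, np.nan,
                                 valid=False)
    R = responsibilities(series, model)
    n = R.shape[0]
    bic = -2.0 * model.loglik + model.n_params * np.log(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(R > 0, R * np.log(R), 0.0)
    entropy = float(-plogp.sum())
    icl = bic + 2.0 * entropy
    mapc = R.argmax(axis=1)
    appa = np.full(G, np.nan)
    sizes = np.bincount(mapc, minlength=G)
    for g in range(G):
        if sizes[g]:
            appa[g] = R[mapc == g, g].mean()
    return SelectionCriteria(bic, icl, appa, int(sizes.min()), entropy)


def criteria_frame(entries) -> pd.DataFrame:
    """Tabulate (spec, model, criteria) triples into one row per fitted spec."""
    rows = []
    for spec, model, crit in entries:
        rows.append({
            "marker": spec.marker_name,
            "n_classes": spec.n_classes,
            "link": spec.link_family,
            "degree": spec.basis.degree,
            "random_effects": spec.random_effects,
            "loglik": model.loglik if model is not None else np.nan,
            "n_params": model.n_params if model is not None else np.nan,
            "converged": bool(model.converged) if model is not None else False,
            "bic": crit.bic,
            "icl": crit.icl,
            "min_appa": (float(np.nanmin(crit.appa_per_class))
                         if np.any(np.isfinite(crit.appa_per_class)) else np.nan),
            "appa_per_class": ";".join(f"{a:.4f}" if np.isfinite(a) else "NA"
                                       for a in crit.appa_per_class),
            "min_class_size": crit.min_class_size,
            "entropy": crit.entropy,
            "valid": crit.valid,
        })
    return pd.DataFrame(rows)


def select_shortlist(criteria: pd.DataFrame, appa_min: float = 0.7,
                     min_class_size: int = 20, icl_window: float = 6.0):
    """Constrained shortlist per marker.

    Returns ``(shortlist, ranking)``: shortlist maps marker -> ordered list
    of row dicts (best first); ranking is the full annotated table.  When
    every candidate violates the constraints the best-BIC model is kept
    with a prominent warning.
    """
    ranking = criteria.copy()
    ok = ranking["valid"] & ranking["converged"]
    # G=1 models have APPA exactly 1 and one class of full size
    appa_ok = ok & ((ranking["n_classes"] == 1)
                    | ((ranking["min_appa"] >= appa_min)
                       & (ranking["min_class_size"] >= min_class_size)))
    ranking["passes_constraints"] = appa_ok
    shortlist = {}
    for marker, g in ranking.groupby("marker"):
        cand = g[g["passes_constraints"]]
        if cand.empty:
            warnings.warn(
                f"{marker}: every candidate violates the APPA/class-size "
                "constraints; falling back to the best-BIC model", stacklevel=2)
            valid = g[g["valid"] & g["converged"]]
            pool = valid if not valid.empty else g
            best = pool.sort_values(["bic", "n_params"]).iloc[:1]
            shortlist[marker] = best.to_dict(orient="records")
            continue
        cand = cand.sort_values(["icl", "bic", "n_params"])
        best_icl = cand["icl"].iloc[0]
        near = cand[cand["icl"] <= best_icl + icl_window]
        near = near.sort_values(["n_params", "icl", "bic"])
        shortlist[marker] = near.to_dict(orient="records")
    return shortlist, ranking


def _spec_from_row(row, marker_series, random_effects):
    """GMM spec for a shortlisted row: natural spline with df matching the
    LCGA polynomial degree, knots at quantiles of the pooled times."""
    times = np.concatenate([s.times for s in marker_series])
    basis = natural_spline_basis(times, int(row["degree"]))
    return TrajectoryModelSpec(row["marker"], int(row["n_classes"]), basis,
                               row["link"], random_effects)


def refine_with_gmm(shortlist: dict, series_by_marker: dict,
                    random_effects: str = "intercept_slope",
                    options: FitOptions | None = None,
                    lcga_models: dict | None = None):
    """Refit each marker's shortlisted specs as GMMs; pick the best ICL.

    ``lcga_models`` maps (marker, n_classes, link, degree) -> fitted LCGA
    model, used as the fallback when no GMM refit converges.  Returns
    ``(final models per marker, refit log frame)``.  Fit failures become
    flagged rows, never an aborted batch.
    """
    finals = {}
    log_rows = []
    for marker, rows in shortlist.items():
        series = series_by_marker[marker]
        best = None
        for row in rows:
            spec = _spec_from_row(row, series, random_effects)
            try:
                model = fit_trajectory_model(series, spec, options)
                crit = compute_criteria(model, series)
                status = "ok" if model.converged else "not converged"
            except Exception as exc:  # noqa: BLE001 - batch must survive
                model, crit, status = None, None, f"failed: {exc}"
            log_rows.append({
                "marker": marker, "n_classes": row["n_classes"],
                "link": row["link"], "degree": row["degree"],
                "status": status,
                "icl": crit.icl if crit else np.nan,
                "bic": crit.bic if crit else np.nan,
            })
            if model is not None and model.converged and crit.valid:
                if best is None or crit.icl < best[1]:
                    best = (model, crit.icl)
        if best is not None:
            finals[marker] = best[0]
        else:
            fallback = None
            if lcga_models:
                for row in rows:
                    key = (marker, int(row["n_classes"]), row["link"], int(row["degree"]))
                    if key in lcga_models:
                        fallback = lcga_models[key]
                        break
            if fallback is None:
                warnings.warn(f"{marker}: no GMM refit converged and no LCGA "
                              "fallback available; marker dropped", stacklevel=2)
                continue
            warnings.warn(f"{marker}: no GMM refit converged; keeping the "
                          "LCGA fit", stacklevel=2)
            finals[marker] = fallback
    return finals, pd.DataFrame(log_rows)
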