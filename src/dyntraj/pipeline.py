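"""End-to-end orchestration: simulate -> preprocess -> fit the LCGA grid ->
criterion-based selection -> (optional) GMM refinement -> dynamic features
-> repeated elastic-net experiments -> class associations.

All randomness flows from a single base seed, so two runs with the same
configuration produce byte-identical result tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .features import build_feature_matrix
from .prediction import ExperimentConfig, ExperimentResult, run_experiment
from .preprocess import preprocess_labs
from .selection import (compute_criteria, criteria_frame, enumerate_lcga_grid,
                        refine_with_gmm, select_shortlist)
from .synthetic import (CohortConfig, default_cohort_config, simulate_cohort,
                        simulate_external_cohort)
from .trajectory import FitOptions, fit_trajectory_model, series_from_labs

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    cohort: CohortConfig = None
    seed: int = 0
    # grid restriction (full study grid: 1-5 classes, 3 links, degrees 1-3)
    class_range: tuple = (1, 2, 3, 4, 5)
    links: tuple = ("linear", "ispline", "beta")
    poly_degrees: tuple = (1, 2, 3)
    top_k_markers: int = 20
    min_class_size: int = 20
    appa_min: float = 0.7
    gmm_refine: bool = True
    random_effects: str = "intercept_slope"
    fit_options: FitOptions = None
    experiments: tuple = ("I", "II", "III")
    cutoffs: tuple = (1, 3, 7, 14, 21)
    feature_sets: tuple = ("ppa", "ppa_sum", "ppa_sum_bl")
    n_repeats: int = 25
    run_associations: bool = True

    def __post_init__(self):
        if self.cohort is None:
            self.cohort = default_cohort_config(self.seed)
        if self.fit_options is None:
            self.fit_options = FitOptions(n_starts=2, max_iter=200, tol=1e-6,
                                          seed=self.seed)


@dataclass
class PipelineResult:
    subjects: pd.DataFrame
    labs: pd.DataFrame
    truth: pd.DataFrame
    clean_labs: pd.DataFrame
    filter_report: pd.DataFrame
    criteria: pd.DataFrame
    shortlist: dict
    models: dict  # marker -> FittedTrajectoryModel
    refine_log: pd.DataFrame
    experiment_results: dict  # experiment id -> ExperimentResult
    associations: pd.DataFrame
    external: tuple  # (subjects, labs, truth) or None

    def result_tables_text(self) -> str:
        """Canonical text serialization of the analysis outputs, used to
        assert rerun determinism."""
        parts = [self.filter_report.to_csv(index=False),
                 self.criteria.to_csv(index=False)]
        for marker in sorted(self.models):
            import json

            parts.append(json.dumps(self.models[marker].to_dict(), sort_keys=True))
        for exp in sorted(self.experiment_results):
            res = self.experiment_results[exp]
            parts.append(res.records.to_csv(index=False))
            parts.append(res.summary.to_csv(index=False))
            parts.append(res.importance.to_csv(index=False))
        if self.associations is not None and not self.associations.empty:
            parts.append(self.associations.to_csv(index=False))
        return "\n".join(parts)


def fit_marker_grid(series_by_marker: dict, specs, options: FitOptions):
    """Fit every grid spec; returns (criteria frame, fitted-model lookup)."""
    entries = []
    models = {}
    for spec in specs:
        series = series_by_marker[spec.marker_name]
        key = (spec.marker_name, spec.n_classes, spec.link_family,
               spec.basis.degree)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_trajectory_model(series, spec, options)
            crit = compute_criteria(model, series)
        except Exception:  # noqa: BLE001 - grid scan must survive bad cells
            model, crit = None, None
        if model is not None:
            models[key] = model
            entries.append((spec, model, crit))
    return criteria_frame(entries), models


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    cohort_cfg = config.cohort
    subjects, labs, truth = simulate_cohort(cohort_cfg, rng_seed=config.seed)
    clean, report, inclusion = preprocess_labs(labs, top_k=config.top_k_markers)
    kept = set(inclusion.loc[inclusion["included"], "subject_id"])
    subjects_kept = subjects[subjects["subject_id"].isin(kept)].reset_index(drop=True)
    markers = sorted(clean["marker"].unique())
    ids = sorted(kept)
    series_by_marker = {m: series_from_labs(clean, m, ids) for m in markers}
    # drop empty series (subject retained overall but had none for a marker
    # cannot happen after inclusion rules, but guard anyway)
    for m in markers:
        series_by_marker[m] = [s for s in series_by_marker[m] if len(s)]

    specs = enumerate_lcga_grid(markers, config.class_range, config.links,
                                config.poly_degrees)
    criteria, lcga_models = fit_marker_grid(series_by_marker, specs,
                                            config.fit_options)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        shortlist, ranking = select_shortlist(criteria, config.appa_min,
                                              config.min_class_size)
    if config.gmm_refine:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models, refine_log = refine_with_gmm(
                shortlist, series_by_marker, config.random_effects,
                config.fit_options, lcga_models)
    else:
        models = {}
        for marker, rows in shortlist.items():
            row = rows[0]
            key = (marker, int(row["n_classes"]), row["link"], int(row["degree"]))
            if key in lcga_models:
                models[marker] = lcga_models[key]
        refine_log = pd.DataFrame()

    external = None
    experiment_results = {}
    for exp in config.experiments:
        if exp == "III":
            if external is None:
                ext_subjects, ext_labs, _ext_truth = simulate_external_cohort(
                    cohort_cfg, rng_seed=config.seed + 10_007)
                ext_clean, _, _ = preprocess_labs(
                    ext_labs, top_k=config.top_k_markers, min_measures=1)
                external = (ext_subjects, ext_labs, _ext_truth)
            exp_subjects, exp_labs = ext_subjects, ext_clean
            fsets = tuple(config.feature_sets)
        else:
            exp_subjects, exp_labs = subjects_kept, clean
            fsets = tuple(config.feature_sets)
        fms = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for cutoff in config.cutoffs:
                for fs in fsets:
                    fms[(cutoff, fs)] = build_feature_matrix(
                        exp_subjects, models, exp_labs, exp, cutoff, fs)
        econfig = ExperimentConfig(exp, tuple(config.cutoffs), fsets,
                                   config.n_repeats, base_seed=config.seed)
        experiment_results[exp] = run_experiment(econfig, fms)

    associations = pd.DataFrame()
    if config.run_associations and models:
        from .trajectory import posterior_probabilities, series_from_labs as sfl

        rows = []
        for marker, model in sorted(models.items()):
            for s in series_by_marker[marker]:
                pa = posterior_probabilities(s, model, 21.0)
                rows.append({"subject_id": s.subject_id, "marker": marker,
                             "map_class": pa.map_class})
        map_df = pd.DataFrame(rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            associations = class_associations_safe(subjects_kept, map_df,
                                                   config.seed)
    return PipelineResult(subjects, labs, truth, clean, report, criteria,
                          shortlist, models, refine_log, experiment_results,
                          associations, external)


def class_associations_safe(subjects, map_df, seed):
    from .associations import class_covariate_associations

    try:
        return class_covariate_associations(subjects, map_df, seed=seed)
    except Exception:  # noqa: BLE001
        return pd.DataFrame()
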