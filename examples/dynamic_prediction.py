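"""Dynamic mortality prediction from trajectory-class membership.

Posterior class probabilities are recomputed at growing data cutoffs
(days 1, 7, 21) and fed to the repeated elastic-net harness.  Out-of-train
ROC-AUC should grow as more of each subject's trajectory is observed —
the dynamic-biomarker effect.
"""

import warnings

import dyntraj as dt

warnings.filterwarnings("ignore")

config = dt.default_cohort_config(rng_seed=0)
subjects, labs, _ = dt.simulate_cohort(config)
clean, _, inclusion = dt.preprocess_labs(labs, top_k=6)
kept = set(inclusion.loc[inclusion["included"], "subject_id"])
ids = sorted(kept)
subjects = subjects[subjects["subject_id"].isin(kept)].reset_index(drop=True)

models = {}
for mk in config.markers:
    series = [s for s in dt.series_from_labs(clean, mk.marker_name, ids) if len(s)]
    spec = dt.TrajectoryModelSpec(mk.marker_name, mk.n_classes, mk.basis,
                                  mk.link.family)
    models[mk.marker_name] = dt.fit_trajectory_model(
        series, spec, dt.FitOptions(n_starts=2, max_iter=150, seed=0))

cutoffs = (1, 7, 21)
fms = {(c, "ppa"): dt.build_feature_matrix(subjects, models, clean, "I", c, "ppa")
       for c in cutoffs}
result = dt.run_experiment(
    dt.ExperimentConfig("I", cutoffs, ("ppa",), n_repeats=10, base_seed=0), fms)

s = result.summary
out = s[(s["split"] == "out_of_train") & (s["metric"] == "roc_auc")]
print("out-of-train ROC-AUC (mean [95% CI] over 10 repeats):")
for _, row in out.sort_values("cutoff").iterrows():
    print(f"  day {int(row['cutoff']):>2}: {row['mean']:.3f} "
          f"[{row['ci_low']:.3f}-{row['ci_high']:.3f}]")
print("\nA mean near 0.5 at day 1 says the early window carries little "
      "class information; the rise by day 21 is the dynamic gain.")

imp = result.importance
top = imp[imp["cutoff"] == 21].nlargest(5, "mean_importance")
print("\ntop day-21 predictors (importance normalized to 100):")
for _, row in top.iterrows():
    print(f"  {row['feature']:<28} {row['mean_importance']:5.1f}")
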