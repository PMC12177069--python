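"""Gait-phase-locked spectral biomarkers of walking performance.

Cleans the pallidal field-potential channel (1 Hz high-pass, gamma-range
outlier blanking, packet-loss exclusion), synchronizes device and
wearable clocks from acceleration peaks, computes wavelet power, z-scores
it per frequency within each visit, averages the beta band over the four
gait phases of every artifact-free cycle, and fits the group mixed model
WPI ~ beta_power + hemisphere + (1 | subject).
"""

from gaitdbs import pipeline, stats, synthetic

config = synthetic.default_cohort_config(
    n_visits=2, settings_per_visit=7, n_strides=24
)
config.sites = ("GP",)  # pallidal channel only, for speed
cohort = synthetic.simulate_cohort(config, seed=4)

metrics, gait_results = pipeline.cohort_trial_metrics(cohort)
wpi_table = pipeline.cohort_wpi(metrics, cohort.manifest)
features = pipeline.extract_features(
    cohort, gait_results, wpi_table,
    sites=("GP",), pairs=(), fmin_hz=12, fmax_hz=30, voices_per_octave=8,
)

for phase in ("DS2", "ILS"):
    sel = features[features["phase"] == phase].dropna(subset=["value", "wpi"])
    res = stats.fit_group_feature_model(sel)
    print(
        f"GP beta {phase}: slope {res.estimate:+.3f} ± {res.se:.3f}, "
        f"t({res.df}) = {res.t_value:.2f}, p = {res.p_wald:.4f}, "
        f"LRT p = {res.lrt_p:.4f} (n = {len(sel)})"
    )

print(
    "\nThe generator imposes a pallidal beta-power decline of -0.22 z-units\n"
    "per baseline-normalized WPI unit during the double-support (DS2) and\n"
    "ipsilateral-swing (ILS) phases; the fitted slopes recover it, i.e.\n"
    "better walking goes with lower pallidal beta power in those phases."
)
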