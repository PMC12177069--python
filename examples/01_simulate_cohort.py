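"""Simulate a small DBS-gait study cohort and look at its ground truth.

Builds three synthetic subjects (two bilateral implants, one unilateral),
draws each subject's stimulation-response surface, simulates one visit of
walking trials per subject and prints the manifest with the true walking
performance behind every trial.
"""

from gaitdbs import synthetic

config = synthetic.default_cohort_config(
    n_subjects=3, n_visits=1, settings_per_visit=4, n_strides=16
)
cohort = synthetic.simulate_cohort(config, seed=1)

print(cohort.manifest.round(3).to_string(index=False))
print()
for subject in cohort.subjects:
    surf = cohort.surfaces[subject.subject_id]
    print(
        f"{subject.subject_id}: optimum at {surf.optimum.round(1)} "
        f"(mA, Hz, us), peak WPI {surf.peak_wpi:.2f}, "
        f"baseline {surf.baseline_wpi:.2f}"
    )
print()
print(
    "Each row is one walking trial; true_wpi is the noise-free surface value\n"
    "at that stimulation setting — the quantity the whole pipeline tries to\n"
    "recover from kinematics and neural recordings."
)
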