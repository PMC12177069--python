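# On-disk formats

All times are seconds from trial start on the wearable clock; intervals
are half-open `[start, end)`; samples are 0-based. Tables are CSV
(written with `%.10g` floats for hash-stable round-trips), structured
results and configs are JSON.

## Pipeline config (JSON)

Fields of `gaitdbs.pipeline.PipelineConfig`; unknown fields are
rejected by `load_config`. `stages` is any subset of
`simulate, gait, wpi, preproc, spectral, optimize, stats` (run in that
order). Every stochastic stage receives a sub-seed derived from the
master `seed` and recorded in the run manifest.

## Signals (float32 column binary + JSON sidecar)

`write_signals` concatenates each channel as little-endian float32; the
sidecar (`<file>.json`) lists per channel: `name`, `rate_hz`, `t0_s`
(time of sample 0 on the common timeline; nonzero after clock sync),
and `n`. NaN marks missing/blanked samples and round-trips.

## Per-run tables

- `cohort_manifest.csv` — trial_id, subject_id, visit_id, amplitude_mA,
  frequency_Hz, pulse_width_us, clinical_flag, true_wpi (generator
  truth, for evaluation only).
- `feedback.csv` — subject_id, visit_id, rater, trial_id, wpi_rank,
  feedback_rank (rank 1 = best).
- `trial_metrics.csv` — trial_id, visit_id, stride_velocity,
  arm_swing_amplitude, step_length_cv, step_time_cv, n_valid_strides,
  usable.
- `wpi.csv` — trial_id, sv_norm, as_norm, vsl_norm, vst_norm, wpi_raw,
  wpi_baseline_normalized, rank, visit_id.
- `preproc.csv` — per-trial sync rows (sync_offset_s,
  sync_residual_sd_s) and artifact interval rows (channel, start_s,
  end_s, provenance ∈ {gamma_outlier, packet_loss}).
- `features.csv` — long format: trial_id, subject_id, hemisphere,
  site_or_pair ∈ {GP, ctxA, ctxB, GP-ctxA, GP-ctxB, ctxA-ctxB}, band,
  phase, value (z units), manifest columns, wpi.
- `sensitivity.csv` — metric, sign, mean_delta_wpi, mean_abs_delta_wpi.
- `subject_models.csv` — subject_id, site_or_pair, band, phase,
  estimate, se, r2, p, p_adj, flag.
- `vif.json`, `group_models.json`, `feedback_model.json`,
  `optimization.json` — keyed results mirroring the dataclasses in
  `gaitdbs.wpi`, `gaitdbs.stats` and `gaitdbs.gpr`.
- `manifest.json` — config echo, per-stage sub-seeds, SHA-256 of every
  output file, stages run.
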