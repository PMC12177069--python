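"""End-to-end orchestration: simulate → gait → WPI → preproc → spectral →
optimize → stats, with seeded determinism, per-stage outputs and a
provenance manifest.

All tabular outputs are CSV, configs/manifests/results are JSON, and raw
signals round-trip through a float32 column binary with a JSON sidecar.
The pipeline is a library: ``run_pipeline(load_config(path))`` runs every
enabled stage into a run directory and returns the provenance manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import gait, gpr, preproc, spectral, stats, synthetic, wpi
from .types import PAIRS, PHASES, SITES, Signal, StimSetting

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "gait", "wpi", "preproc", "spectral", "optimize", "stats")


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run."""

    seed: int = 0
    output_dir: str = "runs/run0"
    stages: tuple[str, ...] = ALL_STAGES
    # cohort
    n_subjects: int = 3
    n_visits: int = 2
    settings_per_visit: int = 3
    n_strides: int = 20
    metric_noise_sd: float = 0.03
    feedback_concordance: float = 0.8
    # spectral
    fmin_hz: float = 1.0
    fmax_hz: float = 30.0
    voices_per_octave: int = 10
    include_coherence: bool = True
    sites: tuple[str, ...] = SITES
    pairs: tuple[str, ...] = PAIRS
    # optimizer
    gpr_restarts: int = 8
    optimizer_budget: int = 14

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.n_strides < 4:
            raise ValueError("n_strides must be >= 4")


def load_config(path: str | Path) -> PipelineConfig:
    """Read and validate a JSON pipeline config, erroring on unknown keys."""
    with open(path) as fh:
        raw = json.load(fh)
    valid = {f.name for f in PipelineConfig.__dataclass_fields__.values()}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    for key in ("stages", "sites", "pairs"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# table / signal I/O


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_signals(signals: dict[str, Signal], path: str | Path) -> None:
    """Float32 column binary + JSON sidecar (channel names, rates, t0)."""
    path = Path(path)
    meta = {"channels": []}
    with open(path, "wb") as fh:
        for name, sig in signals.items():
            data = np.asarray(sig.data, dtype=np.float32)
            meta["channels"].append(
                {
                    "name": name,
                    "rate_hz": sig.rate_hz,
                    "t0_s": sig.t0_s,
                    "n": int(data.size),
                }
            )
            fh.write(data.tobytes())
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_signals(path: str | Path) -> dict[str, Signal]:
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        meta = json.load(fh)
    out: dict[str, Signal] = {}
    with open(path, "rb") as fh:
        for ch in meta["channels"]:
            buf = fh.read(4 * ch["n"])
            data = np.frombuffer(buf, dtype=np.float32).astype(float)
            out[ch["name"]] = Signal(data, ch["rate_hz"], ch["t0_s"], ch["name"])
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# per-trial gait processing


@dataclass
class TrialGaitResult:
    cycles: list  # all cycles, turn-flagged
    walking_cycles: list  # non-turn subset
    stride_metrics: list
    trial_metrics: gait.TrialMetrics
    used_fallback: bool = False


def process_trial_gait(rec: synthetic.TrialRecording) -> TrialGaitResult:
    """Footswitch event detection (goniometer fallback), cycles, metrics."""
    events, flags = gait.detect_events_fsr(rec.kinematics)
    used_fallback = any(flags.values())
    if used_fallback:
        events, gflags = gait.detect_events_goniometer(rec.kinematics)
        if any(gflags.values()):
            log.warning("trial %s: both detectors degraded", rec.trial_id)
    cycles = gait.build_cycles(events, "left")
    walking = gait.exclude_turns(cycles, rec.kinematics.get("heading_deg"))
    sm = gait.compute_stride_metrics(walking, rec.kinematics)
    tm = gait.aggregate_trial_metrics(sm)
    return TrialGaitResult(cycles, walking, sm, tm, used_fallback)


def cohort_trial_metrics(cohort: synthetic.Cohort) -> tuple[pd.DataFrame, dict]:
    """Gait-process every trial; returns the metrics table and per-trial results."""
    rows, results = [], {}
    for rec in cohort.trials:
        res = process_trial_gait(rec)
        results[rec.trial_id] = res
        row = {"trial_id": rec.trial_id, "visit_id": rec.visit_id, **res.trial_metrics.as_dict()}
        row["n_valid_strides"] = res.trial_metrics.n_valid_strides
        row["usable"] = res.trial_metrics.usable
        rows.append(row)
    return pd.DataFrame(rows), results


def cohort_wpi(metrics: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-visit WPI scoring (components, raw, baseline-normalized, rank)."""
    out = []
    for visit_id, grp in metrics.groupby("visit_id", sort=True):
        man = manifest[manifest["visit_id"] == visit_id]
        clinical_id = man.loc[man["clinical_flag"], "trial_id"].iloc[0]
        scored = wpi.score_visit(grp.reset_index(drop=True), clinical_id)
        scored["visit_id"] = visit_id
        out.append(scored)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# spectral feature extraction


def extract_features(
    cohort: synthetic.Cohort,
    gait_results: dict | None = None,
    wpi_table: pd.DataFrame | None = None,
    sites: tuple[str, ...] = SITES,
    pairs: tuple[str, ...] = PAIRS,
    fmin_hz: float = 1.0,
    fmax_hz: float = 30.0,
    voices_per_octave: int = 10,
) -> pd.DataFrame:
    """Phase-band features for every trial/hemisphere/site (and pair).

    Per visit and channel: 1 Hz high-pass, gamma-outlier blanking, packet
    loss detection, clock sync via acceleration anchors, CWT power (or
    wavelet coherence for pairs), per-frequency z-scoring pooled over the
    visit's trials, band averaging and per-phase means over artifact-free
    gait cycles.  Returns the long feature table joined with the manifest
    (plus WPI when supplied).
    """
    if gait_results is None:
        _, gait_results = cohort_trial_metrics(cohort)
    bands = [
        b for b, (lo, hi) in spectral.BANDS.items() if lo >= fmin_hz and lo < fmax_hz
    ]
    subj_map = {s.subject_id: s for s in cohort.subjects}
    rows = []
    for visit_id, man in cohort.manifest.groupby("visit_id", sort=True):
        trials = [cohort.trial(t) for t in man["trial_id"]]
        subject = subj_map[trials[0].subject_id]
        # sync each trial once
        sync_off = {}
        cleaned: dict[tuple[str, str], dict[str, np.ndarray]] = {}
        packet: dict[tuple[str, str], list] = {}
        for rec in trials:
            try:
                sm = preproc.estimate_sync(rec.device_accel, rec.kinematics["chest_accel"])
                sync_off[rec.trial_id] = sm.offset_s
            except preproc.SyncError:
                log.warning("trial %s unsynchronized; skipped", rec.trial_id)
                continue
            for key, sig in rec.neural.items():
                x = preproc.highpass(sig.data, sig.rate_hz)
                mask = preproc.gamma_outlier_mask(x, sig.rate_hz)
                cleaned[(rec.trial_id, key)] = preproc.apply_blanking(x, mask)
                packet[(rec.trial_id, key)] = preproc.detect_packet_loss(
                    sig.data, sig.rate_hz
                )
        for hemi in subject.hemisphere_names:
            channels = [(s, f"{hemi}/{s}") for s in sites]
            for site, key in channels:
                _extract_channel(
                    rows, trials, gait_results, sync_off, cleaned, packet,
                    hemi, site, key, None, bands,
                    fmin_hz, fmax_hz, voices_per_octave,
                )
            for pair in pairs:
                a, b = pair.split("-")
                _extract_channel(
                    rows, trials, gait_results, sync_off, cleaned, packet,
                    hemi, pair, f"{hemi}/{a}", f"{hemi}/{b}", bands,
                    fmin_hz, fmax_hz, voices_per_octave,
                )
    feat = pd.DataFrame(rows)
    if feat.empty:
        return feat
    feat = spectral.build_feature_table(feat, cohort.manifest)
    if wpi_table is not None:
        feat = feat.merge(
            wpi_table[["trial_id", "wpi_baseline_normalized"]].rename(
                columns={"wpi_baseline_normalized": "wpi"}
            ),
            on="trial_id",
            how="left",
        )
    return feat


def _extract_channel(
    rows, trials, gait_results, sync_off, cleaned, packet,
    hemi, site_or_pair, key_a, key_b, bands, fmin, fmax, vpo,
):
    maps, per_trial = [], []
    for rec in trials:
        if rec.trial_id not in sync_off or (rec.trial_id, key_a) not in cleaned:
            continue
        xa = cleaned[(rec.trial_id, key_a)]
        rate = rec.neural[key_a].rate_hz
        if key_b is None:
            m = spectral.cwt_power(xa, rate, fmin, fmax, vpo)
        else:
            if (rec.trial_id, key_b) not in cleaned:
                continue
            m = spectral.wavelet_coherence(
                xa, cleaned[(rec.trial_id, key_b)], rate, fmin, fmax, vpo
            )
        if m.values.shape[1] == 0:
            continue
        m.t0_s = sync_off[rec.trial_id]
        maps.append(m)
        per_trial.append(rec)
    if not maps:
        return
    zmaps = spectral.zscore_per_frequency(maps)
    for rec, zm in zip(per_trial, zmaps):
        gres = gait_results[rec.trial_id]
        pk = packet.get((rec.trial_id, key_a), [])
        if key_b is not None:
            pk = pk + packet.get((rec.trial_id, key_b), [])
        usable, _ = preproc.exclude_contaminated_cycles(
            gres.walking_cycles, None, pk, t0_s=zm.t0_s
        )
        for band in bands:
            series = spectral.band_average(zm, band)
            _, trial_means = spectral.phase_average(
                series, zm.rate_hz, usable, t0_s=zm.t0_s
            )
            for phase in PHASES:
                rows.append(
                    {
                        "trial_id": rec.trial_id,
                        "subject_id": rec.subject_id,
                        "hemisphere": hemi,
                        "site_or_pair": site_or_pair,
                        "band": band,
                        "phase": phase,
                        "value": trial_means[phase],
                    }
                )


# ---------------------------------------------------------------------------
# full pipeline


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the provenance manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    sub_seeds = {
        name: int(s.generate_state(1)[0] & 0x7FFFFFFF)
        for name, s in zip(ALL_STAGES, ss.spawn(len(ALL_STAGES)))
    }
    manifest: dict = {
        "config": asdict(config),
        "sub_seeds": sub_seeds,
        "outputs": {},
        "stages_run": [],
    }
    state: dict = {}

    def _save(df: pd.DataFrame, name: str) -> None:
        path = out / name
        write_table(df, path)
        manifest["outputs"][name] = _sha256(path)

    def _save_json(obj, name: str) -> None:
        path = out / name
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonable)
        manifest["outputs"][name] = _sha256(path)

    stages = [s for s in ALL_STAGES if s in config.stages]
    for stage in stages:
        log.info("stage %s", stage)
        try:
            _run_stage(stage, config, sub_seeds, state, _save, _save_json)
        except Exception:
            log.exception("stage %s failed; partial outputs preserved", stage)
            manifest["failed_stage"] = stage
            break
        manifest["stages_run"].append(stage)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, StimSetting):
        return asdict(obj)
    if hasattr(obj, "__dataclass_fields__"):
        return asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _run_stage(stage, config, sub_seeds, state, _save, _save_json):
    if stage == "simulate":
        cc = synthetic.default_cohort_config(
            n_subjects=config.n_subjects,
            n_visits=config.n_visits,
            settings_per_visit=config.settings_per_visit,
            n_strides=config.n_strides,
        )
        cc.metric_noise_sd = config.metric_noise_sd
        cohort = synthetic.simulate_cohort(cc, sub_seeds["simulate"])
        cohort.feedback = synthetic.simulate_feedback(
            cohort, config.feedback_concordance, sub_seeds["simulate"]
        )
        state["cohort"] = cohort
        _save(cohort.manifest, "cohort_manifest.csv")
        _save(cohort.feedback, "feedback.csv")
    elif stage == "gait":
        metrics, results = cohort_trial_metrics(state["cohort"])
        state["metrics"], state["gait_results"] = metrics, results
        _save(metrics, "trial_metrics.csv")
    elif stage == "wpi":
        cohort = state["cohort"]
        scores = cohort_wpi(state["metrics"], cohort.manifest)
        state["wpi"] = scores
        _save(scores, "wpi.csv")
        usable = state["metrics"][state["metrics"]["usable"]]
        if len(usable) >= 5:
            rep = wpi.vif(usable)
            _save_json({"vif": rep.vif, "infinite": rep.infinite}, "vif.json")
        first_visit = sorted(cohort.manifest["visit_id"])[0]
        man = cohort.manifest[cohort.manifest["visit_id"] == first_visit]
        vm = state["metrics"][state["metrics"]["visit_id"] == first_visit]
        clin = man.loc[man["clinical_flag"], "trial_id"].iloc[0]
        _save(wpi.sensitivity(vm.reset_index(drop=True), clin), "sensitivity.csv")
    elif stage == "preproc":
        cohort = state["cohort"]
        rows = []
        for rec in cohort.trials:
            try:
                sm = preproc.estimate_sync(
                    rec.device_accel, rec.kinematics["chest_accel"]
                )
                off, sd = sm.offset_s, sm.residual_sd_s
            except preproc.SyncError:
                off, sd = np.nan, np.nan
            rows.append(
                {
                    "trial_id": rec.trial_id,
                    "sync_offset_s": off,
                    "sync_residual_sd_s": sd,
                }
            )
            for key, sig in rec.neural.items():
                x = preproc.highpass(sig.data, sig.rate_hz)
                mask = preproc.gamma_outlier_mask(x, sig.rate_hz)
                for s, e, prov in mask.intervals:
                    rows.append(
                        {
                            "trial_id": rec.trial_id,
                            "channel": key,
                            "start_s": s,
                            "end_s": e,
                            "provenance": prov,
                        }
                    )
                for s, e in preproc.detect_packet_loss(sig.data, sig.rate_hz):
                    rows.append(
                        {
                            "trial_id": rec.trial_id,
                            "channel": key,
                            "start_s": s,
                            "end_s": e,
                            "provenance": "packet_loss",
                        }
                    )
        _save(pd.DataFrame(rows), "preproc.csv")
    elif stage == "spectral":
        cohort = state["cohort"]
        feat = extract_features(
            cohort,
            state.get("gait_results"),
            state.get("wpi"),
            sites=config.sites,
            pairs=config.pairs if config.include_coherence else (),
            fmin_hz=config.fmin_hz,
            fmax_hz=config.fmax_hz,
            voices_per_octave=config.voices_per_octave,
        )
        state["features"] = feat
        _save(feat, "features.csv")
    elif stage == "optimize":
        cohort = state["cohort"]
        histories = {}
        rng = np.random.default_rng(sub_seeds["optimize"])
        for subject in cohort.subjects:
            surface = cohort.surfaces[subject.subject_id]

            def oracle(s, _surface=surface, _rng=rng):
                return _surface.value(s) + _surface.observation_noise_sd * _rng.standard_normal()

            box = subject.safe_range
            init = gpr.initial_design(
                subject.clinical_setting, box, seed=sub_seeds["optimize"]
            )
            cfg = gpr.GPRConfig(
                n_restarts=config.gpr_restarts, seed=sub_seeds["optimize"]
            )
            hist = gpr.run_optimization_loop(
                oracle, cfg, init, config.optimizer_budget, box
            )
            histories[subject.subject_id] = {
                "settings": [s.as_array().tolist() for s in hist.settings],
                "observed": hist.observed,
                "running_best": hist.running_best.tolist(),
                "final_best": (
                    hist.final_proposal.best.as_array().tolist()
                    if hist.final_proposal
                    else None
                ),
                "true_optimum": surface.optimum.tolist(),
            }
        _save_json(histories, "optimization.json")
    elif stage == "stats":
        feat = state.get("features")
        if feat is None or feat.empty or "wpi" not in feat.columns:
            log.warning("no features with WPI; stats stage skipped")
            return
        subj_models = stats.fit_subject_phase_models(feat)
        _save(subj_models, "subject_models.csv")
        results = {}
        for phase in ("DS2", "ILS"):
            sel = feat[
                (feat["site_or_pair"] == "GP")
                & (feat["band"] == "beta")
                & (feat["phase"] == phase)
            ].dropna(subset=["value", "wpi"])
            if sel["subject_id"].nunique() >= 3 and len(sel) >= 20:
                res = stats.fit_group_feature_model(sel)
                results[f"GP_beta_{phase}"] = asdict(res)
                if sel["hemisphere"].nunique() > 1:
                    daic, p_int = stats.hemisphere_interaction_check(sel)
                    results[f"GP_beta_{phase}"]["hemisphere_delta_aic"] = daic
                    results[f"GP_beta_{phase}"]["hemisphere_interaction_p"] = p_int
        if results:
            chi_ps = [v["lrt_p"] for v in results.values()]
            adj = stats.bh_adjust(chi_ps)
            for (k, v), a in zip(results.items(), adj):
                v["lrt_p_adj"] = float(a)
        _save_json(results, "group_models.json")
        fb = state["cohort"].feedback
        if fb is not None and len(fb):
            try:
                fres = stats.feedback_rank_model(fb)
                _save_json(asdict(fres), "feedback_model.json")
            except ValueError as exc:
                log.warning("feedback model failed: %s", exc)


__all__ = [
    "PipelineConfig",
    "load_config",
    "run_pipeline",
    "read_table",
    "write_table",
    "read_signals",
    "write_signals",
    "process_trial_gait",
    "cohort_trial_metrics",
    "cohort_wpi",
    "extract_features",
]
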