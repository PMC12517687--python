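"""End-to-end orchestration: simulate -> behavior -> units -> auc -> decode -> tuning.

A :class:`RunConfig` is a flat namespace of every protocol parameter with
standard-protocol defaults; unknown keys are rejected up front and the
resolved config is written next to the outputs of every run.  One global
seed expands into per-stage, per-session sub-seeds through a documented
counter scheme, so each stage is reproducible independently of execution
order.  Stage failures are isolated per session: they are recorded in the
manifest and later independent stages still run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import behavior_summary, classify_outcomes
from .discriminability import (
    attach_null,
    auc_timecourse,
    contrast_builder,
    discrimination_metrics,
    shuffle_null,
)
from .io import Session, load_session
from .population import (
    SessionRejection,
    build_population,
    decode_timecourse,
    decoding_latency,
    fisher_separation,
    lda_decode,
    single_trial_variance,
)
from .tuning import bandwidth, bf_distance_to_go, compute_fra, pairwise_dprime, population_sparseness
from .unit_metrics import firing_properties, responsive_units

__all__ = ["RunConfig", "run_pipeline", "make_report", "stage_seed"]

log = logging.getLogger("neurodisc")

_STAGES = ("behavior", "units", "auc", "decode", "tuning")
_FLOAT_FMT = "%.9f"


@dataclass
class RunConfig:
    """Flat run configuration; defaults are the task-protocol values."""

    seed: int = 0
    protocol: str = "headfixed"  # or "educage"
    # behavior
    lick_threshold: int = 1  # educage protocol uses 5
    response_window: float = 2.0
    window_anchor: str = "offset"
    running_window: int = 25
    running_step: int = 25
    last_k: int = 100
    # units
    alpha: float = 0.05
    # auc
    auc_range: tuple[float, float] = (-0.2, 0.6)
    auc_window: float = 0.05
    auc_step: float = 0.025
    auc_n_sample: int = 20
    auc_n_iter: int = 100
    auc_n_shuffle: int = 100
    auc_two_sided: bool = True
    contrasts: tuple[str, ...] = ("stim_easy", "stim_hard", "choice")
    # decode
    decode_window: tuple[float, float] = (0.0, 0.2)
    min_units: int = 20
    min_trials: int = 20
    n_holdout_per_class: int = 10
    n_repeats: int = 100
    timecourse_bin: float = 0.05
    timecourse_range: tuple[float, float] = (-0.5, 10.0)
    timecourse_repeats: int = 20
    latency_step: float = 0.01
    latency_search_range: tuple[float, float] = (-0.5, 0.3)
    latency_baseline: tuple[float, float] = (-0.5, -0.05)
    # tuning
    analysis_level: float = 62.0
    tuning_response_window: tuple[float, float] = (0.0, 0.15)

    def __post_init__(self) -> None:
        if self.protocol == "educage" and self.lick_threshold == 1:
            self.lick_threshold = 5

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        d = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in d.items()
        }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=list)
            fh.write("\n")


def stage_seed(base_seed: int, stage: str, session_index: int) -> int:
    """Deterministic per-stage, per-session sub-seed (counter scheme)."""
    stage_idx = _STAGES.index(stage)
    return int((base_seed * 1000003 + stage_idx * 10007 + session_index) % (2**31 - 1))


def _dump_json(obj: dict, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def _stage_behavior(session: Session, cfg: RunConfig, out: Path) -> dict:
    trials = classify_outcomes(
        session.trials, session.licks,
        lick_threshold=cfg.lick_threshold,
        response_window=cfg.response_window,
        window_anchor=cfg.window_anchor,
    )
    session.trials = trials
    summary = behavior_summary(
        trials, session.licks, last_k=cfg.last_k,
        running_window=cfg.running_window, running_step=cfg.running_step,
    )
    trials.to_csv(out / "trial_outcomes.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    _dump_json(summary.to_dict(), out / "behavior_summary.json")
    return summary.to_dict()


def _stage_units(session: Session, cfg: RunConfig, out: Path) -> dict:
    rows = []
    resp = {u.unit_id for u in responsive_units(session, alpha=cfg.alpha)}
    for u in session.units:
        included = u.unit_id in resp
        row = {"unit_id": u.unit_id, "region": u.region, "layer": u.layer,
               "depth_um": u.depth_um, "included": included}
        if included:
            fp = firing_properties(u, session.trials)
            row.update(dataclasses.asdict(fp))
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "unit_properties.tsv", sep="\t", index=False,
                              float_format=_FLOAT_FMT)
    return {"n_units": len(session.units), "n_responsive": len(resp)}


def _stage_auc(session: Session, cfg: RunConfig, out: Path, seed: int) -> dict:
    resp = responsive_units(session, alpha=cfg.alpha)
    trace_rows, metric_rows = [], []
    skipped = []
    for contrast in cfg.contrasts:
        try:
            pairs = contrast_builder(session.trials, contrast)
        except ValueError as exc:
            skipped.append({"contrast": contrast, "reason": str(exc)})
            continue
        usable = [
            (a, b) for a, b in pairs
            if len(a) >= cfg.auc_n_sample and len(b) >= cfg.auc_n_sample
        ]
        if not usable:
            skipped.append({"contrast": contrast, "reason": "too few trials per class"})
            continue
        for k, u in enumerate(resp):
            per_pair = []
            for j, (a, b) in enumerate(usable):
                sub = seed + 1000 * k + j
                trace = auc_timecourse(
                    u, a, b, window_range=cfg.auc_range, window=cfg.auc_window,
                    step=cfg.auc_step, n_sample=cfg.auc_n_sample,
                    n_iter=cfg.auc_n_iter, seed=sub, contrast=contrast,
                )
                nm, ns = shuffle_null(
                    u, a, b, window_range=cfg.auc_range, window=cfg.auc_window,
                    step=cfg.auc_step, n_sample=cfg.auc_n_sample,
                    n_iter=cfg.auc_n_iter, n_shuffle=cfg.auc_n_shuffle, seed=sub + 1,
                )
                attach_null(trace, nm, ns)
                m = discrimination_metrics(trace, two_sided=cfg.auc_two_sided)
                per_pair.append((trace, m))
                for c, v, mu, sd in zip(trace.bin_centers, trace.auc, nm, ns):
                    trace_rows.append(
                        {"unit_id": u.unit_id, "contrast": contrast, "pair": j,
                         "bin_center": c, "auc": v, "null_mean": mu, "null_sd": sd}
                    )
            onsets = [m.onset_latency for _, m in per_pair if m.onset_latency is not None]
            metric_rows.append(
                {
                    "unit_id": u.unit_id,
                    "contrast": contrast,
                    "onset_latency": float(np.mean(onsets)) if onsets else np.nan,
                    "max_auc": float(np.mean([m.max_auc for _, m in per_pair])),
                    "duration": float(np.mean([m.duration for _, m in per_pair])),
                    "significant": bool(any(m.significant for _, m in per_pair)),
                }
            )
    trace_cols = ["unit_id", "contrast", "pair", "bin_center", "auc", "null_mean", "null_sd"]
    metric_cols = ["unit_id", "contrast", "onset_latency", "max_auc", "duration", "significant"]
    pd.DataFrame(trace_rows, columns=trace_cols).to_csv(
        out / "auc_traces.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(metric_rows, columns=metric_cols).to_csv(
        out / "auc_metrics.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    return {"n_units": len(resp), "skipped": skipped}


def _stage_decode(session: Session, cfg: RunConfig, out: Path, seed: int) -> dict:
    resp = responsive_units(session, alpha=cfg.alpha)
    result: dict = {}
    tc_rows = []
    for i, task in enumerate(("easy", "hard")):
        pm = build_population(
            session, task, window=cfg.decode_window,
            min_units=cfg.min_units, min_trials=cfg.min_trials, units=resp,
        )
        if isinstance(pm, SessionRejection):
            result[task] = {"rejected": pm.reason, "details": pm.details}
            continue
        acc = lda_decode(pm, n_holdout_per_class=cfg.n_holdout_per_class,
                         n_repeats=cfg.n_repeats, seed=seed + i)
        sep = fisher_separation(pm)
        stv = single_trial_variance(pm)
        centers, tc = decode_timecourse(
            session, task, bin_width=cfg.timecourse_bin,
            time_range=cfg.timecourse_range,
            n_holdout_per_class=cfg.n_holdout_per_class,
            n_repeats=cfg.timecourse_repeats, seed=seed + 10 + i, units=resp,
        )
        lat = decoding_latency(
            session, task, bin_width=cfg.timecourse_bin, step=cfg.latency_step,
            search_range=cfg.latency_search_range,
            baseline_window=cfg.latency_baseline,
            n_holdout_per_class=cfg.n_holdout_per_class,
            n_repeats=cfg.timecourse_repeats, seed=seed + 20 + i, units=resp,
        )
        for c, a in zip(centers, tc):
            tc_rows.append({"task": task, "bin_center": c, "accuracy": a})
        result[task] = {
            "accuracy": acc,
            "latency": lat,
            "separation": sep.S,
            "single_trial_variance": stv,
            "n_units": len(pm.unit_ids),
        }
    pd.DataFrame(tc_rows).to_csv(out / "accuracy_timecourse.tsv", sep="\t",
                                 index=False, float_format=_FLOAT_FMT)
    _dump_json(result, out / "decoding.json")
    return result


def _stage_tuning(session: Session, cfg: RunConfig, out: Path) -> dict:
    resp = responsive_units(session, alpha=cfg.alpha)
    rows = []
    fras = []
    for u in resp:
        fra = compute_fra(u, session.trials, response_window=cfg.tuning_response_window,
                          analysis_level=cfg.analysis_level, alpha=cfg.alpha)
        fras.append(fra)
        pd_ = pairwise_dprime(u, session.trials, level=cfg.analysis_level,
                              response_window=cfg.tuning_response_window)
        rows.append(
            {
                "unit_id": u.unit_id,
                "best_frequency": fra.best_frequency,
                "bandwidth_oct": bandwidth(fra, alpha=cfg.alpha),
                "bf_to_go_oct": bf_distance_to_go(fra),
                "mean_pairwise_dprime": pd_.mean_learned,
                "responsive": fra.responsive,
            }
        )
    pd.DataFrame(rows).to_csv(out / "fra_metrics.tsv", sep="\t", index=False,
                              float_format=_FLOAT_FMT)
    sparse = population_sparseness(fras) if fras else None
    _dump_json({"population_sparseness": sparse, "n_units": len(fras)},
               out / "population_sparseness.json")
    return {"population_sparseness": sparse, "n_units": len(fras)}


def run_pipeline(
    config: RunConfig, session_dirs: list[str | Path], out_dir: str | Path
) -> dict:
    """Run every applicable stage on every session; returns the manifest.

    Task sessions (``meta["protocol"] != "fra"``) run behavior, units, auc
    and decode; passive pure-tone sessions run units and tuning.  Each
    session's outputs land under ``out_dir/<session_name>/``; the manifest
    and resolved config are written at the top level.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config_resolved.json")
    manifest: dict = {"version": __version__, "seed": config.seed, "sessions": {}}

    for s_idx, sdir in enumerate(session_dirs):
        name = Path(sdir).name
        sess_out = out / name
        sess_out.mkdir(parents=True, exist_ok=True)
        stages: dict = {}
        manifest["sessions"][name] = stages
        try:
            session = load_session(sdir)
        except Exception as exc:  # noqa: BLE001 — isolate per session
            stages["load"] = {"status": "failed", "error": str(exc)}
            continue
        stages["_meta"] = {
            "group": session.meta.get("group", "unknown"),
            "protocol": session.meta.get("protocol", "task"),
        }
        is_fra = session.meta.get("protocol") == "fra"
        plan = ("units", "tuning") if is_fra else ("behavior", "units", "auc", "decode")
        for stage in plan:
            seed = stage_seed(config.seed, stage, s_idx)
            t0 = time.perf_counter()
            try:
                if stage == "behavior":
                    info = _stage_behavior(session, config, sess_out)
                elif stage == "units":
                    info = _stage_units(session, config, sess_out)
                elif stage == "auc":
                    info = _stage_auc(session, config, sess_out, seed)
                elif stage == "decode":
                    info = _stage_decode(session, config, sess_out, seed)
                else:
                    info = _stage_tuning(session, config, sess_out)
                stages[stage] = {"status": "ok", "seed": seed,
                                 "wall_s": round(time.perf_counter() - t0, 3),
                                 "summary": info}
                log.info("session=%s stage=%s seed=%d ok", name, stage, seed)
            except Exception as exc:  # noqa: BLE001 — later stages still run
                stages[stage] = {"status": "failed", "seed": seed, "error": str(exc)}
                log.warning("session=%s stage=%s failed: %s", name, stage, exc)
    _dump_json(manifest, out / "manifest.json")
    return manifest


def make_report(out_dir: str | Path) -> dict:
    """Collect per-session and cohort tables from a results tree.

    Reads the manifest and stage outputs under ``out_dir`` and writes
    ``report.json`` plus a human-readable ``report.txt``.  Regeneration is
    idempotent.  Stages that did not run are marked "not run".
    """
    out = Path(out_dir)
    with open(out / "manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    report: dict = {"version": manifest.get("version"), "sessions": {}}
    for name, stages in manifest["sessions"].items():
        entry: dict = {}
        sdir = out / name
        if stages.get("behavior", {}).get("status") == "ok":
            with open(sdir / "behavior_summary.json", encoding="utf-8") as fh:
                b = json.load(fh)
            entry["behavior"] = {k: b[k] for k in ("d_easy", "d_hard", "criterion", "cv_d")}
        else:
            entry["behavior"] = "not run"
        if stages.get("auc", {}).get("status") == "ok":
            m = pd.read_csv(sdir / "auc_metrics.tsv", sep="\t")
            entry["auc"] = (
                m.groupby("contrast")["max_auc"].mean().to_dict() if len(m) else {}
            )
        else:
            entry["auc"] = "not run"
        if stages.get("decode", {}).get("status") == "ok":
            with open(sdir / "decoding.json", encoding="utf-8") as fh:
                entry["decoding"] = json.load(fh)
        else:
            entry["decoding"] = "not run"
        if stages.get("tuning", {}).get("status") == "ok":
            with open(sdir / "population_sparseness.json", encoding="utf-8") as fh:
                entry["tuning"] = json.load(fh)
        else:
            entry["tuning"] = "not run"
        entry["group"] = stages.get("_meta", {}).get("group", "unknown")
        report["sessions"][name] = entry

    _dump_json(report, out / "report.json")
    lines = [f"neurodisc report (v{report['version']})", ""]
    for name, entry in report["sessions"].items():
        lines.append(f"session {name} [group={entry['group']}]")
        for key in ("behavior", "auc", "decoding", "tuning"):
            lines.append(f"  {key}: {entry[key]}")
        lines.append("")
    (out / "report.txt").write_text("\n".join(lines), encoding="utf-8")
    return report
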