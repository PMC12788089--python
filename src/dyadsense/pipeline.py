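"""End-to-end orchestration: preprocessing -> features -> stats -> reports.

``run_study`` consumes either a study directory (see :mod:`dyadsense.io`)
or in-memory session recordings, honours the per-task feature exclusions,
and writes tidy CSV tables, a JSON run manifest, and (optionally) figures.
Participants missing one condition of an analysed task are dropped from
that task with a logged warning; an unreadable modality only blanks the
features that need it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .features import (
    FEATURE_UNITS,
    PsdSet,
    WindowedFeature,
    extract_session_features,
)
from .io import read_study, write_study
from .preprocess import preprocess_streams, resample_align, segment
from .stats import (
    ComparisonReport,
    SpectralComparison,
    confidence_ellipse,
    spectral_compare,
    windowwise_compare,
)
from .streams import IMU_AXES, Condition, SessionRecording, Task

log = logging.getLogger("dyadsense")

SCALAR_FEATURES = (
    "heart_rate",
    "hrv",
    "respiratory_rate",
    "pupil_mean",
    "gaze_variance_h",
    "gaze_variance_v",
    "hand_fraction",
)


class TaskExclusionError(ValueError):
    """Raised when a feature is requested for a task it is excluded from."""


@dataclass
class RunManifest:
    config: dict
    seed: int | None
    version: str
    input_hash: str
    outputs: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "seed": self.seed,
                "version": self.version,
                "input_hash": self.input_hash,
                "outputs": sorted(self.outputs),
            },
            indent=1,
            sort_keys=True,
        )


@dataclass
class StudyResult:
    """In-memory result bundle of one study run."""

    features: dict  # (task, feature) -> {condition: WindowedFeature}
    reports: dict  # (task, feature) -> ComparisonReport
    spectra: dict  # (task, axis) -> SpectralComparison
    psd_sets: dict  # (task, axis, condition) -> PsdSet
    ellipses: dict  # (task, condition) -> GazeEllipse
    gaze_points: dict  # (task, condition) -> ndarray (n, 2)
    manifest: RunManifest | None = None


def get_report(
    result: StudyResult, task: str, feature: str, cfg: AnalysisConfig | None = None
) -> ComparisonReport:
    """Fetch one feature's comparison report, refusing excluded task/feature
    combinations explicitly (e.g. gaze features during the reading task)."""
    cfg = cfg or AnalysisConfig()
    task = Task(task).value
    if feature not in cfg.features_for_task(task):
        raise TaskExclusionError(
            f"feature {feature!r} is excluded from the {task!r} task "
            f"(allowed: {cfg.features_for_task(task)})"
        )
    return result.reports[(task, feature)]


def _hash_layout(root: Path) -> str:
    h = hashlib.sha256()
    for f in sorted(Path(root).rglob("*.csv")):
        h.update(str(f.relative_to(root)).encode())
        h.update(f.read_bytes())
    return h.hexdigest()[:16]


def _process_sessions(sessions: list[SessionRecording], cfg: AnalysisConfig):
    """Preprocess + extract per-session features; returns nested dicts."""
    per_session = {}
    for rec in sessions:
        try:
            streams = preprocess_streams(rec, cfg)
            aligned = resample_align(
                streams, cfg, rec.participant_id, rec.condition, rec.task
            )
            windows = segment(aligned, cfg)
            if not windows:
                log.warning(
                    "session %s/%s/%s too short; skipped",
                    rec.participant_id,
                    rec.condition.value,
                    rec.task.value,
                )
                continue
            feats, psds, info = extract_session_features(aligned, windows, cfg)
        except (ValueError, KeyError) as exc:
            log.warning(
                "session %s/%s/%s failed (%s); skipped",
                rec.participant_id,
                rec.condition.value,
                rec.task.value,
                exc,
            )
            continue
        key = (rec.task.value, rec.condition.value, rec.participant_id)
        per_session[key] = {
            "features": feats,
            "psds": psds,
            "info": info,
            "window_end_times": np.array([w.end_time for w in windows]),
        }
    return per_session


def _assemble(per_session: dict, cfg: AnalysisConfig) -> StudyResult:
    tasks = sorted({k[0] for k in per_session})
    features: dict = {}
    reports: dict = {}
    spectra: dict = {}
    psd_sets: dict = {}
    ellipses: dict = {}
    gaze_points: dict = {}

    for task in tasks:
        pids_by_cond = {
            c.value: sorted(
                pid for (t, cond, pid) in per_session if t == task and cond == c.value
            )
            for c in Condition
        }
        pids = sorted(set(pids_by_cond["in_person"]) & set(pids_by_cond["virtual"]))
        dropped = set(pids_by_cond["in_person"]) ^ set(pids_by_cond["virtual"])
        for pid in sorted(dropped):
            log.warning("participant %s lacks one condition for task %s; dropped", pid, task)
        if len(pids) < 2:
            log.warning("task %s has fewer than 2 complete pairs; skipped", task)
            continue

        # Common window grid: shortest session defines the count.
        n_win = min(
            len(per_session[(task, c, p)]["window_end_times"])
            for c in ("in_person", "virtual")
            for p in pids
        )
        end_times = per_session[(task, "in_person", pids[0])]["window_end_times"][:n_win]

        for feat in cfg.features_for_task(task):
            if feat == "head_psd":
                continue
            per_cond = {}
            for cond in ("in_person", "virtual"):
                mat = np.full((len(pids), n_win), np.nan)
                for i, pid in enumerate(pids):
                    v = per_session[(task, cond, pid)]["features"].get(feat)
                    if v is not None:
                        mat[i] = v[:n_win]
                per_cond[cond] = WindowedFeature(
                    feature_name=feat,
                    units=FEATURE_UNITS[feat],
                    condition=cond,
                    task=task,
                    participants=pids,
                    values=mat,
                    window_end_times=end_times,
                )
            features[(task, feat)] = per_cond
            reports[(task, feat)] = windowwise_compare(
                per_cond["in_person"], per_cond["virtual"], cfg
            )

        if "head_psd" in cfg.features_for_task(task):
            freqs = per_session[(task, "in_person", pids[0])]["info"]["psd_frequencies"]
            for ax in IMU_AXES:
                sets = {}
                for cond in ("in_person", "virtual"):
                    power = np.vstack(
                        [per_session[(task, cond, pid)]["psds"][ax] for pid in pids]
                    )
                    sets[cond] = PsdSet(
                        signal_axis=ax,
                        frequencies=freqs,
                        power=power,
                        participants=pids,
                        condition=cond,
                        task=task,
                    )
                    psd_sets[(task, ax, cond)] = sets[cond]
                spectra[(task, ax)] = spectral_compare(
                    sets["in_person"], sets["virtual"], cfg
                )

        if "gaze_variance_h" in cfg.features_for_task(task):
            for cond in ("in_person", "virtual"):
                pts = np.vstack(
                    [
                        np.column_stack(
                            [
                                per_session[(task, cond, pid)]["info"]["gaze_mean_h"][:n_win],
                                per_session[(task, cond, pid)]["info"]["gaze_mean_v"][:n_win],
                            ]
                        )
                        for pid in pids
                    ]
                )
                gaze_points[(task, cond)] = pts
                ellipses[(task, cond)] = confidence_ellipse(pts, cfg.ellipse_level)

    return StudyResult(
        features=features,
        reports=reports,
        spectra=spectra,
        psd_sets=psd_sets,
        ellipses=ellipses,
        gaze_points=gaze_points,
    )


def analyze_sessions(sessions: list[SessionRecording], cfg: AnalysisConfig | None = None) -> StudyResult:
    """Run the full analysis on in-memory sessions (no disk I/O)."""
    cfg = cfg or AnalysisConfig()
    return _assemble(_process_sessions(sessions, cfg), cfg)


def _write_tables(result: StudyResult, out: Path) -> list[str]:
    out.mkdir(parents=True, exist_ok=True)
    written = []

    rows = []
    for (task, feat), per_cond in result.features.items():
        for cond, wf in per_cond.items():
            for i, pid in enumerate(wf.participants):
                for j, t_end in enumerate(wf.window_end_times):
                    rows.append(
                        {
                            "participant": pid,
                            "condition": cond,
                            "task": task,
                            "window_end_s": t_end,
                            "feature": feat,
                            "value": wf.values[i, j],
                        }
                    )
    if rows:
        f = out / "features.csv"
        pd.DataFrame(rows).to_csv(f, index=False, float_format="%.8g")
        written.append(f.name)

    comp_rows, summary_rows = [], []
    for (task, feat), rep in result.reports.items():
        for j, t_end in enumerate(rep.window_end_times):
            comp_rows.append(
                {
                    "task": task,
                    "feature": feat,
                    "window_end_s": t_end,
                    "p_value": rep.p_values[j],
                    "significant": bool(rep.significant[j]),
                    "significant_bh": bool(rep.significant_bh[j]),
                    "n_pairs": int(rep.n_pairs[j]),
                }
            )
        summary_rows.append(
            {
                "task": task,
                "feature": feat,
                "summary_p": rep.summary_p,
                "mean_in_person": float(np.nanmean(rep.summary_means["in_person"])),
                "mean_virtual": float(np.nanmean(rep.summary_means["virtual"])),
            }
        )
    if comp_rows:
        f = out / "windowwise_comparisons.csv"
        pd.DataFrame(comp_rows).to_csv(f, index=False, float_format="%.8g")
        written.append(f.name)
        f = out / "summary_comparisons.csv"
        pd.DataFrame(summary_rows).to_csv(f, index=False, float_format="%.8g")
        written.append(f.name)

    spec_rows = []
    for (task, ax), sc in result.spectra.items():
        for i, fr in enumerate(sc.frequencies):
            spec_rows.append(
                {
                    "task": task,
                    "signal_axis": ax,
                    "frequency_hz": fr,
                    "normalized_difference": sc.normalized_difference[i],
                    "p_raw": sc.p_raw[i],
                    "p_adjusted": sc.p_adjusted[i],
                    "significant": bool(sc.rejected[i]),
                }
            )
    if spec_rows:
        f = out / "spectral_comparisons.csv"
        pd.DataFrame(spec_rows).to_csv(f, index=False, float_format="%.8g")
        written.append(f.name)

    if result.ellipses:
        ell = {
            f"{task}/{cond}": {
                "center": list(e.center),
                "semi_axes": list(e.semi_axes),
                "angle_rad": e.angle_rad,
                "level": e.level,
                "degenerate": e.degenerate,
            }
            for (task, cond), e in result.ellipses.items()
        }
        f = out / "gaze_ellipses.json"
        f.write_text(json.dumps(ell, indent=1, sort_keys=True))
        written.append(f.name)
    return written


def run_study(
    layout: Path | list[SessionRecording],
    cfg: AnalysisConfig | None = None,
    out: Path | None = None,
    seed: int | None = None,
    make_figures: bool = False,
) -> StudyResult:
    """Analyse a study layout directory (or in-memory sessions) end-to-end.

    Writes tidy feature/comparison/spectral tables, a gaze-ellipse JSON and
    a run manifest under ``out`` when given.
    """
    cfg = cfg or AnalysisConfig()
    if isinstance(layout, (str, Path)):
        sessions = read_study(Path(layout))
        input_hash = _hash_layout(Path(layout))
    else:
        sessions = layout
        input_hash = "in-memory"
    result = analyze_sessions(sessions, cfg)
    if out is not None:
        out = Path(out)
        written = _write_tables(result, out)
        if make_figures:
            from .plotting import render_report_figures

            written += render_report_figures(result, out)
        manifest = RunManifest(
            config=cfg.to_dict(),
            seed=seed,
            version=__version__,
            input_hash=input_hash,
            outputs=written,
        )
        (out / "manifest.json").write_text(manifest.to_json())
        result.manifest = manifest
    return result


def simulate_study(
    seed: int = 0,
    n_participants: int = 18,
    duration: float = 300.0,
    null_effects: bool = False,
    out: Path | None = None,
    tasks: tuple[str, ...] = ("reading", "free_talk"),
):
    """Generate a synthetic paired study (optionally writing the layout)."""
    from .synth import EffectConfig, GroundTruth, generate_dyad_study

    effects = (
        EffectConfig.null(n_participants)
        if null_effects
        else EffectConfig(n_participants=n_participants)
    )
    base = GroundTruth(duration=duration, seed=seed)
    sessions = generate_dyad_study(effects, base, tasks=tasks)
    if out is not None:
        write_study(sessions, Path(out))
    return sessions
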