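"""Nose-touch bout detection, metrics and human-scorer calibration.

A nose touch is scored when the experimental animal's nose comes within a
pixel-distance threshold of a stimulus animal's nose and stays there for a
minimum consecutive duration.  Contact frames are grouped into bouts by
run-length encoding; frames where either nose is tracked with low
confidence (likelihood below 0.90 by default) are excluded and therefore
break runs — "consecutive" is taken literally, with no gap bridging.

Detector thresholds default to 7.5 px and 200 ms (about 7 frames at the
default 35 Hz) and can be re-calibrated against human-scored bout lists by
exhaustive grid search minimising the per-trial total-time RMSE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pose_io import Bout, KeypointTrack, TrialRecord

TARGETS: tuple[str, ...] = ("left_enclosure", "right_enclosure")
_TARGET_NOSE = {"left_enclosure": "stim_left_nose", "right_enclosure": "stim_right_nose"}


@dataclass(frozen=True)
class DetectorParams:
    """Distance / duration / confidence rule defining a nose touch."""

    distance_threshold_px: float = 7.5
    min_duration_ms: float = 200.0
    confidence_floor: float = 0.90

    def __post_init__(self) -> None:
        if self.distance_threshold_px <= 0 or self.min_duration_ms <= 0:
            raise ValueError("distance and duration thresholds must be positive")
        if not 0 <= self.confidence_floor <= 1:
            raise ValueError("confidence_floor must lie in [0, 1]")

    def min_frames(self, frame_rate_hz: float) -> int:
        """Smallest run length (frames) covering at least min_duration_ms."""
        return max(1, math.ceil(self.min_duration_ms / 1000.0 * frame_rate_hz))


@dataclass
class DistanceSeries:
    """Per-frame nose-to-nose distances and validity per enclosure target."""

    distance_px: dict[str, np.ndarray]
    valid: dict[str, np.ndarray]
    frame_rate_hz: float

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.distance_px.values())))


def internose_distances(track: KeypointTrack, params: DetectorParams) -> DistanceSeries:
    """Euclidean distance from the experimental nose to each stimulus nose.

    A frame is valid for a target only when both the experimental nose and
    that target's nose are tracked at or above the confidence floor.
    """
    nose = track.xy("nose")
    nose_conf = track.confidence("nose")
    dist, valid = {}, {}
    for target, bp in _TARGET_NOSE.items():
        sxy = track.xy(bp)
        d = np.sqrt(np.sum((nose - sxy) ** 2, axis=1))
        ok = (nose_conf >= params.confidence_floor) & (
            track.confidence(bp) >= params.confidence_floor
        )
        ok &= np.isfinite(d)
        dist[target] = d
        valid[target] = ok
    return DistanceSeries(dist, valid, track.frame_rate_hz)


def detect_bouts(
    series: DistanceSeries,
    params: DetectorParams,
    frame_rate_hz: float | None = None,
) -> list[Bout]:
    """Run-length encode contact frames into nose-touch bouts.

    A contact frame is a valid frame with distance strictly below the
    threshold; maximal runs shorter than the minimum duration are dropped.
    """
    fps = frame_rate_hz if frame_rate_hz is not None else series.frame_rate_hz
    if fps <= 0:
        raise ValueError("frame_rate_hz must be positive")
    k = params.min_frames(fps)
    bouts: list[Bout] = []
    for target in TARGETS:
        contact = series.valid[target] & (
            series.distance_px[target] < params.distance_threshold_px
        )
        for s, e in _true_runs(contact):
            if e - s >= k:
                bouts.append(
                    Bout(
                        target=target,
                        start_frame=s,
                        end_frame_exclusive=e,
                        duration_s=(e - s) / fps,
                    )
                )
    return sorted(bouts, key=lambda b: (b.start_frame, b.target))


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index ranges of maximal True runs."""
    m = np.asarray(mask, bool)
    if m.size == 0:
        return []
    padded = np.concatenate([[False], m, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


# ---------------------------------------------------------------------------
# Bout metrics
# ---------------------------------------------------------------------------


@dataclass
class NoseTouchMetrics:
    """Totals per enclosure target and pooled, plus the novelty score."""

    per_target: dict[str, dict[str, float]]
    pooled: dict[str, float]
    nose_touch_novelty_score: float  # NaN outside the social-novelty phase


def _bout_summary(bouts: Sequence[Bout]) -> dict[str, float]:
    durations = [b.duration_s for b in bouts]
    total = float(sum(durations))
    return {
        "total_time_s": total,
        "bout_count": float(len(durations)),
        "mean_duration_s": total / len(durations) if durations else float("nan"),
        "longest_bout_s": max(durations) if durations else float("nan"),
    }


def nose_touch_metrics(bouts: Sequence[Bout], record: TrialRecord) -> NoseTouchMetrics:
    """Summarise one trial's bouts per target and pooled.

    In the social-novelty phase ``record.stimulus_side`` names the novel
    animal's side; the novelty score is novel time over novel + familiar
    time, missing when neither target was touched.
    """
    per_target = {t: _bout_summary([b for b in bouts if b.target == t]) for t in TARGETS}
    pooled = _bout_summary(list(bouts))
    score = float("nan")
    if record.phase == "social_novelty":
        novel = per_target[f"{record.stimulus_side}_enclosure"]["total_time_s"]
        fam_side = "right" if record.stimulus_side == "left" else "left"
        familiar = per_target[f"{fam_side}_enclosure"]["total_time_s"]
        denom = novel + familiar
        if denom > 0:
            score = novel / denom
    return NoseTouchMetrics(per_target, pooled, score)


def metrics_row(nt: NoseTouchMetrics, record: TrialRecord) -> dict[str, float]:
    """Flatten nose-touch metrics into tidy-table columns for the phase."""
    row = {
        "total_nose_touch_time_s": nt.pooled["total_time_s"],
        "mean_nose_touch_duration_s": nt.pooled["mean_duration_s"],
        "longest_nose_touch_s": nt.pooled["longest_bout_s"],
    }
    if record.phase == "social_novelty":
        fam_side = "right" if record.stimulus_side == "left" else "left"
        row.update(
            {
                "nose_touch_novelty_score": nt.nose_touch_novelty_score,
                "novel_nose_touch_time_s": nt.per_target[
                    f"{record.stimulus_side}_enclosure"
                ]["total_time_s"],
                "familiar_nose_touch_time_s": nt.per_target[f"{fam_side}_enclosure"][
                    "total_time_s"
                ],
            }
        )
    return row


# ---------------------------------------------------------------------------
# Validation against a human scorer
# ---------------------------------------------------------------------------


@dataclass
class ValidationResult:
    """Machine vs human per-trial total nose-touch times and their RMSE."""

    per_trial: pd.DataFrame  # columns: trial, machine_total_s, human_total_s
    rmse_s: float
    n_trials: int


def rmse_vs_human(
    machine: Mapping[object, Sequence[Bout]],
    human: Mapping[object, Sequence[Bout]],
) -> ValidationResult:
    """Root-mean-squared difference of per-trial total nose-touch time."""
    if set(machine) != set(human):
        raise ValueError(
            f"trial sets differ: machine-only={set(machine) - set(human)}, "
            f"human-only={set(human) - set(machine)}"
        )
    if not machine:
        raise ValueError("no trials to compare")
    rows = []
    for trial in sorted(machine, key=str):
        m = sum(b.duration_s for b in machine[trial])
        h = sum(b.duration_s for b in human[trial])
        rows.append({"trial": trial, "machine_total_s": m, "human_total_s": h})
    df = pd.DataFrame(rows)
    err = df["machine_total_s"] - df["human_total_s"]
    rmse = float(np.sqrt(np.mean(err.to_numpy() ** 2)))
    return ValidationResult(df, rmse, len(df))


def default_grid(frame_rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """Default calibration grid: distance 2-15 px (step 0.5) and durations
    from ~57 to 500 ms in steps of one frame period."""
    distances = np.arange(2.0, 15.0 + 1e-9, 0.5)
    k_min = math.ceil(57.0 / 1000.0 * frame_rate_hz)
    k_max = math.floor(500.0 / 1000.0 * frame_rate_hz)
    durations = np.array([k * 1000.0 / frame_rate_hz for k in range(k_min, k_max + 1)])
    return distances, durations


def optimize_params(
    tracks: Mapping[object, KeypointTrack],
    human: Mapping[object, Sequence[Bout]],
    distance_grid_px: Sequence[float] | None = None,
    duration_grid_ms: Sequence[float] | None = None,
    confidence_floor: float = 0.90,
) -> tuple[DetectorParams, ValidationResult]:
    """Exhaustive grid search for the detector thresholds.

    Minimises the per-trial total-time RMSE against the human annotations;
    ties are broken toward the larger distance threshold, then the larger
    duration (the most conservative rule among equally good fits).
    """
    if set(tracks) != set(human):
        raise ValueError("tracks and human annotations must cover the same trials")
    if len(tracks) < 2:
        raise ValueError("calibration needs at least 2 annotated trials")
    fps = next(iter(tracks.values())).frame_rate_hz
    if distance_grid_px is None or duration_grid_ms is None:
        d_def, t_def = default_grid(fps)
        distance_grid_px = d_def if distance_grid_px is None else distance_grid_px
        duration_grid_ms = t_def if duration_grid_ms is None else duration_grid_ms
    if len(distance_grid_px) == 0 or len(duration_grid_ms) == 0:
        raise ValueError("calibration grid must be nonempty")

    base = DetectorParams(confidence_floor=confidence_floor)
    series = {
        trial: internose_distances(
            tr, DetectorParams(base.distance_threshold_px, base.min_duration_ms, confidence_floor)
        )
        for trial, tr in tracks.items()
    }
    best: tuple[float, float, float] | None = None  # (rmse, -dist, -dur)
    best_params: DetectorParams | None = None
    best_result: ValidationResult | None = None
    for dist in distance_grid_px:
        for dur in duration_grid_ms:
            params = DetectorParams(float(dist), float(dur), confidence_floor)
            machine = {t: detect_bouts(s, params) for t, s in series.items()}
            result = rmse_vs_human(machine, human)
            key = (result.rmse_s, -float(dist), -float(dur))
            if best is None or key < best:
                best, best_params, best_result = key, params, result
    assert best_params is not None and best_result is not None
    return best_params, best_result
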