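"""Trial-level quality control and exclusion rules.

Three quantitative rules are applied, mirroring the behavioural screening a
tracking study performs before statistics:

* trials losing strictly more than 20 s of experimental time to tracking
  failure are excluded entirely;
* animals that did not spend at least 10 s in each flanking chamber during
  the sociability stage are kept for stage 1 but removed from stage 2
  (they never had the chance to become familiar with the stimulus animal);
* trials whose distance traveled is a robust-z outlier within sex are
  flagged for review (poor tracking fidelity), not auto-excluded.

Every removed row is logged with the rule that removed it, and applying the
exclusions twice changes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pose_io import KeypointTrack, TrialRecord
from .zone_scoring import ZoneTimeline

RULE_TRACKING_LOSS = "tracking_loss_gt_max"
RULE_FLANK_TIME = "flank_time_lt_min"
RULE_ANOMALY = "distance_anomaly"
RULE_MANUAL = "manual_exclude"


@dataclass(frozen=True)
class QCConfig:
    max_lost_time_s: float = 20.0
    min_flank_time_s: float = 10.0
    anomaly_distance_z: float = 4.0
    confidence_floor: float = 0.90

    def __post_init__(self) -> None:
        if self.max_lost_time_s <= 0 or self.min_flank_time_s <= 0:
            raise ValueError("QC thresholds must be positive")


@dataclass
class QCReport:
    """Per-trial QC measurements and flags.

    ``table`` has one row per (animal_id, phase) with columns
    lost_time_s, flank_left_s, flank_right_s, exclude_all,
    exclude_stage2_only, anomaly and a semicolon-joined ``reasons`` field.
    """

    table: pd.DataFrame

    def flags_for(self, animal_id: str, phase: str) -> pd.Series:
        m = (self.table["animal_id"] == animal_id) & (self.table["phase"] == phase)
        return self.table.loc[m].iloc[0]


def tracking_loss(track: KeypointTrack, config: QCConfig = QCConfig()) -> float:
    """Seconds of trial time with an unusable body-center fix.

    A frame is lost when the body-center confidence is below the floor or
    its coordinates are missing.
    """
    conf = track.confidence("body_center")
    xy = track.xy("body_center")
    lost = (conf < config.confidence_floor) | ~np.all(np.isfinite(xy), axis=1)
    return float(lost.sum()) / track.frame_rate_hz


def stage1_familiarity_gate(
    sociability_timeline: ZoneTimeline, config: QCConfig = QCConfig()
) -> tuple[bool, float, float]:
    """Whether stage 2 must be dropped, plus per-side flanking-chamber times.

    Flanking-chamber time counts the whole chamber (investigation plus
    distal zone of that side).  The rule is inclusive: exactly the minimum
    passes.
    """
    times = sociability_timeline.zone_times_s()
    left = times["left_invest"] + times["left_distal"]
    right = times["right_invest"] + times["right_distal"]
    exclude = left < config.min_flank_time_s or right < config.min_flank_time_s
    return exclude, left, right


def anomaly_flags(
    metrics: pd.DataFrame, config: QCConfig = QCConfig()
) -> pd.Series:
    """Robust-z outlier flags on distance traveled, computed within sex.

    Uses median/MAD (scaled to be SD-consistent); falls back to the SD when
    the MAD is zero.  Requires at least 10 trials to be meaningful.
    """
    if len(metrics) < 10:
        raise ValueError("anomaly screening needs at least 10 trials")
    flags = pd.Series(False, index=metrics.index)
    if not np.isfinite(config.anomaly_distance_z):
        return flags
    for _, idx in metrics.groupby("sex").groups.items():
        vals = metrics.loc[idx, "distance_traveled_m"].to_numpy(float)
        med = np.nanmedian(vals)
        mad = np.nanmedian(np.abs(vals - med)) * 1.4826
        scale = mad if mad > 0 else np.nanstd(vals)
        if scale == 0 or not np.isfinite(scale):
            continue
        z = (vals - med) / scale
        flags.loc[idx] = np.abs(z) > config.anomaly_distance_z
    return flags


def build_qc_report(
    tracks: dict[tuple[str, str], KeypointTrack],
    timelines: dict[tuple[str, str], ZoneTimeline],
    records: list[TrialRecord],
    metrics: pd.DataFrame | None = None,
    config: QCConfig = QCConfig(),
) -> QCReport:
    """Assemble the per-trial QC table from tracks and sociability timelines.

    ``tracks`` and ``timelines`` are keyed by (animal_id, phase); the
    familiarity gate of an animal's sociability trial propagates to its
    social-novelty row.  When the sociability trial of an animal with a
    novelty trial is missing, the gate is reported unresolved (and the
    novelty row flagged for exclusion from stage 2).
    """
    gate_by_animal: dict[str, bool | None] = {}
    flank_by_animal: dict[str, tuple[float, float]] = {}
    for rec in records:
        if rec.phase != "sociability":
            continue
        key = (rec.animal_id, rec.phase)
        if key in timelines:
            excl, left, right = stage1_familiarity_gate(timelines[key], config)
            gate_by_animal[rec.animal_id] = excl
            flank_by_animal[rec.animal_id] = (left, right)

    anomaly = None
    if metrics is not None and len(metrics) >= 10:
        anomaly = anomaly_flags(metrics, config)

    rows = []
    for rec in records:
        key = (rec.animal_id, rec.phase)
        lost = tracking_loss(tracks[key], config) if key in tracks else float("nan")
        reasons = []
        exclude_all = False
        if rec.manual_exclude:
            exclude_all = True
            reasons.append(RULE_MANUAL)
        if np.isfinite(lost) and lost > config.max_lost_time_s:
            exclude_all = True
            reasons.append(RULE_TRACKING_LOSS)
        exclude_stage2 = False
        flank_l, flank_r = flank_by_animal.get(rec.animal_id, (float("nan"),) * 2)
        if rec.phase == "social_novelty":
            gate = gate_by_animal.get(rec.animal_id)
            if gate or gate is None:  # unresolved gate is treated as failed
                exclude_stage2 = True
                reasons.append(RULE_FLANK_TIME)
        anom = False
        if anomaly is not None and metrics is not None:
            m = (metrics["animal_id"] == rec.animal_id) & (metrics["phase"] == rec.phase)
            if m.any():
                anom = bool(anomaly[m].any())
                if anom:
                    reasons.append(RULE_ANOMALY)
        if exclude_all:
            exclude_stage2 = False  # subsumed
            reasons = [r for r in reasons if r != RULE_FLANK_TIME]
        rows.append(
            {
                "animal_id": rec.animal_id,
                "phase": rec.phase,
                "lost_time_s": lost,
                "flank_left_s": flank_l,
                "flank_right_s": flank_r,
                "exclude_all": exclude_all,
                "exclude_stage2_only": exclude_stage2,
                "anomaly": anom,
                "reasons": ";".join(reasons),
            }
        )
    return QCReport(pd.DataFrame(rows))


def apply_exclusions(
    cohort: pd.DataFrame, report: QCReport
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop excluded (animal, phase) rows from the tidy metric table.

    Returns the filtered table and an exclusion log with one row per
    removed (animal_id, phase, rule).  Anomaly flags are advisory and do
    not remove rows.  Idempotent: re-applying to the output is a no-op.
    """
    rep = report.table.set_index(["animal_id", "phase"])
    keep = np.ones(len(cohort), dtype=bool)
    log_rows = []
    for i, (_, row) in enumerate(cohort.iterrows()):
        key = (row["animal_id"], row["phase"])
        if key not in rep.index:
            continue
        flags = rep.loc[key]
        drop = bool(flags["exclude_all"]) or (
            row["phase"] == "social_novelty" and bool(flags["exclude_stage2_only"])
        )
        if drop:
            keep[i] = False
            rules = [
                r for r in str(flags["reasons"]).split(";") if r and r != RULE_ANOMALY
            ]
            # one log row per removed trial keeps |input| = |output| + |log|
            log_rows.append(
                {
                    "animal_id": row["animal_id"],
                    "phase": row["phase"],
                    "rule": ";".join(rules),
                }
            )
    log = pd.DataFrame(log_rows, columns=["animal_id", "phase", "rule"])
    return cohort.loc[keep].reset_index(drop=True), log
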