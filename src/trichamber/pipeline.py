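"""End-to-end scoring: keypoint tracks -> tidy per-animal metric table."""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .nose_touch import (
    DetectorParams,
    detect_bouts,
    internose_distances,
    metrics_row,
    nose_touch_metrics,
)
from .pose_io import Bout, KeypointTrack, TrialRecord
from .zone_scoring import (
    ArenaGeometry,
    ZoneTimeline,
    assign_zones,
    novelty_metrics,
    sociability_metrics,
)


def score_trial(
    track: KeypointTrack,
    record: TrialRecord,
    geom: ArenaGeometry,
    params: DetectorParams = DetectorParams(),
) -> tuple[dict[str, float], ZoneTimeline, list[Bout]]:
    """Score one test-phase trial: occupancy metrics + nose-touch metrics.

    Returns the flat metric row, the zone timeline and the detected bouts.
    """
    timeline = assign_zones(track, geom)
    if record.phase == "sociability":
        occ = sociability_metrics(timeline, track, record, geom)
    elif record.phase == "social_novelty":
        occ = novelty_metrics(timeline, track, record, geom)
    else:
        raise ValueError("habituation trials carry no behavioural metrics")
    bouts = detect_bouts(internose_distances(track, params), params)
    nt = nose_touch_metrics(bouts, record)
    row = {**occ.values, **metrics_row(nt, record)}
    return row, timeline, bouts


def score_trials(
    trials: Iterable[tuple[KeypointTrack, TrialRecord]],
    geom: ArenaGeometry,
    params: DetectorParams = DetectorParams(),
) -> tuple[pd.DataFrame, dict[tuple[str, str], ZoneTimeline], dict[tuple[str, str], list[Bout]]]:
    """Score many trials into the tidy cohort table.

    Returns (cohort table, timelines, bouts) keyed by (animal_id, phase).
    """
    rows = []
    timelines: dict[tuple[str, str], ZoneTimeline] = {}
    bouts_by_trial: dict[tuple[str, str], list[Bout]] = {}
    for track, record in trials:
        row, timeline, bouts = score_trial(track, record, geom, params)
        key = (record.animal_id, record.phase)
        timelines[key] = timeline
        bouts_by_trial[key] = bouts
        rows.append(
            {
                "animal_id": record.animal_id,
                "litter_id": record.litter_id,
                "sex": record.sex,
                "generation": record.generation,
                "lineage": record.lineage,
                "treatment_first": record.treatment_first,
                "treatment_second": record.treatment_second,
                "treatment": record.treatment_label,
                "phase": record.phase,
                "stimulus_side": record.stimulus_side,
                **row,
            }
        )
    return pd.DataFrame(rows), timelines, bouts_by_trial
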