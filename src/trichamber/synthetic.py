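"""Synthetic three-chamber trials and cohorts with ground truth.

The simulator stands in for the study's videos: it produces keypoint
tracks with the statistical structure the analysis pipeline assumes, plus
the ground truth needed to verify every downstream stage (true zone
timeline, true nose-touch bouts, injected effect sizes).

A trial is a zone-structured random walk of the experimental animal's body
center: dwell times within a zone are exponential with configurable means,
movement between zones follows straight segments through the door
waypoints at a configurable speed, and the remaining body parts ride on a
rigid template oriented along the heading with small jitter.  Stimulus
noses jitter inside their enclosures.  Planted nose-touch bouts are
scheduled appointments: the walk arrives at the enclosure in time, a short
approach ramp sweeps the inter-nose distance down through the detection
threshold, the bout frames hold the nose strictly inside the threshold,
and a retreat ramp leaves again — so a detector at the planted thresholds
recovers the planted bouts exactly, and no other frame comes close enough
to create a spurious contact.

Cohort simulation draws per-animal metric targets from sex-typical
distributions (anchored to the published sex summary statistics of the
~600-per-sex rat cohort this package models) and inverse-tunes the trial
parameters (dwell means, speed, planted bouts) so realized metrics
approximate the targets.  Standardized effect shifts are injected on the
metric targets, which keeps planted effect sizes interpretable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pose_io import (
    ALL_METRICS,
    BODYPARTS,
    EXPERIMENTAL_BODYPARTS,
    NOVELTY_METRICS,
    SOCIABILITY_METRICS,
    Bout,
    KeypointTrack,
    TrialRecord,
    make_track,
)
from .zone_scoring import AREA_RULE_FRACTION, ArenaGeometry, ZoneTimeline

# ---------------------------------------------------------------------------
# Study-scale anchors
# ---------------------------------------------------------------------------

#: Published cohort design: (generation, lineage, treatment label) ->
#: (litters, females, males).  Lineage is "NA" for the directly exposed
#: generation, which has no breeding lineage yet.
STUDY_SAMPLE_SIZES: dict[tuple[str, str, str], tuple[int, int, int]] = {
    ("F1", "NA", "DMSO"): (10, 21, 25),
    ("F1", "NA", "A1221"): (10, 28, 24),
    ("F1", "NA", "VIN"): (10, 28, 24),
    ("F3", "maternal", "DMSO"): (11, 21, 21),
    ("F3", "maternal", "A1221"): (10, 18, 24),
    ("F3", "maternal", "VIN"): (12, 19, 23),
    ("F3", "paternal", "DMSO"): (10, 23, 21),
    ("F3", "paternal", "A1221"): (11, 22, 18),
    ("F3", "paternal", "VIN"): (11, 18, 21),
    ("F4", "maternal", "DMSO/DMSO"): (13, 22, 21),
    ("F4", "maternal", "A1221/A1221"): (9, 15, 18),
    ("F4", "maternal", "A1221/VIN"): (9, 18, 19),
    ("F4", "maternal", "VIN/A1221"): (12, 21, 22),
    ("F4", "maternal", "VIN/VIN"): (13, 20, 22),
    ("F4", "paternal", "DMSO/DMSO"): (12, 25, 22),
    ("F4", "paternal", "A1221/A1221"): (8, 18, 15),
    ("F4", "paternal", "A1221/VIN"): (9, 17, 18),
    ("F4", "paternal", "VIN/A1221"): (11, 21, 21),
    ("F4", "paternal", "VIN/VIN"): (12, 19, 20),
    ("F6", "maternal", "DMSO/DMSO"): (12, 22, 23),
    ("F6", "maternal", "A1221/A1221"): (9, 18, 20),
    ("F6", "maternal", "A1221/VIN"): (9, 22, 18),
    ("F6", "maternal", "VIN/A1221"): (11, 19, 23),
    ("F6", "maternal", "VIN/VIN"): (12, 22, 22),
    ("F6", "paternal", "DMSO/DMSO"): (12, 21, 24),
    ("F6", "paternal", "A1221/A1221"): (8, 18, 20),
    ("F6", "paternal", "A1221/VIN"): (9, 20, 20),
    ("F6", "paternal", "VIN/A1221"): (11, 22, 21),
    ("F6", "paternal", "VIN/VIN"): (10, 19, 22),
}


def study_design_totals() -> dict[str, int]:
    """Litter and per-sex animal totals summed over every design cell."""
    litters = sum(v[0] for v in STUDY_SAMPLE_SIZES.values())
    females = sum(v[1] for v in STUDY_SAMPLE_SIZES.values())
    males = sum(v[2] for v in STUDY_SAMPLE_SIZES.values())
    return {
        "litters": litters,
        "females": females,
        "males": males,
        "animals": females + males,
    }


_N_SEX = {"F": 596, "M": 601}

#: Sex-typical metric summaries (mean, SEM) per phase; SDs are recovered as
#: SEM * sqrt(N).  These are the generator's default study conditions.
SEX_SUMMARY: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "sociability": {
        "distance_traveled_m": {"F": (52.63, 0.36), "M": (38.58, 0.30)},
        "social_preference_score": {"F": (0.62, 0.01), "M": (0.67, 0.01)},
        "stimulus_investigation_time_s": {"F": (224.35, 2.68), "M": (245.90, 3.02)},
        "empty_investigation_time_s": {"F": (135.26, 2.13), "M": (123.31, 2.59)},
        "stimulus_visits": {"F": (10.26, 0.13), "M": (8.68, 0.14)},
        "empty_visits": {"F": (8.42, 0.11), "M": (6.25, 0.09)},
        "stimulus_mean_visit_time_s": {"F": (24.46, 0.50), "M": (34.76, 1.06)},
        "empty_mean_visit_time_s": {"F": (17.58, 0.38), "M": (22.78, 0.68)},
        "total_nonsocial_time_s": {"F": (240.01, 2.79), "M": (229.86, 2.86)},
        "center_isolation_time_s": {"F": (99.54, 1.19), "M": (107.72, 1.60)},
        "total_nose_touch_time_s": {"F": (20.21, 0.40), "M": (19.51, 0.39)},
        "mean_nose_touch_duration_s": {"F": (0.66, 0.01), "M": (0.63, 0.01)},
    },
    "social_novelty": {
        "distance_traveled_m": {"F": (46.35, 0.39), "M": (32.44, 0.29)},
        "social_novelty_score": {"F": (0.62, 0.01), "M": (0.60, 0.01)},
        "familiar_investigation_time_s": {"F": (124.31, 2.16), "M": (142.47, 2.84)},
        "novel_investigation_time_s": {"F": (208.61, 2.81), "M": (215.03, 3.17)},
        "familiar_visits": {"F": (8.01, 0.11), "M": (6.32, 0.09)},
        "novel_visits": {"F": (10.09, 0.13), "M": (7.74, 0.11)},
        "familiar_mean_visit_time_s": {"F": (16.89, 0.55), "M": (24.67, 0.60)},
        "novel_mean_visit_time_s": {"F": (22.46, 0.44), "M": (31.39, 0.72)},
        "total_social_time_s": {"F": (332.92, 2.96), "M": (357.50, 3.16)},
        "total_nonsocial_time_s": {"F": (273.37, 3.77), "M": (249.89, 4.04)},
        "center_isolation_time_s": {"F": (125.54, 1.78), "M": (116.37, 1.92)},
        "nose_touch_novelty_score": {"F": (0.65, 0.01), "M": (0.64, 0.01)},
        "familiar_nose_touch_time_s": {"F": (9.33, 0.27), "M": (8.62, 0.30)},
        "novel_nose_touch_time_s": {"F": (17.77, 0.41), "M": (15.41, 0.38)},
    },
}


def metric_mean_sd(phase: str, metric: str, sex: str) -> tuple[float, float]:
    mean, sem = SEX_SUMMARY[phase][metric][sex]
    return mean, sem * math.sqrt(_N_SEX[sex])


def metric_pooled_sd(phase: str, metric: str) -> float:
    _, sd_f = metric_mean_sd(phase, metric, "F")
    _, sd_m = metric_mean_sd(phase, metric, "M")
    return math.sqrt((sd_f**2 + sd_m**2) / 2.0)


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedBout:
    target: str  # left_enclosure | right_enclosure
    start_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.target not in ("left_enclosure", "right_enclosure"):
            raise ValueError(f"unknown planted-bout target {self.target!r}")
        if self.duration_s <= 0 or self.start_s < 0:
            raise ValueError("planted bout needs start_s >= 0 and duration_s > 0")


_DEFAULT_DWELL = {
    "center": 10.0,
    "left_invest": 18.0,
    "right_invest": 14.0,
    "left_distal": 6.0,
    "right_distal": 6.0,
}
_DEFAULT_BIAS = {z: 1.0 for z in _DEFAULT_DWELL}


@dataclass
class SimulationConfig:
    """Free parameters of the trial simulator.

    ``trial_duration_s`` of None resolves to 600 s for the test phases and
    300 s for habituation.  35 Hz makes the 200 ms nose-touch duration
    criterion an exact 7 frames; 3 px/cm makes the 7.5 px contact distance
    a plausible 2.5 cm.
    """

    seed: int = 0
    frame_rate_hz: float = 35.0
    trial_duration_s: float | None = None
    px_per_cm: float = 3.0
    dwell_means_s: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_DWELL))
    zone_transition_bias: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_BIAS))
    step_speed_cm_s: float = 18.0
    planted_bouts: tuple[PlantedBout, ...] = ()
    confidence_dropout_rate: float = 0.0
    teleport_glitch_rate: float = 0.0
    contact_distance_px: float = 7.5  # planted bouts stay strictly inside this

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0 or self.px_per_cm <= 0 or self.step_speed_cm_s <= 0:
            raise ValueError("rates, calibration and speed must be positive")
        if self.trial_duration_s is not None and self.trial_duration_s <= 0:
            raise ValueError("trial_duration_s must be positive")
        for name, rate in (
            ("confidence_dropout_rate", self.confidence_dropout_rate),
            ("teleport_glitch_rate", self.teleport_glitch_rate),
        ):
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for z, v in self.dwell_means_s.items():
            if z not in _DEFAULT_DWELL or v <= 0:
                raise ValueError(f"bad dwell mean {z}={v}")
        for z, v in self.zone_transition_bias.items():
            if z not in _DEFAULT_DWELL or v < 0:
                raise ValueError(f"bad transition bias {z}={v}")
        self.planted_bouts = tuple(sorted(self.planted_bouts, key=lambda b: b.start_s))
        for a, b in zip(self.planted_bouts, self.planted_bouts[1:]):
            if b.start_s < a.start_s + a.duration_s + 1.0:
                raise ValueError(
                    "planted bouts overlap or are closer than 1 s; the single "
                    "experimental nose cannot service both"
                )

    def duration_for(self, phase: str) -> float:
        if self.trial_duration_s is not None:
            return self.trial_duration_s
        return 300.0 if phase == "habituation" else 600.0


@dataclass(frozen=True)
class EffectSpec:
    """Standardized shift of one metric's mean in one design cell."""

    metric: str
    cell: Mapping[str, str]  # e.g. {"generation": "F3", "lineage": "paternal", "sex": "F", "treatment": "VIN"}
    d: float

    def __post_init__(self) -> None:
        if self.metric not in ALL_METRICS:
            raise ValueError(f"unknown metric {self.metric!r} in effect spec")
        if not math.isfinite(self.d):
            raise ValueError("effect shift must be finite")

    def matches(self, row: Mapping[str, str]) -> bool:
        return all(str(row.get(k)) == str(v) for k, v in self.cell.items())


@dataclass(frozen=True)
class SexEffectSpec:
    """Standardized F-minus-M shift of one metric, replacing the baseline gap."""

    metric: str
    d: float

    def __post_init__(self) -> None:
        if self.metric not in ALL_METRICS:
            raise ValueError(f"unknown metric {self.metric!r} in sex effect spec")
        if not math.isfinite(self.d):
            raise ValueError("effect shift must be finite")


@dataclass
class CohortDesign:
    """Which design cells to simulate and what effects to plant."""

    generations: tuple[str, ...] = ("F1",)
    lineages: tuple[str, ...] = ("maternal", "paternal")
    treatments: tuple[str, ...] = ("DMSO", "A1221", "VIN")
    n_per_cell: int = 20
    effect_specs: tuple[EffectSpec, ...] = ()
    sex_effect_specs: tuple[SexEffectSpec, ...] = ()

    _PAIRS = ("DMSO/DMSO", "A1221/A1221", "A1221/VIN", "VIN/A1221", "VIN/VIN")

    def __post_init__(self) -> None:
        if self.n_per_cell < 2:
            raise ValueError("n_per_cell must be at least 2")
        for g in self.generations:
            if g not in ("F1", "F3", "F4", "F6"):
                raise ValueError(f"unknown generation {g!r}")

    def cells(self) -> list[dict[str, str]]:
        out = []
        for gen in self.generations:
            lineages = ("NA",) if gen == "F1" else tuple(
                l for l in self.lineages if l != "NA"
            )
            if gen in ("F1", "F3"):
                treatments = [t for t in self.treatments if "/" not in t]
            else:
                treatments = [t for t in self.treatments if t in self._PAIRS]
                if not treatments:
                    treatments = list(self._PAIRS)
            for lin in lineages:
                for t in treatments:
                    for sex in ("F", "M"):
                        out.append(
                            {"generation": gen, "lineage": lin, "treatment": t, "sex": sex}
                        )
        return out


@dataclass
class GroundTruth:
    """Simulation oracle for one trial."""

    true_zone_timeline: ZoneTimeline
    true_bouts: list[Bout]
    injected_effects: tuple[EffectSpec, ...] = ()


# ---------------------------------------------------------------------------
# Body template and arena helpers (all pixel units unless noted)
# ---------------------------------------------------------------------------

#: rigid template offsets in cm, +x along the heading
_TEMPLATE_CM = {
    "nose": (6.0, 0.0),
    "ear_left": (4.0, -2.0),
    "ear_right": (4.0, 2.0),
    "flank_left": (0.0, -3.0),
    "flank_right": (0.0, 3.0),
    "body_center": (0.0, 0.0),
    "tail_base": (-5.0, 0.0),
    "tail_end": (-10.0, 0.0),
}
_BODY_MARGIN_CM = 11.0  # max template extent + jitter headroom
_KEYPOINT_JITTER_CM = 0.25
_STIM_JITTER_CM = 4.0
_HOLD_DIST_CM = 16.0  # body-center distance from the enclosure center while waiting
_N_RAMP = 3
_RAMP_FACTORS = (1.6, 1.3, 1.05)  # distance / threshold on approach frames


def _zone_chamber(zone: str) -> str:
    return "center" if zone == "center" else zone.split("_")[0]


class _Arena:
    """Pixel-space helper boxes derived from the geometry."""

    def __init__(self, geom: ArenaGeometry):
        self.geom = geom
        W = geom.size_px
        m = _BODY_MARGIN_CM * geom.px_per_cm
        x1, x2, yi = geom._x1, geom._x2, geom._y_invest
        self.inner = {
            "center": (x1 + m, m, x2 - m, W - m),
            "left_distal": (m, m, x1 - m, yi - m),
            "left_invest": (m, yi + m, x1 - m, W - m),
            "right_distal": (x2 + m, m, W - m, yi - m),
            "right_invest": (x2 + m, yi + m, W - m, W - m),
        }
        self.doors = {"left": np.array([x1, W / 2.0]), "right": np.array([x2, W / 2.0])}
        self.enclosures = geom.enclosure_centers
        # interior diagonal away from each bottom corner
        self.interior = {
            "left_enclosure": np.array([1.0, -1.0]) / math.sqrt(2),
            "right_enclosure": np.array([-1.0, -1.0]) / math.sqrt(2),
        }

    def hold_anchor(self, target: str) -> np.ndarray:
        return (
            self.enclosures[target]
            + self.interior[target] * _HOLD_DIST_CM * self.geom.px_per_cm
        )

    def rand_point(self, zone: str, rng: np.random.Generator) -> np.ndarray:
        x0, y0, x1, y1 = self.inner[zone]
        return np.array([rng.uniform(x0, x1), rng.uniform(y0, y1)])

    def route(self, p: np.ndarray, q: np.ndarray, zone_p: str, zone_q: str) -> list[np.ndarray]:
        """Waypoint polyline from p to q passing through doors as needed."""
        ca, cb = _zone_chamber(zone_p), _zone_chamber(zone_q)
        pts = [p]
        if {ca, cb} == {"left", "center"}:
            pts.append(self.doors["left"])
        elif {ca, cb} == {"right", "center"}:
            pts.append(self.doors["right"])
        elif {ca, cb} == {"left", "right"}:
            first = "left" if ca == "left" else "right"
            second = "right" if first == "left" else "left"
            pts += [self.doors[first], self.doors[second]]
        pts.append(q)
        return pts


def _polyline_length(pts: Sequence[np.ndarray]) -> float:
    return float(sum(np.linalg.norm(b - a) for a, b in zip(pts, pts[1:])))


def _walk_polyline(pts: Sequence[np.ndarray], step_px: float) -> np.ndarray:
    """Positions along a polyline at constant step, excluding the start point."""
    L = _polyline_length(pts)
    n = max(1, math.ceil(L / step_px))
    dists = np.linspace(L / n, L, n)
    seg_len = [np.linalg.norm(b - a) for a, b in zip(pts, pts[1:])]
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    out = np.empty((n, 2))
    for i, d in enumerate(dists):
        k = int(np.searchsorted(cum, d, side="right")) - 1
        k = min(k, len(seg_len) - 1)
        frac = (d - cum[k]) / seg_len[k] if seg_len[k] > 0 else 0.0
        out[i] = pts[k] + frac * (pts[k + 1] - pts[k])
    return out


def _walk_in_region(
    start: np.ndarray,
    region: tuple[float, float, float, float],
    n_frames: int,
    step_px: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Waypoint wander inside an axis-aligned box at ~constant speed."""
    x0, y0, x1, y1 = region
    pos = np.clip(start, [x0, y0], [x1, y1]).astype(float)
    out = np.empty((n_frames, 2))
    target = np.array([rng.uniform(x0, x1), rng.uniform(y0, y1)])
    for i in range(n_frames):
        delta = target - pos
        dist = np.linalg.norm(delta)
        if dist < step_px:
            pos = target.copy()
            target = np.array([rng.uniform(x0, x1), rng.uniform(y0, y1)])
        else:
            pos = pos + delta / dist * step_px
        out[i] = pos
    return out


# ---------------------------------------------------------------------------
# Trial simulation
# ---------------------------------------------------------------------------


def simulate_trial(
    config: SimulationConfig, record: TrialRecord
) -> tuple[KeypointTrack, GroundTruth]:
    """Simulate one trial's keypoint track and its ground truth.

    Deterministic given (config, record).  Habituation trials never leave
    the center chamber and admit no planted bouts.  See the module
    docstring for the movement model.
    """
    rng = np.random.default_rng(config.seed)
    geom = ArenaGeometry(px_per_cm=config.px_per_cm)
    arena = _Arena(geom)
    fps = config.frame_rate_hz
    duration = config.duration_for(record.phase)
    n_frames = int(round(duration * fps))
    step_px = config.step_speed_cm_s * config.px_per_cm / fps
    threshold = config.contact_distance_px

    live_targets = _live_stimulus_targets(record)
    bouts = config.planted_bouts
    if bouts:
        if record.phase == "habituation":
            raise ValueError("planted bouts are impossible in habituation (animal is confined)")
        if config.confidence_dropout_rate >= 1.0:
            raise ValueError(
                "confidence dropout rate 1.0 makes planted bouts unverifiable"
            )
        for b in bouts:
            if b.start_s + b.duration_s > duration:
                raise ValueError(f"planted bout {b} extends past the trial end")
            if b.target not in live_targets:
                raise ValueError(
                    f"planted bout target {b.target} has no stimulus animal in "
                    f"phase {record.phase} (stimulus side {record.stimulus_side})"
                )

    # --- stimulus noses/tails -------------------------------------------
    stim_xy: dict[str, np.ndarray] = {}
    stim_conf: dict[str, np.ndarray] = {}
    for side in ("left", "right"):
        target = f"{side}_enclosure"
        center = arena.enclosures[target]
        live = target in live_targets
        jr = _STIM_JITTER_CM * config.px_per_cm
        nose = center + _smooth_jitter(n_frames, jr, rng)
        tail = center + _smooth_jitter(n_frames, jr * 0.6, rng)
        if live:
            conf_nose = rng.uniform(0.95, 1.0, n_frames)
            conf_tail = rng.uniform(0.95, 1.0, n_frames)
        else:
            # an empty enclosure has no animal: the pose model hallucinates
            # low-confidence positions
            nose = rng.uniform(0, geom.size_px, (n_frames, 2))
            tail = rng.uniform(0, geom.size_px, (n_frames, 2))
            conf_nose = rng.uniform(0.05, 0.60, n_frames)
            conf_tail = rng.uniform(0.05, 0.60, n_frames)
        stim_xy[f"stim_{side}_nose"] = nose
        stim_xy[f"stim_{side}_tail"] = tail
        stim_conf[f"stim_{side}_nose"] = conf_nose
        stim_conf[f"stim_{side}_tail"] = conf_tail

    # --- body-center itinerary ------------------------------------------
    pos = np.empty((n_frames, 2))
    bout_frames: list[tuple[int, int, str]] = []  # (start_f, end_f_excl, target)
    override: dict[int, tuple[str, float]] = {}  # frame -> (target, distance_px)

    if record.phase == "habituation":
        start = np.array(
            [
                (arena.inner["center"][0] + arena.inner["center"][2]) / 2,
                (arena.inner["center"][1] + arena.inner["center"][3]) / 2,
            ]
        )
        pos[:] = _walk_in_region(start, arena.inner["center"], n_frames, step_px * 0.5, rng)
    else:
        _build_itinerary(
            pos, bout_frames, override, config, record, arena, rng, n_frames, step_px
        )

    # --- heading and rigid template -------------------------------------
    heading = _headings(pos)
    parts_xy: dict[str, np.ndarray] = {}
    jitter_px = _KEYPOINT_JITTER_CM * config.px_per_cm
    cosh, sinh = heading[:, 0], heading[:, 1]
    for bp, (ox, oy) in _TEMPLATE_CM.items():
        ox_px, oy_px = ox * config.px_per_cm, oy * config.px_per_cm
        dx = ox_px * cosh - oy_px * sinh
        dy = ox_px * sinh + oy_px * cosh
        parts_xy[bp] = pos + np.stack([dx, dy], axis=1) + rng.normal(0, jitter_px, (n_frames, 2))

    # --- nose overrides for planted bouts and approach ramps -------------
    for f, (target, dist) in override.items():
        snose = stim_xy[f"stim_{target.split('_')[0]}_nose"][f]
        v = arena.hold_anchor(target) - snose
        nv = np.linalg.norm(v)
        v = v / nv if nv > 0 else arena.interior[target]
        parts_xy["nose"][f] = snose + v * dist

    # --- anti-contact guard on non-override frames -----------------------
    guard = 1.5 * threshold
    protected = np.zeros(n_frames, dtype=bool)
    for f in override:
        protected[f] = True
    for target in live_targets:
        snose = stim_xy[f"stim_{target.split('_')[0]}_nose"]
        d = np.linalg.norm(parts_xy["nose"] - snose, axis=1)
        close = (d < guard) & ~protected
        for f in np.flatnonzero(close):
            vec = parts_xy["nose"][f] - snose[f]
            n = np.linalg.norm(vec)
            u = vec / n if n > 0 else arena.interior[target]
            parts_xy["nose"][f] = snose[f] + u * (guard + 0.5)

    # --- confidences, dropouts, teleports --------------------------------
    conf: dict[str, np.ndarray] = {
        bp: rng.uniform(0.95, 1.0, n_frames) for bp in EXPERIMENTAL_BODYPARTS
    }
    conf.update(stim_conf)
    if config.confidence_dropout_rate > 0:
        nose_protect = np.zeros(n_frames, dtype=bool)
        for s, e, _t in bout_frames:
            nose_protect[max(0, s - _N_RAMP - 1) : min(n_frames, e + _N_RAMP + 1)] = True
        for bp in BODYPARTS:
            drop = rng.random(n_frames) < config.confidence_dropout_rate
            if bp in ("nose", "stim_left_nose", "stim_right_nose"):
                drop &= ~nose_protect
            already_low = conf[bp] < 0.90
            conf[bp] = np.where(
                drop & ~already_low, rng.uniform(0.30, 0.895, n_frames), conf[bp]
            )
    if config.teleport_glitch_rate > 0:
        glitch = rng.random(n_frames) < config.teleport_glitch_rate
        nose_protect = np.zeros(n_frames, dtype=bool)
        for s, e, _t in bout_frames:
            nose_protect[max(0, s - _N_RAMP - 1) : min(n_frames, e + _N_RAMP + 1)] = True
        for f in np.flatnonzero(glitch):
            candidates = [
                bp
                for bp in EXPERIMENTAL_BODYPARTS
                if not (bp == "nose" and nose_protect[f])
            ]
            bp = candidates[rng.integers(len(candidates))]
            parts_xy[bp][f] = rng.uniform(0, geom.size_px, 2)

    coords = {**parts_xy, **stim_xy}
    track = make_track(coords, conf, fps)

    # --- ground truth -----------------------------------------------------
    truth_labels = _truth_zone_labels(track, geom, record.phase)
    true_bouts = [
        Bout(target=t, start_frame=s, end_frame_exclusive=e, duration_s=(e - s) / fps)
        for s, e, t in sorted(bout_frames)
    ]
    truth = GroundTruth(
        true_zone_timeline=ZoneTimeline(truth_labels, fps), true_bouts=true_bouts
    )
    return track, truth


def _live_stimulus_targets(record: TrialRecord) -> tuple[str, ...]:
    if record.phase == "habituation":
        return ()
    if record.phase == "sociability":
        return (f"{record.stimulus_side}_enclosure",)
    return ("left_enclosure", "right_enclosure")


def _smooth_jitter(n: int, radius_px: float, rng: np.random.Generator) -> np.ndarray:
    """A bounded smooth jitter path (AR(1) clipped to a disc)."""
    out = np.empty((n, 2))
    p = rng.uniform(-radius_px / 2, radius_px / 2, 2)
    for i in range(n):
        p = 0.9 * p + rng.normal(0, radius_px * 0.15, 2)
        r = np.linalg.norm(p)
        if r > radius_px:
            p = p / r * radius_px
        out[i] = p
    return out


def _headings(pos: np.ndarray) -> np.ndarray:
    disp = np.diff(pos, axis=0, prepend=pos[[0]])
    norms = np.linalg.norm(disp, axis=1)
    heading = np.empty_like(pos)
    current = np.array([1.0, 0.0])
    for i in range(len(pos)):
        if norms[i] > 1e-9:
            current = disp[i] / norms[i]
        heading[i] = current
    return heading


def _build_itinerary(
    pos: np.ndarray,
    bout_frames: list[tuple[int, int, str]],
    override: dict[int, tuple[str, float]],
    config: SimulationConfig,
    record: TrialRecord,
    arena: _Arena,
    rng: np.random.Generator,
    n_frames: int,
    step_px: float,
) -> None:
    fps = config.frame_rate_hz
    threshold = config.contact_distance_px
    zones = list(_DEFAULT_DWELL)
    bias = np.array([config.zone_transition_bias.get(z, 0.0) for z in zones], float)
    if bias.sum() <= 0:
        bias = np.ones(len(zones))

    cur_f = 0
    cur_zone = "center"
    cur_pos = np.array(
        [
            (arena.inner["center"][0] + arena.inner["center"][2]) / 2,
            (arena.inner["center"][3]) - 1.0,
        ]
    )

    # worst-case cross-arena transit (through both doors) in frames
    worst_transit_f = math.ceil(2.8 * arena.geom.size_px / step_px) + 1

    def wander(limit_f: int) -> None:
        """Free dwell/transit walk up to limit_f (no arrival constraint)."""
        nonlocal cur_f, cur_zone, cur_pos
        while cur_f < limit_f:
            remaining = limit_f - cur_f
            dwell_f = max(
                1,
                int(round(rng.exponential(config.dwell_means_s.get(cur_zone, 8.0)) * fps)),
            )
            dwell_f = min(dwell_f, remaining)
            seg = _walk_in_region(
                cur_pos, arena.inner[cur_zone], dwell_f, step_px * 0.6, rng
            )
            pos[cur_f : cur_f + dwell_f] = seg
            cur_pos = seg[-1].copy()
            cur_f += dwell_f
            if cur_f >= limit_f:
                return
            w = bias.copy()
            w[zones.index(cur_zone)] = 0.0
            w = w / w.sum()
            nxt = zones[rng.choice(len(zones), p=w)]
            q = arena.rand_point(nxt, rng)
            path = _walk_polyline(arena.route(cur_pos, q, cur_zone, nxt), step_px)
            n_t = min(len(path), limit_f - cur_f)
            pos[cur_f : cur_f + n_t] = path[:n_t]
            cur_pos = pos[cur_f + n_t - 1].copy()
            cur_f += n_t
            if n_t == len(path):
                cur_zone = nxt

    def fill(until_f: int, final_pos: np.ndarray | None, final_zone: str | None) -> None:
        nonlocal cur_f, cur_zone, cur_pos
        if final_pos is None:
            wander(until_f)
            return
        # wander freely, keeping a reserve that always suffices to reach
        # the appointment from anywhere in the arena
        reserve = worst_transit_f + int(fps)
        wander(max(cur_f, until_f - reserve))
        # refine: keep dwelling in the current zone until the *actual*
        # transit is needed, so the pre-bout hold at the enclosure stays
        # short and does not distort zone occupancy
        route = arena.route(cur_pos, final_pos, cur_zone, final_zone)
        tr_frames = max(1, math.ceil(_polyline_length(route) / step_px))
        x0, y0, x1, y1 = arena.inner[cur_zone]
        drift_f = math.ceil(math.hypot(x1 - x0, y1 - y0) / step_px)
        margin_f = drift_f + int(0.3 * fps)
        extra = (until_f - cur_f) - tr_frames - margin_f
        if extra > 0:
            seg = _walk_in_region(
                cur_pos, arena.inner[cur_zone], extra, step_px * 0.6, rng
            )
            pos[cur_f : cur_f + extra] = seg
            cur_pos = seg[-1].copy()
            cur_f += extra
            route = arena.route(cur_pos, final_pos, cur_zone, final_zone)
            tr_frames = max(1, math.ceil(_polyline_length(route) / step_px))
        remaining = until_f - cur_f
        if tr_frames > remaining:
            raise ValueError(
                "planted bout unschedulable: not enough time to reach the "
                "enclosure before the bout starts"
            )
        path = _walk_polyline(route, step_px)[:remaining]
        n_t = len(path)
        pos[cur_f : cur_f + n_t] = path
        cur_f += n_t
        cur_pos = path[-1].copy()
        cur_zone = final_zone
        if cur_f < until_f:
            hold = _walk_in_region(
                cur_pos,
                _anchor_box(final_pos, 2.0 * arena.geom.px_per_cm),
                until_f - cur_f,
                step_px * 0.2,
                rng,
            )
            pos[cur_f:until_f] = hold
            cur_pos = hold[-1].copy()
            cur_f = until_f

    for bout in config.planted_bouts:
        start_f = int(round(bout.start_s * fps))
        n_b = max(1, int(round(bout.duration_s * fps)))
        end_f = min(start_f + n_b, n_frames)
        target = bout.target
        zone = f"{target.split('_')[0]}_invest"
        anchor = arena.hold_anchor(target)
        ramp_start = start_f - _N_RAMP
        if ramp_start < cur_f:
            raise ValueError("planted bouts too early or too close together to schedule")
        fill(ramp_start, anchor, zone)
        # approach ramp, contact frames, retreat ramp: body stays at the
        # contact anchor; the nose override fixes the inter-nose distance
        ramp_end = min(end_f + _N_RAMP, n_frames)
        hold = _walk_in_region(
            cur_pos, _anchor_box(anchor, 1.5 * arena.geom.px_per_cm), ramp_end - cur_f,
            step_px * 0.1, rng,
        )
        pos[cur_f : ramp_end] = hold
        cur_pos = hold[-1].copy()
        for i, fac in enumerate(_RAMP_FACTORS):
            override[ramp_start + i] = (target, threshold * fac)
        for f in range(start_f, end_f):
            override[f] = (target, threshold * rng.uniform(0.3, 0.9))
        for i, fac in enumerate(reversed(_RAMP_FACTORS)):
            f = end_f + i
            if f < n_frames:
                override[f] = (target, threshold * fac)
        bout_frames.append((start_f, end_f, target))
        cur_f = ramp_end
        cur_zone = zone
    fill(n_frames, None, None)


def _anchor_box(anchor: np.ndarray, half_px: float) -> tuple[float, float, float, float]:
    return (anchor[0] - half_px, anchor[1] - half_px, anchor[0] + half_px, anchor[1] + half_px)


def _truth_zone_labels(
    track: KeypointTrack, geom: ArenaGeometry, phase: str
) -> np.ndarray:
    """Ground-truth per-frame zone labels by the 80%-hull-area rule.

    Shares the low-level area-fraction primitive with the scorer but keeps
    its own labelling loop; frames reaching the threshold in no zone keep
    the previous label (the animal is 'between' zones).
    """
    if phase == "habituation":
        return np.array(["center"] * track.n_frames, dtype=object)
    pts = track.experimental_xy()
    n = len(pts)
    flat = geom.zone_of_points(pts[..., 0].ravel(), pts[..., 1].ravel()).reshape(n, 8)
    unanimous = np.all(flat == flat[:, [0]], axis=1)
    labels = np.empty(n, dtype=object)
    prev = "center"
    for i in range(n):
        if unanimous[i]:
            lab = flat[i, 0]
        else:
            frac = geom.hull_zone_fractions(pts[i])
            if frac is None:
                lab = prev
            else:
                best = max(frac, key=frac.get)
                lab = best if frac[best] >= AREA_RULE_FRACTION else prev
        labels[i] = lab
        prev = lab
    return labels


# ---------------------------------------------------------------------------
# Human-scorer oracle
# ---------------------------------------------------------------------------


def human_scorer_oracle(
    truth: GroundTruth,
    jitter_sd_s: float = 0.0,
    miss_rate: float = 0.0,
    seed: int = 0,
    frame_rate_hz: float | None = None,
) -> list[Bout]:
    """Simulate a human scorer re-annotating the true bouts.

    Bout boundaries get independent Gaussian jitter (SD in seconds, rounded
    to frames) and whole bouts are missed at ``miss_rate``.  With zero
    jitter and zero misses the annotation equals the truth.
    """
    if jitter_sd_s < 0:
        raise ValueError("jitter_sd_s must be nonnegative")
    if not 0 <= miss_rate <= 1:
        raise ValueError("miss_rate must lie in [0, 1]")
    fps = frame_rate_hz or truth.true_zone_timeline.frame_rate_hz
    rng = np.random.default_rng(seed)
    out: list[Bout] = []
    for b in truth.true_bouts:
        if rng.random() < miss_rate:
            continue
        if jitter_sd_s > 0:
            ds = int(round(rng.normal(0, jitter_sd_s) * fps))
            de = int(round(rng.normal(0, jitter_sd_s) * fps))
        else:
            ds = de = 0
        s = max(0, b.start_frame + ds)
        e = max(s + 1, b.end_frame_exclusive + de)
        out.append(Bout(b.target, s, e, (e - s) / fps))
    return sorted(out, key=lambda b: b.start_frame)


# ---------------------------------------------------------------------------
# Cohort target drawing
# ---------------------------------------------------------------------------


#: metrics whose scale does not change with trial duration (ratios and
#: per-event durations); all other targets scale with duration / 600 s
_DURATION_INVARIANT = {
    "social_preference_score",
    "social_novelty_score",
    "nose_touch_novelty_score",
    "stimulus_mean_visit_time_s",
    "empty_mean_visit_time_s",
    "familiar_mean_visit_time_s",
    "novel_mean_visit_time_s",
    "mean_nose_touch_duration_s",
}


def _draw_sociability_targets(
    sex: str, duration: float, shifts: Mapping[str, float], rng: np.random.Generator
) -> dict[str, float]:
    phase = "sociability"
    s = duration / 600.0

    def ms(metric: str) -> tuple[float, float]:
        m, sd = metric_mean_sd(phase, metric, sex)
        f = 1.0 if metric in _DURATION_INVARIANT else s
        return (m + shifts.get(metric, 0.0)) * f, sd * f

    m_sc, sd_sc = ms("social_preference_score")
    score = float(np.clip(rng.normal(m_sc, sd_sc), 0.02, 0.98))
    m_st, sd_st = ms("stimulus_investigation_time_s")
    m_em, sd_em = ms("empty_investigation_time_s")
    total_inv = float(
        np.clip(
            rng.normal(m_st + m_em - shifts.get("total_nonsocial_time_s", 0.0) * s,
                       math.hypot(sd_st, sd_em) / 2.0),
            0.07 * duration,
            0.80 * duration,
        )
    )
    t_stim = score * total_inv
    t_empty = total_inv - t_stim
    m_c, sd_c = ms("center_isolation_time_s")
    center = float(
        np.clip(rng.normal(m_c, sd_c), 0.02 * duration, duration - total_inv - 0.03 * duration)
    )
    m_vs, sd_vs = ms("stimulus_visits")
    m_ve, sd_ve = ms("empty_visits")
    if "stimulus_mean_visit_time_s" in shifts:
        mv = metric_mean_sd(phase, "stimulus_mean_visit_time_s", sex)[0] + shifts[
            "stimulus_mean_visit_time_s"
        ]
        v_stim = max(1, int(round(t_stim / max(mv, 1.0))))
    else:
        v_stim = max(1, int(round(rng.normal(m_vs, sd_vs / 2))))
    if "empty_mean_visit_time_s" in shifts:
        mv = metric_mean_sd(phase, "empty_mean_visit_time_s", sex)[0] + shifts[
            "empty_mean_visit_time_s"
        ]
        v_empty = max(1, int(round(t_empty / max(mv, 1.0))))
    else:
        v_empty = max(1, int(round(rng.normal(m_ve, sd_ve / 2))))
    m_d, sd_d = ms("distance_traveled_m")
    distance = float(np.clip(rng.normal(m_d, sd_d), 5.0 * s, 150.0 * s))
    m_nt, sd_nt = ms("total_nose_touch_time_s")
    nt_total = float(np.clip(rng.normal(m_nt, sd_nt), 0.0, 90.0 * s))
    m_nd, sd_nd = ms("mean_nose_touch_duration_s")
    nt_mean = float(np.clip(rng.normal(m_nd, sd_nd), 0.25, 3.0))
    return {
        "distance_traveled_m": distance,
        "social_preference_score": score,
        "stimulus_investigation_time_s": t_stim,
        "empty_investigation_time_s": t_empty,
        "stimulus_visits": float(v_stim),
        "empty_visits": float(v_empty),
        "stimulus_mean_visit_time_s": t_stim / v_stim,
        "empty_mean_visit_time_s": t_empty / v_empty,
        "total_nonsocial_time_s": duration - total_inv,
        "center_isolation_time_s": center,
        "total_nose_touch_time_s": nt_total,
        "mean_nose_touch_duration_s": nt_mean,
        "longest_nose_touch_s": min(nt_total, nt_mean * rng.uniform(1.5, 3.0)),
    }


def _draw_novelty_targets(
    sex: str, duration: float, shifts: Mapping[str, float], rng: np.random.Generator
) -> dict[str, float]:
    phase = "social_novelty"
    s = duration / 600.0

    def ms(metric: str) -> tuple[float, float]:
        m, sd = metric_mean_sd(phase, metric, sex)
        f = 1.0 if metric in _DURATION_INVARIANT else s
        return (m + shifts.get(metric, 0.0)) * f, sd * f

    m_sc, sd_sc = ms("social_novelty_score")
    score = float(np.clip(rng.normal(m_sc, sd_sc), 0.02, 0.98))
    m_nv, sd_nv = ms("novel_investigation_time_s")
    m_fm, sd_fm = ms("familiar_investigation_time_s")
    total_social = float(
        np.clip(
            rng.normal(
                m_nv + m_fm + shifts.get("total_social_time_s", 0.0) * s,
                math.hypot(sd_nv, sd_fm) / 2.0,
            ),
            0.07 * duration,
            0.80 * duration,
        )
    )
    t_novel = score * total_social
    t_fam = total_social - t_novel
    m_c, sd_c = ms("center_isolation_time_s")
    center = float(
        np.clip(rng.normal(m_c, sd_c), 0.02 * duration, duration - total_social - 0.03 * duration)
    )
    m_vn, sd_vn = ms("novel_visits")
    m_vf, sd_vf = ms("familiar_visits")
    if "novel_mean_visit_time_s" in shifts:
        mv = metric_mean_sd(phase, "novel_mean_visit_time_s", sex)[0] + shifts[
            "novel_mean_visit_time_s"
        ]
        v_novel = max(1, int(round(t_novel / max(mv, 1.0))))
    else:
        v_novel = max(1, int(round(rng.normal(m_vn, sd_vn / 2))))
    if "familiar_mean_visit_time_s" in shifts:
        mv = metric_mean_sd(phase, "familiar_mean_visit_time_s", sex)[0] + shifts[
            "familiar_mean_visit_time_s"
        ]
        v_fam = max(1, int(round(t_fam / max(mv, 1.0))))
    else:
        v_fam = max(1, int(round(rng.normal(m_vf, sd_vf / 2))))
    m_d, sd_d = ms("distance_traveled_m")
    distance = float(np.clip(rng.normal(m_d, sd_d), 5.0 * s, 150.0 * s))
    m_ns, sd_ns = ms("nose_touch_novelty_score")
    nt_score = float(np.clip(rng.normal(m_ns, sd_ns), 0.02, 0.98))
    m_ntn, sd_ntn = ms("novel_nose_touch_time_s")
    m_ntf, sd_ntf = ms("familiar_nose_touch_time_s")
    nt_total = float(
        np.clip(rng.normal(m_ntn + m_ntf, math.hypot(sd_ntn, sd_ntf) / 1.5), 0.5 * s, 90.0 * s)
    )
    nt_novel = nt_score * nt_total
    nt_fam = nt_total - nt_novel
    m_nd, sd_nd = metric_mean_sd("sociability", "mean_nose_touch_duration_s", sex)
    nt_mean = float(np.clip(rng.normal(m_nd, sd_nd), 0.25, 3.0))
    return {
        "distance_traveled_m": distance,
        "social_novelty_score": score,
        "familiar_investigation_time_s": t_fam,
        "novel_investigation_time_s": t_novel,
        "familiar_visits": float(v_fam),
        "novel_visits": float(v_novel),
        "familiar_mean_visit_time_s": t_fam / v_fam,
        "novel_mean_visit_time_s": t_novel / v_novel,
        "total_social_time_s": total_social,
        "total_nonsocial_time_s": duration - total_social,
        "center_isolation_time_s": center,
        "nose_touch_novelty_score": nt_score,
        "familiar_nose_touch_time_s": nt_fam,
        "novel_nose_touch_time_s": nt_novel,
        "total_nose_touch_time_s": nt_total,
        "mean_nose_touch_duration_s": nt_mean,
        "longest_nose_touch_s": min(nt_total, nt_mean * rng.uniform(1.5, 3.0)),
    }


def _shifts_for(
    design: CohortDesign, row: Mapping[str, str], phase: str
) -> dict[str, float]:
    phase_metrics = SOCIABILITY_METRICS if phase == "sociability" else NOVELTY_METRICS
    shifts: dict[str, float] = {}
    for spec in design.sex_effect_specs:
        if spec.metric not in phase_metrics:
            continue
        mean_f = SEX_SUMMARY[phase][spec.metric]["F"][0] if spec.metric in SEX_SUMMARY[phase] else None
        if mean_f is None:
            continue
        mean_m = SEX_SUMMARY[phase][spec.metric]["M"][0]
        pooled_mean = (mean_f + mean_m) / 2.0
        sd = metric_pooled_sd(phase, spec.metric)
        # replace the baseline sex gap by the requested standardized gap
        target_mean = pooled_mean + (spec.d / 2.0 if row["sex"] == "F" else -spec.d / 2.0) * sd
        base_mean = mean_f if row["sex"] == "F" else mean_m
        shifts[spec.metric] = shifts.get(spec.metric, 0.0) + (target_mean - base_mean)
    for spec in design.effect_specs:
        if spec.metric not in phase_metrics:
            continue
        if spec.matches(row):
            sd = (
                metric_pooled_sd(phase, spec.metric)
                if spec.metric in SEX_SUMMARY[phase]
                else 1.0
            )
            shifts[spec.metric] = shifts.get(spec.metric, 0.0) + spec.d * sd
    return shifts


def draw_metric_targets(
    design: CohortDesign,
    seed: int = 0,
    duration_s: float = 600.0,
    phases: Sequence[str] = ("sociability", "social_novelty"),
) -> pd.DataFrame:
    """Draw the per-animal true metric table for a cohort design.

    This is the distributional layer of :func:`simulate_cohort`: one row
    per animal x phase with all design factors and metric targets, before
    any trajectory is rendered.  Deterministic given (design, seed).
    """
    rng = np.random.default_rng(seed)
    rows = []
    counter = 0
    for cell in design.cells():
        parts = cell["treatment"].split("/")
        first = parts[0]
        second = parts[1] if len(parts) > 1 else "NA"
        for k in range(design.n_per_cell):
            counter += 1
            animal_id = f"sim{counter:05d}"
            litter_id = f"L{counter % max(2, design.n_per_cell // 2):03d}-{cell['generation']}"
            side = "left" if rng.random() < 0.5 else "right"
            for phase in phases:
                shifts = _shifts_for(design, cell, phase)
                if phase == "sociability":
                    vals = _draw_sociability_targets(cell["sex"], duration_s, shifts, rng)
                else:
                    vals = _draw_novelty_targets(cell["sex"], duration_s, shifts, rng)
                rows.append(
                    {
                        "animal_id": animal_id,
                        "litter_id": litter_id,
                        "sex": cell["sex"],
                        "generation": cell["generation"],
                        "lineage": cell["lineage"],
                        "treatment_first": first,
                        "treatment_second": second,
                        "treatment": cell["treatment"],
                        "phase": phase,
                        "stimulus_side": side,
                        **vals,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort simulation (targets -> tuned trials)
# ---------------------------------------------------------------------------


def _tuned_config(
    base: SimulationConfig,
    targets: Mapping[str, float],
    record: TrialRecord,
    seed: int,
    duration: float,
) -> SimulationConfig:
    """Inverse-tune dwell means, bias, speed and planted bouts to targets."""
    phase = record.phase
    side = record.stimulus_side
    other = "right" if side == "left" else "left"
    if phase == "sociability":
        t_a, t_b = targets["stimulus_investigation_time_s"], targets["empty_investigation_time_s"]
        v_a, v_b = targets["stimulus_visits"], targets["empty_visits"]
    else:
        t_a, t_b = targets["novel_investigation_time_s"], targets["familiar_investigation_time_s"]
        v_a, v_b = targets["novel_visits"], targets["familiar_visits"]
    center_t = targets["center_isolation_time_s"]
    distal_t = max(10.0, targets["total_nonsocial_time_s"] - center_t)
    speed = float(np.clip(targets["distance_traveled_m"] * 100.0 / (0.55 * duration), 6.0, 45.0))

    # planted nose-touch bouts matching the nose-touch targets.  Each bout
    # pins the animal at an enclosure for the bout plus a few seconds of
    # approach/hold, so the count is capped against the invest-time budget
    # and the pinned time is discounted from the dwell tuning below.
    rng = np.random.default_rng(seed ^ 0x5EED)
    enc_a, enc_b = f"{side}_enclosure", f"{other}_enclosure"
    per_target: dict[str, float] = {}
    if phase == "sociability":
        per_target[enc_a] = targets.get("total_nose_touch_time_s", 0.0)
    else:
        per_target[enc_a] = targets.get("novel_nose_touch_time_s", 0.0)
        per_target[enc_b] = targets.get("familiar_nose_touch_time_s", 0.0)
    mean_dur = max(0.3, targets.get("mean_nose_touch_duration_s", 0.65))

    # draw individual bout durations per enclosure (targets are already at
    # trial scale)
    durs_by_target: dict[str, list[float]] = {}
    for target, total in per_target.items():
        budget = total
        durs = []
        while budget > 0.25:
            d = float(np.clip(rng.gamma(2.0, mean_dur / 2.0), 0.25, 6.0))
            d = min(d, budget) if budget >= 0.5 else budget
            if d < 0.25:
                break
            durs.append(d)
            budget -= d
        durs_by_target[target] = durs

    # cluster bouts that share one enclosure visit (rats typically string
    # several nose touches together within a visit)
    clusters: list[tuple[str, list[float]]] = []
    for target, durs in durs_by_target.items():
        i = 0
        while i < len(durs):
            k = 1 + int(rng.poisson(2.5))
            clusters.append((target, durs[i : i + k]))
            i += k
    rng.shuffle(clusters)

    # schedule clusters; gaps between clusters must cover a worst-case
    # cross-arena transit, gaps inside a cluster are short (same visit)
    overhead_s = 4.0  # approach + hold around each cluster
    budget_cap = {enc_a: 0.6 * t_a, enc_b: 0.6 * t_b}
    cluster_cap = {enc_a: max(1, int(round(0.5 * v_a))),
                   enc_b: max(1, int(round(0.5 * v_b)))}
    bouts: list[PlantedBout] = []
    pinned = {enc_a: 0.0, enc_b: 0.0}
    n_clusters = {enc_a: 0, enc_b: 0}
    gap_min = 2.8 * 100.0 / speed + 2.0
    t_cursor = max(5.0, gap_min)
    for target, durs in clusters:
        start = t_cursor + rng.uniform(gap_min, gap_min + 8.0)
        clus, t = [], start
        for d in durs:
            clus.append(PlantedBout(target, t, d))
            t = t + d + rng.uniform(1.2, 2.5)
        end = clus[-1].start_s + clus[-1].duration_s
        if end > duration - 5.0:
            continue
        if n_clusters[target] >= cluster_cap[target]:
            continue
        if pinned[target] + (end - start) + overhead_s > budget_cap[target]:
            continue
        bouts.extend(clus)
        pinned[target] += (end - start) + overhead_s
        n_clusters[target] += 1
        t_cursor = end

    # dwell tuning on the invest time left after bout-pinned enclosure time.
    # Each cluster is followed by one regular invest dwell, so invest-dwell
    # episodes total about the visit target; the mean splits the free time
    # over (visit target + clusters) episodes to discount those forced dwells
    t_a_free = max(2.0, t_a - pinned[enc_a])
    t_b_free = max(2.0, t_b - pinned[enc_b])
    v_a_free = max(0.5, v_a - n_clusters[enc_a])
    v_b_free = max(0.5, v_b - n_clusters[enc_b])
    n_cross = max(2.0, v_a_free + v_b_free)
    dwell = {
        f"{side}_invest": max(0.5, t_a_free / max(v_a + n_clusters[enc_a], 1.0)),
        f"{other}_invest": max(0.5, t_b_free / max(v_b + n_clusters[enc_b], 1.0)),
        "center": max(0.5, center_t / n_cross),
        "left_distal": max(0.5, distal_t / n_cross),
        "right_distal": max(0.5, distal_t / n_cross),
    }
    bias = {
        f"{side}_invest": v_a_free,
        f"{other}_invest": v_b_free,
        "center": (v_a_free + v_b_free) / 2.0,
        "left_distal": (v_a_free + v_b_free) / 4.0,
        "right_distal": (v_a_free + v_b_free) / 4.0,
    }
    return replace(
        base,
        seed=seed,
        trial_duration_s=duration,
        dwell_means_s=dwell,
        zone_transition_bias=bias,
        step_speed_cm_s=speed,
        planted_bouts=tuple(bouts),
    )


def simulate_cohort(
    design: CohortDesign,
    config: SimulationConfig,
    phases: Sequence[str] = ("sociability", "social_novelty"),
) -> tuple[list[tuple[KeypointTrack, TrialRecord, GroundTruth]], pd.DataFrame]:
    """Simulate a cohort: tuned keypoint tracks plus the true metric table.

    Per-animal metric targets come from :func:`draw_metric_targets`; each
    trial's dwell means, transition bias, speed and planted bouts are tuned
    so realized metrics approximate the targets.  Deterministic given
    (design, config.seed).
    """
    duration = config.trial_duration_s if config.trial_duration_s else 600.0
    table = draw_metric_targets(design, seed=config.seed, duration_s=duration, phases=phases)
    trials = []
    for i, row in table.iterrows():
        record = TrialRecord(
            animal_id=row["animal_id"],
            sex=row["sex"],
            generation=row["generation"],
            lineage=row["lineage"],
            treatment_first=row["treatment_first"],
            treatment_second=row["treatment_second"],
            phase=row["phase"],
            stimulus_side=row["stimulus_side"],
            frame_rate_hz=config.frame_rate_hz,
            litter_id=row["litter_id"],
        )
        trial_seed = (config.seed * 1_000_003 + i * 7919) % (2**31 - 1)
        cfg = _tuned_config(config, row, record, trial_seed, duration)
        track, truth = simulate_trial(cfg, record)
        truth.injected_effects = design.effect_specs
        trials.append((track, record, truth))
    return trials, table
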