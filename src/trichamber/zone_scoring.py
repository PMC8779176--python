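"""Arena geometry, per-frame zone assignment and occupancy metrics.

The apparatus is a 100 x 100 cm square divided into three chambers of equal
width (left / center / right), with a door in each internal wall.  A square
investigation zone (~33 x 33 cm) surrounds the cylindrical stimulus
enclosure in the bottom corner of each flanking chamber; the remainder of a
flanking chamber is its distal zone.  The five scoring zones tile the arena:

    center, left_invest, left_distal, right_invest, right_distal

A frame is assigned to a zone when at least 80% of the animal's area — here
the convex hull of the eight tracked body parts — lies inside that zone
(the "four paws inside" convention).  When no zone reaches 80% the previous
frame's label persists, which suppresses flicker while the hull straddles a
boundary.

Coordinates follow the image convention: origin top-left, y increases
downward, so the "bottom" corners holding the enclosures are at large y.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point, box
from shapely.ops import unary_union

from .pose_io import Bout, KeypointTrack, TrialRecord

ZONES: tuple[str, ...] = (
    "center",
    "left_invest",
    "left_distal",
    "right_invest",
    "right_distal",
)

AREA_RULE_FRACTION = 0.80


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


@dataclass
class ArenaGeometry:
    """Chamber/zone polygons and pixel calibration for the square arena.

    Parameters are in centimetres; polygons are built in pixels via
    ``px_per_cm``.  Door rectangles straddle each internal wall and are
    attributed to the center chamber (doors open from the center).
    """

    px_per_cm: float = 3.0
    arena_cm: float = 100.0
    door_width_cm: float = 10.0  # extent across the wall (x)
    door_height_cm: float = 11.0  # extent along the wall (y)
    enclosure_radius_cm: float = 7.5  # 15 cm wide cylinder

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0 or self.arena_cm <= 0:
            raise ValueError("px_per_cm and arena_cm must be positive")
        W = self.arena_cm * self.px_per_cm
        self.size_px = W
        x1, x2 = W / 3.0, 2 * W / 3.0
        y_invest = 2 * W / 3.0  # investigation zones occupy the bottom third
        self._x1, self._x2, self._y_invest = x1, x2, y_invest
        dw = self.door_width_cm * self.px_per_cm / 2.0
        dh = self.door_height_cm * self.px_per_cm / 2.0
        yc = W / 2.0
        self._door_y = (yc - dh, yc + dh)
        self._door_dx = dw
        left_door = box(x1 - dw, yc - dh, x1 + dw, yc + dh)
        right_door = box(x2 - dw, yc - dh, x2 + dw, yc + dh)
        left_chamber = box(0, 0, x1, W).difference(left_door)
        right_chamber = box(x2, 0, W, W).difference(right_door)
        center = unary_union([box(x1, 0, x2, W), left_door, right_door])
        li = box(0, y_invest, x1, W)
        ri = box(x2, y_invest, W, W)
        self.polygons = {
            "center": center,
            "left_invest": li,
            "left_distal": left_chamber.difference(li),
            "right_invest": ri,
            "right_distal": right_chamber.difference(ri),
        }
        # enclosure cylinders sit in the bottom outer corners
        r = self.enclosure_radius_cm * self.px_per_cm
        self.enclosure_centers = {
            "left_enclosure": np.array([r, W - r]),
            "right_enclosure": np.array([W - r, W - r]),
        }
        self.enclosure_radius_px = r

    # -- fast rectilinear point classification ------------------------------

    def zone_of_points(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorised zone label for point coordinates (pixel units).

        Boundary convention: a point on a shared edge belongs to the
        leftmost/topmost zone reached first in the decision order below;
        ambiguous boundary frames are resolved by the area rule anyway.
        """
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        out = np.full(x.shape, "center", dtype=object)
        in_left = x < self._x1
        in_right = x > self._x2
        in_door_y = (y >= self._door_y[0]) & (y <= self._door_y[1])
        in_left_door = in_left & (x >= self._x1 - self._door_dx) & in_door_y
        in_right_door = in_right & (x <= self._x2 + self._door_dx) & in_door_y
        invest = y >= self._y_invest
        out[in_left & invest] = "left_invest"
        out[in_left & ~invest] = "left_distal"
        out[in_right & invest] = "right_invest"
        out[in_right & ~invest] = "right_distal"
        out[in_left_door | in_right_door] = "center"
        return out

    def hull_zone_fractions(self, points: np.ndarray) -> dict[str, float] | None:
        """Exact area fraction of the convex hull of ``points`` in each zone.

        Returns None for degenerate hulls (fewer than 3 distinct points or
        zero area), in which case callers fall back to a point rule.
        """
        pts = np.asarray(points, float)
        pts = pts[np.all(np.isfinite(pts), axis=1)]
        if len(np.unique(pts, axis=0)) < 3:
            return None
        hull = MultiPoint(pts).convex_hull
        if hull.area <= 0:
            return None
        return {z: hull.intersection(poly).area / hull.area for z, poly in self.polygons.items()}


# ---------------------------------------------------------------------------
# Zone timeline
# ---------------------------------------------------------------------------


@dataclass
class ZoneTimeline:
    """Per-frame zone labels for one trial."""

    labels: np.ndarray  # dtype object/str, one of ZONES per frame
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.size == 0:
            raise ValueError("empty zone timeline")
        bad = set(self.labels) - set(ZONES)
        if bad:
            raise ValueError(f"unknown zone labels: {bad}")

    @property
    def n_frames(self) -> int:
        return self.labels.size

    def zone_times_s(self) -> dict[str, float]:
        period = 1.0 / self.frame_rate_hz
        return {z: float(np.sum(self.labels == z)) * period for z in ZONES}


def assign_zones(track: KeypointTrack, geom: ArenaGeometry) -> ZoneTimeline:
    """Assign each frame to a zone by the 80%-of-hull-area rule.

    The animal's area is approximated by the convex hull of the eight
    experimental-animal keypoints.  Frames whose hull reaches the 80%
    threshold in no zone keep the previous frame's label; the first frame
    defaults to the zone containing the body center.  Degenerate hulls fall
    back to the body-center point rule.
    """
    pts = track.experimental_xy()  # (n, 8, 2)
    n = pts.shape[0]
    # Fast path: frames where all 8 points share a point-rule zone and the
    # hull clears the zone's bounding box need no polygon clipping.
    flat_zone = geom.zone_of_points(pts[..., 0].ravel(), pts[..., 1].ravel()).reshape(n, 8)
    unanimous = np.all(flat_zone == flat_zone[:, [0]], axis=1)
    center_xy = track.xy("body_center")
    center_zone = geom.zone_of_points(center_xy[:, 0], center_xy[:, 1])

    labels = np.empty(n, dtype=object)
    prev = center_zone[0]
    for i in range(n):
        if unanimous[i]:
            # hull of points all inside one (convex-ish) zone: the only zone
            # that can fail convexity is `center` near a door notch of the
            # flanking chambers, but doors belong to center so the hull of
            # center-labelled points stays within center.
            frac = None
            candidate = flat_zone[i, 0]
            if candidate != "center":
                # flanking zones are axis-aligned rectangles minus the door
                # notch; a hull of interior points can poke into the notch,
                # so verify cheaply via the area rule only when near a door.
                if _near_door(pts[i], geom, candidate):
                    frac = geom.hull_zone_fractions(pts[i])
                else:
                    labels[i] = candidate
                    prev = candidate
                    continue
            else:
                # points inside a door notch lie beyond the internal walls;
                # the hull may then sweep flanking-chamber area, so verify.
                xs = pts[i, :, 0]
                if np.any(xs < geom._x1) or np.any(xs > geom._x2):
                    frac = geom.hull_zone_fractions(pts[i])
                else:
                    labels[i] = candidate
                    prev = candidate
                    continue
        else:
            frac = geom.hull_zone_fractions(pts[i])
        if frac is None:
            lab = center_zone[i]
        else:
            best = max(frac, key=frac.get)
            lab = best if frac[best] >= AREA_RULE_FRACTION else prev
        labels[i] = lab
        prev = lab
    return ZoneTimeline(labels, track.frame_rate_hz)


def _near_door(points: np.ndarray, geom: ArenaGeometry, zone: str) -> bool:
    if zone.startswith("left"):
        wall = geom._x1
        near_x = np.any(points[:, 0] > wall - geom._door_dx)
    else:
        wall = geom._x2
        near_x = np.any(points[:, 0] < wall + geom._door_dx)
    y0, y1 = geom._door_y
    near_y = np.any((points[:, 1] > y0 - 1) & (points[:, 1] < y1 + 1))
    return bool(near_x and near_y)


# ---------------------------------------------------------------------------
# Visits (run-length encoding of the label sequence)
# ---------------------------------------------------------------------------


def run_length_encode(labels: np.ndarray) -> list[tuple[object, int, int]]:
    """Maximal constant runs of a label sequence as (label, start, end_excl)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return [(labels[s], int(s), int(e)) for s, e in zip(starts, ends)]


def extract_visits(timeline: ZoneTimeline, frame_rate_hz: float | None = None) -> list[Bout]:
    """Maximal contiguous zone-occupancy runs as visit bouts."""
    fps = frame_rate_hz if frame_rate_hz is not None else timeline.frame_rate_hz
    return [
        Bout(target=str(z), start_frame=s, end_frame_exclusive=e, duration_s=(e - s) / fps)
        for z, s, e in run_length_encode(timeline.labels)
    ]


def visit_stats(visits: Sequence[Bout]) -> dict[str, tuple[int, float, float]]:
    """Per-zone (count, total_time_s, mean_visit_time_s); mean is NaN for 0 visits."""
    out = {}
    for z in ZONES:
        zb = [b for b in visits if b.target == z]
        total = sum(b.duration_s for b in zb)
        count = len(zb)
        out[z] = (count, total, total / count if count else float("nan"))
    return out


# ---------------------------------------------------------------------------
# Distance traveled
# ---------------------------------------------------------------------------


def distance_traveled(
    track: KeypointTrack, geom: ArenaGeometry, confidence_floor: float = 0.90
) -> float:
    """Total body-center path length in metres.

    Frames where the body-center confidence falls below ``confidence_floor``
    are bridged by linear interpolation before summation.  Returns NaN when
    every frame is low-confidence.
    """
    xy = track.xy("body_center").copy()
    conf = track.confidence("body_center")
    bad = (conf < confidence_floor) | ~np.all(np.isfinite(xy), axis=1)
    if bad.all():
        return float("nan")
    xy[bad] = np.nan
    df = pd.DataFrame(xy).interpolate(method="linear", limit_direction="both")
    xy = df.to_numpy()
    steps = np.sqrt(np.sum(np.diff(xy, axis=0) ** 2, axis=1))
    return float(steps.sum() / geom.px_per_cm / 100.0)


# ---------------------------------------------------------------------------
# Occupancy metrics
# ---------------------------------------------------------------------------


@dataclass
class OccupancyMetrics:
    """Flat metric dictionary for one trial plus per-zone breakdown."""

    values: dict[str, float]
    zone_times_s: dict[str, float] = field(default_factory=dict)


def _common_occupancy(
    timeline: ZoneTimeline, track: KeypointTrack, geom: ArenaGeometry
) -> tuple[dict[str, float], dict[str, tuple[int, float, float]], float]:
    times = timeline.zone_times_s()
    stats = visit_stats(extract_visits(timeline))
    dist = distance_traveled(track, geom)
    return times, stats, dist


def sociability_metrics(
    timeline: ZoneTimeline,
    track: KeypointTrack,
    record: TrialRecord,
    geom: ArenaGeometry,
) -> OccupancyMetrics:
    """Stage-1 occupancy metrics.

    The social preference score is the time investigating the stimulus
    animal divided by the summed time investigating the stimulus animal and
    the empty enclosure; total nonsocial time adds the two distal-chamber
    times to the center-chamber (isolation) time.
    """
    if record.phase != "sociability":
        raise ValueError(f"expected a sociability trial, got phase={record.phase!r}")
    times, stats, dist = _common_occupancy(timeline, track, geom)
    stim_zone = f"{record.stimulus_side}_invest"
    empty_side = "right" if record.stimulus_side == "left" else "left"
    empty_zone = f"{empty_side}_invest"
    t_stim, t_empty = times[stim_zone], times[empty_zone]
    denom = t_stim + t_empty
    score = t_stim / denom if denom > 0 else float("nan")
    vals = {
        "distance_traveled_m": dist,
        "social_preference_score": score,
        "stimulus_investigation_time_s": t_stim,
        "empty_investigation_time_s": t_empty,
        "stimulus_visits": float(stats[stim_zone][0]),
        "empty_visits": float(stats[empty_zone][0]),
        "stimulus_mean_visit_time_s": stats[stim_zone][2],
        "empty_mean_visit_time_s": stats[empty_zone][2],
        "total_nonsocial_time_s": times["left_distal"] + times["right_distal"] + times["center"],
        "center_isolation_time_s": times["center"],
    }
    return OccupancyMetrics(vals, times)


def novelty_metrics(
    timeline: ZoneTimeline,
    track: KeypointTrack,
    record: TrialRecord,
    geom: ArenaGeometry,
) -> OccupancyMetrics:
    """Stage-2 occupancy metrics.

    ``record.stimulus_side`` names the side holding the *novel* animal.
    The social novelty score is the time with the novel animal divided by
    the summed time with the novel and familiar animals.
    """
    if record.phase != "social_novelty":
        raise ValueError(f"expected a social-novelty trial, got phase={record.phase!r}")
    times, stats, dist = _common_occupancy(timeline, track, geom)
    novel_zone = f"{record.stimulus_side}_invest"
    fam_side = "right" if record.stimulus_side == "left" else "left"
    fam_zone = f"{fam_side}_invest"
    t_novel, t_fam = times[novel_zone], times[fam_zone]
    denom = t_novel + t_fam
    score = t_novel / denom if denom > 0 else float("nan")
    vals = {
        "distance_traveled_m": dist,
        "social_novelty_score": score,
        "familiar_investigation_time_s": t_fam,
        "novel_investigation_time_s": t_novel,
        "familiar_visits": float(stats[fam_zone][0]),
        "novel_visits": float(stats[novel_zone][0]),
        "familiar_mean_visit_time_s": stats[fam_zone][2],
        "novel_mean_visit_time_s": stats[novel_zone][2],
        "total_social_time_s": t_fam + t_novel,
        "total_nonsocial_time_s": times["left_distal"] + times["right_distal"] + times["center"],
        "center_isolation_time_s": times["center"],
    }
    return OccupancyMetrics(vals, times)
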