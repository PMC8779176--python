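"""Keypoint tables, trial metadata and tidy result files.

The package consumes per-frame keypoint tracks in the layout that pose
estimation toolkits export: a table with a three-level column header
(scorer / bodypart / coordinate) holding x, y and a likelihood per body
part.  Twelve body parts are tracked per trial: eight on the experimental
animal and the nose and tail of the two caged stimulus animals.

Everything downstream (zone scoring, nose-touch detection, QC, statistics)
is keyed on the domain types defined here: :class:`KeypointTrack`,
:class:`TrialRecord` and the tidy per-animal metric table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------

EXPERIMENTAL_BODYPARTS: tuple[str, ...] = (
    "nose",
    "ear_left",
    "ear_right",
    "flank_left",
    "flank_right",
    "body_center",
    "tail_base",
    "tail_end",
)
STIMULUS_BODYPARTS: tuple[str, ...] = (
    "stim_left_nose",
    "stim_left_tail",
    "stim_right_nose",
    "stim_right_tail",
)
BODYPARTS: tuple[str, ...] = EXPERIMENTAL_BODYPARTS + STIMULUS_BODYPARTS

SEXES = ("F", "M")
GENERATIONS = ("F1", "F3", "F4", "F6")
LINEAGES = ("maternal", "paternal", "NA")
TREATMENTS = ("DMSO", "A1221", "VIN")
PHASES = ("habituation", "sociability", "social_novelty")
SIDES = ("left", "right")

#: The five first-hit/second-hit exposure combinations studied in the
#: two-hit generations (F4/F6).  Vehicle is 6% DMSO.
ALLOWED_TREATMENT_PAIRS: frozenset[tuple[str, str]] = frozenset(
    {
        ("DMSO", "DMSO"),
        ("A1221", "A1221"),
        ("A1221", "VIN"),
        ("VIN", "VIN"),
        ("VIN", "A1221"),
    }
)

#: Canonical metric column names for the sociability (stage 1) phase.
SOCIABILITY_METRICS: tuple[str, ...] = (
    "distance_traveled_m",
    "social_preference_score",
    "stimulus_investigation_time_s",
    "empty_investigation_time_s",
    "stimulus_visits",
    "empty_visits",
    "stimulus_mean_visit_time_s",
    "empty_mean_visit_time_s",
    "total_nonsocial_time_s",
    "center_isolation_time_s",
    "total_nose_touch_time_s",
    "mean_nose_touch_duration_s",
    "longest_nose_touch_s",
)

#: Canonical metric column names for the social-novelty (stage 2) phase.
NOVELTY_METRICS: tuple[str, ...] = (
    "distance_traveled_m",
    "social_novelty_score",
    "familiar_investigation_time_s",
    "novel_investigation_time_s",
    "familiar_visits",
    "novel_visits",
    "familiar_mean_visit_time_s",
    "novel_mean_visit_time_s",
    "total_social_time_s",
    "total_nonsocial_time_s",
    "center_isolation_time_s",
    "nose_touch_novelty_score",
    "familiar_nose_touch_time_s",
    "novel_nose_touch_time_s",
    "total_nose_touch_time_s",
    "mean_nose_touch_duration_s",
    "longest_nose_touch_s",
)

ALL_METRICS: tuple[str, ...] = tuple(
    dict.fromkeys(SOCIABILITY_METRICS + NOVELTY_METRICS)
)

MANIFEST_COLUMNS = (
    "animal_id",
    "sex",
    "generation",
    "lineage",
    "treatment_first",
    "treatment_second",
    "phase",
    "stimulus_side",
    "frame_rate_hz",
    "litter_id",
)

BOUT_COLUMNS = (
    "animal_id",
    "phase",
    "target",
    "start_frame",
    "end_frame_exclusive",
    "duration_s",
)


class SchemaError(ValueError):
    """A file or record violates the expected layout or design constraints."""


# ---------------------------------------------------------------------------
# KeypointTrack
# ---------------------------------------------------------------------------


@dataclass
class KeypointTrack:
    """Per-frame keypoint coordinates and confidences for one trial.

    ``data`` has a two-level column index (bodypart, coordinate) with
    coordinates ``x``, ``y``, ``likelihood``; rows are gap-free 0-based
    frame indices.  Image convention: origin top-left, y increases
    downwards.
    """

    data: pd.DataFrame
    frame_rate_hz: float

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        idx = np.asarray(self.data.index)
        if len(idx) == 0:
            raise SchemaError("empty keypoint table")
        if not np.array_equal(idx, np.arange(len(idx))):
            diffs = np.diff(idx)
            if np.any(diffs <= 0):
                raise SchemaError("frame index not strictly increasing (duplicate frames?)")
            raise SchemaError("frame index has gaps; missing frames are not allowed")
        present = set(self.data.columns.get_level_values(0))
        missing = [bp for bp in BODYPARTS if bp not in present]
        if missing:
            raise SchemaError(f"keypoint table missing body parts: {missing}")
        conf = self.data.loc[:, (slice(None), "likelihood")].to_numpy(float)
        finite = conf[np.isfinite(conf)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise SchemaError("likelihood values outside [0, 1]")

    # -- accessors ----------------------------------------------------------

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    def xy(self, bodypart: str) -> np.ndarray:
        """(n_frames, 2) array of pixel coordinates for one body part."""
        return self.data[bodypart][["x", "y"]].to_numpy(float)

    def confidence(self, bodypart: str) -> np.ndarray:
        return self.data[bodypart]["likelihood"].to_numpy(float)

    def experimental_xy(self) -> np.ndarray:
        """(n_frames, 8, 2) coordinates of the experimental animal's parts."""
        out = np.stack([self.xy(bp) for bp in EXPERIMENTAL_BODYPARTS], axis=1)
        return out


def _track_frame(track: KeypointTrack, scorer: str) -> pd.DataFrame:
    df = track.data.copy()
    df.columns = pd.MultiIndex.from_tuples(
        [(scorer, bp, coord) for bp, coord in df.columns],
        names=["scorer", "bodyparts", "coords"],
    )
    return df


def make_track(
    coords: dict[str, np.ndarray],
    confidences: dict[str, np.ndarray],
    frame_rate_hz: float,
) -> KeypointTrack:
    """Assemble a :class:`KeypointTrack` from per-bodypart arrays.

    ``coords[bp]`` is (n, 2); ``confidences[bp]`` is (n,).
    """
    cols = {}
    for bp in BODYPARTS:
        xy = np.asarray(coords[bp], float)
        cols[(bp, "x")] = xy[:, 0]
        cols[(bp, "y")] = xy[:, 1]
        cols[(bp, "likelihood")] = np.asarray(confidences[bp], float)
    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["bodyparts", "coords"])
    return KeypointTrack(df, frame_rate_hz)


def write_keypoint_table(
    track: KeypointTrack, path: str | Path, scorer: str = "trichamber"
) -> None:
    """Write a track as HDF5 (``.h5``) or CSV with the standard 3-level header."""
    path = Path(path)
    df = _track_frame(track, scorer)
    if path.suffix in {".h5", ".hdf5"}:
        df.to_hdf(path, key="keypoints", mode="w")
    elif path.suffix == ".csv":
        df.to_csv(path)
    else:
        raise ValueError(f"unsupported keypoint file extension: {path.suffix}")


def read_keypoint_table(path: str | Path, frame_rate_hz: float) -> KeypointTrack:
    """Read an HDF5 or CSV keypoint table into a validated track.

    The header must declare all 12 body parts with x/y/likelihood triplets;
    missing or duplicated frames raise :class:`SchemaError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in {".h5", ".hdf5"}:
        df = pd.read_hdf(path, key="keypoints")
    elif path.suffix == ".csv":
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    else:
        raise ValueError(f"unsupported keypoint file extension: {path.suffix}")
    if df.columns.nlevels != 3:
        raise SchemaError("expected a 3-level scorer/bodypart/coordinate header")
    df = df.copy()
    df.columns = pd.MultiIndex.from_tuples(
        [(bp, coord) for _, bp, coord in df.columns], names=["bodyparts", "coords"]
    )
    for bp in BODYPARTS:
        for coord in ("x", "y", "likelihood"):
            if (bp, coord) not in df.columns:
                raise SchemaError(f"keypoint table missing column {bp}/{coord}")
    df.index = pd.Index(np.asarray(df.index, dtype=np.int64))
    df = df.astype(float)
    return KeypointTrack(df, frame_rate_hz)


# ---------------------------------------------------------------------------
# TrialRecord and manifest
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialRecord:
    """Design metadata for one trial of one animal."""

    animal_id: str
    sex: str
    generation: str
    lineage: str
    treatment_first: str
    treatment_second: str  # "NA" for single-hit generations
    phase: str
    stimulus_side: str  # sociability: side of the stimulus animal; novelty: side of the novel animal
    frame_rate_hz: float
    litter_id: str = ""
    manual_exclude: bool = False

    def __post_init__(self) -> None:
        checks = [
            (self.sex, SEXES, "sex"),
            (self.generation, GENERATIONS, "generation"),
            (self.lineage, LINEAGES, "lineage"),
            (self.treatment_first, TREATMENTS, "treatment_first"),
            (self.treatment_second, TREATMENTS + ("NA",), "treatment_second"),
            (self.phase, PHASES, "phase"),
            (self.stimulus_side, SIDES, "stimulus_side"),
        ]
        for value, allowed, name in checks:
            if value not in allowed:
                raise SchemaError(f"{name}={value!r} not in {allowed}")
        if self.frame_rate_hz <= 0:
            raise SchemaError("frame_rate_hz must be positive")
        if self.generation == "F1" and self.lineage != "NA":
            raise SchemaError("F1 animals have no breeding lineage (use 'NA')")
        if self.generation in ("F3", "F4", "F6") and self.lineage == "NA":
            raise SchemaError(f"{self.generation} animals require a maternal/paternal lineage")
        if self.generation in ("F1", "F3"):
            if self.treatment_second != "NA":
                raise SchemaError(
                    f"{self.generation} is a single-hit generation; treatment_second must be 'NA'"
                )
        else:
            pair = (self.treatment_first, self.treatment_second)
            if pair not in ALLOWED_TREATMENT_PAIRS:
                raise SchemaError(
                    f"treatment pair {pair} not among the studied combinations "
                    f"{sorted(ALLOWED_TREATMENT_PAIRS)}"
                )

    @property
    def treatment_label(self) -> str:
        if self.treatment_second == "NA":
            return self.treatment_first
        return f"{self.treatment_first}/{self.treatment_second}"


def read_manifest(path: str | Path) -> list[TrialRecord]:
    """Read ``manifest.csv`` into validated :class:`TrialRecord` rows.

    Invalid design combinations are rejected with the offending row number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"manifest missing columns: {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                TrialRecord(
                    animal_id=row["animal_id"],
                    sex=row["sex"],
                    generation=row["generation"],
                    lineage=row["lineage"],
                    treatment_first=row["treatment_first"],
                    treatment_second=row["treatment_second"],
                    phase=row["phase"],
                    stimulus_side=row["stimulus_side"],
                    frame_rate_hz=float(row["frame_rate_hz"]),
                    litter_id=row["litter_id"],
                    manual_exclude=str(row.get("manual_exclude", "")).lower()
                    in {"1", "true", "yes"},
                )
            )
        except (SchemaError, ValueError) as exc:
            raise SchemaError(f"manifest row {i + 2}: {exc}") from exc
    return records


def write_manifest(records: Iterable[TrialRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d["manual_exclude"] = str(r.manual_exclude).lower()
        rows.append(d)
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS + ("manual_exclude",)).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Bout and metric tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Bout:
    """A half-open contact or visit interval in 0-based frames."""

    target: str
    start_frame: int
    end_frame_exclusive: int
    duration_s: float

    def __post_init__(self) -> None:
        if self.end_frame_exclusive <= self.start_frame:
            raise ValueError("bout must span at least one frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame_exclusive - self.start_frame


def write_bouts(
    bouts_by_trial: dict[tuple[str, str], Sequence[Bout]], path: str | Path
) -> None:
    """Write bout lists keyed by (animal_id, phase) as ``bouts.csv``."""
    rows = []
    for (animal_id, phase), bouts in bouts_by_trial.items():
        for b in bouts:
            rows.append(
                {
                    "animal_id": animal_id,
                    "phase": phase,
                    "target": b.target,
                    "start_frame": b.start_frame,
                    "end_frame_exclusive": b.end_frame_exclusive,
                    "duration_s": b.duration_s,
                }
            )
    pd.DataFrame(rows, columns=BOUT_COLUMNS).to_csv(path, index=False)


def read_bouts(path: str | Path) -> dict[tuple[str, str], list[Bout]]:
    df = pd.read_csv(path)
    missing = [c for c in BOUT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"bout file missing columns: {missing}")
    out: dict[tuple[str, str], list[Bout]] = {}
    for _, row in df.iterrows():
        key = (str(row["animal_id"]), str(row["phase"]))
        out.setdefault(key, []).append(
            Bout(
                target=str(row["target"]),
                start_frame=int(row["start_frame"]),
                end_frame_exclusive=int(row["end_frame_exclusive"]),
                duration_s=float(row["duration_s"]),
            )
        )
    return out


def write_metrics(table: pd.DataFrame, path: str | Path) -> None:
    """Write the tidy per-(animal, phase) metric table as UTF-8 CSV."""
    table.to_csv(path, index=False)


def read_metrics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("animal_id", "phase"):
        if col not in df.columns:
            raise SchemaError(f"metrics table missing column {col!r}")
    if df.duplicated(subset=["animal_id", "phase"]).any():
        raise SchemaError("metrics table has duplicate (animal_id, phase) rows")
    return df
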