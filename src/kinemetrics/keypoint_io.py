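"""Reading, writing, confidence-filtering and validating pose-keypoint series.

Input is the per-frame output of a 2D pose estimator: for each frame and each
of the 12 tracked limb joints an (x, y) position in pixels (image convention,
y increasing downward) with a detection confidence in [0, 1].  Two on-disk
dialects are supported:

* ``pose-json`` — the AlphaPose/COCO-17 results dialect: a JSON list of
  per-frame records with an ``image_id`` (or ``frame``) field, a flat
  ``keypoints`` array of 17 (x, y, confidence) triplets in COCO order, and an
  overall detection ``score``.  Face keypoints (indices 0-4) are ignored.
* ``csv`` — long format with header ``infant_id,frame,joint,x,y,confidence``.

Detections with confidence below a threshold (default 0.5) are treated as
measurement errors and removed; the boundary is strict, so a confidence of
exactly 0.5 is retained.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import AmbiguityError, ParseError, SchemaError, ValidationError
from .joints import ANGLE_TRIPLES, COCO_INDEX, JOINTS, Joint

__all__ = [
    "KeypointSeries",
    "ValidityReport",
    "load_keypoints",
    "filter_confidence",
    "validate_series",
    "write_keypoints",
]

_N_JOINTS = len(JOINTS)
_COL: dict[Joint, int] = {j: i for i, j in enumerate(JOINTS)}


@dataclass
class KeypointSeries:
    """Per-video keypoint trajectories on a contiguous frame grid.

    Arrays have shape ``(n_frames, 12)`` with one column per :class:`Joint`
    (in declaration order); missing observations are NaN in all three arrays.
    Frame indices are contiguous from the first to the last frame present in
    the source file, so gaps in the recording appear as all-NaN rows.
    """

    infant_id: str
    frame_rate: float
    frames: np.ndarray  # (n_frames,) int, strictly increasing, contiguous
    x: np.ndarray  # (n_frames, 12) float, pixels
    y: np.ndarray  # (n_frames, 12) float, pixels, y-down
    confidence: np.ndarray  # (n_frames, 12) float in [0, 1] or NaN

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValidationError(f"frame_rate must be > 0, got {self.frame_rate}")
        self.frames = np.asarray(self.frames, dtype=np.int64)
        if np.any(np.diff(self.frames) <= 0):
            raise ValidationError("frame indices must be strictly increasing")
        for name in ("x", "y", "confidence"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(self.frames), _N_JOINTS):
                raise ValidationError(
                    f"{name} has shape {arr.shape}, expected ({len(self.frames)}, {_N_JOINTS})"
                )
            setattr(self, name, arr)
        conf = self.confidence
        bad = conf[np.isfinite(conf)]
        if bad.size and (bad.min() < 0 or bad.max() > 1):
            raise ValidationError("confidence values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        """Recording length in seconds (frame count over frame rate)."""
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds."""
        return self.frames / self.frame_rate

    def column(self, joint: Joint) -> int:
        return _COL[joint]

    def joint_xy(self, joint: Joint) -> tuple[np.ndarray, np.ndarray]:
        c = _COL[joint]
        return self.x[:, c], self.y[:, c]

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_frames, 12) mask of missing observations."""
        return ~(np.isfinite(self.x) & np.isfinite(self.y) & np.isfinite(self.confidence))

    def missing_fraction(self) -> dict[Joint, float]:
        """Fraction of frames with a missing observation, per joint."""
        miss = self.missing_mask().mean(axis=0)
        return {j: float(miss[_COL[j]]) for j in JOINTS}

    def n_observations(self) -> int:
        return int((~self.missing_mask()).sum())


def filter_confidence(series: KeypointSeries, threshold: float = 0.5) -> KeypointSeries:
    """Remove observations whose confidence is strictly below ``threshold``.

    Positions with confidence < threshold are regarded as measurement errors
    and become missing; a confidence exactly equal to the threshold is kept.
    Idempotent, and monotone in the threshold.  Per-joint missing fractions of
    the result are available via :meth:`KeypointSeries.missing_fraction`.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"threshold must be in [0, 1], got {threshold}")
    drop = ~(series.confidence >= threshold)  # NaN compares False -> stays missing
    x = series.x.copy()
    y = series.y.copy()
    conf = series.confidence.copy()
    x[drop] = np.nan
    y[drop] = np.nan
    conf[drop] = np.nan
    return replace(series, x=x, y=y, confidence=conf)


@dataclass
class ValidityReport:
    """Report-only data-adequacy check for one keypoint series.

    A joint passes when its missing fraction is at most ``max_missing_fraction``;
    an angle-bearing joint is usable when the joint itself and both adjacent
    joints pass.  Overall validity requires an adequate duration and all eight
    angle-bearing joints usable.
    """

    infant_id: str
    duration: float
    duration_ok: bool
    missing_fraction: dict[Joint, float]
    joint_ok: dict[Joint, bool]
    angle_joint_ok: dict[Joint, bool]
    reasons: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return self.duration_ok and all(self.angle_joint_ok.values())


def validate_series(
    series: KeypointSeries,
    min_duration: float = 120.0,
    max_missing_fraction: float = 0.30,
) -> ValidityReport:
    """Check duration and per-joint missingness against adequacy thresholds.

    Defaults: at least 120 s of footage and at most 30% missing frames per
    joint.  The check is report-only; nothing is raised or dropped.
    """
    miss = series.missing_fraction()
    joint_ok = {j: miss[j] <= max_missing_fraction for j in JOINTS}
    angle_ok = {
        j: joint_ok[j] and joint_ok[a] and joint_ok[b]
        for j, (a, b) in ANGLE_TRIPLES.items()
    }
    duration_ok = series.duration >= min_duration
    reasons = []
    if not duration_ok:
        reasons.append(f"duration {series.duration:.1f}s < {min_duration:.0f}s")
    for j, ok in joint_ok.items():
        if not ok:
            reasons.append(f"{j.value} missing fraction {miss[j]:.2f} > {max_missing_fraction:.2f}")
    return ValidityReport(
        infant_id=series.infant_id,
        duration=series.duration,
        duration_ok=duration_ok,
        missing_fraction=miss,
        joint_ok=joint_ok,
        angle_joint_ok=angle_ok,
        reasons=reasons,
    )


# ---------------------------------------------------------------------------
# loading


def load_keypoints(
    path: str | Path,
    format: str = "pose-json",
    frame_rate: float = 30.0,
    infant_id: str | None = None,
    person_rule: str | None = "best_mean_confidence",
) -> KeypointSeries:
    """Load a keypoint series from ``pose-json`` or long-format ``csv``.

    Parameters
    ----------
    path
        Source file.
    format
        ``"pose-json"`` (AlphaPose results dialect) or ``"csv"``.
    frame_rate
        Frames per second; pose-JSON does not carry it, so it must be supplied
        (default 30).
    infant_id
        Overrides the identifier; defaults to the file stem (pose-JSON) or the
        ``infant_id`` column (CSV).
    person_rule
        How to resolve frames with multiple detections: currently only
        ``"best_mean_confidence"`` (keep the detection with the highest mean
        keypoint confidence over the 12 joints).  ``None`` raises
        :class:`AmbiguityError` on the first ambiguous frame.
    """
    path = Path(path)
    if format == "pose-json":
        return _load_pose_json(path, frame_rate, infant_id, person_rule)
    if format == "csv":
        return _load_csv(path, frame_rate, infant_id)
    raise ValidationError(f"unknown format {format!r}; expected 'pose-json' or 'csv'")


def _frame_of(record: dict, idx: int) -> int:
    for key in ("frame", "image_id", "idx"):
        if key in record:
            val = record[key]
            if isinstance(val, str):
                val = val.split(".")[0]
            try:
                return int(val)
            except (TypeError, ValueError):
                raise ParseError(f"record {idx}: cannot parse frame index from {record[key]!r}")
    raise ParseError(f"record {idx}: no frame/image_id field")


def _load_pose_json(
    path: Path, frame_rate: float, infant_id: str | None, person_rule: str | None
) -> KeypointSeries:
    try:
        records = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(records, list):
        raise ParseError(f"{path}: expected a JSON list of per-frame records")

    per_frame: dict[int, tuple[float, list[float]]] = {}
    for i, rec in enumerate(records):
        if not isinstance(rec, dict):
            raise ParseError(f"record {i}: expected an object, got {type(rec).__name__}")
        frame = _frame_of(rec, i)
        kps = rec.get("keypoints")
        if not isinstance(kps, list) or len(kps) != 51:
            raise ParseError(
                f"record {i}: 'keypoints' must be a flat list of 51 numbers (17 triplets)"
            )
        limb_conf = [kps[3 * c + 2] for c in COCO_INDEX.values()]
        mean_conf = float(np.mean(limb_conf))
        if frame in per_frame:
            if person_rule is None:
                raise AmbiguityError(
                    f"frame {frame}: multiple detections and no person-selection rule"
                )
            if person_rule != "best_mean_confidence":
                raise ValidationError(f"unknown person_rule {person_rule!r}")
            if mean_conf <= per_frame[frame][0]:
                continue
        per_frame[frame] = (mean_conf, kps)

    if not per_frame:
        raise ParseError(f"{path}: no frame records")
    lo, hi = min(per_frame), max(per_frame)
    frames = np.arange(lo, hi + 1, dtype=np.int64)
    n = len(frames)
    x = np.full((n, _N_JOINTS), np.nan)
    y = np.full((n, _N_JOINTS), np.nan)
    conf = np.full((n, _N_JOINTS), np.nan)
    for frame, (_, kps) in per_frame.items():
        r = frame - lo
        for joint, coco in COCO_INDEX.items():
            c = _COL[joint]
            xv, yv, cv = kps[3 * coco], kps[3 * coco + 1], kps[3 * coco + 2]
            if not (math.isfinite(xv) and math.isfinite(yv) and math.isfinite(cv)):
                continue
            x[r, c], y[r, c], conf[r, c] = xv, yv, cv
    return KeypointSeries(
        infant_id=infant_id or path.stem,
        frame_rate=frame_rate,
        frames=frames,
        x=x,
        y=y,
        confidence=conf,
    )


_CSV_COLUMNS = ("infant_id", "frame", "joint", "x", "y", "confidence")


def _load_csv(path: Path, frame_rate: float, infant_id: str | None) -> KeypointSeries:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(_CSV_COLUMNS) <= set(reader.fieldnames):
            raise SchemaError(
                f"{path}: header must contain columns {', '.join(_CSV_COLUMNS)}"
            )
        rows = []
        for i, row in enumerate(reader):
            try:
                joint = Joint(row["joint"])
            except ValueError:
                raise SchemaError(f"row {i + 2}: unknown joint label {row['joint']!r}")
            try:
                rows.append(
                    (
                        row["infant_id"],
                        int(row["frame"]),
                        joint,
                        float(row["x"]),
                        float(row["y"]),
                        float(row["confidence"]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"row {i + 2}: {exc}") from exc
    if not rows:
        raise ParseError(f"{path}: no data rows")
    ids = {r[0] for r in rows}
    if infant_id is None:
        if len(ids) > 1:
            raise SchemaError(f"{path}: multiple infant_ids {sorted(ids)}; pass infant_id")
        infant_id = next(iter(ids))
    lo = min(r[1] for r in rows)
    hi = max(r[1] for r in rows)
    frames = np.arange(lo, hi + 1, dtype=np.int64)
    n = len(frames)
    x = np.full((n, _N_JOINTS), np.nan)
    y = np.full((n, _N_JOINTS), np.nan)
    conf = np.full((n, _N_JOINTS), np.nan)
    for _, frame, joint, xv, yv, cv in rows:
        r, c = frame - lo, _COL[joint]
        x[r, c], y[r, c], conf[r, c] = xv, yv, cv
    return KeypointSeries(
        infant_id=infant_id,
        frame_rate=frame_rate,
        frames=frames,
        x=x,
        y=y,
        confidence=conf,
    )


# ---------------------------------------------------------------------------
# writing


def write_keypoints(series: KeypointSeries, path: str | Path, format: str = "csv") -> Path:
    """Write a series in the same dialects :func:`load_keypoints` reads.

    CSV rows are emitted only for observed (non-missing) joints with full
    ``repr`` float precision, so a write→load round trip preserves retained
    observations to numeric precision.  In pose-JSON, missing joints are
    encoded with confidence 0 (and are therefore removed again by any
    filtering threshold > 0); face keypoints are written as zeros.
    """
    path = Path(path)
    if format == "csv":
        miss = series.missing_mask()
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_COLUMNS)
            for r, frame in enumerate(series.frames):
                for joint in JOINTS:
                    c = _COL[joint]
                    if miss[r, c]:
                        continue
                    writer.writerow(
                        (
                            series.infant_id,
                            int(frame),
                            joint.value,
                            repr(float(series.x[r, c])),
                            repr(float(series.y[r, c])),
                            repr(float(series.confidence[r, c])),
                        )
                    )
        return path
    if format == "pose-json":
        records = []
        miss = series.missing_mask()
        for r, frame in enumerate(series.frames):
            if miss[r].all():
                continue  # frame gap: no record at all
            kps = [0.0] * 51
            for joint, coco in COCO_INDEX.items():
                c = _COL[joint]
                if miss[r, c]:
                    continue
                kps[3 * coco] = float(series.x[r, c])
                kps[3 * coco + 1] = float(series.y[r, c])
                kps[3 * coco + 2] = float(series.confidence[r, c])
            score = float(np.nanmean(series.confidence[r]))
            records.append({"image_id": f"{int(frame)}.jpg", "keypoints": kps, "score": score})
        path.write_text(json.dumps(records))
        return path
    raise ValidationError(f"unknown format {format!r}")
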