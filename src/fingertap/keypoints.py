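"""Hand-landmark time series: containers, validation and file I/O.

Landmark indexing follows the 21-point MediaPipe hand convention, 0-20:
0 = wrist, 4 = thumb tip, 8 = index-finger tip, 9 = middle-finger MCP.
Coordinates may be metric world coordinates or normalized image coordinates;
palm-size normalization downstream removes the scale either way.

Two on-disk dialects are supported:

* CSV (canonical): columns ``frame,landmark,x,y,z`` with ``# key=value``
  comment lines carrying fps / subject_id / hand_side metadata;
* JSON: ``{"fps": ..., "frames": [[[x, y, z] * 21], ...]}`` for
  interoperability with pose-estimator exports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .signal import TapSignal

N_LANDMARKS = 21
WRIST = 0
THUMB_TIP = 4
INDEX_TIP = 8
MIDDLE_MCP = 9

_HAND_SIDES = {"left", "right", "unknown"}


@dataclass
class HandPoseSeries:
    """Per-frame 21-landmark 3D coordinates plus acquisition metadata.

    ``coords`` has shape (n_frames, 21, 3) in arbitrary consistent length
    units.  Frames containing any non-finite coordinate are *flagged* (see
    :attr:`missing_frames`), never silently dropped; preprocessing
    interpolates over them.
    """

    coords: np.ndarray
    fps: float
    subject_id: str = ""
    hand_side: str = "unknown"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (N_LANDMARKS, 3):
            raise ValidationError(
                f"coords must have shape (n_frames, {N_LANDMARKS}, 3); "
                f"got {self.coords.shape}"
            )
        if self.coords.shape[0] < 2:
            raise ValidationError("a recording needs at least 2 frames")
        if not self.fps > 0:
            raise ValidationError("fps must be positive")
        if self.hand_side not in _HAND_SIDES:
            raise ValidationError(f"hand_side must be one of {sorted(_HAND_SIDES)}")

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    @property
    def missing_frames(self) -> np.ndarray:
        """Indices of frames with any non-finite landmark coordinate."""
        ok = np.isfinite(self.coords).all(axis=(1, 2))
        return np.flatnonzero(~ok)


@dataclass
class Demographics:
    """Subject age (years) and sex, used as the two demographic features."""

    age: int
    sex: str  # "female" | "male"

    def __post_init__(self) -> None:
        if int(self.age) < 0:
            raise ValidationError("age must be >= 0")
        self.age = int(self.age)
        if self.sex not in ("female", "male"):
            raise ValidationError("sex must be 'female' or 'male'")

    @property
    def sex_code(self) -> int:
        """Binary encoding: 0 = female, 1 = male."""
        return 0 if self.sex == "female" else 1


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "json"):
        return suffix
    raise ValidationError(f"cannot infer format from suffix {path.suffix!r}")


def read_keypoints(
    path: str | Path,
    fmt: str | None = None,
    fps: float | None = None,
) -> HandPoseSeries:
    """Read and validate a hand-landmark time series.

    ``fps`` may come from the file's metadata or the argument; the argument
    wins when both are present.  Frame indices are sorted and made contiguous.

    Raises
    ------
    ValidationError
        On a frame missing a landmark (named in the message), a non-numeric
        coordinate (with its row number), or absent fps.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        return _read_csv(path, fps)
    if fmt == "json":
        return _read_json(path, fps)
    raise ValidationError(f"unknown format {fmt!r}")


def _read_csv(path: Path, fps: float | None) -> HandPoseSeries:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    df = pd.read_csv(path, comment="#")
    required = {"frame", "landmark", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"keypoint CSV must have columns {sorted(required)}; got {list(df.columns)}"
        )
    for col in ("x", "y", "z"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0]) + 2  # 1-based + header line
            raise ValidationError(
                f"non-numeric value {df[col][bad].iloc[0]!r} in column {col!r}"
                f" at data row {row}"
            )
        df[col] = coerced
    if fps is None and "fps" in meta:
        fps = float(meta["fps"])
    if fps is None:
        raise ValidationError("fps not found in CSV metadata and not supplied")

    frames = np.sort(df["frame"].unique())
    coords = np.full((frames.size, N_LANDMARKS, 3), np.nan)
    for pos, frame in enumerate(frames):
        sub = df[df["frame"] == frame]
        ids = np.sort(sub["landmark"].to_numpy())
        if ids.size != N_LANDMARKS or not np.array_equal(ids, np.arange(N_LANDMARKS)):
            missing = sorted(set(range(N_LANDMARKS)) - set(ids.tolist()))
            raise ValidationError(
                f"frame {int(frame)}: expected landmarks 0-{N_LANDMARKS - 1}, "
                f"missing {missing or 'none'} ({ids.size} rows)"
            )
        order = np.argsort(sub["landmark"].to_numpy())
        coords[pos] = sub[["x", "y", "z"]].to_numpy()[order]
    return HandPoseSeries(
        coords=coords,
        fps=float(fps),
        subject_id=meta.get("subject_id", ""),
        hand_side=meta.get("hand_side", "unknown"),
    )


def _read_json(path: Path, fps: float | None) -> HandPoseSeries:
    with open(path) as fh:
        payload = json.load(fh)
    if isinstance(payload, list):  # bare array of frames
        payload = {"frames": payload}
    frames = payload.get("frames")
    if frames is None:
        raise ValidationError("JSON keypoint file must contain a 'frames' array")
    coords = np.full((len(frames), N_LANDMARKS, 3), np.nan)
    for i, frame in enumerate(frames):
        if len(frame) != N_LANDMARKS:
            raise ValidationError(
                f"frame {i}: expected {N_LANDMARKS} landmarks, got {len(frame)}"
            )
        arr = np.asarray(frame, dtype=float)
        if arr.shape != (N_LANDMARKS, 3):
            raise ValidationError(f"frame {i}: landmarks must be [x, y, z] triples")
        coords[i] = arr
    if fps is None:
        fps = payload.get("fps")
    if fps is None:
        raise ValidationError("fps not found in JSON metadata and not supplied")
    return HandPoseSeries(
        coords=coords,
        fps=float(fps),
        subject_id=str(payload.get("subject_id", "")),
        hand_side=str(payload.get("hand_side", "unknown")),
    )


def write_keypoints(series: HandPoseSeries, path: str | Path, fmt: str | None = None) -> None:
    """Write a HandPoseSeries in the CSV or JSON dialect (round-trip safe)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        n, m = series.n_frames, N_LANDMARKS
        df = pd.DataFrame(
            {
                "frame": np.repeat(np.arange(n), m),
                "landmark": np.tile(np.arange(m), n),
                "x": series.coords[:, :, 0].ravel(),
                "y": series.coords[:, :, 1].ravel(),
                "z": series.coords[:, :, 2].ravel(),
            }
        )
        with open(path, "w") as fh:
            fh.write(f"# fps={series.fps!r}\n")
            fh.write(f"# subject_id={series.subject_id}\n")
            fh.write(f"# hand_side={series.hand_side}\n")
            df.to_csv(fh, index=False, float_format="%.17g")
    elif fmt == "json":
        payload = {
            "fps": series.fps,
            "subject_id": series.subject_id,
            "hand_side": series.hand_side,
            "frames": series.coords.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
    else:
        raise ValidationError(f"unknown format {fmt!r}")


def distance_series(
    series: HandPoseSeries, a: int = THUMB_TIP, b: int = INDEX_TIP
) -> TapSignal:
    """Per-frame Euclidean distance between landmarks ``a`` and ``b``.

    Defaults to the thumb-tip / index-tip pair used in the finger-tapping
    task.  Frames with non-finite coordinates at either landmark yield NaN
    samples, which preprocessing interpolates.
    """
    if not (0 <= a < N_LANDMARKS and 0 <= b < N_LANDMARKS):
        raise ValidationError(f"landmark indices must be in 0-{N_LANDMARKS - 1}")
    delta = series.coords[:, a, :] - series.coords[:, b, :]
    values = np.linalg.norm(delta, axis=1)
    bad = ~np.isfinite(series.coords[:, [a, b], :]).all(axis=(1, 2))
    values[bad] = np.nan
    return TapSignal(values=values, fps=series.fps, normalized=False, units="raw")


def pose_adapter(frames: "list[object]", fps: float, subject_id: str = "",
                 hand_side: str = "unknown") -> HandPoseSeries:
    """Adapter boundary for external pose estimators.

    ``frames`` is whatever a per-frame hand-landmark estimator emits, as long
    as each frame is convertible to a (21, 3) array of (x, y, z) — e.g. a list
    of objects with ``.x/.y/.z`` attributes or a nested list.  The estimator
    itself is outside this package.
    """
    converted = []
    for i, frame in enumerate(frames):
        try:
            arr = np.asarray(
                [
                    [lm.x, lm.y, lm.z] if hasattr(lm, "x") else list(lm)[:3]
                    for lm in frame
                ],
                dtype=float,
            )
        except Exception as exc:  # noqa: BLE001 - re-raise with frame context
            raise ValidationError(f"frame {i}: cannot convert landmarks ({exc})")
        if arr.shape != (N_LANDMARKS, 3):
            raise ValidationError(
                f"frame {i}: expected {N_LANDMARKS} landmarks, got {arr.shape}"
            )
        converted.append(arr)
    return HandPoseSeries(
        coords=np.stack(converted), fps=fps, subject_id=subject_id, hand_side=hand_side
    )
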