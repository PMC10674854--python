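"""Raw distance signal -> clean, palm-normalized, peak-annotated signal.

The chain is: palm-size normalization (wrist to middle-finger MCP distance),
dropout interpolation, EMD, reconstruction from the leading IMFs, local
polynomial (Savitzky-Golay) smoothing, and prominence/separation-constrained
peak detection.  Everything here is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .emd import emd_decompose
from .errors import UnusableRecordingError, ValidationError
from .keypoints import MIDDLE_MCP, WRIST, HandPoseSeries, distance_series
from .signal import EMDResult, PeakSet, TapSignal

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "palm_size",
    "normalize",
    "interpolate_missing",
    "select_and_clean",
    "detect_peaks",
    "preprocess",
]


@dataclass
class PreprocessConfig:
    """Tunable preprocessing parameters.

    n_keep_imfs
        Number of leading (highest-frequency) IMFs retained; 3 by default.
    keep_residual
        If True the slow EMD residual is added back in full, so amplitudes
        track the raw envelope exactly.  If False (default) only the
        residual's median re-enters, which centres the oscillation on a flat
        baseline and discards slow drift.
    smooth_window_s
        Savitzky-Golay window length in seconds (order 2); rounded to an odd
        number of samples.
    min_prominence_frac
        Peak prominence threshold as a fraction of the cleaned signal's range.
    min_separation_s
        Minimum time between accepted peaks; taps faster than 10 Hz are
        physiologically implausible, hence 0.1 s.
    max_gap_s
        Longest pose-dropout run that is linearly interpolated; longer gaps
        reject the recording.
    """

    n_keep_imfs: int = 3
    keep_residual: bool = False
    smooth_window_s: float = 0.25
    min_prominence_frac: float = 0.1
    min_separation_s: float = 0.1
    max_gap_s: float = 0.5
    palm_floor_frac: float = 1e-6


def palm_size(series: HandPoseSeries) -> np.ndarray:
    """Per-frame palm size: Euclidean distance between wrist and middle MCP.

    Frames where the distance collapses below ``palm_floor_frac`` of the
    median palm size (or is non-finite) are degenerate; their values are
    linearly interpolated from valid neighbours.  If every frame is
    degenerate the recording is unusable.
    """
    delta = series.coords[:, WRIST, :] - series.coords[:, MIDDLE_MCP, :]
    palm = np.linalg.norm(delta, axis=1)
    finite = np.isfinite(palm)
    if not finite.any():
        raise UnusableRecordingError("palm size undefined in every frame")
    floor = PreprocessConfig.palm_floor_frac * float(np.median(palm[finite]))
    valid = finite & (palm > floor)
    if not valid.any():
        raise UnusableRecordingError("palm size degenerate in every frame")
    if not valid.all():
        idx = np.arange(palm.size)
        palm = np.interp(idx, idx[valid], palm[valid])
    return palm


def normalize(signal: TapSignal, palm: np.ndarray) -> TapSignal:
    """Divide the distance signal by the per-frame palm size (dimensionless).

    Removes subject hand size and camera geometry, making amplitudes
    comparable across recordings.
    """
    palm = np.asarray(palm, dtype=float)
    if palm.size != len(signal):
        raise ValidationError(
            f"palm series length {palm.size} != signal length {len(signal)}"
        )
    if np.any(palm <= 0):
        raise ValidationError("palm size must be strictly positive")
    return TapSignal(
        values=signal.values / palm,
        fps=signal.fps,
        normalized=True,
        units="palm",
    )


def interpolate_missing(signal: TapSignal, max_gap_s: float = 0.5) -> TapSignal:
    """Linearly interpolate NaN runs up to ``max_gap_s`` seconds long.

    A longer dropout means the hand left the frame for too long; the
    recording is rejected, mirroring manual quality exclusion.
    """
    values = signal.values.copy()
    bad = ~np.isfinite(values)
    if not bad.any():
        return signal
    if bad.all():
        raise UnusableRecordingError("signal has no valid samples")
    # longest run of consecutive missing samples
    bad_idx = np.flatnonzero(bad)
    runs = np.split(bad_idx, np.flatnonzero(np.diff(bad_idx) > 1) + 1)
    longest = max(len(r) for r in runs)
    if longest > max_gap_s * signal.fps:
        raise UnusableRecordingError(
            f"pose dropout of {longest} frames exceeds {max_gap_s} s"
        )
    idx = np.arange(values.size)
    values[bad] = np.interp(idx[bad], idx[~bad], values[~bad])
    return TapSignal(values, signal.fps, signal.normalized, signal.units)


def _odd_window(signal_len: int, fps: float, window_s: float) -> int:
    w = int(round(window_s * fps))
    w = max(w, 5)
    if w % 2 == 0:
        w += 1
    if w >= signal_len:
        w = signal_len - 1 if signal_len % 2 == 0 else signal_len - 2
        w = max(w, 3)
    return w


def select_and_clean(
    emd: EMDResult,
    fps: float,
    n_keep: int = 3,
    smooth_window: int | None = None,
    keep_residual: bool = False,
) -> TapSignal:
    """Rebuild the signal from the leading IMFs and smooth it.

    The first ``n_keep`` IMFs carry the tapping oscillation; later modes and
    the residual hold tremor-unrelated drift.  With ``keep_residual=False``
    the residual contributes only its median, recentring the oscillation on a
    constant baseline; with True it is added back wholesale.  Smoothing is a
    second-order Savitzky-Golay filter, which preserves peak amplitudes far
    better than a moving average — those amplitudes feed every feature.
    """
    if n_keep < 1:
        raise ValidationError("n_keep must be >= 1")
    n_avail = emd.n_imfs
    if n_avail == 0:
        values = emd.residual.copy()
    else:
        if n_avail < n_keep:
            logger.warning(
                "requested %d IMFs but only %d available; keeping all", n_keep, n_avail
            )
            n_keep = n_avail
        values = np.sum(emd.imfs[:n_keep], axis=0)
        if keep_residual:
            values = values + emd.residual
        else:
            values = values + float(np.median(emd.residual))
    window = smooth_window if smooth_window is not None else _odd_window(
        values.size, fps, PreprocessConfig.smooth_window_s
    )
    if window % 2 == 0 or window < 3 or window >= values.size:
        raise ValidationError("smooth_window must be odd, >= 3 and < signal length")
    smoothed = savgol_filter(values, window_length=window, polyorder=2)
    return TapSignal(smoothed, fps=fps, normalized=True, units="palm")


def detect_peaks(
    signal: TapSignal,
    min_prominence: float = 0.1,
    min_separation: float = 0.1,
) -> PeakSet:
    """Find full-opening peaks (local maxima) of the cleaned signal.

    ``min_prominence`` is a fraction of the signal's range; ``min_separation``
    is in seconds.  Zero detected peaks marks the recording unusable.
    """
    values = signal.values
    rng = float(values.max() - values.min())
    if rng <= 0:
        raise UnusableRecordingError("signal is constant; no tapping detected")
    distance = max(1, int(round(min_separation * signal.fps)))
    idx, _ = find_peaks(values, prominence=min_prominence * rng, distance=distance)
    if idx.size == 0:
        raise UnusableRecordingError("no peaks detected; recording unusable")
    return PeakSet(indices=idx, amplitudes=values[idx], fps=signal.fps)


def preprocess(
    series: HandPoseSeries,
    config: PreprocessConfig | None = None,
) -> tuple[TapSignal, PeakSet]:
    """Full chain: distance -> palm-normalize -> interpolate -> EMD ->
    clean/smooth -> peaks.  Returns the cleaned signal and its PeakSet."""
    cfg = config or PreprocessConfig()
    raw = distance_series(series)
    palm = palm_size(series)
    norm = normalize(raw, palm)
    norm = interpolate_missing(norm, max_gap_s=cfg.max_gap_s)
    decomposition = emd_decompose(norm)
    window = _odd_window(len(norm), series.fps, cfg.smooth_window_s)
    clean = select_and_clean(
        decomposition,
        fps=series.fps,
        n_keep=cfg.n_keep_imfs,
        smooth_window=window,
        keep_residual=cfg.keep_residual,
    )
    peaks = detect_peaks(
        clean,
        min_prominence=cfg.min_prominence_frac,
        min_separation=cfg.min_separation_s,
    )
    return clean, peaks
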