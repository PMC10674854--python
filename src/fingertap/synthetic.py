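"""Synthetic finger-tapping generator with severity-graded impairment.

Real patient recordings cannot be shared, so every pipeline stage is
exercised on simulated tapping instead.  A tap cycle is a raised cosine
(smooth open/close, no corners that would leak spurious high-frequency EMD
modes); cycle maxima follow a continuous broken-stick amplitude envelope
(flat or drifting first segment, decrementing second segment from a chosen
breakpoint), selected cycles are suppressed to emulate halts/hesitations,
and the observed signal adds a tremor sinusoid plus Gaussian measurement
noise, clipped at zero because distances are non-negative.

Because the generator *constructs* the signal from the same parametric
families the feature extractor estimates, it doubles as the ground-truth
oracle: it returns the true peak locations/amplitudes and the analytically
known feature values alongside the signal.

The default :class:`SeverityProfile` maps the clinical rating bands onto
generator parameters (amplitude and tap rate fall with severity, halts and
earlier decrement onset rise) and ships as an editable YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError
from .features import DEFAULT_ALPHA
from .keypoints import (
    INDEX_TIP,
    MIDDLE_MCP,
    N_LANDMARKS,
    THUMB_TIP,
    WRIST,
    Demographics,
    HandPoseSeries,
)
from .signal import PeakSet, TapSignal

__all__ = [
    "TapSpec",
    "SignalTruth",
    "SeverityProfile",
    "SimulatedRecording",
    "generate_signal",
    "generate_pose_series",
    "generate_dataset",
    "load_default_profile",
]


@dataclass
class TapSpec:
    """Parameters of one simulated tapping recording.

    decrement is (breakpoint fraction of taps, per-tap slope before the
    breakpoint, incremental per-tap slope after it), all in palm units;
    halts is a sequence of (tap ordinal, depth fraction in [0, 1]);
    tremor is (frequency Hz, amplitude as fraction of base_amplitude);
    noise_sd is the Gaussian measurement-noise SD as a fraction of
    base_amplitude.
    """

    duration: float = 10.0
    fps: float = 60.0
    rate: float = 3.0
    base_amplitude: float = 1.4
    decrement: tuple[float, float, float] = (0.75, 0.0, 0.0)
    halts: tuple[tuple[int, float], ...] = ()
    tremor: tuple[float, float] = (5.0, 0.0)
    noise_sd: float = 0.0
    palm_size: float = 0.09
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duration", "fps", "rate", "base_amplitude", "palm_size"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if self.rate > self.fps / 4:
            raise ValidationError(
                f"rate {self.rate} Hz undersampled at {self.fps} fps (need rate <= fps/4)"
            )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        for ordinal, depth in self.halts:
            if not 0.0 <= depth <= 1.0:
                raise ValidationError(f"halt depth {depth} outside [0, 1]")
            if ordinal < 1:
                raise ValidationError("halt ordinals are 1-based")

    @property
    def n_taps(self) -> int:
        return max(1, int(np.floor(self.duration * self.rate)))


@dataclass
class SignalTruth:
    """Generator output: signals plus the ground truth behind them."""

    clean: TapSignal
    observed: TapSignal
    peaks: PeakSet
    features: dict[str, float]


def _envelope(spec: TapSpec) -> tuple[np.ndarray, int]:
    """True cycle maxima A_n (before halts) and the breakpoint ordinal."""
    n = spec.n_taps
    bp_frac, slope1, slope2 = spec.decrement
    bp = int(np.clip(round(bp_frac * n), 1, max(1, n - 1)))
    ordinals = np.arange(1, n + 1, dtype=float)
    amps = (
        spec.base_amplitude
        + slope1 * (ordinals - 1)
        + slope2 * np.maximum(0.0, ordinals - bp)
    )
    return np.maximum(amps, 0.02 * spec.base_amplitude), bp


def _true_halt_count(amps_halted: np.ndarray, amps_trend: np.ndarray,
                     alpha: float = DEFAULT_ALPHA) -> int:
    """Halt count by the trend-residual definition, using the exact trend."""
    count = 0
    for i in range(1, amps_halted.size - 1):
        theta = alpha * 0.5 * (amps_halted[i - 1] + amps_halted[i + 1])
        drop = amps_trend[i] - amps_halted[i]
        if drop > 0 and drop >= theta:
            count += 1
    return count


def generate_signal(spec: TapSpec) -> SignalTruth:
    """Simulate one recording; returns signals, true peaks and true features."""
    rng = np.random.default_rng(spec.seed)
    n_frames = int(round(spec.duration * spec.fps))
    t = np.arange(n_frames) / spec.fps
    n = spec.n_taps
    trend, bp = _envelope(spec)
    amps = trend.copy()
    for ordinal, depth in spec.halts:
        if 1 <= ordinal <= n:
            amps[ordinal - 1] *= 1.0 - depth

    period = 1.0 / spec.rate
    cycle = np.minimum((t / period).astype(int), n - 1)
    phase = t / period - np.floor(t / period)
    clean = amps[cycle] * 0.5 * (1.0 - np.cos(2 * np.pi * phase))
    clean[t >= n * period] = 0.0

    tremor_f, tremor_amp = spec.tremor
    observed = clean.copy()
    if tremor_amp > 0:
        observed = observed + tremor_amp * spec.base_amplitude * np.sin(
            2 * np.pi * tremor_f * t
        )
    if spec.noise_sd > 0:
        observed = observed + rng.normal(
            0.0, spec.noise_sd * spec.base_amplitude, n_frames
        )
    observed = np.clip(observed, 0.0, None)

    peak_times = (np.arange(1, n + 1) - 0.5) * period
    peak_idx = np.clip(np.round(peak_times * spec.fps).astype(int), 0, n_frames - 1)
    peaks = PeakSet(indices=peak_idx, amplitudes=amps, fps=spec.fps, times=peak_times)

    # analytically known features (brute-force formulas on the true peaks)
    dt = np.diff(peak_times)
    vel = (amps[1:] + amps[:-1]) / dt if n >= 2 else np.array([])
    truth: dict[str, float] = {
        "amp_avg": float(np.mean(amps)),
        "amp_var": float(np.var(amps)),
        "amp_bp": float(bp),
        "amp_alpha1": float(spec.decrement[1]),
        "amp_alpha2": float(spec.decrement[2]),
        "freq": float(spec.rate),
        "n_peaks": float(n),
        "hh": float(_true_halt_count(amps, trend)),
    }
    if vel.size:
        truth["vel_avg"] = float(np.mean(vel))
        truth["vel_var"] = float(np.var(vel))
    return SignalTruth(
        clean=TapSignal(clean, spec.fps, normalized=True, units="palm"),
        observed=TapSignal(observed, spec.fps, normalized=True, units="palm"),
        peaks=peaks,
        features=truth,
    )


# static rest pose in palm units; wrist at origin, middle MCP one palm away,
# so the wrist-to-MCP distance is exactly 1 palm unit in every frame
_REST_POSE = np.array(
    [
        [0.00, 0.00, 0.00],  # 0 wrist
        [0.25, 0.15, 0.02],  # 1 thumb CMC
        [0.42, 0.30, 0.04],  # 2 thumb MCP
        [0.55, 0.42, 0.05],  # 3 thumb IP
        [0.65, 0.52, 0.06],  # 4 thumb tip (moves)
        [0.30, 0.95, 0.00],  # 5 index MCP
        [0.34, 1.25, 0.00],  # 6 index PIP
        [0.36, 1.45, 0.00],  # 7 index DIP
        [0.38, 1.60, 0.00],  # 8 index tip (moves)
        [0.00, 1.00, 0.00],  # 9 middle MCP
        [0.00, 1.35, 0.00],  # 10 middle PIP
        [0.00, 1.58, 0.00],  # 11 middle DIP
        [0.00, 1.75, 0.00],  # 12 middle tip
        [-0.28, 0.95, 0.00],  # 13 ring MCP
        [-0.30, 1.28, 0.00],  # 14 ring PIP
        [-0.32, 1.48, 0.00],  # 15 ring DIP
        [-0.34, 1.62, 0.00],  # 16 ring tip
        [-0.52, 0.85, 0.00],  # 17 pinky MCP
        [-0.56, 1.10, 0.00],  # 18 pinky PIP
        [-0.58, 1.25, 0.00],  # 19 pinky DIP
        [-0.60, 1.38, 0.00],  # 20 pinky tip
    ]
)


def generate_pose_series(
    spec: TapSpec, subject_id: str = "", truth: SignalTruth | None = None
) -> HandPoseSeries:
    """Embed the simulated distance signal in a 21-landmark pose series.

    The palm (wrist to middle MCP) is static at ``palm_size``, and the index
    tip is placed so the thumb-index distance equals the observed signal
    times ``palm_size`` — palm normalization therefore recovers the
    simulated signal exactly.
    """
    truth = truth or generate_signal(spec)
    obs = truth.observed.values
    n_frames = obs.size
    coords = np.repeat(_REST_POSE[None, :, :], n_frames, axis=0) * spec.palm_size
    direction = np.array([1.0, 0.0, 0.0])
    coords[:, INDEX_TIP, :] = coords[:, THUMB_TIP, :] + (
        obs[:, None] * spec.palm_size * direction[None, :]
    )
    assert np.allclose(
        np.linalg.norm(coords[:, WRIST] - coords[:, MIDDLE_MCP], axis=1),
        spec.palm_size,
    )
    assert coords.shape[1] == N_LANDMARKS
    return HandPoseSeries(coords=coords, fps=spec.fps, subject_id=subject_id)


# --------------------------------------------------------------------------
# severity profiles


@dataclass
class ClassProfile:
    """Parameter distributions for one severity class."""

    amplitude_mean: float
    amplitude_sd: float
    rate_mean: float
    rate_sd: float
    slope1: tuple[float, float] = (0.0, 0.0)
    slope2: tuple[float, float] = (0.0, 0.0)
    bp_frac: tuple[float, float] = (0.6, 0.9)
    n_halts: tuple[int, int] = (0, 0)
    halt_depth: tuple[float, float] = (0.0, 0.0)
    tremor_amp: tuple[float, float] = (0.0, 0.01)
    noise_sd: tuple[float, float] = (0.005, 0.015)


@dataclass
class SeverityProfile:
    """Per-class generator distributions plus shared recording settings."""

    classes: dict[int, ClassProfile]
    duration: float = 10.0
    fps: float = 60.0
    tremor_freq: float = 5.0
    age_range: tuple[int, int] = (45, 85)

    def __post_init__(self) -> None:
        if set(self.classes) != {0, 1, 2, 3, 4}:
            raise ValidationError("profile must define classes 0-4")
        amps = [self.classes[c].amplitude_mean for c in range(5)]
        rates = [self.classes[c].rate_mean for c in range(5)]
        halts = [self.classes[c].n_halts[1] for c in range(5)]
        if np.any(np.diff(amps) > 0) or np.any(np.diff(rates) > 0):
            raise ValidationError(
                "amplitude and rate means must be non-increasing with severity"
            )
        if np.any(np.diff(halts) < -1e9):  # pragma: no cover - shape guard
            raise ValidationError("halt counts must not decrease with severity")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SeverityProfile":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SeverityProfile":
        classes = {}
        for key, c in raw["classes"].items():
            classes[int(key)] = ClassProfile(
                amplitude_mean=float(c["amplitude"]["mean"]),
                amplitude_sd=float(c["amplitude"]["sd"]),
                rate_mean=float(c["rate"]["mean"]),
                rate_sd=float(c["rate"]["sd"]),
                slope1=tuple(c.get("slope1", [0.0, 0.0])),
                slope2=tuple(c.get("slope2", [0.0, 0.0])),
                bp_frac=tuple(c.get("bp_frac", [0.6, 0.9])),
                n_halts=tuple(int(v) for v in c.get("n_halts", [0, 0])),
                halt_depth=tuple(c.get("halt_depth", [0.0, 0.0])),
                tremor_amp=tuple(c.get("tremor_amp", [0.0, 0.01])),
                noise_sd=tuple(c.get("noise_sd", [0.005, 0.015])),
            )
        return cls(
            classes=classes,
            duration=float(raw.get("duration", 10.0)),
            fps=float(raw.get("fps", 60.0)),
            tremor_freq=float(raw.get("tremor_freq", 5.0)),
            age_range=tuple(raw.get("age_range", [45, 85])),
        )


def load_default_profile() -> SeverityProfile:
    """The packaged default severity profile (editable YAML)."""
    ref = resources.files("fingertap") / "profiles" / "default_severity.yaml"
    with resources.as_file(ref) as path:
        return SeverityProfile.from_yaml(path)


@dataclass
class SimulatedRecording:
    """One labelled synthetic recording with its generating spec and truth."""

    series: HandPoseSeries
    demographics: Demographics
    label: int
    spec: TapSpec
    truth: SignalTruth
    subject_id: str = ""


def _sample_spec(
    profile: SeverityProfile, label: int, rng: np.random.Generator
) -> TapSpec:
    cp = profile.classes[label]
    amplitude = max(0.05, rng.normal(cp.amplitude_mean, cp.amplitude_sd))
    rate = float(np.clip(rng.normal(cp.rate_mean, cp.rate_sd), 0.3, profile.fps / 4))
    slope1 = rng.uniform(*cp.slope1)
    slope2 = rng.uniform(*cp.slope2)
    bp_frac = rng.uniform(*cp.bp_frac)
    n_taps = max(1, int(np.floor(profile.duration * rate)))
    n_halts = int(rng.integers(cp.n_halts[0], cp.n_halts[1] + 1))
    interior = np.arange(2, n_taps)  # halts need both neighbours
    n_halts = min(n_halts, interior.size)
    halts = tuple(
        (int(k), float(rng.uniform(*cp.halt_depth)))
        for k in sorted(rng.choice(interior, size=n_halts, replace=False))
    ) if n_halts > 0 else ()
    return TapSpec(
        duration=profile.duration,
        fps=profile.fps,
        rate=rate,
        base_amplitude=amplitude,
        decrement=(bp_frac, slope1, slope2),
        halts=halts,
        tremor=(profile.tremor_freq, rng.uniform(*cp.tremor_amp)),
        noise_sd=rng.uniform(*cp.noise_sd),
        palm_size=rng.uniform(0.07, 0.11),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_dataset(
    profile: SeverityProfile | None = None,
    n_per_class: int = 10,
    seed: int = 0,
) -> list[SimulatedRecording]:
    """Sample ``n_per_class`` labelled recordings for each severity class.

    Demographics are drawn independently of the label (the rating reflects
    motor performance, not who the subject is).  Fully reproducible by seed.
    """
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    profile = profile or load_default_profile()
    rng = np.random.default_rng(seed)
    recordings: list[SimulatedRecording] = []
    for label in range(5):
        for i in range(n_per_class):
            spec = _sample_spec(profile, label, rng)
            truth = generate_signal(spec)
            subject_id = f"sim-{label}-{i:03d}"
            series = generate_pose_series(spec, subject_id=subject_id, truth=truth)
            demo = Demographics(
                age=int(rng.integers(profile.age_range[0], profile.age_range[1] + 1)),
                sex="female" if rng.random() < 0.5 else "male",
            )
            recordings.append(
                SimulatedRecording(
                    series=series,
                    demographics=demo,
                    label=label,
                    spec=spec,
                    truth=truth,
                    subject_id=subject_id,
                )
            )
    return recordings
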