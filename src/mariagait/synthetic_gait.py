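"""Synthetic triaxial gait recordings with class-dependent structure.

Generates labeled accelerometer (and gyroscope) walking bouts so the full
pipeline can be exercised and benchmarked without any external data. The
signal model is deliberately simple: a small number of harmonics of the step
frequency, phase-locked to a stride clock whose per-stride duration jitters
with a controllable coefficient of variation, plus medio-lateral sway and
additive Gaussian sensor noise. Impairment classes differ only through the
generator knobs (cadence, sway amplitude, stride-time variability, harmonic
shape) -- the presets are separable by construction, not a claim about
pharmacology.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_LABELS",
    "GaitClassParams",
    "SensorRecording",
    "SubjectEffects",
    "default_presets",
    "generate_recording",
    "generate_dataset",
    "write_dataset_csv",
    "read_dataset_csv",
]

#: Canonical class label order used throughout the package.
CLASS_LABELS: Tuple[str, ...] = ("sober", "alcohol", "marijuana")

_GRAVITY = 9.81  # m/s^2, carried on the vertical axis

# Fixed per-axis harmonic phase offsets (radians). Axis order: ax (antero-
# posterior), ay (medio-lateral), az (vertical).
_AXIS_PHASES = {
    "ax": (0.6, 2.1, 4.0),
    "az": (0.0, 1.2, 2.9),
}


@dataclass(frozen=True)
class GaitClassParams:
    """Generator knobs for one impairment class."""

    label: str
    step_rate_hz: float
    stride_time_cv: float
    sway_amp: float
    harmonic_weights: Tuple[float, ...]
    noise_sd: float

    def __post_init__(self) -> None:
        if self.label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.label!r}")
        if not self.step_rate_hz > 0:
            raise ValueError("step_rate_hz must be > 0")
        if self.stride_time_cv < 0:
            raise ValueError("stride_time_cv must be >= 0")
        if self.sway_amp < 0:
            raise ValueError("sway_amp must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(w < 0 for w in self.harmonic_weights):
            raise ValueError("harmonic_weights must be >= 0")
        object.__setattr__(self, "harmonic_weights", tuple(self.harmonic_weights))


def default_presets() -> Dict[str, GaitClassParams]:
    """Class presets: sober regular; alcohol slower cadence + more sway;
    marijuana more stride-time variability.  Harmonic shapes also differ so
    that shape information survives per-axis rescaling downstream."""
    return {
        "sober": GaitClassParams(
            label="sober",
            step_rate_hz=1.9,
            stride_time_cv=0.02,
            sway_amp=0.35,
            harmonic_weights=(1.5, 0.55, 0.22),
            noise_sd=0.15,
        ),
        "alcohol": GaitClassParams(
            label="alcohol",
            step_rate_hz=1.5,
            stride_time_cv=0.06,
            sway_amp=1.2,
            harmonic_weights=(1.5, 0.75, 0.08),
            noise_sd=0.2,
        ),
        "marijuana": GaitClassParams(
            label="marijuana",
            step_rate_hz=1.8,
            stride_time_cv=0.15,
            sway_amp=0.55,
            harmonic_weights=(1.5, 0.12, 0.5),
            noise_sd=0.2,
        ),
    }


@dataclass(frozen=True)
class SubjectEffects:
    """Per-subject random effects, drawn once per subject so that
    subject-wise train/test splits are meaningful."""

    gain: float = 1.0
    cadence_offset_hz: float = 0.0
    phase_offset: float = 0.0


@dataclass
class SensorRecording:
    """One walking bout of uniformly sampled triaxial sensor data."""

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    fs: float
    subject_id: str
    label: str
    gx: Optional[np.ndarray] = None
    gy: Optional[np.ndarray] = None
    gz: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.label!r}")
        n = len(self.t)
        for name in ("ax", "ay", "az", "gx", "gy", "gz"):
            ch = getattr(self, name)
            if ch is not None and len(ch) != n:
                raise ValueError(f"channel {name} length {len(ch)} != {n}")
        if n >= 2:
            dt = np.diff(np.asarray(self.t, dtype=float))
            if np.any(dt <= 0) or np.max(np.abs(dt - 1.0 / self.fs)) > 1e-9:
                raise ValueError("timestamps must increase with spacing 1/fs")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def accel(self) -> np.ndarray:
        """Accelerometer channels as a 3 x n array (ax, ay, az)."""
        return np.vstack([self.ax, self.ay, self.az])


def _stride_phase(n: int, fs: float, stride_period: float, cv: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Continuous stride phase (in strides) at each sample time.

    Stride durations are i.i.d. lognormal with mean ``stride_period`` and
    coefficient of variation ``cv``; cv = 0 gives an exactly linear phase.
    """
    t = np.arange(n) / fs
    duration = n / fs
    if cv == 0.0:
        return t / stride_period
    sigma2 = np.log1p(cv * cv)
    mu = np.log(stride_period) - 0.5 * sigma2
    # draw enough strides to cover the bout
    n_strides = int(np.ceil(duration / stride_period * (1 + 4 * cv))) + 8
    durations = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n_strides)
    while durations.sum() < duration:
        durations = np.concatenate(
            [durations, rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=8)])
    starts = np.concatenate([[0.0], np.cumsum(durations)])
    idx = np.searchsorted(starts, t, side="right") - 1
    frac = (t - starts[idx]) / durations[idx]
    return idx + frac


def _harmonic_sum(theta: np.ndarray, weights: Sequence[float],
                  phases: Sequence[float], extra_phase: float) -> np.ndarray:
    out = np.zeros_like(theta)
    for h, w in enumerate(weights):
        ph = phases[h % len(phases)]
        out += w * np.cos((h + 1) * theta + ph + extra_phase)
    return out


def generate_recording(params: GaitClassParams, duration_s: float = 30.0,
                       fs: float = 50.0,
                       subject_offset: Optional[SubjectEffects] = None,
                       seed: int = 0,
                       subject_id: str = "s000",
                       with_gyro: bool = True) -> SensorRecording:
    """Generate one synthetic walking bout.

    The waveform is a sum of harmonics of the step frequency (two steps per
    stride), phase-locked to a jittered stride clock; medio-lateral sway is
    added at the stride frequency; i.i.d. Gaussian noise on every channel.
    Fully reproducible from ``seed``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if fs <= 0:
        raise ValueError("fs must be > 0")
    eff = subject_offset or SubjectEffects()
    rng = np.random.default_rng(seed)

    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    step_rate = max(params.step_rate_hz + eff.cadence_offset_hz, 0.1)
    stride_period = 2.0 / step_rate  # two steps per stride

    phi = _stride_phase(n, fs, stride_period, params.stride_time_cv, rng)
    theta = 2.0 * np.pi * 2.0 * phi  # step-frequency angle
    w = params.harmonic_weights
    g = eff.gain

    ax = g * _harmonic_sum(theta, w, _AXIS_PHASES["ax"], eff.phase_offset)
    az = _GRAVITY + g * _harmonic_sum(theta, w, _AXIS_PHASES["az"],
                                      eff.phase_offset)
    # medio-lateral: sway at stride frequency + a weak step-locked component
    ay = g * (params.sway_amp * np.sin(2.0 * np.pi * phi + eff.phase_offset)
              + 0.25 * w[0] * np.cos(theta + 1.7 + eff.phase_offset))

    channels = {"ax": ax, "ay": ay, "az": az}
    if with_gyro:
        # phase-shifted copies of the accelerometer harmonics, own noise
        channels["gx"] = 0.5 * g * _harmonic_sum(
            theta, w, _AXIS_PHASES["ax"], eff.phase_offset + np.pi / 2)
        channels["gy"] = 0.5 * g * params.sway_amp * np.cos(
            2.0 * np.pi * phi + eff.phase_offset)
        channels["gz"] = 0.5 * g * _harmonic_sum(
            theta, w, _AXIS_PHASES["az"], eff.phase_offset + np.pi / 2)

    if params.noise_sd > 0:
        for name in list(channels):
            channels[name] = channels[name] + rng.normal(
                0.0, params.noise_sd, size=n)

    return SensorRecording(t=t, fs=fs, subject_id=subject_id,
                           label=params.label, **channels)


def generate_dataset(class_mix: Mapping[str, int], bouts_per_subject: int = 1,
                     params_by_class: Optional[Mapping[str, GaitClassParams]] = None,
                     seed: int = 0, duration_s: float = 30.0,
                     fs: float = 50.0,
                     subject_effect_scale: float = 1.0) -> List[SensorRecording]:
    """Generate ``count * bouts_per_subject`` recordings per class with
    distinct subject ids and per-subject random effects.  Deterministic under
    a fixed seed.

    ``subject_effect_scale`` scales the per-subject random effects; 0 makes
    cycles exchangeable across subjects (used by the no-information control,
    where subject-level cluster noise would otherwise dominate the AUC).
    """
    if any(c < 0 for c in class_mix.values()):
        raise ValueError("subject counts must be >= 0")
    if bouts_per_subject < 0:
        raise ValueError("bouts_per_subject must be >= 0")
    presets = dict(default_presets())
    if params_by_class:
        presets.update(params_by_class)

    recordings: List[SensorRecording] = []
    root = np.random.SeedSequence(seed)
    # iterate classes in canonical order for determinism
    for label in CLASS_LABELS:
        count = class_mix.get(label, 0)
        if count == 0:
            continue
        params = presets[label]
        for s in range(count):
            subject_id = f"{label}_s{s:03d}"
            sub_ss = root.spawn(1)[0]
            sub_rng = np.random.default_rng(sub_ss)
            sc = subject_effect_scale
            eff = SubjectEffects(
                gain=float(np.exp(sc * sub_rng.normal(0.0, 0.08))),
                cadence_offset_hz=float(sc * sub_rng.normal(0.0, 0.04)),
                phase_offset=float(sc * sub_rng.uniform(0.0, 2.0 * np.pi)),
            )
            for b in range(bouts_per_subject):
                bout_seed = int(sub_rng.integers(0, 2**31 - 1))
                recordings.append(generate_recording(
                    params, duration_s=duration_s, fs=fs,
                    subject_offset=eff, seed=bout_seed,
                    subject_id=subject_id))
    return recordings


def write_dataset_csv(recordings: Sequence[SensorRecording], out_dir) -> Path:
    """Write one CSV per recording plus a manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(recordings):
        fname = f"rec_{i:04d}.csv"
        cols = {"t": rec.t, "ax": rec.ax, "ay": rec.ay, "az": rec.az}
        for name in ("gx", "gy", "gz"):
            ch = getattr(rec, name)
            if ch is not None:
                cols[name] = ch
        pd.DataFrame(cols).to_csv(out / fname, index=False)
        rows.append({"file": fname, "subject_id": rec.subject_id,
                     "label": rec.label, "fs": rec.fs})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_dataset_csv(manifest_path) -> List[SensorRecording]:
    """Load recordings written by :func:`write_dataset_csv`."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    recordings = []
    for row in manifest.itertuples():
        df = pd.read_csv(base / row.file)
        kwargs = {}
        for name in ("gx", "gy", "gz"):
            if name in df.columns:
                kwargs[name] = df[name].to_numpy()
        recordings.append(SensorRecording(
            t=df["t"].to_numpy(), ax=df["ax"].to_numpy(),
            ay=df["ay"].to_numpy(), az=df["az"].to_numpy(),
            fs=float(row.fs), subject_id=str(row.subject_id),
            label=str(row.label), **kwargs))
    return recordings
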