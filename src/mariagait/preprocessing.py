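"""Raw recording -> validated fixed-length gait cycles.

Pipeline: zero-phase low-pass filtering, Hampel outlier removal, signal
vector magnitude (SVM1), salient-point (local-minimum) cycle segmentation,
duration gating, and normalized cross-correlation validation against a
per-recording template cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .synthetic_gait import CLASS_LABELS, SensorRecording

__all__ = [
    "GaitCycle",
    "SegmentationConfig",
    "lowpass_filter",
    "remove_outliers",
    "compute_svm1",
    "detect_salient_points",
    "segment_cycles",
    "ncc",
    "validate_cycles",
    "resample_cycle",
    "preprocess_recording",
    "save_cycles",
    "load_cycles",
]


@dataclass
class GaitCycle:
    """One segmented, NCC-validated, fixed-length triaxial window.

    ``start_idx``/``end_idx`` are 0-based half-open sample indices into the
    source recording; ``window`` is axes x resampled samples.
    """

    source_id: str
    start_idx: int
    end_idx: int
    window: np.ndarray
    ncc_score: float
    label: str

    def __post_init__(self) -> None:
        if self.end_idx <= self.start_idx:
            raise ValueError("end_idx must be > start_idx")
        self.window = np.asarray(self.window, dtype=float)
        if self.window.ndim != 2 or self.window.shape[0] != 3:
            raise ValueError("window must be a 3 x n matrix")
        if not -1.0 - 1e-9 <= self.ncc_score <= 1.0 + 1e-9:
            raise ValueError("ncc_score must lie in [-1, 1]")
        if self.label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.label!r}")


@dataclass
class SegmentationConfig:
    lowpass_cutoff_hz: float = 10.0
    filter_order: int = 4
    hampel_window: int = 11
    hampel_nsigma: float = 3.0
    min_cycle_s: float = 0.4
    max_cycle_s: float = 2.0
    ncc_threshold: float = 0.6
    resample_len: int = 500

    def __post_init__(self) -> None:
        if not 0 < self.min_cycle_s < self.max_cycle_s:
            raise ValueError("require 0 < min_cycle_s < max_cycle_s")
        if not -1.0 <= self.ncc_threshold <= 1.0:
            raise ValueError("ncc_threshold must lie in [-1, 1]")
        if self.resample_len < 2:
            raise ValueError("resample_len must be >= 2")


def lowpass_filter(x: Sequence[float], fs: float, cutoff_hz: float = 10.0,
                   order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass; unit DC gain."""
    x = np.asarray(x, dtype=float)
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, fs/2={fs / 2}) Hz")
    b, a = butter(order, cutoff_hz, btype="low", fs=fs)
    return filtfilt(b, a, x)


def remove_outliers(x: Sequence[float], window: int = 11,
                    nsigma: float = 3.0) -> np.ndarray:
    """Hampel filter: replace samples deviating from the centered rolling
    median by more than ``nsigma * 1.4826 * MAD`` with that median.

    A deviation of exactly zero is never flagged, so constant stretches
    (MAD = 0) pass through unchanged.  Edges are handled by reflecting the
    sequence so every window is full-width.
    """
    x = np.asarray(x, dtype=float)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if window > len(x):
        raise ValueError(f"window {window} larger than sequence {len(x)}")
    half = window // 2
    padded = np.pad(x, half, mode="reflect")
    windows = np.lib.stride_tricks.sliding_window_view(padded, window)
    med = np.median(windows, axis=1)
    mad = np.median(np.abs(windows - med[:, None]), axis=1)
    dev = np.abs(x - med)
    mask = dev > nsigma * 1.4826 * mad
    out = x.copy()
    out[mask] = med[mask]
    return out


def compute_svm1(ax: Sequence[float], ay: Sequence[float],
                 az: Sequence[float]) -> np.ndarray:
    """Signal vector magnitude: element-wise root-sum-of-squares."""
    ax, ay, az = (np.asarray(c, dtype=float) for c in (ax, ay, az))
    if not (len(ax) == len(ay) == len(az)):
        raise ValueError("axis sequences must have equal length")
    return np.sqrt(ax * ax + ay * ay + az * az)


def detect_salient_points(svm1: Sequence[float],
                          min_separation: int = 1) -> np.ndarray:
    """Indices of strict local minima, greedily thinned by depth.

    Minima closer than ``min_separation`` to an already-accepted (deeper)
    minimum are discarded; ties break toward the earlier index.
    """
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    x = np.asarray(svm1, dtype=float)
    if len(x) < 3:
        return np.array([], dtype=int)
    interior = np.arange(1, len(x) - 1)
    is_min = (x[interior - 1] > x[interior]) & (x[interior] < x[interior + 1])
    minima = interior[is_min]
    if len(minima) == 0:
        return minima
    # greedy accept in order of depth (value ascending, then index)
    order = np.lexsort((minima, x[minima]))
    accepted: List[int] = []
    for i in minima[order]:
        if all(abs(i - j) >= min_separation for j in accepted):
            accepted.append(int(i))
    return np.array(sorted(accepted), dtype=int)


def segment_cycles(recording: SensorRecording, salient_points: Sequence[int],
                   config: SegmentationConfig) -> List[Tuple[int, int]]:
    """Half-open candidate cycles between consecutive salient points,
    gated by the [min_cycle_s, max_cycle_s] duration window."""
    pts = np.asarray(salient_points, dtype=int)
    if len(pts) >= 2 and np.any(np.diff(pts) <= 0):
        raise ValueError("salient points must be ascending")
    fs = recording.fs
    out = []
    for a, b in zip(pts[:-1], pts[1:]):
        dur = (b - a) / fs
        if config.min_cycle_s <= dur <= config.max_cycle_s:
            out.append((int(a), int(b)))
    return out


def ncc(template: Sequence[float], candidate: Sequence[float]) -> float:
    """Pearson-type normalized cross-correlation in [-1, 1]."""
    t = np.asarray(template, dtype=float)
    c = np.asarray(candidate, dtype=float)
    if len(t) != len(c):
        raise ValueError("template and candidate must have equal length")
    t = t - t.mean()
    c = c - c.mean()
    nt, nc = np.linalg.norm(t), np.linalg.norm(c)
    if nt == 0 or nc == 0:
        raise ValueError("ncc undefined for constant input (zero norm)")
    return float(np.clip(np.dot(t, c) / (nt * nc), -1.0, 1.0))


def resample_cycle(window: np.ndarray, target_len: int) -> np.ndarray:
    """Per-axis linear interpolation onto ``target_len`` equally spaced
    points spanning the original support; endpoints preserved exactly."""
    window = np.asarray(window, dtype=float)
    if window.ndim == 1:
        window = window[None, :]
    m = window.shape[1]
    if m < 2:
        raise ValueError("cycle must contain at least 2 samples")
    if target_len < 2:
        raise ValueError("target_len must be >= 2")
    if target_len == m:
        return window.copy()
    old = np.linspace(0.0, 1.0, m)
    new = np.linspace(0.0, 1.0, target_len)
    return np.vstack([np.interp(new, old, row) for row in window])


def _resample_1d(x: np.ndarray, target_len: int) -> np.ndarray:
    return resample_cycle(x[None, :], target_len)[0]


def validate_cycles(recording: SensorRecording,
                    candidates: Sequence[Tuple[int, int]],
                    config: SegmentationConfig,
                    svm1: Optional[np.ndarray] = None,
                    axes: Optional[np.ndarray] = None) -> List[GaitCycle]:
    """Score candidates against the per-recording template and keep those
    with NCC >= threshold.

    The template is the SVM1 profile of the median-duration candidate,
    resampled to ``resample_len``; every candidate is resampled likewise
    before scoring.  ``svm1``/``axes`` default to the raw recording channels
    (pass preprocessed versions from :func:`preprocess_recording`).
    """
    if len(candidates) == 0:
        raise ValueError("validate_cycles requires at least one candidate")
    if axes is None:
        axes = recording.accel()
    if svm1 is None:
        svm1 = compute_svm1(*axes)

    durations = np.array([b - a for a, b in candidates])
    med = np.median(durations)
    template_i = int(np.argmin(np.abs(durations - med)))  # tie -> earlier
    a0, b0 = candidates[template_i]
    template = _resample_1d(svm1[a0:b0], config.resample_len)

    kept: List[GaitCycle] = []
    for a, b in candidates:
        seg = _resample_1d(svm1[a:b], config.resample_len)
        if np.ptp(seg) == 0 or np.ptp(template) == 0:
            continue  # constant segment: NCC undefined, drop
        score = ncc(template, seg)
        if score >= config.ncc_threshold:
            kept.append(GaitCycle(
                source_id=recording.subject_id, start_idx=a, end_idx=b,
                window=resample_cycle(axes[:, a:b], config.resample_len),
                ncc_score=score, label=recording.label))
    return kept


def preprocess_recording(recording: SensorRecording,
                         config: Optional[SegmentationConfig] = None
                         ) -> List[GaitCycle]:
    """Full per-recording chain: Hampel -> low-pass -> SVM1 -> salient
    points -> duration gate -> NCC validation."""
    config = config or SegmentationConfig()
    axes = recording.accel()
    clean = np.vstack([
        lowpass_filter(
            remove_outliers(row, config.hampel_window, config.hampel_nsigma),
            recording.fs, config.lowpass_cutoff_hz, config.filter_order)
        for row in axes])
    svm1 = compute_svm1(*clean)
    min_sep = max(1, int(round(config.min_cycle_s * recording.fs)))
    pts = detect_salient_points(svm1, min_separation=min_sep)
    candidates = segment_cycles(recording, pts, config)
    if not candidates:
        return []
    return validate_cycles(recording, candidates, config, svm1=svm1,
                           axes=clean)


# ---------------------------------------------------------------------------
# HDF5 container I/O

def save_cycles(path, cycles: Sequence[GaitCycle],
                config: Optional[SegmentationConfig] = None) -> None:
    import h5py
    import json

    cycles = list(cycles)
    with h5py.File(path, "w") as f:
        n = len(cycles)
        res = cycles[0].window.shape[1] if n else 0
        f.create_dataset("windows", data=np.stack(
            [c.window for c in cycles]) if n else np.zeros((0, 3, res)))
        f.create_dataset("ncc_scores",
                         data=np.array([c.ncc_score for c in cycles]))
        f.create_dataset("start_idx",
                         data=np.array([c.start_idx for c in cycles], dtype=np.int64))
        f.create_dataset("end_idx",
                         data=np.array([c.end_idx for c in cycles], dtype=np.int64))
        str_dt = h5py.string_dtype()
        f.create_dataset("labels", data=[c.label for c in cycles], dtype=str_dt)
        f.create_dataset("subject_ids", data=[c.source_id for c in cycles],
                         dtype=str_dt)
        if config is not None:
            f.attrs["config"] = json.dumps(asdict(config))


def load_cycles(path) -> List[GaitCycle]:
    import h5py

    out: List[GaitCycle] = []
    with h5py.File(path, "r") as f:
        windows = f["windows"][...]
        scores = f["ncc_scores"][...]
        starts = f["start_idx"][...]
        ends = f["end_idx"][...]
        labels = [s.decode() if isinstance(s, bytes) else s
                  for s in f["labels"][...]]
        subjects = [s.decode() if isinstance(s, bytes) else s
                    for s in f["subject_ids"][...]]
    for i in range(len(scores)):
        out.append(GaitCycle(source_id=subjects[i], start_idx=int(starts[i]),
                             end_idx=int(ends[i]), window=windows[i],
                             ncc_score=float(scores[i]), label=labels[i]))
    return out


def cycles_report(cycles: Sequence[GaitCycle]) -> pd.DataFrame:
    """Cycle-level summary table (one row per emitted cycle)."""
    return pd.DataFrame({
        "subject_id": [c.source_id for c in cycles],
        "label": [c.label for c in cycles],
        "start_idx": [c.start_idx for c in cycles],
        "end_idx": [c.end_idx for c in cycles],
        "ncc_score": [c.ncc_score for c in cycles],
    })
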