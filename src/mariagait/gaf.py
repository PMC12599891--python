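"""Gramian Angular Field encoding of fixed-length triaxial gait cycles.

Each axis of a cycle window is min-max rescaled to [-1, 1], mapped to angles
phi = arccos(x), and imaged as the summation field G[i, j] = cos(phi_i +
phi_j) (GASF; the difference field GADF is available behind a flag).
Channels are stacked in a fixed axis order, giving an n x n x 3 tensor per
cycle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .preprocessing import GaitCycle

__all__ = [
    "GAFImage",
    "rescale_unit",
    "gasf_encode",
    "gadf_encode",
    "paa",
    "encode_cycle",
    "encode_cycles",
    "save_gaf",
    "load_gaf",
    "export_png",
]

logger = logging.getLogger(__name__)

AXIS_NAMES: Tuple[str, str, str] = ("x", "y", "z")


@dataclass
class GAFImage:
    """An n x n x C tensor of pairwise angular sums, one channel per axis."""

    pixels: np.ndarray
    channel_axes: Tuple[str, ...]
    source_cycle_id: str
    label: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be n x n x C")
        n, n2, c = self.pixels.shape
        if n != n2:
            raise ValueError("pixels must be square per channel")
        if c != len(self.channel_axes):
            raise ValueError("channel_axes must name every channel")

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


def rescale_unit(x: Sequence[float]) -> np.ndarray:
    """Min-max rescale to [-1, 1]; rejects constant (degenerate) input."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise ValueError("degenerate cycle: constant sequence cannot be rescaled")
    return 2.0 * (x - lo) / (hi - lo) - 1.0


def _check_unit(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > 1.0 + 1e-12):
        raise ValueError("rescaled values must lie in [-1, 1]")
    return np.clip(x, -1.0, 1.0)


def gasf_encode(x: Sequence[float]) -> np.ndarray:
    """Gramian Angular Summation Field: G[i,j] = cos(phi_i + phi_j) with
    phi = arccos(x), computed in the algebraic form
    x_i x_j - sqrt(1-x_i^2) sqrt(1-x_j^2)."""
    x = _check_unit(x)
    s = np.sqrt(1.0 - x * x)
    return np.outer(x, x) - np.outer(s, s)


def gadf_encode(x: Sequence[float]) -> np.ndarray:
    """Gramian Angular Difference Field: G[i,j] = sin(phi_i - phi_j)."""
    x = _check_unit(x)
    s = np.sqrt(1.0 - x * x)
    return np.outer(s, x) - np.outer(x, s)


def paa(x: Sequence[float], out_len: int) -> np.ndarray:
    """Piecewise aggregate approximation: mean over out_len equal chunks."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if out_len < 1 or out_len > n:
        raise ValueError("out_len must lie in [1, len(x)]")
    edges = np.linspace(0, n, out_len + 1)
    return np.array([x[int(edges[i]):max(int(edges[i]) + 1,
                                         int(edges[i + 1]))].mean()
                     for i in range(out_len)])


def encode_cycle(cycle: GaitCycle, paa_len: Optional[int] = None,
                 method: str = "gasf") -> GAFImage:
    """Encode one cycle: optional PAA downsampling, per-axis rescale, then
    angular-field encoding; channels stacked in fixed axis order."""
    if method not in ("gasf", "gadf"):
        raise ValueError("method must be 'gasf' or 'gadf'")
    encode = gasf_encode if method == "gasf" else gadf_encode
    rows = cycle.window
    if paa_len is not None:
        rows = np.vstack([paa(row, paa_len) for row in rows])
    channels = [encode(rescale_unit(row)) for row in rows]
    cycle_id = f"{cycle.source_id}:{cycle.start_idx}-{cycle.end_idx}"
    return GAFImage(pixels=np.stack(channels, axis=-1),
                    channel_axes=AXIS_NAMES[:len(channels)],
                    source_cycle_id=cycle_id, label=cycle.label)


def encode_cycles(cycles: Sequence[GaitCycle], paa_len: Optional[int] = None,
                  method: str = "gasf") -> List[GAFImage]:
    """Batch encoding; cycles with a constant axis are skipped with a
    warning rather than aborting the batch."""
    images: List[GAFImage] = []
    for cycle in cycles:
        try:
            images.append(encode_cycle(cycle, paa_len=paa_len, method=method))
        except ValueError as exc:
            logger.warning("skipping cycle %s:%d-%d: %s", cycle.source_id,
                           cycle.start_idx, cycle.end_idx, exc)
    return images


# ---------------------------------------------------------------------------
# I/O

def save_gaf(path, images: Sequence[GAFImage]) -> None:
    import h5py

    images = list(images)
    with h5py.File(path, "w") as f:
        if images:
            f.create_dataset("gaf", data=np.stack([im.pixels for im in images]))
        else:
            f.create_dataset("gaf", data=np.zeros((0, 0, 0, 0)))
        str_dt = h5py.string_dtype()
        f.create_dataset("labels", data=[im.label for im in images], dtype=str_dt)
        f.create_dataset("cycle_ids", data=[im.source_cycle_id for im in images],
                         dtype=str_dt)
        f.attrs["channel_axes"] = json.dumps(
            list(images[0].channel_axes) if images else [])


def load_gaf(path) -> List[GAFImage]:
    import h5py

    with h5py.File(path, "r") as f:
        pixels = f["gaf"][...]
        labels = [s.decode() if isinstance(s, bytes) else s
                  for s in f["labels"][...]]
        ids = [s.decode() if isinstance(s, bytes) else s
               for s in f["cycle_ids"][...]]
        axes = tuple(json.loads(f.attrs.get("channel_axes", "[]")))
    return [GAFImage(pixels=pixels[i], channel_axes=axes,
                     source_cycle_id=ids[i], label=labels[i])
            for i in range(len(labels))]


def export_png(image: GAFImage, path) -> None:
    """Quantize [-1, 1] -> [0, 255] per channel for visualization only."""
    from PIL import Image

    arr = np.clip((image.pixels + 1.0) * 127.5, 0, 255).astype(np.uint8)
    if arr.shape[2] == 1:
        arr = arr[:, :, 0]
    elif arr.shape[2] == 2:
        arr = np.dstack([arr, np.zeros(arr.shape[:2], dtype=np.uint8)])
    Image.fromarray(arr).save(Path(path))


def subject_of(image: GAFImage) -> str:
    """Subject id parsed back out of the cycle id."""
    return image.source_cycle_id.split(":", 1)[0]
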