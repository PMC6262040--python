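"""Calibrated time-lapse stacks and their on-disk representation.

A :class:`TimeLapseStack` holds the frames of one cultivation chamber
together with the frame timestamps (hours) and the pixel calibration
(micrometres per pixel).  Stacks are written as multi-page TIFF with a
plain-text ``key = value`` sidecar carrying the calibration, which keeps
the image files readable by any TIFF consumer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class TimeLapseStack:
    """Frames + timestamps + calibration for one chamber.

    ``frames`` is a (T, H, W) float or integer array; ``clean_masks`` is an
    optional (T, H, W) boolean array carrying the noise-free foreground of a
    synthetic render (absent for real data).
    """

    frames: np.ndarray
    timestamps_h: np.ndarray
    pixel_size_um: float
    stack_id: str = "stack"
    clean_masks: np.ndarray | None = None
    qc_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps_h = np.asarray(self.timestamps_h, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if len(self.timestamps_h) != self.frames.shape[0]:
            raise ValueError("one timestamp per frame required")
        if np.any(np.diff(self.timestamps_h) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def write_stack(stack: TimeLapseStack, tiff_path: str | Path) -> None:
    """Write frames as multi-page TIFF plus a ``.meta.txt`` sidecar."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, np.asarray(stack.frames))
    meta = tiff_path.with_suffix(tiff_path.suffix + ".meta.txt")
    lines = [
        f"stack_id = {stack.stack_id}",
        f"pixel_size_um = {stack.pixel_size_um!r}",
        "timestamps_h = " + ",".join(repr(float(t)) for t in stack.timestamps_h),
        "qc_flags = " + ";".join(stack.qc_flags),
    ]
    meta.write_text("\n".join(lines) + "\n")


def read_stack(tiff_path: str | Path) -> TimeLapseStack:
    """Read a stack written by :func:`write_stack`."""
    tiff_path = Path(tiff_path)
    frames = tifffile.imread(tiff_path)
    if frames.ndim == 2:  # single-page stack
        frames = frames[None]
    meta = tiff_path.with_suffix(tiff_path.suffix + ".meta.txt")
    kv: dict[str, str] = {}
    for line in meta.read_text().splitlines():
        if "=" in line:
            k, _, v = line.partition("=")
            kv[k.strip()] = v.strip()
    timestamps = np.array([float(x) for x in kv["timestamps_h"].split(",") if x])
    flags = [f for f in kv.get("qc_flags", "").split(";") if f]
    return TimeLapseStack(
        frames=frames,
        timestamps_h=timestamps,
        pixel_size_um=float(kv["pixel_size_um"]),
        stack_id=kv.get("stack_id", tiff_path.stem),
        qc_flags=flags,
    )
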