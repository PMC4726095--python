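"""Image stack container and TIFF I/O.

An :class:`ImageStack` is the carrier used by every pipeline stage: an ordered
set of 2D grayscale frames plus the acquisition metadata (pixel pitch in
micrometres per pixel and frame interval in seconds) needed to convert
pixel/frame displacements into physical velocities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """Ordered 2D intensity frames with acquisition metadata.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, height, width)
        Intensity frames. Any real dtype; processing stages promote to float.
    pixel_pitch : float
        Physical size of one pixel, micrometres per pixel.
    frame_interval : float
        Time between consecutive frames, seconds.
    meta : dict
        Free-form provenance (config hash, seed, stage log).
    """

    frames: np.ndarray
    pixel_pitch: float
    frame_interval: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (n, h, w), got shape {self.frames.shape}")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def frame_rate(self) -> float:
        """Acquisition frame rate in frames per second."""
        return 1.0 / self.frame_interval

    def copy_with(self, frames: np.ndarray, **meta_updates) -> "ImageStack":
        """New stack sharing metadata, with replaced frames."""
        meta = dict(self.meta)
        meta.update(meta_updates)
        return ImageStack(frames, self.pixel_pitch, self.frame_interval, meta)

    # ------------------------------------------------------------------ I/O
    def save_tiff(self, path: str | Path) -> None:
        """Write a multi-page TIFF plus a JSON metadata sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.frames, photometric="minisblack")
        sidecar = {
            "pixel_pitch_um": self.pixel_pitch,
            "frame_interval_s": self.frame_interval,
            "meta": _jsonable(self.meta),
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True)
        )

    @classmethod
    def from_tiff(
        cls,
        path: str | Path,
        pixel_pitch: float | None = None,
        frame_rate: float | None = None,
    ) -> "ImageStack":
        """Read a multi-page TIFF; metadata from the sidecar unless overridden."""
        path = Path(path)
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        sidecar = path.with_suffix(path.suffix + ".json")
        meta: dict = {}
        pitch, interval = pixel_pitch, None
        if frame_rate is not None:
            interval = 1.0 / frame_rate
        if sidecar.exists():
            info = json.loads(sidecar.read_text())
            pitch = pitch if pitch is not None else info.get("pixel_pitch_um")
            if interval is None:
                interval = info.get("frame_interval_s")
            meta = info.get("meta", {})
        if pitch is None or interval is None:
            raise ValueError(
                "pixel_pitch and frame_rate must be given (no sidecar metadata found)"
            )
        return cls(frames, pitch, interval, meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
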