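"""Frame-sequence I/O and the tank-layout coordinate model.

Coordinate conventions used throughout the package:

* pixel coordinates are 0-based, ``x`` rightward and ``y`` downward, with
  the origin at the top-left corner of the frame;
* tank ROIs are axis-aligned rectangles over half-open pixel intervals
  ``[x_min, x_max) x [y_min, y_max)``;
* calibrated trajectory coordinates are centimetres relative to the
  top-left corner of the fish's own tank ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from . import avi
from .errors import ConfigError, EmptyInputError, FormatError

__all__ = [
    "FrameSequence",
    "TankROI",
    "TankLayout",
    "read_frames",
    "write_frames",
    "to_grayscale",
]

# ITU-R BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert an (h, w) or (h, w, 3) uint8 frame to (h, w) uint8 luma."""
    frame = np.asarray(frame)
    if frame.ndim == 2:
        return frame.astype(np.uint8, copy=False)
    if frame.ndim == 3 and frame.shape[2] in (3, 4):
        luma = frame[:, :, :3].astype(np.float64) @ _LUMA
        return np.round(luma).astype(np.uint8)
    raise FormatError(f"cannot interpret array of shape {frame.shape} as a frame")


@dataclass
class FrameSequence:
    """Ordered 8-bit grayscale frames with a frame rate.

    ``frames`` is a (n_frames, height, width) uint8 array.
    """

    frames: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (n, h, w) array")
        if self.frames.dtype != np.uint8:
            if self.frames.min() < 0 or self.frames.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            self.frames = self.frames.astype(np.uint8)
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self):
        return iter(self.frames)


@dataclass(frozen=True)
class TankROI:
    """One tank's rectangle, half-open pixel intervals."""

    tank_id: int
    x_min: int
    y_min: int
    x_max: int
    y_max: int
    expected_fish: int = 1

    def __post_init__(self) -> None:
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ConfigError(f"tank {self.tank_id}: empty ROI")
        if self.expected_fish < 1:
            raise ConfigError(f"tank {self.tank_id}: expected_fish must be >= 1")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def area(self) -> int:
        return self.width * self.height

    def slices(self) -> tuple[slice, slice]:
        """(row, col) slices selecting this ROI from a frame."""
        return slice(self.y_min, self.y_max), slice(self.x_min, self.x_max)

    def overlaps(self, other: "TankROI") -> bool:
        return not (
            self.x_max <= other.x_min
            or other.x_max <= self.x_min
            or self.y_max <= other.y_min
            or other.y_max <= self.y_min
        )


@dataclass
class TankLayout:
    """The tank grid inside the camera frame plus the pixel calibration."""

    tanks: list[TankROI] = field(default_factory=list)
    px_per_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0:
            raise ConfigError("px_per_cm must be positive")
        ids = [t.tank_id for t in self.tanks]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate tank ids in layout")
        for i, a in enumerate(self.tanks):
            for b in self.tanks[i + 1:]:
                if a.overlaps(b):
                    raise ConfigError(
                        f"tank ROIs {a.tank_id} and {b.tank_id} overlap"
                    )

    def validate_bounds(self, width: int, height: int) -> None:
        for t in self.tanks:
            if t.x_min < 0 or t.y_min < 0 or t.x_max > width or t.y_max > height:
                raise ConfigError(
                    f"tank {t.tank_id} ROI exceeds frame bounds {width}x{height}"
                )

    def tank(self, tank_id: int) -> TankROI:
        for t in self.tanks:
            if t.tank_id == tank_id:
                return t
        raise ConfigError(f"no tank with id {tank_id}")


def _read_stack_dir(path: Path) -> np.ndarray:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".png")
    if not files:
        raise EmptyInputError(f"no PNG frames found in directory {path}")
    return np.stack([iio.imread(p) for p in files])


def read_frames(
    path: str | Path,
    as_grayscale: bool = True,
    fps: float | None = None,
) -> FrameSequence:
    """Read a video file or image stack into a :class:`FrameSequence`.

    Supported inputs: uncompressed AVI, multi-page TIFF, or a directory of
    lexicographically ordered PNG frames. TIFF/PNG stacks carry no frame
    rate, so ``fps`` must be supplied for them; for AVI it is read from the
    container (an explicit ``fps`` overrides it).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")

    if path.is_dir():
        raw = _read_stack_dir(path)
        container_fps = None
    elif path.suffix.lower() == ".avi":
        raw, container_fps = avi.read_avi(path)
    elif path.suffix.lower() in (".tif", ".tiff"):
        try:
            raw = tifffile.imread(path)
        except Exception as exc:  # tifffile raises assorted types
            raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
        if raw.ndim == 2:
            raw = raw[None]
        container_fps = None
    elif path.suffix.lower() == ".png":
        raw = iio.imread(path)[None]
        container_fps = None
    else:
        raise FormatError(f"unsupported video format: {path}")

    if raw.shape[0] == 0:
        raise EmptyInputError(f"zero frames in {path}")

    effective_fps = fps if fps is not None else container_fps
    if effective_fps is None:
        raise ConfigError(
            f"{path} carries no frame-rate metadata; pass fps explicitly"
        )

    if raw.ndim == 4:
        if as_grayscale:
            raw = np.stack([to_grayscale(f) for f in raw])
        else:
            raise FormatError("RGB output is not supported; pass as_grayscale=True")
    return FrameSequence(frames=raw, fps=float(effective_fps))


def write_frames(seq: FrameSequence, path: str | Path) -> None:
    """Write a frame sequence losslessly; format chosen by extension.

    ``.avi`` writes an uncompressed 8-bit AVI carrying ``seq.fps`` in its
    header; ``.tif``/``.tiff`` writes a multi-page TIFF; a path with no
    extension is treated as a directory of PNG frames.
    """
    if seq.n_frames == 0:
        raise EmptyInputError("refusing to write an empty frame sequence")
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".avi":
        avi.write_avi(path, seq.frames, seq.fps)
    elif suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, seq.frames, photometric="minisblack")
    elif suffix == "":
        path.mkdir(parents=True, exist_ok=True)
        digits = max(len(str(seq.n_frames - 1)), 4)
        for i, frame in enumerate(seq.frames):
            iio.imwrite(path / f"frame_{i:0{digits}d}.png", frame)
    else:
        raise FormatError(f"unsupported output format: {path}")
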