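"""Frame ingestion: decode video or still-image input, crop the informative
region of each frame, and tile frames into fixed-size sliding windows.

The sliding window (227×227 RGB by default) is the unit every downstream
stage — texture features, CNN features, classification — operates on.
Coordinates are 0-based ``(x, y) = (column, row)``; rectangles are half-open
``[x0, x0 + w) × [y0, y0 + h)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import avi
from .exceptions import BoundsError, DecodeError, EmptyInputError, TooSmallError

WINDOW_SIZE = 227
DEFAULT_STRIDE = 32

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}
_VIDEO_SUFFIXES = {".avi", ".mp4", ".wmv"}


@dataclass(frozen=True)
class Frame:
    """One decoded video image after ROI cropping."""

    index: int
    pixels: np.ndarray  # H x W x 3, uint8
    roi: tuple[int, int, int, int] = field(default=None)  # (x0, y0, w, h) in the decoded image

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"frame pixels must be H x W x 3, got {px.shape}")
        if self.roi is None:
            object.__setattr__(self, "roi", (0, 0, px.shape[1], px.shape[0]))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class Window:
    """A window-size RGB sub-image with its origin in the parent frame."""

    pixels: np.ndarray  # size x size x 3, uint8
    origin: tuple[int, int]  # (x, y) of the top-left corner
    frame_index: int = 0

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[0] != px.shape[1] or px.shape[2] != 3:
            raise ValueError(f"window pixels must be square S x S x 3, got {px.shape}")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    @property
    def center(self) -> tuple[float, float]:
        x, y = self.origin
        return (x + self.size / 2.0, y + self.size / 2.0)


def _read_image_dir(path: Path) -> list[np.ndarray]:
    import imageio.v3 as iio

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
    if not files:
        raise EmptyInputError(f"no decodable images found in {path}")
    images = []
    for p in files:
        try:
            img = iio.imread(p)
        except Exception as exc:
            raise DecodeError(f"cannot decode image {p}: {exc}") from exc
        img = np.asarray(img)
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        images.append(np.ascontiguousarray(img[:, :, :3], dtype=np.uint8))
    return images


def _read_video(path: Path) -> list[np.ndarray]:
    if path.suffix.lower() == ".avi":
        return avi.read_avi(path)
    try:
        import imageio.v3 as iio

        return [np.ascontiguousarray(np.asarray(f)[:, :, :3], dtype=np.uint8) for f in iio.imiter(path)]
    except (EmptyInputError, DecodeError):
        raise
    except Exception as exc:
        raise DecodeError(f"cannot decode video container {path}: {exc}") from exc


def read_frames(source, kind: str | None = None) -> list[Frame]:
    """Decode ``source`` into an ordered list of :class:`Frame`.

    Parameters
    ----------
    source:
        Path to an AVI/MP4/WMV video file or a directory of still images
        (read in lexicographic order).
    kind:
        ``"video"`` or ``"image_dir"``; inferred from the path when omitted.
    """
    path = Path(source)
    if not path.exists():
        raise DecodeError(f"input path does not exist: {path}")
    if kind is None:
        kind = "image_dir" if path.is_dir() else "video"
    if kind == "image_dir":
        images = _read_image_dir(path)
    elif kind == "video":
        if path.suffix.lower() not in _VIDEO_SUFFIXES:
            raise DecodeError(f"unsupported video container {path} (expected AVI, MP4 or WMV)")
        images = _read_video(path)
    else:
        raise ValueError(f"kind must be 'video' or 'image_dir', got {kind!r}")
    if not images:
        raise EmptyInputError(f"no frames decoded from {path}")
    return [Frame(index=i, pixels=img) for i, img in enumerate(images)]


def _auto_roi(pixels: np.ndarray, darkness_threshold: float) -> tuple[int, int, int, int]:
    """Trim contiguous border rows/columns darker than the threshold."""
    gray = pixels.mean(axis=2)
    h, w = gray.shape
    row_mean = gray.mean(axis=1)
    col_mean = gray.mean(axis=0)

    def trim(means: np.ndarray) -> tuple[int, int]:
        lo, hi = 0, len(means)
        while lo < hi and means[lo] < darkness_threshold:
            lo += 1
        while hi > lo and means[hi - 1] < darkness_threshold:
            hi -= 1
        return lo, hi

    y0, y1 = trim(row_mean)
    x0, x1 = trim(col_mean)
    if y1 <= y0 or x1 <= x0:
        raise TooSmallError("auto ROI removed the entire frame (all rows/columns below darkness threshold)")
    return (x0, y0, x1 - x0, y1 - y0)


def crop_roi(frame: Frame, roi="auto", darkness_threshold: float = 10.0, min_size: int = WINDOW_SIZE) -> Frame:
    """Crop a frame to its informative region.

    ``roi`` is an explicit ``(x0, y0, w, h)`` rectangle or ``"auto"``, which
    strips border rows/columns whose mean intensity falls below
    ``darkness_threshold`` (out of 255) — the typical black letterbox around
    an endoscope's circular image.
    """
    if roi == "auto":
        roi = _auto_roi(frame.pixels, darkness_threshold)
    x0, y0, w, h = (int(v) for v in roi)
    if x0 < 0 or y0 < 0 or w <= 0 or h <= 0 or x0 + w > frame.width or y0 + h > frame.height:
        raise BoundsError(f"roi {roi} lies outside the {frame.width}x{frame.height} frame")
    if w < min_size or h < min_size:
        raise TooSmallError(f"cropped frame {w}x{h} is smaller than the window size {min_size}")
    return Frame(index=frame.index, pixels=frame.pixels[y0 : y0 + h, x0 : x0 + w], roi=(x0, y0, w, h))


def _axis_origins(extent: int, size: int, stride: int) -> list[int]:
    origins = list(range(0, extent - size + 1, stride))
    if origins[-1] != extent - size:  # clamp the final window to the frame edge
        origins.append(extent - size)
    return origins


def generate_windows(frame: Frame, size: int = WINDOW_SIZE, stride: int = DEFAULT_STRIDE) -> list[Window]:
    """Tile a frame into size×size windows, row-major (left→right, top→bottom).

    The final window along each axis is clamped so its far edge coincides
    with the frame edge, guaranteeing full coverage without out-of-bounds
    reads; consequently the last step may be smaller than ``stride``.
    """
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    if frame.height < size or frame.width < size:
        raise TooSmallError(f"frame {frame.width}x{frame.height} is smaller than the window size {size}")
    xs = _axis_origins(frame.width, size, stride)
    ys = _axis_origins(frame.height, size, stride)
    return [
        Window(pixels=frame.pixels[y : y + size, x : x + size], origin=(x, y), frame_index=frame.index)
        for y in ys
        for x in xs
    ]
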