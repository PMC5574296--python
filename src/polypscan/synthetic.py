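"""Seeded synthetic endoscopy-like fixtures.

Real colonoscopy footage cannot ship with the package, so every stage is
exercised on generated imagery that mimics the two properties the pipeline
actually measures: a smooth, red-dominant mucosa-like background (a
low-frequency random field plus pixel noise) and elliptical "polyp" regions
carrying band-pass texture — locally rough structure that separates them
from the background in exactly the way wavelet-detail statistics can see.
Roughly half of the nonpolyp windows receive a smooth brightness blob so
that mean intensity alone does not separate the classes.

Everything is a pure function of an integer seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from . import avi
from .exceptions import BoundsError, EmptyInputError
from .frames import WINDOW_SIZE, Frame, Window


@dataclass(frozen=True)
class Ellipse:
    """Ground-truth polyp region: center (cx, cy), semi-axes (a, b), rotation."""

    cx: float
    cy: float
    a: float
    b: float
    theta: float = 0.0

    def contains(self, x: float, y: float) -> bool:
        dx, dy = x - self.cx, y - self.cy
        ct, st = math.cos(self.theta), math.sin(self.theta)
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        return (u / self.a) ** 2 + (v / self.b) ** 2 <= 1.0

    def mask(self, h: int, w: int, soft_edge: float = 4.0) -> np.ndarray:
        """Soft membership in [0, 1] over an h×w grid."""
        yy, xx = np.mgrid[0:h, 0:w]
        dx, dy = xx - self.cx, yy - self.cy
        ct, st = math.cos(self.theta), math.sin(self.theta)
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        r = np.sqrt((u / self.a) ** 2 + (v / self.b) ** 2)
        scale = soft_edge / min(self.a, self.b)
        return np.clip((1.0 - r) / max(scale, 1e-6), 0.0, 1.0)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic frame.

    The defaults define the package's standard study conditions; the
    ``polyp_texture_amplitude`` is the difficulty knob (smaller = harder).
    """

    height: int = 360
    width: int = 360
    base_color: tuple = (172.0, 82.0, 64.0)  # red-dominant mucosa palette
    smooth_sigma: float = 30.0  # px, scale of the background field
    background_amplitude: float = 18.0  # gray levels
    noise_std: float = 6.0  # per-pixel gaussian noise, gray levels
    ellipse: Ellipse | None = None
    polyp_texture_amplitude: float = 20.0  # gray levels of band-pass texture
    polyp_texture_scale: float = 1.5  # px, inner scale of the band-pass
    polyp_color_shift: tuple = (10.0, 4.0, 2.0)
    distractor_texture_scale: float = 4.0  # px, coarse mucosal-fold texture
    polyp_amplitude_jitter: tuple = (0.5, 1.4)  # per-window multiplier range
    offcenter_fraction: float = 0.4  # nonpolyp windows with a margin polyp
    fold_fraction: float = 0.3  # nonpolyp windows with a coarse textured fold
    seed: int = 0


def _bandpass(h: int, w: int, rng: np.random.Generator, scale: float) -> np.ndarray:
    """Unit-variance band-pass noise (difference of gaussians)."""
    n = rng.standard_normal((h, w))
    t = gaussian_filter(n, scale) - gaussian_filter(n, 2.5 * scale)
    return t / max(t.std(), 1e-9)


def _background(h: int, w: int, rng: np.random.Generator, spec: FixtureSpec) -> np.ndarray:
    field = gaussian_filter(rng.standard_normal((h, w)), spec.smooth_sigma)
    field /= max(field.std(), 1e-9)
    img = np.empty((h, w, 3), dtype=np.float64)
    for k, (base, weight) in enumerate(zip(spec.base_color, (1.0, 0.6, 0.5))):
        img[:, :, k] = base + spec.background_amplitude * weight * field
    img += rng.normal(0.0, spec.noise_std, size=(h, w, 3))
    return img


def _paint_polyp(img: np.ndarray, ellipse: Ellipse, rng: np.random.Generator, spec: FixtureSpec) -> None:
    h, w = img.shape[:2]
    mask = ellipse.mask(h, w)
    texture = _bandpass(h, w, rng, spec.polyp_texture_scale)
    bump = mask * spec.polyp_texture_amplitude * texture
    for k, shift in enumerate(spec.polyp_color_shift):
        img[:, :, k] += bump + mask * shift


def make_frame(spec: FixtureSpec, index: int = 0) -> tuple[Frame, Ellipse | None]:
    """One synthetic frame and its ground-truth ellipse (None if no polyp)."""
    if spec.ellipse is not None:
        e = spec.ellipse
        if not (0 <= e.cx - e.a and e.cx + e.a < spec.width and 0 <= e.cy - e.b and e.cy + e.b < spec.height):
            raise BoundsError(f"polyp ellipse {e} extends outside the {spec.width}x{spec.height} frame")
    rng = np.random.default_rng(spec.seed)
    img = _background(spec.height, spec.width, rng, spec)
    if spec.ellipse is not None:
        _paint_polyp(img, spec.ellipse, rng, spec)
    pixels = np.clip(img, 0, 255).astype(np.uint8)
    return Frame(index=index, pixels=pixels), spec.ellipse


@dataclass(frozen=True)
class LabelledWindowSet:
    """Window-level training data with ground truth."""

    windows: tuple  # of Window
    labels: np.ndarray  # 0 = nonpolyp, 1 = polyp
    ellipses: tuple  # per-window Ellipse or None, in window coordinates

    def __len__(self) -> int:
        return len(self.windows)

    def pixel_array(self) -> np.ndarray:
        return np.stack([w.pixels for w in self.windows])


def _polyp_window_spec(rng: np.random.Generator, spec: FixtureSpec, size: int) -> FixtureSpec:
    # axes ≤ 80 and jitter ≤ 12 keep the ellipse inside a 227 px window and
    # the window center inside the ellipse (labelling rule)
    a = rng.uniform(45.0, 80.0)
    b = rng.uniform(45.0, 80.0)
    cx = size / 2 + rng.uniform(-12.0, 12.0)
    cy = size / 2 + rng.uniform(-12.0, 12.0)
    theta = rng.uniform(0.0, math.pi)
    return replace(
        spec,
        height=size,
        width=size,
        ellipse=Ellipse(cx=cx, cy=cy, a=a, b=b, theta=theta),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def _offcenter_window_spec(rng: np.random.Generator, spec: FixtureSpec, size: int) -> FixtureSpec:
    # a margin polyp: fully textured ellipse whose interior misses the
    # window center, so the center-based labelling rule calls it nonpolyp
    a = rng.uniform(28.0, 45.0)
    b = rng.uniform(28.0, 45.0)
    sx, sy = rng.choice([-1.0, 1.0]), rng.choice([-1.0, 1.0])
    cx = size / 2 + sx * rng.uniform(55.0, 65.0)
    cy = size / 2 + sy * rng.uniform(55.0, 65.0)
    theta = rng.uniform(0.0, math.pi)
    return replace(spec, height=size, width=size, ellipse=Ellipse(cx=cx, cy=cy, a=a, b=b, theta=theta), seed=int(rng.integers(0, 2**31 - 1)))


def _add_fold(pixels: np.ndarray, seed: int, spec: FixtureSpec, size: int) -> np.ndarray:
    """Coarse-scale textured fold: same brightness shift as a polyp but
    band-pass texture at a coarser spatial scale."""
    fold_rng = np.random.default_rng(seed)
    blob = Ellipse(
        cx=size / 2 + fold_rng.uniform(-15, 15),
        cy=size / 2 + fold_rng.uniform(-15, 15),
        a=fold_rng.uniform(45, 80),
        b=fold_rng.uniform(45, 80),
        theta=fold_rng.uniform(0.0, math.pi),
    )
    img = pixels.astype(np.float64)
    m = blob.mask(size, size)
    bump = m * spec.polyp_texture_amplitude * _bandpass(size, size, fold_rng, spec.distractor_texture_scale)
    for k, shift in enumerate(spec.polyp_color_shift):
        img[:, :, k] += bump + m * shift
    return np.clip(img, 0, 255).astype(np.uint8)


def make_dataset(n_polyp: int, n_nonpolyp: int, spec: FixtureSpec | None = None, seed: int = 0, size: int = WINDOW_SIZE) -> LabelledWindowSet:
    """A labelled window set with exact class counts, fully seeded.

    A window is labelled polyp iff the window center lies inside its
    ground-truth ellipse.  Polyp windows carry a textured ellipse covering
    the center; nonpolyp windows are background, a fraction of which carry
    either a *margin* polyp (textured ellipse missing the center) or a
    coarse-textured mucosal fold, so that neither brightness nor mere
    texture presence separates the classes.
    """
    if n_polyp < 0 or n_nonpolyp < 0:
        raise ValueError("class counts must be nonnegative")
    if n_polyp + n_nonpolyp == 0:
        raise EmptyInputError("requested an empty dataset")
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(seed)
    windows, labels, ellipses = [], [], []
    for i in range(n_polyp + n_nonpolyp):
        is_polyp = i < n_polyp
        lo, hi = spec.polyp_amplitude_jitter
        amp = spec.polyp_texture_amplitude * rng.uniform(lo, hi)
        kind_draw = rng.random()
        if is_polyp:
            wspec = replace(_polyp_window_spec(rng, spec, size), polyp_texture_amplitude=amp)
        elif kind_draw < spec.offcenter_fraction:
            wspec = replace(_offcenter_window_spec(rng, spec, size), polyp_texture_amplitude=amp)
        else:
            wspec = replace(spec, height=size, width=size, ellipse=None, seed=int(rng.integers(0, 2**31 - 1)))
        frame, ellipse = make_frame(wspec, index=i)
        pixels = frame.pixels
        if ellipse is not None and ellipse.contains(size / 2, size / 2) != is_polyp:
            raise RuntimeError("fixture geometry violated the center-labelling rule")
        if not is_polyp and ellipse is None and kind_draw < spec.offcenter_fraction + spec.fold_fraction:
            pixels = _add_fold(pixels, wspec.seed + 1, spec, size)
        windows.append(Window(pixels=pixels, origin=(0, 0), frame_index=i))
        labels.append(1 if is_polyp else 0)
        ellipses.append(ellipse)
    return LabelledWindowSet(windows=tuple(windows), labels=np.asarray(labels), ellipses=tuple(ellipses))


def make_video(n_frames: int, path, spec: FixtureSpec | None = None, seed: int = 0, max_drift: float = 5.0) -> list[Ellipse]:
    """Write an n-frame lossless AVI with a drifting polyp; returns the track.

    The polyp's center performs a clipped random walk (≤ ``max_drift`` px
    per frame) around the frame center.
    """
    if n_frames < 1:
        raise EmptyInputError("a video needs at least one frame")
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(seed)
    a, b = rng.uniform(50.0, 70.0), rng.uniform(50.0, 70.0)
    margin = max(a, b) + 2
    cx = spec.width / 2 + rng.uniform(-20, 20)
    cy = spec.height / 2 + rng.uniform(-20, 20)
    theta = rng.uniform(0, math.pi)
    track, frames = [], []
    for i in range(n_frames):
        ellipse = Ellipse(cx=cx, cy=cy, a=a, b=b, theta=theta)
        fspec = replace(spec, ellipse=ellipse, seed=int(rng.integers(0, 2**31 - 1)))
        frame, _ = make_frame(fspec, index=i)
        frames.append(frame.pixels)
        track.append(ellipse)
        step = rng.uniform(-max_drift, max_drift, size=2) / math.sqrt(2)
        cx = float(np.clip(cx + step[0], margin, spec.width - 1 - margin))
        cy = float(np.clip(cy + step[1], margin, spec.height - 1 - margin))
    avi.write_avi(path, frames)
    return track


def write_dataset(dataset: LabelledWindowSet, out_dir) -> None:
    """Export a window set as PNGs + labels.csv + ground_truth.json."""
    import imageio.v3 as iio
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = ["filename,label"]
    truth = {}
    for i, (win, label, ell) in enumerate(zip(dataset.windows, dataset.labels, dataset.ellipses)):
        name = f"window_{i:04d}.png"
        iio.imwrite(out / name, win.pixels)
        rows.append(f"{name},{int(label)}")
        if ell is not None:
            truth[name] = {"cx": ell.cx, "cy": ell.cy, "a": ell.a, "b": ell.b, "theta": ell.theta}
    (out / "labels.csv").write_text("\n".join(rows) + "\n")
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
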