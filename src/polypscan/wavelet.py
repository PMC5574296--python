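"""Color-wavelet texture features.

A window is split into its R, G, B channels; each channel undergoes a
3-level 2-D discrete wavelet transform.  Detail subbands are numbered
``CL = 1..9``: 1–3 are the level-1 (finest) details, 4–6 level-2, 7–9
level-3, and within a level the order is (horizontal, vertical, diagonal).
Texture is best localized at the middle scale, so only the level-2 details
``CL = 4, 5, 6`` are kept — nine images across the three channels.  Each is
quantized and summarised by gray-level co-occurrence matrices (GLCMs) in
four directions, and each GLCM by four Haralick statistics (correlation,
energy, homogeneity, entropy): 3 channels × 3 subbands × 4 directions ×
4 statistics = 144 features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ConfigError, DataError, ShapeError
from .frames import Window

CHANNELS = ("r", "g", "b")
MIDDLE_SUBBANDS = (4, 5, 6)
DIRECTIONS = (0, 45, 90, 135)
STATISTICS = ("correlation", "energy", "homogeneity", "entropy")
N_FEATURES = len(CHANNELS) * len(MIDDLE_SUBBANDS) * len(DIRECTIONS) * len(STATISTICS)

# directed (row, col) offset of the second pixel of a pair, at distance d
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class ChannelDecomposition:
    """3-level DWT of one color channel: approximation + 9 detail images."""

    channel: str
    approx: np.ndarray
    details: tuple  # 9 detail images, CL = 1..9

    def __post_init__(self):
        if len(self.details) != 9:
            raise ShapeError(f"expected 9 detail images, got {len(self.details)}")

    def detail(self, cl: int) -> np.ndarray:
        """Detail image for decomposition index ``CL`` (1-based)."""
        if not 1 <= cl <= 9:
            raise IndexError(f"CL must be in 1..9, got {cl}")
        return self.details[cl - 1]


@dataclass(frozen=True)
class Glcm:
    """Symmetric, normalized gray-level co-occurrence matrix."""

    matrix: np.ndarray
    direction: int
    levels: int
    distance: int = 1


def split_channels(window) -> dict[str, np.ndarray]:
    """Split an RGB window into its three single-channel images."""
    pixels = window.pixels if isinstance(window, Window) else np.asarray(window)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ShapeError(f"expected an H x W x 3 RGB image, got shape {pixels.shape}")
    return {name: pixels[:, :, k] for k, name in enumerate(CHANNELS)}


def dwt3(channel: np.ndarray, wavelet: str = "db6", mode: str = "symmetric", name: str = "") -> ChannelDecomposition:
    """3-level 2-D DWT of a single-channel image.

    Returns the level-3 approximation and the nine detail images ordered by
    CL: finest level first, (horizontal, vertical, diagonal) within a level.
    """
    arr = np.asarray(channel, dtype=np.float64)
    if arr.ndim != 2 or min(arr.shape) < 8:
        raise ShapeError(f"dwt3 needs a 2-D image of at least 8 x 8, got shape {arr.shape}")
    try:
        wav = pywt.Wavelet(wavelet)
    except ValueError as exc:
        raise ConfigError(f"unknown wavelet family {wavelet!r}") from exc
    coeffs = pywt.wavedec2(arr, wav, mode=mode, level=3)
    # wavedec2 returns [cA3, (cH3, cV3, cD3), (cH2, cV2, cD2), (cH1, cV1, cD1)]
    approx = coeffs[0]
    by_level = {3: coeffs[1], 2: coeffs[2], 1: coeffs[3]}
    details = tuple(band for level in (1, 2, 3) for band in by_level[level])
    return ChannelDecomposition(channel=name, approx=approx, details=details)


def select_middle_subbands(decomps: dict[str, ChannelDecomposition]) -> list[np.ndarray]:
    """The nine middle-scale detail images: channels r, g, b × CL 4, 5, 6."""
    return [decomps[c].detail(cl) for c in CHANNELS for cl in MIDDLE_SUBBANDS]


def quantize(subband: np.ndarray, levels: int = 32) -> np.ndarray:
    """Linear min–max quantization of a real image to {0, …, levels-1}.

    A constant image (zero dynamic range) maps to all zeros.
    """
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    arr = np.asarray(subband, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise DataError("subband contains non-finite values")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.int64)
    q = np.floor((arr - lo) / (hi - lo) * levels).astype(np.int64)
    return np.minimum(q, levels - 1)


def compute_glcm(qimage: np.ndarray, direction: int, distance: int = 1, levels: int = 32) -> Glcm:
    """Symmetric normalized co-occurrence matrix of a quantized image.

    Pairs are counted at the directed offset of the given angle (0° is the
    horizontal neighbour to the right, angles grow counter-clockwise), the
    count matrix is symmetrized by adding its transpose, and normalized to
    sum to one.
    """
    img = np.asarray(qimage)
    if direction not in _OFFSETS:
        raise ConfigError(f"direction must be one of {sorted(_OFFSETS)}, got {direction}")
    if img.min() < 0 or img.max() >= levels:
        raise DataError(f"pixel values must lie in [0, {levels - 1}]")
    dr, dc = (o * distance for o in _OFFSETS[direction])
    h, w = img.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r1 <= r0 or c1 <= c0:
        raise DataError(f"image {h}x{w} has no pixel pairs at distance {distance}, direction {direction}")
    a = img[r0:r1, c0:c1].ravel()
    b = img[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    counts = np.zeros((levels, levels), dtype=np.float64)
    np.add.at(counts, (a, b), 1.0)
    counts += counts.T
    return Glcm(matrix=counts / counts.sum(), direction=direction, levels=levels, distance=distance)


def haralick_stats(glcm: Glcm | np.ndarray) -> tuple[float, float, float, float]:
    """(correlation, energy, homogeneity, entropy) of a normalized GLCM.

    With p(i, j) the matrix entries and μ, σ the marginal mean/std:

    - energy       = Σ p(i,j)²
    - entropy      = −Σ p(i,j) log₂ p(i,j), with 0·log 0 := 0
    - homogeneity  = Σ p(i,j) / (1 + |i − j|)
    - correlation  = Σ (i−μᵢ)(j−μⱼ) p(i,j) / (σᵢ σⱼ), defined as 1 when
      σᵢσⱼ = 0 (a constant image is perfectly correlated)
    """
    p = glcm.matrix if isinstance(glcm, Glcm) else np.asarray(glcm, dtype=np.float64)
    g = p.shape[0]
    i = np.arange(g, dtype=np.float64)
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = i @ pi
    mu_j = i @ pj
    var_i = ((i - mu_i) ** 2) @ pi
    var_j = ((i - mu_j) ** 2) @ pj

    energy = float(np.sum(p * p))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    homogeneity = float(np.sum(p / (1.0 + np.abs(i[:, None] - i[None, :]))))
    denom = np.sqrt(var_i * var_j)
    if denom == 0:
        correlation = 1.0
    else:
        correlation = float(((i[:, None] - mu_i) * (i[None, :] - mu_j) * p).sum() / denom)
    return correlation, energy, homogeneity, entropy


def extract_color_wavelet(
    window,
    wavelet: str = "db6",
    glcm_levels: int = 32,
    glcm_distance: int = 1,
    dwt_mode: str = "symmetric",
) -> np.ndarray:
    """The 144-element color-wavelet feature vector of one window.

    Layout order: channel (r, g, b) × subband (CL = 4, 5, 6) × direction
    (0°, 45°, 90°, 135°) × statistic (correlation, energy, homogeneity,
    entropy).  A deterministic, pure function of the pixel values.
    """
    channels = split_channels(window)
    decomps = {c: dwt3(channels[c], wavelet=wavelet, mode=dwt_mode, name=c) for c in CHANNELS}
    features = np.empty(N_FEATURES, dtype=np.float64)
    k = 0
    for subband in select_middle_subbands(decomps):
        q = quantize(subband, glcm_levels)
        for direction in DIRECTIONS:
            glcm = compute_glcm(q, direction, distance=glcm_distance, levels=glcm_levels)
            features[k : k + 4] = haralick_stats(glcm)
            k += 4
    return features


class ColorWaveletExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer mapping RGB windows to 144-D texture vectors.

    Parameters
    ----------
    wavelet : str, default "db6"
        PyWavelets family name for the 3-level decomposition.
    glcm_levels : int, default 32
        Quantization level count G for the co-occurrence matrices.
    glcm_distance : int, default 1
        Pixel-pair offset distance.
    dwt_mode : str, default "symmetric"
        Boundary extension mode of the DWT.
    """

    def __init__(self, wavelet: str = "db6", glcm_levels: int = 32, glcm_distance: int = 1, dwt_mode: str = "symmetric"):
        self.wavelet = wavelet
        self.glcm_levels = glcm_levels
        self.glcm_distance = glcm_distance
        self.dwt_mode = dwt_mode

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        """Extract features for a sequence of windows or an (n, H, W, 3) array."""
        return np.stack(
            [
                extract_color_wavelet(
                    w,
                    wavelet=self.wavelet,
                    glcm_levels=self.glcm_levels,
                    glcm_distance=self.glcm_distance,
                    dwt_mode=self.dwt_mode,
                )
                for w in X
            ]
        )
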