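"""Color-moment, uniform-LBP and Gabor-energy features of slice cross-section images.

A dried *Panax notoginseng* slice photographed against a dark background is
summarised by a fixed 113-dimensional vector:

* 14 color moments — mean and standard deviation of the R, G, B, H, S, a and b
  channels (RGB, HSV hue/saturation, CIELAB opponent axes), each channel
  rescaled to [0, 1] so the moments share a scale;
* 59 uniform local-binary-pattern (LBP, 8 neighbors, radius 1) histogram bins;
* 40 Gabor mean-magnitude energies from a 5-scale × 8-orientation filter bank.

All statistics are computed over foreground pixels only; the foreground mask
defaults to a global Otsu threshold with hole filling and can be disabled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image
from scipy import ndimage, signal
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

# Standard sRGB -> XYZ matrix (D65).  The reference white is taken as the
# matrix's own image of (1,1,1) — numerically the D65 white
# (Xn, Yn, Zn) ~ (95.047, 100.0, 108.883) — so neutral grays land exactly on
# the Lab neutral axis (a = b = 0).
_SRGB_TO_XYZ = np.array([
    [0.4124, 0.3576, 0.1805],
    [0.2126, 0.7152, 0.0722],
    [0.0193, 0.1192, 0.9505],
])
_WHITE_XYZ = _SRGB_TO_XYZ @ np.ones(3)

COLOR_CHANNELS = ("R", "G", "B", "H", "S", "a", "b")


# --------------------------------------------------------------------------- #
# configuration
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class GaborConfig:
    """Parameters of the Gabor filter bank.

    ``f_max`` is the center frequency of the finest scale in cycles/pixel;
    scale u has frequency f_max / sqrt(2)^u.  ``sigma_ratio`` sets the Gaussian
    envelope as sigma = sigma_ratio * wavelength, ``gamma`` is the spatial
    aspect ratio of the envelope.
    """

    n_scales: int = 5
    n_orientations: int = 8
    f_max: float = 0.25
    kernel_size: int = 31
    sigma_ratio: float = 0.56
    gamma: float = 0.5


@dataclass(frozen=True)
class LbpConfig:
    radius: int = 1
    points: int = 8


@dataclass(frozen=True)
class MaskConfig:
    enabled: bool = True
    method: str = "otsu"


@dataclass(frozen=True)
class FeatureConfig:
    gabor: GaborConfig = field(default_factory=GaborConfig)
    lbp: LbpConfig = field(default_factory=LbpConfig)
    mask: MaskConfig = field(default_factory=MaskConfig)

    @staticmethod
    def from_dict(d: dict) -> "FeatureConfig":
        cfg = FeatureConfig()
        if "gabor" in d:
            cfg = replace(cfg, gabor=replace(cfg.gabor, **d["gabor"]))
        if "lbp" in d:
            cfg = replace(cfg, lbp=replace(cfg.lbp, **d["lbp"]))
        if "mask" in d:
            cfg = replace(cfg, mask=replace(cfg.mask, **d["mask"]))
        return cfg


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #

@dataclass
class SliceImage:
    """An RGB raster of a slice cross-section with an optional foreground mask.

    ``pixels`` is H×W×3 with channel values in [0, 1]; ``mask`` is an H×W
    boolean foreground indicator (default: all foreground).
    """

    pixels: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 array")
        h, w = self.pixels.shape[:2]
        if h < 3 or w < 3:
            raise ValueError("image must be at least 3 x 3")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel values must be finite")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("pixel values must lie in [0, 1]")
        if self.mask is None:
            self.mask = np.ones((h, w), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (h, w):
                raise ValueError("mask shape must equal the pixel-plane shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class ColorPlanes:
    """Per-pixel H (degrees), S, and CIELAB a/b planes of an image."""

    H: np.ndarray
    S: np.ndarray
    a: np.ndarray
    b: np.ndarray


@dataclass(frozen=True)
class FeatureVector:
    """The ordered fusion color moments ∥ LBP histogram ∥ Gabor energies."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("values and names must be parallel")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")


def feature_names(config: FeatureConfig | None = None) -> tuple[str, ...]:
    """Stable identifiers of the fused feature vector, in extraction order."""
    config = config or FeatureConfig()
    names = []
    for ch in COLOR_CHANNELS:
        names += [f"color_mu_{ch}", f"color_sigma_{ch}"]
    names += [f"lbp_u2_{i}" for i in range(59)]
    for u in range(config.gabor.n_scales):
        for v in range(config.gabor.n_orientations):
            names.append(f"gabor_e_{u}_{v}")
    return tuple(names)


# --------------------------------------------------------------------------- #
# image loading
# --------------------------------------------------------------------------- #

def read_image(path) -> SliceImage:
    """Read a PNG/JPEG/TIFF image, normalizing the native bit depth to [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.dtype == np.uint8:
        pixels = arr / 255.0
    elif arr.dtype == np.uint16:
        pixels = arr / 65535.0
    else:
        pixels = np.clip(arr.astype(np.float64), 0.0, 1.0)
    return SliceImage(pixels=pixels)


# --------------------------------------------------------------------------- #
# color planes and color moments
# --------------------------------------------------------------------------- #

def convert_color_planes(image: SliceImage) -> ColorPlanes:
    """Compute H, S (HSI form) and CIELAB a, b planes.

    Hue uses the arccos formulation
    ``H = arccos( 0.5*[(R-G)+(R-B)] / sqrt((R-G)^2 + (R-B)(G-B)) )``
    with the standard correction H ← 360° − H when B > G; achromatic pixels
    (R = G = B) get H = 0.  Saturation is ``1 − 3·min(R,G,B)/(R+G+B)`` with
    S = 0 on black pixels.  a and b come from the sRGB → XYZ(D65) → Lab path.
    """
    R = image.pixels[:, :, 0]
    G = image.pixels[:, :, 1]
    B = image.pixels[:, :, 2]

    num = 0.5 * ((R - G) + (R - B))
    den = np.sqrt((R - G) ** 2 + (R - B) * (G - B))
    achromatic = den < 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(achromatic, 1.0, num / np.where(achromatic, 1.0, den))
    H = np.degrees(np.arccos(np.clip(ratio, -1.0, 1.0)))
    H = np.where(B > G, 360.0 - H, H)
    H = np.where(achromatic, 0.0, H)
    H = np.mod(H, 360.0)

    total = R + G + B
    S = np.where(total < 1e-12, 0.0, 1.0 - 3.0 * np.minimum(np.minimum(R, G), B)
                 / np.where(total < 1e-12, 1.0, total))

    a, b = _lab_ab(image.pixels)
    return ColorPlanes(H=H, S=S, a=a, b=b)


def _lab_ab(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """CIELAB a, b planes: sRGB gamma linearization, XYZ(D65), CIE f."""
    srgb = pixels
    linear = np.where(srgb <= 0.04045, srgb / 12.92,
                      ((srgb + 0.055) / 1.055) ** 2.4)
    xyz = linear @ _SRGB_TO_XYZ.T
    t = xyz / _WHITE_XYZ
    delta3 = (6.0 / 29.0) ** 3
    f = np.where(t > delta3, np.cbrt(t),
                 t / (3.0 * (6.0 / 29.0) ** 2) + 4.0 / 29.0)
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return a, b


def _rescaled_channels(image: SliceImage) -> dict[str, np.ndarray]:
    """The 7 moment channels, each mapped to [0, 1]."""
    planes = convert_color_planes(image)
    return {
        "R": image.pixels[:, :, 0],
        "G": image.pixels[:, :, 1],
        "B": image.pixels[:, :, 2],
        "H": planes.H / 360.0,
        "S": planes.S,
        "a": (planes.a + 128.0) / 255.0,
        "b": (planes.b + 128.0) / 255.0,
    }


def color_moments(image: SliceImage) -> np.ndarray:
    """Mean and standard deviation (1/N form) of each of the 7 color channels.

    Output order: (μ_R, σ_R, μ_G, σ_G, …, μ_b, σ_b) — length 14.  Statistics
    are taken over foreground pixels only.
    """
    mask = image.mask
    if not mask.any():
        raise ValueError("color_moments requires at least one foreground pixel")
    channels = _rescaled_channels(image)
    out = np.empty(2 * len(COLOR_CHANNELS))
    for i, ch in enumerate(COLOR_CHANNELS):
        vals = channels[ch][mask]
        out[2 * i] = vals.mean()
        out[2 * i + 1] = vals.std()  # population (1/N) normalization
    return out


# --------------------------------------------------------------------------- #
# foreground segmentation
# --------------------------------------------------------------------------- #

def grayscale_plane(image: SliceImage) -> np.ndarray:
    """8-bit BT.601 luma plane: round(255 * (0.299 R + 0.587 G + 0.114 B))."""
    R, G, B = image.pixels[..., 0], image.pixels[..., 1], image.pixels[..., 2]
    gray = 0.299 * R + 0.587 * G + 0.114 * B
    return np.round(gray * 255.0).astype(np.uint8)


def foreground_mask(image: SliceImage, config: MaskConfig | None = None) -> np.ndarray:
    """Segment the bright slice from the dark background.

    Global Otsu threshold on the grayscale plane, keeping the bright class,
    followed by morphological hole filling.  With masking disabled (or an
    image of zero dynamic range) the mask is all-true.
    """
    config = config or MaskConfig()
    if not config.enabled:
        return np.ones(image.shape, dtype=bool)
    gray = grayscale_plane(image)
    if gray.min() == gray.max():
        logger.warning("image has zero dynamic range; using all-true mask")
        return np.ones(image.shape, dtype=bool)
    thresh = threshold_otsu(gray)
    mask = gray > thresh
    return ndimage.binary_fill_holes(mask)


# --------------------------------------------------------------------------- #
# uniform LBP
# --------------------------------------------------------------------------- #

def _count_transitions(code: int, points: int = 8) -> int:
    """Number of circular 0↔1 transitions in an LBP code."""
    bits = [(code >> p) & 1 for p in range(points)]
    return sum(bits[p] != bits[(p + 1) % points] for p in range(points))


def uniform_pattern_table(points: int = 8) -> np.ndarray:
    """Map each 8-bit code to its u2 histogram bin.

    The 58 uniform patterns (≤ 2 circular transitions) get singleton bins in
    ascending code order; every non-uniform code shares the final catch-all
    bin (index 58).
    """
    n_codes = 1 << points
    uniform = [c for c in range(n_codes) if _count_transitions(c, points) <= 2]
    table = np.full(n_codes, len(uniform), dtype=np.int64)
    for bin_idx, code in enumerate(uniform):
        table[code] = bin_idx
    return table


_U2_TABLE_8 = uniform_pattern_table(8)

# 3x3 neighbor offsets, clockwise from the top-left corner; p = 0 weights 2^0.
_NEIGHBOR_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
)


def lbp_codes(gray: np.ndarray) -> np.ndarray:
    """8-bit LBP code of every interior pixel of an 8-bit grayscale plane.

    A neighbor scores 1 when its gray value is ≥ the center's (ties score 1);
    neighbors are taken clockwise from the top-left of the 3×3 window.
    """
    g = gray.astype(np.int64)
    center = g[1:-1, 1:-1]
    codes = np.zeros_like(center)
    for p, (dy, dx) in enumerate(_NEIGHBOR_OFFSETS):
        neighbor = g[1 + dy: g.shape[0] - 1 + dy, 1 + dx: g.shape[1] - 1 + dx]
        codes += (neighbor >= center).astype(np.int64) << p
    return codes


def lbp_histogram(image: SliceImage) -> np.ndarray:
    """Normalized 59-bin uniform-LBP histogram over interior foreground pixels.

    A pixel contributes only if its whole 3×3 window lies in the foreground,
    so codes straddling the background are dropped.
    """
    gray = grayscale_plane(image)
    codes = lbp_codes(gray)
    # erode mask so every counted window is fully foreground
    window_ok = ndimage.binary_erosion(
        image.mask, structure=np.ones((3, 3), dtype=bool), border_value=False
    )[1:-1, 1:-1]
    kept = codes[window_ok]
    if kept.size == 0:
        raise ValueError("no interior foreground pixels for the LBP histogram")
    hist = np.bincount(_U2_TABLE_8[kept], minlength=59).astype(np.float64)
    return hist / hist.sum()


# --------------------------------------------------------------------------- #
# Gabor filter bank
# --------------------------------------------------------------------------- #

def gabor_kernel_bank(config: GaborConfig | None = None) -> list[np.ndarray]:
    """Complex Gabor kernels, scale-major (u = 0..n_scales−1, then v).

    Scale u has center frequency f_max / √2^u; orientation v is at angle
    v·π/n_orientations.  The Gaussian envelope has σ = sigma_ratio·λ along the
    carrier and σ/γ across it.  Kernels are zero-mean in their real part so a
    constant image yields (near-)zero response, and are L1-normalized.
    """
    config = config or GaborConfig()
    half = config.kernel_size // 2
    y, x = np.mgrid[-half: half + 1, -half: half + 1].astype(np.float64)
    kernels = []
    for u in range(config.n_scales):
        freq = config.f_max / (np.sqrt(2.0) ** u)
        lam = 1.0 / freq
        sigma = config.sigma_ratio * lam
        for v in range(config.n_orientations):
            theta = v * np.pi / config.n_orientations
            xr = x * np.cos(theta) + y * np.sin(theta)
            yr = -x * np.sin(theta) + y * np.cos(theta)
            envelope = np.exp(-(xr**2 + (config.gamma * yr) ** 2) / (2.0 * sigma**2))
            carrier = np.exp(1j * 2.0 * np.pi * freq * xr)
            kern = envelope * carrier
            # remove the DC component so flat regions give zero response
            kern = kern - envelope * (kern.sum() / envelope.sum())
            kern /= np.abs(kern).sum()
            kernels.append(kern)
    return kernels


def gabor_energy(image: SliceImage, config: GaborConfig | None = None) -> np.ndarray:
    """Mean response magnitude of each of the 40 Gabor filters over foreground.

    Convolution uses reflect padding; images smaller than the kernel are
    handled by the same padding with a warning.
    """
    config = config or GaborConfig()
    gray = grayscale_plane(image).astype(np.float64) / 255.0
    mask = image.mask
    if not mask.any():
        raise ValueError("gabor_energy requires at least one foreground pixel")
    h, w = gray.shape
    if config.kernel_size > min(h, w):
        warnings.warn("Gabor kernel larger than image; reflect padding dominates")
    pad = config.kernel_size // 2
    padded = np.pad(gray, pad, mode="reflect")
    energies = np.empty(config.n_scales * config.n_orientations)
    for i, kern in enumerate(gabor_kernel_bank(config)):
        resp = signal.fftconvolve(padded, kern, mode="valid")
        energies[i] = np.abs(resp)[mask].mean()
    # numerically zero responses on flat images stay exactly zero
    energies[energies < 1e-12] = 0.0
    return energies


# --------------------------------------------------------------------------- #
# fusion
# --------------------------------------------------------------------------- #

def extract_features(
    image: SliceImage, config: FeatureConfig | None = None
) -> FeatureVector:
    """The fused 113-dimensional descriptor: color → LBP → Gabor.

    A pure, deterministic function of (pixels, mask, config).  When the image
    carries no explicit mask and masking is enabled in the configuration, the
    Otsu foreground mask is computed first.
    """
    config = config or FeatureConfig()
    if image.mask.all() and config.mask.enabled:
        image = SliceImage(pixels=image.pixels, mask=foreground_mask(image, config.mask))
    values = np.concatenate([
        color_moments(image),
        lbp_histogram(image),
        gabor_energy(image, config.gabor),
    ])
    return FeatureVector(values=values, names=feature_names(config))
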