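"""V1-like model: Gabor-jet magnitudes and correlation dissimilarity.

A bank of 40 quadrature Gabor filter pairs (8 orientations x 5 scales) is
applied to an image and the complex-cell magnitude sqrt(even^2 + odd^2) is
sampled on a uniform spatial grid; the concatenated magnitudes form the
image's "jet" vector.  The dissimilarity between two images is one minus
the Pearson correlation of their jets, ranging from 0 (identical) to 2
(perfectly anti-correlated).  Animation-level dissimilarity averages the 9
ordered frame pairs, as in the pixel model.

Parameter choices not dictated by the model family (wavelengths, jet grid
density, raster size) are octave-spaced / configurable defaults; results
that depend on them are qualitative, not numeric, targets.  Convolution
uses reflect padding, so jets near borders are well defined.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .stimuli import GrayImage

__all__ = [
    "GaborBankSpec",
    "GaborChannel",
    "GaborBank",
    "build_gabor_bank",
    "default_jet_grid",
    "jet_activations",
    "gabor_dissimilarity",
    "animation_dissimilarity_gabor",
]

_DEFAULT_WAVELENGTHS = tuple(4.0 * (8.0 ** (i / 4.0)) for i in range(5))  # 4..32 px


@dataclass(frozen=True)
class GaborBankSpec:
    """Configuration of the filter bank.

    ``bandwidth_octaves`` sets the Gaussian envelope width via the standard
    half-response spatial-frequency bandwidth relation; 1 octave gives
    sigma ~ 0.56 * wavelength.
    """

    n_orientations: int = 8
    wavelengths: tuple[float, ...] = _DEFAULT_WAVELENGTHS
    bandwidth_octaves: float = 1.0
    truncate_sigmas: float = 2.5

    def __post_init__(self):
        if self.n_orientations < 1:
            raise ValueError("need at least one orientation")
        w = self.wavelengths
        if len(w) < 1 or any(w2 <= w1 for w1, w2 in zip(w, w[1:])):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def n_scales(self) -> int:
        return len(self.wavelengths)

    @property
    def n_channels(self) -> int:
        return self.n_orientations * self.n_scales

    @property
    def orientations(self) -> tuple[float, ...]:
        return tuple(
            np.pi * k / self.n_orientations for k in range(self.n_orientations)
        )


@dataclass(frozen=True)
class GaborChannel:
    orientation: float
    wavelength: float
    even: np.ndarray  # cosine-phase kernel, DC-corrected
    odd: np.ndarray  # sine-phase kernel


@dataclass(frozen=True)
class GaborBank:
    spec: GaborBankSpec
    channels: tuple[GaborChannel, ...]

    @property
    def max_half_support(self) -> int:
        return max(c.even.shape[0] // 2 for c in self.channels)


def _sigma_for(wavelength: float, bandwidth_octaves: float) -> float:
    b = bandwidth_octaves
    return (
        wavelength
        / np.pi
        * np.sqrt(np.log(2.0) / 2.0)
        * (2.0**b + 1.0)
        / (2.0**b - 1.0)
    )


def _gabor_pair(theta: float, wavelength: float, sigma: float, truncate: float):
    half = int(np.ceil(truncate * sigma))
    ax = np.arange(-half, half + 1, dtype=float)
    X, Y = np.meshgrid(ax, ax)
    # coordinate along the carrier (normal to the stripes)
    xp = X * np.cos(theta) + Y * np.sin(theta)
    env = np.exp(-(X**2 + Y**2) / (2.0 * sigma**2))
    phase = 2.0 * np.pi * xp / wavelength
    even = env * np.cos(phase)
    odd = env * np.sin(phase)
    even -= even.mean()  # zero DC: uniform input must produce no response
    return even, odd


def build_gabor_bank(spec: GaborBankSpec = GaborBankSpec()) -> GaborBank:
    """Realize the bank as quadrature kernel pairs, scale-major ordering."""
    channels = []
    for wavelength in spec.wavelengths:
        sigma = _sigma_for(wavelength, spec.bandwidth_octaves)
        for theta in spec.orientations:
            even, odd = _gabor_pair(theta, wavelength, sigma, spec.truncate_sigmas)
            channels.append(GaborChannel(theta, wavelength, even, odd))
    return GaborBank(spec=spec, channels=tuple(channels))


def default_jet_grid(height: int, width: int, n: int = 10) -> np.ndarray:
    """An n x n uniform grid of (row, col) sample points inside the image."""
    if n < 1:
        raise ValueError("grid size must be >= 1")
    rows = np.linspace(0, height - 1, n + 2)[1:-1]
    cols = np.linspace(0, width - 1, n + 2)[1:-1]
    R, C = np.meshgrid(rows, cols, indexing="ij")
    return np.stack([np.round(R.ravel()), np.round(C.ravel())], axis=1).astype(int)


def jet_activations(
    img: GrayImage, bank: GaborBank, grid_points: np.ndarray
) -> np.ndarray:
    """Complex-cell magnitudes at each grid point for every channel.

    Returns a vector of length n_points * n_channels (point-major).  The
    response at a point equals the reflect-padded convolution of the image
    with each kernel evaluated there; it is computed as a windowed dot
    product for speed.
    """
    pts = np.asarray(grid_points)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
        raise ValueError("grid_points must be a nonempty (P, 2) array")
    h, w = img.values.shape
    if pts.min() < 0 or pts[:, 0].max() >= h or pts[:, 1].max() >= w:
        raise ValueError("grid points must lie inside the image")
    pad = bank.max_half_support
    padded = np.pad(img.values, pad, mode="reflect")
    n_pts = pts.shape[0]
    mags = np.empty((n_pts, len(bank.channels)))
    # group channels by kernel size so patches are extracted once per scale
    by_half: dict[int, list[int]] = {}
    for ci, ch in enumerate(bank.channels):
        by_half.setdefault(ch.even.shape[0] // 2, []).append(ci)
    for half, idxs in by_half.items():
        k = 2 * half + 1
        patches = np.empty((n_pts, k, k))
        for p, (r, c) in enumerate(pts):
            r0 = r + pad - half
            c0 = c + pad - half
            patches[p] = padded[r0 : r0 + k, c0 : c0 + k]
        # convolution at the center point = correlation with the flipped kernel
        evens = np.stack([bank.channels[i].even[::-1, ::-1] for i in idxs])
        odds = np.stack([bank.channels[i].odd[::-1, ::-1] for i in idxs])
        re = np.einsum("pij,cij->pc", patches, evens)
        ro = np.einsum("pij,cij->pc", patches, odds)
        mags[:, idxs] = np.sqrt(re**2 + ro**2)
    return mags.ravel()


def gabor_dissimilarity(a: np.ndarray, b: np.ndarray) -> float:
    """One minus the Pearson correlation of two jet vectors, in [0, 2]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("jets must be equal-length 1-d vectors with >= 2 entries")
    ac = a - a.mean()
    bc = b - b.mean()
    sa = np.sqrt(np.sum(ac**2))
    sb = np.sqrt(np.sum(bc**2))
    if sa == 0.0 or sb == 0.0:
        raise ValueError("zero-variance jet: correlation undefined (blank image?)")
    if np.array_equal(a, b):
        return 0.0  # exact identity, avoid roundoff above zero
    r = float(np.clip(np.sum(ac * bc) / (sa * sb), -1.0, 1.0))
    return 1.0 - r


def animation_dissimilarity_gabor(
    test: Sequence[GrayImage],
    input_: Sequence[GrayImage],
    bank: GaborBank,
    grid_points: np.ndarray,
) -> float:
    """Mean of the 9 pairwise jet dissimilarities between two animations."""
    if len(test) != 3 or len(input_) != 3:
        raise ValueError("animations must have exactly 3 frames")
    jt = [jet_activations(im, bank, grid_points) for im in test]
    ji = [jet_activations(im, bank, grid_points) for im in input_]
    return float(np.mean([gabor_dissimilarity(t, i) for t in jt for i in ji]))
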