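"""Camouflage metrics for a composited scene.

Five metric families, each computed against the local surround (within one
body length of the target outline) and against the whole background:

* edge disruption ("GabRat"): ratio of Gabor edge energy orthogonal to the
  target outline (disruptive, "false" edges) to total edge energy, averaged
  around the outline — achromatic on CIE L, chromatic on CIE A;
* luminance match: L1 distance between 100-bin CIE L histograms;
* colour-map match: L1 distance between 200x200-bin joint CIE (A, B)
  frequency maps;
* mean-colour match: Euclidean distance between mean (A, B) points;
* pattern match: L1 distance between bandpass "granularity" energy spectra
  (per-scale standard deviation of difference-of-Gaussians images).

All histogram distances live in [0, 2]; GabRat in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import gabor_kernel

from .image_io import Scene, TargetMask

__all__ = [
    "MetricConfig",
    "EnergySpectrum",
    "CamoProfile",
    "MetricError",
    "METRIC_COLUMNS",
    "body_length",
    "fit_circle",
    "surround_region",
    "gabrat",
    "luminance_dist_diff",
    "colour_map_diff",
    "colour_mean_dist",
    "pattern_energy_spectrum",
    "pattern_energy_diff",
    "camo_profile",
]


class MetricError(ValueError):
    """Raised for degenerate metric inputs (empty regions, mismatched scales...)."""


@dataclass(frozen=True)
class MetricConfig:
    """Tunable parameters of the metric battery.

    ``gabrat_sigma_l`` / ``gabrat_sigma_a`` are the Gabor envelope widths (px)
    used on the L and A planes.  ``gabor_bandwidth`` fixes the carrier
    wavelength relative to sigma via the standard one-octave relationship.
    ``granularity_scales`` is the ladder of spatial scales (px) for the
    bandpass spectrum; ``None`` derives a dyadic ladder 2, 4, ... up to a
    quarter of the smaller image dimension.  ``surround_radius_bodylengths``
    sets the width of the local surround annulus.
    """

    gabrat_sigma_l: float = 3.0
    gabrat_sigma_a: float = 4.0
    gabor_bandwidth: float = 1.0
    lum_bins: int = 100
    lum_range: tuple[float, float] = (0.0, 100.0)
    colour_bins_per_axis: int = 200
    colour_range: tuple[float, float] = (-100.0, 100.0)
    granularity_scales: tuple[float, ...] | None = None
    surround_radius_bodylengths: float = 1.0
    edge_energy_epsilon: float = 1e-9

    def __post_init__(self) -> None:
        if self.gabrat_sigma_l <= 0 or self.gabrat_sigma_a <= 0:
            raise MetricError("Gabor sigmas must be positive")
        if self.lum_bins < 2 or self.colour_bins_per_axis < 2:
            raise MetricError("histogram bin counts must be >= 2")
        if self.granularity_scales is not None:
            s = np.asarray(self.granularity_scales, dtype=float)
            if len(s) < 1 or np.any(np.diff(s) <= 0) or np.any(s <= 0):
                raise MetricError("granularity scales must be positive and strictly increasing")

    def scales_for(self, shape: tuple[int, int]) -> np.ndarray:
        """Resolve the granularity ladder for an image of the given shape."""
        if self.granularity_scales is not None:
            return np.asarray(self.granularity_scales, dtype=float)
        top = min(shape) / 4
        scales = []
        s = 2.0
        while s <= top:
            scales.append(s)
            s *= 2.0
        if not scales:
            raise MetricError(f"image of shape {shape} too small for any dyadic scale")
        return np.asarray(scales)


@dataclass(frozen=True)
class EnergySpectrum:
    """Per-scale pattern energy: SD of bandpass pixel values at each scale."""

    scales: np.ndarray
    energy: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "scales", np.asarray(self.scales, dtype=float))
        object.__setattr__(self, "energy", np.asarray(self.energy, dtype=float))
        if self.scales.shape != self.energy.shape:
            raise MetricError("scales and energy must align")
        if np.any(self.energy < 0):
            raise MetricError("energies must be non-negative")


@dataclass
class CamoProfile:
    """Metric vector for one composited scene.

    Comparative metrics carry a ``_surround`` (within one body length) and a
    ``_background`` (whole background, target excluded) variant.
    """

    gabrat_l: float
    gabrat_a: float
    lum_diff_surround: float
    lum_diff_background: float
    colour_map_diff_surround: float
    colour_map_diff_background: float
    colour_dist_surround: float
    colour_dist_background: float
    pattern_diff_surround: float
    pattern_diff_background: float
    crab_area: float
    body_length: float

    def to_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


#: Column names under which profile metrics appear in gameplay logs.
METRIC_COLUMNS = [
    "gabrat_l",
    "gabrat_a",
    "lum_diff_surround",
    "lum_diff_background",
    "colour_map_diff_surround",
    "colour_map_diff_background",
    "colour_dist_surround",
    "colour_dist_background",
    "pattern_diff_surround",
    "pattern_diff_background",
    "body_length",
]


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def fit_circle(points: np.ndarray) -> tuple[float, float, float]:
    """Least-squares (Kasa) circle fit to (x, y) points -> (cx, cy, r).

    Solves the linear system arising from ``x^2 + y^2 = 2 cx x + 2 cy y + c``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise MetricError("circle fit needs >= 3 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise MetricError("degenerate (collinear) outline: circle fit is singular")
    cx, cy, c = sol
    r2 = c + cx * cx + cy * cy
    if r2 <= 0 or not np.isfinite(r2):
        raise MetricError("degenerate outline: non-positive fitted radius")
    return float(cx), float(cy), float(np.sqrt(r2))


def body_length(mask: TargetMask) -> float:
    """Body length: diameter of the least-squares circle fitted to the outline."""
    _, _, r = fit_circle(mask.outline)
    return 2.0 * r


def surround_region(
    scene: Scene, cfg: MetricConfig = MetricConfig(), body_len: float | None = None
) -> np.ndarray:
    """Boolean mask of the local surround: pixels within ``radius x body length``
    of the target, excluding the target itself, clipped to the frame."""
    region = scene.mask_in_scene.region
    if body_len is None:
        body_len = body_length(scene.mask_in_scene)
    dist = ndimage.distance_transform_edt(~region)
    ring = (dist > 0) & (dist <= cfg.surround_radius_bodylengths * body_len)
    if not ring.any():
        raise MetricError("empty surround: target fills the frame")
    return ring


# ---------------------------------------------------------------------------
# edge disruption (GabRat)
# ---------------------------------------------------------------------------


def _outline_tangent_angles(outline: np.ndarray, window: int) -> np.ndarray:
    """Tangent angle at each outline point, from a circularly smoothed trace."""
    n = len(outline)
    window = max(3, min(window | 1, n // 2 * 2 + 1))
    kernel = np.ones(window) / window
    pad = window // 2
    wrapped = np.vstack([outline[-pad:], outline, outline[:pad]])
    sx = np.convolve(wrapped[:, 0], kernel, mode="valid")
    sy = np.convolve(wrapped[:, 1], kernel, mode="valid")
    dx = np.gradient(np.concatenate([sx[-2:], sx, sx[:2]]))[2:-2]
    dy = np.gradient(np.concatenate([sy[-2:], sy, sy[:2]]))[2:-2]
    return np.arctan2(dy, dx)


def _gabor_pair(sigma: float, theta: float, bandwidth: float) -> np.ndarray:
    """Complex quadrature Gabor kernel with zero-mean even part.

    ``theta`` is the direction of the carrier wave vector, i.e. the kernel
    responds maximally to an edge/grating oriented perpendicular to ``theta``.
    """
    sigma_over_lambda = (1.0 / np.pi) * np.sqrt(np.log(2) / 2) * (2**bandwidth + 1) / (2**bandwidth - 1)
    frequency = sigma_over_lambda / sigma
    k = gabor_kernel(frequency, theta=theta, sigma_x=sigma, sigma_y=sigma)
    k = k - k.real.mean()  # zero DC: global intensity offsets must not register
    return k


def gabrat(
    plane: np.ndarray,
    mask_in_scene: TargetMask,
    sigma: float,
    bandwidth: float = 1.0,
    epsilon: float = 1e-9,
    angle_bins: int = 72,
) -> float:
    """Edge-disruption ratio around a target outline on one image plane.

    At each outline point the local Gabor edge energy is measured twice: with
    the carrier along the outline normal (detecting the "true" boundary edge,
    parallel to the outline) and along the tangent (detecting "false"
    disruptive edges crossing the outline).  The metric is the mean over
    outline points of ``orth / (orth + par)``; points whose total energy falls
    below ``epsilon`` are uninformative and excluded, and the metric is 0 when
    every point is below ``epsilon``.

    Tangent directions are quantised to ``angle_bins`` orientations so each
    distinct kernel is built once.
    """
    if sigma <= 0:
        raise MetricError("sigma must be positive")
    plane = np.asarray(plane, dtype=float)
    outline = mask_in_scene.outline
    angles = _outline_tangent_angles(outline, window=int(round(2 * sigma)) | 1)

    # orientation is defined modulo pi (an edge has no direction)
    bin_idx = np.round((angles % np.pi) / (np.pi / angle_bins)).astype(int) % angle_bins

    probe = _gabor_pair(sigma, 0.0, bandwidth)
    half = probe.shape[0] // 2, probe.shape[1] // 2
    padded = np.pad(plane, ((half[0], half[0]), (half[1], half[1])), mode="reflect")

    rows = np.clip(np.round(outline[:, 1]).astype(int), 0, plane.shape[0] - 1)
    cols = np.clip(np.round(outline[:, 0]).astype(int), 0, plane.shape[1] - 1)

    par = np.empty(len(outline))
    orth = np.empty(len(outline))
    for b in np.unique(bin_idx):
        theta = b * np.pi / angle_bins
        # carrier along the normal -> energy of edges parallel to the outline
        k_par = _gabor_pair(sigma, theta + np.pi / 2, bandwidth)
        # carrier along the tangent -> energy of edges crossing the outline
        k_orth = _gabor_pair(sigma, theta, bandwidth)
        sel = np.flatnonzero(bin_idx == b)
        kh, kw = k_par.shape
        for i in sel:
            patch = padded[rows[i] : rows[i] + kh, cols[i] : cols[i] + kw]
            par[i] = np.abs(np.vdot(k_par, patch))
            orth[i] = np.abs(np.vdot(k_orth, patch))

    total = par + orth
    valid = total >= epsilon
    if not valid.any():
        return 0.0
    return float(np.mean(orth[valid] / total[valid]))


# ---------------------------------------------------------------------------
# histogram distances
# ---------------------------------------------------------------------------


def _check_nonempty(*pixel_sets: np.ndarray) -> None:
    for px in pixel_sets:
        if np.size(px) == 0:
            raise MetricError("empty pixel set")


def luminance_dist_diff(
    target_px: np.ndarray,
    ref_px: np.ndarray,
    bins: int = 100,
    value_range: tuple[float, float] = (0.0, 100.0),
) -> float:
    """L1 distance between normalised luminance histograms (in [0, 2])."""
    _check_nonempty(target_px, ref_px)
    lo, hi = value_range
    t = np.clip(np.ravel(target_px), lo, hi)
    r = np.clip(np.ravel(ref_px), lo, hi)
    ht, _ = np.histogram(t, bins=bins, range=value_range)
    hr, _ = np.histogram(r, bins=bins, range=value_range)
    return float(np.abs(ht / ht.sum() - hr / hr.sum()).sum())


def colour_map_diff(
    target_ab: np.ndarray,
    ref_ab: np.ndarray,
    bins: int = 200,
    value_range: tuple[float, float] = (-100.0, 100.0),
) -> float:
    """L1 distance between 2-D (A, B) frequency maps (in [0, 2]).

    Values outside ``value_range`` are clipped into the edge bins rather than
    dropped, so every valid CIELAB pixel contributes.
    """
    t = np.reshape(np.asarray(target_ab, dtype=float), (-1, 2))
    r = np.reshape(np.asarray(ref_ab, dtype=float), (-1, 2))
    _check_nonempty(t, r)
    lo, hi = value_range
    t = np.clip(t, lo, hi)
    r = np.clip(r, lo, hi)
    rng = [value_range, value_range]
    ht, _, _ = np.histogram2d(t[:, 0], t[:, 1], bins=bins, range=rng)
    hr, _, _ = np.histogram2d(r[:, 0], r[:, 1], bins=bins, range=rng)
    return float(np.abs(ht / ht.sum() - hr / hr.sum()).sum())


def colour_mean_dist(target_ab: np.ndarray, ref_ab: np.ndarray) -> float:
    """Euclidean distance between mean (A, B) chromaticity points."""
    t = np.reshape(np.asarray(target_ab, dtype=float), (-1, 2))
    r = np.reshape(np.asarray(ref_ab, dtype=float), (-1, 2))
    _check_nonempty(t, r)
    return float(np.linalg.norm(t.mean(axis=0) - r.mean(axis=0)))


# ---------------------------------------------------------------------------
# pattern energy (granularity)
# ---------------------------------------------------------------------------


def _masked_blur(img: np.ndarray, mask: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian blur that ignores pixels outside ``mask`` (normalised convolution)."""
    if sigma <= 0:
        return np.where(mask, img, 0.0)
    m = mask.astype(float)
    num = ndimage.gaussian_filter(img * m, sigma, mode="reflect")
    den = ndimage.gaussian_filter(m, sigma, mode="reflect")
    out = np.zeros_like(num)
    ok = den > 1e-8
    out[ok] = num[ok] / den[ok]
    return out


# Sigma-to-scale constant for the octave DoG band G(sigma) - G(2 sigma): the
# band's frequency response exp(-2 pi^2 sigma^2 f^2) - exp(-8 pi^2 sigma^2 f^2)
# peaks at wavelength lambda = sigma * pi * sqrt(6 / ln 4), so choosing
# sigma = s / (pi sqrt(6 / ln 4)) makes the band labelled ``s`` peak exactly at
# spatial wavelength s.
DOG_SIGMA_PER_SCALE = float(np.sqrt(np.log(4.0) / 6.0) / np.pi)


def bandpass_stack(
    img: np.ndarray, scales: np.ndarray, mask: np.ndarray | None = None
) -> list[np.ndarray]:
    """Octave difference-of-Gaussians bands, one per scale.

    The band for scale ``s`` is ``G(sigma) - G(2 sigma)`` with
    ``sigma = DOG_SIGMA_PER_SCALE * s``, applied to the (masked) image with
    reflective padding.  Sigmas of adjacent dyadic scales chain, so the bands
    tile the spectrum, and a pattern of dominant wavelength ``s`` concentrates
    its energy in the band labelled ``s``.
    """
    img = np.asarray(img, dtype=float)
    if mask is None:
        mask = np.ones(img.shape, dtype=bool)
    bands = []
    for s in np.asarray(scales, dtype=float):
        sigma = DOG_SIGMA_PER_SCALE * s
        lo = _masked_blur(img, mask, sigma)
        hi = _masked_blur(img, mask, 2.0 * sigma)
        bands.append(lo - hi)
    return bands


def pattern_energy_spectrum(
    img: np.ndarray,
    region: np.ndarray,
    cfg: MetricConfig = MetricConfig(),
    scales: np.ndarray | None = None,
) -> EnergySpectrum:
    """Granularity spectrum of an image region: SD of each bandpass image
    over the region's pixels."""
    img = np.asarray(img, dtype=float)
    region = np.asarray(region, dtype=bool)
    if scales is None:
        scales = cfg.scales_for(img.shape)
    scales = np.asarray(scales, dtype=float)
    if min(img.shape) <= scales[-1]:
        raise MetricError("image smaller than the largest granularity scale")
    if region.sum() < scales[0] ** 2:
        raise MetricError("region smaller than the smallest granularity scale")
    energy = np.array([band[region].std() for band in bandpass_stack(img, scales, region)])
    return EnergySpectrum(scales=scales, energy=energy)


def pattern_energy_diff(s1: EnergySpectrum, s2: EnergySpectrum) -> float:
    """Sum of absolute per-scale energy differences."""
    if s1.scales.shape != s2.scales.shape or not np.allclose(s1.scales, s2.scales):
        raise MetricError("spectra measured at different scale sets")
    return float(np.abs(s1.energy - s2.energy).sum())


# ---------------------------------------------------------------------------
# full profile
# ---------------------------------------------------------------------------


def camo_profile(scene: Scene, cfg: MetricConfig = MetricConfig()) -> CamoProfile:
    """Compute the full metric vector for a composited scene.

    Achromatic GabRat runs on the CIE L plane (sigma ``gabrat_sigma_l``),
    chromatic GabRat on the CIE A plane (sigma ``gabrat_sigma_a``).  Each
    comparative metric is computed twice: against the surround annulus and
    against the whole background (all non-target pixels of the composited
    scene, so occluded background never contributes).
    """
    comp = scene.composited
    region = scene.mask_in_scene.region
    blen = body_length(scene.mask_in_scene)
    surround = surround_region(scene, cfg, body_len=blen)
    background = ~region
    if not background.any():
        raise MetricError("target fills the entire frame")

    ab = np.dstack([comp.A, comp.B])
    crab_l = comp.L[region]
    crab_ab = ab[region]
    scales = cfg.scales_for(comp.shape)
    crab_spec = pattern_energy_spectrum(comp.L, region, cfg, scales)

    out: dict[str, float] = {}
    for name, ref in (("surround", surround), ("background", background)):
        ref_spec = pattern_energy_spectrum(comp.L, ref, cfg, scales)
        out[f"lum_diff_{name}"] = luminance_dist_diff(
            crab_l, comp.L[ref], bins=cfg.lum_bins, value_range=cfg.lum_range
        )
        out[f"colour_map_diff_{name}"] = colour_map_diff(
            crab_ab, ab[ref], bins=cfg.colour_bins_per_axis, value_range=cfg.colour_range
        )
        out[f"colour_dist_{name}"] = colour_mean_dist(crab_ab, ab[ref])
        out[f"pattern_diff_{name}"] = pattern_energy_diff(crab_spec, ref_spec)

    return CamoProfile(
        gabrat_l=gabrat(
            comp.L, scene.mask_in_scene, cfg.gabrat_sigma_l, cfg.gabor_bandwidth, cfg.edge_energy_epsilon
        ),
        gabrat_a=gabrat(
            comp.A, scene.mask_in_scene, cfg.gabrat_sigma_a, cfg.gabor_bandwidth, cfg.edge_energy_epsilon
        ),
        crab_area=float(region.sum()),
        body_length=blen,
        **out,
    )
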