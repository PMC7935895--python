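"""Image calibration, CIELAB conversion, mask extraction, compositing and log IO.

Coordinate convention used throughout the package: 0-based pixel coordinates,
x increases rightwards (columns), y increases downwards (rows).  Rotations are
counter-clockwise, in degrees.  Arrays are indexed ``[row, col]`` i.e. ``[y, x]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import color, measure

__all__ = [
    "RawImage",
    "CalibrationStandard",
    "CalibratedImage",
    "TargetMask",
    "Scene",
    "CalibrationError",
    "MaskExtractionError",
    "CompositionError",
    "LogValidationError",
    "TIMEOUT_MS",
    "LOG_COLUMNS",
    "calibrate_reflectance",
    "srgb_to_cielab",
    "extract_mask",
    "compose_scene",
    "read_image",
    "read_gameplay_log",
    "write_gameplay_log",
    "validate_gameplay_log",
]

#: Hard ceiling on a single presentation: the game ends a slide after 15 s and
#: records it as a censored "timeout" at exactly this value (milliseconds).
TIMEOUT_MS = 15000

#: Required columns of a gameplay log, one row per crab presentation.
LOG_COLUMNS = [
    "session_id",
    "slide",
    "crab_id",
    "morph",
    "x",
    "y",
    "capture_ms",
    "timed_out",
    "played_before",
    "screen_scale",
    "crab_area",
]


class CalibrationError(ValueError):
    """Degenerate or inconsistent grey-standard measurements."""


class MaskExtractionError(ValueError):
    """Automatic target extraction failed (no target, or several candidates)."""


class CompositionError(ValueError):
    """Target cannot be placed on the background under the given constraints."""


class LogValidationError(ValueError):
    """A gameplay log violates the schema or the timeout bookkeeping rules."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class RawImage:
    """Camera image: 3-channel non-negative raster plus acquisition metadata.

    ``pixels`` holds digital numbers in ``[0, 2**bit_depth - 1]`` when
    ``units == "dn"`` or reflectance fractions in ``[0, 1]`` when
    ``units == "reflectance"``.  ``scale`` is pixels per mm, set once known.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    scale: float | None = None
    units: str = "dn"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) array")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if np.any(self.pixels < 0):
            raise ValueError("negative pixel intensities")
        hi = 1.0 if self.units == "reflectance" else 2.0**self.bit_depth - 1
        if np.any(self.pixels > hi + 1e-9):
            raise ValueError(f"pixel values exceed {self.units} range [0, {hi}]")
        if self.scale is not None and self.scale <= 0:
            raise ValueError("scale (px/mm) must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class CalibrationStandard:
    """Two-point grey standard: known reflectances and their measured pixel means.

    The field standard reflects a known low and high fraction of incident light
    (7% and 93% for the standard used in the crab photography); ``low_pixel`` and
    ``high_pixel`` are the mean digital numbers measured on those patches in the
    same frame being calibrated.
    """

    low_reflectance: float = 0.07
    high_reflectance: float = 0.93
    low_pixel: float = 0.0
    high_pixel: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.low_reflectance < self.high_reflectance < 1.0):
            raise CalibrationError("need 0 < low_reflectance < high_reflectance < 1")
        if not self.low_pixel < self.high_pixel:
            raise CalibrationError("need low_pixel < high_pixel (distinct patches)")


@dataclass
class CalibratedImage:
    """Image in CIELAB with per-channel planes and a pixel/mm scale.

    Invariants: ``L`` in [0, 100]; ``A`` and ``B`` in [-128, 127].
    """

    L: np.ndarray
    A: np.ndarray
    B: np.ndarray
    scale: float | None = None

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if not (self.L.shape == self.A.shape == self.B.shape):
            raise ValueError("L, A, B planes must share a shape")
        if np.any(self.L < -1e-6) or np.any(self.L > 100 + 1e-6):
            raise ValueError("L plane outside [0, 100]")
        if np.any(np.abs(self.A) > 128 + 1e-6) or np.any(np.abs(self.B) > 128 + 1e-6):
            raise ValueError("A/B planes outside [-128, 127]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.L.shape

    def stack(self) -> np.ndarray:
        """(H, W, 3) LAB stack."""
        return np.dstack([self.L, self.A, self.B])


@dataclass
class TargetMask:
    """Binary target region with a feathered alpha edge and an outline trace.

    ``region`` is the hard mask (single connected component), ``alpha`` the
    fractional coverage used for blending (1 strictly inside, 0 strictly
    outside, intermediate over a narrow feather band), ``outline`` an ordered
    closed trace of (x, y) sub-pixel boundary points.
    """

    region: np.ndarray
    alpha: np.ndarray
    outline: np.ndarray

    def __post_init__(self) -> None:
        self.region = np.asarray(self.region, dtype=bool)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.outline = np.asarray(self.outline, dtype=float)
        if self.region.shape != self.alpha.shape:
            raise ValueError("region and alpha must share a shape")
        if np.any(self.alpha < 0) or np.any(self.alpha > 1):
            raise ValueError("alpha must lie in [0, 1]")
        if self.outline.ndim != 2 or self.outline.shape[1] != 2:
            raise ValueError("outline must be an (N, 2) array of (x, y)")

    @property
    def area(self) -> int:
        return int(self.region.sum())


@dataclass
class Scene:
    """A target composited onto a background at a given position and rotation."""

    background: CalibratedImage
    target: CalibratedImage
    target_mask: TargetMask
    position: tuple[float, float]
    rotation: float
    composited: CalibratedImage = field(repr=False)
    mask_in_scene: TargetMask = field(repr=False)


# ---------------------------------------------------------------------------
# calibration and colour conversion
# ---------------------------------------------------------------------------


def calibrate_reflectance(raw: RawImage, std: CalibrationStandard) -> RawImage:
    """Linearly map digital numbers to reflectance using a two-point grey standard.

    The map sends ``low_pixel -> low_reflectance`` and ``high_pixel ->
    high_reflectance`` and is applied identically to all three channels (the
    standard is spectrally flat).  Output is clipped to [0, 1].
    """
    span = std.high_pixel - std.low_pixel
    if span <= 0:
        raise CalibrationError("calibration standard pixel values are degenerate")
    gain = (std.high_reflectance - std.low_reflectance) / span
    refl = std.low_reflectance + (raw.pixels - std.low_pixel) * gain
    refl = np.clip(refl, 0.0, 1.0)
    return RawImage(pixels=refl, bit_depth=raw.bit_depth, scale=raw.scale, units="reflectance")


def srgb_to_cielab(raw: RawImage) -> CalibratedImage:
    """Convert an sRGB raster to CIELAB (D65 white point, 2 degree observer)."""
    if raw.units == "reflectance":
        rgb = raw.pixels
    else:
        rgb = raw.pixels / (2.0**raw.bit_depth - 1)
    lab = color.rgb2lab(rgb, illuminant="D65", observer="2")
    lab[..., 1:] = np.clip(lab[..., 1:], -128.0, 127.0)
    return CalibratedImage(L=lab[..., 0], A=lab[..., 1], B=lab[..., 2], scale=raw.scale)


def cielab_to_srgb(img: CalibratedImage) -> np.ndarray:
    """Inverse conversion back to sRGB in [0, 1] (for display / PNG export)."""
    lab = img.stack()
    rgb = color.lab2rgb(lab, illuminant="D65", observer="2")
    return np.clip(rgb, 0.0, 1.0)


def read_image(path: str | Path, scale: float | None = None, bit_depth: int | None = None) -> RawImage:
    """Read a PNG (8- or 16-bit RGB) into a :class:`RawImage`."""
    px = iio.imread(path)
    if px.ndim == 2:
        px = np.dstack([px] * 3)
    if px.shape[2] == 4:
        px = px[..., :3]
    if bit_depth is None:
        bit_depth = 16 if px.dtype == np.uint16 else 8
    return RawImage(pixels=px.astype(float), bit_depth=bit_depth, scale=scale)


# ---------------------------------------------------------------------------
# mask extraction
# ---------------------------------------------------------------------------

# Complementary connectivity avoids topological leaks: 4-connected background
# flood cannot slip diagonally through an 8-connected foreground boundary.
_BG_STRUCTURE = ndimage.generate_binary_structure(2, 1)  # 4-connected
_FG_STRUCTURE = ndimage.generate_binary_structure(2, 2)  # 8-connected


def _feather_alpha(region: np.ndarray, feather_px: float) -> np.ndarray:
    """Fractional coverage from a signed sub-pixel distance to the region edge."""
    inside = ndimage.distance_transform_edt(region)
    outside = ndimage.distance_transform_edt(~region)
    signed = np.where(region, inside - 0.5, -(outside - 0.5))
    return np.clip(0.5 + signed / max(feather_px, 1e-9), 0.0, 1.0)


def _trace_outline(region: np.ndarray) -> np.ndarray:
    """Longest closed iso-contour of the region, as (x, y) sub-pixel points."""
    contours = measure.find_contours(region.astype(float), 0.5)
    if not contours:
        raise MaskExtractionError("region has no traceable outline")
    rc = max(contours, key=len)
    if np.allclose(rc[0], rc[-1]):
        rc = rc[:-1]
    return rc[:, ::-1].copy()  # (row, col) -> (x, y)


def mask_from_region(region: np.ndarray, feather_px: float = 1.5) -> TargetMask:
    """Build a :class:`TargetMask` (alpha + outline) from a hard binary region."""
    region = np.asarray(region, dtype=bool)
    if region.sum() == 0:
        raise MaskExtractionError("empty region")
    return TargetMask(region=region, alpha=_feather_alpha(region, feather_px), outline=_trace_outline(region))


def extract_mask(
    photo_on_grey: CalibratedImage,
    threshold: float = 8.0,
    feather_px: float = 1.5,
    min_area_frac: float = 0.001,
) -> TargetMask:
    """Segment a target photographed on a uniform grey field ("autocrab" step).

    The border grey level is estimated from the frame edge of the L plane;
    pixels within ``threshold`` L units of it are background candidates.  The
    true background is whatever candidate region is reachable by 4-connected
    flood fill from the frame border, so interior patches that happen to match
    the grey are kept as part of the target (holes filled by construction).

    Raises :class:`MaskExtractionError` when zero or more than one large
    foreground component remains — the manual-cleanup case.
    """
    lum = photo_on_grey.L
    border = np.concatenate([lum[0, :], lum[-1, :], lum[1:-1, 0], lum[1:-1, -1]])
    grey = float(np.median(border))
    candidate_bg = np.abs(lum - grey) <= threshold

    labels, _ = ndimage.label(candidate_bg, structure=_BG_STRUCTURE)
    edge_labels = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[1:-1, 0], labels[1:-1, -1]])
    )
    background = np.isin(labels, edge_labels[edge_labels > 0])
    region = ~background

    fg_labels, n_fg = ndimage.label(region, structure=_FG_STRUCTURE)
    if n_fg == 0:
        raise MaskExtractionError("no foreground found on the grey field")
    sizes = ndimage.sum_labels(np.ones_like(fg_labels), fg_labels, index=np.arange(1, n_fg + 1))
    min_area = min_area_frac * lum.size
    large = np.flatnonzero(sizes >= min_area) + 1
    if len(large) == 0:
        raise MaskExtractionError("no foreground component above the size floor")
    if len(large) > 1:
        raise MaskExtractionError(
            f"{len(large)} large foreground components; needs manual clean-up"
        )
    region = fg_labels == large[0]
    return mask_from_region(region, feather_px=feather_px)


# ---------------------------------------------------------------------------
# compositing
# ---------------------------------------------------------------------------


def _rotate_target(
    target: CalibratedImage, mask: TargetMask, rotation_deg: float
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate LAB planes and alpha together (bilinear, alpha-premultiplied)."""
    alpha = mask.alpha
    if rotation_deg % 360 == 0:
        return target.stack(), alpha
    planes = target.stack() * alpha[..., None]
    rot_planes = np.dstack(
        [
            ndimage.rotate(planes[..., i], rotation_deg, reshape=True, order=1, cval=0.0)
            for i in range(3)
        ]
    )
    rot_alpha = np.clip(ndimage.rotate(alpha, rotation_deg, reshape=True, order=1, cval=0.0), 0.0, 1.0)
    safe = np.maximum(rot_alpha, 1e-9)[..., None]
    lab = rot_planes / safe
    lab[..., 0] = np.clip(lab[..., 0], 0.0, 100.0)
    lab[..., 1:] = np.clip(lab[..., 1:], -128.0, 127.0)
    lab[rot_alpha == 0] = 0.0
    return lab, rot_alpha


def compose_scene(
    background: CalibratedImage,
    target: CalibratedImage,
    target_mask: TargetMask,
    position: tuple[float, float] | None = None,
    rotation_deg: float | None = None,
    rng: np.random.Generator | None = None,
    feather_px: float = 1.5,
) -> Scene:
    """Alpha-blend a rotated target onto a background at natural size.

    ``position`` is the (x, y) pixel centre of the placed target; when it or
    ``rotation_deg`` is omitted they are drawn uniformly (rotation over
    [0, 360), position over all placements that keep the target fully inside
    the frame) using ``rng``.  Background pixels outside the alpha support are
    left bit-identical.
    """
    if background.scale is not None and target.scale is not None:
        if not np.isclose(background.scale, target.scale, rtol=1e-6):
            raise CompositionError(
                f"pixel/mm scales differ (bg {background.scale}, target {target.scale})"
            )
    if rng is None:
        rng = np.random.default_rng()
    if rotation_deg is None:
        rotation_deg = float(rng.uniform(0.0, 360.0))

    lab, alpha = _rotate_target(target, target_mask, rotation_deg)
    th, tw = alpha.shape
    bh, bw = background.shape
    if th > bh or tw > bw:
        raise CompositionError("rotated target larger than the background")

    if position is None:
        # centre offset from the top-left paste corner
        x = float(rng.integers(0, bw - tw + 1)) + (tw - 1) / 2.0
        y = float(rng.integers(0, bh - th + 1)) + (th - 1) / 2.0
        position = (x, y)
    x, y = position
    top = int(round(y - (th - 1) / 2.0))
    left = int(round(x - (tw - 1) / 2.0))
    if top < 0 or left < 0 or top + th > bh or left + tw > bw:
        raise CompositionError(f"target does not fit at position {position}")

    comp = background.stack().copy()
    window = comp[top : top + th, left : left + tw]
    window += alpha[..., None] * (lab - window)

    full_alpha = np.zeros((bh, bw))
    full_alpha[top : top + th, left : left + tw] = alpha
    region = full_alpha > 0.5
    scene_mask = TargetMask(region=region, alpha=full_alpha, outline=_trace_outline(region))

    composited = CalibratedImage(
        L=comp[..., 0], A=comp[..., 1], B=comp[..., 2], scale=background.scale
    )
    return Scene(
        background=background,
        target=target,
        target_mask=target_mask,
        position=(float(x), float(y)),
        rotation=float(rotation_deg),
        composited=composited,
        mask_in_scene=scene_mask,
    )


# ---------------------------------------------------------------------------
# gameplay logs
# ---------------------------------------------------------------------------


def validate_gameplay_log(log: pd.DataFrame) -> pd.DataFrame:
    """Check schema and timeout bookkeeping of a gameplay log; return it."""
    missing = [c for c in LOG_COLUMNS if c not in log.columns]
    if missing:
        raise LogValidationError(f"missing columns: {missing}")
    if len(log) == 0:
        return log
    if (log["capture_ms"] > TIMEOUT_MS).any():
        raise LogValidationError(f"capture_ms above the {TIMEOUT_MS} ms ceiling")
    if (log["capture_ms"] <= 0).any():
        raise LogValidationError("non-positive capture_ms")
    timed_out = log["timed_out"].astype(bool)
    if (log.loc[timed_out, "capture_ms"] != TIMEOUT_MS).any():
        raise LogValidationError(f"timed-out rows must have capture_ms == {TIMEOUT_MS}")
    return log


def write_gameplay_log(records: pd.DataFrame, path: str | Path) -> None:
    """Write a validated gameplay log as CSV (lossless round-trip)."""
    validate_gameplay_log(records)
    records.to_csv(path, index=False)


def read_gameplay_log(path: str | Path) -> pd.DataFrame:
    """Read and validate a gameplay-log CSV; an empty file yields an empty log."""
    try:
        log = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"empty gameplay log: {path}", stacklevel=2)
        return pd.DataFrame(columns=LOG_COLUMNS)
    log["timed_out"] = log["timed_out"].astype(bool) if "timed_out" in log else False
    return validate_gameplay_log(log)
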