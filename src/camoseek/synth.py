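"""Synthetic imagery and gameplay with known ground truth.

Generates everything the pipeline consumes without any external data:
spectrally shaped background textures, parametric crab-like targets in six
morph classes (differing in lightness, hue, marking style and pattern grain),
full catalogs, and gameplay logs drawn from a known hazard model — so metric
behaviour and model parameter recovery can be tested end to end.

Crabs are parametric shapes (Fourier-perturbed discs with simple marking
textures), not photo-realistic animals; the point is controlled structure in
colour, luminance, pattern and edge disruption.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

from .image_io import CalibratedImage, TargetMask, compose_scene, mask_from_region, write_gameplay_log
from .metrics import MetricConfig, camo_profile
from .game import (
    MORPHS,
    Catalog,
    GameConfig,
    HazardParams,
    generate_sessions,
    simulate_observer,
)

__all__ = [
    "BackgroundGeneratorParams",
    "CrabGeneratorParams",
    "MORPH_PARAMS",
    "DEFAULT_MORPH_MIX",
    "make_background",
    "make_crab",
    "make_catalog",
    "make_gameplay_dataset",
    "default_hazard_params",
]

#: Morph composition of the crab image catalog.
DEFAULT_MORPH_MIX = {
    "Black": 22,
    "Disruptive": 15,
    "Green": 50,
    "Mottled": 28,
    "Pale": 20,
    "Spotted": 20,
}


@dataclass(frozen=True)
class BackgroundGeneratorParams:
    """Natural-texture stand-in: 1/f^slope broadband noise plus a narrowband
    "grain" component of dominant spatial wavelength ``dominant_grain`` px.

    ``lum_amplitude`` scales the L-channel texture SD (CIELAB units);
    ``colour_jitter_sd`` scales chromatic (A, B) texture.  ``grain_strength``
    is the fraction of luminance texture carried by the narrowband grain.
    """

    base_colour: tuple[float, float, float] = (55.0, -8.0, 12.0)
    spectrum_slope: float = 1.0
    dominant_grain: float = 8.0
    lum_amplitude: float = 8.0
    grain_strength: float = 0.8
    colour_jitter_sd: float = 4.0

    def __post_init__(self) -> None:
        if self.dominant_grain < 1:
            raise ValueError("dominant grain must be >= 1 px")


@dataclass(frozen=True)
class CrabGeneratorParams:
    """Parametric crab target.

    ``irregularity`` perturbs the disc outline with low-order Fourier modes;
    ``marking_style`` is one of none / blotch-interior / bars-crossing-outline
    / spots; ``marking_contrast`` is the L-channel amplitude of the markings
    and ``marking_scale`` their characteristic size in px.
    """

    body_radius: float = 40.0
    irregularity: float = 0.08
    base_colour: tuple[float, float, float] = (50.0, -5.0, 10.0)
    marking_style: str = "none"
    marking_contrast: float = 0.0
    marking_scale: float = 8.0

    def __post_init__(self) -> None:
        if self.marking_style not in ("none", "blotch-interior", "bars-crossing-outline", "spots"):
            raise ValueError(f"unknown marking style {self.marking_style!r}")
        if self.marking_contrast < 0:
            raise ValueError("marking contrast must be >= 0")
        if self.body_radius <= self.marking_scale:
            raise ValueError("body radius must exceed marking scale")


#: Per-morph generator distributions.  Centre values chosen so the morph label
#: predicts the profile metrics: Pale = high L / low contrast; Black = low L;
#: Green = background-like hue; Disruptive = high-contrast bars crossing the
#: outline; Mottled = interior blotches; Spotted = small spots.
MORPH_PARAMS: dict[str, dict] = {
    "Black": dict(base_l=22.0, base_a=2.0, base_b=4.0, style="none", contrast=2.0, scale=8.0),
    # disruptive morphs match the substrate in base lightness (weak "true"
    # boundary edge) and carry strong bars across the outline
    "Disruptive": dict(base_l=55.0, base_a=-6.0, base_b=10.0, style="bars-crossing-outline", contrast=30.0, scale=5.0),
    "Green": dict(base_l=34.0, base_a=-16.0, base_b=18.0, style="none", contrast=3.0, scale=8.0),
    "Mottled": dict(base_l=38.0, base_a=-6.0, base_b=10.0, style="blotch-interior", contrast=14.0, scale=12.0),
    "Pale": dict(base_l=78.0, base_a=-2.0, base_b=8.0, style="none", contrast=2.0, scale=8.0),
    "Spotted": dict(base_l=36.0, base_a=-6.0, base_b=10.0, style="spots", contrast=18.0, scale=5.0),
}


# ---------------------------------------------------------------------------
# textures
# ---------------------------------------------------------------------------


def _powerlaw_noise(shape: tuple[int, int], slope: float, rng: np.random.Generator) -> np.ndarray:
    """Real noise field with isotropic amplitude spectrum ~ 1/f^slope, unit SD."""
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    f = np.hypot(fy, fx)
    amp = np.zeros_like(f)
    nz = f > 0
    amp[nz] = f[nz] ** (-slope)
    spectrum = np.fft.fft2(rng.standard_normal(shape)) * amp
    field_ = np.real(np.fft.ifft2(spectrum))
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def _grain_noise(shape: tuple[int, int], grain: float, rng: np.random.Generator) -> np.ndarray:
    """Narrowband noise with dominant spatial wavelength ``grain`` px, unit SD.

    Uses a narrow difference-of-Gaussians (sigma ratio 1.25) with
    ``sigma = grain / 4``: integrating the squared band responses over the 2-D
    frequency plane, white noise shaped this way deposits its maximum
    granularity energy in the analysis band labelled ``grain`` across the
    dyadic ladder (the admissible sigma range is roughly 0.2-0.3 grain; the
    midpoint is used).
    """
    s = grain / 4.0
    white = rng.standard_normal(shape)
    band = ndimage.gaussian_filter(white, s, mode="wrap") - ndimage.gaussian_filter(
        white, 1.25 * s, mode="wrap"
    )
    sd = band.std()
    return band / sd if sd > 0 else band


def make_background(
    params: BackgroundGeneratorParams = BackgroundGeneratorParams(),
    size: tuple[int, int] = (600, 800),
    rng: np.random.Generator | None = None,
    scale: float = 1.0,
) -> CalibratedImage:
    """Generate a CIELAB background texture (size = (height, width))."""
    if min(size) <= 2 * params.dominant_grain:
        raise ValueError("image must be larger than twice the dominant grain")
    if rng is None:
        rng = np.random.default_rng()
    base_l, base_a, base_b = params.base_colour

    lum = np.zeros(size)
    if params.lum_amplitude > 0:
        broad = (1.0 - params.grain_strength) * _powerlaw_noise(size, params.spectrum_slope, rng)
        grain = params.grain_strength * _grain_noise(size, params.dominant_grain, rng)
        tex = broad + grain
        sd = tex.std()
        if sd > 0:
            lum = params.lum_amplitude * tex / sd
    A = np.full(size, base_a)
    B = np.full(size, base_b)
    if params.colour_jitter_sd > 0:
        A = A + params.colour_jitter_sd * _grain_noise(size, params.dominant_grain, rng)
        B = B + params.colour_jitter_sd * _grain_noise(size, params.dominant_grain, rng)
    return CalibratedImage(
        L=np.clip(base_l + lum, 0.0, 100.0),
        A=np.clip(A, -100.0, 100.0),
        B=np.clip(B, -100.0, 100.0),
        scale=scale,
    )


# ---------------------------------------------------------------------------
# crabs
# ---------------------------------------------------------------------------


def _crab_region(params: CrabGeneratorParams, rng: np.random.Generator, canvas: int) -> np.ndarray:
    """Rasterise a Fourier-perturbed disc outline into a boolean region."""
    theta = np.linspace(0.0, 2.0 * np.pi, 720, endpoint=False)
    radius = np.full_like(theta, params.body_radius)
    if params.irregularity > 0:
        for k in range(2, 6):
            amp = params.irregularity * params.body_radius * rng.normal(0.0, 1.0 / k)
            radius = radius + amp * np.cos(k * theta + rng.uniform(0.0, 2.0 * np.pi))
        radius = np.clip(radius, 0.3 * params.body_radius, 0.49 * canvas)
    c = canvas / 2.0
    rows = c + radius * np.sin(theta)
    cols = c + radius * np.cos(theta)
    rr, cc = draw_polygon(rows, cols, shape=(canvas, canvas))
    region = np.zeros((canvas, canvas), dtype=bool)
    region[rr, cc] = True
    return ndimage.binary_fill_holes(region)


def _marking_field(
    params: CrabGeneratorParams, region: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Signed L-channel marking texture in [-1, 1] for the chosen style."""
    canvas = region.shape[0]
    style = params.marking_style
    if style == "none" or params.marking_contrast == 0:
        return np.zeros(region.shape)
    if style == "bars-crossing-outline":
        # hard-edged stripes across the whole body, crossing the outline
        ang = rng.uniform(0.0, np.pi)
        yy, xx = np.mgrid[0:canvas, 0:canvas]
        coord = xx * np.cos(ang) + yy * np.sin(ang)
        return np.sign(np.sin(np.pi * coord / params.marking_scale))
    if style == "blotch-interior":
        # low-frequency blobs kept away from the outline
        noise = ndimage.gaussian_filter(rng.standard_normal(region.shape), params.marking_scale / 2.0)
        blotch = np.where(noise > 0, 1.0, -1.0)
        interior = ndimage.binary_erosion(region, iterations=int(round(params.marking_scale)))
        return blotch * interior
    # spots: small discs at random interior centres
    spots = np.zeros(region.shape)
    interior = ndimage.binary_erosion(region, iterations=int(round(params.marking_scale)))
    coords = np.argwhere(interior)
    n_spots = max(3, int(region.sum() / (8.0 * params.marking_scale**2)))
    if len(coords) == 0:
        return spots
    yy, xx = np.mgrid[0:canvas, 0:canvas]
    for r, c in coords[rng.integers(len(coords), size=n_spots)]:
        spots[(yy - r) ** 2 + (xx - c) ** 2 <= (params.marking_scale / 2.0) ** 2] = 1.0
    return spots


def make_crab(
    params: CrabGeneratorParams = CrabGeneratorParams(),
    rng: np.random.Generator | None = None,
    scale: float = 1.0,
    feather_px: float = 1.5,
) -> tuple[CalibratedImage, TargetMask]:
    """Generate one crab cutout: CIELAB planes plus its target mask."""
    if rng is None:
        rng = np.random.default_rng()
    canvas = int(np.ceil(params.body_radius * 2.6)) | 1
    region = _crab_region(params, rng, canvas)
    mask = mask_from_region(region, feather_px=feather_px)

    # base colour painted across the whole canvas so the feathered alpha band
    # blends body colour, not black, just outside the hard region
    base_l, base_a, base_b = params.base_colour
    marks = _marking_field(params, region, rng) * params.marking_contrast
    L = np.clip(base_l + marks, 0.0, 100.0)
    A = base_a + 0.15 * marks
    B = base_b + 0.15 * marks
    img = CalibratedImage(L=L, A=np.clip(A, -100, 100), B=np.clip(B, -100, 100), scale=scale)
    return img, mask


# ---------------------------------------------------------------------------
# catalogs and gameplay
# ---------------------------------------------------------------------------


def _sample_crab_params(morph: str, rng: np.random.Generator, body_radius: float) -> CrabGeneratorParams:
    p = MORPH_PARAMS[morph]
    return CrabGeneratorParams(
        body_radius=body_radius * rng.uniform(0.85, 1.15),
        irregularity=rng.uniform(0.04, 0.12),
        base_colour=(
            float(np.clip(p["base_l"] + rng.normal(0, 4.0), 5, 95)),
            float(p["base_a"] + rng.normal(0, 2.0)),
            float(p["base_b"] + rng.normal(0, 2.0)),
        ),
        marking_style=p["style"],
        marking_contrast=max(0.0, p["contrast"] * rng.uniform(0.7, 1.3)),
        marking_scale=min(p["scale"] * rng.uniform(0.8, 1.2), 0.45 * body_radius),
    )


def make_catalog(
    n_crabs: int = 155,
    n_backgrounds: int = 105,
    morph_mix: dict[str, int] | None = None,
    rng: np.random.Generator | None = None,
    background_params: BackgroundGeneratorParams = BackgroundGeneratorParams(),
    image_size: tuple[int, int] = (600, 800),
    body_radius: float = 40.0,
    metric_cfg: MetricConfig = MetricConfig(),
    store_images: bool = False,
) -> Catalog:
    """Build a catalog of synthetic crabs with image-derived camouflage profiles.

    Each crab is generated from its morph's parameter distribution, composited
    once (random position/rotation) onto a randomly drawn generated background,
    and measured with the full metric battery; those profile metrics are the
    per-crab summaries the game simulation uses.  Morph counts default to the
    catalog composition 22/15/50/28/20/20 (n_crabs must match their total).
    """
    if morph_mix is None:
        morph_mix = dict(DEFAULT_MORPH_MIX)
        if n_crabs != sum(morph_mix.values()):
            # scale the default mix down proportionally, preserving >= 1 per morph
            total = sum(morph_mix.values())
            morph_mix = {m: max(1, round(c * n_crabs / total)) for m, c in morph_mix.items()}
            drift = n_crabs - sum(morph_mix.values())
            morph_mix["Green"] += drift
    if sum(morph_mix.values()) != n_crabs:
        raise ValueError(f"morph mix sums to {sum(morph_mix.values())}, expected {n_crabs}")
    if rng is None:
        rng = np.random.default_rng()

    backgrounds = [
        make_background(background_params, size=image_size, rng=rng) for _ in range(n_backgrounds)
    ]

    rows = []
    images = {}
    crab_no = 0
    for morph in MORPHS:
        for _ in range(morph_mix.get(morph, 0)):
            cid = f"crab{crab_no:03d}"
            crab_no += 1
            params = _sample_crab_params(morph, rng, body_radius)
            img, mask = make_crab(params, rng)
            bg = backgrounds[rng.integers(len(backgrounds))]
            scene = compose_scene(bg, img, mask, rng=rng)
            profile = camo_profile(scene, metric_cfg)
            row = {"crab_id": cid, "morph": morph, **profile.to_dict()}
            rows.append(row)
            if store_images:
                images[cid] = (img, mask)
    crabs = pd.DataFrame(rows).set_index("crab_id")
    catalog = Catalog(crabs=crabs, backgrounds=[f"bg{i:03d}" for i in range(n_backgrounds)])
    if store_images:
        catalog.images = images  # type: ignore[attr-defined]
        catalog.background_images = backgrounds  # type: ignore[attr-defined]
    return catalog


def default_hazard_params() -> HazardParams:
    """Hazard parameterisation used for the study-condition simulations.

    Directions mirror the study system: both GabRat channels lower the
    detection hazard (disruption protects); colour and luminance mismatch
    raise it (poor matching exposes); encounters raise it (search image);
    the chromatic-disruption and colour-match interactions with encounters
    are negative (good camouflage slows search-image formation); morph
    switches transiently lower it.  Magnitudes are set to give capture-time
    medians of a few seconds and a timeout fraction of a few percent under
    the default generators.
    """
    return HazardParams(
        baseline=-8.2,
        metric_coefs={
            "gabrat_l": -1.5,
            "gabrat_a": -1.0,
            "colour_dist_surround": 0.03,
            "lum_diff_surround": 0.3,
        },
        encounters_coef=0.05,
        interaction_coefs={"gabrat_a": -0.08, "colour_dist_surround": -0.002},
        morph_switch_penalty=-0.15,
        session_sd=0.25,
    )


def make_gameplay_dataset(
    catalog: Catalog,
    params: HazardParams | None = None,
    n_sessions: int = 100,
    game_cfg: GameConfig = GameConfig(),
    rng: np.random.Generator | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate gameplay and return (log, truth record of generating parameters).

    When ``out_dir`` is given, writes ``gameplay.csv`` and ``truth.json``.
    """
    if params is None:
        params = default_hazard_params()
    if rng is None:
        rng = np.random.default_rng()
    sessions = generate_sessions(catalog, n_sessions, game_cfg, rng)
    log = simulate_observer(sessions, catalog.crabs.drop(columns=["morph"]), params, rng)

    truth = {
        "hazard_params": {
            "baseline": params.baseline,
            "metric_coefs": dict(params.metric_coefs),
            "encounters_coef": params.encounters_coef,
            "interaction_coefs": dict(params.interaction_coefs),
            "novelty_coefs": dict(params.novelty_coefs),
            "morph_switch_penalty": params.morph_switch_penalty,
            "session_sd": params.session_sd,
            "weibull_shape": params.weibull_shape,
        },
        "n_sessions": n_sessions,
        "n_slides": game_cfg.n_slides,
        "repeat_p": game_cfg.repeat_p,
        "n_crabs": len(catalog.crabs),
        "n_presentations": len(log),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_gameplay_log(log, out_dir / "gameplay.csv")
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=2))
    return log, truth
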