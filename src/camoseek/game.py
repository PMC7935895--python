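"""Search-image game simulation.

The game shows one camouflaged crab per slide, 24 slides per session.  The
sequencing rule that creates search-image pressure is simple: with probability
0.8 the next slide repeats the same individual crab phenotype (against a fresh
random background, position and rotation); otherwise a different crab is drawn.
This yields runs of the same phenotype (median run length around 5) punctuated
by switch events, which may or may not also switch the broad morph category.

A synthetic observer turns a sequence into capture times via a proportional-
hazards model on the log detection hazard: camouflage metrics slow detection,
accumulated encounters with the current phenotype (the forming search image)
speed it up, metric-by-encounters interactions let camouflage modulate search
image formation, and a morph-switch penalty makes cross-morph switches harder.
Searches exceeding 15 s are censored as timeouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .image_io import TIMEOUT_MS

__all__ = [
    "MORPHS",
    "Catalog",
    "HazardParams",
    "GameConfig",
    "SimulationError",
    "generate_session",
    "generate_sessions",
    "simulate_sequences",
    "run_length_stats",
    "run_length_pmf",
    "simulate_observer",
]

#: The six broad appearance categories.
MORPHS = ("Black", "Disruptive", "Green", "Mottled", "Pale", "Spotted")


class SimulationError(ValueError):
    """Raised for impossible sequencing or non-finite hazards."""


@dataclass
class Catalog:
    """Crab and background inventory for the game.

    ``crabs`` is a DataFrame indexed by ``crab_id`` with a ``morph`` column and
    one column per camouflage-profile metric; ``backgrounds`` a list of
    background ids.
    """

    crabs: pd.DataFrame
    backgrounds: list

    def __post_init__(self) -> None:
        if len(self.crabs) < 1 or len(self.backgrounds) < 1:
            raise SimulationError("catalog needs at least one crab and one background")
        bad = set(self.crabs["morph"]) - set(MORPHS)
        if bad:
            raise SimulationError(f"unknown morph labels: {sorted(bad)}")

    @property
    def crab_ids(self) -> np.ndarray:
        return self.crabs.index.to_numpy()


@dataclass
class GameConfig:
    """Presentation geometry of the game screen."""

    n_slides: int = 24
    repeat_p: float = 0.8
    screen_w: int = 800
    screen_h: int = 600
    margin: int = 60
    #: per-session display scaling factor range (participants play on screens
    #: of different resolutions; drawn uniformly per session)
    screen_scale_range: tuple[float, float] = (0.8, 1.3)


@dataclass
class HazardParams:
    """Synthetic-observer parameterisation of the detection log-hazard.

    The hazard of finding the crab (per millisecond) is
    ``exp(baseline + sum beta_m * metric + beta_e * encounters
    + sum gamma_m * metric * encounters + morph-switch penalty + session intercept)``.

    Defaults give a median capture time of roughly 2-4 s and a timeout fraction
    of a few percent, with effect directions mirroring the study system: edge
    disruption and colour/luminance mismatch scale detection in opposite
    directions (better camouflage -> lower hazard), encounters raise the hazard
    (search-image formation), negative interactions make good camouflage slow
    search-image formation, and a morph switch transiently lowers the hazard.
    """

    baseline: float = -8.2
    metric_coefs: dict[str, float] = field(default_factory=dict)
    encounters_coef: float = 0.05
    interaction_coefs: dict[str, float] = field(default_factory=dict)
    morph_switch_penalty: float = 0.0
    #: hazard terms ``coef * metric * novel_crab``: lets a metric's effect
    #: differ at switch slides (encounters = 0) from within-run slides
    novelty_coefs: dict[str, float] = field(default_factory=dict)
    session_sd: float = 0.25
    weibull_shape: float = 1.0
    #: per-presentation metric variation, as a fraction of each metric's
    #: between-crab SD: every slide re-composites the crab on a fresh
    #: background/position/rotation, so its measured camouflage fluctuates
    #: around the crab's catalog summary
    presentation_jitter_frac: float = 0.15

    def __post_init__(self) -> None:
        if self.session_sd < 0:
            raise SimulationError("session_sd must be >= 0")
        if self.weibull_shape <= 0:
            raise SimulationError("weibull_shape must be positive")


# ---------------------------------------------------------------------------
# sequence generation
# ---------------------------------------------------------------------------


def _sequence_indices(n_crabs: int, n_slides: int, repeat_p: float, rng: np.random.Generator) -> np.ndarray:
    """Crab index per slide under the repeat-with-probability-p rule."""
    if not 0.0 <= repeat_p <= 1.0:
        raise SimulationError("repeat_p must lie in [0, 1]")
    if n_crabs < 2 and repeat_p < 1.0:
        raise SimulationError("switching requires at least two crabs in the catalog")
    idx = np.empty(n_slides, dtype=int)
    idx[0] = rng.integers(n_crabs)
    repeats = rng.random(n_slides - 1) < repeat_p
    for i in range(1, n_slides):
        if repeats[i - 1]:
            idx[i] = idx[i - 1]
        else:
            j = rng.integers(n_crabs - 1)  # uniform over the *other* crabs
            idx[i] = j if j < idx[i - 1] else j + 1
    return idx


def simulate_sequences(
    n_crabs: int,
    n_sessions: int,
    n_slides: int = 24,
    repeat_p: float = 0.8,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Crab-index matrix (n_sessions, n_slides) under the repeat rule.

    Lean batch path for sequence-law studies (switch rates, run lengths)
    that skips the per-slide presentation bookkeeping.
    """
    if rng is None:
        rng = np.random.default_rng()
    return np.vstack(
        [_sequence_indices(n_crabs, n_slides, repeat_p, rng) for _ in range(n_sessions)]
    )


def generate_session(
    catalog: Catalog,
    session_id,
    cfg: GameConfig = GameConfig(),
    rng: np.random.Generator | None = None,
    played_before: bool = False,
    screen_scale: float | None = None,
) -> pd.DataFrame:
    """Generate one session's presentation sequence (no capture times yet).

    Slide 1 draws a crab uniformly; each later slide repeats the previous
    phenotype with probability ``repeat_p``, else draws uniformly among the
    other crabs.  Background, position and rotation are redrawn every slide.
    ``encounters`` counts all prior presentations of the slide's phenotype
    within the session; ``novel_crab`` flags a phenotype different from the
    previous slide; ``morph_switch`` labels each slide with the type of the
    most recent phenotype switch (1.0 = the run in progress began with a
    cross-morph switch, 0.0 = same-morph switch, NaN = no switch yet this
    session).
    """
    if rng is None:
        rng = np.random.default_rng()
    if screen_scale is None:
        screen_scale = float(rng.uniform(*cfg.screen_scale_range))
    ids = catalog.crab_ids
    idx = _sequence_indices(len(ids), cfg.n_slides, cfg.repeat_p, rng)
    crab_ids = ids[idx]
    morphs = catalog.crabs["morph"].to_numpy()[idx]

    seen: dict = {}
    encounters = np.empty(cfg.n_slides, dtype=int)
    for i, cid in enumerate(crab_ids):
        encounters[i] = seen.get(cid, 0)
        seen[cid] = encounters[i] + 1

    novel = np.ones(cfg.n_slides, dtype=bool)
    novel[1:] = crab_ids[1:] != crab_ids[:-1]
    # morph_switch classifies the most recent phenotype-switch event (was it to
    # a different morph?) and carries that label through the following run;
    # slides before the session's first switch have no label (NaN)
    morph_switch = np.full(cfg.n_slides, np.nan)
    current = np.nan
    for i in range(1, cfg.n_slides):
        if novel[i]:
            current = float(morphs[i] != morphs[i - 1])
        morph_switch[i] = current

    n = cfg.n_slides
    return pd.DataFrame(
        {
            "session_id": session_id,
            "slide": np.arange(1, n + 1),
            "crab_id": crab_ids,
            "morph": morphs,
            "background_id": rng.choice(catalog.backgrounds, size=n),
            "x": rng.uniform(cfg.margin, cfg.screen_w - cfg.margin, size=n),
            "y": rng.uniform(cfg.margin, cfg.screen_h - cfg.margin, size=n),
            "rotation": rng.uniform(0.0, 360.0, size=n),
            "encounters": encounters,
            "novel_crab": novel,
            "morph_switch": morph_switch,
            "played_before": played_before,
            "screen_scale": screen_scale,
        }
    )


def generate_sessions(
    catalog: Catalog,
    n_sessions: int,
    cfg: GameConfig = GameConfig(),
    rng: np.random.Generator | None = None,
    played_before_frac: float = 0.63,
) -> pd.DataFrame:
    """Generate many sessions and concatenate them into one sequence table."""
    if rng is None:
        rng = np.random.default_rng()
    frames = [
        generate_session(
            catalog, s, cfg, rng, played_before=bool(rng.random() < played_before_frac)
        )
        for s in range(n_sessions)
    ]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# run-length statistics
# ---------------------------------------------------------------------------


def run_length_stats(log: pd.DataFrame | np.ndarray) -> dict:
    """Run-length summary over sessions.

    A run is a maximal block of consecutive slides showing the same phenotype,
    truncated at the session end.  Accepts a gameplay log or a crab-index
    matrix from :func:`simulate_sequences`.  Returns the mean, median and the
    pooled distribution (length -> count).
    """
    if len(log) == 0:
        raise SimulationError("no sessions")
    if isinstance(log, np.ndarray):
        per_session = list(log)
    else:
        per_session = [
            sess.sort_values("slide")["crab_id"].to_numpy()
            for _, sess in log.groupby("session_id", sort=False)
        ]
    lengths: list[int] = []
    for crabs in per_session:
        boundaries = np.flatnonzero(crabs[1:] != crabs[:-1]) + 1
        edges = np.concatenate([[0], boundaries, [len(crabs)]])
        lengths.extend(np.diff(edges).tolist())
    arr = np.asarray(lengths)
    dist = dict(zip(*np.unique(arr, return_counts=True)))
    return {
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
        "n_runs": int(len(arr)),
        "distribution": {int(k): int(v) for k, v in dist.items()},
    }


def run_length_pmf(n_slides: int = 24, repeat_p: float = 0.8) -> dict[int, float]:
    """Exact expected run-length distribution for the truncated geometric law.

    Enumerates run starts: slide 1 always starts a run; slide i > 1 starts one
    with probability ``1 - repeat_p``.  A run starting at slide i has length l
    with probability ``p^(l-1) (1-p)`` when it ends before the session does,
    and ``p^(n_slides - i)`` for the run truncated at the session end.  Returns
    expected counts per length for a single session (sums to the expected
    number of runs).
    """
    p, n = repeat_p, n_slides
    counts: dict[int, float] = {}
    for i in range(1, n + 1):
        start_p = 1.0 if i == 1 else (1.0 - p)
        max_len = n - i + 1
        for length in range(1, max_len):
            counts[length] = counts.get(length, 0.0) + start_p * p ** (length - 1) * (1.0 - p)
        counts[max_len] = counts.get(max_len, 0.0) + start_p * p ** (max_len - 1)
    return counts


# ---------------------------------------------------------------------------
# synthetic observer
# ---------------------------------------------------------------------------


def simulate_observer(
    session: pd.DataFrame,
    profiles: pd.DataFrame,
    params: HazardParams,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw capture times for a presentation sequence under the hazard model.

    ``profiles`` maps ``crab_id`` (index) to metric columns; every metric named
    in ``params.metric_coefs`` / ``interaction_coefs`` must be present.  Times
    above 15 000 ms are censored as timeouts (capture_ms fixed at 15 000).
    Returns the session table extended with metric columns, ``capture_ms``,
    ``timed_out`` and ``crab_area``.
    """
    if rng is None:
        rng = np.random.default_rng()
    missing = set(session["crab_id"]) - set(profiles.index)
    if missing:
        raise SimulationError(f"no profile for crabs: {sorted(missing)[:5]}")

    out = session.merge(
        profiles, left_on="crab_id", right_index=True, how="left", sort=False
    ).reset_index(drop=True)

    # scene-to-scene measurement variation: each presentation re-composites the
    # crab, so the realised metrics scatter around the per-crab summary
    if params.presentation_jitter_frac > 0:
        for m in profiles.columns:
            if not pd.api.types.is_numeric_dtype(out[m]):
                continue
            sd = float(profiles[m].std())
            if sd > 0:
                out[m] = out[m] + rng.normal(
                    0.0, params.presentation_jitter_frac * sd, size=len(out)
                )

    log_h = np.full(len(out), params.baseline, dtype=float)
    enc = out["encounters"].to_numpy(dtype=float)
    for m, beta in params.metric_coefs.items():
        log_h += beta * out[m].to_numpy(dtype=float)
    log_h += params.encounters_coef * enc
    for m, gamma in params.interaction_coefs.items():
        log_h += gamma * out[m].to_numpy(dtype=float) * enc
    novel = out["novel_crab"].to_numpy(dtype=float)
    for m, gamma in params.novelty_coefs.items():
        log_h += gamma * out[m].to_numpy(dtype=float) * novel
    if params.morph_switch_penalty:
        cross = novel * np.nan_to_num(out["morph_switch"].to_numpy(dtype=float))
        log_h += params.morph_switch_penalty * cross

    intercepts = {}
    for sid in pd.unique(out["session_id"]):
        intercepts[sid] = rng.normal(0.0, params.session_sd) if params.session_sd > 0 else 0.0
    log_h += out["session_id"].map(intercepts).to_numpy(dtype=float)

    if not np.all(np.isfinite(log_h)):
        raise SimulationError("non-finite log-hazard; check coefficients and metrics")

    # Weibull with shape k and rate-parameterised scale; k = 1 is exponential.
    scale = 1.0 / np.exp(log_h)
    times = scale * rng.weibull(params.weibull_shape, size=len(out))
    timed_out = times >= TIMEOUT_MS
    capture = np.where(timed_out, float(TIMEOUT_MS), np.maximum(times, 1.0))

    out["capture_ms"] = capture
    out["timed_out"] = timed_out
    if "crab_area" not in out.columns:
        out["crab_area"] = np.nan
    return out
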