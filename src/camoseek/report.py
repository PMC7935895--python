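"""Summary statistics, percentage effects and survival-curve summaries.

The derived numbers of a capture-time study: presentation/timeout bookkeeping,
median capture times stratified by phenotype novelty and camouflage level,
integer percentage effects between condition medians, Kaplan-Meier curves with
right-censored timeouts, and the morph-switch heat map.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .image_io import validate_gameplay_log
from .game import MORPHS

__all__ = [
    "StudySummary",
    "summarise",
    "percent_change",
    "survival_curves",
    "km_median",
    "morph_switch_heatmap",
]


@dataclass
class StudySummary:
    """Study-level bookkeeping and stratified medians.

    ``median_by_stratum`` maps (novelty, camouflage level) -> median capture
    time in ms, for the four cells novel/repeat x above/below the within-data
    median of the chosen camouflage metric.  Raw medians use uncensored times
    only; KM medians account for the censored timeouts (the two coincide while
    censoring is light).
    """

    n_sessions: int
    n_first_time_players: int
    n_captures: int
    n_timeouts: int
    timeout_pct: float
    median_by_stratum: dict = field(default_factory=dict)
    km_median_by_stratum: dict = field(default_factory=dict)

    @property
    def n_presentations(self) -> int:
        return self.n_captures + self.n_timeouts


def summarise(log: pd.DataFrame, camo_metric: str | None = None) -> StudySummary:
    """Counts, timeout percentage and stratified medians for a gameplay log.

    When ``camo_metric`` names a profile column, medians are computed in the
    four novelty x above/below-median-camouflage strata.
    """
    if len(log) == 0:
        raise ValueError("empty gameplay log")
    validate_gameplay_log(log)
    timed_out = log["timed_out"].astype(bool)
    n_timeouts = int(timed_out.sum())
    n_captures = int((~timed_out).sum())
    played_before = log.groupby("session_id")["played_before"].first().astype(bool)

    medians: dict = {}
    km_medians: dict = {}
    if camo_metric is not None:
        cut = log[camo_metric].median()
        for novel in (True, False):
            for above in (True, False):
                sel = (log["novel_crab"].astype(bool) == novel) & (
                    (log[camo_metric] > cut) == above
                )
                key = ("novel" if novel else "repeat", "above" if above else "below")
                uncens = log.loc[sel & ~timed_out, "capture_ms"]
                medians[key] = float(uncens.median()) if len(uncens) else math.nan
                km_medians[key] = km_median(log.loc[sel]) if sel.any() else math.nan

    return StudySummary(
        n_sessions=int(log["session_id"].nunique()),
        n_first_time_players=int((~played_before).sum()),
        n_captures=n_captures,
        n_timeouts=n_timeouts,
        timeout_pct=100.0 * n_timeouts / (n_captures + n_timeouts),
        median_by_stratum=medians,
        km_median_by_stratum=km_medians,
    )


def percent_change(value_ms: float, reference_ms: float) -> int:
    """Signed integer percentage change of ``value`` relative to ``reference``.

    ``round(100 * (value - reference) / reference)`` with ties rounded half
    away from zero (the convention of printed integer percentages).  A
    "X% longer/increased" effect is a positive return value; "X% quicker" is
    the corresponding negative value.
    """
    if reference_ms <= 0:
        raise ValueError("reference must be positive")
    pct = 100.0 * (value_ms - reference_ms) / reference_ms
    return int(math.copysign(math.floor(abs(pct) + 0.5), pct))


def km_median(log: pd.DataFrame) -> float:
    """Kaplan-Meier median capture time of a log subset (timeouts censored)."""
    kmf = KaplanMeierFitter()
    kmf.fit(log["capture_ms"], event_observed=~log["timed_out"].astype(bool))
    return float(kmf.median_survival_time_)


def survival_curves(log: pd.DataFrame, strata_cols: list[str]) -> dict:
    """Kaplan-Meier survival tables per stratum, with 95% Greenwood-based CIs.

    Returns {stratum value(s) -> DataFrame(timeline, survival, ci_lower,
    ci_upper)}.  Strata with no uncensored event are dropped with a warning.
    """
    out: dict = {}
    for key, sub in log.groupby(strata_cols, sort=False, observed=False):
        if len(sub) == 0:
            continue
        events = ~sub["timed_out"].astype(bool)
        if events.sum() == 0:
            warnings.warn(f"stratum {key!r} has no uncensored events; dropped", stacklevel=2)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub["capture_ms"], event_observed=events)
        ci = kmf.confidence_interval_survival_function_
        out[key if len(strata_cols) > 1 else key[0] if isinstance(key, tuple) else key] = pd.DataFrame(
            {
                "timeline": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "ci_lower": ci.iloc[:, 0].to_numpy(),
                "ci_upper": ci.iloc[:, 1].to_numpy(),
            }
        )
    return out


def morph_switch_heatmap(diffs: pd.DataFrame, include_same_morph: bool = True) -> pd.DataFrame:
    """Mean log capture-time difference over novel-crab switches, by morph pair.

    Cell (previous morph, current morph) averages ``time_diff`` over switch
    events from one morph to the other; positive cells mean the current morph
    is harder to find than the previous one.  Empty cells are NaN.  With
    ``include_same_morph=False`` the 6 diagonal (same-morph switch) cells are
    masked, leaving the 30 cross-morph cells.
    """
    switches = diffs[diffs["novel_crab"].astype(bool)]
    table = (
        switches.groupby(["p_morph", "morph"], observed=False)["time_diff"]
        .mean()
        .unstack()
        .reindex(index=list(MORPHS), columns=list(MORPHS))
    )
    if not include_same_morph:
        for m in MORPHS:
            table.loc[m, m] = np.nan
    table.index.name = "previous_morph"
    table.columns.name = "current_morph"
    return table
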