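"""Survival and capture-time-difference models for gameplay logs.

Four model families:

i.   metric ranking — one Cox proportional-hazards fit per camouflage metric
     on top of a base set of nuisance covariates (screen scale, prior play,
     quadratic screen position, crab size), metrics ranked by |z|;
ii.  encounter interaction — Cox fit with a metric, the number of previous
     encounters with the current phenotype, and their interaction;
iii. switch differences — linear mixed model on the log capture-time
     difference between consecutive slides, with camouflage *differences*
     (current minus previous crab) interacting with phenotype novelty;
iv.  morph switches — the same difference response with a
     morph-switch-by-novelty interaction, plus the 6x6 mean-difference matrix
     over (previous morph -> current morph) switch events.

Timeouts (15 s) enter the Cox fits as right-censored observations.  Session
dependence is handled with a cluster-robust (sandwich) variance clustered on
session id, optionally an exact session-stratified fit; the mixed models carry
a session random intercept (REML) with an ordinary-least-squares fallback when
the intercept variance degenerates to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "ModelFit",
    "FitError",
    "BASE_COX_TERMS",
    "BASE_DIFF_TERMS",
    "orthogonal_poly",
    "build_design",
    "fit_cox",
    "rank_metrics",
    "fit_encounters_interaction",
    "build_diff_records",
    "fit_timediff_lmm",
    "fit_morph_switch",
]


class FitError(RuntimeError):
    """Model could not be fitted (separation, no events, rank deficiency...)."""


#: Nuisance covariates of the capture-time survival models: screen resolution,
#: prior play, quadratic screen position of the crab, and crab size.
BASE_COX_TERMS: tuple = ("screen_scale", "played_before", ("x", 2), ("y", 2), "crab_area")

#: Nuisance covariates of the difference models: sizes and screen positions of
#: the current and the previous crab, prior play, and slide number.
BASE_DIFF_TERMS: tuple = (
    "crab_area",
    "p_area",
    "played_before",
    "slide",
    ("x", 2),
    ("y", 2),
    ("p_x", 2),
    ("p_y", 2),
)


@dataclass
class ModelSpec:
    """Declarative model description.

    ``terms`` mixes plain column names and ``(column, degree)`` pairs, the
    latter expanded into orthogonal polynomial columns (R ``poly`` style:
    centred, QR-orthogonalised, unit-norm).  ``interactions`` are pairs of
    declared term names multiplied into product columns.  ``cluster`` names the
    grouping column for robust variances / random intercepts.
    """

    terms: tuple = ()
    interactions: tuple = ()
    cluster: str = "session_id"
    duration_col: str = "capture_ms"
    event_col: str = "event"
    strata: str | None = None


@dataclass
class ModelFit:
    """Fitted-model summary: per-term coefficient table plus fit metadata.

    ``table`` has one row per coefficient with columns ``coef``, ``se``, ``z``
    and ``p`` (``z`` doubles as the t statistic for the linear mixed models).
    """

    table: pd.DataFrame
    loglik: float
    n_obs: int
    n_events: int
    n_censored: int
    cluster_variance: float | None
    method: str
    converged: bool = True

    def z(self, term: str) -> float:
        return float(self.table.loc[term, "z"])

    def coef(self, term: str) -> float:
        return float(self.table.loc[term, "coef"])


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------


def orthogonal_poly(x: np.ndarray, degree: int) -> np.ndarray:
    """R-style orthogonal polynomial basis (degree columns, no intercept).

    Columns are the QR orthonormalisation of the centred Vandermonde matrix,
    so they are mutually orthogonal, orthogonal to the constant, and have unit
    norm — coefficients are comparable across fits on the same data.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise FitError("cannot build polynomial basis on a constant column")
    xc = x - x.mean()
    V = np.vander(xc, degree + 1, increasing=True)
    Q, R = np.linalg.qr(V)
    Q = Q * np.sign(np.diag(R))
    return Q[:, 1:]


def build_design(df: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Expand a ModelSpec into a numeric design DataFrame."""
    cols: dict[str, np.ndarray] = {}
    for term in spec.terms:
        if isinstance(term, tuple):
            name, degree = term
            if name not in df.columns:
                raise FitError(f"covariate {name!r} missing from the log")
            basis = orthogonal_poly(df[name].to_numpy(), degree)
            for d in range(degree):
                cols[f"{name}_poly{d + 1}"] = basis[:, d]
        else:
            if term not in df.columns:
                raise FitError(f"covariate {term!r} missing from the log")
            cols[term] = df[term].to_numpy(dtype=float)
    for a, b in spec.interactions:
        for t in (a, b):
            if t not in cols:
                raise FitError(f"interaction references undeclared term {t!r}")
        cols[f"{a}:{b}"] = cols[a] * cols[b]
    design = pd.DataFrame(cols, index=df.index)
    zero_var = [c for c in design.columns if design[c].std() == 0]
    if zero_var:
        raise FitError(f"zero-variance covariates: {zero_var}")
    return design


# ---------------------------------------------------------------------------
# Cox models
# ---------------------------------------------------------------------------


def fit_cox(log: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Cox proportional-hazards fit (Efron ties) on a gameplay log.

    Timed-out presentations are right-censored at 15 s.  Variance is the
    cluster-robust sandwich clustered on ``spec.cluster``; pass
    ``spec.strata`` (e.g. the session column) for a stratified fit that gives
    each stratum its own baseline hazard.
    """
    events = ~log["timed_out"].astype(bool)
    if events.sum() < 2:
        raise FitError("need at least two uncensored capture events")
    design = build_design(log, spec)
    df = design.copy()
    df["_duration"] = log["capture_ms"].to_numpy(dtype=float)
    df["_event"] = events.to_numpy()
    df["_cluster"] = log[spec.cluster].to_numpy()
    strata = None
    if spec.strata is not None:
        df["_strata"] = log[spec.strata].to_numpy()
        strata = "_strata"

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df,
                duration_col="_duration",
                event_col="_event",
                cluster_col="_cluster",
                strata=strata,
                robust=True,
            )
    except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
        raise FitError(f"Cox model failed to converge: {exc}") from exc

    table = pd.DataFrame(
        {
            "coef": cph.params_,
            "se": cph.standard_errors_,
            "z": cph.params_ / cph.standard_errors_,
            "p": cph.summary["p"],
        }
    )
    # between-cluster heterogeneity diagnostic: variance across sessions of the
    # session-mean scaled partial-hazard residual (0 for a homogeneous log)
    haz = cph.predict_partial_hazard(df).to_numpy()
    resid = pd.Series(df["_event"].to_numpy(dtype=float) - haz / haz.mean(), index=df.index)
    cluster_var = float(resid.groupby(df["_cluster"].to_numpy()).mean().var())
    return ModelFit(
        table=table,
        loglik=float(cph.log_likelihood_),
        n_obs=len(df),
        n_events=int(events.sum()),
        n_censored=int((~events).sum()),
        cluster_variance=cluster_var,
        method="cox_cluster_robust" if strata is None else "cox_stratified",
    )


def rank_metrics(
    log: pd.DataFrame,
    metric_cols: list[str],
    base_spec: ModelSpec | None = None,
) -> tuple[pd.DataFrame, dict[str, ModelFit]]:
    """Fit each metric separately in the base model and rank by |z| (family i)."""
    if base_spec is None:
        base_spec = ModelSpec(terms=BASE_COX_TERMS)
    fits: dict[str, ModelFit] = {}
    rows = []
    for m in metric_cols:
        spec = ModelSpec(
            terms=tuple(base_spec.terms) + (m,),
            cluster=base_spec.cluster,
            strata=base_spec.strata,
        )
        fit = fit_cox(log, spec)
        fits[m] = fit
        rows.append({"metric": m, "coef": fit.coef(m), "z": fit.z(m), "abs_z": abs(fit.z(m))})
    ranking = (
        pd.DataFrame(rows).sort_values("abs_z", ascending=False).reset_index(drop=True)
    )
    return ranking, fits


def fit_encounters_interaction(
    log: pd.DataFrame,
    metric: str,
    base_spec: ModelSpec | None = None,
) -> ModelFit:
    """Cox fit with metric * encounters interaction (family ii).

    The headline quantity is the interaction coefficient ``{metric}:encounters``:
    negative means the metric's camouflage benefit strengthens, and search-image
    formation is slowed, for better-camouflaged phenotypes.
    """
    if base_spec is None:
        base_spec = ModelSpec(terms=BASE_COX_TERMS + ("slide",))
    spec = ModelSpec(
        terms=tuple(base_spec.terms) + (metric, "encounters"),
        interactions=((metric, "encounters"),),
        cluster=base_spec.cluster,
        strata=base_spec.strata,
    )
    return fit_cox(log, spec)


# ---------------------------------------------------------------------------
# difference records and linear mixed models
# ---------------------------------------------------------------------------


def build_diff_records(log: pd.DataFrame, metric_cols: list[str] | None = None) -> pd.DataFrame:
    """One record per slide >= 2: log capture-time difference vs the previous slide.

    ``time_diff = log(current capture_ms) - log(previous capture_ms)`` (censored
    times enter at the 15 s ceiling).  Each camouflage metric contributes a
    ``{metric}_diff`` column (current minus previous); the previous crab's
    size and screen position are carried as ``p_area``, ``p_x``, ``p_y``.
    Length-1 sessions are skipped with a warning.
    """
    if metric_cols is None:
        metric_cols = [c for c in log.columns if c.endswith(("_surround", "_background")) or c.startswith("gabrat")]
    frames = []
    for sid, sess in log.groupby("session_id", sort=False):
        sess = sess.sort_values("slide")
        if len(sess) < 2:
            warnings.warn(f"session {sid!r} has a single slide; skipped", stacklevel=2)
            continue
        cur = sess.iloc[1:].reset_index(drop=True)
        prev = sess.iloc[:-1].reset_index(drop=True)
        rec = pd.DataFrame(
            {
                "session_id": sid,
                "slide": cur["slide"].to_numpy(),
                "time_diff": np.log(cur["capture_ms"].to_numpy())
                - np.log(prev["capture_ms"].to_numpy()),
                "novel_crab": cur["novel_crab"].to_numpy(dtype=bool),
                "morph_switch": cur["morph_switch"].to_numpy(dtype=float),
                "morph": cur["morph"].to_numpy(),
                "p_morph": prev["morph"].to_numpy(),
                "crab_area": cur["crab_area"].to_numpy(dtype=float),
                "p_area": prev["crab_area"].to_numpy(dtype=float),
                "x": cur["x"].to_numpy(dtype=float),
                "y": cur["y"].to_numpy(dtype=float),
                "p_x": prev["x"].to_numpy(dtype=float),
                "p_y": prev["y"].to_numpy(dtype=float),
                "played_before": cur["played_before"].to_numpy(dtype=float),
                "encounters": cur["encounters"].to_numpy(dtype=float),
            }
        )
        for m in metric_cols:
            if m in sess.columns:
                rec[f"{m}_diff"] = cur[m].to_numpy(dtype=float) - prev[m].to_numpy(dtype=float)
        frames.append(rec)
    if not frames:
        raise FitError("no sessions with two or more slides")
    out = pd.concat(frames, ignore_index=True)
    if not np.all(np.isfinite(out["time_diff"])):
        raise FitError("non-finite log time differences")
    return out


def _lmm_fit(
    diffs: pd.DataFrame,
    design: pd.DataFrame,
    cluster: str,
    reml: bool = True,
    var_tol: float = 1e-8,
) -> ModelFit:
    """Random-intercept LMM via REML with a documented OLS fallback.

    When the estimated session-intercept variance collapses to (numerically)
    zero the mixed model is equivalent to ordinary least squares, which is then
    used for the reported coefficients — mirroring cross-validation of the
    mixed fits with plain GLMs.
    """
    X = sm.add_constant(design)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = design.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        aliased = corr.stack().idxmax() if corr.size else ()
        raise FitError(f"rank-deficient design (worst-aliased columns: {aliased})")
    y = diffs["time_diff"].to_numpy(dtype=float)
    groups = diffs[cluster].to_numpy()

    # standardise covariates for the REML optimiser (mixed columns of wildly
    # different variance make X'V^-1 X near-singular); coefficients are mapped
    # back to the original scale afterwards
    sds = X.std().replace(0.0, 1.0)
    sds["const"] = 1.0
    Xs = X / sds

    mixed = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mixed = sm.MixedLM(y, Xs, groups=groups).fit(reml=reml, method="lbfgs")
        re_var = float(mixed.cov_re.iloc[0, 0]) if mixed.cov_re.size else 0.0
    except np.linalg.LinAlgError:
        re_var = 0.0

    if mixed is None or not mixed.converged or re_var <= var_tol * float(mixed.scale):
        ols = sm.OLS(y, X).fit()
        table = pd.DataFrame(
            {"coef": ols.params, "se": ols.bse, "z": ols.tvalues, "p": ols.pvalues}
        )
        return ModelFit(
            table=table,
            loglik=float(ols.llf),
            n_obs=len(y),
            n_events=len(y),
            n_censored=0,
            cluster_variance=0.0,
            method="ols_fallback",
        )
    params = np.asarray(mixed.params[: X.shape[1]]) / sds.to_numpy()
    bse = np.asarray(mixed.bse[: X.shape[1]]) / sds.to_numpy()
    table = pd.DataFrame(
        {
            "coef": params,
            "se": bse,
            "z": params / bse,
            "p": np.asarray(mixed.pvalues[: X.shape[1]]),
        },
        index=X.columns,
    )
    return ModelFit(
        table=table,
        loglik=float(mixed.llf),
        n_obs=len(y),
        n_events=len(y),
        n_censored=0,
        cluster_variance=re_var,
        method="lmm_reml",
    )


def fit_timediff_lmm(
    diffs: pd.DataFrame,
    metric_diff: str,
    base_terms: tuple = BASE_DIFF_TERMS,
    cluster: str = "session_id",
) -> ModelFit:
    """Switch-difference mixed model (family iii).

    ``time_diff ~ base terms + metric_diff * novel_crab + (1 | session)``.
    The headline term is ``{metric_diff}:novel_crab``: how the camouflage
    *difference* between consecutive crabs shifts capture time specifically
    when the phenotype actually switches.
    """
    spec = ModelSpec(
        terms=tuple(base_terms) + (metric_diff, "novel_crab"),
        interactions=((metric_diff, "novel_crab"),),
        cluster=cluster,
    )
    d = diffs.copy()
    d["novel_crab"] = d["novel_crab"].astype(float)
    design = build_design(d, spec)
    return _lmm_fit(d, design, cluster)


def fit_morph_switch(
    diffs: pd.DataFrame,
    base_terms: tuple = BASE_DIFF_TERMS,
    cluster: str = "session_id",
) -> tuple[ModelFit, pd.DataFrame]:
    """Morph-switch model (family iv) plus the 6x6 switch matrix.

    Fits ``time_diff ~ base terms + morph_switch * novel_crab + (1 | session)``
    and returns the mean ``time_diff`` matrix over novel-crab switch events,
    cell (previous morph, current morph); cells with no events are NaN.
    A positive cell means the current morph is harder to find than the
    previous one after that switch.

    ``morph_switch`` labels the type of each slide's most recent phenotype
    switch (cross-morph vs same-morph); slides preceding a session's first
    switch carry no label and are dropped, so the interaction contrasts the
    switch slide itself (novel) against the run it initiates.
    """
    spec = ModelSpec(
        terms=tuple(base_terms) + ("morph_switch", "novel_crab"),
        interactions=(("morph_switch", "novel_crab"),),
        cluster=cluster,
    )
    d = diffs[np.isfinite(diffs["morph_switch"].astype(float))].copy()
    if len(d) == 0:
        raise FitError("no slides with a labelled morph switch")
    d["novel_crab"] = d["novel_crab"].astype(float)
    d["morph_switch"] = d["morph_switch"].astype(float)
    design = build_design(d, spec)
    fit = _lmm_fit(d, design, cluster)

    from .game import MORPHS

    switches = diffs[diffs["novel_crab"].astype(bool)]
    matrix = (
        switches.groupby(["p_morph", "morph"], observed=False)["time_diff"]
        .mean()
        .unstack()
        .reindex(index=list(MORPHS), columns=list(MORPHS))
    )
    matrix.index.name = "previous_morph"
    matrix.columns.name = "current_morph"
    return fit, matrix
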