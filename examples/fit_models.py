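"""Rank camouflage metrics and test search-image interactions with Cox models.

Simulates gameplay whose hazard is driven by known coefficients, then (i)
ranks each metric by |z| from single-metric Cox fits (timeouts right-censored,
variance clustered on session) and (ii) fits the metric-by-encounters
interaction model.  A negative interaction means good camouflage slows
search-image formation.
"""

import numpy as np

from camoseek.game import GameConfig, generate_sessions, simulate_observer
from camoseek.models import fit_encounters_interaction, rank_metrics
from camoseek.synth import default_hazard_params, make_catalog

rng = np.random.default_rng(11)
mix = {m: 5 for m in ("Black", "Disruptive", "Green", "Mottled", "Pale", "Spotted")}
catalog = make_catalog(
    n_crabs=30, n_backgrounds=8, morph_mix=mix, rng=rng,
    image_size=(256, 256), body_radius=24.0,
)
sessions = generate_sessions(catalog, 400, GameConfig(), rng)
log = simulate_observer(sessions, catalog.crabs.drop(columns=["morph"]), default_hazard_params(), rng)

metrics = ["gabrat_l", "gabrat_a", "colour_dist_surround", "lum_diff_surround", "pattern_diff_surround"]
ranking, fits = rank_metrics(log, metrics)
print("metric ranking by |z| (single-metric Cox fits):")
print(ranking.to_string(index=False))

fit = fit_encounters_interaction(log, "gabrat_a")
print("\nchromatic edge disruption x encounters model:")
print(fit.table.loc[["gabrat_a", "encounters", "gabrat_a:encounters"]].round(4).to_string())
print(
    "\nNegative metric coefficients mean the trait lowers the detection hazard"
    "\n(longer survival); a negative interaction means its benefit grows while"
    "\nthe observer is still forming a search image."
)
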