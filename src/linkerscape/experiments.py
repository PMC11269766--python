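"""Replicated synthetic experiments: effect recovery and null calibration.

These drive the ground-truth checks of the pipeline: with a landscape effect
injected into the worker-foraging kernel, the single-metric movement model
should recover the effect's sign; with all effects at zero, the estimated
coefficient should be centred on zero across replicates.  The landscape (and
hence the metric table) is held fixed across replicates -- as in the field
design, where one set of windows is sampled repeatedly -- and only nests,
workers and genotypes are redrawn.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .config import PipelineConfig, SynthConfig
from .genotypes import GenotypeTable
from .selection import Term, fit_model, prepare_model_data
from .sibship import consensus_pairs, movement_indicators, two_run_blocks
from .synthetic import generate_landscape, generate_nests_and_workers

__all__ = [
    "movement_effect_replicates", "sibship_accuracy", "fit_single_metric",
]


def _study_maps(cfg: SynthConfig) -> list:
    return [generate_landscape(cfg, w) for w in range(cfg.n_windows)]


def _node_wide(maps: list, cfg_pipe: PipelineConfig, metrics, radii) -> pd.DataFrame:
    from .landscape import metric_wide, node_metrics
    tidy = pd.concat(
        [node_metrics(m, m.patch_centroids, radii, metrics=metrics) for m in maps],
        ignore_index=True,
    )
    return metric_wide(tidy)


def fit_single_metric(
    wide: pd.DataFrame, responses: pd.DataFrame, response: str, column: str,
    level: str = "node", degree: int = 1,
):
    """Box-Cox + standardize, then fit ``response ~ column`` with the window
    random intercept; returns the fitted model (or None on failure)."""
    cols = ["window", "unit", column]
    data = prepare_model_data(wide[cols], responses, level, [response])
    metric, scale = column, "-"
    for cand_scale in ("125", "250", "500", "1000", "2000"):
        if column.endswith(cand_scale):
            metric, scale = column[: -len(cand_scale)], cand_scale
    return data, fit_model(data, response, [Term(metric, scale, degree)])


def movement_effect_replicates(
    n_reps: int,
    seed: int,
    synth: SynthConfig | None = None,
    response: str = "NESTS_shared",
    column: str = "MAIZE2000",
    restarts: int = 2,
    new_landscape_each_rep: bool = False,
) -> pd.DataFrame:
    """Replicated end-to-end recovery of a landscape effect on movement.

    For each replicate: redraw nests/workers on the fixed landscape, run the
    two-run consensus sibship reconstruction, compute the movement
    indicators, and fit the single-metric movement model.  Returns one row
    per replicate with the standardized coefficient and its p-value.
    With ``new_landscape_each_rep`` the windows themselves are redrawn per
    replicate, which averages out landscape-specific structure (used for
    null calibration).
    """
    synth = synth if synth is not None else SynthConfig()
    metrics = ("MAIZE", "SEMNATGRASS", "LANDHET")
    radii = (125.0, 2000.0)
    maps = _study_maps(synth)
    wide = _node_wide(maps, PipelineConfig(), metrics=metrics, radii=radii)
    rows = []
    for rep in range(n_reps):
        rep_cfg = replace(synth, rng_seed=(seed + 104729 * (rep + 1)) % (2**31 - 1))
        if new_landscape_each_rep:
            maps = _study_maps(rep_cfg)
            wide = _node_wide(maps, PipelineConfig(), metrics=metrics, radii=radii)
        bee_tables = []
        for lum in maps:
            bees, _ = generate_nests_and_workers(lum, rep_cfg)
            bee_tables.append(bees)
        bees = _concat(bee_tables)
        runs_a, runs_b = two_run_blocks(bees, seed=rep_cfg.rng_seed % 99991,
                                        restarts=restarts)
        families: list[set] = []
        for key in runs_a:
            families.extend(consensus_pairs(runs_a[key], runs_b[key], 0.8))
        worker_patch = dict(zip(bees.ids, bees.pops))
        window_of_patch = dict(zip(bees.pops, bees.windows))
        movement = movement_indicators(families, worker_patch, window_of_patch)
        responses = movement.drop(columns=["n_nests"])
        _, fit = fit_single_metric(wide, responses, response, column)
        if fit is None:
            rows.append({"rep": rep, "b": np.nan, "p": np.nan, "ok": False})
            continue
        j = list(fit.names).index(column)
        rows.append({"rep": rep, "b": fit.beta[j], "p": fit.pvalues[j], "ok": True})
    return pd.DataFrame(rows)


def sibship_accuracy(bees: GenotypeTable, truth_nest: dict, seed: int = 1,
                     restarts: int = 2, threshold: float = 0.8) -> dict:
    """Pairwise precision/recall of the consensus reconstruction vs truth."""
    import itertools

    runs_a, runs_b = two_run_blocks(bees, seed=seed, restarts=restarts)
    families: list[set] = []
    for key in runs_a:
        families.extend(consensus_pairs(runs_a[key], runs_b[key], threshold))
    est_pairs = {
        frozenset(p) for f in families for p in itertools.combinations(sorted(f), 2)
    }
    by_nest: dict[str, list] = {}
    for w in bees.ids:
        by_nest.setdefault(truth_nest[w], []).append(w)
    true_pairs = {
        frozenset(p) for f in by_nest.values()
        for p in itertools.combinations(sorted(f), 2)
    }
    tp = len(est_pairs & true_pairs)
    return {
        "precision": tp / len(est_pairs) if est_pairs else 1.0,
        "recall": tp / len(true_pairs) if true_pairs else 1.0,
        "n_est_pairs": len(est_pairs),
        "n_true_pairs": len(true_pairs),
        "families": families,
    }


def _concat(tables: list[GenotypeTable]) -> GenotypeTable:
    from .synthetic import _concat_tables
    return _concat_tables(tables)
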