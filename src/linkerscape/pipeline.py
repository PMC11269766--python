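"""End-to-end orchestration: metrics -> indicators -> four-step selection.

``compute_inputs`` turns a study (maps + genotype tables) into the two
analysis tables the mixed models consume: a node-level table (one row per
forest patch: movement indicators and herb genetic measures, joined with all
buffer metrics) and a link-level table (one row per within-window patch pair:
BomD_PS and PolD_PS joined with all strip metrics plus geographic distance).
``run_selection`` then executes Steps 1-4 and ``write_report`` dumps tidy
CSVs and the AICc-density figure.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig, LINK_RATIO_LABELS, all_metric_names
from .landscape import link_metrics, metric_wide, node_metrics
from .popgen import pairwise_dps, population_measures
from .selection import (
    ModelData, Term, best_models, prepare_model_data, step1, step2_fit,
    step3_enumerate, step4_percentile,
)
from .sibship import consensus_pairs, movement_indicators, two_run_blocks

NODE_MOVEMENT = ("NESTS_shared", "FOREST_PATCHES_shared")
LINK_MOVEMENT = ("BomDPS",)
NODE_MEASURES = ("A_r", "He", "Ho", "F")
LINK_MEASURES = ("PolDPS",)

__all__ = [
    "compute_inputs", "run_selection", "write_report", "run_stage",
    "NODE_MOVEMENT", "LINK_MOVEMENT", "NODE_MEASURES", "LINK_MEASURES",
]


def compute_inputs(study: dict, cfg: PipelineConfig, *, err: float = 0.0,
                   restarts: int | None = None) -> dict:
    """Landscape metric tables plus node- and link-level response tables."""
    cfg.validate()
    restarts = cfg.sibship_restarts if restarts is None else restarts
    maps = study["maps"]
    node_tidy = pd.concat([
        node_metrics(m, m.patch_centroids, cfg.node_radii,
                     period=cfg.dominance_period)
        for m in maps
    ], ignore_index=True)
    link_tidy = pd.concat([
        link_metrics(m, m.patch_centroids, cfg.link_ratios,
                     period=cfg.dominance_period)
        for m in maps
    ], ignore_index=True)

    # two independently seeded sibship runs, per (window, year) block
    bees = study["bees"]
    runs_a, runs_b = two_run_blocks(bees, seed=cfg.seed, restarts=restarts, err=err)
    worker_patch = dict(zip(bees.ids, bees.pops))
    window_of_patch = dict(zip(bees.pops, bees.windows))
    families: list[set] = []
    for key in runs_a:
        families.extend(consensus_pairs(runs_a[key], runs_b[key],
                                        cfg.consensus_threshold))
    movement = movement_indicators(families, worker_patch, window_of_patch)

    plants = study["plants"]
    genetics = population_measures(plants)
    node_responses = movement.merge(
        genetics.drop(columns=["n"]), on=["window", "unit"], how="outer",
    ).drop(columns=["n_nests"])

    link_responses = pairwise_dps(bees, name="BomDPS").merge(
        pairwise_dps(plants, name="PolDPS"), on=["window", "unit"], how="outer",
    )
    return {
        "node_metrics": node_tidy, "link_metrics": link_tidy,
        "node_wide": metric_wide(node_tidy), "link_wide": metric_wide(link_tidy),
        "node_responses": node_responses, "link_responses": link_responses,
        "families": families,
        "sibship_runs": (runs_a, runs_b),
    }


def _scales(cfg: PipelineConfig, level: str) -> list[str]:
    if level == "link":
        return [LINK_RATIO_LABELS.get(r, f"{r:g}") for r in cfg.link_ratios]
    return [f"{r:g}" for r in cfg.node_radii]


def run_selection(inputs: dict, cfg: PipelineConfig, *,
                  step3_max_models: int | None = None,
                  measures: tuple[str, ...] | None = None) -> dict:
    """Steps 1-4 at both analysis levels; returns a nested report dict."""
    metrics = all_metric_names()
    report: dict = {"node": {}, "link": {}}
    for level, movement_resps, measure_resps, wide, responses in (
        ("node", NODE_MOVEMENT, NODE_MEASURES,
         inputs["node_wide"], inputs["node_responses"]),
        ("link", LINK_MOVEMENT, LINK_MEASURES,
         inputs["link_wide"], inputs["link_responses"]),
    ):
        resp_cols = list(movement_resps) + list(measure_resps)
        data = prepare_model_data(wide, responses, level, resp_cols)
        level_metrics = metrics + (["DISTANCE"] if level == "link" else [])
        scales = _scales(cfg, level)
        rep: dict = {"data": data, "step1": {}, "step2": None, "step3": {},
                     "step4": {}}
        term_sets: list[tuple[Term, ...]] = []
        for resp in movement_resps:
            if resp not in data.responses:
                continue
            res = step1(data, resp, level_metrics, scales, cfg)
            rep["step1"][resp] = res
            for ts in best_models(res["models"]):
                if ts not in term_sets:
                    term_sets.append(ts)
        use_measures = [m for m in measure_resps if m in data.responses
                        and (measures is None or m in measures)]
        rep["step2"] = step2_fit(data, use_measures, term_sets)
        for measure in use_measures:
            res3 = step3_enumerate(
                data, measure, level_metrics, scales, cfg,
                max_models=step3_max_models, seed=cfg.seed,
            )
            rep["step3"][measure] = res3
            s2 = rep["step2"]
            rows = []
            if not s2.empty:
                for _, r in s2[s2["measure"] == measure].iterrows():
                    pct, ok = step4_percentile(r["aicc"], res3["aicc"],
                                               cfg.percentile_criterion)
                    rows.append({
                        "measure": measure, "labels": r["labels"],
                        "aicc": r["aicc"], "percentile": pct, "passed": ok,
                    })
            rep["step4"][measure] = pd.DataFrame(rows)
        report[level] = rep
    return report


# ---- reporting -----------------------------------------------------------

def _step1_table(rep: dict) -> pd.DataFrame:
    rows = []
    for resp, res in rep["step1"].items():
        models = res["models"]
        if models.empty:
            continue
        for _, r in models[models["best"]].iterrows():
            fit = r["fit"]
            for term, b, p in zip(fit.names, fit.beta, fit.pvalues):
                if term == "(Intercept)":
                    continue
                rows.append({
                    "response": resp, "model": r["labels"], "term": term,
                    "b": b, "p": p, "aicc": r["aicc"],
                    "r2m": r["r2m"], "r2c": r["r2c"],
                })
    return pd.DataFrame(rows)


def _step2_table(rep: dict) -> pd.DataFrame:
    rows = []
    s2 = rep["step2"]
    if s2 is None or s2.empty:
        return pd.DataFrame(rows)
    for _, r in s2.iterrows():
        fit = r["fit"]
        for term, b, p in zip(fit.names, fit.beta, fit.pvalues):
            if term == "(Intercept)":
                continue
            rows.append({
                "measure": r["measure"], "model": r["labels"], "term": term,
                "b": b, "p": p, "aicc": r["aicc"], "r2m": r["r2m"],
                "r2c": r["r2c"],
            })
    return pd.DataFrame(rows)


def write_report(report: dict, outdir: str | Path, make_figure: bool = True) -> list[Path]:
    """Tidy CSV tables per step plus the scaled AICc-density figure."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _w(df: pd.DataFrame, name: str) -> None:
        p = outdir / name
        df.to_csv(p, index=False)
        written.append(p)

    for level in ("node", "link"):
        rep = report[level]
        _w(_step1_table(rep), f"step1_{level}.csv")
        _w(_step2_table(rep), f"step2_{level}.csv")
        for measure, res3 in rep["step3"].items():
            best = res3["models"]
            _w(
                best[best["best"]][["labels", "aicc", "delta_aicc", "r2m", "r2c"]],
                f"step3_best_{level}_{measure}.csv",
            )
        s4 = pd.concat(
            [df for df in rep["step4"].values() if not df.empty],
            ignore_index=True,
        ) if rep["step4"] else pd.DataFrame()
        _w(s4, f"step4_{level}.csv")

    if make_figure:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        panels = [
            (level, measure, res3)
            for level in ("node", "link")
            for measure, res3 in report[level]["step3"].items()
        ]
        if panels:
            fig, axes = plt.subplots(len(panels), 1,
                                     figsize=(6, 2.2 * len(panels)),
                                     squeeze=False)
            for ax, (level, measure, res3) in zip(axes[:, 0], panels):
                aicc = np.asarray(res3["aicc"], dtype=float)
                scaled = (aicc - aicc.mean()) / (aicc.std() or 1.0)
                from scipy.stats import gaussian_kde
                xs = np.linspace(scaled.min() - 0.5, scaled.max() + 0.5, 200)
                if len(scaled) > 1 and scaled.std() > 0:
                    ax.fill_between(xs, gaussian_kde(scaled)(xs), color="0.8")
                q05 = np.quantile(scaled, 0.05)
                ax.axvline(q05, color="tab:blue", label="95% boundary")
                s4 = report[level]["step4"].get(measure)
                if s4 is not None and not s4.empty:
                    for a in s4["aicc"]:
                        z = (a - aicc.mean()) / (aicc.std() or 1.0)
                        ax.axvline(z, color="gold")
                ax.set_title(f"{measure} ({level} level)", fontsize=9)
                ax.set_yticks([])
            axes[-1, 0].set_xlabel("scaled AICc")
            fig.tight_layout()
            p = outdir / "aicc_density.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)
    return written


# ---- staged driver -------------------------------------------------------

def _content_hash(parts: list[str]) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(p.encode())
    return h.hexdigest()[:16]


def run_stage(study: dict, cfg: PipelineConfig, stage: str, outdir: str | Path,
              **kwargs) -> int:
    """Run one pipeline stage (or ``all``) writing outputs under ``outdir``.

    Idempotent on unchanged inputs: a content hash of the configuration and
    genotype tables is stored alongside the outputs and the stage is skipped
    when it matches.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stage not in ("inputs", "selection", "all"):
        raise ValueError(f"unknown stage {stage!r}")
    stamp = outdir / f".stage_{stage}.hash"
    digest = _content_hash([
        json.dumps(sorted(cfg.__dict__.items(), key=str), default=str),
        str(study["plants"].to_frame().to_csv(index=False)),
        str(study["bees"].to_frame().to_csv(index=False)),
        stage, str(sorted(kwargs.items())),
    ])
    if stamp.exists() and stamp.read_text() == digest:
        return 0
    inputs = compute_inputs(study, cfg, restarts=kwargs.get("restarts"))
    for name in ("node_metrics", "link_metrics", "node_responses",
                 "link_responses"):
        inputs[name].to_csv(outdir / f"{name}.csv", index=False)
    if stage in ("selection", "all"):
        report = run_selection(inputs, cfg,
                               step3_max_models=kwargs.get("step3_max_models"))
        write_report(report, outdir, make_figure=kwargs.get("figure", True))
    stamp.write_text(digest)
    return 0
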