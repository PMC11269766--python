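"""Four-step model-selection framework linking landscape, linker and herb.

Step 1 models the pollinator movement indicators (NESTS_shared and
FOREST_PATCHES_shared at the node level, BomD_PS at the link level) as
functions of landscape metrics: first the best spatial scale (buffer radius
or strip ratio) and polynomial degree are chosen per metric by AICc, then
metrics are preselected by likelihood-ratio tests at a tolerant alpha = 0.15,
and finally all subsets of the preselected metrics (at most two distinct
metrics at the node level, four at the link level, collinear combinations
with |r| >= 0.7 excluded) are ranked by AICc.  All models within Delta AICc
< 2 of the best are kept.

Step 2 refits the term sets of the Step 1 best models with the forest herb's
population-genetic measures (A_r, He, Ho, F at the node level; PolD_PS at the
link level) as responses.  Step 3 enumerates models over *all* landscape
metrics at *all* scales (quadratic terms free, but only together with their
linear term) under the same limits, giving a reference AICc distribution per
measure.  Step 4 asks whether a Step 2 model beats 95% of the Step 3
distribution: the percentile is the fraction of Step 3 AICc values strictly
greater than the Step 2 model's AICc (ties count as not exceeded; the Step 2
model itself is not part of the distribution).

The term-count limits count distinct metrics: a quadratic term rides along
with its linear term without using up a slot.  Geographic distance enters the
link-level candidate set as one extra scale-free metric.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .mixed_models import (
    FitResult, box_cox_transform, fit_link_mlpe, fit_node_lmm, lrt, standardize,
)

__all__ = [
    "Term", "ModelData", "prepare_model_data", "fit_model",
    "step1_scale_selection", "step1_preselect", "step1_subset_search",
    "step1", "step2_fit", "step3_enumerate", "step4_percentile",
    "count_enumerated_models", "best_models",
]


@dataclass(frozen=True)
class Term:
    """One candidate model term: a metric at a scale, linear or quadratic."""

    metric: str
    scale: str          # radius ("125".."2000"), ratio ("1to7".."2to3") or "-"
    degree: int = 1     # 2 = linear + quadratic of the same column

    @property
    def column(self) -> str:
        return self.metric if self.scale == "-" else f"{self.metric}{self.scale}"

    def labels(self) -> list[str]:
        if self.degree == 2:
            return [self.column, f"{self.column}^2"]
        return [self.column]


@dataclass
class ModelData:
    """Merged, Box-Cox-transformed and standardized analysis table."""

    df: pd.DataFrame
    level: str                       # "node" | "link"
    windows: np.ndarray
    pairs: list[tuple] | None        # link level only
    candidates: list[str]            # usable metric column names
    responses: list[str]
    lambdas: dict[str, float] = field(default_factory=dict)

    def corr(self, cols: Sequence[str]) -> pd.DataFrame:
        return self.df[list(cols)].corr()


def prepare_model_data(
    wide_metrics: pd.DataFrame,
    responses: pd.DataFrame,
    level: str,
    response_cols: Sequence[str],
) -> ModelData:
    """Merge responses with wide metric columns and transform everything.

    Every variable (responses and metrics alike) is Box-Cox transformed
    (lambda on a [-3, 3] grid, automatic shift for non-positive values) and
    then standardized to mean 0, SD 1.  Metric columns that are constant
    over units are dropped from the candidate list.
    """
    df = responses.merge(wide_metrics, on=["window", "unit"], how="inner")
    if df.empty:
        raise ValueError("responses and metric table share no units")
    meta = {"window", "unit"}
    numeric = [c for c in df.columns if c not in meta]
    candidates, lambdas = [], {}
    for col in numeric:
        x = df[col].to_numpy(dtype=float)
        if np.std(x) == 0 or not np.isfinite(x).all():
            continue
        y, lam, _ = box_cox_transform(x)
        z, _, _ = standardize(y)
        df[col] = z
        lambdas[col] = lam
        if col not in response_cols:
            candidates.append(col)
    pairs = None
    if level == "link":
        split = df["unit"].astype(str).str.split("|", expand=True)
        if split.shape[1] != 2:
            raise ValueError("link-level units must be 'popA|popB' pairs")
        pairs = list(zip(split[0], split[1]))
    usable_responses = [c for c in response_cols if c in lambdas]
    return ModelData(df=df, level=level, windows=df["window"].to_numpy(),
                     pairs=pairs, candidates=candidates,
                     responses=usable_responses, lambdas=lambdas)


def _design(data: ModelData, terms: Sequence[Term]) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(data.df))]
    names = ["(Intercept)"]
    for t in terms:
        z = data.df[t.column].to_numpy(dtype=float)
        cols.append(z)
        names.append(t.column)
        if t.degree == 2:
            q, _, _ = standardize(z ** 2)
            cols.append(q)
            names.append(f"{t.column}^2")
    return np.column_stack(cols), names


def fit_model(data: ModelData, response: str, terms: Sequence[Term]
              ) -> FitResult | None:
    """Fit one model; returns None on convergence/feasibility failure."""
    y = data.df[response].to_numpy(dtype=float)
    try:
        X, names = _design(data, terms)
        if data.level == "link":
            fit = fit_link_mlpe(y, X, data.pairs, data.windows, names)
        else:
            fit = fit_node_lmm(y, X, data.windows, names)
    except (np.linalg.LinAlgError, ValueError):
        return None
    return fit if fit.converged else None


# ---- Step 1 --------------------------------------------------------------

def step1_scale_selection(
    data: ModelData, response: str, metrics: Iterable[str],
    scales: Iterable[str],
) -> pd.DataFrame:
    """Best scale and degree per metric for one movement indicator.

    Fits the single-metric model at every scale, linear and with an added
    quadratic term, and keeps the variant with the lowest AICc.  Ties break
    toward the smaller scale and the lower degree.
    """
    rows = []
    scales = list(scales)
    for metric in metrics:
        best = None
        for si, scale in enumerate(scales):
            for degree in (1, 2):
                term = Term(metric, scale, degree)
                if term.column not in data.candidates:
                    continue
                fit = fit_model(data, response, [term])
                if fit is None:
                    continue
                key = (fit.aicc, si, degree)
                if best is None or key < best[0]:
                    best = (key, term, fit)
        if best is None:
            continue
        _, term, fit = best
        rows.append({
            "response": response, "metric": metric, "scale": term.scale,
            "degree": term.degree, "aicc": fit.aicc, "loglik": fit.loglik,
        })
    return pd.DataFrame(rows)


def step1_preselect(data: ModelData, response: str, scale_table: pd.DataFrame,
                    alpha: float = 0.15) -> pd.DataFrame:
    """Retain metrics whose chosen single-metric model beats the null (LRT).

    The chosen variant (with its scale and degree from scale selection) is
    tested against the intercept-only model; metrics with p <= alpha pass.
    """
    null_fit = fit_model(data, response, [])
    if null_fit is None:
        raise RuntimeError("intercept-only model failed to fit")
    out = scale_table.copy()
    ps = []
    for _, row in out.iterrows():
        fit = fit_model(data, response, [Term(row["metric"], row["scale"], int(row["degree"]))])
        ps.append(np.nan if fit is None else lrt(fit, null_fit))
    out["lrt_p"] = ps
    out["retained"] = out["lrt_p"] <= alpha
    return out


def _collinear_ok(data: ModelData, terms: Sequence[Term], threshold: float) -> bool:
    cols = [t.column for t in terms]
    if len(cols) < 2:
        return True
    corr = data.df[cols].corr().to_numpy()
    iu = np.triu_indices(len(cols), k=1)
    return bool((np.abs(corr[iu]) < threshold).all())


def _rank(models: list[tuple[tuple[Term, ...], FitResult]], delta: float
          ) -> pd.DataFrame:
    rows = []
    for terms, fit in models:
        rows.append({
            "terms": terms,
            "labels": " + ".join(l for t in terms for l in t.labels()) or "(null)",
            "aicc": fit.aicc, "loglik": fit.loglik,
            "r2m": fit.r2_marginal, "r2c": fit.r2_conditional,
            "fit": fit,
        })
    df = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    df["delta_aicc"] = df["aicc"] - df["aicc"].min()
    df["best"] = df["delta_aicc"] < delta
    return df


def step1_subset_search(
    data: ModelData, response: str, retained: pd.DataFrame,
    max_metrics: int, collinearity: float = 0.7, delta: float = 2.0,
) -> pd.DataFrame:
    """All-subsets search over retained metrics at their selected scale/degree."""
    terms_pool = [
        Term(r["metric"], r["scale"], int(r["degree"]))
        for _, r in retained[retained["retained"]].iterrows()
    ]
    models = []
    for size in range(1, max_metrics + 1):
        for combo in itertools.combinations(terms_pool, size):
            if not _collinear_ok(data, combo, collinearity):
                continue
            fit = fit_model(data, response, list(combo))
            if fit is not None:
                models.append((combo, fit))
    if not models:
        return pd.DataFrame(columns=["terms", "labels", "aicc", "loglik",
                                     "r2m", "r2c", "fit", "delta_aicc", "best"])
    return _rank(models, delta)


def step1(
    data: ModelData, response: str, metrics: Iterable[str], scales: Iterable[str],
    cfg: PipelineConfig,
) -> dict:
    """Full Step 1 for one movement indicator; returns tables keyed by stage."""
    max_metrics = cfg.max_terms_link if data.level == "link" else cfg.max_terms_node
    scale_table = step1_scale_selection(data, response, metrics, scales)
    presel = step1_preselect(data, response, scale_table, cfg.alpha_preselect)
    subsets = step1_subset_search(
        data, response, presel, max_metrics, cfg.collinearity_r, cfg.delta_aicc,
    )
    return {"scale_table": scale_table, "preselection": presel, "models": subsets}


def best_models(subsets: pd.DataFrame) -> list[tuple[Term, ...]]:
    """Term sets of the Delta-AICc < 2 band of a ranked model table."""
    if subsets.empty:
        return []
    return [tuple(t) for t in subsets.loc[subsets["best"], "terms"]]


# ---- Step 2 --------------------------------------------------------------

def step2_fit(
    data: ModelData, measures: Sequence[str],
    term_sets: Sequence[tuple[Term, ...]],
) -> pd.DataFrame:
    """Refit the Step 1 best term sets with genetic measures as responses."""
    rows = []
    for measure in measures:
        for terms in term_sets:
            fit = fit_model(data, measure, list(terms))
            if fit is None:
                continue
            rows.append({
                "measure": measure, "terms": terms,
                "labels": " + ".join(l for t in terms for l in t.labels()),
                "aicc": fit.aicc, "r2m": fit.r2_marginal,
                "r2c": fit.r2_conditional, "fit": fit,
            })
    return pd.DataFrame(rows)


# ---- Step 3 --------------------------------------------------------------

def _candidate_terms(data: ModelData, metrics: Iterable[str],
                     scales: Iterable[str]) -> list[tuple[str, list[str]]]:
    """Per metric, the scales actually available in the data."""
    out = []
    for metric in metrics:
        if metric == "DISTANCE":
            if "DISTANCE" in data.candidates:
                out.append((metric, ["-"]))
            continue
        avail = [s for s in scales if f"{metric}{s}" in data.candidates]
        if avail:
            out.append((metric, avail))
    return out


def count_enumerated_models(
    n_scales_per_metric: Sequence[int], max_metrics: int,
    quadratics: bool = True,
) -> int:
    """Closed-form model count without collinearity exclusions.

    Each chosen metric contributes (number of scales) x (2 if quadratics are
    allowed else 1) variants; models take 1..max_metrics distinct metrics.
    """
    per = [s * (2 if quadratics else 1) for s in n_scales_per_metric]
    total = 0
    for size in range(1, max_metrics + 1):
        for combo in itertools.combinations(per, size):
            total += math.prod(combo)
    return total


def step3_enumerate(
    data: ModelData, measure: str, metrics: Iterable[str], scales: Iterable[str],
    cfg: PipelineConfig, max_models: int | None = None, seed: int = 0,
    quadratics: bool = True,
) -> dict:
    """AICc distribution over all landscape-metric combinations for one measure.

    Enumerates every model of 1..max distinct metrics, each at any scale,
    with and (optionally) without a quadratic term per metric, excluding
    collinear combinations and convergence failures.  With ``max_models`` the
    universe is uniformly subsampled (seeded) -- the documented scaled-down
    mode for large link-level universes.
    """
    max_metrics = cfg.max_terms_link if data.level == "link" else cfg.max_terms_node
    pool = _candidate_terms(data, metrics, scales)
    universe: list[tuple[Term, ...]] = []
    for size in range(1, max_metrics + 1):
        for metric_combo in itertools.combinations(pool, size):
            scale_choices = [
                [Term(m, s, d) for s in avail for d in ((1, 2) if quadratics else (1,))]
                for m, avail in metric_combo
            ]
            for terms in itertools.product(*scale_choices):
                universe.append(terms)
    n_universe = len(universe)
    if max_models is not None and n_universe > max_models:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n_universe, size=max_models, replace=False)
        universe = [universe[i] for i in sorted(idx)]
    aiccs, kept, n_excluded, n_failed = [], [], 0, 0
    for terms in universe:
        if not _collinear_ok(data, terms, cfg.collinearity_r):
            n_excluded += 1
            continue
        fit = fit_model(data, measure, list(terms))
        if fit is None:
            n_failed += 1
            continue
        aiccs.append(fit.aicc)
        kept.append((terms, fit))
    if not aiccs:
        raise RuntimeError(f"no Step 3 model could be fitted for {measure}")
    ranked = _rank(kept, cfg.delta_aicc)
    return {
        "measure": measure,
        "aicc": np.array(aiccs),
        "models": ranked,
        "n_universe": n_universe,
        "n_collinear_excluded": n_excluded,
        "n_convergence_failed": n_failed,
        "subsampled": max_models is not None and n_universe > max_models,
    }


# ---- Step 4 --------------------------------------------------------------

def step4_percentile(step2_aicc: float, step3_aiccs: np.ndarray,
                     criterion: float = 0.95) -> tuple[float, bool]:
    """Fraction of Step 3 AICc values strictly above the Step 2 value.

    Ties count as not exceeded (conservative); the model passes when the
    percentile reaches the criterion (default 95%).
    """
    step3_aiccs = np.asarray(step3_aiccs, dtype=float)
    if len(step3_aiccs) == 0:
        raise ValueError("empty Step 3 AICc distribution")
    pct = float(np.mean(step3_aiccs > step2_aicc))
    return pct, pct >= criterion
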