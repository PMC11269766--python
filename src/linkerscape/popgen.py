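"""Population-genetic measures for co-dominant markers.

Node-level measures per population: rarefied allelic richness (A_r), unbiased
expected heterozygosity (He), observed heterozygosity (Ho) and the F-value.
Link-level measure per population pair: D_PS, one minus the proportion of
shared alleles.  All measures average over loci with per-locus complete-case
handling of missing genotypes.

The F-value follows the convention F = 1 - Ho/He, so heterozygote excess
(Ho > He), the typical state of partially clonal herb populations with few
effective pollen donors, yields negative F, and F approaches 0 as gene flow
pushes populations toward Hardy-Weinberg proportions.  A legacy ratio variant
He/Ho is available behind a flag.
"""

from __future__ import annotations

import warnings
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import GenotypeTable

__all__ = [
    "observed_heterozygosity", "expected_heterozygosity", "f_value",
    "allelic_richness", "dps", "detect_clones", "population_measures",
    "pairwise_dps",
]


def _locus_calls(table: GenotypeTable, locus: int) -> np.ndarray:
    """(m, 2) allele pairs with complete calls at one locus."""
    a = table.alleles[:, locus, :]
    return a[(a > 0).all(axis=1)]


def observed_heterozygosity(table: GenotypeTable, pop=None) -> float:
    """Mean over loci of the fraction of heterozygous individuals."""
    t = table if pop is None else table.for_pop(pop)
    vals = []
    for l in range(t.n_loci):
        calls = _locus_calls(t, l)
        if len(calls) == 0:
            continue
        vals.append(float(np.mean(calls[:, 0] != calls[:, 1])))
    if not vals:
        raise ValueError("no complete genotypes")
    return float(np.mean(vals))


def expected_heterozygosity(table: GenotypeTable, pop=None) -> float:
    """Unbiased gene diversity (2n/(2n-1)) (1 - sum p_k^2), averaged over loci."""
    t = table if pop is None else table.for_pop(pop)
    vals = []
    for l in range(t.n_loci):
        calls = _locus_calls(t, l)
        if len(calls) < 2:
            if len(calls):
                warnings.warn(f"locus {t.locus_names[l]}: <2 complete genotypes, skipped")
            continue
        copies = calls.ravel()
        _, counts = np.unique(copies, return_counts=True)
        p = counts / counts.sum()
        n2 = len(copies)
        vals.append(n2 / (n2 - 1) * (1.0 - float((p ** 2).sum())))
    if not vals:
        raise ValueError("no locus with enough data")
    return float(np.mean(vals))


def f_value(he: float, ho: float,
            convention: Literal["one_minus_ratio", "ratio"] = "one_minus_ratio") -> float:
    """Departure from Hardy-Weinberg proportions; negative under het excess."""
    if he == 0:
        raise ValueError("F undefined for He = 0 (monomorphic population)")
    if convention == "ratio":
        return he / ho
    return 1.0 - ho / he


def _rarefied_locus_richness(counts: np.ndarray, g: int) -> float:
    """Expected allele count in g gene copies drawn without replacement."""
    n = counts.sum()
    if g > n:
        raise ValueError(f"rarefaction size g={g} exceeds {n} copies")
    # P(allele k present) = 1 - C(N - N_k, g) / C(N, g), via log-gammas
    def logc(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
    present = np.ones(len(counts))
    ok = n - counts >= g
    present[ok] = 1.0 - np.exp(logc(n - counts[ok], g) - logc(n, g))
    return float(present.sum())


def allelic_richness(table: GenotypeTable, pop=None, g: int | None = None) -> float:
    """Rarefied allelic richness, averaged over loci.

    ``g`` is the rarefaction size in gene copies.  By default it is the
    smallest complete-call copy count over all (population, locus) cells of
    the full table, so values are comparable across populations.
    """
    if g is None:
        g = min_copy_count(table)
    t = table if pop is None else table.for_pop(pop)
    vals = []
    for l in range(t.n_loci):
        calls = _locus_calls(t, l)
        if len(calls) == 0:
            continue
        _, counts = np.unique(calls.ravel(), return_counts=True)
        vals.append(_rarefied_locus_richness(counts, g))
    if not vals:
        raise ValueError("no complete genotypes")
    return float(np.mean(vals))


def min_copy_count(table: GenotypeTable) -> int:
    """Smallest per-(population, locus) number of complete gene copies."""
    best = None
    for pop in table.populations():
        t = table.for_pop(pop)
        for l in range(t.n_loci):
            m = 2 * len(_locus_calls(t, l))
            if m and (best is None or m < best):
                best = m
    if best is None:
        raise ValueError("empty genotype table")
    return best


def _pop_freqs(table: GenotypeTable, locus: int) -> dict[int, float]:
    calls = _locus_calls(table, locus).ravel()
    if len(calls) == 0:
        return {}
    al, counts = np.unique(calls, return_counts=True)
    return dict(zip(al.tolist(), (counts / counts.sum()).tolist()))


def dps(table: GenotypeTable, pop_a, pop_b,
        method: Literal["frequency", "individual"] = "frequency") -> float:
    """D_PS = 1 minus the proportion of shared alleles between two populations.

    The default compares population allele-frequency profiles per locus
    (shared proportion = sum_k min(p_kA, p_kB), averaged over loci).  The
    ``individual`` variant averages the classic shared-allele proportion over
    all between-population individual pairs.
    """
    ta, tb = table.for_pop(pop_a), table.for_pop(pop_b)
    if method == "individual":
        return _dps_individual(ta, tb)
    shared = []
    for l in range(ta.n_loci):
        fa, fb = _pop_freqs(ta, l), _pop_freqs(tb, l)
        if not fa or not fb:
            continue
        s = sum(min(fa[k], fb.get(k, 0.0)) for k in fa)
        shared.append(s)
    if not shared:
        raise ValueError("no shared locus with data")
    return 1.0 - float(np.mean(shared))


def _dps_individual(ta: GenotypeTable, tb: GenotypeTable) -> float:
    sims = []
    for i in range(ta.n):
        for j in range(tb.n):
            per_locus = []
            for l in range(ta.n_loci):
                g1 = ta.alleles[i, l]
                g2 = tb.alleles[j, l]
                if (g1 == 0).any() or (g2 == 0).any():
                    continue
                shared = 0
                pool = list(g2)
                for a in g1:
                    if a in pool:
                        shared += 1
                        pool.remove(a)
                per_locus.append(shared / 2.0)
            if per_locus:
                sims.append(np.mean(per_locus))
    return 1.0 - float(np.mean(sims))


def detect_clones(table: GenotypeTable, missing_tolerant: bool = False) -> list[list]:
    """Group individuals with identical multilocus genotypes.

    Genotypes are compared with alleles sorted within each locus.  With
    ``missing_tolerant`` a locus missing in either individual is treated as a
    match (groups are then built by single linkage).
    """
    keys = np.sort(table.alleles, axis=2)
    if not missing_tolerant:
        groups: dict[bytes, list] = {}
        for i in range(table.n):
            groups.setdefault(keys[i].tobytes(), []).append(table.ids[i])
        return [g for g in groups.values()]
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(range(table.n))
    for i in range(table.n):
        for j in range(i + 1, table.n):
            a, b = keys[i], keys[j]
            ok = True
            for l in range(table.n_loci):
                if (a[l] == 0).any() or (b[l] == 0).any():
                    continue
                if not np.array_equal(a[l], b[l]):
                    ok = False
                    break
            if ok:
                g.add_edge(i, j)
    return [[table.ids[i] for i in comp] for comp in nx.connected_components(g)]


# ---- tables --------------------------------------------------------------

def population_measures(table: GenotypeTable, g: int | None = None) -> pd.DataFrame:
    """Per-population A_r, He, Ho and F for every population in the table."""
    if g is None:
        g = min_copy_count(table)
    rows = []
    for pop in table.populations():
        t = table.for_pop(pop)
        he = expected_heterozygosity(t)
        ho = observed_heterozygosity(t)
        rows.append({
            "window": t.windows[0], "unit": pop,
            "A_r": allelic_richness(t, g=g), "He": he, "Ho": ho,
            "F": f_value(he, ho), "n": t.n,
        })
    return pd.DataFrame(rows)


def pairwise_dps(table: GenotypeTable, name: str = "DPS") -> pd.DataFrame:
    """Within-window pairwise D_PS table (one row per population pair)."""
    rows = []
    for w in pd.unique(table.windows):
        tw = table.for_window(w)
        pops = sorted(tw.populations())
        for i, a in enumerate(pops):
            for b in pops[i + 1:]:
                rows.append({
                    "window": w, "unit": f"{a}|{b}",
                    name: dps(tw, a, b),
                })
    return pd.DataFrame(rows)
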