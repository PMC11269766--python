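"""Full-sib family (nest) reconstruction and among-patch movement indicators.

Bumblebee workers from the same nest are full siblings: under monogamy every
nest is one queen mated with a single male.  The module reconstructs nests
from worker multilocus genotypes by maximising the full partition likelihood
-- the product over families of the family likelihood, where each family
likelihood marginalises over the unobserved parental pair assuming
Hardy-Weinberg parental genotypes at window allele frequencies and Mendelian
transmission, with an optional uniform per-allele mistyping rate.

The search is a greedy pair-merge from the all-singletons partition followed
by simulated-annealing refinement (move / merge / split moves).  Repeated
restarts with different random seeds yield per-pair support values: the
fraction of restarts in which two workers land in the same family.  Two
independently seeded reconstruction runs are combined by the consensus rule:
a worker pair is accepted as full sibs only if its support exceeds the
threshold (default 0.8) in both runs; consensus families are the connected
components of accepted pairs.

Per-family parental allele support is restricted to alleles observed in the
family plus one pooled "any other allele" class.  At mistyping rate 0 this
lumping is exact (unobserved parental alleles are exchangeable); at small
positive rates it is a close approximation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .genotypes import GenotypeTable
from .popgen import dps as _dps

__all__ = [
    "allele_frequencies", "pair_fullsib_lr", "reconstruct_families",
    "consensus_pairs", "movement_indicators", "bom_dps", "SibshipPartition",
]


# ---- allele frequencies --------------------------------------------------

def allele_frequencies(table: GenotypeTable) -> list[dict[int, float]]:
    """Per-locus allele frequency dictionaries from all complete calls."""
    out = []
    for l in range(table.n_loci):
        a = table.alleles[:, l, :]
        calls = a[(a > 0).all(axis=1)].ravel()
        if len(calls) == 0:
            out.append({})
            continue
        al, counts = np.unique(calls, return_counts=True)
        out.append(dict(zip(al.tolist(), (counts / counts.sum()).tolist())))
    return out


def _floor_freqs(freqs: dict[int, float], alleles: np.ndarray, n_copies: int
                 ) -> dict[int, float]:
    """Floor frequencies of observed-but-unlisted alleles at 1/(2N+1)."""
    floor = 1.0 / (n_copies + 1)
    out = dict(freqs)
    missing = [int(a) for a in np.unique(alleles) if a > 0 and a not in out]
    if missing:
        warnings.warn(f"{len(missing)} observed allele(s) had zero reference "
                      f"frequency; floored at {floor:.4g}")
        for a in missing:
            out[a] = floor
        z = sum(out.values())
        out = {k: v / z for k, v in out.items()}
    return out


# ---- family likelihood ---------------------------------------------------

def _locus_family_loglik(genos: np.ndarray, freqs: dict[int, float], err: float
                         ) -> float:
    """Log-likelihood of one family's genotypes at one locus under monogamy.

    ``genos``: (s, 2) observed allele labels, rows with 0 are skipped
    (missing).  Marginalises over the queen and male genotype pair
    (Hardy-Weinberg parental priors, Mendelian transmission, mistyping
    smeared toward population frequencies).  Scalar inner loops: the
    problem sizes (<= ~6 candidate alleles, small families) are below the
    regime where array dispatch pays off.
    """
    rows = [(int(a), int(b)) for a, b in genos if a > 0 and b > 0]
    s = len(rows)
    if s == 0:
        return 0.0
    obs = sorted({a for g in rows for a in g})
    n_obs = len(obs)
    idx = {a: k for k, a in enumerate(obs)}
    f_obs = [freqs.get(a, 0.0) for a in obs]
    rest = 1.0 - sum(f_obs)
    cand_f = f_obs + [rest] if rest > 1e-12 else list(f_obs)
    m = len(cand_f)
    # parental genotypes (unordered allele pairs over candidate alleles);
    # the pooled remainder allele (index >= n_obs) never transmits an
    # observed allele except through mistyping
    prior: list[float] = []
    emis: list[list[float]] = []    # per genotype, P(observe allele k)
    for i in range(m):
        for j in range(i, m):
            prior.append(cand_f[i] ** 2 if i == j else 2.0 * cand_f[i] * cand_f[j])
            emis.append([
                (1.0 - err) * 0.5 * ((i == k) + (j == k)) + err * f_obs[k]
                for k in range(n_obs)
            ])
    G = len(prior)
    xs = [idx[a] for a, _ in rows]
    ys = [idx[b] for _, b in rows]
    het = [a != b for a, b in rows]
    lik = 0.0
    for g in range(G):
        og = emis[g]
        pg = prior[g]
        if pg == 0.0:
            continue
        for h in range(G):
            ph = prior[h]
            if ph == 0.0:
                continue
            oh = emis[h]
            prod = 1.0
            for k in range(s):
                x, y = xs[k], ys[k]
                p = og[x] * oh[y]
                if het[k]:
                    p += og[y] * oh[x]
                prod *= p
                if prod == 0.0:
                    break
            lik += pg * ph * prod
    if lik <= 0.0:
        return -745.0 * s
    return math.log(lik)


class _FamilyScorer:
    """Cached family log-likelihoods over a fixed worker block.

    Singleton likelihoods use the closed form (a family of one marginalises
    to the plain Hardy-Weinberg genotype probability, for any mistyping
    rate); larger families go through the parental-pair enumeration, cached
    by member set so restarts and the second run reuse earlier evaluations.
    """

    def __init__(self, genos: np.ndarray, freqs: list[dict[int, float]],
                 err: float) -> None:
        self.genos = np.asarray(genos)          # (n, L, 2)
        self.n = len(self.genos)
        self.freqs = [
            _floor_freqs(freqs[l], self.genos[:, l, :], 2 * self.n)
            for l in range(self.genos.shape[1])
        ]
        self.err = err
        self._cache: dict[frozenset, float] = {}
        self._singleton = np.array([
            self._singleton_loglik(i) for i in range(self.n)
        ])
        self.candidates = self._candidate_pairs()

    def _singleton_loglik(self, i: int) -> float:
        total = 0.0
        for l, f in enumerate(self.freqs):
            x, y = self.genos[i, l]
            if x == 0 or y == 0:
                continue
            fx, fy = f[int(x)], f[int(y)]
            total += math.log(2.0 * fx * fy if x != y else fx * fx)
        return total

    def _candidate_pairs(self, min_share_frac: float = 0.75) -> np.ndarray:
        """Pairs sharing an allele at most loci -- the only plausible sibs.

        Full sibs share at least one allele at almost every locus, unrelated
        workers far less often with polymorphic markers; the screen prunes
        the quadratic search space without deciding anything by itself
        (annealing moves remain free to join any pair).
        """
        n, L = self.n, self.genos.shape[1]
        share = np.zeros((n, n))
        comparable = np.zeros((n, n))
        for l in range(L):
            a = self.genos[:, l, 0]
            b = self.genos[:, l, 1]
            ok = (a > 0)
            s = (
                (a[:, None] == a[None, :]) | (a[:, None] == b[None, :])
                | (b[:, None] == a[None, :]) | (b[:, None] == b[None, :])
            )
            both = ok[:, None] & ok[None, :]
            share += s & both
            comparable += both
        with np.errstate(invalid="ignore"):
            frac = np.where(comparable > 0, share / np.maximum(comparable, 1), 0.0)
        out = frac >= min_share_frac
        np.fill_diagonal(out, False)
        return out

    def loglik(self, members: frozenset) -> float:
        if len(members) == 1:
            (i,) = members
            return float(self._singleton[i])
        val = self._cache.get(members)
        if val is None:
            idx = sorted(members)
            val = sum(
                _locus_family_loglik(self.genos[idx, l, :], self.freqs[l], self.err)
                for l in range(self.genos.shape[1])
            )
            self._cache[members] = val
        return val

    def partition_loglik(self, families: list[frozenset]) -> float:
        return sum(self.loglik(f) for f in families)


def pair_fullsib_lr(g1: np.ndarray, g2: np.ndarray,
                    freqs: list[dict[int, float]], err: float = 0.0) -> float:
    """Log-likelihood ratio of two workers being full sibs versus unrelated.

    ``g1``/``g2`` are (L, 2) allele arrays.  The ratio sums per-locus
    log P(g1, g2 | FS) / [P(g1 | HWE) P(g2 | HWE)]; monomorphic loci
    contribute zero.
    """
    genos = np.stack([g1, g2])
    scorer = _FamilyScorer(genos, freqs, err)
    both = scorer.loglik(frozenset({0, 1}))
    singles = scorer.loglik(frozenset({0})) + scorer.loglik(frozenset({1}))
    return both - singles


# ---- partition search ----------------------------------------------------

@dataclass
class SibshipPartition:
    """Best-found full-sib partition of one worker block."""

    worker_ids: np.ndarray
    families: list[frozenset]               # index sets into worker_ids
    loglik: float
    support: np.ndarray                     # (n, n) co-assignment freq over restarts
    seed: int
    converged: bool = True

    def family_labels(self) -> np.ndarray:
        lab = np.empty(len(self.worker_ids), dtype=int)
        for k, fam in enumerate(self.families):
            for i in fam:
                lab[i] = k
        return lab

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "worker": self.worker_ids,
            "family": self.family_labels(),
        })


def _greedy_partition(scorer: _FamilyScorer, rng: np.random.Generator
                      ) -> list[frozenset]:
    """Best-first pair merging from singletons, over candidate pairs only."""
    n = scorer.n
    perm = rng.permutation(n)           # randomised worker order per restart
    families: dict[int, frozenset] = {int(i): frozenset({int(i)}) for i in perm}
    cand = scorer.candidates
    adj = {i: set(np.nonzero(cand[i])[0].tolist()) for i in range(n)}

    def linked(a: int, b: int) -> bool:
        fb = families[b]
        return any(not adj[i].isdisjoint(fb) for i in families[a])

    gains: dict[tuple[int, int], float] = {}

    def gain(a: int, b: int) -> float:
        key = (a, b) if a < b else (b, a)
        if key not in gains:
            fa, fb = families[a], families[b]
            gains[key] = (scorer.loglik(fa | fb)
                          - scorer.loglik(fa) - scorer.loglik(fb))
        return gains[key]

    # seed the agenda with families joined by a candidate worker pair
    agenda = {
        (int(i), int(j))
        for i, j in zip(*np.nonzero(np.triu(cand, k=1)))
    }
    while agenda:
        best, best_g = None, 1e-9
        for a, b in agenda:
            g = gain(a, b)
            if g > best_g:
                best, best_g = (a, b), g
        if best is None:
            break
        a, b = best
        families[a] = families[a] | families[b]
        del families[b]
        agenda = {p for p in agenda if b not in p and a not in p}
        gains = {k: v for k, v in gains.items() if a not in k and b not in k}
        for c in families:
            if c != a and linked(a, c):
                agenda.add((min(a, c), max(a, c)))
    return list(families.values())


def _anneal(scorer: _FamilyScorer, families: list[frozenset],
            rng: np.random.Generator, n_iter: int, t0: float = 2.0) -> list[frozenset]:
    n = len(scorer.genos)
    fams = [set(f) for f in families]
    member_of = {}
    for k, f in enumerate(fams):
        for i in f:
            member_of[i] = k
    cur = scorer.partition_loglik([frozenset(f) for f in fams if f])

    def flatten() -> list[frozenset]:
        return [frozenset(f) for f in fams if f]

    best, best_ll = flatten(), cur
    for it in range(n_iter):
        temp = t0 * (1.0 - it / max(1, n_iter)) + 1e-3
        kind = rng.random()
        if kind < 0.6:      # move one worker
            i = int(rng.integers(n))
            src = member_of[i]
            partners = np.nonzero(scorer.candidates[i])[0]
            targets = sorted({
                member_of[int(p)] for p in partners
                if member_of[int(p)] != src
            })
            if not targets:  # occasionally try an arbitrary family
                targets = [k for k in range(len(fams)) if fams[k] and k != src]
            dst = int(rng.choice(targets)) if targets and rng.random() < 0.7 else None
            old_src = frozenset(fams[src])
            new_src = frozenset(fams[src] - {i})
            if dst is None:
                if len(fams[src]) == 1:
                    continue
                delta = (scorer.loglik(new_src) + scorer.loglik(frozenset({i}))
                         - scorer.loglik(old_src))
                if delta > 0 or rng.random() < math.exp(delta / temp):
                    fams[src].discard(i)
                    fams.append({i})
                    member_of[i] = len(fams) - 1
                    cur += delta
            else:
                old_dst = frozenset(fams[dst])
                new_dst = frozenset(fams[dst] | {i})
                delta = (scorer.loglik(new_src) + scorer.loglik(new_dst)
                         - scorer.loglik(old_src) - scorer.loglik(old_dst))
                if delta > 0 or rng.random() < math.exp(delta / temp):
                    fams[src].discard(i)
                    fams[dst].add(i)
                    member_of[i] = dst
                    cur += delta
        elif kind < 0.85:   # merge two families
            alive = [k for k in range(len(fams)) if fams[k]]
            if len(alive) < 2:
                continue
            a, b = rng.choice(alive, size=2, replace=False)
            fa, fb = frozenset(fams[a]), frozenset(fams[b])
            delta = scorer.loglik(fa | fb) - scorer.loglik(fa) - scorer.loglik(fb)
            if delta > 0 or rng.random() < math.exp(delta / temp):
                fams[a] |= fams[b]
                for i in fams[b]:
                    member_of[i] = a
                fams[b] = set()
                cur += delta
        else:               # split a family by random bipartition
            alive = [k for k in range(len(fams)) if len(fams[k]) > 1]
            if not alive:
                continue
            a = int(rng.choice(alive))
            members = list(fams[a])
            pick = rng.random(len(members)) < 0.5
            left = {m for m, p in zip(members, pick) if p}
            right = set(members) - left
            if not left or not right:
                continue
            delta = (scorer.loglik(frozenset(left)) + scorer.loglik(frozenset(right))
                     - scorer.loglik(frozenset(fams[a])))
            if delta > 0 or rng.random() < math.exp(delta / temp):
                fams[a] = left
                fams.append(right)
                for i in right:
                    member_of[i] = len(fams) - 1
                cur += delta
        if cur > best_ll:
            best, best_ll = flatten(), cur
    return best


def reconstruct_families(
    table: GenotypeTable,
    seed: int,
    restarts: int = 20,
    err: float = 0.0,
    freqs: list[dict[int, float]] | None = None,
    anneal_iters_per_worker: int = 15,
    max_iter: int = 200_000,
    scorer: _FamilyScorer | None = None,
) -> SibshipPartition:
    """Reconstruct full-sib families for one (window, year) worker block.

    Runs ``restarts`` independent greedy + annealing searches; returns the
    highest-likelihood partition together with a per-pair support matrix
    (co-assignment frequency across restarts).  A prebuilt scorer may be
    passed to share its likelihood cache between runs.
    """
    n = table.n
    if n < 2:
        raise ValueError("need at least two workers")
    if freqs is None:
        freqs = allele_frequencies(table)
    if scorer is None:
        scorer = _FamilyScorer(table.alleles, freqs, err)
    rng = np.random.default_rng(seed)
    n_iter = min(max_iter, anneal_iters_per_worker * n)
    support = np.zeros((n, n))
    best_fams: list[frozenset] | None = None
    best_ll = -np.inf
    for _ in range(restarts):
        fams = _greedy_partition(scorer, rng)
        fams = _anneal(scorer, fams, rng, n_iter)
        ll = scorer.partition_loglik(fams)
        if ll > best_ll:
            best_ll, best_fams = ll, fams
        for fam in fams:
            idx = sorted(fam)
            for ii, a in enumerate(idx):
                for b in idx[ii + 1:]:
                    support[a, b] += 1
                    support[b, a] += 1
    support /= restarts
    np.fill_diagonal(support, 1.0)
    assert best_fams is not None
    singleton_ll = scorer.partition_loglik([frozenset({i}) for i in range(n)])
    return SibshipPartition(
        worker_ids=table.ids, families=sorted(best_fams, key=min),
        loglik=best_ll, support=support, seed=seed,
        converged=bool(best_ll >= singleton_ll - 1e-9),
    )


def reconstruct_blocks(
    table: GenotypeTable, seed: int, restarts: int = 20, err: float = 0.0,
    scorers: dict[tuple, _FamilyScorer] | None = None,
    **kwargs,
) -> dict[tuple, SibshipPartition]:
    """Reconstruct each (window, year) block separately, as in the field design."""
    years = table.years if table.years is not None else np.zeros(table.n, dtype=int)
    out: dict[tuple, SibshipPartition] = {}
    for bi, key in enumerate(sorted({(w, y) for w, y in zip(table.windows, years)})):
        w, y = key
        mask = (table.windows == w) & (years == y)
        block = table.subset(mask)
        out[key] = reconstruct_families(
            block, seed=seed + 7919 * bi, restarts=restarts, err=err,
            scorer=None if scorers is None else scorers.get(key), **kwargs,
        )
    return out


def two_run_blocks(
    table: GenotypeTable, seed: int, restarts: int = 20, err: float = 0.0,
    **kwargs,
) -> tuple[dict[tuple, SibshipPartition], dict[tuple, SibshipPartition]]:
    """Two independently seeded reconstruction runs per block.

    The two runs differ only in their random seeds (restart initialisation
    and annealing moves); likelihood evaluations are deterministic, so the
    runs share one cached scorer per block.
    """
    years = table.years if table.years is not None else np.zeros(table.n, dtype=int)
    scorers: dict[tuple, _FamilyScorer] = {}
    for key in sorted({(w, y) for w, y in zip(table.windows, years)}):
        mask = (table.windows == key[0]) & (years == key[1])
        block = table.subset(mask)
        scorers[key] = _FamilyScorer(block.alleles, allele_frequencies(block), err)
    run_a = reconstruct_blocks(table, seed=2 * seed + 1, restarts=restarts,
                               err=err, scorers=scorers, **kwargs)
    run_b = reconstruct_blocks(table, seed=2 * seed + 2, restarts=restarts,
                               err=err, scorers=scorers, **kwargs)
    return run_a, run_b


# ---- consensus and indicators --------------------------------------------

def consensus_pairs(
    run_a: SibshipPartition, run_b: SibshipPartition, threshold: float = 0.8,
) -> list[set]:
    """Families as connected components of pairs supported in both runs.

    A worker pair counts as a shared-nest pair only if its co-assignment
    support is strictly greater than ``threshold`` in both runs.
    """
    if not np.array_equal(run_a.worker_ids, run_b.worker_ids):
        raise ValueError("runs cover different workers")
    ids = run_a.worker_ids
    g = nx.Graph()
    g.add_nodes_from(range(len(ids)))
    ok = (run_a.support > threshold) & (run_b.support > threshold)
    for i, j in zip(*np.nonzero(np.triu(ok, k=1))):
        g.add_edge(int(i), int(j))
    return [{ids[i] for i in comp} for comp in nx.connected_components(g)]


def movement_indicators(
    families: list[set], worker_patch: dict, window_of_patch: dict | None = None,
) -> pd.DataFrame:
    """Per-patch among-patch movement indicators from assigned nests.

    A nest (family) is assigned to every patch where at least one of its
    workers was captured.  ``NESTS_shared`` for patch i is the fraction of
    nests assigned to i that are also assigned to at least one other patch;
    ``FOREST_PATCHES_shared`` is the number of other patches with which i
    shares at least one nest.
    """
    patches = sorted({worker_patch[w] for fam in families for w in fam})
    nest_patches = [sorted({worker_patch[w] for w in fam}) for fam in families]
    rows = []
    for p in patches:
        assigned = [ps for ps in nest_patches if p in ps]
        shared = [ps for ps in assigned if len(ps) > 1]
        partners = {q for ps in assigned for q in ps if q != p}
        rows.append({
            "unit": p,
            "NESTS_shared": len(shared) / len(assigned) if assigned else 0.0,
            "FOREST_PATCHES_shared": len(partners),
            "n_nests": len(assigned),
        })
    df = pd.DataFrame(rows)
    if window_of_patch is not None:
        df.insert(0, "window", df["unit"].map(window_of_patch))
    return df


def bom_dps(table: GenotypeTable, pop_a, pop_b, **kwargs) -> float:
    """Pairwise D_PS between the bumblebee samples of two patches."""
    return _dps(table, pop_a, pop_b, **kwargs)
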