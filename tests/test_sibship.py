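"""Sibship likelihoods against enumeration oracles; consensus and indicators."""

import itertools
import math

import numpy as np
import pytest

from linkerscape.sibship import (
    SibshipPartition, _FamilyScorer, allele_frequencies, consensus_pairs,
    movement_indicators, pair_fullsib_lr, reconstruct_families,
)
from tests.conftest import make_table


class TestAlleleFrequencies:
    def test_single_homozygote(self):
        t = make_table([("i", "A", [(3, 3)])])
        assert allele_frequencies(t) == [{3: 1.0}]

    def test_sum_to_one(self):
        rng = np.random.default_rng(0)
        t = make_table([
            (f"i{k}", "A", [tuple(rng.integers(1, 6, 2)), tuple(rng.integers(1, 4, 2))])
            for k in range(20)
        ])
        for f in allele_frequencies(t):
            assert sum(f.values()) == pytest.approx(1.0)

    def test_toy_table_oracle(self):
        t = make_table([("i", "A", [(1, 2)]), ("j", "A", [(2, 2)])])
        assert allele_frequencies(t) == [{1: 0.25, 2: 0.75}]


def fs_pair_prob_enumeration(g1, g2, freqs):
    """P(g1, g2 | full sibs) by summing over all 9 (or more) parental pairs."""
    alleles = sorted(freqs)
    genotypes = [
        (a, b) for i, a in enumerate(alleles) for b in alleles[i:]
    ]

    def hwe(g):
        a, b = g
        return freqs[a] ** 2 if a == b else 2 * freqs[a] * freqs[b]

    def transmit(parent, allele):
        return 0.5 * ((parent[0] == allele) + (parent[1] == allele))

    def mendel(child, q, m):
        x, y = child
        p = transmit(q, x) * transmit(m, y)
        if x != y:
            p += transmit(q, y) * transmit(m, x)
        return p

    return sum(
        hwe(q) * hwe(m) * mendel(g1, q, m) * mendel(g2, q, m)
        for q in genotypes for m in genotypes
    )


class TestPairLikelihood:
    def test_nine_parental_pair_enumeration_oracle(self):
        # one locus, two alleles at p = q = 0.5, both workers heterozygous
        freqs = [{1: 0.5, 2: 0.5}]
        g = np.array([[1, 2]])
        lr = pair_fullsib_lr(g, g, freqs)
        joint = fs_pair_prob_enumeration((1, 2), (1, 2), freqs[0])
        expected = math.log(joint / (0.5 * 0.5))  # HWE het prob = 2pq = 0.5
        assert lr == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("g1,g2", [
        ((1, 1), (1, 2)), ((1, 2), (3, 4)), ((2, 2), (3, 3)), ((1, 3), (1, 3)),
    ])
    def test_enumeration_oracle_multiple_genotypes(self, g1, g2):
        freqs = [{1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1}]
        lr = pair_fullsib_lr(np.array([g1]), np.array([g2]), freqs)

        def hwe(g):
            a, b = g
            return freqs[0][a] ** 2 if a == b else 2 * freqs[0][a] * freqs[0][b]

        joint = fs_pair_prob_enumeration(g1, g2, freqs[0])
        assert lr == pytest.approx(math.log(joint / (hwe(g1) * hwe(g2))), abs=1e-10)

    def test_monomorphic_locus_contributes_zero(self):
        freqs = [{1: 1.0}]
        lr = pair_fullsib_lr(np.array([[1, 1]]), np.array([[1, 1]]), freqs)
        assert lr == pytest.approx(0.0, abs=1e-12)

    def test_identical_rare_homozygotes_positive(self):
        freqs = [{1: 0.05, 2: 0.95}]
        g = np.array([[1, 1]])
        assert pair_fullsib_lr(g, g, freqs) > 0.0

    def test_missing_locus_skipped(self):
        freqs = [{1: 0.5, 2: 0.5}, {1: 0.5, 2: 0.5}]
        g1 = np.array([[1, 2], [0, 0]])
        g2 = np.array([[1, 2], [1, 1]])
        lr_two = pair_fullsib_lr(g1, g2, freqs)
        lr_one = pair_fullsib_lr(g1[:1], g2[:1], freqs[:1])
        assert lr_two == pytest.approx(lr_one)


def all_partitions(items):
    """Every set partition (Bell number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def simulate_nests(rng, n_nests, workers_per_nest, n_loci, n_alleles,
                   conc=1.0):
    """Monogamous nests: diploid queen, haploid male, Mendelian workers."""
    freqs = [rng.dirichlet(np.full(n_alleles, conc)) for _ in range(n_loci)]
    rows, truth = [], {}
    for nk in range(n_nests):
        queen = [(1 + rng.choice(n_alleles, p=f), 1 + rng.choice(n_alleles, p=f))
                 for f in freqs]
        male = [1 + rng.choice(n_alleles, p=f) for f in freqs]
        for wk in range(workers_per_nest):
            geno = [
                (queen[l][rng.integers(2)], male[l]) for l in range(n_loci)
            ]
            wid = f"n{nk}w{wk}"
            rows.append((wid, "P0", geno))
            truth[wid] = f"nest{nk}"
    rng.shuffle(rows)
    return make_table(rows), truth


class TestReconstruction:
    def test_three_workers_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        table, _ = simulate_nests(rng, n_nests=2, workers_per_nest=2,
                                  n_loci=6, n_alleles=8)
        table = table.subset(np.arange(3))
        freqs = allele_frequencies(table)
        scorer = _FamilyScorer(table.alleles, freqs, err=0.0)
        # 5 partitions of 3 items
        partitions = list(all_partitions(range(3)))
        assert len(partitions) == 5
        best_ll = max(
            scorer.partition_loglik([frozenset(f) for f in part])
            for part in partitions
        )
        part = reconstruct_families(table, seed=0, restarts=4)
        assert part.loglik == pytest.approx(best_ll, abs=1e-9)

    def test_identical_multilocus_genotypes_joined(self):
        geno = [(1, 2), (3, 4), (5, 6), (2, 7), (1, 8), (3, 3), (4, 9), (2, 5)]
        t = make_table([("a", "P", geno), ("b", "P", geno),
                        ("c", "P", [(x + 1, y + 1) for x, y in geno])])
        part = reconstruct_families(t, seed=1, restarts=3)
        fams = {frozenset(sorted(f)) for f in part.families}
        assert frozenset({0, 1}) in fams

    def test_partition_beats_singletons(self):
        rng = np.random.default_rng(6)
        table, _ = simulate_nests(rng, 4, 4, n_loci=8, n_alleles=10)
        part = reconstruct_families(table, seed=2, restarts=2)
        freqs = allele_frequencies(table)
        scorer = _FamilyScorer(table.alleles, freqs, 0.0)
        singles = scorer.partition_loglik(
            [frozenset({i}) for i in range(table.n)]
        )
        assert part.loglik >= singles - 1e-9
        assert part.converged

    def test_family_recovery_high_polymorphism(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(7)
        table, truth = simulate_nests(rng, 8, 4, n_loci=8, n_alleles=12)
        part = reconstruct_families(table, seed=3, restarts=4)
        lab_true = [truth[w] for w in table.ids]
        ari = adjusted_rand_score(lab_true, part.family_labels())
        assert ari >= 0.9


def make_partition(ids, families, support):
    return SibshipPartition(
        worker_ids=np.array(ids), families=[frozenset(f) for f in families],
        loglik=0.0, support=np.array(support, dtype=float), seed=0,
    )


class TestConsensus:
    def test_threshold_rules(self):
        ids = ["a", "b"]
        run_hi = make_partition(ids, [{0, 1}], [[1, 0.9], [0.9, 1]])
        run_lo = make_partition(ids, [{0}, {1}], [[1, 0.7], [0.7, 1]])
        accepted = consensus_pairs(run_hi, run_hi, 0.8)
        assert {frozenset(f) for f in accepted} == {frozenset({"a", "b"})}
        rejected = consensus_pairs(run_hi, run_lo, 0.8)
        assert all(len(f) == 1 for f in rejected)

    def test_transitive_chain_components(self):
        ids = ["a", "b", "c"]
        sup = [[1, 0.9, 0.0], [0.9, 1, 0.9], [0.0, 0.9, 1]]
        run = make_partition(ids, [{0, 1, 2}], sup)
        fams = consensus_pairs(run, run, 0.8)
        assert {frozenset(f) for f in fams} == {frozenset({"a", "b", "c"})}

    def test_threshold_one_subset_of_unanimous(self):
        rng = np.random.default_rng(8)
        table, _ = simulate_nests(rng, 5, 3, 8, 10)
        a = reconstruct_families(table, seed=1, restarts=5)
        b = reconstruct_families(table, seed=2, restarts=5)
        fams = consensus_pairs(a, b, threshold=1.0 - 1e-12)
        for fam in fams:
            idx = [list(table.ids).index(w) for w in fam]
            for i, j in itertools.combinations(idx, 2):
                assert a.support[i, j] == 1.0 and b.support[i, j] == 1.0


class TestMovementIndicators:
    def test_quarter_shared(self):
        families = [{"w1"}, {"w2"}, {"w3"}, {"w4", "w5"}]
        patch = {"w1": "A", "w2": "A", "w3": "A", "w4": "A", "w5": "B"}
        out = movement_indicators(families, patch).set_index("unit")
        assert out.loc["A", "NESTS_shared"] == pytest.approx(0.25)
        assert out.loc["A", "FOREST_PATCHES_shared"] == 1

    def test_no_multi_patch_nests(self):
        families = [{"w1"}, {"w2"}]
        patch = {"w1": "A", "w2": "B"}
        out = movement_indicators(families, patch).set_index("unit")
        assert (out["NESTS_shared"] == 0).all()
        assert (out["FOREST_PATCHES_shared"] == 0).all()

    def test_three_patch_hand_enumeration(self):
        # nest1 spans A+B, nest2 spans B+C, nest3 only C
        families = [{"a1", "b1"}, {"b2", "c1"}, {"c2"}]
        patch = {"a1": "A", "b1": "B", "b2": "B", "c1": "C", "c2": "C"}
        out = movement_indicators(families, patch).set_index("unit")
        assert out.loc["A", "NESTS_shared"] == 1.0
        assert out.loc["B", "NESTS_shared"] == 1.0
        assert out.loc["C", "NESTS_shared"] == pytest.approx(0.5)
        assert out.loc["A", "FOREST_PATCHES_shared"] == 1
        assert out.loc["B", "FOREST_PATCHES_shared"] == 2
        assert out.loc["C", "FOREST_PATCHES_shared"] == 1

    def test_invariant_to_family_relabeling(self):
        families = [{"a1", "b1"}, {"b2"}, {"c1"}]
        patch = {"a1": "A", "b1": "B", "b2": "B", "c1": "C"}
        out1 = movement_indicators(families, patch)
        out2 = movement_indicators(list(reversed(families)), patch)
        assert out1.equals(out2)
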