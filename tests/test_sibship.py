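"""Sibship Nb estimator: pair likelihoods, clustering, Q-fraction inversion."""

import itertools
import math

import numpy as np
import pytest

from cohortnb import sibship, synthdata
from cohortnb.sibship import PairRelationship, SibshipSummary

from conftest import matrix_from_dosage


# ---------------------------------------------------------------------------
# single-locus likelihood oracle: exhaustive enumeration over parental
# genotypes at one diallelic locus
# ---------------------------------------------------------------------------

def enumerate_pair_probs(p, relationship):
    """P(g1, g2) for dosages by brute-force enumeration of parents.

    unrelated: two children of two independent parent pairs;
    half-sib: children of (M, F1) and (M, F2);
    full-sib: two children of the same (M, F) pair. Parents drawn from
    HWE at allele-1 frequency p; fair Mendelian transmission.
    """
    q = 1 - p
    gp = {0: q * q, 1: 2 * p * q, 2: p * p}

    def transmit(g):  # P(allele | parent dosage)
        return {0: {0: 1.0, 1: 0.0}, 1: {0: 0.5, 1: 0.5}, 2: {0: 0.0, 1: 1.0}}[g]

    out = np.zeros((3, 3))
    parents = list(itertools.product([0, 1, 2], repeat=4))  # M, F1, F2, F_extra
    for gm, gf1, gf2, gm2 in parents:
        w = gp[gm] * gp[gf1] * gp[gf2] * gp[gm2]
        for a1, pa1 in transmit(gm).items():
            for b1, pb1 in transmit(gf1).items():
                g1 = a1 + b1
                if relationship == "full-sib":
                    pairs2 = [(transmit(gm), transmit(gf1))]
                elif relationship == "half-sib":
                    pairs2 = [(transmit(gm), transmit(gf2))]
                else:
                    pairs2 = [(transmit(gm2), transmit(gf2))]
                for tm, tf in pairs2:
                    for a2, pa2 in tm.items():
                        for b2, pb2 in tf.items():
                            out[g1, a2 + b2] += w * pa1 * pb1 * pa2 * pb2
    return out


class TestPairTables:
    @pytest.mark.parametrize("p", [0.2, 0.5, 0.73])
    @pytest.mark.parametrize("rel", ["unrelated", "half-sib", "full-sib"])
    def test_tables_match_parental_enumeration(self, p, rel):
        tables = sibship.locus_pair_tables(np.array([p]), error_rate=0.0)
        got = np.exp(tables[rel][0])
        want = enumerate_pair_probs(p, rel)
        assert np.allclose(got, want, atol=1e-12)

    def test_tables_are_proper_distributions(self):
        tables = sibship.locus_pair_tables(np.array([0.3, 0.6]), error_rate=0.01)
        for h, t in tables.items():
            sums = np.exp(t).sum(axis=(1, 2))
            assert np.allclose(sums, 1.0, atol=1e-9), h

    def test_rare_allele_sharing_favours_full_sib(self):
        L = 60
        p = np.full(L, 0.03)
        g = np.full(L, 2.0)  # both individuals homozygous for the rare allele
        pr = sibship.pair_loglik(g, g, p, error_rate=0.001, min_shared=10)
        assert pr.best == "full-sib"
        assert pr.logliks["full-sib"] > pr.logliks["unrelated"]


class TestClassifyPairs:
    def test_clone_cohort_all_full_sib(self):
        rng = np.random.default_rng(0)
        base = rng.binomial(2, rng.uniform(0.3, 0.7, 400)).astype(float)
        dos = np.tile(base, (6, 1))
        calls = sibship.classify_pairs(matrix_from_dosage(dos), min_shared=50)
        assert all(c.best == "full-sib" for c in calls)

    def test_unrelated_pairs_called_unrelated(self):
        m, _, truth = synthdata.sample_cohort_from_parent_pool(
            400, 1000, 30, 1500, seed=1
        )
        calls = sibship.classify_pairs(m)
        mom, dad = truth["mother_of"], truth["father_of"]
        wrong = total = 0
        for c in calls:
            a, b = c.pair
            if mom[a] != mom[b] and dad[a] != dad[b]:
                total += 1
                wrong += c.best != "unrelated"
        assert total > 0
        assert wrong / total <= 0.01

    def test_permuted_genotypes_destroy_relationships(self):
        m, _, _ = synthdata.sample_cohort_from_parent_pool(50, 500, 30, 1500, seed=2)
        rng = np.random.default_rng(3)
        dos = m.dosage()
        for j in range(dos.shape[1]):
            rng.shuffle(dos[:, j])
        calls = sibship.classify_pairs(matrix_from_dosage(dos))
        sib_rate = np.mean([c.best != "unrelated" for c in calls])
        assert sib_rate <= 0.01

    def test_planted_family_recall(self):
        m, _, truth = synthdata.sample_cohort_from_parent_pool(50, 1000, 50, 3000, seed=4)
        calls = sibship.classify_pairs(m)
        mom, dad = truth["mother_of"], truth["father_of"]
        tp = fn = 0
        for c in calls:
            a, b = c.pair
            if mom[a] == mom[b] and dad[a] == dad[b]:
                tp += c.best == "full-sib"
                fn += c.best != "full-sib"
        assert tp / (tp + fn) >= 0.95

    def test_sparse_pair_demoted_with_nan_support(self):
        rng = np.random.default_rng(5)
        dos = rng.binomial(2, 0.5, (3, 120)).astype(float)
        dos[0, 30:] = np.nan  # only 30 co-called loci for pairs with s0
        calls = sibship.classify_pairs(matrix_from_dosage(dos), min_shared=100)
        with_s0 = [c for c in calls if "s0" in c.pair]
        assert all(c.best == "unrelated" and math.isnan(c.support) for c in with_s0)


class TestBuildSibgroups:
    def _fs(self, a, b, w=50.0):
        return PairRelationship((a, b), {}, "full-sib", w)

    def _hs(self, a, b, w=20.0):
        return PairRelationship((a, b), {}, "half-sib", w)

    def _un(self, a, b):
        return PairRelationship((a, b), {}, "unrelated", 0.0)

    def test_no_calls_all_q_zero(self):
        ids = [f"s{i}" for i in range(6)]
        calls = [self._un(a, b) for a, b in itertools.combinations(ids, 2)]
        s = sibship.build_sibgroups(calls, sample_ids=ids)
        assert (s.Q1, s.Q2, s.Q3) == (0.0, 0.0, 0.0)
        assert s.N1 == s.N2 == 6

    def test_family_of_three_combinatorics(self):
        ids = [f"s{i}" for i in range(10)]
        calls = [self._fs("s0", "s1"), self._fs("s1", "s2"), self._fs("s0", "s2")]
        s = sibship.build_sibgroups(calls, sample_ids=ids)
        assert s.Q3 == pytest.approx(3 / math.comb(10, 2))
        assert s.N2 == 8  # one family of three plus seven singletons

    def test_triangle_conflict_drops_weakest_edge(self):
        ids = ["a", "b", "c"]
        calls = [self._fs("a", "b", w=60), self._fs("b", "c", w=5), self._un("a", "c")]
        s = sibship.build_sibgroups(calls, sample_ids=ids)
        assert s.family_of["a"] == s.family_of["b"]
        assert s.family_of["c"] != s.family_of["a"]

    def test_half_sib_links_join_paternal_groups(self):
        ids = ["a", "b", "c", "d"]
        calls = [self._fs("a", "b"), self._fs("c", "d"), self._hs("a", "c")]
        s = sibship.build_sibgroups(calls, sample_ids=ids)
        assert s.N2 == 2  # two maternal families
        assert s.N1 == 1  # joined into one paternal group
        # implied half-sib dyads: all cross-family pairs within the group
        assert s.half_sib_pairs == 4
        assert s.Q1 == pytest.approx(4 / 6)

    def test_perfect_input_recovers_pedigree_counts(self):
        m, ped, truth = synthdata.sample_cohort_from_parent_pool(
            40, 600, 40, 10, seed=6
        )
        mom, dad = truth["mother_of"], truth["father_of"]
        ids = m.sample_ids
        calls = []
        for a, b in itertools.combinations(ids, 2):
            if mom[a] == mom[b] and dad[a] == dad[b]:
                calls.append(self._fs(a, b))
            elif mom[a] == mom[b] or dad[a] == dad[b]:
                calls.append(self._hs(a, b))
            else:
                calls.append(self._un(a, b))
        s = sibship.build_sibgroups(calls, sample_ids=ids)
        assert s.N2 == len({mom[i] for i in ids})
        # under bijective monogamy fathers mirror mothers
        assert s.N1 == len({dad[i] for i in ids})
        true_q3 = np.mean([mom[a] == mom[b] and dad[a] == dad[b]
                           for a, b in itertools.combinations(ids, 2)])
        assert s.Q3 == pytest.approx(true_q3)


class TestNbFromSibship:
    def _summary(self, q1=0.0, q2=0.0, q3=0.0, alpha=0.0, n1=10, n2=10):
        return SibshipSummary(Q1=q1, Q2=q2, Q3=q3, alpha=alpha, N1=n1, N2=n2,
                              full_sib_pairs=0, half_sib_pairs=0, n_samples=50)

    def test_direct_arithmetic(self):
        # alpha = 0, Q1 + Q2 + 2 Q3 = 0.02 -> Nb = 200
        s = self._summary(q1=0.01, q3=0.005)
        assert sibship.nb_from_sibship(s).point == pytest.approx(200.0)

    def test_no_signal_gives_infinity(self):
        assert math.isinf(sibship.nb_from_sibship(self._summary()).point)

    def test_alpha_zero_reduces_to_quarter_rule(self):
        s = self._summary(q1=0.004, q2=0.002, q3=0.003)
        expect = 4.0 / (0.004 + 0.002 + 2 * 0.003)
        assert sibship.nb_from_sibship(s).point == pytest.approx(expect)

    def test_monotone_in_sib_fractions(self):
        pts = [sibship.nb_from_sibship(self._summary(q3=q)).point
               for q in (0.001, 0.005, 0.01, 0.05)]
        assert all(b < a for a, b in zip(pts, pts[1:]))


class TestBootstrap:
    def test_seed_determinism(self):
        m, _, _ = synthdata.sample_cohort_from_parent_pool(50, 500, 40, 800, seed=7)
        a = sibship.bootstrap_ci(m, n_boot=50, seed=9)
        b = sibship.bootstrap_ci(m, n_boot=50, seed=9)
        c = sibship.bootstrap_ci(m, n_boot=50, seed=10)
        assert a == b
        assert a != c

    def test_clone_cohort_degenerate_interval(self):
        rng = np.random.default_rng(8)
        base = rng.binomial(2, rng.uniform(0.3, 0.7, 300)).astype(float)
        m = matrix_from_dosage(np.tile(base, (8, 1)))
        lo, hi, med = sibship.bootstrap_ci(m, n_boot=50, seed=1, error_rate=0.0)
        assert lo == pytest.approx(hi)

    def test_interval_covers_point_for_planted_cohort(self):
        m, _, truth = synthdata.sample_cohort_from_parent_pool(50, 1000, 50, 2000, seed=11)
        est = sibship.estimate_nb_sa(m, n_boot=100, seed=2)
        assert est.ci_low <= est.point <= est.ci_high
        assert est.ci_low <= truth["nb_demo"] <= est.ci_high
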