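"""QC cascade: threshold filters, HWE mid-p, Fis, duplicates, screens."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cohortnb import qc
from conftest import matrix_from_dosage


# ---------------------------------------------------------------------------
# HWE mid-p
# ---------------------------------------------------------------------------

def enumerate_hwe_midp(counts):
    """Independent oracle: direct counting of genotype tables.

    For fixed allele counts, the number of ordered-allele arrangements
    giving heterozygote count h is n!/(nAA! h! nBB!) * 2^h; probabilities
    follow by normalisation over all compatible h.
    """
    naa, nab, nbb = counts
    n = naa + nab + nbb
    na = 2 * naa + nab
    nb = 2 * nbb + nab
    if na == 0 or nb == 0:
        return 1.0
    weights = {}
    for h in range(min(na, nb) + 1):
        if (na - h) % 2 or (nb - h) % 2:
            continue
        a, b = (na - h) // 2, (nb - h) // 2
        weights[h] = (
            math.factorial(n)
            / (math.factorial(a) * math.factorial(h) * math.factorial(b))
            * 2**h
        )
    tot = sum(weights.values())
    probs = {h: w / tot for h, w in weights.items()}
    obs = probs[nab]
    return sum(p for p in probs.values() if p < obs - 1e-12) + 0.5 * sum(
        p for p in probs.values() if abs(p - obs) <= 1e-12
    )


class TestHweMidp:
    def test_monomorphic_is_one(self):
        assert qc.hwe_midp((10, 0, 0)) == 1.0

    def test_two_homozygotes_enumeration(self):
        # n=2, one AA and one aa: het counts {0, 2} with probs {1/3, 2/3};
        # observed h=0 -> mid-p = 0.5 * 1/3
        assert qc.hwe_midp((1, 0, 1)) == pytest.approx(1.0 / 6.0)

    def test_matches_full_enumeration_up_to_n10(self):
        for n in range(1, 11):
            for naa in range(n + 1):
                for nab in range(n - naa + 1):
                    counts = (naa, nab, n - naa - nab)
                    assert qc.hwe_midp(counts) == pytest.approx(
                        enumerate_hwe_midp(counts), abs=1e-10
                    ), counts

    def test_uniform_under_null(self):
        """At exact HW proportions mid-p is ~uniform: median near 0.5."""
        rng = np.random.default_rng(42)
        ps = []
        for _ in range(300):
            p = rng.uniform(0.2, 0.8)
            g = rng.multinomial(80, [(1 - p) ** 2, 2 * p * (1 - p), p**2])
            ps.append(qc.hwe_midp(tuple(g)))
        assert 0.42 < np.median(ps) < 0.58

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    @settings(max_examples=80, deadline=None)
    def test_in_unit_interval(self, naa, nab, nbb):
        if naa + nab + nbb == 0:
            return
        assert 0.0 <= qc.hwe_midp((naa, nab, nbb)) <= 1.0

    def test_multiallelic_mc_moderate_under_null(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 6, size=(120, 2))
        p = qc.hwe_midp_multiallelic(calls, n_permutations=2000, rng=rng)
        assert 0.01 < p <= 1.0

    def test_multiallelic_mc_detects_het_excess(self):
        # every genotype heterozygous across 4 alleles
        rng = np.random.default_rng(2)
        a = rng.integers(0, 4, size=200)
        b = (a + rng.integers(1, 4, size=200)) % 4
        calls = np.stack([a, b], axis=1)
        p = qc.hwe_midp_multiallelic(calls, n_permutations=2000, rng=rng)
        assert p < 0.01


# ---------------------------------------------------------------------------
# Fis
# ---------------------------------------------------------------------------

class TestFis:
    def test_all_heterozygotes_near_minus_one(self):
        m = matrix_from_dosage(np.ones((20, 1)))
        v = qc.fis(m, 0)
        assert v == pytest.approx(-1.0, abs=0.06)  # unbiased-He correction

    def test_hw_proportions_near_zero(self):
        rng = np.random.default_rng(9)
        dos = rng.binomial(2, 0.5, size=(5000, 1))
        assert abs(qc.fis(matrix_from_dosage(dos), 0)) < 0.05

    def test_matches_brute_force(self):
        rng = np.random.default_rng(10)
        dos = rng.binomial(2, 0.3, size=(40, 5))
        m = matrix_from_dosage(dos)
        for j in range(5):
            col = dos[:, j]
            n = len(col)
            ho = (col == 1).mean()
            p = col.mean() / 2
            he = 2 * p * (1 - p) * (2 * n) / (2 * n - 1)
            if he == 0:
                assert math.isnan(qc.fis(m, j))
            else:
                assert qc.fis(m, j) == pytest.approx(1 - ho / he)


# ---------------------------------------------------------------------------
# threshold filters (planted truth)
# ---------------------------------------------------------------------------

def hw_column(rng, n):
    """A dosage column at exact (rounded) HW proportions, shuffled.

    Guaranteed to pass the MAC, HWE and Fis screens for any rng state."""
    p = rng.uniform(0.35, 0.65)
    n_het = int(round(2 * p * (1 - p) * n))
    n_hom1 = int(round(p * p * n))
    n_hom0 = n - n_het - n_hom1
    col = np.array([0.0] * n_hom0 + [1.0] * n_het + [2.0] * n_hom1)
    rng.shuffle(col)
    return col


def planted_fixture():
    """40 individuals; loci with planted violations of each filter."""
    rng = np.random.default_rng(77)
    n = 40
    cols, names, meta = [], [], []

    def add(dos, name, rep=1.0, depth=15.0, clone=None):
        cols.append(np.asarray(dos, float))
        names.append(name)
        meta.append({"reproducibility": rep, "depth": depth,
                     "clone_id": clone or f"clone_{name}"})

    good = lambda: hw_column(rng, n)
    for i in range(30):
        add(good(), f"good{i}")
    add(good(), "low_rep", rep=0.95)
    mac3 = np.zeros(n); mac3[:3] = 1
    add(mac3, "mac3")  # MAC = 3 -> removed (strictly greater than 3 required)
    mac4 = np.zeros(n); mac4[:4] = 1
    add(mac4, "mac4")  # MAC = 4 -> kept
    add(good(), "low_depth", depth=3.0)
    add(good(), "high_depth", depth=30.0)
    add(good(), "clone_b", clone="shared")
    add(good(), "clone_dup", clone="shared")  # second on the tag -> removed
    add(np.zeros(n), "mono")
    hwe_bad = np.ones(n)  # all heterozygous -> extreme HWE departure
    add(hwe_bad, "hwe_fail")
    dos = np.column_stack(cols)
    return matrix_from_dosage(dos, locus_ids=names, locus_meta=pd.DataFrame(meta)), names


class TestFilterCascade:
    def test_planted_loci_removed_exactly(self):
        m, names = planted_fixture()
        out, report = qc.run_qc(m, remove_duplicates=False)
        removed = {l for v in report.removed_loci.values() for l in v}
        assert removed == {"low_rep", "mac3", "low_depth", "high_depth",
                          "clone_dup", "mono", "hwe_fail"}
        # the MAC screen runs before the monomorphic screen, so it also
        # catches the monomorphic locus (MAC = 0)
        assert report.removed_loci["minor_allele_count"] == ["mac3", "mono"]
        assert "mac4" in out.locus_ids

    def test_fis_filter_binds_at_small_n(self):
        # 10 individuals, counts (4, 2, 4): Fis ~ +0.62 (removed at the
        # inclusive 0.5 bound) while HWE mid-p ~ 0.041 passes the 0.01 screen
        col = np.array([0] * 4 + [1] * 2 + [2] * 4, float)
        good = np.array([0, 1, 1, 0, 2, 1, 0, 1, 2, 1], float)
        m = matrix_from_dosage(np.column_stack([col, good]),
                               locus_ids=["fis_fail", "good"])
        out, report = qc.filter_hwe_fis(m)
        assert report.removed_loci["fis"] == ["fis_fail"]
        assert report.removed_loci["hwe_midp"] == []
        assert out.locus_ids == ["good"]

    def test_cascade_idempotent(self):
        m, _ = planted_fixture()
        out, _ = qc.run_qc(m, remove_duplicates=True)
        again, rep2 = qc.run_qc(out, remove_duplicates=True)
        assert again.locus_ids == out.locus_ids
        assert again.sample_ids == out.sample_ids

    def test_thresholds_logged(self):
        m, _ = planted_fixture()
        _, report = qc.run_qc(m)
        joined = "\n".join(report.log)
        for frag in ("0.98", "<= 3", "[5.0, 25.0]", "> 0.2", "0.01", "0.5"):
            assert frag in joined, frag

    def test_missing_metadata_filters_skipped_with_warning(self, hwe_cohort):
        out, report = qc.filter_loci(hwe_cohort)
        assert any("skipped" in line for line in report.log)
        assert out.n_loci <= hwe_cohort.n_loci

    def test_all_monomorphic_errors(self):
        m = matrix_from_dosage(np.zeros((10, 4)))
        with pytest.raises(ValueError, match="no loci"):
            qc.filter_loci(m)

    def test_surviving_count_matches_brute_recount(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.0, 0.5, 200)
        dos = rng.binomial(2, p[None, :], size=(50, 200)).astype(float)
        m = matrix_from_dosage(dos)
        out, _ = qc.filter_loci(m)
        expect = 0
        for j in range(200):
            col = dos[:, j]
            mac = min(col.sum(), 2 * 50 - col.sum())
            expect += (mac > 3) and (mac > 0)
        assert out.n_loci == expect


class TestFilterIndividuals:
    def test_boundary_20_percent(self):
        dos = np.full((3, 100), 1.0)
        dos[0, :21] = np.nan  # 21% -> dropped
        dos[1, :20] = np.nan  # exactly 20% -> kept
        m = matrix_from_dosage(dos)
        out, report = qc.filter_individuals(m)
        assert out.sample_ids == ["s1", "s2"]
        assert report.removed_individuals["missingness"] == ["s0"]

    def test_no_missing_identity(self, hwe_cohort):
        out, _ = qc.filter_individuals(hwe_cohort)
        assert out.sample_ids == hwe_cohort.sample_ids


# ---------------------------------------------------------------------------
# duplicates / divergent individuals / outlier loci
# ---------------------------------------------------------------------------

class TestDuplicates:
    def test_planted_copy_detected_with_errors(self, hwe_cohort):
        dos = hwe_cohort.dosage()
        copy = dos[0].copy()
        flip = np.random.default_rng(0).choice(400, size=2, replace=False)
        copy[flip] = 2 - copy[flip]  # 0.5% planted discordance
        m = matrix_from_dosage(np.vstack([dos, copy[None, :]]),
                               sample_ids=[f"s{i}" for i in range(60)] + ["dup"])
        pairs = qc.detect_duplicates(m)
        assert ("s0", "dup") in [(a, b) for a, b, _ in pairs]

    def test_unrelated_cohort_no_pairs(self, hwe_cohort):
        assert qc.detect_duplicates(hwe_cohort) == []


class TestDivergentIndividuals:
    def test_planted_migrants_flagged(self, hwe_cohort):
        rng = np.random.default_rng(8)
        dos = hwe_cohort.dosage()
        p = np.nanmean(dos, axis=0) / 2
        pmig = np.clip(1 - p, 0.02, 0.98)
        mig = rng.binomial(2, pmig[None, :], size=(2, 400)).astype(float)
        ids = [f"s{i}" for i in range(60)] + ["mig1", "mig2"]
        m = matrix_from_dosage(np.vstack([dos, mig]), sample_ids=ids)
        assert sorted(qc.detect_divergent_individuals(m)) == ["mig1", "mig2"]

    def test_single_population_rarely_flags(self):
        rng = np.random.default_rng(123)
        n_flagged = 0
        for rep in range(5):
            p = rng.uniform(0.1, 0.9, 300)
            dos = rng.binomial(2, p[None, :], size=(50, 300))
            n_flagged += len(qc.detect_divergent_individuals(matrix_from_dosage(dos)))
        assert n_flagged <= 1

    def test_duplicate_individual_not_flagged(self, hwe_cohort):
        dos = hwe_cohort.dosage()
        m = matrix_from_dosage(np.vstack([dos, dos[0][None, :]]),
                               sample_ids=[f"s{i}" for i in range(60)] + ["dup"])
        assert "dup" not in qc.detect_divergent_individuals(m)


class TestOutlierScan:
    def test_null_flagged_fraction_below_fdr(self, hwe_cohort):
        flagged, _ = qc.outlier_scan(hwe_cohort, k=3, fdr=0.05)
        assert len(flagged) <= 0.05 * hwe_cohort.n_loci

    def test_duplicated_locus_identical_statistics(self, hwe_cohort):
        dos = hwe_cohort.dosage()
        dos2 = np.column_stack([dos, dos[:, 0]])
        m = matrix_from_dosage(dos2, locus_ids=[f"l{j}" for j in range(400)] + ["copy"])
        _, stats = qc.outlier_scan(m, k=3, fdr=0.05)
        s = stats.set_index("locus_id")
        assert s.loc["copy", "mahalanobis_d2"] == pytest.approx(
            s.loc["l0", "mahalanobis_d2"], rel=1e-6
        )

    def test_planted_differentiated_loci_enriched(self):
        rng = np.random.default_rng(6)
        L, n_out = 400, 8
        p = rng.uniform(0.2, 0.8, L)
        pB = p.copy()
        pB[:n_out] = np.clip(p[:n_out] + 0.8 * np.sign(0.5 - p[:n_out]), 0.02, 0.98)
        dos = np.vstack([rng.binomial(2, p[None, :], (50, L)),
                         rng.binomial(2, pB[None, :], (50, L))])
        flagged, _ = qc.outlier_scan(matrix_from_dosage(dos), k=3, fdr=0.05)
        hits = sum(1 for f in flagged if int(f[1:]) < n_out)
        false_flags = len(flagged) - hits
        assert hits >= 6
        assert false_flags <= 0.05 * L

    def test_k_larger_than_rank_rejected(self):
        m = matrix_from_dosage(np.random.default_rng(0).binomial(2, 0.5, (4, 20)))
        with pytest.raises(ValueError):
            qc.outlier_scan(m, k=3)
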