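"""Synthetic-data engine: pedigree constraints, Mendelian dropping, WF harness."""

import math

import numpy as np
import pytest

from cohortnb import synthdata
from cohortnb.types import BreedingScheme, LifeTable, Pedigree


def tiny_life_table(n1=60, max_age=6, maturity=2):
    ages = np.arange(1, max_age + 1)
    surv = np.full(max_age, 0.8)
    surv[-1] = 0.0
    fec = np.where(ages >= maturity, 1.0, 0.0)
    return LifeTable(ages, {"F": surv, "M": surv.copy()},
                     {"F": fec, "M": fec.copy()}, n1)


class TestSimulatePedigree:
    def test_recruit_count_and_parent_validity(self):
        lt = tiny_life_table()
        ped = synthdata.simulate_pedigree(lt, BreedingScheme(), n_cycles=8, seed=1)
        for t in range(1, 9):
            assert len(ped.cohort_members(t)) == 60
        # Pedigree __init__ already validates sexes/ordering; check k bookkeeping
        k = ped.offspring_counts()
        assert k.sum() == 2 * 8 * 60

    def test_single_pair_forces_full_sibs(self):
        ages = np.array([1])
        lt = LifeTable(ages, {"F": np.array([0.0]), "M": np.array([0.0])},
                       {"F": np.array([1.0]), "M": np.array([1.0])}, 10)
        # founders: 5 of each sex at age 1; restrict pool to one pair by
        # using a 2-recruit table then checking a 1F/1M cycle directly
        ped = synthdata.simulate_pedigree(lt, BreedingScheme(), 1, n1_recruits=10, seed=3)
        kids = ped.cohort_members(1)
        mothers = set(ped.mother[kids].tolist())
        # all recruits of one cycle under monogamy share one sire per mother
        for m in mothers:
            sires = set(ped.father[kids][ped.mother[kids] == m].tolist())
            assert len(sires) == 1

    def test_skip_pattern_blocks_consecutive_breeding(self):
        lt = tiny_life_table(n1=40)
        scheme = BreedingScheme(skip_pattern=1)
        ped = synthdata.simulate_pedigree(lt, scheme, n_cycles=10, seed=5)
        mothers_by_cycle = {
            t: set(ped.mother[ped.cohort_members(t)].tolist()) for t in range(1, 11)
        }
        for t in range(1, 10):
            assert not (mothers_by_cycle[t] & mothers_by_cycle[t + 1])

    def test_skip_reduces_distinct_mothers(self):
        lt = tiny_life_table(n1=100)
        m0 = synthdata.simulate_pedigree(lt, BreedingScheme(skip_pattern=0), 12, seed=7)
        m1 = synthdata.simulate_pedigree(lt, BreedingScheme(skip_pattern=1), 12, seed=7)
        mean0 = m0.cycle_info["n_mothers"][4:].mean()
        mean1 = m1.cycle_info["n_mothers"][4:].mean()
        assert mean1 < mean0

    def test_mean_k_matches_recruit_arithmetic(self):
        lt = tiny_life_table(n1=200, max_age=4)
        ped = synthdata.simulate_pedigree(
            lt, BreedingScheme(mating_system="both-polygamous"), 6, seed=11
        )
        # parents of cycle 6: mean offspring over the eligible pool equals
        # n1 * 2 / n_parents by direct count from the pedigree
        info = ped.cycle_info.set_index("cycle").loc[6]
        kids = ped.cohort_members(6)
        n_parents = info["n_eligible_f"] + info["n_eligible_m"]
        mean_k = 2 * len(kids) / n_parents
        assert mean_k == pytest.approx(2 * 200 / n_parents)

    def test_no_eligible_parents_names_cycle(self):
        # females mature at age 2 but never survive age 1: no eligible
        # mothers in any cycle
        ages = np.array([1, 2])
        lt = LifeTable(ages,
                       {"F": np.array([0.0, 0.0]), "M": np.array([1.0, 0.0])},
                       {"F": np.array([0.0, 1.0]), "M": np.array([0.0, 1.0])}, 10)
        with pytest.raises(RuntimeError, match="cycle 1"):
            synthdata.simulate_pedigree(lt, BreedingScheme(), 3, seed=0)

    def test_age_structure_near_stable(self):
        lt = tiny_life_table(n1=200)
        ped = synthdata.simulate_pedigree(lt, BreedingScheme(), 20, seed=13)
        # survivors after the cycle-20 survival step hold the age structure
        # entering cycle 21
        alive = ped.death_cycle == -1
        ages = 21 - ped.birth_cycle[alive]
        observed = np.array([(ages == a).sum() for a in lt.ages])
        expected = 2 * lt.stable_age_numbers("F")
        assert np.all(np.abs(observed - expected) < 5 * np.sqrt(expected + 1))


class TestDropGenotypes:
    def _trio_pedigree(self):
        ids = ["M", "F", "C1", "C2"]
        return Pedigree(ids, ["F", "M", "F", "M"], [0, 0, 1, 1],
                        [-1, -1, 0, 0], [-1, -1, 1, 1], [-1] * 4)

    def test_mendelian_certainty(self):
        ped = self._trio_pedigree()
        freqs = np.zeros(5)  # founders all (0,0)
        m = synthdata.drop_genotypes(ped, 5, freqs, error_rate=0.0, seed=1)
        assert np.all(m.calls == 0)

    def test_opposite_homozygotes_give_hets(self):
        ped = self._trio_pedigree()
        # force founder genotypes by dropping with p=0 then p=1 per parent is
        # not possible; instead check via allele freq p=1 for one locus
        freqs = np.array([0.5])
        rng = np.random.default_rng(0)
        found = False
        for s in range(40):
            m = synthdata.drop_genotypes(ped, 1, freqs, error_rate=0.0, seed=s)
            gm, gf = m.calls[0, 0], m.calls[1, 0]
            if tuple(gm) == (0, 0) and tuple(gf) == (1, 1):
                assert tuple(m.calls[2, 0]) == (0, 1)
                assert tuple(m.calls[3, 0]) == (0, 1)
                found = True
        assert found

    def test_founder_frequency_within_binomial_se(self):
        n = 5000
        ped = Pedigree([f"f{i}" for i in range(n)], ["F", "M"] * (n // 2),
                       np.zeros(n, int), np.full(n, -1), np.full(n, -1),
                       np.full(n, -1))
        m = synthdata.drop_genotypes(ped, 1, np.array([0.3]), seed=2)
        obs = m.dosage().mean() / 2
        se = math.sqrt(0.3 * 0.7 / (2 * n))
        assert abs(obs - 0.3) < 3 * se

    def test_missing_rate_applied(self):
        ped = self._trio_pedigree()
        m = synthdata.drop_genotypes(ped, 2000, np.full(2000, 0.5),
                                     missing_rate=0.1, seed=3)
        assert m.missing_mask().mean() == pytest.approx(0.1, abs=0.02)

    def test_monomorphic_with_error_warns(self):
        ped = self._trio_pedigree()
        with pytest.warns(UserWarning, match="unobservable"):
            synthdata.drop_genotypes(ped, 1, np.array([0.0]), error_rate=0.01, seed=4)

    def test_allele_frequency_conserved_across_cycle(self):
        """No mutation: expected offspring frequency equals parental."""
        lt = tiny_life_table(n1=100, max_age=3)
        deltas = []
        for s in range(10):
            ped = synthdata.simulate_pedigree(lt, BreedingScheme(), 4, seed=s)
            ids = [ped.ids[i] for i in ped.cohort_members(4)]
            m = synthdata.drop_genotypes(ped, 50, np.full(50, 0.4),
                                         seed=s, for_ids=ids, error_rate=0.0)
            deltas.append(np.nanmean(m.dosage()) / 2 - 0.4)
        assert abs(np.mean(deltas)) < 0.02


class TestIdealWf:
    def test_seed_determinism(self):
        a = synthdata.make_ideal_wf_population(50, 100, 20, seed=9)
        b = synthdata.make_ideal_wf_population(50, 100, 20, seed=9)
        c = synthdata.make_ideal_wf_population(50, 100, 20, seed=10)
        assert np.array_equal(a.calls, b.calls)
        assert not np.array_equal(a.calls, c.calls)

    def test_drift_fixes_loci_at_tiny_ne(self):
        m = synthdata.make_ideal_wf_population(2, 300, 2, seed=1, n_generations=60)
        mono = 0
        for j in range(300):
            d = m.dosage()[:, j]
            mono += d.min() == d.max() and d[0] in (0.0, 2.0)
        assert mono > 240  # most loci fixed after 60 generations at Ne=2

    def test_sampling_bounds(self):
        with pytest.raises(ValueError):
            synthdata.make_ideal_wf_population(10, 5, 20, seed=0)


class TestLengths:
    def test_noiseless_on_curve(self):
        recs = synthdata.simulate_lengths(
            [("a", 2010), ("b", 2010)], synthdata.FIXTURE_VBGF, 0.0,
            [2015, 2015], seed=0, include_tl=True,
        )
        expect = synthdata.FIXTURE_VBGF.length_at_age(5)
        assert recs[0].total_length_cm == pytest.approx(expect)
        assert recs[0].total_length_cm == recs[1].total_length_cm
        # FL back-computed through the conversion
        fl = recs[0].fork_length_cm
        assert 6.80 + 1.07 * fl == pytest.approx(expect)

    def test_age_beyond_maximum_rejected(self):
        with pytest.raises(ValueError, match="maximum"):
            synthdata.simulate_lengths([("a", 1950)], synthdata.FIXTURE_VBGF,
                                       0.0, [2015], seed=0, max_age=40)

    def test_ageing_recovers_birth_years(self):
        """Cohort ageing of emitted records recovers >= 95% of true years."""
        from cohortnb import cohorts

        study = synthdata.simulate_study(seed=21, n_loci=10, n_per_cohort=40,
                                         sd_noise=4.0)
        part = cohorts.assign_cohorts(study["samples"], synthdata.FIXTURE_CONVERSION,
                                      synthdata.FIXTURE_VBGF, min_n=1)
        truth = study["truth"]["birth_year_of"]
        acc = np.mean([part.birth_year[s] == truth[s] for s in part.birth_year])
        assert acc >= 0.95


class TestVkProperties:
    def test_poisson_vk_near_kbar(self):
        """Polygamous multinomial litters: per-cycle Vk ~ kbar (binomial limit)."""
        lt = tiny_life_table(n1=300, max_age=4)
        ped = synthdata.simulate_pedigree(
            lt, BreedingScheme(mating_system="both-polygamous"), 8, seed=17
        )
        kids = ped.cohort_members(8)
        moms = ped.mother[kids]
        info = ped.cycle_info.set_index("cycle").loc[8]
        counts = np.bincount(moms)
        k = np.zeros(int(info["n_eligible_f"]))
        nz = counts[counts > 0]
        k[: len(nz)] = nz
        assert k.var() == pytest.approx(k.mean(), rel=0.35)
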