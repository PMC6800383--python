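"""Pseudohaploidization, EHH decay and the XP-EHH contrast."""

import numpy as np
import pytest

from ampliscan import sim, sweep
from ampliscan.types import GenotypeMatrix, PseudohaploidMatrix

from conftest import brute_force_ehh


def _genos(dosages, positions=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        chrom="chr5",
        positions=positions if positions is not None else np.arange(1, m + 1),
        genotypes=dosages,
    )


def _haps(alleles, positions=None):
    alleles = np.asarray(alleles, dtype=np.int8)
    n, m = alleles.shape
    return PseudohaploidMatrix(
        sample_ids=[f"h{i}" for i in range(n)],
        chrom="chr5",
        positions=positions if positions is not None else np.arange(1, m + 1),
        alleles=alleles,
        seed=0,
    )


class TestPseudohaploidize:
    def test_homozygous_matrix_deterministic_any_seed(self):
        g = _genos([[0, 2, 0], [2, 2, 0]])
        for seed in (0, 1, 99):
            h = sweep.pseudohaploidize(g, seed)
            assert h.alleles.tolist() == [[0, 1, 0], [1, 1, 0]]

    def test_missing_stays_missing(self):
        g = _genos([[-1, 1], [0, -1]])
        h = sweep.pseudohaploidize(g, 0)
        assert h.alleles[0, 0] == -1 and h.alleles[1, 1] == -1

    def test_het_site_samples_alt_half_the_time(self):
        """One heterozygous genotype sampled over many seeds draws the alt
        allele in 50% +/- 1.5% of draws."""
        g = _genos([[1]])
        draws = sum(
            int(sweep.pseudohaploidize(g, seed).alleles[0, 0])
            for seed in range(10_000)
        )
        assert abs(draws / 10_000 - 0.5) < 0.015

    def test_population_frequency_preserved(self):
        """Haploid alt frequencies stay within 2 SE of the diploid
        frequencies site by site."""
        rng = np.random.default_rng(23)
        p = rng.uniform(0.1, 0.9, 1000)
        n = 60
        g = (
            (rng.random((n, 1000)) < p).astype(np.int8)
            + (rng.random((n, 1000)) < p).astype(np.int8)
        )
        h = sweep.pseudohaploidize(_genos(g), seed=5)
        p_dip = g.mean(axis=0) / 2
        p_hap = h.alleles.mean(axis=0)
        se = np.sqrt(p_dip * (1 - p_dip) / n)
        frac_within = np.mean(np.abs(p_hap - p_dip) <= 2 * se + 1e-12)
        assert frac_within >= 0.93

    def test_same_seed_reproducible(self):
        g = _genos(np.ones((10, 50), dtype=np.int8))
        a = sweep.pseudohaploidize(g, 42).alleles
        b = sweep.pseudohaploidize(g, 42).alleles
        assert np.array_equal(a, b)


class TestEHH:
    def test_identical_haplotypes_hold_ehh_at_one(self):
        h = _haps(np.tile([0, 1, 0, 1, 1], (6, 1)), positions=np.array([10, 20, 30, 40, 50]))
        decay = sweep.ehh(h, core_pos=30, max_extend=100)
        assert np.all(decay.ehh == 1.0)
        assert decay.ihh_left == pytest.approx(100.0)
        assert decay.ihh_right == pytest.approx(100.0)

    def test_all_distinct_stretches_drop_ehh_to_zero(self):
        # 4 haplotypes whose flanking stretches become pairwise distinct
        alleles = np.array(
            [[0, 0, 0], [0, 0, 1], [0, 1, 0], [0, 1, 1]], dtype=np.int8
        )
        h = _haps(alleles, positions=np.array([100, 200, 300]))
        decay = sweep.ehh(h, core_pos=100, max_extend=1000)
        right = decay.ehh[decay.distances >= 0]
        # groups after first flank: {00, 11} -> (1+1)/6; after second: all
        # distinct -> 0, where extension stops
        assert right.tolist() == pytest.approx([1.0, 1 / 3, 0.0])

    def test_matches_hand_enumerated_group_oracle(self):
        """EHH at each flanking site equals the explicit identity-group
        enumeration sum C(n_g,2)/C(n,2) on a printed 6x5 toy panel."""
        alleles = np.array(
            [
                [0, 1, 0, 0, 1],
                [0, 1, 0, 0, 1],
                [1, 1, 0, 1, 1],
                [1, 0, 0, 1, 0],
                [0, 0, 0, 1, 0],
                [0, 1, 0, 0, 0],
            ],
            dtype=np.int8,
        )
        positions = np.array([10, 20, 30, 40, 50])
        core_idx = 2
        h = _haps(alleles, positions=positions)
        decay = sweep.ehh(h, core_pos=30, cutoff=0.0, max_extend=25)
        for target_idx in (3, 4):
            expected = brute_force_ehh(alleles, core_idx, target_idx)
            d = positions[target_idx] - positions[core_idx]
            got = decay.ehh[decay.distances == d][0]
            assert got == pytest.approx(expected, abs=1e-12)
        for target_idx in (0, 1):
            expected = brute_force_ehh(alleles, core_idx, target_idx)
            d = positions[target_idx] - positions[core_idx]
            got = decay.ehh[decay.distances == d][0]
            assert got == pytest.approx(expected, abs=1e-12)

    def test_ehh_monotone_nonincreasing_with_distance(self):
        rng = np.random.default_rng(31)
        alleles = (rng.random((12, 80)) < 0.4).astype(np.int8)
        h = _haps(alleles)
        decay = sweep.ehh(h, core_pos=40, cutoff=0.0, max_extend=100)
        right = decay.ehh[decay.distances >= 0]
        left = decay.ehh[decay.distances <= 0][::-1]
        assert np.all(np.diff(right) <= 1e-12)
        assert np.all(np.diff(left) <= 1e-12)
        assert decay.ehh[decay.distances == 0][0] == 1.0

    def test_too_few_haplotypes_rejected(self):
        h = _haps(np.zeros((3, 5), dtype=np.int8))
        with pytest.raises(ValueError, match=">= 4"):
            sweep.ehh(h, core_pos=3)


class TestXPEHH:
    def test_identical_groups_give_zero(self):
        rng = np.random.default_rng(32)
        alleles = (rng.random((8, 60)) < 0.5).astype(np.int8)
        h = _haps(alleles)
        assert sweep.xpehh(h, h, core_pos=30) == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(33)
        a = _haps((rng.random((8, 60)) < 0.5).astype(np.int8))
        b = _haps((rng.random((8, 60)) < 0.3).astype(np.int8))
        ab = sweep.xpehh(a, b, core_pos=30)
        ba = sweep.xpehh(b, a, core_pos=30)
        assert ab == pytest.approx(-ba, abs=1e-12)

    def test_hard_sweep_gives_positive_raw_score(self, sweep_scenario_factory):
        wins = 0
        for seed in range(8):
            scen = sweep_scenario_factory("hard", seed=seed, decay=2e6)
            genos, truth = sim.simulate_genotypes(scen)
            haps = sweep.pseudohaploidize(genos, seed=seed)
            amp = [s for s in truth.sample_ids if truth.origin_of[s]]
            non = [s for s in truth.sample_ids if not truth.origin_of[s]]
            raw = sweep.xpehh(
                sweep._subset(haps, amp), sweep._subset(haps, non), 500_000
            )
            wins += raw > 0
        assert wins >= 7

    def test_neutral_standardized_scores_centered(self, sweep_scenario_factory):
        scen = sweep_scenario_factory("neutral", seed=1, n_snps=1500)
        genos, truth = sim.simulate_genotypes(scen)
        haps = sweep.pseudohaploidize(genos, seed=1)
        half = len(truth.sample_ids) // 2
        a = sweep._subset(haps, truth.sample_ids[:half])
        b = sweep._subset(haps, truth.sample_ids[half:])
        cores = np.linspace(100_000, 900_000, 60).astype(int)
        raw, z = sweep.xpehh_scan(a, b, cores)
        assert abs(np.nanmean(z)) < 0.2


class TestAmplifiedContrast:
    def test_identical_groups_fst_and_delta_pi_near_zero(self):
        rng = np.random.default_rng(34)
        p = rng.uniform(0.2, 0.8, 400)
        pos = np.sort(rng.choice(np.arange(1, 400_001), 400, replace=False))
        g = (
            (rng.random((20, 400)) < p).astype(np.int8)
            + (rng.random((20, 400)) < p).astype(np.int8)
        )
        genos = _genos(g, positions=pos)
        amplified = {f"s{i}": i < 10 for i in range(20)}
        df = sweep.amplified_contrast(genos, amplified, (1, 400_001))
        assert abs(df["fst"].mean()) < 0.03
        assert abs(df["delta_pi"].mean()) < 0.03

    def test_hard_sweep_pi_minimum_localizes_at_focal_gene(
        self, sweep_scenario_factory
    ):
        hits = 0
        for seed in range(6):
            scen = sweep_scenario_factory("hard", seed=seed, decay=100_000)
            genos, truth = sim.simulate_genotypes(scen)
            amplified = {
                s: truth.origin_of[s] is not None for s in truth.sample_ids
            }
            df = sweep.amplified_contrast(
                genos, amplified, (1, 1_000_001), window=100_000, step=10_000
            )
            best = df.loc[df["pi_amplified"].idxmin()]
            center = (best["start"] + best["end"]) / 2
            hits += abs(center - 500_000) <= 100_000
        assert hits >= 5

    def test_soft_sweep_depletes_less_than_hard(self, sweep_scenario_factory):
        """Soft sweeps (5 founders) leave more carrier diversity at the focal
        gene than hard sweeps, seed by seed."""
        softer = 0
        n_seeds = 6
        for seed in range(n_seeds):
            ratios = {}
            for kind, k in (("hard", 1), ("soft", 5)):
                scen = sweep_scenario_factory(kind, seed=seed, decay=2e6, k=k)
                genos, truth = sim.simulate_genotypes(scen)
                ci = [
                    genos.sample_ids.index(s)
                    for s in truth.sample_ids
                    if truth.origin_of[s]
                ]
                lo, hi = np.searchsorted(genos.positions, [450_000, 550_000])
                from ampliscan import popgen

                ratios[kind] = popgen.pi(genos.genotypes[ci, lo:hi])
            softer += ratios["soft"] > ratios["hard"]
        assert softer >= n_seeds - 1
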