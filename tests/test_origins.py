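"""Profile extraction, rank correlation and origin counting."""

import numpy as np
import pytest

from ampliscan import coverage, origins, sim
from ampliscan.types import AmpOriginSpec, ProfileCorrelation, SimScenario

from conftest import brute_force_spearman


class TestSpearman:
    def test_identity_gives_one(self):
        x = np.arange(12, dtype=float)
        assert origins.spearman_rho(x, x) == pytest.approx(1.0)

    def test_monotone_decreasing_map_gives_minus_one(self):
        x = np.arange(12, dtype=float)
        assert origins.spearman_rho(x, -(x**3)) == pytest.approx(-1.0)

    def test_matches_hand_rank_oracle(self):
        # explicit mid-rank Pearson oracle on a permuted sequence
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10], dtype=float)
        y = np.array([2, 1, 4, 3, 5, 7, 6, 9, 10, 8], dtype=float)
        assert origins.spearman_rho(x, y) == pytest.approx(
            brute_force_spearman(x, y), abs=1e-12
        )

    def test_oracle_equivalence_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            assert origins.spearman_rho(x, y) == pytest.approx(
                brute_force_spearman(x, y), abs=1e-12
            )

    def test_ties_use_average_ranks(self):
        x = np.array([1, 1, 2, 2, 3, 3, 4, 4, 5, 5], dtype=float)
        y = np.array([5, 5, 4, 4, 3, 3, 2, 2, 1, 2], dtype=float)
        assert origins.spearman_rho(x, y) == pytest.approx(
            brute_force_spearman(x, y), abs=1e-12
        )

    def test_zero_variance_reported_missing_not_zero(self):
        x = np.ones(12)
        y = np.arange(12, dtype=float)
        assert np.isnan(origins.spearman_rho(x, y))

    def test_invariance_under_strictly_increasing_transforms(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0.5, 5, size=40)
        y = rng.uniform(0.5, 5, size=40)
        base = origins.spearman_rho(x, y)
        assert origins.spearman_rho(2 * x + 1, y) == pytest.approx(base, abs=1e-12)
        assert origins.spearman_rho(x**3, y) == pytest.approx(base, abs=1e-12)


class TestExtractProfile:
    def test_window_count_arithmetic(self, flat_scenario):
        tracks, _ = sim.simulate_depth(flat_scenario)
        tr = next(iter(tracks.values()))
        norm = coverage.estimate_mode_depth(tr)
        prof = origins.extract_profile(
            tr, coverage.normalize(tr, norm), (55_000, 65_000),
            flank=25_000, resolution=1_000,
        )
        assert len(prof) == 50  # 2 * flank / resolution

    def test_constant_coverage_gives_constant_profile(self):
        from ampliscan.types import DepthTrack

        pos = np.arange(1, 100_001, 10)
        tr = DepthTrack("s", "chr5", pos, np.full(len(pos), 20))
        prof = origins.extract_profile(
            tr, np.full(len(pos), 2.0), (45_000, 55_000), flank=20_000, resolution=1000
        )
        assert np.allclose(prof, 2.0)

    def test_step_positions_near_true_breakpoints(self):
        """The largest successive profile differences localize the true
        segment breakpoints to within one window."""
        spec = AmpOriginSpec(
            "o0", (20_000, 45_000, 75_000, 100_000), (3, 8, 5), 1.0, "p"
        )
        scen = SimScenario(
            chrom_length=120_000,
            populations=[("p", "r", 2)],
            origins=[spec],
            mean_depth=30.0,
            seed=2,
            focal_gene=(55_000, 65_000),
        )
        tracks, truth = sim.simulate_depth(scen)
        s = next(s for s in truth.sample_ids if truth.origin_of[s])
        tr = tracks[s]
        norm = coverage.estimate_mode_depth(tr)
        prof = origins.extract_profile(
            tr, coverage.normalize(tr, norm), scen.focal_gene,
            flank=50_000, resolution=1000,
        )
        start = 60_000 - 50_000
        diffs = np.abs(np.diff(prof))
        # four step edges fall inside the profiled region (span ends + two
        # interior breakpoints); the largest diffs should localize them all
        top4 = np.sort(np.argsort(diffs)[-4:])
        found = start + (top4 + 1) * 1000
        for bp in (20_000, 45_000, 75_000, 100_000):
            assert np.min(np.abs(found - bp)) <= 1000

    def test_too_many_missing_windows_rejected(self):
        from ampliscan.types import DepthTrack

        pos = np.arange(1, 10_000, 10)  # track ends far short of the flank
        tr = DepthTrack("s", "chr5", pos, np.full(len(pos), 20))
        with pytest.raises(ValueError, match="missing"):
            origins.extract_profile(
                tr, np.ones(len(pos)), (45_000, 55_000), flank=40_000, resolution=1000
            )


def _corr(rho, ids=None, labels=None):
    n = len(rho)
    ids = ids or [f"s{i}" for i in range(n)]
    labels = labels or {s: ("pop0", "regA") for s in ids}
    return ProfileCorrelation(
        sample_ids=ids, rho=np.asarray(rho, dtype=float), labels=labels,
        region_of_interest=(0, 1),
    )


class TestPairwiseMatrix:
    def test_identical_profiles_correlate_perfectly(self):
        p = np.arange(20, dtype=float)
        corr = origins.pairwise_matrix(
            {"a": p, "b": p.copy()}, {"a": ("p", "r"), "b": ("p", "r")}
        )
        assert np.allclose(corr.rho, 1.0)

    def test_amplitude_invariance(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(1, 5, 30)
        q = rng.uniform(1, 5, 30)
        c1 = origins.pairwise_matrix(
            {"a": p, "b": q}, {"a": ("p", "r"), "b": ("p", "r")}
        )
        c2 = origins.pairwise_matrix(
            {"a": p * 7.3, "b": q}, {"a": ("p", "r"), "b": ("p", "r")}
        )
        assert c1.rho[0, 1] == pytest.approx(c2.rho[0, 1], abs=1e-12)

    def test_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(2)
        profs = {f"s{i}": rng.uniform(0, 4, 25) for i in range(5)}
        labels = {s: ("p", "r") for s in profs}
        corr = origins.pairwise_matrix(profs, labels)
        assert np.allclose(corr.rho, corr.rho.T)
        assert np.allclose(np.diag(corr.rho), 1.0)

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            origins.pairwise_matrix({"a": np.arange(20.0)}, {"a": ("p", "r")})


class TestGroupMeanRho:
    def test_within_one_between_less(self):
        rho = [
            [1.0, 1.0, 0.2, 0.2],
            [1.0, 1.0, 0.2, 0.2],
            [0.2, 0.2, 1.0, 1.0],
            [0.2, 0.2, 1.0, 1.0],
        ]
        labels = {
            "s0": ("A", "r"), "s1": ("A", "r"), "s2": ("B", "r"), "s3": ("B", "r"),
        }
        out = origins.group_mean_rho(_corr(rho, labels=labels), "population")
        assert out["within"]["A"] == 1.0
        assert out["within"]["B"] == 1.0
        assert out["between"][("A", "B")] == pytest.approx(0.2)

    def test_all_identical_cohort_all_means_one(self):
        rho = np.ones((3, 3))
        out = origins.group_mean_rho(_corr(rho.tolist()), "population")
        assert out["overall"] == 1.0
        assert all(v == 1.0 for v in out["within"].values())

    def test_singleton_group_mean_missing(self):
        labels = {"s0": ("A", "r"), "s1": ("B", "r"), "s2": ("B", "r")}
        rho = [[1, 0.5, 0.5], [0.5, 1, 0.9], [0.5, 0.9, 1]]
        out = origins.group_mean_rho(_corr(rho, labels=labels), "population")
        assert np.isnan(out["within"]["A"])
        assert out["within"]["B"] == pytest.approx(0.9)


class TestCallOrigins:
    def test_uniform_high_rho_single_origin(self):
        rho = np.full((4, 4), 0.95)
        np.fill_diagonal(rho, 1.0)
        call = origins.call_origins(_corr(rho.tolist()))
        assert call.n_origins == 1

    def test_two_blocks_two_origins(self):
        rho = np.full((6, 6), 0.1)
        rho[:3, :3] = 0.95
        rho[3:, 3:] = 0.95
        np.fill_diagonal(rho, 1.0)
        call = origins.call_origins(_corr(rho.tolist()))
        assert call.n_origins == 2
        assert len(set(call.cluster[:3])) == 1
        assert len(set(call.cluster[3:])) == 1

    def test_missing_rho_imputed_with_matrix_minimum(self, caplog):
        rho = np.full((4, 4), 0.9)
        np.fill_diagonal(rho, 1.0)
        rho[0, 3] = rho[3, 0] = np.nan
        with caplog.at_level("WARNING", logger="ampliscan.origins"):
            call = origins.call_origins(_corr(rho.tolist()))
        assert "imputing" in caplog.text
        assert call.n_origins == 1  # average linkage absorbs one bad pair

    def test_simulated_origin_count_recovery(self):
        """A scaled-down version of the recovery grid: k in {1, 3} with
        8 carriers each at 20x, exact recovery expected."""
        for k in (1, 3):
            for seed in (0, 1):
                scen = sim.origin_cohort_scenario(k, 8, seed=seed, mean_depth=20.0)
                tracks, truth = sim.simulate_depth(scen)
                profs = {}
                for s, tr in tracks.items():
                    norm = coverage.estimate_mode_depth(tr)
                    profs[s] = origins.extract_profile(
                        tr, coverage.normalize(tr, norm), scen.focal_gene,
                        flank=300_000, resolution=2000,
                    )
                corr = origins.pairwise_matrix(profs, scen.sample_population)
                assert origins.call_origins(corr).n_origins == k

    def test_accuracy_degrades_toward_low_depth(self):
        """Mean within-origin rho falls monotonically as depth drops toward
        the low-coverage regime."""
        means = []
        for depth in (30.0, 10.0, 5.0):
            vals = []
            for seed in (0, 1, 2):
                scen = sim.origin_cohort_scenario(1, 6, seed=seed, mean_depth=depth)
                tracks, _ = sim.simulate_depth(scen)
                profs = {}
                for s, tr in tracks.items():
                    norm = coverage.estimate_mode_depth(tr)
                    profs[s] = origins.extract_profile(
                        tr, coverage.normalize(tr, norm), scen.focal_gene,
                        flank=300_000, resolution=2000,
                    )
                corr = origins.pairwise_matrix(profs, scen.sample_population)
                off = corr.rho[~np.eye(len(corr.sample_ids), dtype=bool)]
                vals.append(np.nanmean(off))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]
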