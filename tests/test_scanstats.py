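import numpy as np
import pandas as pd
import pytest

from tempsweep import scanstats
from tempsweep.containers import GenotypeMatrix, WindowStat
from oracles import ehh_oracle, ihh_oracle, pi_oracle, wc84_components_oracle


class TestWcFst:
    def test_complete_differentiation(self):
        a = np.zeros((20, 1), dtype=np.int8)
        b = np.full((20, 1), 2, dtype=np.int8)
        out = scanstats.wc_fst_site(a, b)
        assert out["fst"][0] == pytest.approx(1.0)

    def test_identical_cohorts_give_no_positive_differentiation(self):
        # the unbiased estimator is slightly negative (never positive) when
        # both cohorts are literally the same finite sample
        g = np.array([[0, 1, 2, 1, 0, 2]], dtype=np.int8).T.reshape(6, 1)
        out = scanstats.wc_fst_site(g, g.copy())
        oa, ob, oc = wc84_components_oracle([g[:, 0], g[:, 0]])
        assert out["a"][0] == pytest.approx(oa, abs=1e-12)
        assert out["a"][0] <= 0
        assert out["fst"][0] <= 0

    def test_worked_example_against_oracle(self):
        a = np.array([[0, 0, 1, 1, 2, 2]], dtype=np.int8).T.reshape(6, 1)
        b = np.zeros((6, 1), dtype=np.int8)
        out = scanstats.wc_fst_site(a, b)
        oa, ob, oc = wc84_components_oracle([a[:, 0], b[:, 0]])
        assert out["a"][0] == pytest.approx(oa, abs=1e-12)
        assert out["denom"][0] == pytest.approx(oa + ob + oc, abs=1e-12)

    def test_monomorphic_site_flagged(self):
        g = np.zeros((5, 1), dtype=np.int8)
        out = scanstats.wc_fst_site(g, g)
        assert not out["informative"][0]
        assert out["a"][0] == 0 and out["denom"][0] == 0


class TestWindows:
    def test_tiling_arithmetic(self):
        assert scanstats.make_windows(25_000, 10_000, 5_000) == [
            (0, 10_000),
            (5_000, 15_000),
            (10_000, 20_000),
            (15_000, 25_000),
        ]

    def test_step_larger_than_window_rejected(self):
        with pytest.raises(ValueError):
            scanstats.make_windows(100, 10, 20)

    def test_ratio_of_sums_and_identical_sites(self):
        a = np.array([[0, 0, 1, 1, 2, 2]], dtype=np.int8).T
        b = np.zeros((6, 1), dtype=np.int8)
        comp1 = scanstats.wc_fst_site(np.repeat(a, 3, axis=1), np.repeat(b, 3, axis=1))
        w = scanstats.fst_windows(
            comp1,
            np.array(["chr1"] * 3, dtype=object),
            np.array([100, 200, 300]),
            window=1000,
            step=1000,
        )
        # identical per-site components: window ratio-of-sums equals site Fst
        site = comp1["a"][0] / comp1["denom"][0]
        assert w[0].value == pytest.approx(site, abs=1e-12)
        assert w[0].n_snps == 3
        hand = comp1["a"].sum() / comp1["denom"].sum()
        assert w[0].value == pytest.approx(hand, abs=1e-12)


class TestEhh:
    hap = np.array(
        [
            [1, 1, 0, 1, 0],
            [0, 1, 0, 1, 0],
            [1, 1, 0, 0, 1],
            [0, 1, 0, 0, 1],
            [1, 0, 1, 1, 1],
            [0, 0, 1, 0, 0],
        ],
        dtype=np.int8,
    )
    pos = np.array([100, 200, 300, 400, 500])

    def test_core_is_one_and_shared_haplotype_stays_one(self):
        h = np.tile(np.array([1, 0, 1, 0, 1], dtype=np.int8), (4, 1))
        up, down = scanstats.ehh(h, self.pos, core_site=2, core_allele=1)
        assert up.ehh[0] == 1.0
        assert np.all(down.ehh == 1.0)

    def test_two_plus_two_split_gives_one_third(self):
        # 4 carriers of allele 1 at core (site 1) split 2+2 at the next site
        up, down = scanstats.ehh(self.hap, self.pos, core_site=1, core_allele=1)
        assert down.ehh[2] == pytest.approx(1 / 3)

    def test_monotone_non_increasing_and_matches_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            h = rng.integers(0, 2, size=(8, 10)).astype(np.int8)
            h[:, 4] = [1, 1, 1, 1, 0, 0, 0, 0]
            up, down = scanstats.ehh(h, np.arange(10) * 50 + 1, 4, 1, cutoff=0.0)
            for curve in (up, down):
                assert np.all(np.diff(curve.ehh) <= 1e-12)
            carriers = [0, 1, 2, 3]
            for k, v in enumerate(down.ehh):
                j = 4 + k
                assert v == pytest.approx(ehh_oracle(h, carriers, 4, j), abs=1e-12)

    def test_too_few_carriers_raise(self):
        single = np.zeros((4, 5), dtype=np.int8)
        single[0, 2] = 1  # one carrier only
        with pytest.raises(ValueError, match="carriers"):
            scanstats.ehh(single, self.pos, core_site=2, core_allele=1)


class TestXpehh:
    def _phased(self, hap, pos):
        n = hap.shape[0] // 2
        return GenotypeMatrix(
            chrom=np.array(["chr1"] * len(pos), dtype=object),
            pos=np.asarray(pos),
            ref=np.array(["A"] * len(pos), dtype=object),
            alt=np.array(["G"] * len(pos), dtype=object),
            dosage=(hap[0::2] + hap[1::2]).astype(np.int8),
            samples=[f"s{i}" for i in range(n)],
            haplotypes=hap.astype(np.int8),
        )

    def test_identical_cohorts_give_zero(self):
        rng = np.random.default_rng(1)
        hap = rng.integers(0, 2, (8, 12)).astype(np.int8)
        pos = np.arange(12) * 100 + 1
        v = scanstats.xpehh(hap, hap.copy(), pos, core_site=6)
        assert v == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry_under_cohort_swap(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 2, (10, 15)).astype(np.int8)
        b = rng.integers(0, 2, (10, 15)).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 5000), 15, replace=False))
        for core in (3, 7, 11):
            v1 = scanstats.xpehh(a, b, pos, core)
            v2 = scanstats.xpehh(b, a, pos, core)
            if np.isfinite(v1):
                assert v1 == pytest.approx(-v2, abs=1e-12)

    def test_ln_ratio_matches_brute_force_integration(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.integers(0, 2, (8, 12)).astype(np.int8)
            b = rng.integers(0, 2, (8, 12)).astype(np.int8)
            pos = np.sort(rng.choice(np.arange(1, 3000), 12, replace=False))
            core = 6
            ia = ihh_oracle(a.tolist(), pos.tolist(), core)
            ib = ihh_oracle(b.tolist(), pos.tolist(), core)
            v = scanstats.xpehh(a, b, pos, core)
            if ia > 0 and ib > 0:
                assert v == pytest.approx(np.log(ib / ia), abs=1e-10)
            else:
                assert np.isnan(v)

    def test_scan_refuses_unphased(self, toy_genotypes, toy_meta):
        unphased = GenotypeMatrix(
            chrom=toy_genotypes.chrom,
            pos=toy_genotypes.pos,
            ref=toy_genotypes.ref,
            alt=toy_genotypes.alt,
            dosage=toy_genotypes.dosage,
            samples=toy_genotypes.samples,
        )
        with pytest.raises(ValueError, match="phase"):
            scanstats.xpehh_scan(unphased, unphased)


class TestThresholds:
    def test_linear_interpolation_quantile(self):
        cut = scanstats.empirical_threshold(np.arange(1, 101), 0.01, "upper")
        assert cut == pytest.approx(99.01)

    def test_constant_values(self):
        assert scanstats.empirical_threshold(np.full(200, 3.5), 0.01) == 3.5

    def test_two_sided_symmetric(self):
        vals = np.concatenate([np.arange(-500, 0), np.arange(1, 501)])
        lo, hi = scanstats.empirical_threshold(vals, 0.01, "both")
        assert lo == pytest.approx(-hi, abs=1e-9)

    def test_empty_raises_and_small_warns(self):
        with pytest.raises(ValueError):
            scanstats.empirical_threshold([], 0.01)
        with pytest.warns(UserWarning):
            scanstats.empirical_threshold(np.arange(50), 0.01)


class TestRegionIntersection:
    def _w(self, chrom, start, end, stat="fst", value=1.0):
        return WindowStat(chrom, start, end, stat, value, 1)

    def test_disjoint_gives_nothing(self):
        out = scanstats.intersect_candidate_windows(
            [self._w("chr1", 0, 10_000)], [self._w("chr1", 20_000, 30_000)]
        )
        assert out == []

    def test_identical_sets_merge(self):
        ws = [self._w("chr1", 0, 10_000), self._w("chr1", 5_000, 15_000)]
        out = scanstats.intersect_candidate_windows(ws, ws)
        assert [(r.chrom, r.start, r.end) for r in out] == [("chr1", 0, 15_000)]

    def test_partial_overlap_worked_example(self):
        fst = [self._w("chr1", 0, 10_000), self._w("chr1", 5_000, 15_000)]
        xp = [self._w("chr1", 10_000, 20_000, "xpehh")]
        out = scanstats.intersect_candidate_windows(fst, xp)
        assert [(r.chrom, r.start, r.end) for r in out] == [("chr1", 10_000, 15_000)]
        assert set(out[0].provenance) == {"fst", "xpehh"}


class TestDiversity:
    def _gm(self, hap, pos):
        n = hap.shape[0] // 2
        return GenotypeMatrix(
            chrom=np.array(["chr1"] * len(pos), dtype=object),
            pos=np.asarray(pos),
            ref=np.array(["A"] * len(pos), dtype=object),
            alt=np.array(["G"] * len(pos), dtype=object),
            dosage=(hap[0::2] + hap[1::2]).astype(np.int8),
            samples=[f"s{i}" for i in range(n)],
            haplotypes=hap.astype(np.int8),
        )

    def test_identical_haplotypes_zero(self):
        hap = np.tile(np.array([1, 0, 1], dtype=np.int8), (4, 1))
        out = scanstats.nucleotide_diversity(self._gm(hap, [10, 20, 30]), window=100)
        assert out[0].value == 0.0

    def test_single_pair_three_differences(self):
        hap = np.zeros((2, 3), dtype=np.int8)
        hap[1] = 1
        out = scanstats.nucleotide_diversity(
            self._gm(hap, [10, 500, 900]), window=10_000, chrom_lengths={"chr1": 10_000}
        )
        assert out[0].value == pytest.approx(3 / 10_000)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            hap = rng.integers(0, 2, (10, 50)).astype(np.int8)
            pos = np.sort(rng.choice(np.arange(1, 9999), 50, replace=False))
            out = scanstats.nucleotide_diversity(
                self._gm(hap, pos), window=10_000, chrom_lengths={"chr1": 10_000}
            )
            assert out[0].value == pytest.approx(
                pi_oracle(hap.tolist(), 10_000), abs=1e-12
            )


class TestPca:
    def test_duplicated_sample_coincides_and_orthonormal(self, small_sim):
        gm = small_sim["gm"]
        idx = list(range(gm.n_samples)) + [0]
        dup = gm.take_samples(np.array(idx))
        coords, eigvals, _ = scanstats.genotype_pca(dup, k=3)
        np.testing.assert_allclose(coords[0], coords[-1], atol=1e-8)
        u = coords / np.linalg.norm(coords, axis=0)
        np.testing.assert_allclose(u.T @ u, np.eye(3), atol=1e-10)

    def test_separates_diverged_cohorts(self, small_sim):
        gm, meta = small_sim["gm"], small_sim["meta"]
        coords, _, _ = scanstats.genotype_pca(gm, k=2)
        g = meta["generation"].to_numpy()
        c1, c10 = coords[g == 1, 0], coords[g == 10, 0]
        sep = abs(c1.mean() - c10.mean())
        # permutation test on PC1 centroid separation
        rng = np.random.default_rng(0)
        null = []
        for _ in range(199):
            perm = rng.permutation(coords[(g == 1) | (g == 10), 0])
            null.append(abs(perm[: len(c1)].mean() - perm[len(c1):].mean()))
        assert sep > np.quantile(null, 0.95)


class TestTrajectory:
    def test_hand_counts_on_toy(self, toy_genotypes, toy_meta):
        out = scanstats.frequency_trajectory(toy_genotypes, toy_meta)
        # site 1: gen1 cohort (s1, s2) dosages 1, 0 -> ALT 1/4
        assert out["gen1"][0] == pytest.approx(0.25)
        assert out["n_gen1"][0] == 4
        # site 4: gen10 cohort (s3, s4) dosages 1, 1 -> 2/4
        assert out["gen10"][3] == pytest.approx(0.5)

    def test_fixed_locus_flat_at_one(self):
        gm = GenotypeMatrix(
            chrom=np.array(["chr1"], dtype=object),
            pos=np.array([5]),
            ref=np.array(["A"], dtype=object),
            alt=np.array(["G"], dtype=object),
            dosage=np.full((4, 1), 2, dtype=np.int8),
            samples=["a", "b", "c", "d"],
        )
        meta = pd.DataFrame(
            {"sample_id": ["a", "b", "c", "d"], "generation": [1, 1, 10, 10], "sex": list("MFMF")}
        )
        out = scanstats.frequency_trajectory(gm, meta)
        assert out["gen1"][0] == 1.0 and out["gen10"][0] == 1.0

    def test_selected_locus_rises_in_most_replicates(self, small_sim):
        gm, meta, registry = small_sim["gm"], small_sim["meta"], small_sim["registry"]
        traj = scanstats.frequency_trajectory(gm, meta)
        causal = traj[traj.pos.isin(registry.pos)]
        freqs = causal[["gen1", "gen4", "gen7", "gen10"]].to_numpy()
        from scipy.stats import spearmanr

        rhos = [spearmanr([1, 4, 7, 10], row).statistic for row in freqs if np.ptp(row) > 0]
        assert np.mean([r > 0 for r in rhos]) >= 0.6


class TestDnds:
    def test_count_ratio(self):
        r, counts = scanstats.dnds_proportion(["N"] * 10 + ["S"] * 20)
        assert r == 0.5 and counts == {"N": 10, "S": 20, "undefined": False}
        assert scanstats.dnds_proportion(["N", "S"])[0] == 1.0

    def test_zero_synonymous_flagged(self):
        r, counts = scanstats.dnds_proportion(["nonsynonymous"] * 3)
        assert np.isnan(r) and counts["undefined"]

    def test_sampling_recovery_of_target_ratio(self):
        rng = np.random.default_rng(9)
        # N/S target 0.8 -> P(nonsyn) = 4/9
        labels = np.where(rng.random(500) < 4 / 9, "N", "S")
        r, counts = scanstats.dnds_proportion(labels)
        p = counts["N"] / 500
        se = np.sqrt(p * (1 - p) / 500)
        lo, hi = (p - 3 * se), (p + 3 * se)
        assert lo / (1 - lo) < 0.8 < hi / (1 - hi)
        assert r == pytest.approx(0.8, rel=0.3)
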