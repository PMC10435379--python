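import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qcpop.data import MISSING, GeneticMap
from qcpop.simulate import balding_nichols_freqs, sample_haplotypes
from qcpop.structure import (
    HmmParams,
    LrldRegion,
    detect_lrld_hmm,
    fit_z2_mixture,
    forward_backward,
    fst_matrix,
    iterate_lrld_pca,
    ld_prune,
    local_pca,
    merge_regions,
    project_samples,
    regional_outliers,
    run_pca,
    select_informative_pcs,
    transition_matrices,
    weir_cockerham_fst,
)


class TestLdPrune:
    def test_independent_variants_all_kept(self):
        rng = np.random.default_rng(0)
        calls = rng.binomial(2, 0.4, (300, 60)).astype(np.int8)
        kept = ld_prune(calls, r2_threshold=0.3)
        assert len(kept) >= 58  # chance correlations only

    def test_perfectly_correlated_pair_keeps_one(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.4, (200, 1)).astype(np.int8)
        calls = np.hstack([g, g, rng.binomial(2, 0.4, (200, 1)).astype(np.int8)])
        kept = ld_prune(calls, r2_threshold=0.2)
        assert sorted(kept)[-1] == 2
        assert len(kept) == 2

    def test_postcondition_no_window_pair_above_threshold(self):
        rng = np.random.default_rng(2)
        base = rng.binomial(2, 0.5, (150, 40)).astype(np.int8)
        # correlated neighbours: copy with noise
        noisy = base.copy()
        flip = rng.random(base.shape) < 0.1
        noisy[flip] = rng.integers(0, 3, flip.sum())
        calls = np.empty((150, 80), dtype=np.int8)
        calls[:, 0::2] = base
        calls[:, 1::2] = noisy
        kept = ld_prune(calls, window_snps=20, step_snps=5, r2_threshold=0.2)
        g = calls[:, kept].astype(float)
        for a, b in itertools.combinations(range(len(kept)), 2):
            if abs(kept[a] - kept[b]) >= 20:
                continue
            r = np.corrcoef(g[:, a], g[:, b])[0, 1]
            assert r**2 <= 0.2 + 1e-9


class TestPca:
    def _two_pops(self, seed=3, n=200, m=2000, fst=0.01):
        rng = np.random.default_rng(seed)
        p0 = rng.uniform(0.05, 0.95, m)
        pa = balding_nichols_freqs(p0, fst, rng)
        pb = balding_nichols_freqs(p0, fst, rng)
        calls = np.vstack([rng.binomial(2, pa, (n, m)),
                           rng.binomial(2, pb, (n, m))]).astype(np.int8)
        labels = np.repeat([0, 1], n)
        return calls, labels

    def test_pc1_separates_populations(self):
        calls, labels = self._two_pops()
        pca = run_pca(calls, n_pcs=4)
        pc1 = pca.scores[:, 0]
        thr = (pc1[labels == 0].mean() + pc1[labels == 1].mean()) / 2
        pred = (pc1 > thr).astype(int)
        acc = max((pred == labels).mean(), (1 - pred == labels).mean())
        assert acc >= 0.99

    def test_sample_permutation_equivariance(self):
        calls, _ = self._two_pops(seed=4, n=60, m=400)
        rng = np.random.default_rng(5)
        perm = rng.permutation(calls.shape[0])
        pca = run_pca(calls, n_pcs=3)
        pca_p = run_pca(calls[perm], n_pcs=3)
        np.testing.assert_allclose(pca_p.scores, pca.scores[perm], atol=1e-8)

    def test_score_variance_matches_eigenvalues(self):
        calls, _ = self._two_pops(seed=6, n=80, m=500)
        pca = run_pca(calls, n_pcs=5)
        var = pca.scores.var(axis=0, ddof=1)
        np.testing.assert_allclose(var, pca.eigenvalues, rtol=1e-10)

    def test_monomorphic_variants_dropped_with_warning(self):
        calls, _ = self._two_pops(seed=7, n=50, m=100)
        calls[:, 0] = 2
        with pytest.warns(UserWarning, match="monomorphic"):
            pca = run_pca(calls, n_pcs=3)
        assert 0 not in pca.variant_idx


class TestProjection:
    def test_training_samples_reproduce_their_scores(self):
        rng = np.random.default_rng(8)
        calls = rng.binomial(2, rng.uniform(0.1, 0.9, 400), (120, 400)
                             ).astype(np.int8)
        pca = run_pca(calls, n_pcs=5)
        proj = project_samples(pca, calls)
        rel = np.abs(proj - pca.scores) / (np.abs(pca.scores).max())
        assert rel.max() < 1e-8

    def test_noisy_duplicate_projects_close(self):
        rng = np.random.default_rng(9)
        freqs = rng.uniform(0.1, 0.9, 600)
        calls = rng.binomial(2, freqs, (150, 600)).astype(np.int8)
        pca = run_pca(calls, n_pcs=3)
        noisy = calls[:1].copy()
        err = rng.random(600) < 0.01
        noisy[0, err] = rng.binomial(2, freqs[err])
        proj = project_samples(pca, noisy)
        spread = pca.scores[:, 0].std()
        assert np.linalg.norm(proj[0] - pca.scores[0]) < spread

    def test_all_missing_sample_rejected(self):
        rng = np.random.default_rng(10)
        calls = rng.binomial(2, 0.5, (50, 100)).astype(np.int8)
        pca = run_pca(calls, n_pcs=2)
        empty = np.full((1, 100), MISSING, dtype=np.int8)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no genotypes"):
                project_samples(pca, empty)


class TestInformativePcSelection:
    def test_single_class_degenerate_k_zero(self):
        rng = np.random.default_rng(11)
        s = rng.normal(0, 1, (100, 5))
        assert select_informative_pcs(s, ["x"] * 100, "multinomial")["k"] == 0

    def test_hierarchical_three_populations_k_two(self):
        rng = np.random.default_rng(12)
        p0 = rng.uniform(0.05, 0.95, 2000)
        pab = balding_nichols_freqs(p0, 0.02, rng)
        pops = [balding_nichols_freqs(pab, 0.005, rng),
                balding_nichols_freqs(pab, 0.005, rng),
                balding_nichols_freqs(p0, 0.02, rng)]
        calls = np.vstack([rng.binomial(2, p, (100, 2000)) for p in pops]
                          ).astype(np.int8)
        labels = np.repeat([0, 1, 2], 100)
        pca = run_pca(calls, n_pcs=6)
        assert select_informative_pcs(pca.scores, labels, "multinomial")["k"] == 2

    def test_label_shuffle_destroys_informativeness(self):
        rng = np.random.default_rng(13)
        calls, labels = TestPca()._two_pops(seed=13, n=100, m=1000)
        pca = run_pca(calls, n_pcs=5)
        assert select_informative_pcs(pca.scores, labels, "multinomial")["k"] >= 1
        ks = [select_informative_pcs(pca.scores, rng.permutation(labels),
                                     "multinomial")["k"] for _ in range(20)]
        assert np.mean(np.array(ks) == 0) >= 0.95

    def test_linear_2d_geography_model(self):
        rng = np.random.default_rng(14)
        s = rng.normal(0, 1, (200, 4))
        coords = np.column_stack([
            10 + 2.0 * s[:, 0] + rng.normal(0, 0.3, 200),
            100 + 1.5 * s[:, 1] + rng.normal(0, 0.3, 200)])
        sel = select_informative_pcs(s, coords, "linear_2d")
        assert sel["k"] == 2

    def test_binary_model(self):
        rng = np.random.default_rng(15)
        s = rng.normal(0, 1, (300, 3))
        y = (s[:, 0] + rng.normal(0, 0.7, 300)) > 0
        assert select_informative_pcs(s, y.astype(int), "binary")["k"] == 1


class TestHmmCore:
    def test_posteriors_match_brute_force_enumeration(self):
        rng = np.random.default_rng(16)
        params = HmmParams()
        for m in (2, 5, 9, 12):
            e = rng.random((m, 2)) + 0.02
            cm = np.sort(rng.uniform(0, 8, m))
            T = transition_matrices(cm, params)
            init = np.array([1 - params.pi_in, params.pi_in])
            post = forward_backward(e, T, init)
            brute = np.zeros((m, 2))
            for path in itertools.product([0, 1], repeat=m):
                p = init[path[0]] * e[0, path[0]]
                for i in range(1, m):
                    p *= T[i - 1, path[i - 1], path[i]] * e[i, path[i]]
                for i, s in enumerate(path):
                    brute[i, s] += p
            brute /= brute.sum(axis=1, keepdims=True)
            np.testing.assert_allclose(post, brute, atol=1e-12)

    def test_transition_matrices_row_stochastic(self):
        T = transition_matrices(np.array([0.0, 0.5, 3.0]), HmmParams())
        np.testing.assert_allclose(T.sum(axis=2), 1.0)
        assert (T > 0).all()

    def test_params_validated(self):
        with pytest.raises(ValueError):
            HmmParams(pi_in=0)
        with pytest.raises(ValueError):
            HmmParams(rho=-1)

    def test_mixture_recovers_inflated_component(self):
        rng = np.random.default_rng(17)
        x = np.concatenate([rng.chisquare(1, 1800), 8 * rng.chisquare(1, 200)])
        mix = fit_z2_mixture(x)
        assert not mix["degenerate"]
        assert 5 < mix["scale"] < 12
        assert 0.05 < mix["weight"] < 0.2


class TestLrldDetection:
    GMAP = GeneticMap.uniform({"1": 20_000_000})

    def _track(self, rng, block=None, var=10.0, m=2000):
        pos = np.sort(rng.choice(20_000_000, m, replace=False))
        load = rng.normal(0, 1, m)
        if block:
            sel = (pos >= block[0]) & (pos <= block[1])
            load[sel] = rng.normal(0, np.sqrt(var), sel.sum())
        return pos, load

    def test_null_track_yields_no_regions(self):
        rng = np.random.default_rng(18)
        hits = 0
        for _ in range(25):
            pos, load = self._track(rng)
            hits += bool(detect_lrld_hmm(load, ["1"] * len(pos), pos, self.GMAP))
        assert hits <= 1

    def test_planted_block_recovered_with_high_jaccard(self):
        rng = np.random.default_rng(19)
        jacs = []
        for _ in range(10):
            pos, load = self._track(rng, block=(8e6, 10e6))
            regs = detect_lrld_hmm(load, ["1"] * len(pos), pos, self.GMAP)
            inter = sum(max(0, min(r.end, 10e6) - max(r.start, 8e6))
                        for r in regs)
            union = 2e6 + sum(r.end - r.start for r in regs) - inter
            jacs.append(inter / union)
        assert np.mean(jacs) >= 0.8

    def test_nearby_runs_merged_into_one_region(self):
        rng = np.random.default_rng(20)
        # two inflated blocks 0.5 Mb apart -> single merged region
        pos = np.arange(1, 2001) * 10_000
        load = rng.normal(0, 1, 2000)
        b1 = (pos >= 8.0e6) & (pos <= 9.0e6)
        b2 = (pos >= 9.5e6) & (pos <= 10.5e6)
        load[b1 | b2] = rng.normal(0, 4, (b1 | b2).sum())
        regs = detect_lrld_hmm(load, ["1"] * 2000, pos, self.GMAP)
        assert len(regs) == 1
        assert regs[0].start < 8.2e6 and regs[0].end > 10.3e6

    def test_merge_regions_respects_distance(self):
        a = LrldRegion("1", 100, 200, 0, 0.9)
        b = LrldRegion("1", 500_000, 600_000, 0, 0.8)
        c = LrldRegion("1", 5_000_000, 5_100_000, 1, 0.7)
        merged = merge_regions([a, b, c], merge_bp=1_000_000)
        assert len(merged) == 2
        assert merged[0].end == 600_000

    def test_short_chromosome_not_scanned(self):
        rng = np.random.default_rng(21)
        pos = np.arange(1, 51) * 100_000
        load = rng.normal(0, 4, 50)
        assert detect_lrld_hmm(load, ["1"] * 50, pos, self.GMAP,
                               min_chrom_variants=100) == []


class TestIterativeLrldPca:
    def _cohort_with_block(self, seed=22, block=True):
        rng = np.random.default_rng(seed)
        m = 1200
        pos = np.sort(rng.choice(20_000_000, m, replace=False))
        p0 = rng.uniform(0.1, 0.9, m)
        pa = balding_nichols_freqs(p0, 0.02, rng)
        pb = balding_nichols_freqs(p0, 0.02, rng)
        haps = []
        calls = np.vstack([rng.binomial(2, pa, (120, m)),
                           rng.binomial(2, pb, (120, m))]).astype(np.int8)
        if block:
            sel = (pos >= 8e6) & (pos <= 10e6)
            pool = sample_haplotypes(p0[sel], 4, rng)
            for i in range(calls.shape[0]):
                pick = rng.integers(4, size=2)
                calls[i, sel] = (pool[pick[0]] + pool[pick[1]]).astype(np.int8)
        variants = pd.DataFrame({"id": [f"v{i}" for i in range(m)],
                                 "chrom": "1", "pos": pos,
                                 "allele1": "A", "allele2": "G"})
        labels = np.repeat(["a", "b"], 120)
        return calls, variants, labels

    def test_clean_cohort_terminates_first_round_empty(self):
        calls, variants, labels = self._cohort_with_block(block=False)
        gmap = GeneticMap.uniform({"1": 20_000_000})
        pca, regions, k = iterate_lrld_pca(calls, variants, labels, gmap,
                                           n_pcs=5)
        assert regions == []
        assert k >= 1

    def test_planted_block_found_and_removed(self):
        calls, variants, labels = self._cohort_with_block()
        gmap = GeneticMap.uniform({"1": 20_000_000})
        pca, regions, k = iterate_lrld_pca(calls, variants, labels, gmap,
                                           n_pcs=5)
        assert regions, "planted LRLD block not found"
        covered = any(r.start < 9e6 < r.end for r in regions)
        assert covered
        # final variant set excludes the block
        pos = variants["pos"].to_numpy()[pca.variant_idx]
        for r in regions:
            assert not ((pos >= r.start) & (pos <= r.end)).any()
        # regions disjoint after merging
        for r1, r2 in itertools.combinations(regions, 2):
            if r1.chrom == r2.chrom:
                assert r1.end < r2.start or r2.end < r1.start

    def test_invariant_to_chromosome_relabeling(self):
        calls, variants, labels = self._cohort_with_block(seed=23)
        gmap = GeneticMap.uniform({"1": 20_000_000, "9": 20_000_000})
        _, regions1, _ = iterate_lrld_pca(calls, variants, labels, gmap, n_pcs=5)
        v2 = variants.assign(chrom="9")
        _, regions2, _ = iterate_lrld_pca(calls, v2, labels, gmap, n_pcs=5)
        assert [(r.start, r.end) for r in regions1] == \
            [(r.start, r.end) for r in regions2]


class TestRegionalOutliers:
    def test_centroid_sample_not_flagged(self):
        rng = np.random.default_rng(24)
        s = rng.normal(0, 1, (200, 3))
        s[0] = 0.0
        out = regional_outliers(s, ["r"] * 200, k=3)
        assert not out["flagged"][0]

    def test_planted_migrants_flagged(self):
        rng = np.random.default_rng(25)
        flagged = 0
        for rep in range(20):
            s = rng.normal(0, 1, (120, 2))
            s[:10] += np.array([12.0, -9.0])  # migrants from another cluster
            out = regional_outliers(s, ["r"] * 120, k=2, seed=rep)
            flagged += out["flagged"][:10].sum()
        assert flagged / 200 >= 0.95

    def test_null_flag_fraction_small(self):
        rng = np.random.default_rng(26)
        s = rng.normal(0, 1, (2000, 2))
        out = regional_outliers(s, ["r"] * 2000, k=2)
        assert out["flagged"].mean() < 0.02

    def test_small_region_skipped(self):
        rng = np.random.default_rng(27)
        s = rng.normal(0, 1, (30, 2))
        out = regional_outliers(s, ["r"] * 30, k=2, min_region=50)
        assert (out["method"] == "region_too_small").all()
        assert not out["flagged"].any()


class TestLocalPca:
    def test_two_geographic_subclusters_informative(self):
        rng = np.random.default_rng(28)
        p0 = rng.uniform(0.1, 0.9, 1500)
        pa = balding_nichols_freqs(p0, 0.01, rng)
        pb = balding_nichols_freqs(p0, 0.01, rng)
        calls = np.vstack([rng.binomial(2, pa, (80, 1500)),
                           rng.binomial(2, pb, (80, 1500))]).astype(np.int8)
        coords = np.vstack([np.tile([30.0, 110.0], (80, 1)),
                            np.tile([31.5, 112.0], (80, 1))])
        out = local_pca(calls, np.ones(160, dtype=bool), coords)
        assert out["k"] >= 1

    def test_single_center_region_k_zero(self):
        rng = np.random.default_rng(29)
        calls = rng.binomial(2, 0.4, (60, 300)).astype(np.int8)
        coords = np.tile([30.0, 110.0], (60, 1))
        assert local_pca(calls, np.ones(60, dtype=bool), coords)["k"] == 0

    def test_shuffled_coordinates_uninformative(self):
        rng = np.random.default_rng(30)
        p0 = rng.uniform(0.1, 0.9, 800)
        calls = rng.binomial(2, p0, (100, 800)).astype(np.int8)
        ks = []
        for _ in range(20):
            coords = rng.normal(30, 1, (100, 2))
            ks.append(local_pca(calls, np.ones(100, dtype=bool), coords)["k"])
        assert np.mean(np.array(ks) == 0) >= 0.95


class TestFst:
    def _dataset(self, calls, regions):
        from qcpop.data import GenotypeDataset
        m = calls.shape[1]
        variants = pd.DataFrame({"id": [f"v{i}" for i in range(m)],
                                 "chrom": "1", "pos": np.arange(1, m + 1),
                                 "allele1": "A", "allele2": "G"})
        samples = pd.DataFrame({"id": [f"s{i}" for i in range(calls.shape[0])],
                                "sex": "F", "region": regions})
        return GenotypeDataset(calls, variants, samples)

    def test_split_single_population_near_zero(self):
        rng = np.random.default_rng(31)
        p = rng.uniform(0.1, 0.9, 20_000)
        calls = rng.binomial(2, p, (200, 20_000)).astype(np.int8)
        est = weir_cockerham_fst(calls[:100], calls[100:])
        assert abs(est) < 0.002

    def test_balding_nichols_parameter_recovery(self):
        rng = np.random.default_rng(32)
        p0 = rng.uniform(0.05, 0.95, 20_000)
        pa = balding_nichols_freqs(p0, 0.02, rng)
        pb = balding_nichols_freqs(p0, 0.02, rng)
        ga = rng.binomial(2, pa, (200, 20_000)).astype(np.int8)
        gb = rng.binomial(2, pb, (200, 20_000)).astype(np.int8)
        est = weir_cockerham_fst(ga, gb)
        assert abs(est - 0.02) < 0.002  # |bias| < 0.1 F

    def test_matrix_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(33)
        p0 = rng.uniform(0.1, 0.9, 800)
        calls = np.vstack([
            rng.binomial(2, balding_nichols_freqs(p0, 0.01, rng), (40, 800))
            for _ in range(3)]).astype(np.int8)
        regions = np.repeat(["a", "b", "c"], 40)
        mat = fst_matrix(self._dataset(calls, regions))
        np.testing.assert_allclose(mat.to_numpy(), mat.to_numpy().T)
        np.testing.assert_allclose(np.diag(mat.to_numpy()), 0.0)
        assert (mat.to_numpy()[np.triu_indices(3, 1)] > 0).all()

    def test_single_region_rejected(self):
        rng = np.random.default_rng(34)
        calls = rng.binomial(2, 0.4, (30, 100)).astype(np.int8)
        with pytest.raises(ValueError, match="2 regions"):
            fst_matrix(self._dataset(calls, ["r"] * 30))
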