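import numpy as np
import pytest

from xdecsm import simulate as sim
from xdecsm.stage0 import ReferenceSet, build_pseudobulks
from xdecsm.transform import TransformedMatrix


class TestReferenceGenerator:
    def test_deterministic_given_seed(self):
        a, la = sim.generate_reference_profiles(seed=3)
        b, lb = sim.generate_reference_profiles(seed=3)
        np.testing.assert_array_equal(a.values, b.values)
        assert la == lb

    def test_distinct_seeds_differ(self):
        a, _ = sim.generate_reference_profiles(seed=3)
        b, _ = sim.generate_reference_profiles(seed=4)
        assert not np.array_equal(a.values, b.values)

    def test_marker_fold_must_exceed_one(self):
        spec = [sim.TypeSpec("a", 3, marker_fold=1.0), sim.TypeSpec("b", 3)]
        with pytest.raises(ValueError, match="marker_fold"):
            sim.generate_reference_profiles(type_spec=spec, seed=0)

    def test_planted_markers_are_disjoint_blocks(self):
        markers = sim.planted_markers()
        all_markers = [g for ms in markers.values() for g in ms]
        assert len(all_markers) == 100
        assert len(set(all_markers)) == 100

    def test_markers_elevated_in_their_class(self):
        refs = sim.simulated_reference_set(seed=2)
        markers = sim.planted_markers()
        for cls, ms in markers.items():
            rows = [refs.profiles.gene_ids.index(g) for g in ms]
            own = refs.profiles.values[np.ix_(rows, refs.class_columns(cls))].mean()
            other_cols = [i for i, l in enumerate(refs.class_labels) if l != cls]
            other = refs.profiles.values[np.ix_(rows, other_cols)].mean()
            assert own > other


class TestProfileNoise:
    def _mid_range_refs(self, n_genes=10000, reps=3):
        rng = np.random.default_rng(0)
        V = np.clip(rng.normal(0.5, 0.05, size=(n_genes, 2 * reps)), 0.05, 0.9)
        T = TransformedMatrix(V, [f"g{i}" for i in range(n_genes)],
                              [f"r{j}" for j in range(2 * reps)], 1.0)
        return ReferenceSet(T, ["cancer_epithelial"] * reps + ["stroma"] * reps)

    def test_noise_variance_calibration(self):
        # mid-range values avoid clipping, so the empirical variance of the
        # perturbation over 10^4 genes must match frac * max per-gene variance
        refs = self._mid_range_refs()
        noisy = sim.add_profile_noise(refs, seed=1)
        V, W = refs.profiles.values, noisy.profiles.values
        for cls, frac in (("cancer_epithelial", 0.10), ("stroma", 0.05)):
            cols = refs.class_columns(cls)
            expected = frac * V[:, cols].var(axis=1, ddof=1).max()
            got = (W[:, cols] - V[:, cols]).var()
            assert abs(got - expected) / expected < 0.05

    def test_cancer_perturbation_larger_than_normal(self):
        refs = self._mid_range_refs()
        noisy = sim.add_profile_noise(refs, seed=2)
        d = np.abs(noisy.profiles.values - refs.profiles.values)
        assert d[:, refs.class_columns("cancer_epithelial")].mean() > \
            d[:, refs.class_columns("stroma")].mean()

    def test_vanishing_fraction_limit(self):
        refs = self._mid_range_refs(n_genes=500)
        noisy = sim.add_profile_noise(refs, cancer_noise_frac=1e-9,
                                      normal_noise_frac=1e-9, seed=3)
        np.testing.assert_allclose(noisy.profiles.values, refs.profiles.values,
                                   atol=1e-4)

    def test_single_replicate_type_rejected(self):
        rng = np.random.default_rng(0)
        V = rng.uniform(0.2, 0.8, size=(50, 3))
        T = TransformedMatrix(V, [f"g{i}" for i in range(50)], ["a", "b", "c"], 1.0)
        # ReferenceSet itself requires >= 2 profiles per class, so drive the
        # variance helper directly
        with pytest.raises(ValueError, match="single replicate"):
            sim._type_noise_sd(V, ["x", "x", "y"], {"x": 0.1, "y": 0.05})


class TestMixtures:
    def test_proportions_sum_to_one_and_classes_counted(self):
        refs = sim.simulated_reference_set(n_genes=300, seed=5)
        mix, truth = sim.generate_mixtures(refs, n=40, seed=6)
        np.testing.assert_allclose(truth.true_proportions.sum(axis=0), 1.0)
        assert len(truth.purity_class) == 40
        assert mix.n_samples == 40

    def test_control_mixtures_exactly_match_design(self):
        refs = sim.simulated_reference_set(n_genes=300, seed=5)
        _, truth = sim.generate_mixtures(refs, n=40, seed=6)
        i_cancer = truth.type_names.index("cancer_epithelial")
        i_normal = truth.type_names.index("normal_epithelial")
        controls = [j for j, c in enumerate(truth.purity_class) if c == "control"]
        assert controls
        np.testing.assert_array_equal(truth.true_proportions[i_cancer, controls], 0.0)
        np.testing.assert_allclose(truth.true_proportions[i_normal, controls], 0.70)

    def test_purity_class_constraints(self):
        refs = sim.simulated_reference_set(n_genes=300, seed=5)
        _, truth = sim.generate_mixtures(refs, n=60, seed=7)
        i_cancer = truth.type_names.index("cancer_epithelial")
        i_normal = truth.type_names.index("normal_epithelial")
        for j, cls in enumerate(truth.purity_class):
            c = truth.true_proportions[i_cancer, j]
            if cls == "high":
                assert 0.6 <= c <= 0.9
            elif cls == "impure":
                assert c == pytest.approx(0.40)
            elif cls == "low":
                assert c == pytest.approx(0.10)
                assert 0.5 <= truth.true_proportions[i_normal, j] <= 0.8

    def test_noiseless_identical_replicates_mix_linearly(self):
        # with replicate spread zero, every replicate equals the type profile,
        # so the mixture must equal the proportion-weighted combination exactly
        spec = [
            sim.TypeSpec("cancer_epithelial", 3, lineage="epithelial"),
            sim.TypeSpec("normal_epithelial", 3, lineage="epithelial"),
            sim.TypeSpec("immune", 3),
            sim.TypeSpec("stroma", 3),
        ]
        refs = sim.simulated_reference_set(
            n_genes=200, type_spec=spec, seed=8, replicate_log_sd=1e-12
        )
        mix, truth = sim.generate_mixtures(refs, n=20, seed=9, noise=False)
        expected = truth.true_profiles @ truth.true_proportions
        np.testing.assert_allclose(mix.values, expected, atol=1e-9)
        assert np.linalg.matrix_rank(mix.values, tol=1e-8) <= 4

    def test_class_mix_must_sum_to_n(self):
        refs = sim.simulated_reference_set(n_genes=300, seed=5)
        with pytest.raises(ValueError, match="sum to n"):
            sim.generate_mixtures(refs, n=10, class_mix={"high": 4, "control": 4}, seed=0)


class TestSyntheticScrna:
    def test_planted_shallow_cells_are_filtered(self):
        sc, labels = sim.generate_synthetic_scrna(
            class_cells={"epithelial": 23, "stromal": 13}, n_low_coverage=3, seed=4
        )
        refs = build_pseudobulks(sc, labels)
        # 20 and 10 passing cells -> 4 and 2 pseudo-bulks
        assert refs.class_labels.count("epithelial") == 4
        assert refs.class_labels.count("stromal") == 2

    def test_markers_enriched_in_own_class_pseudobulks(self):
        sc, labels = sim.generate_synthetic_scrna(seed=5)
        refs = build_pseudobulks(sc, labels)
        classes = list(dict.fromkeys(labels))
        for i, cls in enumerate(classes):
            rows = slice(i * 20, (i + 1) * 20)
            own = refs.profiles.values[rows, refs.class_columns(cls)].mean()
            rest = [j for j, l in enumerate(refs.class_labels) if l != cls]
            assert own > refs.profiles.values[rows, :][:, rest].mean()


class TestScoreRecovery:
    def test_exact_result_scores_one(self, rng):
        k, n, g = 3, 25, 40
        P = rng.dirichlet(np.ones(k), size=n).T
        M = rng.uniform(0, 1, size=(g, k))
        truth = sim.SimulationTruth(
            true_profiles=M, true_proportions=P,
            type_names=["a", "b", "c"], gene_ids=[f"g{i}" for i in range(g)],
            purity_class=["high"] * n, seed=0,
        )

        class Result:
            pass

        res = Result()
        res.k, res.P, res.M = k, P.copy(), M.copy()
        res.gene_ids = truth.gene_ids
        report = sim.score_recovery(res, truth)
        assert report.min_proportion_r2 == pytest.approx(1.0)
        assert report.min_profile_r2 == pytest.approx(1.0)

        # permuted components score 1 after matching
        res.P, res.M = P[::-1, :].copy(), M[:, ::-1].copy()
        report = sim.score_recovery(res, truth)
        assert report.min_proportion_r2 == pytest.approx(1.0)
        np.testing.assert_array_equal(sorted(report.permutation), [0, 1, 2])
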