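"""Gaussian scenario generators and the synthetic two-cohort fixture."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from ceda.simulate import (
    OVERLAP_TARGETS,
    SampleSizeRanges,
    add_uniform_noise,
    make_experiment,
    random_covariance,
    sample_domain,
    synth_fall_cohort,
)


class TestRandomCovariance:
    @pytest.mark.parametrize("seed", range(5))
    def test_eigenvalues_match_drawn_diagonal(self, seed):
        S = random_covariance(6, (1.0, 3.0), seed)
        np.testing.assert_array_equal(S, S.T)
        w = np.linalg.eigvalsh(S)
        assert np.all(w >= 1.0 - 1e-8) and np.all(w <= 3.0 + 1e-8)

    def test_scalar_case(self):
        S = random_covariance(1, (2.0, 5.0), 0)
        assert S.shape == (1, 1) and 2.0 <= S[0, 0] <= 5.0

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            random_covariance(3, (0.0, 1.0), 0)
        with pytest.raises(ValueError):
            random_covariance(3, (3.0, 1.0), 0)


class TestSampleDomain:
    def test_one_sample_per_class(self):
        src, tgt, config = make_experiment("overlap", "a", 0, return_config=True)
        config.source.n_per_class = [1, 1]
        ds = sample_domain(config, "source")
        assert ds.n_samples == 2
        np.testing.assert_array_equal(ds.labels, [1, 2])

    def test_sample_mean_clt_bound(self):
        from ceda.simulate import DomainSpec, ScenarioConfig

        spec = DomainSpec(
            means=[np.array([1.0, -2.0]), np.array([4.0, 0.0])],
            covs=[np.eye(2), np.eye(2)],
            n_per_class=[5000, 5000],
        )
        config = ScenarioConfig(spec, spec, seed=11)
        ds = sample_domain(config, "source")
        for c, mu in ((1, [1.0, -2.0]), (2, [4.0, 0.0])):
            emp = ds.features[ds.labels == c].mean(axis=0)
            np.testing.assert_allclose(emp, mu, atol=0.06)

    def test_determinism(self):
        a1 = make_experiment("sample_size", "a", 42)
        a2 = make_experiment("sample_size", "a", 42)
        np.testing.assert_array_equal(a1[0].features, a2[0].features)
        np.testing.assert_array_equal(a1[1].features, a2[1].features)


class TestUniformNoise:
    def test_zero_width_is_identity(self):
        src, _ = make_experiment("overlap", "a", 0)
        out = add_uniform_noise(src, 0.0, 0.0, 1)
        np.testing.assert_array_equal(out.features, src.features)

    def test_support_bound_and_mean(self):
        src, _ = make_experiment("overlap", "a", 0)
        base = np.zeros((100, 100))
        from ceda.datasets import DomainDataset

        noisy = add_uniform_noise(DomainDataset(base + 1.0), -3.0, 3.0, 2)
        pert = noisy.features - 1.0
        assert np.max(np.abs(pert)) <= 3.0
        assert abs(pert.mean()) <= 0.1

    def test_invalid_bounds(self):
        src, _ = make_experiment("overlap", "a", 0)
        with pytest.raises(ValueError):
            add_uniform_noise(src, 1.0, -1.0, 0)


class TestMakeExperiment:
    def test_overlap_a_source_moments(self):
        src, _ = make_experiment("overlap", "a", 3)
        X1 = src.features[src.labels == 1]
        assert X1.shape == (100, 2)
        np.testing.assert_allclose(X1.mean(axis=0), [2.5, 7.5], atol=0.8)
        np.testing.assert_allclose(
            np.diag(np.cov(X1.T)), [3.0, 1.0], rtol=0.6
        )

    def test_overlap_d_target_class1_mean(self):
        _, tgt = make_experiment("overlap", "d", 4)
        emp = tgt.features[tgt.labels == 1].mean(axis=0)
        np.testing.assert_allclose(emp, [2.5, 6.0], atol=1.2)

    def test_noise_d_perturbations_bounded(self):
        src, tgt, config = make_experiment("noise", "d", 5, return_config=True)
        clean_t = sample_domain(config, "target")
        diff = tgt.features - clean_t.features
        assert np.max(np.abs(diff)) <= 4.0
        assert np.max(np.abs(diff)) > 3.0  # noise really applied

    def test_sample_size_counts(self):
        for scen, n in (("a", 50), ("d", 500)):
            src, tgt = make_experiment("sample_size", scen, 1)
            assert src.n_samples == 2 * n and tgt.n_samples == 2 * n

    def test_sample_size_ranges_respected(self):
        _, _, config = make_experiment("sample_size", "b", 6, return_config=True)
        ranges = SampleSizeRanges()
        assert ranges.dim[0] <= config.source.dim <= ranges.dim[1]
        for S in config.source.covs:
            w = np.linalg.eigvalsh(S)
            assert np.all(w >= ranges.source_diag[0] - 1e-8)
            assert np.all(w <= ranges.source_diag[1] + 1e-8)
        for S in config.target.covs:
            w = np.linalg.eigvalsh(S)
            assert np.all(w >= ranges.target_diag[0] - 1e-8)

    def test_unknown_tokens_rejected(self):
        with pytest.raises(ValueError):
            make_experiment("bogus", "a", 0)
        with pytest.raises(ValueError):
            make_experiment("overlap", "e", 0)

    def test_target_bayes_error_nondecreasing_a_to_c(self):
        """The printed target parameterizations order the scenarios by
        intrinsic difficulty: the Gaussian Bayes error rises from (a) to (c)."""
        errors = []
        r = np.random.default_rng(123)
        for scen in ("a", "b", "c"):
            params = OVERLAP_TARGETS[scen]
            dists = {
                c: multivariate_normal(mean=mu, cov=S) for c, (mu, S) in params.items()
            }
            err = 0.0
            n = 100_000
            for c in (1, 2):
                draws = dists[c].rvs(size=n, random_state=r)
                other = 2 if c == 1 else 1
                wrong = dists[other].logpdf(draws) > dists[c].logpdf(draws)
                err += 0.5 * np.mean(wrong)
            errors.append(err)
        assert errors[0] <= errors[1] <= errors[2]


class TestSynthFallCohort:
    def test_default_shapes_and_names(self):
        src, tgt = synth_fall_cohort(seed=0)
        assert src.features.shape == (171, 50)
        assert tgt.features.shape == (49, 50)
        assert sum(n.startswith("lin_") for n in src.feature_names) == 28
        assert sum(n.startswith("nl_") for n in src.feature_names) == 22
        # imbalanced binary labels, minority = fallers (label 2)
        for ds in (src, tgt):
            counts = np.bincount(ds.labels)[1:]
            assert counts[1] < counts[0]

    def test_determinism(self):
        a = synth_fall_cohort(seed=9)
        b = synth_fall_cohort(seed=9)
        np.testing.assert_array_equal(a[0].features, b[0].features)
        np.testing.assert_array_equal(a[1].labels, b[1].labels)

    def test_block_correlation_structure(self):
        """Within-block correlations dominate between-block, both in the
        generating matrix and in a large check draw."""
        src, _, params = synth_fall_cohort(
            n_source=2000, n_target=10, seed=3, return_params=True
        )
        R = params["correlation"]
        k = params["n_linear"]
        off = ~np.eye(50, dtype=bool)
        within = np.zeros((50, 50), dtype=bool)
        within[:k, :k] = True
        within[k:, k:] = True
        assert np.mean(np.abs(R[within & off])) > np.mean(np.abs(R[~within]))
        emp = np.corrcoef(src.features[src.labels == 1].T)
        assert np.mean(np.abs(emp[within & off])) > np.mean(np.abs(emp[~within]))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            synth_fall_cohort(minority_fraction=0.7)
        with pytest.raises(ValueError):
            synth_fall_cohort(n_features=20, n_linear=28)
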