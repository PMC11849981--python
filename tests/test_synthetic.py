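"""Generator contracts: planted templates, weights, noise, labels, embedding."""

import numpy as np
import pytest

import chromafactor as cf
from chromafactor.decomposition import flatten_tensor
from chromafactor.synthetic import (_cmdscale, default_template_spec,
                                    embed_to_coordinates,
                                    generate_distance_tensor,
                                    generate_transcription_labels,
                                    make_block_templates, sample_weight_matrix)


class TestBlockTemplates:
    def test_two_block_motif_has_stated_values(self):
        config = cf.SyntheticConfig(b=8, k_true=1, template_spec=(("boundary", 4),))
        W = make_block_templates(config)
        M = W[:, :, 0]
        assert M[0, 1] == 0.1 and M[0, 7] == 0.9 and M[5, 6] == 0.1

    def test_stripe_row_elevated_over_background(self):
        config = cf.SyntheticConfig(b=8, k_true=1, template_spec=(("stripe", 3),))
        M = make_block_templates(config)[:, :, 0]
        off_stripe = np.delete(np.delete(M, 3, axis=0), 3, axis=1)
        assert M[3, 0] > off_stripe.max()

    @pytest.mark.parametrize("b,k_true", [(8, 1), (8, 2), (16, 3), (32, 3)])
    def test_templates_wellformed_and_distinct(self, b, k_true):
        W = make_block_templates(cf.SyntheticConfig(b=b, k_true=k_true))
        assert (W >= 0).all() and W.max() <= 1
        assert np.allclose(W, W.transpose(1, 0, 2))
        assert not W[np.arange(b), np.arange(b), :].any()
        off = ~np.eye(b, dtype=bool)
        for i in range(k_true):
            for j in range(i + 1, k_true):
                r = np.corrcoef(W[:, :, i][off], W[:, :, j][off])[0, 1]
                assert r < 0.8

    def test_identical_motifs_rejected(self):
        config = cf.SyntheticConfig(b=8, k_true=2,
                                    template_spec=(("boundary", 4), ("boundary", 4)))
        with pytest.raises(ValueError, match="redundant"):
            make_block_templates(config)

    def test_motif_out_of_range(self):
        config = cf.SyntheticConfig(b=8, k_true=1, template_spec=(("stripe", 9),))
        with pytest.raises(ValueError, match="outside"):
            make_block_templates(config)

    def test_default_spec_covers_any_k(self):
        spec = default_template_spec(16, 5)
        assert len(spec) == 5
        assert {kind for kind, _ in spec} <= {"boundary", "stripe", "checkerboard"}


class TestWeightMatrix:
    def test_full_support_at_sparsity_one(self):
        H = sample_weight_matrix(cf.SyntheticConfig(b=8, k_true=3, n=100,
                                                    weight_sparsity=1.0, seed=0))
        assert (H > 0).all()

    def test_nonzero_fraction_tracks_sparsity(self):
        # rescue of all-zero columns inflates the fraction by (1-s)^k / k,
        # i.e. expected 1/3 + (2/3)^8/8 = 0.338 at k=8
        config = cf.SyntheticConfig(b=16, k_true=8, n=3000,
                                    weight_sparsity=1 / 3, seed=5)
        H = sample_weight_matrix(config)
        assert (H > 0).mean() == pytest.approx(1 / 3, abs=0.03)
        assert (H > 0).any(axis=0).all()  # no empty cell

    def test_deterministic_given_seed(self):
        config = cf.SyntheticConfig(b=8, k_true=3, n=50, seed=9)
        assert np.array_equal(sample_weight_matrix(config),
                              sample_weight_matrix(config))


class TestDistanceTensor:
    def test_noiseless_mixture_is_exact(self):
        config = cf.SyntheticConfig(b=8, k_true=2, n=10, noise_sd=0.0,
                                    dropout_frac=0.0, seed=3)
        W = make_block_templates(config)
        H = sample_weight_matrix(config)
        ds = generate_distance_tensor(W, H, 0.0, 0.0, seed=3)
        expected = np.einsum("ijk,kn->ijn", W, H)
        assert np.array_equal(ds.tensor.data, expected)

    def test_unit_weight_column_reproduces_template(self):
        config = cf.SyntheticConfig(b=8, k_true=2, n=2)
        W = make_block_templates(config)
        H = np.array([[1.0, 0.0], [0.0, 1.0]])
        ds = generate_distance_tensor(W, H, 0.0, 0.0, seed=0)
        assert np.array_equal(ds.tensor.data[:, :, 1], W[:, :, 1])

    def test_dropout_masks_exact_locus_count(self):
        config = cf.SyntheticConfig(b=10, k_true=2, n=30)
        W = make_block_templates(config)
        H = sample_weight_matrix(config)
        ds = generate_distance_tensor(W, H, 0.0, 0.2, seed=1)
        assert (ds.missing_mask.sum(axis=1) == 2).all()

    def test_negative_noise_rejected(self):
        config = cf.SyntheticConfig(b=8, k_true=1)
        W = make_block_templates(config)
        H = sample_weight_matrix(config)
        with pytest.raises(ValueError):
            generate_distance_tensor(W, H, -0.1, 0.0, seed=0)

    def test_noiseless_flatten_has_planted_rank(self):
        config = cf.SyntheticConfig(b=12, k_true=3, n=60, noise_sd=0.0,
                                    dropout_frac=0.0, seed=8)
        ds = cf.generate_dataset(config)
        V = flatten_tensor(ds.tensor)
        s = np.linalg.svd(V, compute_uv=False)
        assert (s > 1e-8 * s[0]).sum() <= 3


class TestTranscriptionLabels:
    def test_zero_effect_gives_half_prevalence(self):
        config = cf.SyntheticConfig(b=8, k_true=2, n=5000, seed=7)
        H = sample_weight_matrix(config)
        labels = generate_transcription_labels(H, (0,), 0.0, seed=7)
        assert labels.mean() == pytest.approx(0.5, abs=0.02)

    def test_saturation_at_large_effect(self):
        config = cf.SyntheticConfig(b=8, k_true=2, n=2000, seed=2)
        H = sample_weight_matrix(config)
        labels = generate_transcription_labels(H, (0,), 50.0, seed=2)
        z = (H[0] - H[0].mean()) / H[0].std()
        # the intercept centers prevalence at 0.5, so the threshold sits near
        # the score median; nearly every cell follows the indicator
        thresh = np.median(z)
        agree = (labels == (z > thresh)).mean()
        assert agree > 0.97

    def test_deterministic_and_rejects_empty_components(self):
        config = cf.SyntheticConfig(b=8, k_true=2, n=500, seed=4)
        H = sample_weight_matrix(config)
        a = generate_transcription_labels(H, (1,), 1.0, seed=4)
        b = generate_transcription_labels(H, (1,), 1.0, seed=4)
        assert np.array_equal(a, b)
        with pytest.raises(ValueError):
            generate_transcription_labels(H, (), 1.0, seed=4)

    def test_label_coupling_increases_with_effect(self):
        config = cf.SyntheticConfig(b=8, k_true=3, n=2000, seed=9)
        H = sample_weight_matrix(config)
        corrs = []
        for effect in (0.5, 1.0, 2.0):
            labels = generate_transcription_labels(H, (1,), effect, seed=9)
            corrs.append(np.corrcoef(H[1], labels)[0, 1])
        assert corrs[0] > 0
        assert corrs[0] < corrs[1] < corrs[2]


class TestEmbedding:
    def test_euclidean_matrix_recovered_exactly(self):
        rng = np.random.default_rng(0)
        points = rng.normal(0, 100, size=(10, 3))
        D = np.linalg.norm(points[:, None] - points[None, :], axis=2)
        X = _cmdscale(D)
        D2 = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        assert np.allclose(D2, D, rtol=1e-6, atol=1e-6)

    def test_two_points_recover_separation(self):
        D = np.array([[0.0, 3.5], [3.5, 0.0]])
        X = _cmdscale(D)
        assert np.linalg.norm(X[0] - X[1]) == pytest.approx(3.5)

    def test_mixture_matrix_correlation(self):
        config = cf.SyntheticConfig(b=32, k_true=3, n=5, noise_sd=0.02,
                                    dropout_frac=0.0, seed=6)
        ds = cf.generate_dataset(config)
        coords = embed_to_coordinates(ds)
        iu = np.triu_indices(32, 1)
        for c in range(5):
            D2 = np.linalg.norm(coords[c][:, None] - coords[c][None, :], axis=2)
            r = np.corrcoef(D2[iu], ds.tensor.data[:, :, c][iu])[0, 1]
            assert r >= 0.8

    def test_nan_matrix_rejected(self):
        data = np.zeros((4, 4, 1))
        tensor = cf.DistanceTensor(data)
        tensor.data[0, 1, 0] = np.nan  # corrupt after validation
        tensor.data[1, 0, 0] = np.nan
        with pytest.raises(ValueError):
            embed_to_coordinates(tensor)
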