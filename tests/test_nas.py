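import numpy as np
import pytest

from pxafkit.nas import (N_EDGES, NASConfig, NetworkSpec, OPS, Alpha,
                         Genotype, assemble_network, derive_genotype,
                         load_genotype, mixed_op_weights, retrain,
                         save_genotype, search)
from pxafkit.types import InvalidParameterError


def toy_data(n, rng, offset=0.5):
    imgs = rng.random((2 * n, 40, 40))
    imgs[n:] += offset
    labels = np.array([0] * n + [1] * n)
    return imgs, labels


class TestMixedOpWeights:
    def test_uniform_alphas_give_uniform_weights(self):
        w = mixed_op_weights(np.zeros(len(OPS)))
        np.testing.assert_allclose(w, 1.0 / len(OPS))

    def test_dominant_alpha_limit(self):
        a = np.zeros(len(OPS))
        a[2] = 100.0
        w = mixed_op_weights(a)
        assert w[2] == pytest.approx(1.0, abs=1e-20)

    def test_normalization(self, rng):
        for _ in range(20):
            w = mixed_op_weights(rng.standard_normal(len(OPS)))
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(w >= 0.0)

    def test_wrong_length_rejected(self):
        with pytest.raises(InvalidParameterError):
            mixed_op_weights(np.zeros(3))


class TestDeriveGenotype:
    def test_unique_maximum_selected(self, rng):
        mat = 0.01 * rng.standard_normal((N_EDGES, len(OPS)))
        mat[:, 1] += 5.0   # sep_conv_5x5 dominates everywhere
        geno = derive_genotype(Alpha(mat, mat.copy()))
        for node in geno.normal:
            assert all(op == OPS[1] for op, _ in node)

    def test_exactly_eight_edges_per_cell(self, rng):
        mat = rng.standard_normal((N_EDGES, len(OPS)))
        geno = derive_genotype(Alpha(mat, rng.standard_normal(mat.shape)))
        for cell in (geno.normal, geno.reduce):
            assert sum(len(node) for node in cell) == 8
            assert all(len(node) == 2 for node in cell)

    def test_edges_reference_only_predecessors(self, rng):
        mat = rng.standard_normal((N_EDGES, len(OPS)))
        geno = derive_genotype(Alpha(mat, mat.copy()))
        for j, node in enumerate(geno.normal):
            assert all(i < j + 2 for _, i in node)

    def test_ties_break_to_lowest_operator_index(self):
        mat = np.zeros((N_EDGES, len(OPS)))   # all-tied alphas
        geno = derive_genotype(Alpha(mat, mat.copy()))
        for node in geno.normal:
            assert all(op == OPS[0] for op, _ in node)

    def test_nonfinite_alpha_rejected(self):
        mat = np.zeros((N_EDGES, len(OPS)))
        mat[0, 0] = np.nan
        with pytest.raises(InvalidParameterError):
            derive_genotype(Alpha(mat, np.zeros_like(mat)))

    def test_json_round_trip(self, tmp_path, rng):
        geno = derive_genotype(Alpha(rng.standard_normal((N_EDGES, len(OPS))),
                                     rng.standard_normal((N_EDGES, len(OPS)))))
        path = save_genotype(geno, tmp_path / "geno.json")
        back = load_genotype(path)
        assert back.normal == geno.normal and back.reduce == geno.reduce


class TestAssembly:
    def test_full_scale_cell_sequence(self):
        spec = NetworkSpec(n_normal_cells=18, n_reduction_cells=2)
        seq = spec.cell_sequence()
        assert len(seq) == 20
        assert [i for i, red in enumerate(seq) if red] == [6, 13]

    def test_desk_scale_three_cells(self):
        assert len(NetworkSpec(2, 1).cell_sequence()) == 3

    def test_two_reductions_quarter_the_feature_map(self, rng):
        geno = derive_genotype(Alpha(
            0.1 * rng.standard_normal((N_EDGES, len(OPS))),
            0.1 * rng.standard_normal((N_EDGES, len(OPS)))))
        spec = NetworkSpec(n_normal_cells=2, n_reduction_cells=2,
                           init_channels=4)
        model = assemble_network(geno, spec, seed=0)
        import pxafkit.autodiff as ad
        x = ad.Tensor(rng.random((1, 1, 40, 40)))
        s0 = s1 = model.stem(x, False)
        for cell in model.cells:
            s0, s1 = s1, cell(s0, s1, False)
        assert s1.shape[2:] == (10, 10)

    def test_predictions_binary(self, rng):
        geno = derive_genotype(Alpha(
            rng.standard_normal((N_EDGES, len(OPS))),
            rng.standard_normal((N_EDGES, len(OPS)))))
        model = assemble_network(geno, NetworkSpec(1, 1, 4), seed=1)
        pred = model.predict(rng.random((3, 40, 40)))
        assert set(pred) <= {0, 1}


class TestSearch:
    def test_zero_epochs_derives_from_initial_alphas(self, rng):
        imgs, labels = toy_data(6, rng)
        net, hist, geno = search(imgs, labels, imgs, labels,
                                 NetworkSpec(1, 0, 4),
                                 NASConfig(epochs=0, seed=0))
        assert hist == []
        assert sum(len(n) for n in geno.normal) == 8

    def test_one_epoch_alphas_finite_and_updated(self, rng):
        imgs, labels = toy_data(8, rng)
        net, hist, geno = search(imgs[:8], labels[:8], imgs[8:], labels[8:],
                                 NetworkSpec(1, 0, 4),
                                 NASConfig(epochs=1, batch_size=4, seed=0))
        assert len(hist) == 1
        assert np.isfinite(net.alpha.normal).all()
        assert not np.allclose(net.alpha.normal, hist[0].normal) or \
            np.isfinite(hist[0].normal).all()


class TestRetrain:
    def test_zero_epochs_no_history(self, rng):
        geno = derive_genotype(Alpha(
            rng.standard_normal((N_EDGES, len(OPS))),
            rng.standard_normal((N_EDGES, len(OPS)))))
        model = assemble_network(geno, NetworkSpec(1, 0, 4), seed=0)
        hist = retrain(model, rng.random((4, 40, 40)), np.array([0, 1, 0, 1]),
                       NASConfig(epochs=0))
        assert hist == {"loss": [], "accuracy": []}

    def test_learns_separable_toy_data(self, rng):
        imgs, labels = toy_data(10, rng, offset=1.0)
        geno = derive_genotype(Alpha(
            0.1 * rng.standard_normal((N_EDGES, len(OPS))),
            0.1 * rng.standard_normal((N_EDGES, len(OPS)))))
        model = assemble_network(geno, NetworkSpec(1, 0, 4), seed=0)
        hist = retrain(model, imgs, labels,
                       NASConfig(epochs=5, batch_size=10, seed=0,
                                 learning_rate=0.05))
        assert hist["accuracy"][-1] >= 0.9

    def test_same_seed_identical_curves(self, rng):
        imgs, labels = toy_data(6, rng)
        geno = derive_genotype(Alpha(
            0.1 * rng.standard_normal((N_EDGES, len(OPS))),
            0.1 * rng.standard_normal((N_EDGES, len(OPS)))))
        cfg = NASConfig(epochs=2, batch_size=6, seed=3)
        m1 = assemble_network(geno, NetworkSpec(1, 0, 4), seed=5)
        h1 = retrain(m1, imgs, labels, cfg)
        m2 = assemble_network(geno, NetworkSpec(1, 0, 4), seed=5)
        h2 = retrain(m2, imgs, labels, cfg)
        assert h1 == h2
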