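"""Layer-wise equivariance, end-to-end invariance, and training behaviour."""

import numpy as np
import pytest

from holoprot import (
    AA_ALPHABET,
    AAProfile,
    BasisSpec,
    CGNetwork,
    EquivariantTensor,
    NetworkConfig,
    cg_nonlinearity,
    collect_invariants,
    encode,
    linear_layer,
    make_random_neighborhood,
    random_rotation,
    rotate_coefficients,
    spherical_batch_norm,
    train,
)
from holoprot.network import _cross_entropy


def random_tensor(rng, l_max=3, channels=3):
    return EquivariantTensor(
        {l: rng.standard_normal((channels, 2 * l + 1)) for l in range(l_max + 1)}
    )


class TestAAProfile:
    def test_probabilities_sum_to_one(self, rng):
        prof = AAProfile(rng.standard_normal(20))
        assert prof.probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_shift_invariance_of_probabilities(self, rng):
        pe = rng.standard_normal(20)
        np.testing.assert_allclose(AAProfile(pe).probabilities,
                                   AAProfile(pe + 3.7).probabilities, atol=1e-12)

    def test_pseudoenergy_equals_log_probability_up_to_constant(self, rng):
        prof = AAProfile(rng.standard_normal(20))
        diffs = [prof.pseudoenergy(a) - prof.log_probability(a) for a in AA_ALPHABET]
        assert np.ptp(diffs) < 1e-12


class TestLinearLayer:
    def test_identity_and_zero_weights(self, rng):
        t = random_tensor(rng)
        eye = {l: np.eye(t.blocks[l].shape[0]) for l in t.blocks}
        out = linear_layer(t, eye)
        for l in t.blocks:
            np.testing.assert_array_equal(out.blocks[l], t.blocks[l])
        zero = {l: np.zeros_like(eye[l]) for l in eye}
        out = linear_layer(t, zero)
        assert all(np.all(b == 0) for b in out.blocks.values())

    def test_commutes_with_rotation(self, rng):
        t = random_tensor(rng)
        w = {l: rng.standard_normal((4, t.blocks[l].shape[0])) for l in t.blocks}
        for _ in range(20):
            rot = random_rotation(rng)
            a = linear_layer(t.rotated(rot), w)
            b = linear_layer(t, w).rotated(rot)
            for l in a.blocks:
                np.testing.assert_allclose(a.blocks[l], b.blocks[l],
                                           rtol=1e-6, atol=1e-9)

    def test_shape_mismatch_raises(self, rng):
        t = random_tensor(rng)
        with pytest.raises(ValueError):
            linear_layer(t, {l: np.ones((2, 99)) for l in t.blocks})


class TestCGNonlinearity:
    def test_equal_vectors_couple_to_zero_cross_product(self, rng):
        v = rng.standard_normal(3)
        t = EquivariantTensor({1: v[None, :]})
        out = cg_nonlinearity(t, mode="simply", l_max=2)
        # l3=1 output of (v, v) is the cross product: zero
        assert np.abs(out.blocks[1]).max() < 1e-12
        # l3=0 output is the dot product: nonzero for v != 0
        assert np.abs(out.blocks[0]).max() > 1e-8

    def test_commutes_with_rotation(self, rng):
        for mode in ("simply", "fully"):
            t = random_tensor(rng, l_max=2, channels=2)
            for _ in range(20):
                rot = random_rotation(rng)
                a = cg_nonlinearity(t.rotated(rot), mode=mode, l_max=3)
                b = cg_nonlinearity(t, mode=mode, l_max=3).rotated(rot)
                for l in a.blocks:
                    np.testing.assert_allclose(a.blocks[l], b.blocks[l],
                                               rtol=1e-5, atol=1e-8)

    def test_fully_mode_channel_count(self, rng):
        t = EquivariantTensor({0: rng.standard_normal((2, 1)),
                               1: rng.standard_normal((2, 3))})
        out = cg_nonlinearity(t, mode="fully", l_max=2)
        # l3=0: (0,0) pairs 2*2 + (1,1) pairs 2*2 = 8 channels
        assert out.blocks[0].shape[0] == 8


class TestSphericalBatchNorm:
    def test_statistic_invariant_under_rotation(self, rng):
        batch = {l: rng.standard_normal((6, 3, 2 * l + 1)) for l in range(3)}
        stats_a, stats_b = {}, {}
        spherical_batch_norm({l: b.copy() for l, b in batch.items()}, stats_a, True)
        rot = random_rotation(rng)
        from holoprot import real_wigner_d
        rotated = {l: batch[l] @ real_wigner_d(l, rot).T for l in batch}
        spherical_batch_norm(rotated, stats_b, True)
        for l in stats_a:
            np.testing.assert_allclose(stats_a[l], stats_b[l], rtol=1e-6)

    def test_unit_mean_norm_after_training_normalisation(self, rng):
        batch = {l: rng.standard_normal((8, 4, 2 * l + 1)) for l in range(3)}
        out, _ = spherical_batch_norm(batch, {}, True)
        for l in out:
            mean_norm = np.linalg.norm(out[l], axis=2).mean(axis=0)
            np.testing.assert_allclose(mean_norm, 1.0, atol=1e-5)

    def test_equivariance(self, rng):
        from holoprot import real_wigner_d
        batch = {l: rng.standard_normal((5, 3, 2 * l + 1)) for l in range(3)}
        rot = random_rotation(rng)
        out_plain, _ = spherical_batch_norm({l: b.copy() for l, b in batch.items()},
                                            {}, True)
        rotated = {l: batch[l] @ real_wigner_d(l, rot).T for l in batch}
        out_rot, _ = spherical_batch_norm(rotated, {}, True)
        for l in out_plain:
            np.testing.assert_allclose(out_rot[l],
                                       out_plain[l] @ real_wigner_d(l, rot).T,
                                       rtol=1e-6, atol=1e-9)


class TestCollectInvariants:
    def test_length_and_missing_block(self, rng):
        t = EquivariantTensor({0: rng.standard_normal((5, 1))})
        assert collect_invariants([t]).shape == (5,)
        bad = EquivariantTensor({1: rng.standard_normal((2, 3))})
        with pytest.raises(ValueError):
            collect_invariants([bad])

    def test_invariant_under_rotation(self, rng):
        t = random_tensor(rng)
        rot = random_rotation(rng)
        np.testing.assert_allclose(collect_invariants([t]),
                                   collect_invariants([t.rotated(rot)]), atol=1e-12)


@pytest.fixture(scope="module")
def untrained_model():
    basis = BasisSpec(l_max=3, n_max=5)
    cfg = NetworkConfig(n_layers=2, mode="fully", hidden_channels=4, l_max=3,
                        head_widths=(16,), seed=0)
    return CGNetwork(cfg, basis, ("carbon", "oxygen"))


class TestForward:
    def test_probabilities_sum_to_one(self, untrained_model):
        nb = make_random_neighborhood(20, radius=9.0, seed=2,
                                      channels=("carbon", "oxygen"))
        prof = untrained_model.forward(encode(nb, untrained_model.basis))
        assert prof.probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rotation_invariance(self, untrained_model, rng):
        nb = make_random_neighborhood(20, radius=9.0, seed=3,
                                      channels=("carbon", "oxygen"))
        c = encode(nb, untrained_model.basis)
        p0 = untrained_model.forward(c).probabilities
        for _ in range(20):
            rot = random_rotation(rng)
            p1 = untrained_model.forward(rotate_coefficients(c, rot)).probabilities
            np.testing.assert_allclose(p1, p0, atol=1e-5)

    def test_zeroed_head_gives_uniform_probabilities(self, untrained_model):
        import copy
        model = copy.deepcopy(untrained_model)
        for lin in model.head:
            lin["w"] = np.zeros_like(lin["w"])
            lin["b"] = np.zeros_like(lin["b"])
        nb = make_random_neighborhood(15, radius=9.0, seed=4,
                                      channels=("carbon", "oxygen"))
        prof = model.forward(encode(nb, model.basis))
        np.testing.assert_allclose(prof.probabilities, 0.05, atol=1e-12)

    def test_basis_mismatch_raises(self, untrained_model):
        nb = make_random_neighborhood(10, radius=9.0, seed=5,
                                      channels=("carbon", "oxygen"))
        wrong = encode(nb, BasisSpec(l_max=2, n_max=4))
        with pytest.raises(ValueError):
            untrained_model.forward(wrong)

    def test_parameter_count_is_function_of_config(self):
        basis = BasisSpec(l_max=3, n_max=5)
        cfg = NetworkConfig(n_layers=2, mode="fully", hidden_channels=4, l_max=3,
                            head_widths=(16,), seed=0)
        m1 = CGNetwork(cfg, basis, ("carbon", "oxygen"))
        cfg2 = NetworkConfig(n_layers=2, mode="fully", hidden_channels=4, l_max=3,
                             head_widths=(16,), seed=99)
        m2 = CGNetwork(cfg2, basis, ("carbon", "oxygen"))
        assert m1.n_parameters == m2.n_parameters  # seed does not change shapes
        assert m1.n_parameters == 3572  # frozen regression value


class TestBackprop:
    def test_gradients_match_finite_differences(self, untrained_model, rng):
        import copy
        model = copy.deepcopy(untrained_model)
        coeffs = [encode(make_random_neighborhood(10, radius=9.0, seed=s,
                                                  channels=("carbon", "oxygen")),
                         model.basis) for s in range(4)]
        x = model._stack(coeffs)
        y = np.array([0, 5, 11, 19])

        def loss_value():
            cache = {}
            logits = model._forward_batch(x, train=False, cache_out=cache)
            loss, dl = _cross_entropy(logits, y)
            return loss, cache, dl

        loss, cache, dl = loss_value()
        grads = model._backward_batch(cache, dl)
        items = list(model._param_items())
        for it in (items[0], items[4], items[9], items[-1]):
            p = model._get_param(it)
            g = np.ravel(CGNetwork._get_grad(grads, it))
            flat = np.ravel(p)
            for pos in rng.choice(flat.size, size=3, replace=False):
                old = flat[pos]
                eps = 1e-6
                flat[pos] = old + eps
                lp, _, _ = loss_value()
                flat[pos] = old - eps
                lm, _, _ = loss_value()
                flat[pos] = old
                num = (lp - lm) / (2 * eps)
                assert g[pos] == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestTrain:
    def make_data(self, n_per_class=10, seed=0):
        from holoprot import make_class_dataset
        basis = BasisSpec(l_max=3, n_max=5)
        ds = make_class_dataset(3, n_per_class, jitter=0.2, seed=seed)
        return [(encode(nb, basis), lab) for nb, lab in ds]

    def test_loss_decreases(self):
        data = self.make_data()
        cfg = NetworkConfig(n_layers=1, mode="simply", hidden_channels=4, l_max=2,
                            head_widths=(8,), seed=0)
        _, log = train(data, cfg, epochs=8, lr=2e-3, seed=0)
        assert log.loss[-1] < log.loss[0]

    def test_deterministic_given_seed(self):
        data = self.make_data()
        cfg = NetworkConfig(n_layers=1, mode="simply", hidden_channels=4, l_max=2,
                            head_widths=(8,), seed=0)
        _, log1 = train(data, cfg, epochs=3, lr=1e-3, seed=42)
        _, log2 = train(data, cfg, epochs=3, lr=1e-3, seed=42)
        assert log1.loss == log2.loss and log1.accuracy == log2.accuracy

    def test_single_class_rejected(self):
        data = self.make_data()
        one_class = [(c, "A") for c, _ in data[:5]]
        cfg = NetworkConfig(seed=0)
        with pytest.raises(ValueError):
            train(one_class, cfg, epochs=1)

    def test_separable_fixture_reaches_high_accuracy(self, tiny_trained_model):
        model, log = tiny_trained_model
        assert log.accuracy[-1] >= 0.95

    def test_save_load_round_trip(self, tiny_trained_model, tmp_path):
        model, _ = tiny_trained_model
        path = tmp_path / "model.npz"
        model.save(path)
        back = CGNetwork.load(path)
        nb = make_random_neighborhood(20, radius=9.0, seed=9)
        c = encode(nb, model.basis)
        np.testing.assert_allclose(back.forward(c).pseudoenergies,
                                   model.forward(c).pseudoenergies, atol=1e-12)
        assert back.alphabet == model.alphabet
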