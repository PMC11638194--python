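"""Loss arithmetic, stop-gradient contracts and the MI probe."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from causalsepsis.mi import (
    MIHeads,
    VariationalHead,
    contrastive_loss,
    delta_init,
    fit_heads_loss,
    freeze_params,
    gaussian_loglik,
    mi_probe,
)
from causalsepsis.nn import Tensor


def head_outputs_np(head, cond):
    """Independent numpy re-evaluation of a head's (mu, sigma)."""
    h = np.tanh(cond @ head.l1.weight.data + head.l1.bias.data)
    out = h @ head.l2.weight.data + head.l2.bias.data
    m = head.target_dim
    mu = out[:, :m]
    sigma = np.tanh(out[:, m:] / head.sigma_bound) * head.sigma_bound
    return mu, sigma


def loglik_np(x, mu, sigma):
    return np.sum(-((x - mu) ** 2) * np.exp(-sigma) - sigma, axis=-1)


class TestGaussianLoglik:
    def test_exact_fit_unit_variance_is_zero(self):
        assert gaussian_loglik(np.zeros(3), np.zeros(3), np.zeros(3)).item() == 0.0

    def test_unit_error_unit_variance_is_minus_one(self):
        v = gaussian_loglik(np.array([1.0]), np.array([0.0]), np.array([0.0]))
        assert v.item() == -1.0

    def test_random_case_matches_elementwise_evaluation(self, rng):
        x = rng.normal(size=(4, 5))
        mu = rng.normal(size=(4, 5))
        sigma = rng.normal(size=(4, 5))
        expected = loglik_np(x, mu, sigma)
        assert np.allclose(gaussian_loglik(x, mu, sigma).data, expected,
                           atol=1e-12)

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            gaussian_loglik(np.array([np.nan]), np.zeros(1), np.zeros(1))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_never_exceeds_perfect_fit_at_same_variance(self, seed):
        r = np.random.default_rng(seed)
        x, mu, s = r.normal(size=(3, 4)), r.normal(size=(3, 4)), r.normal(size=(3, 4))
        worse = gaussian_loglik(x, mu, s).data
        best = gaussian_loglik(x, x, s).data
        assert np.all(worse <= best + 1e-12)


class TestFitHeads:
    def test_zero_weights_zero_targets_reach_the_minimum(self, rng):
        heads = MIHeads(rng, a_dim=6, c_dim=6, x_dim=6)
        for head in (heads.ax, heads.ay, heads.cx, heads.cy, heads.ac):
            head.l2.weight.data[:] = 0.0
            head.l2.bias.data[:] = 0.0
        z = Tensor(np.zeros((3, 6)))
        bundle = fit_heads_loss(heads, z, z, z, np.zeros(3))
        assert bundle.total.item() == 0.0

    def test_gradients_never_reach_encoder_outputs(self, rng):
        heads = MIHeads(rng, a_dim=6, c_dim=6, x_dim=6)
        src = Tensor(rng.normal(size=(4, 6)), requires_grad=True)
        A = src * 1.0  # graph-connected derived tensor
        bundle = fit_heads_loss(heads, A, A, A, np.ones(4))
        bundle.total.backward()
        assert src.grad is None
        assert all(p.grad is not None for p in heads.parameters())

    def test_three_sample_batch_matches_hand_summed_value(self, rng):
        heads = MIHeads(rng, a_dim=5, c_dim=5, x_dim=5)
        A = rng.normal(size=(3, 5))
        C = rng.normal(size=(3, 5))
        X = rng.normal(size=(3, 5))
        Y = np.array([0.0, 1.0, 1.0]).reshape(3, 1)
        expected = 0.0
        for head, cond, target in [(heads.ax, A, X), (heads.ay, A, Y),
                                   (heads.cx, C, X), (heads.cy, C, Y),
                                   (heads.ac, A, C)]:
            mu, sigma = head_outputs_np(head, cond)
            expected += -np.mean(loglik_np(target, mu, sigma))
        bundle = fit_heads_loss(heads, Tensor(A), Tensor(C), Tensor(X), Y[:, 0])
        assert abs(bundle.total.item() - expected) < 1e-10

    def test_single_sample_batch_rejected(self, rng):
        heads = MIHeads(rng, a_dim=4, c_dim=4, x_dim=4)
        z = Tensor(np.zeros((1, 4)))
        with pytest.raises(ValueError, match="at least 2"):
            fit_heads_loss(heads, z, z, z, np.zeros(1))


def contrastive_components_np(heads, A, C, X, Y):
    """Brute-force pair enumeration of Eq-style double sums."""
    Y = Y.reshape(-1, 1)
    signs = {"ax": -1.0, "ay": +1.0, "cx": -1.0, "cy": -1.0, "ac": +1.0}
    comps = {}
    for name, (head, cond, target) in zip(
            MIHeads.NAMES,
            [(heads.ax, A, X), (heads.ay, A, Y), (heads.cx, C, X),
             (heads.cy, C, Y), (heads.ac, A, C)]):
        mu, sigma = head_outputs_np(head, cond)
        d = len(cond)
        acc = 0.0
        for i in range(d):
            for j in range(d):
                acc += (loglik_np(target[i], mu[i], sigma[i])
                        - loglik_np(target[j], mu[i], sigma[i]))
        comps[name] = signs[name] * acc / d**2
    return comps


class TestContrastive:
    def test_identical_samples_make_every_component_zero(self, rng):
        heads = MIHeads(rng, a_dim=4, c_dim=4, x_dim=4)
        row = rng.normal(size=4)
        A = Tensor(np.tile(row, (3, 1)))
        d1 = Tensor(np.array(delta_init()), requires_grad=True)
        d2 = Tensor(np.array(delta_init()), requires_grad=True)
        bundle = contrastive_loss(heads, A, A, A, np.ones(3), d1, d2)
        for name in MIHeads.NAMES:
            assert abs(bundle.components[f"l_{name}"]) < 1e-10

    def test_two_sample_batch_matches_pair_enumeration(self, rng):
        heads = MIHeads(rng, a_dim=3, c_dim=3, x_dim=3)
        A, C, X = (rng.normal(size=(2, 3)) for _ in range(3))
        Y = np.array([0.0, 1.0])
        expected = contrastive_components_np(heads, A, C, X, Y)
        d1 = Tensor(np.array(delta_init()), requires_grad=True)
        d2 = Tensor(np.array(delta_init()), requires_grad=True)
        bundle = contrastive_loss(heads, Tensor(A), Tensor(C), Tensor(X), Y,
                                  d1, d2)
        for name in MIHeads.NAMES:
            assert abs(bundle.components[f"l_{name}"] - expected[name]) < 1e-10
        cap = 10.0
        soft = {k: cap * np.tanh(v / cap) for k, v in expected.items()}
        total = (soft["ax"] + soft["ay"]
                 + soft["cx"] + soft["cy"] + soft["ac"])
        assert abs(bundle.total.item() - total) < 1e-10  # deltas init to 1

    def test_sample_order_invariance_of_components(self, rng):
        heads = MIHeads(rng, a_dim=3, c_dim=3, x_dim=3)
        A, C, X = (rng.normal(size=(4, 3)) for _ in range(3))
        Y = np.array([0.0, 1.0, 0.0, 1.0])
        d1 = Tensor(np.array(delta_init()), requires_grad=True)
        d2 = Tensor(np.array(delta_init()), requires_grad=True)
        base = contrastive_loss(heads, Tensor(A), Tensor(C), Tensor(X), Y,
                                d1, d2)
        perm = np.array([2, 0, 3, 1])
        swapped = contrastive_loss(heads, Tensor(A[perm]), Tensor(C[perm]),
                                   Tensor(X[perm]), Y[perm], d1, d2)
        for name in MIHeads.NAMES:
            assert abs(base.components[f"l_{name}"]
                       - swapped.components[f"l_{name}"]) < 1e-10

    def test_excluded_component_drops_out_of_total(self, rng):
        heads = MIHeads(rng, a_dim=3, c_dim=3, x_dim=3)
        A, C, X = (rng.normal(size=(3, 3)) for _ in range(3))
        Y = np.array([0.0, 1.0, 1.0])
        d1 = Tensor(np.array(delta_init()), requires_grad=True)
        d2 = Tensor(np.array(delta_init()), requires_grad=True)
        full = contrastive_loss(heads, Tensor(A), Tensor(C), Tensor(X), Y,
                                d1, d2)
        without = contrastive_loss(heads, Tensor(A), Tensor(C), Tensor(X), Y,
                                   d1, d2, exclude=("ay",))
        cap = 10.0
        diff = full.total.item() - without.total.item()
        soft_ay = cap * np.tanh(full.components["l_ay"] / cap)
        assert abs(diff - soft_ay) < 1e-10

    def test_freeze_params_blocks_head_updates_but_not_flow(self, rng):
        heads = MIHeads(rng, a_dim=3, c_dim=3, x_dim=3)
        src = Tensor(rng.normal(size=(3, 3)), requires_grad=True)
        A = src * 1.0
        d1 = Tensor(np.array(delta_init()), requires_grad=True)
        d2 = Tensor(np.array(delta_init()), requires_grad=True)
        bundle = contrastive_loss(heads, A, A, A, np.ones(3), d1, d2)
        with freeze_params(heads):
            bundle.total.backward()
        assert all(p.grad is None for p in heads.parameters())
        assert src.grad is not None and np.isfinite(src.grad).all()
        assert d1.grad is not None and d2.grad is not None


class TestDeltas:
    def test_softplus_of_init_is_one(self):
        assert abs(np.logaddexp(0.0, delta_init()) - 1.0) < 1e-12


class TestProbe:
    def test_independent_inputs_estimate_near_zero(self):
        vals = []
        for seed in range(3):
            r = np.random.default_rng(seed + 40)
            vals.append(mi_probe(r.normal(size=800), r.normal(size=800),
                                 seed=seed))
        assert abs(np.mean(vals)) < 0.05

    def test_identical_inputs_dominate_partial_dependence(self):
        r = np.random.default_rng(7)
        u = r.normal(size=800)
        noisy = 0.6 * u + 0.8 * r.normal(size=800)
        assert mi_probe(u, u.copy(), seed=0) > mi_probe(u, noisy, seed=0) > 0

    def test_gaussian_estimate_tracks_analytic_value(self):
        # rho = 0.9 -> MI = -log(1 - rho^2)/2 = 0.830 nats
        r = np.random.default_rng(11)
        u = r.normal(size=2000)
        v = 0.9 * u + np.sqrt(1 - 0.81) * r.normal(size=2000)
        est = mi_probe(u, v, seed=0)
        assert abs(est - 0.830) < 0.3 * 0.830
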