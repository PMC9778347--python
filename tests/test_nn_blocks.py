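"""Contracts of the inception-residual block (EB) and dense spatial
attention (DSAM): shapes, swish identities, dense-chain channel growth,
parameter accounting and gradient flow."""

import numpy as np
import pytest

from fetalbrain.nn import losses
from fetalbrain.nn.blocks import DenseSpatialAttention, InceptionResidualBlock
from fetalbrain.nn.tensor import Parameter, Tensor, swish, tsum


class TestSwish:
    def test_zero_maps_to_zero(self):
        assert swish(Tensor(np.array([0.0], np.float32))).data[0] == 0.0

    def test_limits(self):
        big = swish(Tensor(np.array([30.0], np.float32))).data[0]
        small = swish(Tensor(np.array([-30.0], np.float32))).data[0]
        assert big == pytest.approx(30.0, abs=1e-4)
        assert small == pytest.approx(0.0, abs=1e-4)

    def test_value_at_one_is_sigmoid_one(self):
        # independent evaluation of sigma(1)
        expected = 1.0 / (1.0 + np.exp(-1.0))
        assert swish(Tensor(np.array([1.0], np.float32))).data[0] == pytest.approx(
            expected, abs=1e-6
        )
        assert expected == pytest.approx(0.73106, abs=1e-5)


class TestInceptionResidualBlock:
    def test_output_shape_and_channels(self, rng):
        eb = InceptionResidualBlock(8, 16, rng=rng)
        x = Tensor(rng.normal(size=(2, 8, 16, 16)).astype(np.float32))
        out = eb(x)
        assert out.shape == (2, 16, 16, 16)

    def test_spatial_dims_preserved_any_size(self, rng):
        eb = InceptionResidualBlock(4, 4, rng=rng)
        for h, w in ((10, 14), (7, 9)):
            out = eb(Tensor(rng.normal(size=(2, 4, h, w)).astype(np.float32)))
            assert out.shape == (2, 4, h, w)

    def test_inference_is_deterministic(self, rng):
        eb = InceptionResidualBlock(3, 8, rng=rng).eval()
        x = Tensor(rng.normal(size=(2, 3, 8, 8)).astype(np.float32))
        np.testing.assert_array_equal(eb(x).data, eb(x).data)

    def test_parameter_count_matches_closed_form(self, rng):
        c_in, c_out = 8, 16
        k1, k2 = 3, 5
        eb = InceptionResidualBlock(c_in, c_out, (k1, k2), rng=rng)
        c_mid = max(c_out // 8, 1)
        conv = lambda ci, co, k: co * ci * k * k + co  # noqa: E731  weight+bias
        bn = lambda c: 2 * c  # noqa: E731  gamma+beta
        expected = (
            conv(c_in, c_mid, 1) + bn(c_mid)                     # branch 1
            + conv(c_in, c_mid, 1) + bn(c_mid)                   # branch 2
            + conv(c_in, c_mid, 1)                               # branch 3 bottleneck
            + 2 * (conv(c_mid, c_mid, k1) + bn(c_mid))
            + conv(c_in, c_mid, 1)                               # branch 4 bottleneck
            + 2 * (conv(c_mid, c_mid, k2) + bn(c_mid))
            + conv(4 * c_mid, c_out, 1) + bn(c_out)              # projection
            + conv(c_in, c_out, 1) + bn(c_out)                   # residual (c_in != c_out)
        )
        assert eb.n_parameters() == expected

    def test_identity_residual_when_channels_match(self, rng):
        eb = InceptionResidualBlock(8, 8, rng=rng)
        assert eb.residual is None

    def test_gradient_reaches_large_kernel_branch(self, rng):
        eb = InceptionResidualBlock(3, 8, rng=rng).train()
        x = Tensor(rng.normal(size=(4, 3, 8, 8)).astype(np.float32))
        loss = tsum(eb(x) * eb(x))
        loss.backward()
        g = eb.b4_conv1.weight.grad
        assert g is not None and np.abs(g).max() > 0


class TestDenseSpatialAttention:
    def test_zero_input_gives_zero_output(self, rng):
        dsam = DenseSpatialAttention(rng=rng).eval()
        out = dsam(Tensor(np.zeros((2, 6, 8, 8), np.float32)))
        np.testing.assert_array_equal(out.data, 0.0)

    @pytest.mark.parametrize("c,h,w", [(3, 8, 8), (6, 12, 10), (1, 16, 16)])
    def test_shape_preserved(self, rng, c, h, w):
        dsam = DenseSpatialAttention(n_dense=4, growth=2, rng=rng).eval()
        out = dsam(Tensor(rng.normal(size=(2, c, h, w)).astype(np.float32)))
        assert out.shape == (2, c, h, w)

    def test_channel_growth_schedule_matches_dense_concatenation(self, rng):
        dsam = DenseSpatialAttention(n_dense=12, growth=4, rng=rng)
        assert dsam.channel_schedule() == [2 + (i + 1) * 4 for i in range(12)]
        # the conv input widths inside the chain follow the same law
        assert [c.c_in for c in dsam.convs] == [2 + i * 4 for i in range(12)]
        assert dsam.proj.c_in == 2 + 12 * 4

    def test_forced_unit_gate_reduces_to_swish_product(self, rng):
        dsam = DenseSpatialAttention(n_dense=3, growth=2, rng=rng).eval()
        x = rng.normal(size=(2, 4, 6, 6)).astype(np.float32)
        out = dsam(Tensor(x), gate_override=np.ones((2, 1, 6, 6), np.float32))
        expected = x * (x / (1.0 + np.exp(-x)))
        np.testing.assert_allclose(out.data, expected, atol=1e-6)

    def test_gate_is_single_channel(self, rng):
        dsam = DenseSpatialAttention(n_dense=2, growth=2, rng=rng).eval()
        g = dsam.gate(Tensor(rng.normal(size=(2, 5, 8, 8)).astype(np.float32)))
        assert g.shape == (2, 1, 8, 8)

    def test_gradient_flows_through_chain(self, rng):
        dsam = DenseSpatialAttention(n_dense=3, growth=2, rng=rng).train()
        x = Tensor(rng.normal(size=(4, 3, 8, 8)).astype(np.float32))
        tsum(dsam(x)).backward()
        assert np.abs(dsam.convs[0].weight.grad).max() > 0


class TestLosses:
    def test_combo_alpha_one_is_weighted_cross_entropy(self, rng):
        p = Tensor(rng.uniform(0.05, 0.95, size=(2, 4, 5, 5)).astype(np.float32))
        t = (rng.uniform(size=(2, 4, 5, 5)) > 0.5).astype(np.float32)
        combo = losses.combo_loss(p, t, alpha=1.0, beta=0.3)
        ce = losses.weighted_bce(p, t, beta=0.3)
        assert float(combo.data) == pytest.approx(float(ce.data), abs=1e-7)

    def test_combo_alpha_zero_is_negative_dice_term(self, rng):
        p = Tensor(rng.uniform(0.05, 0.95, size=(2, 4, 5, 5)).astype(np.float32))
        t = (rng.uniform(size=(2, 4, 5, 5)) > 0.5).astype(np.float32)
        combo = losses.combo_loss(p, t, alpha=0.0)
        dt = losses.dice_term(p, t)
        assert float(combo.data) == pytest.approx(-float(dt.data), abs=1e-7)

    def test_perfect_one_hot_prediction_minimises_combo(self, rng):
        t = np.eye(4, dtype=np.float32)[rng.integers(0, 4, size=(3, 6, 6))]
        t = np.moveaxis(t, -1, 1)
        perfect = float(losses.combo_loss(Tensor(t), t).data)
        for _ in range(20):
            noise = rng.uniform(0, 0.4, size=t.shape).astype(np.float32)
            perturbed = np.clip(t * (1 - noise) + (1 - t) * noise, 1e-5, 1 - 1e-5)
            assert float(losses.combo_loss(Tensor(perturbed), t).data) > perfect

    def test_beta_weights_false_negative_term(self, rng):
        p = Tensor(np.full((1, 2, 3, 3), 0.4, np.float32))
        t = np.ones((1, 2, 3, 3), np.float32)
        # all-positive target: only the beta-weighted positive term is active
        high_beta = float(losses.weighted_bce(p, t, beta=0.9).data)
        low_beta = float(losses.weighted_bce(p, t, beta=0.1).data)
        assert high_beta == pytest.approx(9 * low_beta, rel=1e-5)

    def test_loss_registry_covers_all_variants(self, rng):
        p = Tensor(rng.uniform(0.05, 0.95, size=(2, 3, 4, 4)).astype(np.float32))
        t = (rng.uniform(size=(2, 3, 4, 4)) > 0.5).astype(np.float32)
        vals = {name: float(losses.get_loss(name)(p, t).data)
                for name in ("bce", "dice", "bce_dice", "combo")}
        assert all(np.isfinite(v) for v in vals.values())
        assert vals["bce_dice"] == pytest.approx(vals["bce"] + vals["dice"], abs=1e-6)
        with pytest.raises(ValueError):
            losses.get_loss("focal")
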