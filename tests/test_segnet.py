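import numpy as np
import pytest

from leafseg import nn
from leafseg.segnet import (
    DenseASPP,
    DenseASPPConfig,
    SegModelConfig,
    StripPooling,
    aspp_rf,
    atrous_rf,
    build_model,
    denseaspp_rf,
    load_checkpoint,
    save_checkpoint,
    strip_pool_cols,
    strip_pool_rows,
)


def _support_width_single(k: int, d: int, length: int = 128) -> int:
    """Empirical receptive field of one 1-D atrous conv: positions of the
    input with nonzero gradient from the center output."""
    x = nn.Tensor(np.zeros((1, 1, 1, length), np.float32), requires_grad=True)
    w = nn.Tensor(np.ones((1, 1, 1, k), np.float32), requires_grad=True)
    y = nn.conv2d(x, w, None, dilation=(1, d))
    mask = np.zeros(y.shape, np.float32)
    mask[0, 0, 0, length // 2] = 1.0
    nn.mul(y, nn.Tensor(mask)).backward()
    support = np.flatnonzero(x.grad[0, 0, 0])
    return support[-1] - support[0] + 1


def _support_width_dense_cascade(rates: list[int], k: int = 3, length: int = 64) -> int:
    """Empirical receptive field of a 1-D densely connected cascade: layer l
    convolves the concatenation of the input and all earlier outputs."""
    x = nn.Tensor(np.zeros((1, 1, 1, length), np.float32), requires_grad=True)
    feats = [x]
    for d in rates:
        cin = len(feats)
        inp = feats[0] if cin == 1 else nn.concat(feats, axis=1)
        w = nn.Tensor(np.ones((1, cin, 1, k), np.float32), requires_grad=True)
        feats.append(nn.conv2d(inp, w, None, dilation=(1, d)))
    out = feats[-1]
    mask = np.zeros(out.shape, np.float32)
    mask[0, 0, 0, length // 2] = 1.0
    nn.mul(out, nn.Tensor(mask)).backward()
    support = np.flatnonzero(x.grad[0, 0, 0])
    return support[-1] - support[0] + 1


class TestReceptiveFields:
    def test_ordinary_conv(self):
        assert atrous_rf(3, 1) == 3

    @pytest.mark.parametrize("d,expect", [(6, 13), (24, 49)])
    def test_single_layer_formula_matches_gradient_support(self, d, expect):
        assert atrous_rf(3, d) == expect
        assert _support_width_single(3, d) == expect

    def test_aspp_worked_example(self):
        assert aspp_rf([6, 12, 18, 24], 3) == 49

    def test_aspp_single_rate_and_permutation(self):
        assert aspp_rf([12], 3) == atrous_rf(3, 12)
        assert aspp_rf([24, 6, 18, 12], 3) == aspp_rf([6, 12, 18, 24], 3)

    def test_denseaspp_worked_examples(self):
        assert denseaspp_rf([6, 12, 18, 24], 3) == 121  # 13+25+37+49-3
        assert denseaspp_rf([3, 6, 12, 18], 3) == 79    # 7+13+25+37-3
        assert denseaspp_rf([12], 3) == atrous_rf(3, 12)

    @pytest.mark.parametrize("rates", [[1, 2], [2, 3]])
    def test_dense_cascade_formula_matches_gradient_support(self, rates):
        assert _support_width_dense_cascade(rates) == denseaspp_rf(rates, 3)

    def test_dense_dominates_parallel_for_multi_rate_lists(self, rng):
        for _ in range(20):
            rates = sorted(rng.choice(np.arange(1, 25), size=3, replace=False))
            rates = [int(r) for r in rates]
            assert denseaspp_rf(rates) >= aspp_rf(rates)


class TestStripPoolFunctions:
    def test_two_by_two_example(self):
        x = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        np.testing.assert_allclose(strip_pool_rows(x), [[1.5, 3.5]])
        np.testing.assert_allclose(strip_pool_cols(x), [[2.0, 3.0]])

    def test_constant_map(self):
        x = np.full((2, 5, 7), 3.5)
        np.testing.assert_allclose(strip_pool_rows(x), 3.5)
        np.testing.assert_allclose(strip_pool_cols(x), 3.5)

    def test_matches_elementwise_loop_oracle(self, rng):
        x = rng.normal(size=(3, 17, 9))
        rows = strip_pool_rows(x)
        cols = strip_pool_cols(x)
        for c in range(3):
            for i in range(17):
                assert rows[c, i] == pytest.approx(
                    sum(x[c, i, j] for j in range(9)) / 9, abs=1e-6)
            for j in range(9):
                assert cols[c, j] == pytest.approx(
                    sum(x[c, i, j] for i in range(17)) / 17, abs=1e-6)


class TestStripPoolingModule:
    def test_output_shape_equals_input_shape(self, rng):
        sp = StripPooling(4, rng=rng)
        x = nn.Tensor(rng.normal(size=(2, 4, 13, 7)).astype(np.float32))
        assert sp(x).shape == x.shape

    def test_identity_params_closed_form_on_constant_input(self):
        # with identity expansion/fusion convs and x = k everywhere:
        # row pool = col pool = k, summed gate input = 2k, output = k*sigmoid(2k)
        sp = StripPooling(3)
        sp.set_identity()
        for k in (-1.5, 0.0, 0.7, 2.0):
            x = nn.Tensor(np.full((1, 3, 5, 8), k, np.float32))
            expect = k / (1.0 + np.exp(-2.0 * k))
            np.testing.assert_allclose(sp(x).data, expect, atol=1e-6)

    def test_gate_never_amplifies(self, rng):
        sp = StripPooling(2, rng=rng)
        x = nn.Tensor(rng.normal(size=(1, 2, 6, 6)).astype(np.float32))
        assert np.all(np.abs(sp(x).data) <= np.abs(x.data) + 1e-7)

    def test_zero_input_stays_zero(self, rng):
        sp = StripPooling(2, rng=rng)
        x = nn.Tensor(np.zeros((1, 2, 4, 4), np.float32))
        np.testing.assert_array_equal(sp(x).data, 0.0)


class TestDenseASPPModule:
    def test_channel_bookkeeping(self, rng):
        cfg = DenseASPPConfig(dilation_rates=(3, 6, 12, 18), mid_channels=32)
        mod = DenseASPP(64, cfg, rng=rng)
        x = nn.Tensor(rng.normal(size=(1, 64, 6, 6)).astype(np.float32))
        y = mod(x)
        assert y.shape == (1, 64 + 4 * 32, 6, 6)

    def test_single_rate_degenerates_to_one_atrous_block(self, rng):
        cfg = DenseASPPConfig(dilation_rates=(6,), mid_channels=8)
        mod = DenseASPP(16, cfg, rng=rng)
        y = mod(nn.Tensor(rng.normal(size=(1, 16, 5, 5)).astype(np.float32)))
        assert y.shape == (1, 24, 5, 5)

    @pytest.mark.parametrize("hw", [(1, 1), (3, 8), (7, 5)])
    def test_spatial_size_preserved(self, rng, hw):
        cfg = DenseASPPConfig(dilation_rates=(3, 6), mid_channels=4)
        mod = DenseASPP(8, cfg, rng=rng)
        x = nn.Tensor(rng.normal(size=(1, 8, *hw)).astype(np.float32))
        assert mod(x).shape[2:] == hw

    def test_rates_must_increase(self):
        with pytest.raises(ValueError):
            DenseASPPConfig(dilation_rates=(6, 6, 12))


@pytest.mark.parametrize("head,use_sp", [("aspp", False), ("denseaspp", False),
                                         ("aspp", True), ("denseaspp", True)])
class TestModelAssembly:
    def test_forward_shape_and_gradient_flow(self, rng, head, use_sp):
        cfg = SegModelConfig(
            n_classes=3, head=head, use_sp=use_sp, input_size=64,
            denseaspp=DenseASPPConfig(dilation_rates=(3, 6), mid_channels=8))
        model = build_model(cfg, seed=0)
        x = nn.Tensor(rng.normal(size=(1, 3, 64, 64)).astype(np.float32))
        logits = model(x)
        assert logits.shape == (1, 3, 64, 64)
        target = rng.integers(0, 3, size=(1, 64, 64))
        model.zero_grad()
        nn.cross_entropy(model(x), target).backward()
        for p in model.parameters():
            assert p.grad is not None and np.any(p.grad != 0)


class TestCheckpointRoundTrip:
    def test_save_load_preserves_predictions(self, rng, tmp_path):
        cfg = SegModelConfig(n_classes=3, denseaspp=DenseASPPConfig((3, 6), 8))
        model = build_model(cfg, seed=1)
        model.eval()
        x = nn.Tensor(rng.normal(size=(1, 3, 32, 32)).astype(np.float32))
        before = model(x).data.copy()
        save_checkpoint(model, tmp_path / "m.npz")
        other = load_checkpoint(build_model(cfg, seed=99), tmp_path / "m.npz")
        other.eval()
        np.testing.assert_array_equal(other(x).data, before)

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError, match="unknown backbone"):
            build_model(SegModelConfig(n_classes=2, backbone_name="resnet101"))
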