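"""Architecture contracts: dense growth, gating, shapes, parameter counts."""

import numpy as np
import pytest

from hdaunet.autodiff import Tensor
from hdaunet.core import ShapeError
from hdaunet.models import ArchConfig, build_model, count_parameters
from hdaunet.nn import AttentionGate, Conv3d, DenseConv, DenseDown


class TestDenseConv:
    def test_adds_growth_rate_channels(self, rng):
        blk = DenseConv(16, 16, rng=rng)
        out = blk(Tensor(rng.normal(size=(16, 6, 6, 4))))
        assert out.shape == (32, 6, 6, 4)

    def test_composition_adds_twice(self, rng):
        b1 = DenseConv(8, 4, rng=rng)
        b2 = DenseConv(12, 4, rng=rng)
        out = b2(b1(Tensor(rng.normal(size=(8, 4, 4, 4)))))
        assert out.shape[0] == 16

    def test_zero_input_keeps_new_channels_zero(self, rng):
        blk = DenseConv(3, 5, rng=rng)  # bias initialized to zero
        out = blk(Tensor(np.zeros((3, 4, 4, 4))))
        assert not out.data[3:].any()


class TestDenseDown:
    def test_halves_space_and_grows_channels(self, rng):
        blk = DenseDown(32, 16, rng=rng)
        out = blk(Tensor(rng.normal(size=(32, 32, 32, 16))))
        assert out.shape == (48, 16, 16, 8)

    def test_channel_count_after_k_downsamples(self, rng):
        c = 8
        x = Tensor(rng.normal(size=(8, 16, 16, 16)))
        for k in range(1, 4):
            blk = DenseDown(c, 4, rng=rng)
            x = blk(x)
            c += 4
            assert x.shape[0] == 8 + k * 4

    def test_rejects_singleton_axis(self, rng):
        blk = DenseDown(2, 2, rng=rng)
        with pytest.raises(ShapeError):
            blk(Tensor(rng.normal(size=(2, 4, 4, 1))))


class TestAttentionGate:
    def test_coefficients_always_in_unit_interval(self, rng):
        ag = AttentionGate(4, 3, 8, rng=rng)
        for _ in range(100):
            skip = Tensor(rng.normal(scale=5, size=(4, 5, 5, 3)))
            gate = Tensor(rng.normal(scale=5, size=(3, 3, 3, 2)))
            alpha = ag.coefficients(skip, gate).data
            assert alpha.min() >= 0.0 and alpha.max() <= 1.0

    def test_saturated_gate_passes_skip_through(self, rng):
        ag = AttentionGate(2, 2, 4, rng=rng)
        ag.psi.bias.data[:] = 50.0  # drive sigmoid to ~1
        skip = Tensor(rng.normal(size=(2, 4, 4, 4)))
        out = ag(skip, Tensor(rng.normal(size=(2, 4, 4, 4))))
        np.testing.assert_allclose(out.data, skip.data, rtol=1e-6)

    def test_closed_gate_zeroes_output(self, rng):
        ag = AttentionGate(2, 2, 4, rng=rng)
        ag.psi.bias.data[:] = -60.0
        skip = Tensor(rng.normal(size=(2, 4, 4, 4)))
        out = ag(skip, Tensor(rng.normal(size=(2, 4, 4, 4))))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-20)


TINY = dict(levels=3, growth_rate=4, ag_features=8, base_features=4)


class TestBuildModel:
    @pytest.mark.parametrize("variant", ["hd", "hda", "attention"])
    def test_output_shape_matches_input_grid(self, variant):
        cfg = ArchConfig(variant, in_channels=5, **TINY)
        model = build_model(cfg, seed=0, dtype=np.float32)
        x = Tensor(np.random.default_rng(0).random((5, 16, 16, 12)).astype(np.float32))
        out = model(x)
        assert out.shape == (1, 16, 16, 12)

    def test_odd_extents_survive_roundtrip(self):
        cfg = ArchConfig("hda", in_channels=2, **TINY)
        model = build_model(cfg, seed=0, dtype=np.float32)
        x = Tensor(np.random.default_rng(0).random((2, 20, 14, 10)).astype(np.float32))
        assert model(x).shape == (1, 20, 14, 10)

    def test_forward_is_deterministic_in_eval_mode(self):
        cfg = ArchConfig("hda", in_channels=3, **TINY)
        model = build_model(cfg, seed=1, dtype=np.float64)
        model.eval()
        x = Tensor(np.random.default_rng(2).random((3, 16, 16, 8)))
        np.testing.assert_array_equal(model(x).data, model(x).data)

    def test_output_finite_for_finite_input(self):
        cfg = ArchConfig("hd", in_channels=3, **TINY)
        model = build_model(cfg, seed=1, dtype=np.float64)
        x = Tensor(np.random.default_rng(3).random((3, 16, 16, 8)) * 100)
        assert np.all(np.isfinite(model(x).data))

    def test_same_seed_same_weights(self):
        cfg = ArchConfig("hda", in_channels=3, **TINY)
        m1 = build_model(cfg, seed=7)
        m2 = build_model(cfg, seed=7)
        for (k1, p1), (k2, p2) in zip(m1.named_parameters(), m2.named_parameters()):
            assert k1 == k2
            np.testing.assert_array_equal(p1.data, p2.data)


class TestParameterCounts:
    def test_single_conv_counts(self, rng):
        assert count_parameters(Conv3d(1, 1, 3, rng=rng)) == 28  # 27 weights + bias
        assert count_parameters(Conv3d(64, 1, 1, rng=rng)) == 65

    def test_dense_channel_growth_is_linear(self, rng):
        # channels after n dense ops = start + n * growth
        cfg = ArchConfig("hd", in_channels=7, **TINY)
        model = build_model(cfg, seed=0)
        c = 7
        for seq in model.enc_blocks:
            for blk in seq.blocks:
                c += cfg.growth_rate
                assert blk.out_channels == c
            c += cfg.growth_rate  # dense downsampling

    def test_hda_minus_hd_equals_gates_plus_batchnorm(self):
        """The hda/hd parameter difference is exactly the closed-form count of
        the attention gates plus the batch-norm affine terms."""
        cfg_kwargs = dict(in_channels=6, levels=4, growth_rate=8, ag_features=16)
        hd = count_parameters(build_model(ArchConfig("hd", **cfg_kwargs), seed=0))
        hda = count_parameters(build_model(ArchConfig("hda", **cfg_kwargs), seed=0))

        g, f, lv = 8, 16, 4
        skip_channels = []
        c = 6
        for _ in range(lv - 1):
            c += 2 * g
            skip_channels.append(c)
            c += g
        gates = sum(
            (cs * f + f) + (f * f + f) + (f + 1)  # skip proj + gate proj + psi
            for cs in skip_channels
        )
        n_dense = 2 * (lv - 1) + 4 + 2 * (lv - 1)  # encoder + bottom + decoder
        n_down = lv - 1
        bn = 2 * g * (n_dense + n_down) + 2 * f * (lv - 1)  # dense ops + up-convs
        assert hda - hd == gates + bn
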