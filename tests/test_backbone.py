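"""Signal backbone: convolution oracle, shapes, SE gating, causality."""

import numpy as np
import pytest

from fhrfusion.backbone import BackboneConfig, MDSC, SETCNBackbone, receptive_field
from fhrfusion.nn import CausalConv1d, SEBlock, Tensor, causal_dilated_conv

from conftest import SMALL_CHANNELS


def brute_force_causal_conv(x, w, d, stride):
    """Direct evaluation of Y(t) = sum_i w(i) X(t - d i), then subsampling."""
    n, k = len(x), len(w)
    full = np.zeros(n)
    for t in range(n):
        for i in range(k):
            j = t - d * i
            if j >= 0:
                full[t] += w[i] * x[j]
    return full[::stride]


class TestCausalDilatedConv:
    def test_running_sum_example(self):
        np.testing.assert_allclose(
            causal_dilated_conv([1, 2, 3, 4], [1, 1, 1]), [1, 3, 6, 9]
        )

    @pytest.mark.parametrize("d", [1, 2, 5])
    def test_identity_kernel(self, d):
        x = np.arange(10.0)
        np.testing.assert_allclose(causal_dilated_conv(x, [1.0], dilation=d), x)

    @pytest.mark.parametrize("d,stride,k", [(1, 1, 3), (2, 1, 5), (3, 2, 4), (2, 3, 5)])
    def test_matches_brute_force(self, rng, d, stride, k):
        x = rng.normal(size=37)
        w = rng.normal(size=k)
        np.testing.assert_allclose(
            causal_dilated_conv(x, w, dilation=d, stride=stride),
            brute_force_causal_conv(x, w, d, stride),
            atol=1e-12,
        )

    def test_layer_matches_brute_force_multichannel(self, rng):
        # the layer's (k*Cin, Cout) matmul against a per-channel double loop
        n, cin, cout, k, d, stride = 20, 3, 2, 4, 2, 2
        layer = CausalConv1d(cin, cout, k, rng, dilation=d, stride=stride, bias=False)
        x = rng.normal(size=(1, n, cin)).astype(np.float64)
        out = layer(Tensor(x)).data[0]
        w = layer.weight.data.reshape(k, cin, cout)  # oldest tap first
        expect = np.zeros_like(out)
        for c_out in range(cout):
            for c_in in range(cin):
                taps = w[::-1, c_in, c_out]  # w[0] newest for the oracle
                expect[:, c_out] += brute_force_causal_conv(
                    x[0, :, c_in], taps, d, stride
                )
        np.testing.assert_allclose(out, expect, atol=1e-5)

    def test_causality_perturbation(self, rng):
        x = rng.normal(size=50)
        w = rng.normal(size=5)
        base = causal_dilated_conv(x, w, dilation=2)
        x2 = x.copy()
        x2[30] += 10.0
        pert = causal_dilated_conv(x2, w, dilation=2)
        assert np.all(base[:30] == pert[:30])
        assert np.any(base[30:] != pert[30:])


class TestReceptiveField:
    def test_degenerate_kernel(self):
        assert receptive_field(BackboneConfig(kernel_size=1)) == 1

    def test_single_layer(self):
        cfg = BackboneConfig(
            kernel_size=3, dilations=(1,), strides=(1,), channels=(4,)
        )
        assert receptive_field(cfg) == 5

    def test_default_value(self):
        assert receptive_field(BackboneConfig()) == 1 + 2 * 14 * 62 == 1737


class TestMDSC:
    def test_output_channels_and_length(self, rng):
        cfg = BackboneConfig()
        mdsc = MDSC(cfg, rng)
        x = Tensor(rng.normal(size=(2, 100, 1)).astype(np.float32))
        out = mdsc(x)
        assert out.shape == (2, 100, 64)

    def test_zero_weights_zero_output(self, rng):
        cfg = BackboneConfig()
        mdsc = MDSC(cfg, rng)
        for p in mdsc.parameters():
            p.data[...] = 0.0
        x = Tensor(rng.normal(size=(1, 50, 1)).astype(np.float32))
        np.testing.assert_array_equal(mdsc(x, activate=False).data, 0.0)

    def test_wrong_channel_count_errors(self, rng):
        mdsc = MDSC(BackboneConfig(), rng)
        with pytest.raises(ValueError):
            mdsc(Tensor(np.zeros((1, 50, 2), dtype=np.float32)))


class TestSEBlock:
    def test_forced_half_gates_halve_channels(self, rng):
        se = SEBlock(8, rng)
        # zero excitation weights -> sigmoid(0) = 0.5 gates
        for p in se.parameters():
            p.data[...] = 0.0
        x = rng.normal(size=(2, 10, 8)).astype(np.float32)
        np.testing.assert_allclose(se(Tensor(x)).data, 0.5 * x, rtol=1e-6)

    def test_gates_strictly_inside_unit_interval(self, rng):
        se = SEBlock(8, rng)
        g = se.gates(Tensor(rng.normal(size=(3, 20, 8)).astype(np.float32))).data
        assert np.all(g > 0) and np.all(g < 1)

    def test_time_permutation_invariant_gates(self, rng):
        se = SEBlock(8, rng)
        x = rng.normal(size=(1, 30, 8)).astype(np.float32)
        perm = rng.permutation(30)
        g1 = se.gates(Tensor(x)).data
        g2 = se.gates(Tensor(x[:, perm, :])).data
        np.testing.assert_allclose(g1, g2, rtol=1e-5)


class TestBackbone:
    def test_table_shape_ladder_default_config(self, default_latent):
        cfg, bb, z, shapes = default_latent
        assert shapes == [
            (2, 7200, 64),
            (2, 2400, 64),
            (2, 2400, 64),
            (2, 800, 128),
            (2, 800, 128),
            (2, 400, 256),
        ]
        assert z.shape == (2, 400, 256)

    def test_shape_ladder_any_batch_small_config(self, small_backbone_cfg, rng):
        bb = SETCNBackbone(small_backbone_cfg).eval()
        x = rng.normal(size=(3, 7200, 1)).astype(np.float32)
        _, shapes = bb(x, return_intermediate=True)
        lengths = [s[1] for s in shapes]
        assert lengths == [7200, 2400, 2400, 800, 800, 400]
        assert [s[2] for s in shapes] == [8, *SMALL_CHANNELS]

    def test_eval_forward_deterministic(self, small_backbone_cfg, rng):
        bb = SETCNBackbone(small_backbone_cfg).eval()
        x = rng.normal(size=(1, 7200, 1)).astype(np.float32)
        np.testing.assert_array_equal(bb(x).data, bb(x).data)

    def test_same_seed_same_weights(self, small_backbone_cfg):
        a = SETCNBackbone(small_backbone_cfg)
        b = SETCNBackbone(small_backbone_cfg)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_residual_path_isolation(self, rng):
        # zeroing the main path leaves output = ReLU(SE(1x1 conv(x)))
        from fhrfusion.backbone import SETCNBlock

        blk = SETCNBlock(4, 6, 15, 2, 3, rng)
        for layer in (blk.conv1, blk.conv2):
            layer.weight.data[...] = 0.0
            layer.bias.data[...] = 0.0
        blk.eval()
        x = Tensor(rng.normal(size=(2, 30, 4)).astype(np.float32))
        out = blk(x).data
        short = blk.se(blk.shortcut(x)).data
        np.testing.assert_allclose(out, np.maximum(short, 0.0), atol=1e-6)

    def test_wrong_input_length_errors(self, small_backbone_cfg):
        bb = SETCNBackbone(small_backbone_cfg)
        with pytest.raises(ValueError):
            bb(np.zeros((1, 100, 1), dtype=np.float32))

    def test_parameter_count_logged(self, default_latent, capsys):
        # the full-width backbone's size is reported for comparison only
        cfg, bb, _, _ = default_latent
        n = bb.n_parameters()
        print(f"default backbone parameters: {n/1e6:.2f} M")
        assert n > 0


def probe_causality(bb, cfg, positions, rng):
    """Perturb inputs one position at a time and compare against baseline.

    Returns (position, first changed output index) pairs.  Probes run in a
    single batched forward pass (row 0 = unperturbed reference).
    """
    x = rng.normal(size=(1, cfg.input_length, 1)).astype(np.float32)
    batch = np.repeat(x, len(positions) + 1, axis=0)
    for row, pos in enumerate(positions, start=1):
        batch[row, pos, 0] += 100.0
    out = bb(batch).data
    results = []
    for row, pos in enumerate(positions, start=1):
        changed = np.flatnonzero(np.any(out[row] != out[0], axis=-1))
        results.append((pos, int(changed[0]) if changed.size else None))
    return results


class TestCausality:
    def test_no_future_leakage_50_probes(self, rng):
        # strict causality requires the global SE gate disabled; the conv
        # stack itself never reads ahead of the stride-mapped position
        cfg = BackboneConfig(
            channels=SMALL_CHANNELS, mdsc_channels=2, se_enabled=False, seed=0
        )
        bb = SETCNBackbone(cfg).eval()
        total_stride = int(np.prod(cfg.strides))
        positions = rng.integers(0, cfg.input_length, size=50)
        for pos, first_changed in probe_causality(bb, cfg, list(positions), rng):
            if first_changed is None:
                continue  # perturbation died in the strided pipeline
            # output t may depend on inputs up to (t+1)*stride - 1 only
            assert (first_changed + 1) * total_stride - 1 >= pos

    def test_se_gate_is_global(self, rng):
        # with SE enabled the channel gate pools over all time, so an early
        # perturbation touches every output position: documented behaviour
        cfg = BackboneConfig(
            channels=SMALL_CHANNELS, mdsc_channels=2, se_enabled=True, seed=0
        )
        bb = SETCNBackbone(cfg).eval()
        (result,) = probe_causality(bb, cfg, [7000], rng)
        assert result[1] is not None and result[1] == 0
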