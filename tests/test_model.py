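"""Architecture ledger and the assembled network."""

import numpy as np
import pytest

from dmfnet.model import DMFNet, canonical_ledger, count_parameters


@pytest.fixture(scope="module")
def ledger():
    return canonical_ledger()


@pytest.fixture(scope="module")
def net():
    return DMFNet(seed=0)


def force_identity_passthrough(net):
    """Zero the noise branch and make the refinement blocks pass through.

    Tap and NFB weights/biases are zeroed so the estimated noise map is
    exactly zero (BN with identity running stats maps 0 to 0); each PFRB
    block is set to a centre-tap channel relay with unit BN scale, so for a
    non-negative input the network output equals its input.
    """
    for blk in net.taps + net.nfb:
        blk.conv.w[...] = 0.0
        if blk.conv.b is not None:
            blk.conv.b[...] = 0.0
    for blk in net.pfrb:
        w = blk.conv.w
        w[...] = 0.0
        for f in range(w.shape[0]):  # centre-tap relay (fan-out/fan-in via ch 0)
            w[f, f % w.shape[1], 1, 1] = 1.0
        if blk.bn is not None:
            blk.bn.running_mean[...] = 0.0
            blk.bn.running_var[...] = 1.0 - blk.bn.eps
            blk.bn.gamma[...] = 1.0
            blk.bn.beta[...] = 0.0


class TestLedger:
    def test_total_conv_layer_count(self, ledger):
        assert ledger.n_layers == 26

    def test_three_dilated_layers(self, ledger):
        assert ledger.n_dilated == 3
        assert [l.index for l in ledger.layers if l.dilation > 1] == [2, 5, 12]

    def test_eighteen_conv_bn_relu_layers(self, ledger):
        assert ledger.n_conv_bn_relu == 18

    def test_taps_read_backbone_14_15_16(self, ledger):
        assert ledger.tap_sources == (14, 15, 16)
        taps = [l for l in ledger.layers if l.block == "CFB"]
        assert [l.reads_from for l in taps] == [14, 15, 16]
        assert all(l.filters == 1 and l.activation == "none" for l in taps)

    def test_all_kernels_3x3_stride_1_padding_matches_dilation(self, ledger):
        for l in ledger.layers:
            assert l.kernel == (3, 3)
            assert l.stride == 1
            assert l.padding == l.dilation

    def test_block_structure_partitions_the_ledger(self, ledger):
        indices = [i for block in ledger.structure.values() for i in block]
        assert sorted(indices) == list(range(1, 27))

    def test_table_export_has_26_rows(self, ledger):
        rows = [ln for ln in ledger.as_table().splitlines() if ln.split() and ln.split()[0].isdigit()]
        assert len(rows) == 26


class TestParameterCount:
    def test_single_conv_closed_form(self):
        # one 64-filter 3x3x1 conv with bias: 3*3*1*64 + 64
        led = canonical_ledger()
        l1 = led[1]
        assert l1.kind == "conv" and l1.in_channels == 1 and l1.filters == 64
        assert l1.filters * l1.in_channels * 9 + l1.filters == 640

    def test_count_matches_built_network(self, ledger, net):
        assert count_parameters(ledger) == net.n_parameters()

    def test_deterministic(self, ledger):
        assert count_parameters(ledger) == count_parameters(canonical_ledger())

    def test_removing_one_conv_bn_layer_delta(self, ledger):
        # 64->64 conv (no bias under BN) + BN scale/shift: 64*64*9 + 2*64
        import dataclasses
        trimmed = dataclasses.replace(ledger, layers=[l for l in ledger.layers if l.index != 7])
        delta = count_parameters(ledger) - count_parameters(trimmed)
        assert delta == 64 * 64 * 9 + 2 * 64 == 36_992


class TestForward:
    def test_128_input_gives_128_output(self, net):
        x = np.random.default_rng(0).random((128, 128), dtype=np.float32)
        noise_map, denoised = net.forward(x)
        assert noise_map.shape == (128, 128)
        assert denoised.shape == (128, 128)

    @pytest.mark.parametrize("size", [64, 96])
    def test_fully_convolutional_sizes(self, net, size):
        x = np.random.default_rng(1).random((size, size), dtype=np.float32)
        noise_map, denoised = net.forward(x)
        assert noise_map.shape == (size, size) and denoised.shape == (size, size)

    def test_multichannel_rejected(self, net):
        with pytest.raises(ValueError, match="channel"):
            net.forward(np.zeros((1, 3, 32, 32), dtype=np.float32))

    def test_tiny_input_rejected(self, net):
        with pytest.raises(ValueError, match="small"):
            net.forward(np.zeros((8, 8), dtype=np.float32))

    def test_residual_identity_when_noise_branch_zeroed(self):
        surrogate = DMFNet(seed=3)
        force_identity_passthrough(surrogate)
        x = np.random.default_rng(2).random((32, 32), dtype=np.float32) * 0.8 + 0.1
        noise_map, denoised = surrogate.forward(x)
        np.testing.assert_allclose(noise_map, 0.0, atol=1e-7)
        np.testing.assert_allclose(denoised, x, rtol=1e-4, atol=1e-5)

    def test_inference_deterministic(self, net):
        x = np.random.default_rng(3).random((48, 48), dtype=np.float32)
        _, a = net.forward(x)
        _, b = net.forward(x)
        np.testing.assert_array_equal(a, b)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        # end-to-end check of the hand-written backward pass (float64)
        net = DMFNet(seed=1, dtype=np.float64)
        rng = np.random.default_rng(2)
        x = rng.random((2, 1, 16, 16))
        t = rng.random((2, 1, 16, 16))
        net.zero_grad()
        _, p = net.forward(x, train=True)
        net.backward(2.0 * (p - t) / p.size)
        grads = {k: v.copy() for k, v in net.gradients()}

        def objective():
            _, q = net.forward(x, train=True)
            return float(np.mean((q - t) ** 2))

        eps = 1e-6
        rng2 = np.random.default_rng(7)
        checked = 0
        for name, arr in net.parameters():
            if rng2.random() < 0.15:
                idx = tuple(rng2.integers(s) for s in arr.shape)
                orig = arr[idx]
                arr[idx] = orig + eps
                fp = objective()
                arr[idx] = orig - eps
                fm = objective()
                arr[idx] = orig
                num = (fp - fm) / (2 * eps)
                ana = grads[name][idx]
                assert abs(num - ana) <= 1e-5 * max(1.0, abs(num)), name
                checked += 1
        assert checked >= 5


class TestCheckpoint:
    def test_roundtrip_bitwise_identical_outputs(self, tmp_path):
        net = DMFNet(seed=4)
        x = np.random.default_rng(5).random((32, 32), dtype=np.float32)
        _, before = net.forward(x)
        path = tmp_path / "epoch_1.ckpt"
        net.save(path, extra={"epoch": 1})
        loaded = DMFNet.load(path)
        _, after = loaded.forward(x)
        np.testing.assert_array_equal(before, after)
        assert DMFNet.checkpoint_meta(path)["epoch"] == 1

    def test_non_checkpoint_rejected(self, tmp_path):
        path = tmp_path / "bogus.ckpt"
        with open(path, "wb") as fh:
            np.savez(fh, a=np.zeros(3), __meta__=np.frombuffer(b'{"magic": "x"}', dtype=np.uint8))
        with pytest.raises(ValueError, match="checkpoint"):
            DMFNet.load(path)
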