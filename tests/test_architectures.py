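"""Structural conformance of the U-Net family and the freezing ensemble.

Networks are built width-reduced (the block structure is unaffected by
channel width) and probed at 64 or 96 px — the architectures are fully
convolutional, so any input divisible by the encoder reduction works.
"""

import numpy as np
import pytest

from wsiseg import nn
from wsiseg.architectures import (BACKBONES, DEFAULT_STRATEGIES,
                                  FREEZE_ALL_ENCODER, FREEZE_EARLY_STAGES,
                                  FREEZE_NONE, BasicBlock, FreezingStrategy,
                                  apply_freezing, build_ensemble,
                                  build_network, load_checkpoint,
                                  save_checkpoint, summarize)

W = 0.125  # width multiplier used throughout; structure is width-invariant


def forward(net, size=64, batch=1, seed=0):
    x = np.random.default_rng(seed).random((batch, 3, size, size),
                                           dtype=np.float32)
    return net(nn.Tensor(x))


@pytest.fixture(scope="module", params=BACKBONES)
def any_net(request):
    return build_network(request.param, input_size=64, width=W, seed=0)


class TestBuildNetwork:
    def test_output_matches_input_size_and_classes(self, any_net):
        out = forward(any_net)
        assert out.data.shape == (1, 3, 64, 64)

    def test_shape_equivariance_on_other_sizes(self, any_net):
        out = forward(any_net, size=96)
        assert out.data.shape[2:] == (96, 96)

    def test_five_encoder_levels_halving(self, any_net):
        feats = any_net.encoder(nn.Tensor(
            np.zeros((1, 3, 64, 64), np.float32)))
        sizes = [f.data.shape[2] for f in feats]
        assert len(sizes) == 5
        assert all(a == 2 * b for a, b in zip(sizes, sizes[1:]))

    def test_unknown_backbone_lists_valid_names(self):
        with pytest.raises(ValueError) as exc:
            build_network("vgg16")
        for name in BACKBONES:
            assert name in str(exc.value)

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            build_network("efficientnetb2", input_size=100, width=W)

    def test_seeded_determinism(self):
        a = build_network("efficientnetb2", width=W, seed=4)
        b = build_network("efficientnetb2", width=W, seed=4)
        for (na, pa), (nb, pb) in zip(a.named_parameters(),
                                      b.named_parameters()):
            assert na == nb and np.array_equal(pa.data, pb.data)
        assert np.array_equal(forward(a).data, forward(b).data)
        c = build_network("efficientnetb2", width=W, seed=5)
        assert not np.array_equal(forward(a).data, forward(c).data)


@pytest.fixture(scope="module")
def net():
    return build_network("efficientnetb2", width=W, seed=0)


class TestEfficientNetB2Structure:
    def test_mbconv_census_is_22(self, net):
        assert summarize(net, 64).mbconv_block_count == 22

    def test_stage_table_resolutions(self, net):
        table = net.encoder.stage_table(256)
        assert [res for _, res, _ in table] == [128, 128, 64, 32, 16, 16,
                                                8, 8, 8]
        ops = [op for op, _, _ in table]
        assert ops[0] == "Conv3x3_s2" and ops[-1] == "Conv1x1"
        assert ops[1] == "MBConv1_3x3"

    def test_stage_table_agrees_with_module_census(self, net):
        """Repeat counts in the table must equal the number of MBConv
        modules actually built (traversal cross-check)."""
        table_total = sum(rep for op, _, rep in net.encoder.stage_table()
                          if op.startswith("MBConv"))
        assert table_total == summarize(net, 64).mbconv_block_count

    def test_resolutions_non_increasing(self, net):
        res = [r for _, r, _ in net.encoder.stage_table(256)]
        assert all(a >= b for a, b in zip(res, res[1:]))

    def test_first_stage_128_deepest_8_for_256_input(self, net):
        feats = net.encoder(nn.Tensor(np.zeros((1, 3, 256, 256),
                                               np.float32)))
        assert feats[0].data.shape[2] == 128
        assert feats[-1].data.shape[2] == 8

    def test_table_1_literal_depths_are_buildable(self):
        """The published per-stage repeat column (2,3,3,4,4,5,2) is the
        standard B2 depth schedule; it remains constructible."""
        net = build_network("efficientnetb2", width=W, seed=0,
                            repeats=(1, 2, 3, 3, 4, 4, 5, 2, 1))
        assert summarize(net, 64).mbconv_block_count == 23


class TestResNet34Structure:
    def test_conv_census_matches_structural_walk(self):
        net = build_network("resnet34", width=W, seed=0)
        # independent oracle: walk the block layout (stem + 2 per block)
        n_blocks = sum(1 for m in net.encoder.modules()
                       if isinstance(m, BasicBlock))
        assert n_blocks == 3 + 4 + 6 + 3
        expected = 1 + 2 * n_blocks
        assert summarize(net, 64).encoder_conv_layer_count == expected == 33


class TestSummaries:
    def test_four_decoder_blocks_everywhere(self, any_net):
        assert summarize(any_net, 64).upsampling_block_count == 4

    def test_plain_unet_conv_count_manual_enumeration(self):
        net = build_network("unet_plain", width=W, seed=0)
        # 5 encoder DoubleConvs (2 each) + 4 decoder blocks (2 each) + head
        assert summarize(net, 64).conv_layer_count == 10 + 8 + 1

    def test_trainable_bounded_by_total(self, any_net):
        s = summarize(any_net, 64)
        assert 0 < s.trainable_parameter_count <= s.total_parameter_count


class TestFreezing:
    def test_freeze_all_encoder(self):
        net = build_network("efficientnetb2", width=W, seed=0)
        total = summarize(net, 64).total_parameter_count
        enc_params = sum(p.data.size for p in net.encoder.parameters())
        apply_freezing(net, FREEZE_ALL_ENCODER)
        s = summarize(net, 64)
        assert sum(p.data.size for p in net.encoder.parameters()
                   if p.trainable) == 0
        assert s.trainable_parameter_count == total - enc_params

    def test_freeze_none_keeps_everything_trainable(self):
        net = build_network("efficientnetb2", width=W, seed=0)
        apply_freezing(net, FREEZE_NONE)
        s = summarize(net, 64)
        assert s.trainable_parameter_count == s.total_parameter_count

    def test_freeze_early_stages_enumeration(self):
        """Trainable set == parameters of stages 4-5 + decoder + head."""
        net = build_network("efficientnetb2", width=W, seed=0)
        apply_freezing(net, FREEZE_EARLY_STAGES)
        frozen = {id(p) for i in (1, 2, 3)
                  for p in net.encoder.stages[i - 1].parameters()}
        expected_trainable = {id(p) for p in net.parameters()} - frozen
        actual_trainable = {id(p) for p in net.parameters() if p.trainable}
        assert actual_trainable == expected_trainable

    def test_missing_stage_rejected(self):
        net = build_network("unet_plain", width=W, seed=0)
        with pytest.raises(ValueError, match="missing"):
            apply_freezing(net, FreezingStrategy("bad", frozenset({9})))

    def test_named_strategies_pairwise_distinct(self):
        sets = [s.frozen_stage_indices for s in DEFAULT_STRATEGIES]
        assert len(set(sets)) == 3


@pytest.fixture(scope="module")
def ens():
    return build_ensemble(seed=0, width=W)


class TestEnsemble:
    def test_fusion_consumes_nine_channels(self, ens):
        assert ens.fusion.in_ch == 3 * 3

    def test_probabilities_sum_to_one(self, ens):
        x = np.random.default_rng(1).random((2, 64, 64, 3),
                                            dtype=np.float32)
        p = ens.predict_proba(x)
        assert p.shape == (2, 64, 64, 3)
        np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-6)

    def test_heads_do_not_share_parameters(self, ens):
        ids = [{id(p) for p in h.parameters()} for h in ens.heads]
        assert not (ids[0] & ids[1] or ids[0] & ids[2] or ids[1] & ids[2])

    def test_heads_carry_their_strategies(self, ens):
        assert [h.freezing.name for h in ens.heads] == [
            s.name for s in DEFAULT_STRATEGIES]

    def test_duplicate_strategies_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            build_ensemble(strategies=(FREEZE_NONE, FREEZE_NONE,
                                       FREEZE_ALL_ENCODER), width=W)

    def test_frozen_stages_unchanged_by_training_step(self, ens):
        frozen_before = {
            name: p.data.copy() for name, p in ens.named_parameters()
            if not p.trainable}
        opt = nn.Adam([p for p in ens.parameters() if p.trainable], lr=0.01)
        x = np.random.default_rng(2).random((2, 3, 64, 64),
                                            dtype=np.float32)
        labels = np.random.default_rng(3).integers(0, 3, (2, 64, 64))
        loss = nn.softmax_cross_entropy(ens(nn.Tensor(x)), labels)
        loss.backward()
        opt.step()
        after = dict(ens.named_parameters())
        assert frozen_before  # the default ensemble does freeze something
        for name, data in frozen_before.items():
            assert data.tobytes() == after[name].data.tobytes()


def test_checkpoint_round_trip(tmp_path):
    net = build_network("resnet34", width=W, seed=2)
    out = forward(net)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(net, path)
    restored = load_checkpoint(path)
    assert np.array_equal(forward(restored).data, out.data)


def test_ensemble_checkpoint_round_trip(tmp_path):
    ens = build_ensemble(seed=3, width=W)
    x = np.random.default_rng(0).random((1, 64, 64, 3), dtype=np.float32)
    p = ens.predict_proba(x)
    path = tmp_path / "ens.npz"
    save_checkpoint(ens, path)
    restored = load_checkpoint(path)
    assert [s.name for s in restored.strategies] == [
        s.name for s in ens.strategies]
    np.testing.assert_allclose(restored.predict_proba(x), p, atol=1e-7)
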