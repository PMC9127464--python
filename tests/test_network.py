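"""U-Net architecture, parameter counts, training loop, prediction, stitching."""

import numpy as np
import pytest

from upaint import (ContractError, SimulationConfig, TrainConfig, UNet, UNetSpec,
                    build_network, count_parameters, generate_dataset, load_checkpoint,
                    predict, save_checkpoint, stitch_tiles, tile_image, train)


def double_conv_params(cin, cout):
    """Closed-form parameter count of a double 3x3 convolution block."""
    return (9 * cin * cout + cout) + (9 * cout * cout + cout)


def unet_params_closed_form(in_channels, depth, base):
    """Layer-by-layer analytic sum for the encoder-decoder with 2x2
    transposed-convolution upsampling and a 1x1 output convolution."""
    total = double_conv_params(in_channels, base)
    for i in range(depth):
        total += double_conv_params(base << i, base << (i + 1))
    for i in reversed(range(depth)):
        cin = base << (i + 1)
        total += 4 * cin * (cin // 2) + cin // 2          # transposed conv
        total += double_conv_params(cin, cin // 2)        # after skip concat
    total += base * 1 + 1                                  # 1x1 output conv
    return total


class TestArchitecture:
    def test_tiny_spec_count_hand_enumerated(self):
        # depth 1, base 2, 1 input channel:
        #   inc  DoubleConv(1->2):  (9*1*2+2) + (9*2*2+2) = 58
        #   down DoubleConv(2->4):  (9*2*4+4) + (9*4*4+4) = 224
        #   up   ConvT(4->2):       4*4*2 + 2             = 34
        #   updc DoubleConv(4->2):  (9*4*2+2) + (9*2*2+2) = 112
        #   outc 1x1 (2->1):        2 + 1                 = 3
        model = build_network(UNetSpec(1, 1, depth=1, base_channels=2, tile_size=8))
        assert count_parameters(model) == 58 + 224 + 34 + 112 + 3 == 431

    @pytest.mark.parametrize("in_ch,depth,base", [(1, 2, 4), (2, 2, 4), (1, 3, 16)])
    def test_counts_match_closed_form(self, in_ch, depth, base):
        model = build_network(UNetSpec(in_ch, 1, depth, base, tile_size=32))
        assert count_parameters(model) == unet_params_closed_form(in_ch, depth, base)

    def test_default_spec_exceeds_31_million(self):
        model = build_network(UNetSpec())
        assert count_parameters(model) > 31_000_000

    def test_second_channel_adds_first_layer_weights_only(self):
        one = count_parameters(build_network(UNetSpec(in_channels=1)))
        two = count_parameters(build_network(UNetSpec(in_channels=2)))
        assert two - one == 9 * 64  # kernel area x base channels

    def test_indivisible_tile_rejected(self):
        with pytest.raises(ContractError):
            UNetSpec(tile_size=250)

    @pytest.mark.parametrize("tile", [16, 32])
    def test_forward_preserves_spatial_shape(self, tile):
        model = UNet(UNetSpec(1, 1, depth=2, base_channels=4, tile_size=tile), seed=0)
        out = model.forward(np.zeros((2, 1, tile, tile), dtype=np.float32))
        assert out.shape == (2, 1, tile, tile)
        assert np.all(np.isfinite(out))

    def test_channel_mismatch_rejected(self):
        model = UNet(UNetSpec(2, 1, depth=1, base_channels=2, tile_size=8), seed=0)
        with pytest.raises(ContractError):
            model.forward(np.zeros((1, 1, 8, 8), dtype=np.float32))


@pytest.fixture(scope="module")
def one_triplet():
    cfg = SimulationConfig(field_width=32, tile_size=32, n_frames=50,
                           step_length=1.0, wf_blur_sd=2.5, wf_small_size=8,
                           seed=3)
    return generate_dataset(cfg, 1)


class TestTraining:
    def test_single_sample_memorization(self, one_triplet):
        model = UNet(UNetSpec(1, 1, depth=2, base_channels=8, tile_size=32), seed=1)
        cfg = TrainConfig(epochs=500, batch_size=1, learning_rate=1e-3, seed=2)
        model, history = train(model, one_triplet, cfg, variant="3000")
        assert len(history) == 500
        assert history[-1] < 0.01 * history[0]

    def test_zero_epochs_rejected(self):
        with pytest.raises(ContractError):
            TrainConfig(epochs=0)

    def test_variant_channel_contract(self, one_triplet):
        model = UNet(UNetSpec(1, 1, depth=2, base_channels=4, tile_size=32), seed=0)
        with pytest.raises(ContractError):
            train(model, one_triplet, TrainConfig(epochs=1), variant="WF+3000")
        with pytest.raises(ContractError):
            train(model, one_triplet, TrainConfig(epochs=1), variant="nope")

    def test_training_deterministic_under_seed(self, one_triplet):
        histories = []
        for _ in range(2):
            model = UNet(UNetSpec(1, 1, depth=1, base_channels=4, tile_size=32), seed=7)
            _, h = train(model, one_triplet,
                         TrainConfig(epochs=5, batch_size=1, seed=9), variant="3000")
            histories.append(h)
        assert histories[0] == histories[1]

    def test_epoch_loss_below_first_epoch_late_in_training(self, desk_experiment):
        history, _, _ = desk_experiment
        assert all(history[e] < history[0] for e in range(50, len(history)))


class TestPredict:
    def test_two_channel_model_requires_widefield(self):
        model = UNet(UNetSpec(2, 1, depth=1, base_channels=2, tile_size=8), seed=0)
        with pytest.raises(ContractError):
            predict(model, sparse_tile=np.zeros((8, 8), dtype=np.float32))

    def test_zero_input_gives_finite_clamped_output(self):
        model = UNet(UNetSpec(1, 1, depth=1, base_channels=2, tile_size=8), seed=0)
        out = predict(model, sparse_tile=np.zeros((8, 8), dtype=np.float32))
        assert out.shape == (8, 8)
        assert np.all(np.isfinite(out)) and out.min() >= 0.0 and out.max() <= 1.0

    def test_checkpoint_roundtrip(self, tmp_path):
        model = UNet(UNetSpec(1, 1, depth=1, base_channels=2, tile_size=8), seed=4)
        x = np.random.default_rng(0).random((8, 8)).astype(np.float32)
        before = predict(model, sparse_tile=x)
        path = str(tmp_path / "model.npz")
        save_checkpoint(model, path, TrainConfig(epochs=1))
        after = predict(load_checkpoint(path), sparse_tile=x)
        np.testing.assert_array_equal(before, after)


class TestStitch:
    def test_round_trip_with_tiling(self):
        img = np.random.default_rng(0).random((512, 512))
        assert np.array_equal(stitch_tiles(tile_image(img)), img)

    def test_four_tiles_give_512_field(self):
        tiles = [((r, c), np.zeros((256, 256))) for r in range(2) for c in range(2)]
        assert stitch_tiles(tiles).shape == (512, 512)

    def test_missing_cell_named(self):
        tiles = [((r, c), np.zeros((4, 4))) for r in range(2) for c in range(2)
                 if (r, c) != (1, 1)]
        with pytest.raises(ContractError, match=r"\(1, 1\)"):
            stitch_tiles(tiles)
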