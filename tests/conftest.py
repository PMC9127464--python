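"""Shared fixtures.

The desk-scale experiment fixture runs the package's core end-to-end check
once per session — simulating 200 small microtubule fields, training a
reduced U-Net on the sparse->dense task, and evaluating held-out tiles —
and is shared by every test that asserts on its outcome.
"""

from __future__ import annotations

import numpy as np
import pytest

from upaint import (SimulationConfig, TrainConfig, UNet, UNetSpec, evaluate_pair,
                    generate_dataset, predict, split_dataset, train)

#: Desk-scale analogue of the published simulation protocol: 64 px fields,
#: 50 frames, 10% sparse fraction; blur/grid sizes scaled with the field
#: (sigma_wf 5 px, widefield grid 8 px at 64 px tiles ~ sigma 20/grid 32 at
#: 256); step length 1.5 px so trajectories cross most of the field within
#: 50 frames, as the 0.5 px x 500-frame walks do at full scale.
DESK_SIM = dict(field_width=64, tile_size=64, n_frames=50, step_length=1.5,
                heading_noise_sd=0.35, gt_blur_sd=1.25, wf_blur_sd=5.0,
                wf_small_size=8, sparse_fraction=0.1)


@pytest.fixture(scope="session")
def desk_experiment():
    """Simulate 200 triplets, train a reduced U-Net (depth 3, base 16) for
    200 epochs on the sparse channel, and evaluate 40 held-out tiles.

    Returns (loss_history, model_reports, sparse_reports) where the report
    lists hold per-tile PSNR/RMSE/SSIM of the reconstruction and of the raw
    sparse input against the dense ground truth.
    """
    cfg = SimulationConfig(seed=11, **DESK_SIM)
    triplets = generate_dataset(cfg, 200)
    train_set, test_set = split_dataset(triplets, 0.2, np.random.default_rng(1))
    assert len(test_set) >= 20
    model = UNet(UNetSpec(in_channels=1, depth=3, base_channels=16, tile_size=64),
                 seed=5)
    tcfg = TrainConfig(epochs=200, batch_size=2, learning_rate=1e-3, seed=13)
    model, history = train(model, train_set, tcfg, variant="3000")
    model_reports, sparse_reports = [], []
    for t in test_set:
        recon = predict(model, sparse_tile=t.sparse)
        model_reports.append(evaluate_pair(t.dense, recon))
        sparse_reports.append(evaluate_pair(t.dense, t.sparse))
    return history, model_reports, sparse_reports
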