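"""Shared fixtures: phantoms and (expensive, session-scoped) trained models."""

from __future__ import annotations

import numpy as np
import pytest

from scoutrange.phantom import PhantomConfig, generate_phantom
from scoutrange.projection import normalize_resize, project_mask, project_volume


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default-habitus phantom without noise or pathology."""
    cfg = PhantomConfig(noise_sd=0.0, pathology_fraction=0.0)
    volume, mask = generate_phantom(cfg, seed=1)
    return cfg, volume, mask


@pytest.fixture(scope="session")
def ap_projection_256(noiseless_phantom):
    """Normalized 256x256 AP projection + mask of the noiseless phantom."""
    _, volume, mask = noiseless_phantom
    proj = project_volume(volume, "AP")
    mask2 = project_mask(mask, "AP")
    return normalize_resize(proj, mask2, size=256)


@pytest.fixture(scope="session")
def trained_model():
    """Network trained on 200 synthetic AP projections for 10 epochs.

    This is the package's reference desk-scale training run; several tests
    (held-out Dice, prediction quality, scout fine-tuning) share it because
    training dominates the suite's runtime.
    """
    from scoutrange.segmentation import SegModelConfig, build_model, make_dataset, train

    config = SegModelConfig(seed=0, epochs=10)
    dataset = make_dataset(200, seed=11)
    model = build_model(config)
    model, report = train(model, dataset, config)
    return model, report, dataset
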