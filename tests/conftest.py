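"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import pytest

from chromotype import (
    SynthConfig,
    generate_dataset,
    train_head,
)


def small_synth_config(image_size: int = 64) -> SynthConfig:
    """A reduced-raster generator config with geometry scaled to fit."""
    scale = image_size / 224.0
    return SynthConfig(
        image_size=image_size,
        chromatid_length_range=(80 * scale, 105 * scale),
        chromatid_width_range=(max(2.5, 10 * scale), max(3.5, 16 * scale)),
        centromere_gap_by_type={
            "A": (0.0, 0.0),
            "B": (0.0, 0.0),
            "C": (14 * scale, 26 * scale),
        },
        min_c_gap=max(2.0, 8 * scale),
    )


@pytest.fixture(scope="session")
def default_config() -> SynthConfig:
    return SynthConfig()


@pytest.fixture(scope="session")
def tiny_config() -> SynthConfig:
    """64-pixel raster for tests that only need labels/geometry, not features."""
    return small_synth_config(64)


@pytest.fixture(scope="session")
def small_images(default_config):
    """A small labelled batch at full resolution (6 per type)."""
    return generate_dataset({"A": 6, "B": 6, "C": 6}, default_config, seed=11)


@pytest.fixture(scope="session")
def trained_model(default_config):
    """A small trained classifier shared by saliency/genotype tests."""
    train = generate_dataset({"A": 20, "B": 20, "C": 20}, default_config, seed=21)
    val = generate_dataset({"A": 10, "B": 10, "C": 10}, default_config, seed=22)
    return train_head("small_scratch", train, val, seed=0)
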