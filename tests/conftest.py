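"""Shared fixtures: a small synthetic dataset exercised by many tests."""
from __future__ import annotations

import pytest

from histmod_dex import BinScheme, build_ratios, call_degs, generate, quantify
from histmod_dex.synthetic_data import small_panel_config


@pytest.fixture(scope="session")
def small_config():
    """4 marks (2 drivers), 120 genes, default +/-5 kb scheme."""
    return small_panel_config(n_genes=120, n_hms=4, n_drivers=2, seed=1)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate(small_config)


@pytest.fixture(scope="session")
def small_tensors(small_config, small_dataset):
    return quantify(small_dataset.anchors, small_dataset.tracks, small_config.scheme)


@pytest.fixture(scope="session")
def small_degs(small_dataset):
    return call_degs(small_dataset.counts, small_dataset.anchors)


@pytest.fixture(scope="session")
def small_region_matrix(small_tensors, small_degs):
    return build_ratios(
        small_tensors["normal"], small_tensors["cancer"], small_degs, mode="region"
    )


@pytest.fixture(scope="session")
def small_perbin_matrix(small_tensors, small_degs):
    return build_ratios(
        small_tensors["normal"], small_tensors["cancer"], small_degs, mode="per_bin"
    )


@pytest.fixture(scope="session")
def tiny_scheme():
    """A 20-bin scheme (+/-1 kb) for fast per-bin tests."""
    return BinScheme(flank_bp=1000, bin_bp=100)
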