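"""Shared fixtures: small synthetic libraries at several scales."""
import numpy as np
import pytest

from gasam import simulate, spectra


def make_tiny_library(seed: int = 5) -> spectra.SpectralLibrary:
    """3 species x 6 leaves on a 12-band grid with 3 planted features.

    Small enough for exhaustive subset search (C(12,3) = 220 candidates).
    """
    grid = spectra.SpectralGrid(np.linspace(3.0, 5.2, 12), np.ones(12, dtype=bool))
    feats = (
        simulate.FeatureSpec(3.2, 0.08, {"A": 0.05, "B": 0.15, "C": 0.10}, 0.01),
        simulate.FeatureSpec(4.0, 0.08, {"A": 0.15, "B": 0.05, "C": 0.10}, 0.01),
        simulate.FeatureSpec(4.8, 0.08, {"A": 0.10, "B": 0.10, "C": 0.18}, 0.01),
    )
    cfg = simulate.SimConfig(
        n_species=3,
        n_leaves=6,
        grid=grid,
        features=feats,
        iid_noise_sd=0.012,
        seed=seed,
        species_codes=("A", "B", "C"),
    )
    return simulate.generate_library(cfg)


@pytest.fixture(scope="session")
def tiny_library() -> spectra.SpectralLibrary:
    return make_tiny_library()


@pytest.fixture(scope="session")
def tiny_split(tiny_library) -> spectra.SplitLibrary:
    return spectra.split_per_species(tiny_library, n_train=3, seed=11)


@pytest.fixture(scope="session")
def paperlike_cfg() -> simulate.SimConfig:
    """The shipped 13-species x 35-leaf fixture configuration."""
    return simulate.default_paperlike_config(seed=1)


@pytest.fixture(scope="session")
def paperlike_lib(paperlike_cfg) -> spectra.SpectralLibrary:
    return simulate.generate_library(paperlike_cfg)


@pytest.fixture(scope="session")
def paperlike_split(paperlike_lib) -> spectra.SplitLibrary:
    return spectra.split_per_species(paperlike_lib, n_train=17, seed=100)


@pytest.fixture(scope="session")
def true_bands(paperlike_cfg, paperlike_lib) -> list[int]:
    """Grid bands nearest the five planted feature centres."""
    return sorted(
        paperlike_lib.grid.nearest_band(c)
        for c in simulate.planted_centers(paperlike_cfg)
    )
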