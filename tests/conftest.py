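"""Shared fixtures: small synthetic images and profiles built at test time."""

import numpy as np
import pytest
from hypothesis import settings

from chromoquant import ImageStack, LineProfile

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from chromoquant.synthetic import SyntheticNucleusSpec, generate_nucleus_image


def make_profile(dapi, marker=None, step=0.05):
    """A LineProfile straight from value arrays (positions in µm)."""
    dapi = np.asarray(dapi, dtype=float)
    intensity = {"DAPI": dapi}
    if marker is not None:
        intensity["marker"] = np.asarray(marker, dtype=float)
    n = dapi.size
    positions = (np.arange(n) - (n - 1) / 2) * step
    return LineProfile(
        positions=positions,
        intensity=intensity,
        line_endpoints=((0.0, 0.0), (0.0, float(n - 1))),
    )


@pytest.fixture
def noiseless_colocalized():
    spec = SyntheticNucleusSpec(marker_mode="colocalized", noise_sd=0.0, seed=11)
    return spec, *generate_nucleus_image(spec)


@pytest.fixture
def noiseless_cloudy():
    spec = SyntheticNucleusSpec(marker_mode="cloudy", noise_sd=0.0, seed=11)
    return spec, *generate_nucleus_image(spec)


@pytest.fixture
def flat_image():
    arr = np.full((40, 40), 500.0)
    return ImageStack({"DAPI": arr, "marker": arr.copy()}, voxel_size=(0.1, 0.1))
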