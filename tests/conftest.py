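"""Shared fixtures and the independent DFT-domain MODWPT oracle."""

from __future__ import annotations

import numpy as np
import pytest

from thzburn.modwpt import daubechies_filters
from thzburn.pipeline import (
    FeatureConfig,
    condition_air,
    extract_observations,
    plan_from_scene,
)
from thzburn.synthdata import demo_config, generate_dataset


def dft_modwpt_oracle(x: np.ndarray, vanishing_moments: int, J: int) -> np.ndarray:
    """Brute-force MODWPT via frequency-domain transfer functions.

    Independent of the time-domain cascade: each terminal sub-band's
    coefficients are the inverse DFT of the input spectrum multiplied by
    the cascade product of up-sampled filter transfer functions
    U_j(f) = sum_k u(k) exp(-2 pi i f 2**(j-1) k / N) along the root-to-leaf
    path, with the filter at each step chosen by the sequency (n mod 4)
    rule applied to the child index on that path.
    """
    x = np.asarray(x, dtype=float)
    N = x.size
    g, h = daubechies_filters(vanishing_moments)
    X = np.fft.fft(x)
    f = np.arange(N)
    out = np.empty((2**J, N))
    for n in range(2**J):
        prod = np.ones(N, dtype=complex)
        for j in range(1, J + 1):
            child = n >> (J - j)
            u = g if child % 4 in (0, 3) else h
            k = np.arange(u.size)
            U = np.exp(-2j * np.pi * np.outer(f, k) * (2 ** (j - 1)) / N) @ u
            prod *= U
        out[n] = np.fft.ifft(X * prod).real
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def demo_scene():
    """Reduced-scale scene on a 25x25 grid (25 tiles before masking)."""
    return demo_config(snr_db=30.0, nx=25, ny=25, seed=101)


@pytest.fixture(scope="session")
def demo_plan(demo_scene):
    # 12.8-ps gate -> 256 gated samples at dt = 0.05 ps
    return plan_from_scene(demo_scene, gate_width=12.8)


@pytest.fixture(scope="session")
def demo_dataset(demo_scene):
    cubes, air = generate_dataset(demo_scene, {"H": 2, "SPT": 2, "DPT": 2, "FT": 2}, seed=101)
    return cubes, air


@pytest.fixture(scope="session")
def demo_observations(demo_dataset, demo_plan):
    cubes, air = demo_dataset
    observations = extract_observations(cubes, demo_plan, air)
    air_gated = condition_air(air, demo_plan)
    return observations, air_gated


@pytest.fixture(scope="session")
def demo_features_config():
    return FeatureConfig(vanishing_moments=1, level=8, f_lo=0.1, f_hi=1.0)
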