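"""Shared fixtures: presets, datasets and one full pipeline run per preset.

Dataset generation and pipeline fits are the expensive pieces, so they are
session-scoped; tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

import photoxs as px
from photoxs.kinetics import Structure


@pytest.fixture(scope="session")
def redgreen():
    preset = px.make_preset("redgreen")
    return preset, px.generate_dataset(preset)


@pytest.fixture(scope="session")
def overlap680():
    preset = px.make_preset("overlap680")
    return preset, px.generate_dataset(preset)


@pytest.fixture(scope="session")
def dual_reversion():
    preset = px.make_preset("dual_reversion")
    return preset, px.generate_dataset(preset)


@pytest.fixture(scope="session")
def dimer():
    preset = px.make_preset("dimer")
    return preset, px.generate_dataset(preset)


@pytest.fixture(scope="session")
def noisy_rf():
    preset = px.make_preset("noisy_rf")
    return preset, px.generate_dataset(preset, seed=0)


def run_pipeline_on(preset, dataset, *, n_pools, n_phi=20, n_starts=20, seed=1,
                    structure=None, profile=False):
    m = preset.model
    return px.analyse_dataset(
        dataset["forward"],
        dataset["reverse"],
        dataset["dark"],
        c_tot=m.c_tot,
        path_length=m.path_length,
        lights=(preset.light_act, preset.light_inact),
        structure=structure or m.structure,
        n_pools=n_pools,
        n_phi=n_phi,
        n_starts=n_starts,
        seed=seed,
        profile=profile,
    )


@pytest.fixture(scope="session")
def redgreen_result(redgreen):
    preset, dataset = redgreen
    return run_pipeline_on(preset, dataset, n_pools=1)


@pytest.fixture(scope="session")
def overlap680_result(overlap680):
    preset, dataset = overlap680
    return run_pipeline_on(preset, dataset, n_pools=1)


@pytest.fixture(scope="session")
def noisy_rf_result(noisy_rf):
    preset, dataset = noisy_rf
    return run_pipeline_on(preset, dataset, n_pools=1, n_phi=15, n_starts=12)
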