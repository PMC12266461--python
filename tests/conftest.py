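"""Shared fixtures: small simulated datasets and pipelines reused across tests."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings

import oligopeel as op

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


THREE_COMPONENTS = [
    # identical envelope shapes so apex/total ratios equal abundance ratios
    op.SimComponent("PEG", 18.0106, abundance=1.0, mean_eo=18.3),
    op.SimComponent("glycerol-EO", 92.0473, abundance=0.5, mean_eo=18.3),
    op.SimComponent("cetyl-EO", 242.2610, abundance=0.2, mean_eo=18.3),
]


@pytest.fixture(scope="session")
def three_component_sim():
    """Noiseless three-series spectrum with ground truth, binned and peeled."""
    peaklist, truth = op.simulate_spectrum(
        THREE_COMPONENTS, noise_sd=0.0, seed=3, mz_range=(500.0, 2000.0)
    )
    spec = op.bin_to_grid(peaklist, 0.1, (500.0, 2000.0))
    result = op.peel_spectrum(spec)
    return peaklist, truth, spec, result


@pytest.fixture(scope="session")
def peg_dataset():
    """Small default-design (batch-variation) PEG castor dataset + pipeline run."""
    dataset = op.simulate_dataset(op.peg_castor_design(), 6, 4, seed=4)
    result = op.run_pipeline_on_dataset(dataset)
    return dataset, result


@pytest.fixture(scope="session")
def two_class_result():
    """The two-class design under its stated study conditions, fully processed."""
    design = replace(op.peg_castor_design(), abundance_cv=0.0)
    dataset = op.simulate_dataset(design, 20, 4, seed=0)
    return op.run_pipeline_on_dataset(dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
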