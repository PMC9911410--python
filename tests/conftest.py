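"""Shared fixtures: small synthetic bundles and trained models."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from rebel import pipeline, synthetic
from rebel.model import ModelConfig

#: small grid used wherever grid extent is not itself under test
SMALL_GRID = ((1, 3), (1, 6), (5, 3), (5, 6))


@pytest.fixture(scope="session")
def small_model_config() -> ModelConfig:
    return ModelConfig(seed=11, grid=SMALL_GRID, boosting_rounds=60,
                       early_stop=10)


@pytest.fixture(scope="session")
def planted_config() -> synthetic.SyntheticConfig:
    cfg = synthetic.SyntheticConfig(
        n_motifs=40, elements_per_category=60, seed=11
    )
    library = synthetic.generate_motif_library(cfg)
    return replace(
        cfg,
        signatures=synthetic.default_signatures(
            library, n_required=2, penetrance=0.7
        ),
    )


@pytest.fixture(scope="session")
def planted_bundle(planted_config) -> synthetic.SyntheticBundle:
    return synthetic.generate_bundle(planted_config)


@pytest.fixture(scope="session")
def planted_run(planted_bundle, small_model_config):
    """Categorized elements, motif matrix and trained one-vs-all bundles."""
    return pipeline.benchmark_protocol(planted_bundle, small_model_config)
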