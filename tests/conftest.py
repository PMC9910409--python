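"""Shared fixtures: one default synthetic dataset per session, plus a
pipeline run over it (census + locate done, characterize on demand)."""

from __future__ import annotations

from types import SimpleNamespace

import pytest

from diploidizer.pipeline import Pipeline
from diploidizer.synthetic_data import SimulationConfig, generate_dataset

DATASET_SEED = 1
PIPELINE_SEED = 11


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("default_dataset")
    cfg = SimulationConfig(seed=DATASET_SEED)
    paths, truth = generate_dataset(cfg, out)
    return SimpleNamespace(cfg=cfg, paths=paths, truth=truth, dir=out)


@pytest.fixture(scope="session")
def pipeline(dataset):
    pipe = Pipeline(dataset.paths["config"], seed=PIPELINE_SEED)
    pipe.run_census()
    pipe.run_locate()
    return pipe


@pytest.fixture(scope="session")
def characterized(pipeline):
    """The characterize stage with the full 1000-trial conserved control."""
    summary = pipeline.run_characterize(n_trials=1000)
    return SimpleNamespace(pipe=pipeline, summary=summary)
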