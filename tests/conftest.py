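from pathlib import Path

import numpy as np
import pytest

from riboten import (
    AnnotationSet,
    SimulationConfig,
    TranscriptAnnotation,
    simulate_experiment,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_experiment():
    """200-gene, shallow-depth simulated experiment shared across tests."""
    cfg = SimulationConfig(n_genes=200, library_depth=100_000, seed=42)
    annotation, truth, counts = simulate_experiment(cfg)
    return cfg, annotation, truth, counts


@pytest.fixture
def toy_annotation() -> AnnotationSet:
    return AnnotationSet(
        [
            TranscriptAnnotation("gA", 500, 100, 400),
            TranscriptAnnotation("gB", 700, 50, 650),
            TranscriptAnnotation("gC", 120, 12, 111),  # 33 codons, tiny window
        ]
    )
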