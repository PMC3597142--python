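from __future__ import annotations

import numpy as np
import pytest

from nucleofinder import GammaHyper, UniformPrior, compute_centers
from nucleofinder.synthetic import SimulationConfig, simulate_reads


@pytest.fixture
def hyper() -> GammaHyper:
    return GammaHyper(0.7, 0.3)


@pytest.fixture
def prior() -> UniformPrior:
    return UniformPrior(25.0)


@pytest.fixture
def phased_pipeline_inputs():
    """Signal/control centers and truth from the default phased-array conditions."""

    def _make(seed: int, **overrides):
        cfg = SimulationConfig(seed=seed, **overrides)
        signal, control, truth = simulate_reads(cfg)
        sizes = {cfg.chrom: cfg.chrom_length}
        return (
            compute_centers(signal, sizes),
            compute_centers(control, sizes),
            truth,
            cfg,
        )

    return _make
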