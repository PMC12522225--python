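import numpy as np
import pandas as pd
import pytest

from motifscreen.simulate import (
    SimulationConfig,
    generate_metadata,
    generate_motif_counts,
    generate_protein_panel,
)

#: desk-scale cohort: ~200 cases vs ~200 controls with the study's group
#: structure, reused by every pipeline-level test
SMALL_COHORT = {
    "Health": 30,
    "Benign": 170,
    "LGIN": 34,
    "HGIN": 33,
    "StageI": 67,
    "StageII": 22,
    "StageIII": 22,
    "StageIV": 22,
}


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    defaults = dict(
        n_per_subgroup=dict(SMALL_COHORT),
        fragments_mean=20_000.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def cohort_default():
    """One seeded cohort with planted effects: metadata, motif counts,
    ground truth, proteins."""
    cfg = small_config(seed=11)
    meta = generate_metadata(cfg)
    counts, truth = generate_motif_counts(meta, cfg)
    proteins = generate_protein_panel(meta, cfg)
    return {"config": cfg, "meta": meta, "counts": counts, "truth": truth, "proteins": proteins}


@pytest.fixture(scope="session")
def labels_default(cohort_default):
    return (cohort_default["meta"]["group"] != "control").astype(int).to_numpy()
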