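import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from septorg.classify import orient_many
from septorg.profiles import align_to_polar_cap, normalize_profile
from septorg.synth import (
    StrainSpec,
    SyntheticDatasetConfig,
    default_templates,
    generate_strain_dataset,
)


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def planted_dataset(templates):
    """A 600-cell equal-frequency mixture of all six classes, low noise."""
    spec = StrainSpec(
        strain_id="mix",
        class_frequencies={t.class_id: 1 / 6 for t in templates},
        n_cells=600,
        n_timepoints=1,
    )
    cfg = SyntheticDatasetConfig(noise_sd=0.05, seed=101)
    scans, truth = generate_strain_dataset(spec, templates, cfg)
    return scans, truth


@pytest.fixture(scope="session")
def planted_oriented(planted_dataset):
    """Aligned, normalized, oriented profiles of the planted mixture."""
    scans, truth = planted_dataset
    profiles = [
        normalize_profile(align_to_polar_cap(s), s.spacing_um, s.cell_id, s.timepoint)
        for s in scans
    ]
    return orient_many(profiles), truth
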