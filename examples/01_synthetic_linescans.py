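"""Generate synthetic two-channel line scans with planted septin classes.

Builds a 40-cell dataset from the six default shape templates, then shows
that polar-cap alignment undoes the random perimeter rotation: the aligned
septin profile of a rotated cell matches its unrotated twin exactly when
noise is off.
"""

import numpy as np

from septorg import (
    SyntheticDatasetConfig,
    StrainSpec,
    align_to_polar_cap,
    default_templates,
    generate_cell,
    generate_strain_dataset,
    normalize_profile,
)

templates = default_templates()
spec = StrainSpec(
    strain_id="WT",
    class_frequencies={t.class_id: 1 / 6 for t in templates},
    n_cells=40,
    n_timepoints=3,
)
cfg = SyntheticDatasetConfig(noise_sd=0.05, seed=1)
scans, truth = generate_strain_dataset(spec, templates, cfg)
print(f"generated {len(scans)} scans ({spec.n_cells} cells x {spec.n_timepoints} timepoints)")
print("planted class counts:")
print(truth["class_id"].value_counts().sort_index().to_string())

# rotation is a nuisance the alignment step removes
noise_free = SyntheticDatasetConfig(noise_sd=0.0, rotation="random", seed=2)
ref_cfg = SyntheticDatasetConfig(noise_sd=0.0, rotation="none")
ref, _ = generate_cell(templates[1], ref_cfg, np.random.default_rng(0))
scan, rot = generate_cell(templates[1], noise_free, np.random.default_rng(3))
aligned = normalize_profile(align_to_polar_cap(scan))
expected = normalize_profile(ref.septin)
err = np.abs(aligned.values - expected.values).max()
print(f"\ncell rotated by {rot} samples; max alignment error after recovery: {err:.2e}")
print("(zero error: the polar-cap peak defines position 0 regardless of rotation)")
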