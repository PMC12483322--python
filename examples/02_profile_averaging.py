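"""Average septin profiles with bootstrap confidence bands.

Two synthetic strains — one dominated by the central septin class, one by the
peripheral symmetric class — are averaged and compared.  Positions where the
two 95% bands do not overlap are read as significant differences (p < 0.05),
exactly how strain averages are compared in practice.
"""

import numpy as np

from septorg import (
    StrainSpec,
    SyntheticDatasetConfig,
    align_to_polar_cap,
    average_with_ci,
    ci_nonoverlap,
    default_templates,
    generate_strain_dataset,
    normalize_profile,
)

templates = default_templates()
base = {t.class_id: 0.0 for t in templates}
cfg = SyntheticDatasetConfig(noise_sd=0.05, seed=4)

bands = {}
for name, freqs in (
    ("central", {**base, 1: 0.8, 2: 0.2}),   # septin on the polar cap
    ("flanking", {**base, 1: 0.2, 2: 0.8}),  # septin flanking the cap
):
    spec = StrainSpec(name, freqs, n_cells=80, n_timepoints=1)
    scans, _ = generate_strain_dataset(spec, templates, cfg)
    profiles = [normalize_profile(align_to_polar_cap(s), s.spacing_um) for s in scans]
    bands[name] = average_with_ci(profiles, n_boot=1000, rng=0)

a, b = bands["central"], bands["flanking"]
sig = ci_nonoverlap(a, b)
pos = a.positions
print(f"grid: {pos.size} positions, {pos[0]:+.1f} to {pos[-1]:+.1f} um")
print(f"significant positions (non-overlapping 95% bands): {int(sig.sum())}/{sig.size}")
center = np.abs(pos) < 0.5
print(f"  near the cap (|x| < 0.5 um): {int(sig[center].sum())}/{int(center.sum())}")
print(
    "central-strain mean at 0 um: "
    f"{a.mean[pos.size // 2]:.4f} vs flanking-strain: {b.mean[pos.size // 2]:.4f}"
)
print("(the central strain carries significantly more septin signal on the cap)")
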