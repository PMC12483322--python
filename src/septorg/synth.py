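"""Synthetic line-scan generator with planted septin-organization classes.

The study's raw inputs are time-lapse micrographs; this module emulates them at
the line-scan level so every downstream stage (alignment, classification,
similarity) is testable with known ground truth.  Each synthetic cell is a
two-channel perimeter scan: the polarity channel is a single polar-cap bump at
a known (optionally rotated) perimeter position, and the septin channel is a
planted class template — a mixture of Gaussian bumps placed relative to the cap
— plus clipped additive noise.

The six default templates are synthetic surrogates for the six empirical shape
classes: a central peak colocalized with the polar cap, a symmetric pair of
peaks ~2 µm either side of the cap, a broad/flat distribution, and three
asymmetric one-sided variants.  They are not data-derived centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import LineScan, center_index, positions_um

__all__ = [
    "ClassTemplate",
    "StrainSpec",
    "SyntheticDatasetConfig",
    "default_templates",
    "generate_cell",
    "generate_strain_dataset",
    "generate_polarity_profiles",
]


@dataclass(frozen=True)
class ClassTemplate:
    """A planted septin shape: a mixture of Gaussian bumps on the perimeter.

    Each component is ``(center_offset_um, width_um, amplitude)`` where the
    offset is signed distance from the polar-cap center and width is the
    Gaussian sigma.
    """

    class_id: int
    components: tuple[tuple[float, float, float], ...]

    def __post_init__(self):
        if not self.components:
            raise ValueError("template needs at least one component")
        for off, width, amp in self.components:
            if width <= 0:
                raise ValueError("component widths must be strictly positive")
            if amp < 0:
                raise ValueError("component amplitudes must be nonnegative")


@dataclass(frozen=True)
class StrainSpec:
    """How one strain uses the planted classes.

    ``class_frequencies`` maps class_id -> probability (sums to 1).  ``drift``
    optionally gives a per-timepoint frequency schedule as a mapping
    timepoint -> {class_id: frequency}, overriding the overall frequencies so
    class usage can change over the pheromone-response time course.
    """

    strain_id: str
    class_frequencies: dict[int, float]
    n_cells: int
    n_timepoints: int
    drift: dict[int, dict[int, float]] | None = None

    def __post_init__(self):
        if self.n_cells <= 0 or self.n_timepoints <= 0:
            raise ValueError("counts must be positive")
        self._check_freqs(self.class_frequencies)
        if self.drift is not None:
            for t, freqs in self.drift.items():
                self._check_freqs(freqs)

    @staticmethod
    def _check_freqs(freqs: dict[int, float]) -> None:
        vals = np.array(list(freqs.values()), dtype=float)
        if (vals < 0).any():
            raise ValueError("frequencies must be nonnegative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies must sum to 1, got {vals.sum()!r}")

    def frequencies_at(self, timepoint: int) -> dict[int, float]:
        if self.drift is not None and timepoint in self.drift:
            return self.drift[timepoint]
        return self.class_frequencies


@dataclass(frozen=True)
class SyntheticDatasetConfig:
    """Acquisition-level knobs of the synthetic microscope.

    Defaults: 100 samples at 0.1 µm spacing (a 10 µm perimeter), polar cap
    sigma 0.5 µm, additive noise SD 5% of unit bump amplitude.
    """

    samples_per_perimeter: int = 100
    sample_spacing_um: float = 0.1
    noise_sd: float = 0.05
    polar_cap_width_um: float = 0.5
    rotation: str = "random"  # "random" | "none"
    seed: int = 0

    def __post_init__(self):
        if self.samples_per_perimeter < 16:
            raise ValueError("samples_per_perimeter must be >= 16")
        if self.sample_spacing_um <= 0:
            raise ValueError("sample_spacing_um must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.polar_cap_width_um <= 0:
            raise ValueError("polar_cap_width_um must be positive")
        if self.rotation not in ("random", "none"):
            raise ValueError("rotation must be 'random' or 'none'")

    @property
    def perimeter_um(self) -> float:
        return self.samples_per_perimeter * self.sample_spacing_um


def default_templates() -> tuple[ClassTemplate, ...]:
    """Six well-separated planted templates.

    1: central single peak colocalized with the polar cap
    2: symmetric pair of peaks flanking the cap at ±1.6 µm
    3: broad distribution at the rear of the cell, away from the cap
    4: mid-range asymmetric peak at +2.5 µm
    5: far asymmetric peak at +3.7 µm
    6: asymmetric pair — strong at +2.9 µm, weak at −2.9 µm

    The six shapes are engineered to be nearly equidistant in oriented,
    normalized profile space: multi-bump classes use bumps of mass 1/k and
    width σ/k, which leaves the post-normalization L2 norm unchanged, and
    supports are disjoint so cross-class inner products vanish.  Comparable
    class separations are what makes the curvature-based K selection
    well-posed; a mixture with one dominant split would report that split
    instead of the finest well-supported partition.
    """
    return (
        ClassTemplate(1, ((0.0, 0.30, 1.0),)),
        ClassTemplate(2, ((-1.6, 0.15, 0.5), (1.6, 0.15, 0.5))),
        ClassTemplate(3, ((5.0, 0.60, 1.0),)),
        ClassTemplate(4, ((2.5, 0.30, 1.0),)),
        ClassTemplate(5, ((3.7, 0.30, 1.0),)),
        ClassTemplate(6, ((2.9, 0.15, 0.7), (-2.9, 0.15, 0.3))),
    )


def _circular_bump(
    positions: np.ndarray, perimeter: float, center: float, width: float, amp: float
) -> np.ndarray:
    """Gaussian bump evaluated with wrap-around (circular) distance."""
    d = np.abs(positions - center)
    d = np.minimum(d, perimeter - d)
    return amp * np.exp(-0.5 * (d / width) ** 2)


def _template_channel(
    template: ClassTemplate, cfg: SyntheticDatasetConfig
) -> np.ndarray:
    n = cfg.samples_per_perimeter
    pos = positions_um(n, cfg.sample_spacing_um)
    half_span = cfg.perimeter_um / 2.0
    out = np.zeros(n)
    for off, width, amp in template.components:
        if abs(off) > half_span:
            raise ValueError(
                f"template {template.class_id}: bump center {off} µm is outside "
                f"the representable perimeter span ±{half_span} µm"
            )
        out += _circular_bump(pos, cfg.perimeter_um, off, width, amp)
    return out


def generate_cell(
    template: ClassTemplate,
    cfg: SyntheticDatasetConfig,
    rng: np.random.Generator,
    cell_id: str = "cell0",
    timepoint: int = 0,
) -> tuple[LineScan, int]:
    """One synthetic two-channel scan; returns ``(scan, rotation_samples)``.

    The unrotated scan has the polar-cap peak at the central index and the
    septin template placed relative to it; rotation is a uniform circular
    shift by an integer number of samples, applied identically to both
    channels, so alignment can recover the pre-rotation profile exactly in the
    noise-free case.
    """
    n = cfg.samples_per_perimeter
    pos = positions_um(n, cfg.sample_spacing_um)
    polarity = _circular_bump(pos, cfg.perimeter_um, 0.0, cfg.polar_cap_width_um, 1.0)
    septin = _template_channel(template, cfg)
    if cfg.noise_sd > 0:
        septin = np.clip(septin + rng.normal(0.0, cfg.noise_sd, size=n), 0.0, None)
        polarity = np.clip(
            polarity + rng.normal(0.0, cfg.noise_sd * 0.2, size=n), 0.0, None
        )
    rot = int(rng.integers(0, n)) if cfg.rotation == "random" else 0
    scan = LineScan(
        cell_id=cell_id,
        timepoint=timepoint,
        polarity=np.roll(polarity, rot),
        septin=np.roll(septin, rot),
        spacing_um=cfg.sample_spacing_um,
    )
    return scan, rot


def generate_strain_dataset(
    spec: StrainSpec,
    templates: tuple[ClassTemplate, ...],
    cfg: SyntheticDatasetConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[LineScan], pd.DataFrame]:
    """A full strain dataset with ground truth.

    For every cell and timepoint a class is sampled from the (possibly
    drifting) frequencies, then a scan is generated.  Returns the scans and a
    truth table with columns ``cell_id, timepoint, class_id, rotation``.
    """
    by_id = {t.class_id: t for t in templates}
    missing = set(spec.class_frequencies) - set(by_id)
    if missing:
        raise ValueError(f"no template for class id(s) {sorted(missing)}")
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    scans: list[LineScan] = []
    rows = []
    for t in range(spec.n_timepoints):
        freqs = spec.frequencies_at(t)
        ids = sorted(freqs)
        probs = np.array([freqs[i] for i in ids], dtype=float)
        draws = rng.choice(ids, size=spec.n_cells, p=probs)
        for c in range(spec.n_cells):
            cid = f"{spec.strain_id}_c{c:04d}"
            class_id = int(draws[c])
            scan, rot = generate_cell(
                by_id[class_id], cfg, rng, cell_id=cid, timepoint=t
            )
            scans.append(scan)
            rows.append((cid, t, class_id, rot))
    truth = pd.DataFrame(rows, columns=["cell_id", "timepoint", "class_id", "rotation"])
    return scans, truth


def generate_polarity_profiles(
    width_bem1_um: float,
    width_exo84_um: float,
    grid: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Bell-shaped surrogate Bem1 and Exo84 spatial profiles.

    The measured distributions from the pheromone response are not tabulated
    anywhere reusable, so unimodal Gaussian surrogates centered on the grid
    midpoint stand in.  Each returned profile is nonnegative and sums to 1.
    """
    if width_bem1_um <= 0 or width_exo84_um <= 0:
        raise ValueError("widths must be positive")
    grid = np.asarray(grid, dtype=float)
    mid = 0.5 * (grid[0] + grid[-1])
    bem1 = np.exp(-0.5 * ((grid - mid) / width_bem1_um) ** 2)
    exo84 = np.exp(-0.5 * ((grid - mid) / width_exo84_um) ** 2)
    return bem1 / bem1.sum(), exo84 / exo84.sum()
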