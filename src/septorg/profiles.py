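"""Perimeter line-scan processing: alignment to the polar cap, normalization,
ensemble averaging with bootstrap confidence bands, and kymographs.

Every fluorescence line scan follows the edge of a cell and carries two
channels: a polarity marker (Bem1-GFP, peaked at the polar cap) and a septin
marker (Cdc3-mCherry).  All downstream analysis works in a frame where the
polar-cap peak sits at position 0 µm; positions are signed, negative to the
left.  Profiles are made comparable across cells by subtracting the per-profile
minimum and scaling to unit sum, so a profile reads as the fraction of septin
signal at each position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LineScan",
    "NormalizedProfile",
    "CIBand",
    "align_to_polar_cap",
    "normalize_profile",
    "average_with_ci",
    "ci_nonoverlap",
    "make_kymograph",
    "positions_um",
    "center_index",
]

MIN_SAMPLES = 16


def center_index(n: int) -> int:
    """Central sample index of an n-point perimeter grid.

    Odd grids have a unique center; even grids use index n // 2.
    """
    return n // 2


def positions_um(n: int, spacing_um: float) -> np.ndarray:
    """Signed positions (µm) of an n-point grid relative to its center."""
    return (np.arange(n) - center_index(n)) * spacing_um


@dataclass(frozen=True)
class LineScan:
    """One two-channel perimeter scan of a single cell at one timepoint."""

    cell_id: str
    timepoint: int
    polarity: np.ndarray
    septin: np.ndarray
    spacing_um: float = 0.1

    def __post_init__(self):
        pol = np.asarray(self.polarity, dtype=float)
        sep = np.asarray(self.septin, dtype=float)
        object.__setattr__(self, "polarity", pol)
        object.__setattr__(self, "septin", sep)
        if pol.ndim != 1 or sep.ndim != 1:
            raise ValueError("channels must be 1-D")
        if pol.shape != sep.shape:
            raise ValueError(
                f"channel length mismatch for cell {self.cell_id!r} "
                f"t={self.timepoint}: {pol.size} vs {sep.size}"
            )
        if pol.size < MIN_SAMPLES:
            raise ValueError(f"line scan needs >= {MIN_SAMPLES} samples, got {pol.size}")
        if (pol < 0).any() or (sep < 0).any():
            raise ValueError(
                f"negative intensity in cell {self.cell_id!r} t={self.timepoint}"
            )
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be positive")

    @property
    def n_samples(self) -> int:
        return self.polarity.size


@dataclass(frozen=True)
class NormalizedProfile:
    """Septin intensity fractions centered on the polar-cap peak.

    Invariants: min(values) == 0, sum(values) == 1, values >= 0.  Index
    ``center_index(len(values))`` corresponds to the polarity peak (0 µm).
    """

    values: np.ndarray
    spacing_um: float = 0.1
    cell_id: str = ""
    timepoint: int = 0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)

    @property
    def positions(self) -> np.ndarray:
        return positions_um(self.values.size, self.spacing_um)


@dataclass(frozen=True)
class CIBand:
    """Per-position mean with bootstrap confidence bounds."""

    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    confidence_level: float = 0.95
    n_boot: int = 0
    spacing_um: float = 0.1

    @property
    def positions(self) -> np.ndarray:
        return positions_um(self.mean.size, self.spacing_um)


class ConstantChannelError(ValueError):
    """Raised when a polarity channel is flat and has no unique peak."""


def _circular_smooth3(x: np.ndarray) -> np.ndarray:
    """3-sample circular moving average."""
    return (np.roll(x, 1) + x + np.roll(x, -1)) / 3.0


def find_polar_cap_peak(polarity: np.ndarray, smooth: bool = True) -> int:
    """Index of the polar-cap peak.

    The channel is smoothed with a 3-sample circular moving average before the
    argmax (raw argmax is noise-sensitive); remaining ties break to the lowest
    index, keeping runs reproducible.
    """
    pol = np.asarray(polarity, dtype=float)
    if np.ptp(pol) == 0:
        raise ConstantChannelError(
            "constant polarity channel: no unique polar-cap peak"
        )
    sm = _circular_smooth3(pol) if smooth else pol
    return int(np.argmax(sm))  # np.argmax already takes the lowest index on ties


def align_to_polar_cap(scan: LineScan, smooth: bool = True) -> np.ndarray:
    """Circularly shift the septin channel so the polarity peak is central.

    Returns the shifted septin samples; index ``center_index(n)`` then sits at
    the polar-cap peak.  Raises :class:`ConstantChannelError` for a flat
    polarity channel.
    """
    k = find_polar_cap_peak(scan.polarity, smooth=smooth)
    n = scan.n_samples
    shift = (center_index(n) - k) % n
    return np.roll(scan.septin, shift)


def normalize_profile(
    values: np.ndarray,
    spacing_um: float = 0.1,
    cell_id: str = "",
    timepoint: int = 0,
) -> NormalizedProfile:
    """Min-subtract and scale to unit sum.

    Raises ``ValueError`` on constant input (zero range after the minimum is
    subtracted), which carries no spatial information.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("profile must be 1-D with length >= 2")
    v = v - v.min()
    total = v.sum()
    if total == 0:
        raise ValueError("uninformative profile: constant values")
    return NormalizedProfile(
        values=v / total, spacing_um=spacing_um, cell_id=cell_id, timepoint=timepoint
    )


def _as_matrix(profiles) -> tuple[np.ndarray, float]:
    """Stack an ensemble of profiles into (n, p); enforce one common grid."""
    if isinstance(profiles, np.ndarray) and profiles.ndim == 2:
        return np.asarray(profiles, dtype=float), 0.1
    plist = list(profiles)
    if not plist:
        raise ValueError("empty ensemble")
    if isinstance(plist[0], NormalizedProfile):
        sizes = {p.values.size for p in plist}
        spacings = {p.spacing_um for p in plist}
        if len(sizes) != 1 or len(spacings) != 1:
            raise ValueError("profiles must share a common grid")
        return np.stack([p.values for p in plist]), plist[0].spacing_um
    mat = np.asarray(plist, dtype=float)
    if mat.ndim != 2:
        raise ValueError("profiles must share a common grid")
    return mat, 0.1


def average_with_ci(
    profiles,
    n_boot: int = 1000,
    level: float = 0.95,
    rng: np.random.Generator | int | None = None,
) -> CIBand:
    """Mean profile with a percentile-bootstrap confidence band.

    Whole profiles (cell-timepoints) are resampled with replacement, which
    respects within-profile spatial correlation.  Non-overlap of two such 95%
    bands is the significance criterion used throughout (p < 0.05).
    """
    mat, spacing = _as_matrix(profiles)
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    if n == 1:
        warnings.warn("single profile: degenerate zero-width confidence band")
        return CIBand(mean, mean.copy(), mean.copy(), level, n_boot, spacing)
    rng = np.random.default_rng(rng)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = mat[idx].mean(axis=1)  # (n_boot, p)
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(boot_means, alpha, axis=0)
    upper = np.quantile(boot_means, 1.0 - alpha, axis=0)
    # percentile bounds always bracket the bootstrap mean, not necessarily the
    # sample mean at tiny n_boot; clip so the band invariant lower<=mean<=upper holds
    lower = np.minimum(lower, mean)
    upper = np.maximum(upper, mean)
    return CIBand(mean, lower, upper, level, n_boot, spacing)


def ci_nonoverlap(a: CIBand, b: CIBand) -> np.ndarray:
    """Boolean flags, true where the two confidence bands do not overlap.

    Non-overlapping 95% bands are read as a significant difference (p < 0.05).
    """
    if a.mean.size != b.mean.size or a.spacing_um != b.spacing_um:
        raise ValueError("confidence bands are on different grids")
    return (a.upper < b.lower) | (b.upper < a.lower)


def make_kymograph(profiles) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-timepoint mean profiles as a (timepoint x position) matrix.

    ``profiles`` is an iterable of :class:`NormalizedProfile`.  Rows cover the
    contiguous timepoint range present in the data; rows with no profiles are
    NaN and flagged missing.

    Returns ``(timepoints, matrix, missing)``.
    """
    plist = list(profiles)
    if not plist:
        raise ValueError("empty ensemble")
    sizes = {p.values.size for p in plist}
    if len(sizes) != 1:
        raise ValueError("profiles must share a common grid")
    tps = sorted({p.timepoint for p in plist})
    t_index = np.arange(tps[0], tps[-1] + 1)
    p = plist[0].values.size
    mat = np.full((t_index.size, p), np.nan)
    missing = np.ones(t_index.size, dtype=bool)
    groups: dict[int, list[np.ndarray]] = {}
    for prof in plist:
        groups.setdefault(prof.timepoint, []).append(prof.values)
    for i, t in enumerate(t_index):
        if t in groups:
            mat[i] = np.mean(groups[t], axis=0)
            missing[i] = False
    if missing.any():
        warnings.warn(f"{int(missing.sum())} timepoint(s) have no profiles")
    return t_index, mat, missing
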