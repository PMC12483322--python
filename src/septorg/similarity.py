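"""Strain-level comparison of septin class usage.

Two complementary views: (1) average-linkage hierarchical clustering of the
pairwise Euclidean distances between strains' class-usage frequency vectors,
with bootstrap clade support; (2) a two-reference coordinate projection that
places the wild-type and hyperactive-Gα reference strains at (−d/2, 0) and
(+d/2, 0) and positions every other strain at the intersection of the two
circles whose radii are its usage distances to the references.  The x
coordinate then reads as position along the "Gα activity" axis and y as the
orthogonal component of septin organization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DistanceMatrix",
    "ProjectionPoint",
    "usage_distance_matrix",
    "hcluster",
    "clades_from_linkage",
    "bootstrap_cluster_support",
    "project_onto_axis",
    "bootstrap_positions",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise strain distances with a zero diagonal."""

    strain_ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (len(self.strain_ids),) * 2:
            raise ValueError("matrix shape must match strain count")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(m) != 0).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (m < 0).any():
            raise ValueError("distances must be nonnegative")

    def get(self, a: str, b: str) -> float:
        i, j = self.strain_ids.index(a), self.strain_ids.index(b)
        return float(self.matrix[i, j])

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)


@dataclass(frozen=True)
class ProjectionPoint:
    """One strain's position on the two-reference coordinate plane."""

    strain_id: str
    x: float
    y: float
    degenerate: bool = False
    ci_x: tuple[float, float] | None = None
    ci_y: tuple[float, float] | None = None


def _usage_vectors(usages) -> tuple[tuple[str, ...], np.ndarray]:
    ulist = list(usages)
    if not ulist:
        raise ValueError("no usages")
    ref_classes = tuple(ulist[0].class_ids.tolist())
    for u in ulist:
        if tuple(u.class_ids.tolist()) != ref_classes:
            raise ValueError(
                f"strain {u.strain_id!r} has a different class set than "
                f"{ulist[0].strain_id!r}"
            )
    ids = tuple(u.strain_id for u in ulist)
    return ids, np.stack([u.frequencies for u in ulist])


def usage_distance_matrix(usages) -> DistanceMatrix:
    """Pairwise Euclidean distances between overall class-frequency vectors."""
    ids, vecs = _usage_vectors(usages)
    return DistanceMatrix(ids, squareform(pdist(vecs, metric="euclidean")))


def hcluster(dist: DistanceMatrix) -> np.ndarray:
    """Average-linkage (UPGMA-style) merge tree; scipy linkage format."""
    if len(dist.strain_ids) < 2:
        raise ValueError("need at least 2 strains")
    return linkage(dist.condensed, method="average")


def clades_from_linkage(z: np.ndarray, labels) -> list[frozenset]:
    """Non-trivial clades (leaf-label sets of internal nodes) of a merge tree."""
    n = z.shape[0] + 1
    members: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    clades = []
    for i, (a, b, _h, _c) in enumerate(z):
        merged = members[int(a)] | members[int(b)]
        members[n + i] = merged
        if 1 < len(merged) < n:
            clades.append(merged)
    return clades


def _resample_usage(labels_by_strain, class_ids, rng) -> np.ndarray:
    """Bootstrap usage vectors: resample classified profiles within strain."""
    vecs = []
    for labels in labels_by_strain.values():
        labels = np.asarray(labels)
        take = labels[rng.integers(0, labels.size, size=labels.size)]
        counts = np.array([(take == c).sum() for c in class_ids], dtype=float)
        vecs.append(counts / counts.sum())
    return np.stack(vecs)


def bootstrap_cluster_support(
    labels_by_strain: dict[str, np.ndarray],
    class_ids,
    n_boot: int = 200,
    rng: np.random.Generator | int | None = None,
    support_threshold: float = 0.95,
) -> tuple[np.ndarray, dict[frozenset, float]]:
    """Clade support by bootstrap: resample each strain's classified profiles,
    recompute usage, distances, and tree, and count how often each original
    clade recurs.

    Returns ``(original_linkage, {clade: support fraction})``; clades at or
    above the threshold are the ones reported as confident.
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    if n_boot < 50:
        warnings.warn("n_boot < 50 gives unstable clade support")
    class_ids = np.asarray(class_ids)
    rng = np.random.default_rng(rng)
    ids = list(labels_by_strain)
    base_vecs = []
    for labels in labels_by_strain.values():
        labels = np.asarray(labels)
        counts = np.array([(labels == c).sum() for c in class_ids], dtype=float)
        base_vecs.append(counts / counts.sum())
    base_z = linkage(pdist(np.stack(base_vecs)), method="average")
    clades = clades_from_linkage(base_z, ids)
    hits = {c: 0 for c in clades}
    for _ in range(n_boot):
        vecs = _resample_usage(labels_by_strain, class_ids, rng)
        z = linkage(pdist(vecs), method="average")
        found = set(clades_from_linkage(z, ids))
        for c in clades:
            if c in found:
                hits[c] += 1
    support = {c: hits[c] / n_boot for c in clades}
    return base_z, support


def _project_one(r1: float, r2: float, d: float) -> tuple[float, float, bool]:
    x = (r1**2 - r2**2) / (2 * d)
    # stable product form of r1^2 - (x + d/2)^2; avoids cancellation when the
    # intersection lies on (or near) the reference axis
    y2 = ((r1 + r2) ** 2 - d**2) * (d**2 - (r1 - r2) ** 2) / (4 * d**2)
    degenerate = y2 < -1e-9
    return x, float(np.sqrt(max(0.0, y2))), degenerate


def project_onto_axis(
    dist: DistanceMatrix, ref_wt: str, ref_mut: str
) -> dict[str, ProjectionPoint]:
    """Place every strain at the intersection of two circles.

    The references sit at (−d/2, 0) and (+d/2, 0) where d is their usage
    distance; a strain with distances r1 (to WT) and r2 (to the mutant) lands
    at x = (r1² − r2²)/(2d), y = +sqrt(r1² − (x + d/2)²).  The positive y
    intersection is kept.  Circles that fail to intersect (possible for
    bootstrap resamples) get y clamped to 0 and a degenerate flag.
    """
    d = dist.get(ref_wt, ref_mut)
    if d <= 0:
        raise ValueError("reference strains must be at positive distance")
    out = {}
    for s in dist.strain_ids:
        x, y, degen = _project_one(dist.get(s, ref_wt), dist.get(s, ref_mut), d)
        out[s] = ProjectionPoint(s, x, y, degen)
    return out


def bootstrap_positions(
    labels_by_strain: dict[str, np.ndarray],
    class_ids,
    ref_wt: str,
    ref_mut: str,
    n_boot: int = 200,
    rng: np.random.Generator | int | None = None,
    level: float = 0.95,
) -> dict[str, ProjectionPoint]:
    """Projection points with percentile bootstrap CIs on x and y.

    Each resample redraws every strain's classified profiles with replacement
    (preserving per-strain n), recomputes usage vectors and all pairwise
    distances, and re-derives the reference axis, so the intervals reflect
    reference uncertainty too.
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    class_ids = np.asarray(class_ids)
    rng = np.random.default_rng(rng)
    ids = list(labels_by_strain)
    iw, im = ids.index(ref_wt), ids.index(ref_mut)
    base_vecs = []
    for labels in labels_by_strain.values():
        labels = np.asarray(labels)
        counts = np.array([(labels == c).sum() for c in class_ids], dtype=float)
        base_vecs.append(counts / counts.sum())
    base = _points_from_vectors(np.stack(base_vecs), iw, im)
    xs = np.empty((n_boot, len(ids)))
    ys = np.empty((n_boot, len(ids)))
    for b in range(n_boot):
        vecs = _resample_usage(labels_by_strain, class_ids, rng)
        pts = _points_from_vectors(vecs, iw, im)
        xs[b] = [p[0] for p in pts]
        ys[b] = [p[1] for p in pts]
    alpha = (1 - level) / 2
    out = {}
    for j, s in enumerate(ids):
        out[s] = ProjectionPoint(
            strain_id=s,
            x=base[j][0],
            y=base[j][1],
            degenerate=base[j][2],
            ci_x=(float(np.quantile(xs[:, j], alpha)), float(np.quantile(xs[:, j], 1 - alpha))),
            ci_y=(float(np.quantile(ys[:, j], alpha)), float(np.quantile(ys[:, j], 1 - alpha))),
        )
    return out


def _points_from_vectors(vecs: np.ndarray, iw: int, im: int):
    d = float(np.linalg.norm(vecs[iw] - vecs[im]))
    pts = []
    for j in range(vecs.shape[0]):
        if d == 0:
            pts.append((0.0, 0.0, True))
            continue
        r1 = float(np.linalg.norm(vecs[j] - vecs[iw]))
        r2 = float(np.linalg.norm(vecs[j] - vecs[im]))
        pts.append(_project_one(r1, r2, d))
    return pts
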