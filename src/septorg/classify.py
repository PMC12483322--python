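"""Septin shape classification: orientation, PCA reduction, K-means with a
second-derivative rule for choosing K, and class-usage frequencies.

A mating yeast has rotational symmetry about its projection axis, so a profile
that is septin-heavy to the left of the polar cap and its mirror image are the
same biology.  Orientation removes this nuisance symmetry by mirroring every
profile whose signal is heavier on the left, so all profiles are heavier on the
right.  Oriented profiles are reduced to their top principal-component scores
(enough to explain 95% of variance, capped at 12) and clustered with K-means
over K = 1..20.  K is chosen at the local maximum of the discrete second
derivative of the within-cluster sum-of-squares curve — the point of sharpest
elbow, past which extra classes buy little.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .profiles import NormalizedProfile, center_index

__all__ = [
    "OrientedProfile",
    "ClassModel",
    "StrainUsage",
    "remove_symmetry",
    "orient_many",
    "fit_pca",
    "choose_n_scores",
    "fit_class_model",
    "kmeans_sweep",
    "select_k",
    "assign_classes",
    "relabel_by_reference",
    "usage_frequencies",
]


@dataclass(frozen=True)
class OrientedProfile:
    """A normalized profile, mirrored if needed so the right half is heavier."""

    values: np.ndarray
    flipped: bool
    cell_id: str = ""
    timepoint: int = 0


@dataclass
class ClassModel:
    """Fitted shape classifier: PCA basis, retained scores, K-means centroids."""

    pca_mean: np.ndarray
    pca_components: np.ndarray  # (n_components, p), orthonormal rows
    explained_variance_ratio: np.ndarray
    n_scores: int
    centroids: np.ndarray  # (K, n_scores)
    chosen_k: int
    seed: int
    w_curve: dict[int, float] | None = None
    class_ids: np.ndarray | None = None  # maps centroid row -> published class id

    def __post_init__(self):
        if self.class_ids is None:
            self.class_ids = np.arange(1, self.chosen_k + 1)
        if self.chosen_k != self.centroids.shape[0]:
            raise ValueError("chosen_k must equal the number of centroids")
        g = self.pca_components @ self.pca_components.T
        if not np.allclose(g, np.eye(g.shape[0]), atol=1e-8):
            raise ValueError("PCA components must be orthonormal")

    def transform(self, profiles: np.ndarray) -> np.ndarray:
        """Project profiles (n, p) onto the retained score space (n, n_scores)."""
        x = np.atleast_2d(np.asarray(profiles, dtype=float))
        return (x - self.pca_mean) @ self.pca_components[: self.n_scores].T


@dataclass(frozen=True)
class StrainUsage:
    """Class-usage frequencies of one strain, overall and per timepoint."""

    strain_id: str
    class_ids: np.ndarray
    frequencies: np.ndarray  # (K,), sums to 1
    timepoints: np.ndarray
    per_timepoint: np.ndarray  # (T, K), each present row sums to 1
    missing_timepoints: np.ndarray  # bool (T,)
    n_profiles: int = 0


def _mirror(values: np.ndarray) -> np.ndarray:
    """Reflect a profile about its center index on the circular grid."""
    n = values.size
    c = center_index(n)
    idx = (2 * c - np.arange(n)) % n
    return values[idx]


def _half_sums(values: np.ndarray) -> tuple[float, float]:
    """Left/right half sums, excluding the center sample.

    On even grids the index-0 sample is the polar cap's antipode and is its
    own mirror image; it is excluded from both halves so that an exactly
    symmetric profile compares as a tie.
    """
    n = values.size
    c = center_index(n)
    start = 1 if n % 2 == 0 else 0
    return float(values[start:c].sum()), float(values[c + 1 :].sum())


def remove_symmetry(profile: NormalizedProfile | np.ndarray) -> OrientedProfile:
    """Mirror the profile iff its left half carries more signal than its right.

    Ties (exactly equal halves) do not flip.  Idempotent: orienting an already
    oriented profile changes nothing.
    """
    if isinstance(profile, NormalizedProfile):
        values, cid, tp = profile.values, profile.cell_id, profile.timepoint
    else:
        values, cid, tp = np.asarray(profile, dtype=float), "", 0
    left, right = _half_sums(values)
    if left > right:
        return OrientedProfile(_mirror(values), True, cid, tp)
    return OrientedProfile(values.copy(), False, cid, tp)


def orient_many(profiles) -> list[OrientedProfile]:
    return [remove_symmetry(p) for p in profiles]


def _to_matrix(profiles) -> np.ndarray:
    plist = list(profiles)
    if plist and isinstance(plist[0], OrientedProfile):
        return np.stack([p.values for p in plist])
    return np.atleast_2d(np.asarray(plist, dtype=float))


def choose_n_scores(
    explained_variance_ratio: np.ndarray,
    threshold: float = 0.95,
    max_scores: int = 12,
) -> int:
    """Smallest score count whose cumulative explained variance reaches the
    threshold, capped at ``max_scores``."""
    cum = np.cumsum(explained_variance_ratio)
    reached = np.flatnonzero(cum >= threshold - 1e-12)
    n = int(reached[0]) + 1 if reached.size else cum.size
    return min(n, max_scores)


def fit_pca(profiles, n_components: int | None = None) -> PCA:
    """Center-only PCA of oriented profiles (no variance scaling)."""
    x = _to_matrix(profiles)
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 profiles")
    if n_components is not None and n_components > min(x.shape):
        warnings.warn(
            f"requested {n_components} components but only {min(x.shape)} "
            "are available; capping"
        )
        n_components = min(x.shape)
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(x)
    return pca


def kmeans_sweep(
    scores: np.ndarray,
    k_range=range(1, 21),
    n_replicates: int = 10,
    seed: int = 0,
) -> dict[int, float]:
    """Within-cluster total sum of squared distances W(k) over a K sweep.

    The best of ``n_replicates`` k-means++ restarts is kept per K; the run is
    deterministic under a fixed seed.  K values exceeding the number of points
    are skipped with a warning.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == 0:
        raise ValueError("no score vectors to cluster")
    w: dict[int, float] = {}
    for k in k_range:
        if k > scores.shape[0]:
            warnings.warn(f"k={k} exceeds the {scores.shape[0]} points; skipped")
            continue
        km = KMeans(
            n_clusters=k, n_init=n_replicates, random_state=seed, algorithm="lloyd"
        ).fit(scores)
        w[k] = float(km.inertia_)
    return w


def select_k(w: dict[int, float]) -> tuple[int, dict[int, float]]:
    """Choose K at the largest strict local maximum of d2 W(k).

    d2(k) = W(k−1) − 2 W(k) + W(k+1) on interior k; the strict local maximum
    with the largest d2 wins, ties break toward larger k.  When no strict
    local maximum exists (e.g. a linear curve), fall back to the global
    interior maximum with a warning.

    Returns ``(chosen_k, d2)``.
    """
    ks = sorted(w)
    if len(ks) < 4:
        raise ValueError("need W(k) on a k-range of length >= 4")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("W(k) must be defined on a contiguous k-range")
    wv = np.array([w[k] for k in ks])
    d2v = wv[:-2] - 2 * wv[1:-1] + wv[2:]
    interior = ks[1:-1]
    d2 = dict(zip(interior, d2v))
    best_k, best_val = None, -np.inf
    for i, k in enumerate(interior):
        left = d2v[i - 1] if i > 0 else -np.inf
        right = d2v[i + 1] if i < len(interior) - 1 else -np.inf
        if d2v[i] > left and d2v[i] > right:  # strict local maximum
            if d2v[i] > best_val or (d2v[i] == best_val):
                # ties break toward larger k (iteration is in increasing k)
                best_k, best_val = k, d2v[i]
    if best_k is None:
        warnings.warn("no strict local maximum in d2 W(k); using global interior max")
        best_k = interior[int(np.argmax(d2v))]
    return int(best_k), d2


def fit_class_model(
    oriented_profiles,
    variance_threshold: float = 0.95,
    max_scores: int = 12,
    k_range=range(1, 21),
    n_replicates: int = 10,
    seed: int = 0,
) -> ClassModel:
    """Full classifier fit: PCA -> score truncation -> K sweep -> K selection."""
    x = _to_matrix(oriented_profiles)
    pca = fit_pca(x)
    n_scores = choose_n_scores(
        pca.explained_variance_ratio_, variance_threshold, max_scores
    )
    scores = pca.transform(x)[:, :n_scores]
    w = kmeans_sweep(scores, k_range, n_replicates, seed)
    chosen_k, _ = select_k(w)
    km = KMeans(
        n_clusters=chosen_k, n_init=n_replicates, random_state=seed, algorithm="lloyd"
    ).fit(scores)
    return ClassModel(
        pca_mean=pca.mean_,
        pca_components=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_scores=n_scores,
        centroids=km.cluster_centers_,
        chosen_k=chosen_k,
        seed=seed,
        w_curve=w,
    )


def assign_classes(profiles, model: ClassModel) -> np.ndarray:
    """Label each profile with the published id of its nearest centroid."""
    scores = model.transform(_to_matrix(profiles))
    d2 = ((scores[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    return model.class_ids[np.argmin(d2, axis=1)]


def relabel_by_reference(
    model: ClassModel,
    usage_a: np.ndarray,
    usage_b: np.ndarray,
) -> ClassModel:
    """Permute class ids so the two classes differing most between two
    reference strains become 1 and 2 (larger difference first); the remaining
    classes follow the leaf order of an average-linkage dendrogram of their
    centroids.

    ``usage_a``/``usage_b`` are frequency vectors indexed by centroid row.
    """
    diff = np.abs(np.asarray(usage_a) - np.asarray(usage_b))
    if diff.size != model.chosen_k:
        raise ValueError("usage vectors must have one entry per centroid")
    order = np.argsort(-diff, kind="stable")
    first, second = order[0], order[1]
    rest = np.array([i for i in range(model.chosen_k) if i not in (first, second)])
    if rest.size > 1:
        sub = model.centroids[rest]
        rest = rest[leaves_list(linkage(pdist(sub), method="average"))]
    new_ids = np.empty(model.chosen_k, dtype=int)
    new_ids[first] = 1
    new_ids[second] = 2
    for rank, row in enumerate(rest, start=3):
        new_ids[row] = rank
    model.class_ids = new_ids
    return model


def usage_frequencies(
    labels: np.ndarray,
    timepoints: np.ndarray,
    class_ids: np.ndarray,
    strain_id: str = "",
) -> StrainUsage:
    """Overall and per-timepoint class-usage frequency vectors.

    Timepoints in the contiguous observed range with no profiles yield NaN
    rows flagged missing.
    """
    labels = np.asarray(labels)
    timepoints = np.asarray(timepoints)
    class_ids = np.asarray(class_ids)
    if labels.size == 0:
        raise ValueError("no labels")
    if labels.size != timepoints.size:
        raise ValueError("labels and timepoints must have equal length")
    counts = np.array([(labels == c).sum() for c in class_ids], dtype=float)
    overall = counts / counts.sum()
    t_index = np.arange(timepoints.min(), timepoints.max() + 1)
    per_t = np.full((t_index.size, class_ids.size), np.nan)
    missing = np.ones(t_index.size, dtype=bool)
    for i, t in enumerate(t_index):
        sel = labels[timepoints == t]
        if sel.size:
            row = np.array([(sel == c).sum() for c in class_ids], dtype=float)
            per_t[i] = row / row.sum()
            missing[i] = False
    if missing.any():
        warnings.warn(f"{int(missing.sum())} timepoint(s) have no labels")
    return StrainUsage(
        strain_id=strain_id,
        class_ids=class_ids,
        frequencies=overall,
        timepoints=t_index,
        per_timepoint=per_t,
        missing_timepoints=missing,
        n_profiles=int(labels.size),
    )
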