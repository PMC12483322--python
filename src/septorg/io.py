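"""Delimited-text readers and writers, Newick export, and run manifests.

All tabular files are comma-separated UTF-8 with a mandatory header row and a
one-line format-version comment on top (``# septorg <kind> v1 ...``); readers
reject unknown kinds or versions so stale files fail loudly.  Positions are
signed µm from the polar-cap center, negative to the left.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import warnings
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ClassModel, StrainUsage
from .profiles import CIBand, LineScan, NormalizedProfile, positions_um

FORMAT_VERSION = 1

__all__ = [
    "read_linescan_table",
    "write_linescan_table",
    "read_profiles_table",
    "write_profiles_table",
    "write_ci_band",
    "write_kymograph",
    "write_event_log",
    "save_class_model",
    "load_class_model",
    "write_usage_table",
    "write_newick",
    "write_manifest",
    "file_sha256",
]


def _header_line(kind: str, **meta) -> str:
    extra = " ".join(f"{k}={v}" for k, v in meta.items())
    return f"# septorg {kind} v{FORMAT_VERSION}" + (f" {extra}" if extra else "")


def _check_header(path: Path, kind: str) -> dict:
    with open(path) as fh:
        first = fh.readline().strip()
    parts = first.split()
    if len(parts) < 3 or parts[0] != "#" or parts[1] != "septorg":
        raise ValueError(f"{path}: missing septorg format header")
    if parts[2] != kind:
        raise ValueError(f"{path}: expected a {kind!r} file, found {parts[2]!r}")
    if parts[3] != f"v{FORMAT_VERSION}":
        raise ValueError(f"{path}: unknown format version {parts[3]!r}")
    meta = {}
    for tok in parts[4:]:
        if "=" in tok:
            k, v = tok.split("=", 1)
            meta[k] = v
    return meta


def _write_table(path: Path, df: pd.DataFrame, kind: str, **meta) -> None:
    buf = _io.StringIO()
    buf.write(_header_line(kind, **meta) + "\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def _read_table(path: Path, kind: str) -> tuple[pd.DataFrame, dict]:
    meta = _check_header(Path(path), kind)
    df = pd.read_csv(path, comment="#")
    return df, meta


# ---------------------------------------------------------------- line scans


def write_linescan_table(path, scans: list[LineScan]) -> None:
    """One row per cell-timepoint-channel; columns are perimeter samples."""
    if not scans:
        raise ValueError("no scans to write")
    n = scans[0].n_samples
    cols = [f"s{i:04d}" for i in range(n)]
    rows = []
    for s in scans:
        rows.append([s.cell_id, s.timepoint, "polarity", *s.polarity])
        rows.append([s.cell_id, s.timepoint, "septin", *s.septin])
    df = pd.DataFrame(rows, columns=["cell_id", "timepoint", "channel", *cols])
    _write_table(Path(path), df, "linescan", spacing_um=scans[0].spacing_um)


def read_linescan_table(path, spacing_um: float | None = None) -> list[LineScan]:
    """Read and validate a line-scan table.

    Malformed records (negative intensities, channel-length mismatches,
    missing channels) are rejected with the offending cell/timepoint named.
    """
    df, meta = _read_table(path, "linescan")
    if df.empty:
        warnings.warn(f"{path}: empty line-scan table")
        return []
    spacing = spacing_um if spacing_um is not None else float(meta.get("spacing_um", 0.1))
    sample_cols = [c for c in df.columns if c.startswith("s")]
    scans = []
    for (cid, tp), grp in df.groupby(["cell_id", "timepoint"], sort=False):
        chans = {}
        for _, row in grp.iterrows():
            vals = row[sample_cols].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            chans[row["channel"]] = vals
        if set(chans) != {"polarity", "septin"}:
            raise ValueError(f"{path}: cell {cid!r} t={tp} lacks both channels")
        try:
            scans.append(
                LineScan(str(cid), int(tp), chans["polarity"], chans["septin"], spacing)
            )
        except ValueError as e:
            raise ValueError(f"{path}: invalid record ({e})") from e
    return scans


# ------------------------------------------------------------------ profiles


def write_profiles_table(path, profiles: list[NormalizedProfile]) -> None:
    if not profiles:
        raise ValueError("no profiles to write")
    pos = profiles[0].positions
    cols = [f"{p:+.3f}" for p in pos]
    rows = [[p.cell_id, p.timepoint, *p.values] for p in profiles]
    df = pd.DataFrame(rows, columns=["cell_id", "timepoint", *cols])
    _write_table(Path(path), df, "profiles", spacing_um=profiles[0].spacing_um)


def read_profiles_table(path) -> list[NormalizedProfile]:
    df, meta = _read_table(path, "profiles")
    spacing = float(meta.get("spacing_um", 0.1))
    val_cols = df.columns[2:]
    return [
        NormalizedProfile(
            values=row[val_cols].to_numpy(dtype=float),
            spacing_um=spacing,
            cell_id=str(row["cell_id"]),
            timepoint=int(row["timepoint"]),
        )
        for _, row in df.iterrows()
    ]


def write_ci_band(path, band: CIBand) -> None:
    df = pd.DataFrame(
        {
            "position_um": band.positions,
            "mean": band.mean,
            "lower": band.lower,
            "upper": band.upper,
        }
    )
    _write_table(
        Path(path), df, "ciband", level=band.confidence_level, n_boot=band.n_boot
    )


def write_kymograph(path, timepoints, matrix, spacing_um: float = 0.1) -> None:
    pos = positions_um(matrix.shape[1], spacing_um)
    df = pd.DataFrame(matrix, columns=[f"{p:+.3f}" for p in pos])
    df.insert(0, "timepoint", timepoints)
    _write_table(Path(path), df, "kymograph", spacing_um=spacing_um)


def write_event_log(path, events: pd.DataFrame) -> None:
    _write_table(Path(path), events, "events")


# --------------------------------------------------------------- class model


def save_class_model(path, model: ClassModel) -> None:
    """Persist the fitted classifier (basis, centroids, K, seed) as JSON."""
    payload = {
        "format": f"septorg classmodel v{FORMAT_VERSION}",
        "pca_mean": model.pca_mean.tolist(),
        "pca_components": model.pca_components.tolist(),
        "explained_variance_ratio": model.explained_variance_ratio.tolist(),
        "n_scores": model.n_scores,
        "centroids": model.centroids.tolist(),
        "chosen_k": model.chosen_k,
        "seed": model.seed,
        "class_ids": model.class_ids.tolist(),
        "w_curve": {str(k): v for k, v in (model.w_curve or {}).items()},
    }
    Path(path).write_text(json.dumps(payload))


def load_class_model(path) -> ClassModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != f"septorg classmodel v{FORMAT_VERSION}":
        raise ValueError(f"{path}: unknown class-model format")
    return ClassModel(
        pca_mean=np.array(payload["pca_mean"]),
        pca_components=np.array(payload["pca_components"]),
        explained_variance_ratio=np.array(payload["explained_variance_ratio"]),
        n_scores=int(payload["n_scores"]),
        centroids=np.array(payload["centroids"]),
        chosen_k=int(payload["chosen_k"]),
        seed=int(payload["seed"]),
        w_curve={int(k): v for k, v in payload["w_curve"].items()} or None,
        class_ids=np.array(payload["class_ids"], dtype=int),
    )


def write_usage_table(path, usages: list[StrainUsage]) -> None:
    rows = []
    for u in usages:
        for c, f in zip(u.class_ids, u.frequencies):
            rows.append([u.strain_id, int(c), float(f), u.n_profiles])
    df = pd.DataFrame(rows, columns=["strain_id", "class_id", "frequency", "n_profiles"])
    _write_table(Path(path), df, "usage")


# -------------------------------------------------------------------- newick


def write_newick(
    z: np.ndarray, labels, support: dict[frozenset, float] | None = None
) -> str:
    """Serialize a scipy linkage tree as Newick text.

    Branch lengths are differences of merge heights; bootstrap support values
    (if given) become internal-node labels.
    """
    n = z.shape[0] + 1
    height = {i: 0.0 for i in range(n)}
    members = {i: frozenset([labels[i]]) for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for i, (a, b, h, _c) in enumerate(z):
        node = n + i
        children[node] = (int(a), int(b))
        height[node] = float(h)
        members[node] = members[int(a)] | members[int(b)]

    def render(node: int, parent_h: float) -> str:
        blen = parent_h - height[node]
        if node < n:
            return f"{labels[node]}:{blen:.6g}"
        a, b = children[node]
        inner = f"({render(a, height[node])},{render(b, height[node])})"
        label = ""
        if support is not None and members[node] in support:
            label = f"{support[members[node]]:.2f}"
        return f"{inner}{label}:{blen:.6g}"

    root = n + z.shape[0] - 1
    a, b = children[root]
    body = f"({render(a, height[root])},{render(b, height[root])})"
    if support is not None and members[root] in support:
        body += f"{support[members[root]]:.2f}"
    return body + ";"


# ------------------------------------------------------------------ manifest


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    out_dir, command: str, config: dict, seed: int, outputs: list[str]
) -> Path:
    """Write the run manifest: command, config snapshot, seed, output hashes."""
    from . import __version__

    out_dir = Path(out_dir)
    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "outputs": {
            name: file_sha256(out_dir / name)
            for name in outputs
            if (out_dir / name).exists()
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
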