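"""End-to-end reproducible pipeline: synthesize -> align -> classify -> usage
-> similarity, with a run manifest for auditability.

The pipeline is driven by a plain config dict (typically loaded from YAML).
All randomness flows from one named seed, fanned out to per-stage child seeds
with :class:`numpy.random.SeedSequence`, so re-running with the same manifest
reproduces every deterministic output bit-for-bit.
"""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .classify import assign_classes, fit_class_model, orient_many, usage_frequencies
from .profiles import align_to_polar_cap, normalize_profile
from .similarity import (
    bootstrap_cluster_support,
    bootstrap_positions,
    usage_distance_matrix,
)
from .synth import (
    ClassTemplate,
    StrainSpec,
    SyntheticDatasetConfig,
    default_templates,
    generate_strain_dataset,
)

__all__ = ["pipeline_run", "validate_config"]

REQUIRED_FIELDS = ("seed", "strains")


def validate_config(config: dict) -> None:
    """Schema check; raises ``ValueError`` naming the first missing field."""
    for field in REQUIRED_FIELDS:
        if field not in config:
            raise ValueError(f"pipeline config is missing required field {field!r}")
    if not config["strains"]:
        raise ValueError("pipeline config field 'strains' must not be empty")
    for i, s in enumerate(config["strains"]):
        for field in ("strain_id", "class_frequencies", "n_cells", "n_timepoints"):
            if field not in s:
                raise ValueError(f"strains[{i}] is missing required field {field!r}")


def _templates_from_config(config: dict) -> tuple[ClassTemplate, ...]:
    if "templates" not in config:
        return default_templates()
    return tuple(
        ClassTemplate(
            class_id=int(t["class_id"]),
            components=tuple(tuple(c) for c in t["components"]),
        )
        for t in config["templates"]
    )


def pipeline_run(config: dict, out_dir) -> dict:
    """Execute the full synthetic pipeline and write outputs + manifest.

    Stages: per-strain synthetic dataset generation, polar-cap alignment and
    normalization, classifier fit on the pooled oriented profiles, per-strain
    class assignment and usage frequencies, strain distance matrix, tree with
    bootstrap clade support (Newick), and two-reference projection (when the
    config names ``ref_wt``/``ref_mut``).  Any stage failure aborts with the
    stage name in the exception message.

    Returns a summary dict with stage timings and key in-memory results.
    """
    validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    ss = np.random.SeedSequence(seed)
    synth_seeds, fit_seed, boot_seed = ss.spawn(3)
    templates = _templates_from_config(config)
    timings: dict[str, float] = {}
    outputs: list[str] = []
    summary: dict = {"timings": timings}

    stage = "synth"
    t0 = time.perf_counter()
    try:
        ds_cfg = SyntheticDatasetConfig(**config.get("dataset", {}))
        strain_scans: dict[str, list] = {}
        truths = []
        child = synth_seeds.spawn(len(config["strains"]))
        for s, cseed in zip(config["strains"], child):
            spec = StrainSpec(
                strain_id=s["strain_id"],
                class_frequencies={int(k): float(v) for k, v in s["class_frequencies"].items()},
                n_cells=int(s["n_cells"]),
                n_timepoints=int(s["n_timepoints"]),
                drift={
                    int(t): {int(k): float(v) for k, v in f.items()}
                    for t, f in s["drift"].items()
                }
                if s.get("drift")
                else None,
            )
            scans, truth = generate_strain_dataset(
                spec, templates, ds_cfg, rng=np.random.default_rng(cseed)
            )
            strain_scans[spec.strain_id] = scans
            truth = truth.assign(strain_id=spec.strain_id)
            truths.append(truth)
            fname = f"linescans_{spec.strain_id}.csv"
            sio.write_linescan_table(out_dir / fname, scans)
            outputs.append(fname)
        truth_all = pd.concat(truths, ignore_index=True)
        truth_all.to_csv(out_dir / "ground_truth.csv", index=False)
        outputs.append("ground_truth.csv")
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    timings[stage] = time.perf_counter() - t0

    stage = "align"
    t0 = time.perf_counter()
    try:
        strain_profiles = {
            sid: [
                normalize_profile(
                    align_to_polar_cap(scan), scan.spacing_um, scan.cell_id, scan.timepoint
                )
                for scan in scans
            ]
            for sid, scans in strain_scans.items()
        }
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    timings[stage] = time.perf_counter() - t0

    stage = "classify"
    t0 = time.perf_counter()
    try:
        oriented = {sid: orient_many(ps) for sid, ps in strain_profiles.items()}
        pooled = [o for ops in oriented.values() for o in ops]
        cls_cfg = config.get("classify", {})
        model = fit_class_model(
            pooled,
            variance_threshold=float(cls_cfg.get("variance_threshold", 0.95)),
            max_scores=int(cls_cfg.get("max_scores", 12)),
            k_range=range(1, int(cls_cfg.get("kmax", 20)) + 1),
            n_replicates=int(cls_cfg.get("n_replicates", 10)),
            seed=int(fit_seed.generate_state(1)[0] % (2**31)),
        )
        sio.save_class_model(out_dir / "class_model.json", model)
        outputs.append("class_model.json")
        labels_by_strain = {}
        usages = []
        for sid, ops in oriented.items():
            labels = assign_classes(ops, model)
            labels_by_strain[sid] = labels
            tps = np.array([o.timepoint for o in ops])
            usages.append(usage_frequencies(labels, tps, model.class_ids, sid))
        sio.write_usage_table(out_dir / "usage.csv", usages)
        outputs.append("usage.csv")
        summary["model"] = model
        summary["usages"] = usages
        summary["labels_by_strain"] = labels_by_strain
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    timings[stage] = time.perf_counter() - t0

    stage = "similarity"
    t0 = time.perf_counter()
    try:
        dist = usage_distance_matrix(usages)
        pd.DataFrame(
            dist.matrix, index=dist.strain_ids, columns=dist.strain_ids
        ).to_csv(out_dir / "distances.csv")
        outputs.append("distances.csv")
        n_boot = int(config.get("n_boot", 200))
        boot_rng = np.random.default_rng(boot_seed)
        if len(dist.strain_ids) >= 2:
            z, support = bootstrap_cluster_support(
                labels_by_strain, model.class_ids, n_boot=n_boot, rng=boot_rng
            )
            (out_dir / "tree.nwk").write_text(
                sio.write_newick(z, list(labels_by_strain), support) + "\n"
            )
            outputs.append("tree.nwk")
            summary["tree"] = z
            summary["support"] = support
        if "ref_wt" in config and "ref_mut" in config:
            points = bootstrap_positions(
                labels_by_strain,
                model.class_ids,
                config["ref_wt"],
                config["ref_mut"],
                n_boot=n_boot,
                rng=boot_rng,
            )
            rows = [
                [
                    p.strain_id, p.x, p.y, p.degenerate,
                    p.ci_x[0], p.ci_x[1], p.ci_y[0], p.ci_y[1],
                ]
                for p in points.values()
            ]
            pd.DataFrame(
                rows,
                columns=[
                    "strain_id", "x", "y", "degenerate",
                    "ci_x_lo", "ci_x_hi", "ci_y_lo", "ci_y_hi",
                ],
            ).to_csv(out_dir / "projection.csv", index=False)
            outputs.append("projection.csv")
            summary["projection"] = points
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    timings[stage] = time.perf_counter() - t0

    manifest_path = sio.write_manifest(
        out_dir, command="pipeline", config=config, seed=seed, outputs=outputs
    )
    summary["manifest"] = manifest_path
    summary["outputs"] = outputs
    return summary
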