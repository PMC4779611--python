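"""End-to-end analysis runs: QC -> normalize -> ratios / windows / sex bias.

A run is described by a RunConfig, consumes a count matrix + sample
sheet + annotation (TSV or GFF3), and writes TSV tables plus a JSON
manifest recording seeds and input checksums so any run is reproducible
from its config and inputs.  When replicate QC flags divergent
replicates, the ratio analysis is emitted twice: once with all
replicates and once with the flagged replicates excluded.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import annotation as ann_mod
from . import normalization as norm
from . import qc as qc_mod
from . import ratios as ratio_mod
from . import sexbias as sb_mod
from . import windows as win_mod


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    counts_path: str
    samples_path: str
    annotation_path: str
    output_dir: str
    normalization: str = "uq"  # total | uq | median
    thresholds: Sequence[float] = ratio_mod.DEFAULT_THRESHOLDS
    n_boot: int = 10_000
    level: float = 0.95
    seed: int = 0
    window: int = win_mod.DEFAULT_WINDOW
    step: int = win_mod.DEFAULT_STEP
    window_threshold: float = 1.0
    window_min_genes: int = 5
    q_cut: float = sb_mod.DEFAULT_Q_CUT
    fold_cut: float = sb_mod.DEFAULT_FOLD_CUT
    qc_n_perm: int = 10_000
    qc_alpha: float = 0.001
    run_qc: bool = True
    downsample: int | None = None


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()[:16]


def _load_annotation(path: str) -> pd.DataFrame:
    if path.endswith((".gff", ".gff3")):
        return ann_mod.annotation_frame(ann_mod.read_gff3(path))
    return ann_mod.read_annotation_tsv(path)


def _normalize(cm: ann_mod.CountMatrix, annotation: pd.DataFrame, how: str) -> norm.ExpressionMatrix:
    total = norm.rpkm_total(cm, annotation["exonic_length"])
    if how == "total":
        return total
    if how == "uq":
        return norm.rescale_quantile(total, 0.75)
    if how == "median":
        return norm.rescale_quantile(total, 0.5)
    raise PipelineError(f"unknown normalization {how!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "inputs": {},
        "outputs": {},
        "stages": [],
        "complete": False,
    }
    for key in ("counts_path", "samples_path", "annotation_path"):
        p = getattr(config, key)
        manifest["inputs"][key] = {"path": p, "sha256_16": _checksum(p)}

    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {name: int(s.generate_state(1)[0] % (2**31))
                   for name, s in zip(("qc", "ratios", "downsample"), ss.spawn(3))}

    def stage(name):
        manifest["stages"].append(name)

    try:
        stage("load")
        annotation = _load_annotation(config.annotation_path)
        cm = ann_mod.read_counts_tsv(config.counts_path, config.samples_path)
        annotation, cm = ann_mod.filter_placed(annotation, cm)
        if config.downsample is not None:
            cm = norm.downsample_counts(cm, config.downsample, seed=stage_seeds["downsample"])

        stage("normalize")
        expr = _normalize(cm, annotation, config.normalization)
        expr_path = out / "expression.tsv"
        expr.values.to_csv(expr_path, sep="\t", index_label="gene_id")
        with open(out / "expression_method.json", "w") as fh:
            json.dump({"method": expr.method}, fh)
        manifest["outputs"]["expression"] = str(expr_path)

        males = cm.samples_where(sex="male")
        females = cm.samples_where(sex="female")

        stage("qc")
        flagged: list[str] = []
        if config.run_qc:
            qc_rows = []
            for group in (males, females):
                if len(group) >= 3:
                    res = qc_mod.permutation_test(
                        expr, group, n_perm=config.qc_n_perm,
                        alpha=config.qc_alpha, seed=stage_seeds["qc"],
                    )
                    qc_rows.append(res)
            if qc_rows:
                qc_table = pd.concat(qc_rows)
                qc_table.to_csv(out / "qc_replicates.tsv", sep="\t")
                manifest["outputs"]["qc"] = str(out / "qc_replicates.tsv")
                flagged = list(qc_table.index[qc_table["flagged"]])
        manifest["flagged_replicates"] = flagged

        stage("ratios")
        sweeps = {"all_replicates": (males, females)}
        if flagged:
            sweeps["flagged_excluded"] = (
                [s for s in males if s not in flagged],
                [s for s in females if s not in flagged],
            )
        for label, (m_s, f_s) in sweeps.items():
            if not m_s or not f_s:
                raise PipelineError(f"no samples left for sweep {label!r}")
            sweep = ratio_mod.threshold_sweep(
                expr, annotation, m_s, f_s,
                thresholds=config.thresholds, n_boot=config.n_boot,
                level=config.level, seed=stage_seeds["ratios"],
            )
            path = out / f"ratios_{label}.tsv"
            sweep.to_csv(path, sep="\t", index=False)
            manifest["outputs"][f"ratios_{label}"] = str(path)

        stage("windows")
        mean_expr = expr.values.mean(axis=1)
        density = win_mod.window_density(
            annotation, mean_expr, window=config.window, step=config.step,
            thresholds=(0.0, config.window_threshold),
        )
        xa = win_mod.window_xa(
            annotation, mean_expr, window=config.window, step=config.step,
            threshold=config.window_threshold, min_genes=config.window_min_genes,
        )
        for d, x in zip(density, xa):
            x.n_genes_at_threshold = d.n_genes_at_threshold
        win_table = win_mod.profiles_frame(xa)
        win_table.to_csv(out / "windows_x.tsv", sep="\t", index=False)
        manifest["outputs"]["windows"] = str(out / "windows_x.tsv")
        corr = win_mod.density_departure_correlation(xa, threshold=config.window_threshold)
        manifest["window_density_correlation"] = {
            "r": corr.r, "p_value": corr.p_value, "n_windows": corr.n_windows,
            "undefined_reason": corr.undefined_reason,
        }

        stage("sexbias")
        if len(males) >= 2 and len(females) >= 2:
            records = sb_mod.classify_bias(
                expr, annotation, males, females,
                q_cut=config.q_cut, fold_cut=config.fold_cut,
            )
            records.to_csv(out / "sexbias_records.tsv", sep="\t", index_label="gene_id")
            manifest["outputs"]["sexbias"] = str(out / "sexbias_records.tsv")
            n_biased = int(records["bias_class"].isin(["male_biased", "female_biased"]).sum())
            if n_biased >= 1:
                enr = sb_mod.fisher_enrichment(records)
                with open(out / "enrichment.json", "w") as fh:
                    json.dump({
                        "table": enr.table.to_dict(),
                        "odds_ratio": enr.odds_ratio,
                        "p_value": enr.p_value,
                        "zero_cell": enr.zero_cell,
                    }, fh, indent=2)
                manifest["outputs"]["enrichment"] = str(out / "enrichment.json")

        manifest["seeds"] = stage_seeds
        manifest["complete"] = True
    except Exception as exc:  # annotate which stage failed
        manifest["error"] = f"stage {manifest['stages'][-1]}: {exc}"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise PipelineError(manifest["error"]) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
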