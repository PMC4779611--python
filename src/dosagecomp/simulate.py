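"""Synthetic RNA-seq count generator with known compensation status.

Emulates, at roughly 1/10 of the real gene complement, a mosquito-like
genome with chromosomes chr2, chr3 and X (plus optional unplaced
scaffolds): per-gene exon-union lengths drawn log-normal, per-gene
baseline expression drawn log-normal and rescaled so the baseline is the
gene's expected RPKM, and negative-binomial read counts with per-sample
library-size jitter.

The male X carries a multiplicative compensation factor ``c``: c = 1
models complete dosage compensation (male X expression matches the
autosomes), c = 0.5 models its absence (single-copy output).  The female
X can carry its own factor to model X overexpression in females.
Configurable fractions of genes are male- or female-biased, a contiguous
X block may escape compensation, and one replicate may be perturbed to
emulate a divergent library.

Every simulation records full per-gene ground truth, and identical
config + seed yields identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    CountMatrix,
    GeneAnnotation,
    SampleInfo,
    annotation_frame,
    write_annotation_tsv,
    write_counts_tsv,
)

CHROMOSOMES = ("chr2", "chr3", "X", "unplaced")

DEFAULT_N_GENES = {"chr2": 860, "chr3": 760, "X": 110, "unplaced": 20}
DEFAULT_CHROM_LENGTHS = {
    "chr2": 111_000_000,
    "chr3": 95_000_000,
    "X": 24_400_000,
    "unplaced": 5_000_000,
}


class SimulationError(ValueError):
    pass


def _per_chrom(value, chrom: str) -> float:
    if isinstance(value, Mapping):
        return float(value.get(chrom, 0.0))
    return float(value)


@dataclass
class SexBiasSim:
    """Fractions and effect-size law for sex-biased genes.

    Fractions may be scalars or per-chromosome mappings; fold changes for
    the favoured sex are drawn log-normal (default median 6-fold).
    """

    male_frac: float | Mapping[str, float] = 0.0
    female_frac: float | Mapping[str, float] = 0.0
    fold_log_mean: float = float(np.log(6.0))
    fold_log_sd: float = 0.3


@dataclass
class OutlierSim:
    """A divergent replicate: a random gene subset scaled by ``fold``."""

    sample_id: str
    fraction: float = 0.3
    fold: float = 4.0


def default_samples(stage: str = "pupa", n_per_sex: int = 3) -> list[SampleInfo]:
    """Default sample design: n same-stage libraries per sex.

    Pupae use one library per time point (4, 10, 20 h) treated as
    replicates of the stage; larvae use true replicates at one time.
    """
    times = [4.0, 10.0, 20.0] if stage == "pupa" else [12.0] * n_per_sex
    out = []
    for sex in ("male", "female"):
        for i in range(n_per_sex):
            t = times[i % len(times)]
            out.append(SampleInfo(
                sample_id=f"{sex}_{stage}_{i + 1}",
                sex=sex, stage=stage, time_point=t, replicate=i + 1,
            ))
    return out


@dataclass
class SimulationConfig:
    n_genes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_GENES))
    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    length_log_mean: float = float(np.log(1_500.0))  # median exon-union length 1.5 kb
    length_log_sd: float = 0.6
    expr_log_sd: float = 0.2  # spread of baseline expression across genes
    silent_frac: float | Mapping[str, float] = 0.05
    dispersion: float = 0.1  # NB dispersion phi; var = mu + phi mu^2
    lib_size: float = 2_000_000.0
    lib_jitter: float = 0.2  # uniform +-20% library-size variation
    samples: list[SampleInfo] = field(default_factory=default_samples)
    compensation_c: float = 1.0
    female_x_factor: float = 1.0
    sex_bias: SexBiasSim = field(default_factory=SexBiasSim)
    outlier: OutlierSim | None = None
    x_block: tuple[int, int] | None = None  # X region escaping compensation
    x_block_c: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not self.samples:
            raise SimulationError("config has no samples")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise SimulationError("duplicate sample ids in config")
        if not 0.25 <= self.compensation_c <= 1.5:
            raise SimulationError("compensation_c must lie in [0.25, 1.5]")
        if self.dispersion < 0:
            raise SimulationError("dispersion must be >= 0")
        if self.lib_size <= 0:
            raise SimulationError("lib_size must be > 0")
        for chrom in self.n_genes:
            for frac in (
                _per_chrom(self.silent_frac, chrom),
                _per_chrom(self.sex_bias.male_frac, chrom),
                _per_chrom(self.sex_bias.female_frac, chrom),
            ):
                if not 0.0 <= frac <= 1.0:
                    raise SimulationError(f"fraction out of [0, 1] for {chrom}")
        if self.outlier is not None:
            if self.outlier.sample_id not in ids:
                raise SimulationError(
                    f"outlier sample {self.outlier.sample_id} not in sample list"
                )
            if not 0.0 <= self.outlier.fraction <= 1.0:
                raise SimulationError("outlier fraction out of [0, 1]")


@dataclass
class SimulationResult:
    genes: list[GeneAnnotation]
    annotation: pd.DataFrame
    counts: CountMatrix
    truth: pd.DataFrame
    config: SimulationConfig


def _gene_positions(rng: np.random.Generator, n: int, chrom_len: int) -> np.ndarray:
    """Sorted, distinct gene midpoints uniform along the chromosome."""
    mids = np.sort(rng.integers(50_000, max(chrom_len - 50_000, 100_000), size=n))
    # enforce distinct midpoints (ties are vanishingly rare but possible)
    for i in range(1, n):
        if mids[i] <= mids[i - 1]:
            mids[i] = mids[i - 1] + 1
    return mids


def _exon_structure(
    rng: np.random.Generator, midpoint: int, exonic_length: int
) -> tuple[int, int, list[tuple[int, int]]]:
    """Split an exon-union length into exons separated by introns."""
    n_exons = 1 + int(rng.poisson(1.5))
    w = rng.dirichlet(np.ones(n_exons))
    lens = np.maximum(1, np.round(w * exonic_length).astype(int))
    lens[-1] = max(1, exonic_length - int(lens[:-1].sum()))
    introns = rng.integers(60, 2_000, size=n_exons - 1) if n_exons > 1 else np.array([], dtype=int)
    span = int(lens.sum() + introns.sum())
    start = max(1, midpoint - span // 2)
    exons = []
    pos = start
    for i, l in enumerate(lens):
        exons.append((pos, pos + int(l) - 1))
        if i < len(introns):
            pos += int(l) + int(introns[i])
        else:
            pos += int(l)
    end = exons[-1][1]
    return start, end, exons


def simulate(config: SimulationConfig, seed: int | None = None) -> SimulationResult:
    """Generate annotation, counts, sample sheet and ground truth.

    ``seed`` overrides ``config.seed`` when given.  Expected count of
    gene g in sample s is baseline(g) * length_kb(g) * multiplier(g, s)
    * lib(s)/1e6, with baselines rescaled so that baseline equals the
    gene's expected RPKM; counts are negative-binomial (gamma-Poisson)
    with the configured dispersion, or rounded expectations when the
    dispersion is zero and the library jitter disabled.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    genes: list[GeneAnnotation] = []
    rows = []
    for chrom in CHROMOSOMES:
        n = int(config.n_genes.get(chrom, 0))
        if n == 0:
            continue
        clen = int(config.chrom_lengths[chrom])
        mids = _gene_positions(rng, n, clen)
        lengths = np.round(
            np.exp(rng.normal(config.length_log_mean, config.length_log_sd, size=n))
        ).astype(int)
        lengths = np.maximum(lengths, 150)
        silent = rng.random(n) < _per_chrom(config.silent_frac, chrom)
        u = rng.random(n)
        pm = _per_chrom(config.sex_bias.male_frac, chrom)
        pf = _per_chrom(config.sex_bias.female_frac, chrom)
        bias = np.where(u < pm, "male_biased",
                        np.where(u < pm + pf, "female_biased", "unbiased"))
        bias = np.where(silent, "undefined", bias)
        folds = np.exp(rng.normal(
            config.sex_bias.fold_log_mean, config.sex_bias.fold_log_sd, size=n
        ))
        base = np.exp(rng.normal(0.0, config.expr_log_sd, size=n))
        base[silent] = 0.0
        for i in range(n):
            gid = f"SIM_{chrom}_{i + 1:05d}"
            start, end, exons = _exon_structure(rng, int(mids[i]), int(lengths[i]))
            genes.append(GeneAnnotation(
                gene_id=gid, chromosome=chrom, start=start, end=end,
                strand="+" if rng.random() < 0.5 else "-", exons=exons,
            ))
            rows.append({
                "gene_id": gid, "chromosome": chrom,
                "midpoint": int(mids[i]), "exonic_length": int(genes[-1].exonic_length),
                "silent": bool(silent[i]), "bias_class": str(bias[i]),
                "bias_fold": float(folds[i]) if bias[i] in ("male_biased", "female_biased") else 1.0,
                "baseline": float(base[i]),
            })
    truth = pd.DataFrame(rows).set_index("gene_id")

    # rescale so baseline == expected RPKM (sum of baseline * kb == 1e6)
    len_kb = truth["exonic_length"].to_numpy(float) / 1_000.0
    total = float((truth["baseline"].to_numpy() * len_kb).sum())
    if total <= 0:
        raise SimulationError("all genes silent; nothing to simulate")
    truth["baseline"] = truth["baseline"] * (1e6 / total)

    # sex- and chromosome-specific expression multipliers
    is_x = (truth["chromosome"] == "X").to_numpy()
    male_mult = np.ones(len(truth))
    female_mult = np.ones(len(truth))
    c_per_gene = np.full(len(truth), config.compensation_c)
    if config.x_block is not None:
        lo, hi = config.x_block
        in_block = is_x & (truth["midpoint"].to_numpy() >= lo) & (truth["midpoint"].to_numpy() <= hi)
        c_per_gene[in_block] = config.x_block_c
    male_mult[is_x] = c_per_gene[is_x]
    female_mult[is_x] *= config.female_x_factor
    bias_arr = truth["bias_class"].to_numpy()
    fold_arr = truth["bias_fold"].to_numpy()
    male_mult[bias_arr == "male_biased"] *= fold_arr[bias_arr == "male_biased"]
    female_mult[bias_arr == "female_biased"] *= fold_arr[bias_arr == "female_biased"]
    truth["male_mult"] = male_mult
    truth["female_mult"] = female_mult
    truth["compensation_c"] = np.where(is_x, c_per_gene, np.nan)

    # counts
    base = truth["baseline"].to_numpy()
    deterministic = config.dispersion == 0 and config.lib_jitter == 0
    counts = {}
    lib_sizes = {}
    for s in config.samples:
        jit = rng.uniform(1 - config.lib_jitter, 1 + config.lib_jitter) if config.lib_jitter > 0 else 1.0
        lib = config.lib_size * jit
        lib_sizes[s.sample_id] = lib
        mult = male_mult if s.sex == "male" else female_mult
        mu = base * len_kb * mult * (lib / 1e6)
        if config.outlier is not None and s.sample_id == config.outlier.sample_id:
            hit = rng.random(len(mu)) < config.outlier.fraction
            mu = np.where(hit, mu * config.outlier.fold, mu)
        if deterministic:
            counts[s.sample_id] = np.rint(mu).astype(np.int64)
        elif config.dispersion == 0:
            counts[s.sample_id] = rng.poisson(mu).astype(np.int64)
        else:
            lam = np.zeros_like(mu)
            pos = mu > 0
            lam[pos] = rng.gamma(1.0 / config.dispersion, mu[pos] * config.dispersion)
            counts[s.sample_id] = rng.poisson(lam).astype(np.int64)

    annotation = annotation_frame(genes)
    truth = truth.loc[annotation.index]
    sheet = pd.DataFrame(
        [(s.sample_id, s.sex, s.stage, s.time_point, s.replicate) for s in config.samples],
        columns=["sample_id", "sex", "stage", "time_point", "replicate"],
    ).set_index("sample_id")
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=annotation.index), samples=sheet
    )
    return SimulationResult(genes=genes, annotation=annotation, counts=cm, truth=truth, config=config)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

PRESETS = ("pupae_complete", "larvae_female_high", "no_compensation", "testes_like")


def preset(name: str, seed: int = 0) -> SimulationConfig:
    """Named scenario configurations.

    * ``pupae_complete`` — complete compensation (c = 1), no sex bias:
      X:A and chr3:2 should both sit near 1.0 in both sexes.
    * ``larvae_female_high`` — larval design with female X overexpression
      (female_x_factor 1.3, an illustrative magnitude).
    * ``no_compensation`` — male X at single-copy output (c = 0.5).
    * ``testes_like`` — male-only, shallow library, c = 0.5 and a
      reduced expressed-X fraction, mimicking a germline transcriptome.
    """
    if name == "pupae_complete":
        return SimulationConfig(seed=seed)
    if name == "larvae_female_high":
        return SimulationConfig(
            samples=default_samples(stage="larva"),
            female_x_factor=1.3,
            seed=seed,
        )
    if name == "no_compensation":
        return SimulationConfig(compensation_c=0.5, seed=seed)
    if name == "testes_like":
        return SimulationConfig(
            samples=[SampleInfo(sample_id="testes_1", sex="male", stage="pupa",
                                time_point=4.0, replicate=1)],
            compensation_c=0.5,
            silent_frac={"chr2": 0.10, "chr3": 0.10, "X": 0.45, "unplaced": 0.10},
            lib_size=450_000.0,
            seed=seed,
        )
    raise SimulationError(f"unknown preset {name!r}; choose from {PRESETS}")


# ---------------------------------------------------------------------------
# Output dialects
# ---------------------------------------------------------------------------

def write_gff3(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    """Emit gene/mRNA/exon features in GFF3 (arms are not re-split)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chromosome}\tdosagecomp\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            rna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chromosome}\tdosagecomp\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={rna};Parent={g.gene_id}\n"
            )
            for j, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chromosome}\tdosagecomp\texon\t{s}\t{e}\t.\t{g.strand}\t.\tID={rna}.e{j};Parent={rna}\n"
                )


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["samples"] = [asdict(s) for s in config.samples]
    return d


def write_simulation(result: SimulationResult, outdir: str | Path) -> dict[str, str]:
    """Write annotation (TSV + GFF3), counts, sample sheet, truth, config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": str(outdir / "annotation.tsv"),
        "gff3": str(outdir / "genes.gff3"),
        "counts": str(outdir / "counts.tsv"),
        "samples": str(outdir / "samples.tsv"),
        "truth": str(outdir / "truth.tsv"),
        "config": str(outdir / "sim_config.json"),
    }
    write_annotation_tsv(result.annotation, paths["annotation"])
    write_gff3(result.genes, paths["gff3"])
    write_counts_tsv(result.counts, paths["counts"], paths["samples"])
    result.truth.to_csv(paths["truth"], sep="\t", index_label="gene_id")
    with open(paths["config"], "w") as fh:
        json.dump(_config_dict(result.config), fh, indent=2, default=str)
    return paths
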