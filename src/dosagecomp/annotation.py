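"""Gene annotation ingestion and the genomic frame for chromosome ratios.

Everything downstream (RPKM, X:A and chr3:2 ratios, sliding windows) is
anchored to a per-gene table of chromosome assignment, coordinates and
exon-union length.  Annotations come either from a GFF3 file (genes with
exons, possibly via mRNA parents) or from a precomputed tab-separated
table.  Chromosome arms (2L/2R/3L/3R) are merged into whole-chromosome
labels so that chromosomes 2 and 3 can be treated as the analysis units;
anything not covered by the arm map is labelled ``unplaced`` and excluded
from ratio analyses.

Coordinates are 1-based inclusive throughout, matching GFF3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

UNPLACED = "unplaced"
PLACED_CHROMOSOMES = ("chr2", "chr3", "X")
AUTOSOMES = ("chr2", "chr3")

#: Default arm -> chromosome map for the *A. gambiae* AgamP4 assembly.
DEFAULT_ARM_MAP: dict[str, str] = {
    "2L": "chr2",
    "2R": "chr2",
    "3L": "chr3",
    "3R": "chr3",
    "X": "X",
    "chr2": "chr2",
    "chr3": "chr3",
}

ANNOTATION_COLUMNS = ["gene_id", "chromosome", "start", "end", "strand", "exonic_length"]


class AnnotationError(ValueError):
    """Raised for malformed annotation inputs."""


def exon_union_length(exons: Sequence[tuple[int, int]]) -> int:
    """Total length of the union of 1-based inclusive exon intervals.

    Overlapping (and bookended) exons are counted once, so the result is
    the number of distinct genomic bases covered by at least one exon.

    Parameters
    ----------
    exons
        Non-empty sequence of ``(start, end)`` intervals with
        ``end >= start``.

    Raises
    ------
    AnnotationError
        If the list is empty or any interval is inverted.
    """
    if len(exons) == 0:
        raise AnnotationError("a gene must have at least one exon")
    ivs = sorted((int(s), int(e)) for s, e in exons)
    for s, e in ivs:
        if e < s:
            raise AnnotationError(f"inverted exon interval ({s}, {e})")
    total = 0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s <= cur_e + 1:  # overlap or adjacency: same union length either way
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    total += cur_e - cur_s + 1
    return total


@dataclass
class GeneAnnotation:
    """One gene: identifier, chromosome label, span and exon structure."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "."
    exons: list[tuple[int, int]] = field(default_factory=list)
    exonic_length: int | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise AnnotationError(
                f"gene {self.gene_id}: invalid span ({self.start}, {self.end})"
            )
        if self.exons:
            for s, e in self.exons:
                if s < self.start or e > self.end:
                    raise AnnotationError(
                        f"gene {self.gene_id}: exon ({s}, {e}) outside gene span"
                    )
            computed = exon_union_length(self.exons)
            if self.exonic_length is None:
                self.exonic_length = computed
            elif self.exonic_length != computed:
                raise AnnotationError(
                    f"gene {self.gene_id}: stated exonic_length {self.exonic_length} "
                    f"!= exon union {computed}"
                )
        elif self.exonic_length is None:
            raise AnnotationError(
                f"gene {self.gene_id}: no exons and no exonic_length"
            )
        if self.exonic_length < 1:
            raise AnnotationError(f"gene {self.gene_id}: zero-length exon model")


@dataclass
class SampleInfo:
    """One RNA-seq library: identity, sex, stage, time point, replicate."""

    sample_id: str
    sex: str
    stage: str = "other"
    time_point: float | None = None
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sample {self.sample_id}: sex must be male/female")


@dataclass
class CountMatrix:
    """Raw integer read counts, genes x samples, with sample metadata.

    ``counts`` is a DataFrame indexed by gene_id with one column per
    sample; ``samples`` is the sample sheet indexed by sample_id with
    columns sex, stage, time_point, replicate.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise AnnotationError(f"duplicate gene ids in count matrix: {dups[:5]}")
        if self.samples.index.duplicated().any():
            raise AnnotationError("duplicate sample ids in sample sheet")
        missing = [c for c in self.counts.columns if c not in self.samples.index]
        if missing:
            raise AnnotationError(f"samples missing from sample sheet: {missing}")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise AnnotationError("negative entries in count matrix")
        # keep the sheet in column order
        self.samples = self.samples.loc[list(self.counts.columns)]

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_where(self, **criteria) -> list[str]:
        """Sample ids matching all given sheet-column criteria (e.g. sex='male')."""
        mask = pd.Series(True, index=self.samples.index)
        for key, val in criteria.items():
            mask &= self.samples[key] == val
        return list(self.samples.index[mask])


# ---------------------------------------------------------------------------
# GFF3 ingestion
# ---------------------------------------------------------------------------

def _prescan_gff3(path: Path) -> int:
    """Validate basic GFF3 line structure; return number of feature lines."""
    n_features = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):  # trailing FASTA section
                break
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path}: malformed GFF3 line {lineno}: expected 9 "
                    f"tab-separated fields, found {len(fields)}"
                )
            n_features += 1
    return n_features


def read_gff3(
    path: str | Path,
    arm_map: Mapping[str, str] | None = None,
) -> list[GeneAnnotation]:
    """Read gene models from a GFF3 file.

    Exons are attached to genes directly or through an mRNA level; each
    gene's exon-union length is computed with :func:`exon_union_length`.
    Sequence names are passed through ``arm_map`` (default merges the
    *A. gambiae* arms 2L/2R and 3L/3R into chr2 and chr3); unmapped
    sequences become ``unplaced``.
    """
    import gffutils

    path = Path(path)
    if arm_map is None:
        arm_map = DEFAULT_ARM_MAP
    if _prescan_gff3(path) == 0:
        return []
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneAnnotation] = []
    claimed_exons: set[str] = set()
    for g in db.features_of_type("gene", order_by="start"):
        exons = []
        for ex in db.children(g.id, featuretype="exon"):
            exons.append((ex.start, ex.end))
            claimed_exons.add(ex.id)
        if not exons:
            raise AnnotationError(f"gene {g.id}: no exon features found")
        genes.append(
            GeneAnnotation(
                gene_id=g.id,
                chromosome=arm_map.get(g.seqid, UNPLACED),
                start=g.start,
                end=g.end,
                strand=g.strand if g.strand in ("+", "-") else ".",
                exons=exons,
            )
        )
    orphans = [
        f.id for f in db.features_of_type("exon") if f.id not in claimed_exons
    ]
    if orphans:
        raise AnnotationError(
            f"exon features without a resolvable parent gene: {orphans[:10]}"
        )
    return genes


def annotation_frame(genes: Iterable[GeneAnnotation]) -> pd.DataFrame:
    """Tabulate GeneAnnotation records (index gene_id)."""
    rows = [
        (g.gene_id, g.chromosome, g.start, g.end, g.strand, g.exonic_length)
        for g in genes
    ]
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise AnnotationError(f"duplicate gene ids in annotation: {dups[:5]}")
    return df.set_index("gene_id")


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    """Read the annotation TSV dialect (header required, tab-separated)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"annotation TSV missing columns: {missing}")
    df = df.set_index("gene_id")
    if (df["exonic_length"] < 1).any():
        bad = df.index[df["exonic_length"] < 1].tolist()
        raise AnnotationError(f"zero-length gene annotation rejected: {bad[:5]}")
    return df


def write_annotation_tsv(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.reset_index()[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Count matrix / sample sheet I/O
# ---------------------------------------------------------------------------

def read_counts_tsv(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    """Read a count TSV (first column gene_id) plus a sample-sheet TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    samples = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in samples.columns:
        raise AnnotationError("sample sheet must have a sample_id column")
    samples = samples.set_index("sample_id")
    if not np.issubdtype(counts.to_numpy().dtype, np.number):
        raise AnnotationError("count matrix contains non-numeric entries")
    arr = counts.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        raise AnnotationError("count matrix contains non-integer entries")
    return CountMatrix(counts=counts.round().astype(np.int64), samples=samples)


def write_counts_tsv(cm: CountMatrix, counts_path: str | Path, samples_path: str | Path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    cm.samples.to_csv(samples_path, sep="\t", index_label="sample_id")


def filter_placed(
    annotation: pd.DataFrame,
    counts: CountMatrix,
    placed: Sequence[str] = PLACED_CHROMOSOMES,
) -> tuple[pd.DataFrame, CountMatrix]:
    """Drop genes on unplaced scaffolds from annotation and count matrix.

    Mirrors the exclusion of UNKN scaffolds from the analysis.  Count
    values of retained genes are untouched; sample columns are unchanged.
    """
    missing = [g for g in counts.gene_ids if g not in annotation.index]
    if missing:
        raise AnnotationError(
            f"genes in count matrix absent from annotation: {missing[:10]}"
        )
    ann = annotation.loc[counts.gene_ids]
    keep = ann["chromosome"].isin(placed)
    if not keep.any():
        warnings.warn("all genes are unplaced; returning empty matrix")
    kept_ids = ann.index[keep]
    return (
        annotation.loc[kept_ids],
        CountMatrix(counts=counts.counts.loc[kept_ids], samples=counts.samples),
    )
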