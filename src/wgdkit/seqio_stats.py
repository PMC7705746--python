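"""Sequence/annotation I/O and assembly summary statistics.

Reads FASTA and GFF3 inputs into light-weight records and computes the
summary statistics conventionally reported for a genome assembly:
Nxx lengths, GC content, gap (N) totals, gene densities, and
between-genome gene-count ratios.
"""

from __future__ import annotations

import io
import json
from collections import Counter
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import FastaFormatError

__all__ = [
    "SequenceRecord",
    "GeneModel",
    "AssemblySummary",
    "read_fasta",
    "read_gene_models",
    "nxx_statistic",
    "assembly_summary",
    "gene_density",
    "genome_count_ratio",
    "write_summary",
]

_NUCLEOTIDES = set("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence; ``kind`` is ``"nucleotide"`` or ``"protein"``."""

    id: str
    residues: str
    kind: str = "nucleotide"

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("sequence record with empty id")
        if self.kind not in ("nucleotide", "protein"):
            raise ValueError(f"unknown sequence kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneModel:
    """A gene locus with its ordinal position (rank) along its chromosome.

    Coordinates are 1-based inclusive, as in GFF3; spans are converted to
    half-open intervals only inside arithmetic helpers.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    rank: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.rank < 1:
            raise ValueError(f"gene {self.gene_id}: rank must be >= 1")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AssemblySummary:
    seq_count: int
    total_length_bp: int
    n50_bp: int
    n90_bp: int
    max_bp: int
    gc_fraction: float
    gap_length_bp: int

    def __post_init__(self) -> None:
        if not (self.n90_bp <= self.n50_bp <= self.max_bp <= self.total_length_bp):
            raise ValueError("assembly summary violates N90 <= N50 <= max <= total")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction outside [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def read_fasta(path: str | Path, kind: str = "nucleotide") -> list[SequenceRecord]:
    """Read a (wrapped or unwrapped) multi-record FASTA file.

    Residues are uppercased; record order is preserved.  An empty file or
    one with no FASTA header raises :class:`FastaFormatError`.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FastaFormatError(f"{path}: empty FASTA file")
    if not text.lstrip().startswith(">"):
        raise FastaFormatError(f"{path}: not a FASTA file (no '>' header)")
    records = [
        SequenceRecord(id=rec.id, residues=str(rec.seq).upper(), kind=kind)
        for rec in SeqIO.parse(io.StringIO(text), "fasta")
    ]
    if not records:
        raise FastaFormatError(f"{path}: no records parsed")
    return records


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene features from GFF3 and rank them along each chromosome.

    Only ``type=gene`` records are used and an ``ID`` attribute is
    required.  Ranks are 1-based by start coordinate within a chromosome.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[tuple[str, str, int, int, str]] = []
    for feat in db.features_of_type("gene"):
        if "ID" not in feat.attributes:
            raise FastaFormatError(f"gene feature at {feat.seqid}:{feat.start} lacks ID")
        genes.append((feat.attributes["ID"][0], feat.seqid, feat.start, feat.end,
                      feat.strand if feat.strand in "+-" else "+"))
    models: list[GeneModel] = []
    by_chrom: dict[str, list[tuple[str, str, int, int, str]]] = {}
    for g in genes:
        by_chrom.setdefault(g[1], []).append(g)
    for chrom in sorted(by_chrom):
        for rank, (gid, chrom_, start, end, strand) in enumerate(
            sorted(by_chrom[chrom], key=lambda g: (g[2], g[3], g[0])), start=1
        ):
            models.append(GeneModel(gid, chrom_, start, end, strand, rank))
    return models


def nxx_statistic(lengths: Sequence[int], x: float) -> int:
    """Nxx length: shortest sequence in the set covering x% of the total.

    Sort descending, cumulate, and return the first length whose running
    sum reaches at least ``x`` percent of the total (>= comparison, so
    ties are handled deterministically).  N50 and N90 are ``x=50`` and
    ``x=90``.
    """
    if not lengths:
        raise ValueError("nxx_statistic requires a nonempty length list")
    if not 0 < x < 100:
        raise ValueError("x must be in (0, 100)")
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    threshold = sum(lengths) * x / 100.0
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc >= threshold:
            return length
    raise AssertionError("unreachable: cumulative sum must reach total")


def assembly_summary(
    records: Iterable[SequenceRecord], min_len_bp: int = 1000
) -> AssemblySummary:
    """Summarise an assembly over sequences of at least ``min_len_bp``.

    ``gap_length_bp`` counts N residues; ``gc_fraction`` is
    (G+C)/(A+C+G+T), excluding N and other ambiguity codes from the
    denominator.
    """
    kept = [r for r in records if r.kind == "nucleotide" and len(r) >= min_len_bp]
    if not kept:
        raise ValueError(f"no sequence of length >= {min_len_bp} bp")
    counts: Counter[str] = Counter()
    for rec in kept:
        counts.update(rec.residues)
    lengths = [len(r) for r in kept]
    acgt = sum(counts[b] for b in "ACGT")
    gc = counts["G"] + counts["C"]
    return AssemblySummary(
        seq_count=len(kept),
        total_length_bp=sum(lengths),
        n50_bp=nxx_statistic(lengths, 50),
        n90_bp=nxx_statistic(lengths, 90),
        max_bp=max(lengths),
        gc_fraction=(gc / acgt) if acgt else 0.0,
        gap_length_bp=counts["N"],
    )


def gene_density(gene_count: int, span_mb: float) -> float:
    """Genes per megabase; rounding is left to the reporting layer."""
    if span_mb <= 0:
        raise ValueError("span_mb must be positive")
    if gene_count < 0:
        raise ValueError("gene_count must be >= 0")
    return gene_count / span_mb


def genome_count_ratio(count_a: int, count_b: int) -> float:
    """Ratio of gene counts between two genomes (a / b)."""
    if count_b <= 0:
        raise ValueError("count_b must be positive")
    return count_a / count_b


def write_summary(summary: AssemblySummary, tsv_path=None, json_path=None) -> None:
    """Write a (metric, value) TSV and/or a JSON mirror of the summary."""
    d = summary.to_dict()
    if tsv_path is not None:
        lines = ["metric\tvalue"] + [f"{k}\t{v}" for k, v in d.items()]
        Path(tsv_path).write_text("\n".join(lines) + "\n")
    if json_path is not None:
        Path(json_path).write_text(json.dumps(d, indent=2) + "\n")
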