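"""Collinear-block detection: which gene pairs enter the 4DTv distribution.

Candidate homologous gene pairs are found by a shared k-mer screen over
the two proteomes, scored by local alignment (BLOSUM62, affine gaps),
normalised to C-scores (score over the best score involving either
gene), filtered at C > 0.5, and chained by dynamic programming over
gene ranks into collinear blocks.  Gene pairs inside blocks are the
syntenic pairs whose 4DTv distances date duplication events.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .seqio_stats import SequenceRecord

__all__ = [
    "AnchorHit",
    "RankedAnchor",
    "CollinearBlock",
    "score_protein_pairs",
    "assign_c_scores",
    "c_score_filter",
    "chain_anchors",
    "blocks_to_pairs",
]


@dataclass(frozen=True)
class AnchorHit:
    """A scored candidate homologous gene pair.

    ``c_score`` is score / max(best score of gene_a, best score of
    gene_b) over the whole hit set, so a reciprocal best pair has
    c_score 1.0.
    """

    gene_a: str
    gene_b: str
    score: float
    c_score: float | None = None

    def __post_init__(self) -> None:
        if self.score <= 0:
            raise ValueError("anchor score must be positive")
        if self.c_score is not None and not 0 < self.c_score <= 1:
            raise ValueError("c_score must lie in (0, 1]")


@dataclass(frozen=True)
class RankedAnchor:
    """An anchor placed by gene rank on one chromosome pair."""

    gene_a: str
    gene_b: str
    rank_a: int
    rank_b: int
    score: float = 1.0


@dataclass(frozen=True)
class CollinearBlock:
    """A chained run of anchors, monotone in both genomes.

    ``orientation`` is ``"parallel"`` (rank_b increasing with rank_a) or
    ``"antiparallel"`` (rank_b decreasing: an inverted segment).
    """

    chrom_a: str
    chrom_b: str
    anchors: tuple[RankedAnchor, ...]
    orientation: str

    def __post_init__(self) -> None:
        ra = [a.rank_a for a in self.anchors]
        rb = [a.rank_b for a in self.anchors]
        if any(y <= x for x, y in zip(ra, ra[1:])):
            raise ValueError("block not strictly increasing in rank_a")
        inc = all(y > x for x, y in zip(rb, rb[1:]))
        dec = all(y < x for x, y in zip(rb, rb[1:]))
        if self.orientation == "parallel" and not inc:
            raise ValueError("parallel block not increasing in rank_b")
        if self.orientation == "antiparallel" and not dec:
            raise ValueError("antiparallel block not decreasing in rank_b")
        if self.orientation not in ("parallel", "antiparallel"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def size(self) -> int:
        return len(self.anchors)

    @property
    def total_score(self) -> float:
        return sum(a.score for a in self.anchors)


def _build_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def score_protein_pairs(
    proteome_a: Sequence[SequenceRecord],
    proteome_b: Sequence[SequenceRecord],
    min_score: float = 50.0,
    k: int = 5,
) -> list[AnchorHit]:
    """Score candidate protein pairs sharing at least one k-mer.

    Pairs are screened by exact shared k-mers (k=5 by default), scored
    by local alignment with BLOSUM62 and affine gap penalties (-11 open,
    -1 extend), filtered at ``min_score``, and annotated with C-scores.
    Duplicate gene copies yield one hit per pair, so multiplicity is
    preserved for the C-score filter to arbitrate.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("empty proteome")
    aligner = _build_aligner()
    index_b: dict[str, list[int]] = {}
    for j, rec in enumerate(proteome_b):
        for kmer in _kmers(rec.residues, k):
            index_b.setdefault(kmer, []).append(j)
    hits: list[AnchorHit] = []
    for rec_a in proteome_a:
        candidates: set[int] = set()
        for kmer in _kmers(rec_a.residues, k):
            candidates.update(index_b.get(kmer, ()))
        for j in sorted(candidates):
            rec_b = proteome_b[j]
            score = aligner.score(rec_a.residues, rec_b.residues)
            if score >= min_score:
                hits.append(AnchorHit(rec_a.id, rec_b.id, float(score)))
    return assign_c_scores(hits)


def assign_c_scores(hits: Iterable[AnchorHit]) -> list[AnchorHit]:
    """Attach C-scores: score over the best score involving either gene."""
    hits = list(hits)
    best_a: dict[str, float] = {}
    best_b: dict[str, float] = {}
    for h in hits:
        best_a[h.gene_a] = max(best_a.get(h.gene_a, 0.0), h.score)
        best_b[h.gene_b] = max(best_b.get(h.gene_b, 0.0), h.score)
    return [
        replace(h, c_score=h.score / max(best_a[h.gene_a], best_b[h.gene_b]))
        for h in hits
    ]


def c_score_filter(hits: Iterable[AnchorHit], threshold: float = 0.5) -> list[AnchorHit]:
    """Keep hits with C-score strictly above ``threshold`` (default 0.5)."""
    out = []
    for h in hits:
        if h.c_score is None:
            raise ValueError("hit lacks a c_score; call assign_c_scores first")
        if h.c_score > threshold:
            out.append(h)
    return out


def _best_chain(
    anchors: list[RankedAnchor], orientation: str, max_gap: int
) -> list[int]:
    """Best (largest, then highest-scoring) monotone chain by DP.

    Anchors must be pre-sorted by (rank_a, rank_b).  Adjacent chain
    members must advance rank_a by 1..max_gap and rank_b by 1..max_gap
    in the direction given by ``orientation``.  Returns indices into
    ``anchors``; ties break toward the earliest predecessor so the
    result is deterministic.
    """
    n = len(anchors)
    best_len = [1] * n
    best_score = [a.score for a in anchors]
    parent = [-1] * n
    for i in range(n):
        ai = anchors[i]
        for j in range(i):
            aj = anchors[j]
            da = ai.rank_a - aj.rank_a
            if not 0 < da <= max_gap:
                continue
            db = ai.rank_b - aj.rank_b if orientation == "parallel" else aj.rank_b - ai.rank_b
            if not 0 < db <= max_gap:
                continue
            cand = (best_len[j] + 1, best_score[j] + ai.score)
            if cand > (best_len[i], best_score[i]):
                best_len[i], best_score[i] = cand
                parent[i] = j
    end = max(range(n), key=lambda i: (best_len[i], best_score[i], -i))
    chain = []
    while end != -1:
        chain.append(end)
        end = parent[end]
    return chain[::-1]


def chain_anchors(
    anchors: Sequence[RankedAnchor],
    max_gap: int = 25,
    min_block: int = 5,
    chrom_a: str = "",
    chrom_b: str = "",
) -> list[CollinearBlock]:
    """Chain anchors on one chromosome pair into collinear blocks.

    Repeatedly extracts the best chain (largest, then highest total
    score, parallel before antiparallel on exact ties), removes its
    anchors, and stops when no remaining chain reaches ``min_block``.
    Each anchor therefore belongs to at most one block.  Gaps are
    measured in gene ranks, not base pairs.
    """
    remaining = sorted(anchors, key=lambda a: (a.rank_a, a.rank_b, a.gene_a, a.gene_b))
    blocks: list[CollinearBlock] = []
    while remaining:
        best: tuple[tuple[int, float, int], str, list[int]] | None = None
        for pref, orientation in enumerate(("parallel", "antiparallel")):
            idx = _best_chain(remaining, orientation, max_gap)
            size = len(idx)
            score = sum(remaining[i].score for i in idx)
            key = (size, score, -pref)
            if best is None or key > best[0]:
                best = (key, orientation, idx)
        (size, _, _), orientation, idx = best
        if size < min_block:
            break
        chosen = [remaining[i] for i in idx]
        blocks.append(
            CollinearBlock(chrom_a, chrom_b, tuple(chosen), orientation)
        )
        picked = set(idx)
        remaining = [a for i, a in enumerate(remaining) if i not in picked]
    return blocks


def blocks_to_pairs(blocks: Iterable[CollinearBlock]) -> list[tuple[str, str]]:
    """Flat, deduplicated (gene_a, gene_b) list from all block anchors."""
    seen: set[tuple[str, str]] = set()
    pairs: list[tuple[str, str]] = []
    for block in blocks:
        for a in block.anchors:
            key = (a.gene_a, a.gene_b)
            if key not in seen:
                seen.add(key)
                pairs.append(key)
    return pairs
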