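"""Genetic-code degeneracy, the 4DTv statistic, and the Kimura distance.

The 4DTv statistic is the transversion proportion at fourfold-degenerate
codon third positions of an in-frame pairwise alignment.  Because the
third position of a fourfold-degenerate codon is free of amino-acid
constraint, 4DTv approximates neutral divergence and is the standard
x-axis for dating whole-genome duplications from paralog pairs.

The Kimura two-parameter (K2P) distance corrects observed transition
(P) and transversion (Q) proportions for multiple hits:

    d = -1/2 * ln( (1 - 2P - Q) * sqrt(1 - 2Q) )
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from Bio.Data import CodonTable

from .errors import SaturationError

__all__ = [
    "GeneticCode",
    "STANDARD_CODE",
    "CodonPairAlignment",
    "FourDTvResult",
    "KimuraResult",
    "is_fourfold_degenerate",
    "classify_substitution",
    "four_dtv",
    "kimura_distance",
    "hky_correct_4dtv",
]

_BASES = "ACGT"
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
GAP = "-"


class GeneticCode:
    """A codon translation table with derived third-position degeneracy.

    Degeneracy is computed from the table itself (a codon is fourfold
    degenerate iff all four third-position variants translate to the
    same amino acid), not hard-coded per codon family.
    """

    def __init__(self, table_id: int = 1):
        table = CodonTable.unambiguous_dna_by_id[table_id]
        self.codon_to_aa: dict[str, str] = dict(table.forward_table)
        self.stop_codons: frozenset[str] = frozenset(table.stop_codons)
        if len(self.codon_to_aa) + len(self.stop_codons) != 64:
            raise ValueError("genetic code table does not cover 64 codons")
        self._fourfold = frozenset(
            c for c in self.codon_to_aa if self._is_4d(c)
        )

    def _is_4d(self, codon: str) -> bool:
        aas = {self.codon_to_aa.get(codon[:2] + b) for b in _BASES}
        return len(aas) == 1 and None not in aas

    @property
    def fourfold_codons(self) -> frozenset[str]:
        return self._fourfold


STANDARD_CODE = GeneticCode(1)


def is_fourfold_degenerate(codon: str, code: GeneticCode = STANDARD_CODE) -> bool:
    """True iff the codon's third position is fourfold degenerate.

    Codons containing gaps or ambiguity codes return False (the site is
    skipped, not an error); under the standard code exactly 32 of the 64
    codons qualify.
    """
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        return False
    return codon in code.fourfold_codons


def classify_substitution(base_x: str, base_y: str) -> str:
    """Classify a base pair as identity / transition / transversion.

    Purine<->purine or pyrimidine<->pyrimidine changes are transitions;
    cross-class changes are transversions.  Gaps or ambiguity codes give
    ``"unscored"``.
    """
    if base_x not in _BASES or base_y not in _BASES:
        return "unscored"
    if base_x == base_y:
        return "identity"
    same_class = ({base_x, base_y} <= _PURINES) or ({base_x, base_y} <= _PYRIMIDINES)
    return "transition" if same_class else "transversion"


@dataclass(frozen=True)
class CodonPairAlignment:
    """Two in-frame aligned coding sequences.

    Lengths must be equal and a multiple of three, and gaps must cover
    whole codons (each codon is either ``---`` or gap-free) so the
    reading frame is preserved across the alignment.
    """

    seq_a: str
    seq_b: str
    pair_id: str = ""

    def __post_init__(self) -> None:
        a, b = self.seq_a.upper(), self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise ValueError(f"pair {self.pair_id!r}: aligned lengths differ")
        if len(a) % 3 != 0:
            raise ValueError(f"pair {self.pair_id!r}: length not a multiple of 3")
        for seq in (a, b):
            for i in range(0, len(seq), 3):
                codon = seq[i : i + 3]
                if GAP in codon and codon != GAP * 3:
                    raise ValueError(
                        f"pair {self.pair_id!r}: gap does not cover a whole codon "
                        f"at position {i}"
                    )

    def codons(self):
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


@dataclass(frozen=True)
class FourDTvResult:
    pair_id: str
    sites_4d: int
    transversions: int
    v: float | None
    corrected_v: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.transversions <= max(self.sites_4d, 0):
            raise ValueError("transversions outside [0, sites_4d]")


@dataclass(frozen=True)
class KimuraResult:
    P: float
    Q: float
    d: float
    sites: int


def four_dtv(pair: CodonPairAlignment, code: GeneticCode = STANDARD_CODE) -> FourDTvResult:
    """Transversion proportion at comparable fourfold-degenerate sites.

    A codon column is a comparable 4D site iff both codons are gap-free
    and unambiguous, both are fourfold degenerate at the third position,
    and the two codons agree at their first two positions (so both third
    positions are synonymous for the same amino acid).  With zero
    comparable sites ``v`` is None.
    """
    fourfold = code.fourfold_codons
    sites = 0
    tv = 0
    for ca, cb in pair.codons():
        if ca not in fourfold or cb not in fourfold:
            continue
        if ca[:2] != cb[:2]:
            continue
        sites += 1
        if classify_substitution(ca[2], cb[2]) == "transversion":
            tv += 1
    v = (tv / sites) if sites else None
    return FourDTvResult(pair.pair_id, sites, tv, v)


def kimura_distance(seq_a: str, seq_b: str) -> KimuraResult:
    """Kimura two-parameter distance over comparable aligned columns.

    Columns where either base is a gap or ambiguity code are excluded
    from both numerator and denominator.  Raises
    :class:`SaturationError` when the log arguments leave their domain.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    sites = ts = tv = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        kind = classify_substitution(x, y)
        if kind == "unscored":
            continue
        sites += 1
        if kind == "transition":
            ts += 1
        elif kind == "transversion":
            tv += 1
    if sites == 0:
        raise ValueError("no comparable sites")
    P, Q = ts / sites, tv / sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P distance undefined for P={P:.4f}, Q={Q:.4f} (saturated)"
        )
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return KimuraResult(P=P, Q=Q, d=d, sites=sites)


def hky_correct_4dtv(
    result: FourDTvResult, base_composition: Mapping[str, float]
) -> float:
    """Multiple-hit correction of the raw 4DTv proportion.

    Uses the transversion-only distance under unequal base frequencies:
    with purine frequency piR and pyrimidine frequency piY, the expected
    transversion proportion saturates at 2*piR*piY, and

        v_corrected = -2*piR*piY * ln(1 - v / (2*piR*piY))

    For equal frequencies this reduces to -(1/2) ln(1 - 2v).  Off by
    default in the pipeline; the raw proportion is the primary output.
    """
    if result.v is None:
        raise ValueError("v undefined (no comparable 4D sites)")
    total = sum(base_composition.get(b, 0.0) for b in _BASES)
    if total <= 0:
        raise ValueError("base composition empty")
    pi_r = sum(base_composition.get(b, 0.0) for b in _PURINES) / total
    pi_y = 1.0 - pi_r
    cap = 2.0 * pi_r * pi_y
    if result.v >= cap:
        raise SaturationError(
            f"4DTv {result.v:.4f} at or beyond saturation bound {cap:.4f}"
        )
    return -cap * math.log(1.0 - result.v / cap)
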