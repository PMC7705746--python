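"""Allopolyploid subgenome partitioning by homology identity.

An allotetraploid carries two parental chromosome sets.  When each
chromosome's genes are aligned against a diploid reference genome, the
subgenome inherited from the parent closer to the reference shows
systematically higher percent identity.  Chromosomes are ranked by
median identity and split at the largest gap in the ranked medians; the
higher-identity group is labelled A, the rest B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import PartitionAmbiguityError

__all__ = ["IdentityProfile", "SubgenomePartition", "identity_profile", "partition_subgenomes"]


@dataclass(frozen=True)
class IdentityProfile:
    """Per-gene best-hit identities (percent) for one chromosome."""

    chrom: str
    identities: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.identities:
            raise ValueError(f"chromosome {self.chrom!r}: empty identity profile")
        if any(not 0.0 <= v <= 100.0 for v in self.identities):
            raise ValueError(f"chromosome {self.chrom!r}: identity outside [0, 100]")

    @property
    def median(self) -> float:
        return float(np.median(self.identities))

    @property
    def mean(self) -> float:
        return float(np.mean(self.identities))


@dataclass(frozen=True)
class SubgenomePartition:
    """Assignment of chromosomes to subgenomes A (higher identity) and B."""

    assignment: dict[str, str]
    medians: dict[str, float]
    separation: float

    def group(self, label: str) -> list[str]:
        return sorted(c for c, g in self.assignment.items() if g == label)


def identity_profile(table: pd.DataFrame) -> list[IdentityProfile]:
    """Group a (chrom, gene_id, identity_pct) table into per-chromosome profiles.

    Input row order is preserved within each chromosome.  Chromosomes
    with no genes (possible with categorical chrom columns) are excluded
    with a warning; an empty table is an error.
    """
    required = {"chrom", "gene_id", "identity_pct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"identity table lacks columns: {sorted(missing)}")
    if table.empty:
        raise ValueError("identity table is empty")
    if (table["identity_pct"] < 0).any() or (table["identity_pct"] > 100).any():
        raise ValueError("identity values must lie in [0, 100]")
    profiles = []
    for chrom, sub in table.groupby("chrom", sort=False, observed=False):
        if sub.empty:
            warnings.warn(f"chromosome {chrom!r} has no genes; excluded")
            continue
        profiles.append(
            IdentityProfile(str(chrom), tuple(float(v) for v in sub["identity_pct"]))
        )
    return profiles


def partition_subgenomes(
    profiles: Sequence[IdentityProfile], min_separation: float = 0.0
) -> SubgenomePartition:
    """Split chromosomes into A/B at the largest gap in ranked medians.

    Chromosomes are ordered by median identity (ties broken by mean,
    then name); the partition boundary is the largest gap between
    adjacent ranked medians, and the higher-median group is A.  If the
    largest gap is <= ``min_separation`` (default 0, i.e. all medians
    equal) the chromosomes do not separate and
    :class:`PartitionAmbiguityError` is raised.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two chromosomes to partition")
    ranked = sorted(profiles, key=lambda p: (-p.median, -p.mean, p.chrom))
    medians = [p.median for p in ranked]
    gaps = [medians[i] - medians[i + 1] for i in range(len(medians) - 1)]
    split = max(range(len(gaps)), key=lambda i: (gaps[i], -i))
    if gaps[split] <= min_separation:
        raise PartitionAmbiguityError(
            f"largest median gap {gaps[split]:.4g} <= min_separation "
            f"{min_separation:.4g}; chromosomes do not separate"
        )
    assignment = {
        p.chrom: ("A" if i <= split else "B") for i, p in enumerate(ranked)
    }
    return SubgenomePartition(
        assignment=assignment,
        medians={p.chrom: p.median for p in ranked},
        separation=gaps[split],
    )
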