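"""Simulators generating inputs with the structure the analyses assume.

Sequences evolve under a continuous-time two-rate (Kimura) substitution
process: transitions at rate alpha per site per year, each of the two
possible transversions at rate beta.  Closed-form transition
probabilities for elapsed time tau are

    p_same    = 1/4 + 1/4 e^(-4 b tau) + 1/2 e^(-2 (a + b) tau)
    p_ts      = 1/4 + 1/4 e^(-4 b tau) - 1/2 e^(-2 (a + b) tau)
    p_tv_each = 1/4 - 1/4 e^(-4 b tau)

so a pair of descendants separated by total time T shows an expected
transversion proportion of (1 - e^(-4 b T)) / 2 at neutral sites, which
is what the planted-peak helpers invert.

Coding-sequence simulation samples ancestors codon-wise from sense
codons and slows codon positions 1-2 by a fixed factor relative to
position 3, mimicking purifying selection on nonsynonymous sites; this
is what keeps first-two-position codon identity (and hence comparable
fourfold-degenerate sites) abundant at high synonymous divergence, as
in real proteomes.  All generators are bit-reproducible given a seed;
one global seed expands to per-component substreams by fixed offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chronology import LTRPair
from .codon_model import STANDARD_CODE, CodonPairAlignment
from .seqio_stats import SequenceRecord
from .synteny import RankedAnchor

__all__ = [
    "SimulationConfig",
    "evolve_sequence_pair",
    "random_cds",
    "time_for_expected_4dtv",
    "expected_4dtv",
    "simulate_wgd_pairs",
    "simulate_ltr_elements",
    "simulate_allopolyploid",
    "simulate_scaffold_set",
    "simulate_anchor_genome",
]

_NUC = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
# transition partner per base index (A<->G, C<->T)
_TS_PARTNER = np.array([2, 3, 0, 1])
# the two transversion targets per base index
_TV_TARGETS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])

_SENSE_CODONS = sorted(STANDARD_CODE.codon_to_aa)
_SENSE_TRIPLES = np.array(
    [[_BASE_INDEX[b] for b in codon] for codon in _SENSE_CODONS]
)

# substream offsets so one global seed drives independent components
_STREAM_WGD, _STREAM_LTR, _STREAM_ALLO, _STREAM_SCAF, _STREAM_ANCHOR = 1, 2, 3, 4, 5


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for the divergence-cohort (WGD) CDS simulation.

    Defaults mirror the study system: three divergence cohorts whose
    expected 4DTv values sit at the observed peaks (0.01, 0.08, 0.48),
    a mid-interval Salicaceae synonymous rate of 0.88e-9 /site/year
    split as kappa = alpha/beta = 2, and coding pairs of 800 codons.
    """

    seed: int = 0
    alpha: float = 0.44e-9
    beta: float = 0.22e-9
    expected_peaks: tuple[float, ...] = (0.01, 0.08, 0.48)
    weights: tuple[float, ...] | None = None
    n_pairs: int = 9000
    seq_len: int = 2400
    pos12_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta <= 0:
            raise ValueError("rates must be positive")
        if self.seq_len % 3 != 0:
            raise ValueError("seq_len must be a multiple of 3")
        if self.weights is not None and len(self.weights) != len(self.expected_peaks):
            raise ValueError("weights must match expected_peaks")

    @property
    def kappa(self) -> float:
        return self.alpha / self.beta

    @property
    def times(self) -> tuple[float, ...]:
        """Per-branch divergence times (years) planted for each cohort."""
        return tuple(
            time_for_expected_4dtv(v, self.beta) for v in self.expected_peaks
        )


def _probs(alpha: float, beta: float, tau):
    e4 = np.exp(-4.0 * beta * np.asarray(tau, dtype=float))
    e2 = np.exp(-2.0 * (alpha + beta) * np.asarray(tau, dtype=float))
    p_same = 0.25 + 0.25 * e4 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e4 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e4
    return p_same, p_ts, p_tv_each


def _evolve_idx(
    idx: np.ndarray,
    time_years: float,
    alpha: float,
    beta: float,
    rng: np.random.Generator,
    rate_scale: np.ndarray | None = None,
) -> np.ndarray:
    """Evolve an array of base indices for ``time_years`` on one branch."""
    tau = time_years if rate_scale is None else time_years * rate_scale
    p_same, p_ts, p_tv = _probs(alpha, beta, tau)
    r = rng.random(idx.shape)
    pick_tv2 = rng.random(idx.shape) < 0.5
    out = idx.copy()
    is_ts = (r >= p_same) & (r < p_same + p_ts)
    is_tv = r >= p_same + p_ts
    out[is_ts] = _TS_PARTNER[idx[is_ts]]
    tv_choice = np.where(pick_tv2, 1, 0)
    out[is_tv] = _TV_TARGETS[idx[is_tv], tv_choice[is_tv]]
    return out


def _to_str(idx: np.ndarray) -> str:
    return "".join(_NUC[idx])


def _from_str(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in seq.upper()])
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in ancestor sequence") from exc


def evolve_sequence_pair(
    ancestor: str,
    time_years: float,
    alpha: float,
    beta: float,
    seed: int = 0,
    rate_scale: np.ndarray | None = None,
) -> tuple[str, str]:
    """Two independent descendants of ``ancestor`` after ``time_years`` each.

    Deterministic given the seed.  ``rate_scale`` optionally multiplies
    the elapsed time per site (used for the codon-position rate cycle).
    """
    idx = _from_str(ancestor)
    rng = _rng(seed, _STREAM_WGD)
    d1 = _evolve_idx(idx, time_years, alpha, beta, rng, rate_scale)
    d2 = _evolve_idx(idx, time_years, alpha, beta, rng, rate_scale)
    return _to_str(d1), _to_str(d2)


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """A random coding sequence: codons drawn uniformly from the 61 sense codons."""
    picks = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return _to_str(_SENSE_TRIPLES[picks].reshape(-1))


def expected_4dtv(beta: float, total_time_years: float) -> float:
    """Expected raw transversion proportion after total divergence T."""
    return 0.5 * (1.0 - math.exp(-4.0 * beta * total_time_years))


def time_for_expected_4dtv(v: float, beta: float) -> float:
    """Per-branch time (years) so two descendants show expected 4DTv ``v``."""
    if not 0 <= v < 0.5:
        raise ValueError("expected 4DTv must lie in [0, 0.5)")
    return -math.log(1.0 - 2.0 * v) / (4.0 * beta) / 2.0


def simulate_wgd_pairs(
    config: SimulationConfig,
) -> tuple[list[CodonPairAlignment], pd.DataFrame]:
    """CDS pairs from a mixture of divergence cohorts, plus a truth table.

    Pairs are assigned to cohorts by the configured mixture weights;
    each pair descends from a fresh random coding ancestor, with codon
    positions 1-2 evolving at ``pos12_scale`` times the position-3 rate.
    The truth table records each pair's cohort, planted per-branch time,
    and the cohort's expected 4DTv.
    """
    rng = _rng(config.seed, _STREAM_WGD)
    n_cohorts = len(config.expected_peaks)
    weights = np.full(n_cohorts, 1.0 / n_cohorts) if config.weights is None else (
        np.asarray(config.weights, dtype=float) / sum(config.weights)
    )
    cohort_of = rng.choice(n_cohorts, size=config.n_pairs, p=weights)
    n_codons = config.seq_len // 3
    scale = np.tile([config.pos12_scale, config.pos12_scale, 1.0], n_codons)
    pairs: list[CodonPairAlignment] = []
    rows = []
    times = config.times
    for i in range(config.n_pairs):
        c = int(cohort_of[i])
        anc = _from_str(random_cds(n_codons, rng))
        d1 = _evolve_idx(anc, times[c], config.alpha, config.beta, rng, scale)
        d2 = _evolve_idx(anc, times[c], config.alpha, config.beta, rng, scale)
        pair_id = f"pair{i:05d}"
        pairs.append(CodonPairAlignment(_to_str(d1), _to_str(d2), pair_id))
        rows.append(
            {
                "pair_id": pair_id,
                "cohort": c,
                "time_years": times[c],
                "expected_4dtv": config.expected_peaks[c],
            }
        )
    return pairs, pd.DataFrame(rows)


def simulate_ltr_elements(
    ages_my,
    clock_rate: float = 7.3e-9,
    n_per_age: int = 100,
    ltr_len: int = 1000,
    seed: int = 0,
    kappa: float = 2.0,
) -> tuple[list[LTRPair], pd.DataFrame]:
    """LTR element pairs whose copies diverged since insertion.

    Each element's 5' and 3' LTRs descend from one ancestral LTR with a
    per-branch time equal to the planted age, under a total substitution
    rate (alpha + 2 beta) equal to ``clock_rate``, so the K2P distance
    between the copies has expectation 2 * clock_rate * age.
    """
    rng = _rng(seed, _STREAM_LTR)
    beta = clock_rate / (kappa + 2.0)
    alpha = kappa * beta
    elements: list[LTRPair] = []
    rows = []
    for age in ages_my:
        if age < 0:
            raise ValueError("ages must be >= 0")
        t = float(age) * 1.0e6
        for j in range(n_per_age):
            anc = rng.integers(0, 4, size=ltr_len)
            l5 = _evolve_idx(anc, t, alpha, beta, rng)
            l3 = _evolve_idx(anc, t, alpha, beta, rng)
            eid = f"ltr_{age:g}my_{j:04d}"
            elements.append(LTRPair(eid, _to_str(l5), _to_str(l3)))
            rows.append({"element_id": eid, "age_my": float(age)})
    return elements, pd.DataFrame(rows)


def simulate_allopolyploid(
    ident_a_pct: float = 92.0,
    ident_b_pct: float = 85.0,
    n_chrom_per_subgenome: int = 19,
    genes_per_chrom: int = 101,
    sd_pct: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene identity table for a two-subgenome chromosome set.

    Gene identities are drawn Normal(level, sd) and clipped to [0, 100];
    subgenome A uses ``ident_a_pct``, B ``ident_b_pct``.  The truth
    table carries the planted label per chromosome and a ``separable``
    flag (False when the two levels coincide).
    """
    for v in (ident_a_pct, ident_b_pct):
        if not 0 <= v < 100:
            raise ValueError("identity levels must lie in [0, 100)")
    rng = _rng(seed, _STREAM_ALLO)
    separable = ident_a_pct != ident_b_pct
    rows, truth = [], []
    for label, level in (("A", ident_a_pct), ("B", ident_b_pct)):
        for c in range(1, n_chrom_per_subgenome + 1):
            chrom = f"chr{c:02d}{label}"
            vals = np.clip(rng.normal(level, sd_pct, size=genes_per_chrom), 0.0, 100.0)
            for g, v in enumerate(vals, start=1):
                rows.append(
                    {"chrom": chrom, "gene_id": f"{chrom}_g{g:04d}", "identity_pct": float(v)}
                )
            truth.append({"chrom": chrom, "subgenome": label, "separable": separable})
    return pd.DataFrame(rows), pd.DataFrame(truth)


def simulate_scaffold_set(
    n: int | None = None,
    lengths=None,
    gap_rate: float = 0.0,
    seed: int = 0,
    mean_length_bp: float = 30000.0,
    sigma_log: float = 1.0,
    mean_gap_run_bp: int = 50,
) -> tuple[list[SequenceRecord], dict]:
    """Random scaffolds with planted N-gap runs, plus truth totals.

    Either explicit ``lengths`` or a count ``n`` (lengths drawn
    log-normal around ``mean_length_bp``) must be given.  ``gap_rate``
    is the expected fraction of N residues, planted as geometric runs
    of mean ``mean_gap_run_bp``.
    """
    rng = _rng(seed, _STREAM_SCAF)
    if lengths is None:
        if n is None or n < 1:
            raise ValueError("give explicit lengths or n >= 1")
        mu = math.log(mean_length_bp) - sigma_log**2 / 2.0
        lengths = np.maximum(
            rng.lognormal(mu, sigma_log, size=n).astype(int), 100
        ).tolist()
    lengths = [int(l) for l in lengths]
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    records: list[SequenceRecord] = []
    total_gap = 0
    for i, length in enumerate(lengths):
        seq = _NUC[rng.integers(0, 4, size=length)]
        if gap_rate > 0:
            n_runs = rng.poisson(gap_rate * length / mean_gap_run_bp)
            for _ in range(n_runs):
                run = 1 + rng.geometric(1.0 / mean_gap_run_bp)
                start = int(rng.integers(0, max(length - run, 1)))
                seq[start : start + run] = "N"
        s = "".join(seq)
        total_gap += s.count("N")
        records.append(SequenceRecord(f"scaffold{i + 1:04d}", s))
    truth = {
        "lengths": lengths,
        "total_length_bp": sum(lengths),
        "gap_length_bp": total_gap,
    }
    return records, truth


def simulate_anchor_genome(
    n_chrom_pairs: int = 4,
    blocks_per_pair: int = 2,
    block_size: int = 30,
    chrom_len_ranks: int = 400,
    skip_prob: float = 0.2,
    max_skip: int = 3,
    n_noise_per_pair: int = 30,
    seed: int = 0,
) -> tuple[dict[tuple[str, str], list[RankedAnchor]], set[tuple[str, str]]]:
    """Anchors with planted duplicated (collinear) blocks plus noise.

    For each chromosome pair, ``blocks_per_pair`` collinear runs of
    ``block_size`` anchors are planted (alternating parallel and
    antiparallel orientation, with occasional rank skips of up to
    ``max_skip``), then ``n_noise_per_pair`` anchors are scattered at
    random ranks.  Returns anchors grouped by chromosome pair and the
    set of planted (gene_a, gene_b) pairs.
    """
    rng = _rng(seed, _STREAM_ANCHOR)
    anchors_by_pair: dict[tuple[str, str], list[RankedAnchor]] = {}
    truth: set[tuple[str, str]] = set()
    span = block_size * (1 + max_skip) + 5
    for p in range(1, n_chrom_pairs + 1):
        key = (f"chrA{p}", f"chrB{p}")
        anchors: list[RankedAnchor] = []
        region = chrom_len_ranks // blocks_per_pair
        for b in range(blocks_per_pair):
            parallel = (b % 2 == 0)
            start_a = b * region + int(rng.integers(1, max(region - span, 2)))
            start_b = b * region + int(rng.integers(1, max(region - span, 2)))
            ra, rb = start_a, start_b + (0 if parallel else span)
            for _ in range(block_size):
                gene_a = f"{key[0]}_g{ra:04d}"
                gene_b = f"{key[1]}_g{rb:04d}"
                anchors.append(RankedAnchor(gene_a, gene_b, ra, rb, score=2.0))
                truth.add((gene_a, gene_b))
                step_a = 1 + (int(rng.integers(1, max_skip + 1)) if rng.random() < skip_prob else 0)
                step_b = 1 + (int(rng.integers(1, max_skip + 1)) if rng.random() < skip_prob else 0)
                ra += step_a
                rb += step_b if parallel else -step_b
        for _ in range(n_noise_per_pair):
            ra = int(rng.integers(1, chrom_len_ranks + 1))
            rb = int(rng.integers(1, chrom_len_ranks + 1))
            anchors.append(
                RankedAnchor(f"{key[0]}_n{ra:04d}_{rb:04d}", f"{key[1]}_n{rb:04d}_{ra:04d}", ra, rb, score=1.0)
            )
        anchors_by_pair[key] = anchors
    return anchors_by_pair, truth
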