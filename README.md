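# wgdkit

Dating whole-genome duplications (WGDs) and retrotransposon insertions
from genome comparisons.

Allopolyploid plant genomes — the motivating case is the allotetraploid
Chinese willow, with 38 chromosomes split between two parental
subgenomes — record their history in the divergence of duplicated
sequence. `wgdkit` implements the computations that read that record:

- **4DTv distances** on collinear (syntenic) gene pairs. For two
  in-frame aligned coding sequences, the statistic *v* is the
  transversion proportion at fourfold-degenerate codon third positions
  (sites where any of the four bases encodes the same amino acid, so
  divergence is approximately neutral). Peaks in the distribution of
  *v* across thousands of paralog pairs mark duplication events.
- **Kimura two-parameter (K2P) distances**,
  *d* = −½ ln((1 − 2P − Q)·√(1 − 2Q)), correcting observed transition
  (P) and transversion (Q) proportions for multiple hits.
- **Molecular-clock conversion** of a distance to a time,
  *T* = *d* / (2R), with R in substitutions/site/year — divergence
  accumulates on both lineages. A rate interval gives a time interval.
- **Synteny detection**: protein pairs screened by shared 5-mers,
  scored by local alignment (BLOSUM62, affine gaps), filtered by
  C-score (score over the best score involving either gene, keep
  C > 0.5), and chained by dynamic programming over gene ranks into
  collinear blocks (parallel or antiparallel, i.e. inverted).
- **LTR insertion ages**: the two long terminal repeats of a
  retrotransposon are identical at insertion; their K2P divergence
  under a 7.3 × 10⁻⁹ /site/year clock dates the element,
  *T* = K / (2r).
- **Subgenome partitioning**: chromosomes ranked by the median percent
  identity of their genes against a diploid reference and split at the
  largest gap in the ranked medians; the higher-identity group is the
  A subgenome.
- **Assembly statistics**: N50/N90, GC content, gap totals, gene
  densities, and between-genome gene-count ratios.
- **Simulators** for every input: CDS pairs diverged in planted
  cohorts under a two-rate (transition/transversion) substitution
  process, LTR element pairs at planted ages, two-subgenome identity
  tables, and scaffold sets with planted gaps — each with a truth
  table, so every estimator can be validated by parameter recovery.

## Worked example

Date the distance peaks of a Salicaceae-like 4DTv distribution using
the family's synonymous-rate interval (0.67–1.09 × 10⁻⁹ /site/year):

```
$ wgdkit date --peak 0.48 --rate-low 0.67e-9 --rate-high 1.09e-9
{
  "peak": 0.48,
  "rate": 8.8e-10,
  "time_my": 272.72727272727275,
  "time_my_display": 273.0,
  "rate_low": 6.7e-10,
  "rate_high": 1.09e-09,
  "time_min_my": 220.18348623853208,
  "time_max_my": 358.2089552238806,
  "time_min_my_display": 220.0,
  "time_max_my_display": 358.0
}
```

A peak at 0.48 corresponds to a duplication 220–358 million years ago
(the fast rate bounds the time from below, the slow rate from above);
peaks at 0.08 and 0.01 date to 36.7–59.7 MY and 4.6–7.5 MY the same
way. The same arithmetic in the library:

```python
>>> import wgdkit as w
>>> [w.format_my(t) for t in w.divergence_time_range(0.08, w.SALICACEAE_CLOCK)]
[36.7, 59.7]
>>> res = w.four_dtv(w.CodonPairAlignment("GGTCCA", "GGGCCA"))
>>> res.sites_4d, res.transversions, res.v
(2, 1, 0.5)
>>> round(w.gene_density(23985, 252.68))   # A-subgenome genes per Mb
95
```

An end-to-end simulated run — plant two divergence cohorts, compute
4DTv per pair, detect the peaks:

```python
>>> cfg = w.SimulationConfig(seed=1, expected_peaks=(0.08, 0.48),
...                          n_pairs=6000, seq_len=2400)
>>> pairs, truth = w.simulate_wgd_pairs(cfg)
>>> values = [r.v for r in map(w.four_dtv, pairs) if r.v is not None]
>>> sorted(round(p.location, 4) for p in w.detect_peaks(values)[:2])
[0.0803, 0.4808]
```

Both planted peaks are recovered to well within one histogram bin
(0.01).

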