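# Methods

## Substitution model and distances

All distances assume a Kimura two-parameter (K2P) process: transitions
(A↔G, C↔T) at rate α per site per year, each of the two possible
transversions at rate β, total rate μ = α + 2β, κ = α/β. From observed
transition and transversion proportions P and Q over comparable aligned
columns, the distance is d = −½ ln((1 − 2P − Q)·√(1 − 2Q)). Columns
containing gaps or ambiguity codes are excluded from numerator and
denominator alike. When 1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0 the distance is
undefined and a saturation error is raised; downstream code reports
such elements with a null age rather than dropping them, so saturated
inputs remain auditable.

The 4DTv statistic is deliberately *uncorrected* by default: v is the
raw transversion proportion at comparable fourfold-degenerate sites,
because the clock arithmetic that reproduces the published dating
intervals applies the rate interval directly to raw peak locations. A
codon column counts as a comparable site only when both codons are
gap-free and unambiguous, both are fourfold degenerate at the third
position, and the two codons agree at their first two positions —
degeneracy at the third position is determined by the first two bases,
so agreement there guarantees both third positions are synonymous for
the same amino acid. This is the conservative convention; it discards
sites rather than risk comparing non-synonymous third positions. An
optional multiple-hit correction (`hky_correct_4dtv`) is provided
behind an explicit flag: with purine/pyrimidine frequencies πR, πY from
the observed base composition, v′ = −2πRπY ln(1 − v/(2πRπY)), which
reduces to −½ ln(1 − 2v) at equal frequencies.

Fourfold degeneracy is derived from the genetic-code table at run time
(all four third-position variants translate identically), not
hard-coded; under the standard code exactly 32 of 64 codons qualify.

## Clock conversion

A pairwise distance accumulates on both diverging lineages (or both
LTR copies of one element), so T = d / (2·rate). Two clocks are
bundled: the Salicaceae synonymous-rate interval 0.67–1.09 × 10⁻⁹
/site/year (midpoint 0.88 × 10⁻⁹ used where a single rate is needed)
for 4DTv peaks, and 7.3 × 10⁻⁹ /site/year for LTR elements. The fast
rate bounds a time interval from below and the slow rate from above.
Display rounding — one decimal below 100 MY, integer above — is
confined to the reporting layer; all files carry full precision.

## Peak detection

`detect_peaks` is histogram-first: a fixed-width histogram (default
0.01, the resolution of the smallest peak of interest) is scanned for
strict local maxima with count ≥ min_fraction·n (default 1%), and each
candidate's location is refined to the mode of a Gaussian KDE
(Scott bandwidth, fitted to all values) evaluated within ±2 bins of
the bin midpoint. The window is two bins rather than one because for a
broad peak (sd of several bins) the tallest histogram bin is a noisy
estimator that can sit two bins off the true mode, while the KDE mode
is stable; ±2 bins lets the refinement recover it. Degenerate inputs
(constant values, single occupied bin) fall back to the mean of the
values in the bin. Peaks are returned sorted by bin count, and
locations are invariant to input order by construction.

## Synteny

Candidate homologous protein pairs must share at least one exact
5-mer; candidates are scored by local alignment (BLOSUM62, gap open
−11, extend −1, via Biopython's PairwiseAligner) and kept above a raw
score threshold (default 50). The C-score of a hit is its score
divided by the best score involving either gene, and the default
filter keeps C > 0.5 — a deliberately self-contained replacement for
database-size-dependent E-values; the C-score filter is the
discriminating step. Chaining operates on gene *ranks* (ordinal
position along the chromosome), which makes gap parameters scale-free:
a dynamic program finds the largest (then highest-scoring) chain whose
consecutive anchors advance by 1–25 ranks in both genomes, separately
for parallel and antiparallel (inversion) orientation. Blocks are
extracted greedily — best chain first, its anchors removed, repeat —
so each anchor joins at most one block; chains under 5 anchors are
discarded. Ties break deterministically (parallel first, then earliest
start). The DP is validated against an exhaustive depth-first chain
enumeration on instances of ≤ 12 anchors.

## LTR insertion ages

The 5′ and 3′ LTRs of an element are globally aligned (match +2,
mismatch −1, gap open −5, extend −1), the K2P distance is computed
over ungapped columns, and the age is d/(2r). The per-element variance
of d scales as 1/length, so single short elements scatter widely;
class means over ≥ 50 kb aggregate LTR length per age class are the
meaningful estimate and recover planted ages within 5%.

## Subgenome partitioning

Chromosomes are ranked by the median of their genes' best-hit percent
identities to the reference (ties broken by mean, then name) and split
at the largest gap between adjacent ranked medians; the higher group
is labelled A. This mirrors the boxplot-inspection procedure the
partition emulates, is deterministic, and needs no seeds. Equal group
sizes (the 19+19 outcome) are reported, never enforced. If the largest
gap does not exceed `min_separation` (default 0, i.e. all medians
equal) the chromosomes do not separate and an ambiguity error is
raised; callers comparing two near-identical subgenome levels should
set `min_separation` to a meaningful identity difference (e.g. one
percentage point). Because the split acts on ranked medians, it is
invariant to input order, and invariant to strictly monotone
transforms of the identities insofar as the dominant gap remains
dominant — exact for well-separated groups (and medians of odd-sized
samples are order statistics, which commute with monotone maps), but
not guaranteed on data with no real group structure.

## Simulators: what they emulate, and what they do not

Sequences evolve by the closed-form K2P transition probabilities for
elapsed time τ per branch; two descendants of one ancestor separated
by total time T = 2τ then show an expected transversion proportion
(1 − e^(−4βT))/2 at neutral sites, which the planted-peak helper
inverts to choose cohort times. Defaults mirror the study system:
cohort expected 4DTv at the observed peaks (0.01, 0.08, 0.48), total
rate μ = 0.88 × 10⁻⁹ /site/year (interval midpoint), κ = 2, 800-codon
pairs. CDS ancestors are drawn codon-wise from the 61 sense codons, so
frames are valid and stop-free.

Codon positions 1–2 evolve at 0.1× the position-3 rate. This fixed
two-class rate cycle stands in for purifying selection on
nonsynonymous sites and is what keeps comparable fourfold-degenerate
sites abundant at high synonymous divergence — exactly the property
that makes 4DTv usable on real proteomes. Without it, at v ≈ 0.48 only
~3.5% of codons remain comparable, per-pair site counts of ~10–35
impose a k/m lattice on the v distribution, and the peak estimate
acquires a systematic +0.015 bias. The simulator still omits indels,
random across-site rate variation, explicit codon-level selection, GC
bias, and alignment error; passing recovery tests therefore
demonstrates estimator correctness under the model, not robustness to
real-data artefacts such as misalignment or rate heterogeneity.

LTR elements descend from a random ancestral LTR with per-branch time
equal to the planted age at total rate equal to the clock; the
recovery experiment uses 100 elements × 1 kb per age class (100 kb
aggregate). Identity tables draw per-gene identities Normal(level, 1%)
clipped to [0, 100], 19 chromosomes × 101 genes per subgenome at 92%
vs 85%. The anchor-genome generator plants collinear runs of 30
anchors (alternating orientation, rank skips of up to 3 at rate 0.2)
plus scattered noise anchors. Scaffold sets plant N-gap runs of
geometric length; truth tables record actual totals.

All generators derive their randomness from one seed expanded into
fixed per-component substreams, so runs are bit-reproducible and
components are decoupled.

## Problem sizes and numerical choices

The recovery experiments use 6000 CDS pairs × 2400 nt (two cohorts),
300 LTR elements × 1 kb, 38 chromosomes × 101 genes, and 10³ random
chaining instances of ≤ 12 anchors — sizes at which each estimator's
sampling error is comfortably inside the tolerance it is checked
against (peak locations within ±0.01; class-mean ages within 5%),
chosen prospectively by a small power analysis of the peak-mode
estimator. Nxx uses a ≥ threshold on the cumulative sum (deterministic
ties); GC denominators exclude N and ambiguity codes, which are gaps,
not composition; GFF3 coordinates are 1-based inclusive at the
boundary and half-open internally; alignment gaps must cover whole
codons or the pair is rejected at parse, since a frame-breaking gap
would silently corrupt every downstream codon.

## Known limitations

- The raw 4DTv statistic saturates near 0.5; cohorts much beyond the
  0.48 peak are not resolvable without the optional correction, and
  the correction itself diverges at the transversion ceiling.
- Chain extraction is greedy; overlapping duplications sharing anchors
  resolve deterministically but not necessarily optimally as a set.
- The subgenome split assumes exactly two identity levels; three-way
  mixtures (e.g. segmental introgression) would need the gap search
  generalised.
- The protein-pair screen requires an exact shared 5-mer, which can
  miss extremely diverged homolog pairs that an SSearch/Smith-Waterman
  scan of all pairs would find.
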