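# Methods

## Model and procedure

The pipeline treats an MHC allele as a black-box scoring function over
peptides (higher score = stronger predicted binding) and asks two
questions: *which alleles bind similar sets of viral peptides* (functional
clustering), and *which viruses does an allele present more or less than
chance* (epitope density). Both questions are answered entirely in terms
of binder sets derived from percentile ranks, so any deterministic
scoring backend can be plugged in; the package ships a synthetic
anchor-motif model so the full analysis runs and is testable without an
external predictor.

### Digestion

Each protein is cut into all overlapping windows ("digestion products")
of the configured lengths: 8–11 for viral and self proteins, 8–12 for the
rank-calibration reference. Both ranges are configuration, not
hard-coded, because the two stages legitimately differ. Windows
overlapping a nonstandard residue (X, B, Z, J, U, O, `*`) are excluded
rather than scored — predictors cannot score them, and inventing scores
would bias ranks; a `reject` policy is available for callers who prefer a
hard error. A `DigestResult` keeps both the total window count (with
multiplicity — the epitope-density denominator) and the per-length unique
peptide sets (the repertoire substrate), because the two consumers need
different counts. Internally peptides are packed 5 bits/residue into
`uint64` codes (length ≤ 12), which keeps digestion, deduplication and
scoring vectorized end to end.

### Synthetic binding model

For a peptide p of length k:

    score(p) = w_P2[p_2] + w_C[p_k] + mean_{i ∈ interior}(w_bg[p_i])
               + noise_scale · h(model, p)

with interior = all positions except P2 and the C-terminus. The two
anchor positions dominate, mimicking class I anchor-residue binding. The
noise term h ∈ [−1, 1) is a splitmix64-style hash of the packed peptide
code and a key derived from the weight tables and seed — *not* an RNG
stream — so a (model, peptide) pair scores identically regardless of call
order, and two models with identical tables are identical binding
functions (a duplicated allele has functional distance exactly 0).

### Percentile-rank self-calibration

Predictors without built-in rank tables are calibrated against natural
peptides; the same procedure is used here for every allele so all alleles
are treated uniformly: digest a reference proteome into lengths 8–12,
sample 25,000 unique products per length uniformly without replacement
(seeded), score, and pool — 125,000 scores at the defaults. The rank of a
query score is the percentage of pool scores strictly greater, so ties
favor the query, rank 0 is the strongest possible, and the boundary is
exact. Binder calls use rank ≤ threshold (inclusive; the "top 1%" wording
is ambiguous exactly at the boundary and the inclusive choice is
documented). Ranks pool across lengths rather than per length, matching
the single-pool construction; per-length ranking would only change calls
when length-conditional score distributions differ strongly.

Under exchangeability — query peptides drawn from the same distribution
as the pool — the rank is uniform on [0, 100] by construction, so the
binder fraction at a t% threshold converges to t%. This is the
calibration null the tests and `scripts/acceptance.py` verify (100,000
queries, ±3 Monte-Carlo SE ≈ ±0.094 percentage points at 1%).

### Redundancy collapsing

Virus pairs are compared by Needleman–Wunsch global alignment of their
id-sorted concatenated proteomes (record order therefore cannot change
the result; the alignment substrate for multi-protein viruses is a
documented choice). Scoring follows EMBOSS Needle protein defaults:
BLOSUM62, gap open 10, extend 0.5, end gaps free; identity is identical
aligned positions over alignment length including gaps. Collapsing is
greedy in input order: a virus is kept iff its identity to every already
kept virus is ≤ the threshold — strictly-greater-than collapses, so
exactly 95.0% is retained. Greedy order and the strict boundary are
deterministic and documented rather than claimed to match any external
tool's tie behavior.

### Functional clustering

J_ab,v is the Jaccard similarity of the two alleles' unique-binder sets
on virus v; D_ab = 1 − mean_v J_ab,v. If both sets are empty the virus is
counted as J = 1 (indistinguishable repertoires); the alternative —
dropping the virus and renormalizing — changes nothing when repertoires
are non-empty and is a config-level variant rather than the default.
UPGMA uses size-weighted average linkage with merge height d/2 and a
deterministic tie rule (lexicographically smallest name-sorted cluster
pair), so equal-distance inputs always produce the same tree; PHYLIP- or
ape-compatible tie behavior under exact ties is not guaranteed.

Bootstrap supports resample ceil(0.2 · N) viruses per replicate *without*
replacement: sampling with replacement would duplicate viruses, and N in
the distance definition is "the number of viruses". 1000 replicates by
default. Supports are clade frequencies in [0, 1]. The extended
majority-rule consensus includes every clade in >50% of replicates, then
greedily adds remaining clades in decreasing frequency (ties: smaller,
then lexicographically smaller leaf sets) when compatible; consensus node
heights average the clade's merge heights over the replicates containing
it (a presentation choice — consensus trees need not be ultrametric).
Trees serialize to Newick with supports as internal labels and labels
quoted when they contain Newick metacharacters (allele names contain
`:`).

### Epitope density and statistics

density(v, a) = |unique binders| / ((threshold/100) · total digestion
products of v). The numerator counts unique binder peptides — consistent
with the repertoire definition — while the denominator counts windows
with multiplicity; for realistic proteins duplicate windows are rare, so
the distinction is second-order, but both counts are kept explicit.
Self-proteome presentation, by contrast, counts observed binders with
multiplicity per protein so that a 100% threshold gives a ratio of
exactly 1 by construction.

Group contrasts pool per-(allele, virus) density values within each group
(per-allele means are available as a config unit) and run two-sided
Mann–Whitney U per unordered group pair with Bonferroni correction over
all pairs. SciPy's `method="auto"` gives the exact null distribution for
small tie-free samples and the tie-corrected normal approximation
otherwise. The permutation test for "focal group presents virus v at
lower density" uses the statistic mean(focal) − mean(rest); when all
C(n, k) label assignments fit in the permutation budget it enumerates
them exactly, otherwise it samples with the +1 convention so p > 0. The
sweep-candidate screen passes a virus iff density < low (default 1) for
*every* focal allele and density > high (default 2) for ≥ min_count
(default 10) other alleles, both inequalities strict.

## Synthetic data: what it emulates and what it does not

The generators emulate the *shape* of the real inputs — a large random
reference proteome, virus sets with controllable relatedness, allele
panels with supertype structure — not their content:

- **Reference/self proteomes** are i.i.d. sequences from a uniform (by
  default) residue background, lengths uniform on 100–600. Uniformity
  keeps the exchangeability null exact; real proteomes have biased
  composition, low-complexity regions and shared domains, so real
  calibration pools are more correlated than synthetic ones.
- **Virus families** descend from independent ancestor proteomes by
  per-site substitution (no indels by default, so identity is controlled
  analytically: expected pairwise within-family identity ≈ (1 − rate)²).
  Real viral genomes share genes across families and evolve by indel and
  recombination as well.
- **Allele panels** plant one anchor archetype per supertype (distinct
  preferred P2 and C-terminal residues) and perturb it per allele with
  Gaussian noise of magnitude `anchor_divergence`. With divergence 0 the
  alleles of a supertype are the *same* binding function; with disjoint
  anchors and low noise, between-supertype binder sets are nearly
  disjoint. Real supertypes overlap and real motifs are softer.

Passing tests on these inputs therefore demonstrate that the *procedure*
is correct (calibration is unbiased, planted structure is recovered,
statistics match their oracles) — not that any particular biological
conclusion holds on real proteomes or a real predictor.

### The planted low-density contrast

`make_low_density_supertype` deserves its own note. Self-calibration
makes epitope density distribution-matched by design: any allele, however
selective its motif, calls ~1% of exchangeable peptides binders, so
sharpening a motif alone cannot push a group's density below 1. A group
can only be a systematically poor presenter when the peptides its motif
prefers are *rarer in viral proteomes than in the calibration
reference*. The helper therefore does two things at strength s: it
scales the focal alleles' anchor weights by (1 + s) (so their binder
sets concentrate on anchor-carrying peptides), and it returns a config
whose viral residue background depletes the focal anchors' preferred
residues by (1 − s), renormalized. Reference and self proteomes keep the
undistorted background. At s = 0.8 the focal group's mean density falls
to ~0.2 while the other groups sit slightly above 1 (renormalization
mildly enriches their anchors), and all focal-vs-other Mann–Whitney
contrasts are Bonferroni-significant — the qualitative analogue of a
supertype that under-presents viruses.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| viral digestion lengths | 8–11 | candidate ligand lengths for viruses and self |
| reference lengths | 8–12 | calibration pool lengths |
| per-length reference count | 25,000 | unique products sampled per length (pool 125,000) |
| rank threshold | 1.0 % | binder call boundary (inclusive) |
| collapse threshold | 95.0 % | strict identity boundary for redundancy |
| bootstrap reps / fraction | 1000 / 0.2 | replicates; viruses subsampled without replacement |
| filter low / high / min_count | 1.0 / 2.0 / 10 | sweep-candidate screen |
| anchor_strength / divergence / noise_scale | 6.0 / 0.25 / 0.5 | synthetic panel separation knobs |

## Numerical choices and degenerate inputs

- Percentile ranks count strictly-greater pool scores; ties favor the
  query. Rank is monotone non-increasing in score.
- UPGMA tie-break: smallest name-sorted cluster pair; bootstrap replicate
  seeds derive from one master seed via `numpy` SeedSequence, so runs are
  reproducible and independent of thread count.
- Proteins shorter than every window length digest to zero products (not
  an error); density on a virus with zero products is an error.
- J(∅, ∅) = 1; an empty virus subset for a distance is an error.
- Permutation p uses exact enumeration when C(n, k) ≤ n_perm, else
  Monte-Carlo with the +1 convention; comparisons use a 1e-12 tolerance
  so floating-point-equal statistics count as ties.
- Rank-reference construction fails loudly (naming the length and
  shortfall) when the reference proteome yields too few unique products.

## Problem sizes used in the test suite

Unit and property tests run on toy inputs (tens of proteins, ≤ 12
viruses). The cross-module recovery checks use a 4-supertype × 6-allele
panel on 50 viruses × 10 proteins × 300 aa with a 400-protein calibration
reference at 5,000 products per length and 200 bootstrap replicates —
small enough to run in seconds while leaving the planted structure
generously separated. The calibration null runs at the native pool size
(5,000 reference proteins, 125,000 scores, 100,000 queries). These sizes
are the package's chosen verification scale; the library itself has no
size limits beyond memory.

## Known limitations

- The synthetic model is a stand-in with a three-term additive motif; it
  does not approximate any trained predictor's score surface, and an
  adapter to an external predictor is deliberately out of the tested
  surface.
- Virus identity is computed on concatenated proteomes; per-protein
  best-match averaging would behave differently for rearranged genomes.
- Consensus tie-breaking follows the documented greedy rule, which can
  differ from specific PHYLIP builds under exact frequency ties.
- Greedy collapsing depends on input order (documented, deterministic);
  it is not a globally optimal clustering.
- The Mann–Whitney unit (pooled allele×virus values) treats cells as
  exchangeable; viruses induce correlation between alleles, so p-values
  on real data should be read as descriptive, as in the screening use
  here.
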