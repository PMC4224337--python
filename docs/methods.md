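# Methods

This note documents the models, numerical conventions and design
choices behind `mitotfbs`, and what the synthetic-data generator does
and does not emulate.

## Circular coordinates

All coordinates are 1-based inclusive positions on the circle, the
convention of the rCRS/mtDNA literature; BED exports convert to 0-based
half-open and split origin-spanning intervals into two records.
Origin-spanning features are represented natively via a `wraps` flag;
rotation (`rotate(k)`: remove the first k bases, paste them at the end)
is provided as a validation tool, with exact coordinate maps in both
directions, because analyses on a rotated reference must agree with the
native circular analysis after mapping — a property the motif, peak and
footprint tests all assert.

Codon positions are computed strand-aware from a gene's 5' end on its
strand, after trimming the `phase` offset; bases inside the phase-
trimmed leading partial codon or an incomplete trailing codon have no
codon position.  When a position lies in several annotated genes the
first annotation in file order is primary (overlaps are logged).

`N` bases are accepted in input sequences but any motif or footprint
window containing `N` is excluded from scoring rather than given a
fabricated value.

## Motif model

A PFM column of counts `n_b` becomes log-odds weights
`w_b = log2(((n_b + c·q_b)/(N + c))/q_b)` with pseudocount `c = 0.8`
distributed over the background `q` (uniform by default; a genome-
composition background is available).  Scores are sums over columns;
the *relative score* normalizes by the best/worst achievable sums so a
single threshold (default 0.80, the classic web-scan default; ties are
hits) is comparable across motifs.  Scanning treats the genome as a
circle by scoring the doubled sequence truncated to L start positions;
minus-strand windows are scored through the reverse-complemented PWM
and reported on plus-strand coordinates.  All overlapping hits are
reported — the selection screen needs every candidate site, so no
greedy merging is done.

Variant rescoring substitutes a single allele into the reference window
(complementing for minus-strand hits) and rescores; "retained" means
the rescored relative score still clears the scan threshold, the same
bound used at discovery.  Multiple variants at one site are rescored
independently, not as combined haplotypes, because the screen evaluates
each variant's effect individually.  A stricter drop-based retention
mode was considered and rejected as the default: the discovery
threshold is the only bound the screen itself defines.

## DNase footprint score

For fragment width `w` (default 20), position `p` is the
`(w+1)//2`-th base of the central fragment (base 10 for w = 20; the
convention is arbitrary but fixed and documented for reproducibility).
The proximal and distal fragments are the `w` bp immediately before and
after; `F = (C+1)/L + (C+1)/R` from the three fragment means.  Low F
marks protein-protected DNA, high F hypersensitive DNA; outputs are
labeled neutrally ("low-F"/"high-F") since the field uses both
readings.  Positions with a zero flank mean are undefined (NaN), since
the formula's +1 guard applies only to C; a `flank_pseudocount` option
(default 0) is available as a documented deviation for users who prefer
a guarded denominator.

Extreme-site calling selects `k = ceil(percentile · n_defined)`
positions from the sorted defined values (ties at the cut included),
then merges runs with gaps ≤ `merge_gap` (default 5 bp), wrapping at
the origin.

A structural property of F worth knowing: a uniform depleted block
longer than the whole 3w window is invisible at its own middle (all
three fragments equally depleted, F returns to baseline), and every
block boundary induces a secondary excursion of the opposite sign
(flank depleted, center not).  Consequently the recovery analyses match
`w` to the planted feature scale (w = 60 for 60-bp blocks) and assess
protected and hypersensitive features on separate tracks so boundary
artifacts of one feature class cannot be mis-attributed to the other.
The percentile used for recovery equals the planted-feature fraction of
the genome (60/L).

## Peak caller

This is an explicit simplified re-implementation in the spirit of
kernel-density ChIP peak estimation, not a reproduction of any existing
caller's internals.  Per strand, read-start counts are smoothed with a
discrete Gaussian kernel (sd = `bandwidth`, truncated at 4 sd,
normalized to unit mass so the density integrates to the read count);
the plus density is shifted downstream and the minus density upstream
by `fragment_size // 2`, and the combined density is their sum.

The candidate threshold is expressed in *equivalent overlapping
fragments*: density × bandwidth·√(2π), so the default of 30 demands
roughly 30 co-occurring fragments.  Candidates are circular local
maxima clearing both the threshold and the fold-enrichment ratio
(default 3×) over the depth-scaled background density; candidates
closer than one fragment length are merged keeping the highest.  Peak
intervals extend to half-maximum (capped at fragment_size + 2·bandwidth
per side).  Bimodality requires the plus-strand sub-peak (unshifted
densities) to precede the minus-strand sub-peak at a circular
separation within fragment_size ± bandwidth.

`p_raw` is the Poisson upper tail of the in-interval ChIP start count
given the depth-scaled background count (floored at one read);
`q_proxy` is Benjamini–Hochberg over the called peaks — a descriptive
proxy, documented as such, since the original pipeline's q values are
not reproducible from published information.  An all-zero background
falls back to a uniform pseudo-background with a logged warning.

## NUMT read discrimination

Diagnostic positions are character-wise mismatches between the mtDNA
region (TFBS ± 50 bp by convention) and a pre-aligned, gapless NUMT
candidate.  A read is mt-like if it matches the mtDNA allele at every
covered diagnostic (≥ 1 covered), NUMT-like if it matches the NUMT
allele at every covered diagnostic, and ambiguous otherwise — including
reads covering no diagnostic, carrying third alleles, or mixing the two
haplotypes; mixed reads are counted and reported rather than assigned,
since allele-at-diagnostic logic is the only evidence used (sequencing
mismatches at non-diagnostic positions are deliberately ignored).
Covering-read classes sum to depth at every position by construction.
Consensus reconstruction is majority rule at ≥ `min_coverage`, with
exact ties masked (lowercase `n`) and logged.

## Tip/nodal classification

Lineages are label paths (coarse → fine, e.g. `L3/N/R/H1`); a
sublineage is the set of sampled individuals sharing a path prefix, so
the 85% criterion is computed over *sampled* individuals, not nominal
haplogroup membership.  A variant is a *tip* when carried by exactly
one individual; *nodal* when some sublineage S satisfies
|carriers ∩ S| ≥ 5 and |carriers ∩ S|/|S| ≥ 0.85, reporting the
smallest such S (ties: deepest path, then lexicographic); otherwise
*unclassified* — variants carried by 2–4 individuals, or widely
scattered, are excluded from both tallies.  Classification is a pure
function of the carrier set, so recurrent variants pooled across
lineages are classified on the pooled set; a clade that fully qualifies
still makes the variant nodal even when extra carriers exist elsewhere.
A Newick tree with labeled internal nodes can be converted to a lineage
table (unlabeled internals get synthetic labels).

## Selection decision tree

Per site, using only third-codon-position variants contained in it:
no variants → `NO_VARIANTS`; only tips → `TIPS_ONLY`; any nodal →
`NODAL_RETAINED` if every nodal variant's rescored relative score
clears the threshold, else `NODAL_DISRUPTED`.  The first three
categories are consistent with negative selection.  Sites with both
tips and nodal variants are decided by the nodal variants alone (tips
are rescored and reported but cannot speak to selection — they are too
young); sites whose only variants are unclassified fall to
`NO_VARIANTS`, since unclassified variants are neither demonstrably old
nor single-carrier young.  The CPR-vs-CNR comparison reports the CNR
nodal-count five-number summary and mean, each CPR site's empirical
percentile (fraction of CNR sites with nodal count ≤ the CPR's), and
per-site fractions of variants retaining the motif.  No significance
test is asserted; the percentile is descriptive.

## Synthetic-data generator

The generator's role is to produce every pipeline input with known
ground truth at desk scale.  What it emulates, and how:

**Population.**  A two-level clade structure (default 20 clades × 10
individuals under 4 coarse groups) stands in for the mtDNA phylogeny —
sufficient to exercise the ≥5-carrier/≥85% classifier, while a richer
Newick-driven topology can be supplied for the classifier itself.
Stem mutations (Poisson, mean `mu_internal` = 3 per clade) propagate to
whole clades (true class nodal); leaf mutations (mean `mu_leaf` = 0.5)
hit single individuals (true class tip).  Mutation positions are drawn
from a weight field: ×5 on third codon positions and ×400 inside
planted motif footprints.  The concentration compensates for panel
size: a population study draws on thousands of genomes to populate a
handful of 9-bp motifs with variants; a 200-individual desk panel needs
the weighting to produce comparable per-site counts.  Positions already
mutated on the same branch are redrawn, so each (position, branch) pair
carries one substitution; recurrent mutations across branches are
allowed and pooled at observation time, with expected classes derived
by applying the printed definitions to the true carrier history (two
independent leaf events at the same position and allele are, by
definition, no longer a tip variant).

**Selection.**  A motif flagged `selected` rejects (and redraws) any
stem mutation whose substituted allele would drop the motif's relative
score below the scan threshold — purifying selection acting on old
alleles only; leaf mutations are never rejected.  The bundled test PWM
(width 9) places its high-information columns (97/1/1/1) at columns 3,
6 and 9 and low-information columns (35/25/25/15) elsewhere; planted in
frame, the critical columns sit exactly on third codon positions.
This is the biological scenario under study — binding-energy-critical
bases at synonymous sites, where the protein leaves selection on the
motif free to act — and it makes every third-codon substitution at a
selected motif disrupting (rejected), while neutral motifs accumulate
them freely.

**ChIP.**  Background read starts are per-position Poisson on each
strand; each planted fragment pair contributes a plus-strand start near
center − fragment_size/2 and a minus-strand start near
center + fragment_size/2, each with Gaussian jitter (sd = bandwidth/2) —
the bimodal signature of true binding.  Site strength is parameterized
directly as fragment-pair counts (the primitive quantity; a fold-
enrichment parameterization is undefined over a zero background).
Reads can be materialized for the NUMT workflow, with a stated fraction
rebased onto a NUMT haplotype by allele swap at diagnostic positions.

**DNase.**  Per-position Poisson counts at a baseline depth, scaled by
0.1 inside protected and 5× inside hypersensitive intervals.

All randomness flows through a single `numpy.random.Generator`; a seed
fixes every output byte.  Ground truth records each mutation event,
read origin and planted interval, and replaying recorded events over
the clade structure regenerates the emitted sequences exactly (a tested
invariant).

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: the real mtDNA mutational spectrum
(transition bias is configurable but off), heteroplasmy, rate variation
along the molecule, sequencing error in ChIP reads, fragment-length
dispersion, mappability structure, or realistic phylogenies deeper than
the two-level clade model.  Recovery results on synthetic data
demonstrate algorithmic correctness under the stated model, not
field performance.

## Problem sizes and numerical choices

The acceptance layer runs 20 replicates of the full screen on 16,569-bp
genomes with 200 individuals, 20 peak-caller simulations at mtDNA
scale, 10,000 reads for NUMT recovery and 20 DNase replicates — sizes
chosen so the whole suite completes in seconds while keeping Poisson
counting noise far from the asserted margins.  Oracle comparisons
(naive F recomputation, doubled-sequence motif scan, exhaustive carrier
subsets, direct kernel sums) are exact up to floating-point rounding;
scores are compared at 1e-9 granularity.  Degenerate inputs are
defined, not guessed: zero-flank F is NaN, consensus ties mask, an
empty CNR set is an error (the null distribution is undefined), an
all-zero ChIP track warns and yields no peaks.

## Known limitations

- The peak caller's p/q values are descriptive proxies; cross-dataset
  q-value comparability is not claimed.
- Gapless alignment is assumed throughout the NUMT module; indel
  diagnostics are out of scope, as is running the homology search that
  produces NUMT candidates.
- No dN/dS or codon-model inference: "consistent with negative
  selection" is a pattern statement about motif variants, not a fitness
  estimate.
- Overlapping genes are resolved by annotation order rather than a
  biological primary-transcript rule.
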