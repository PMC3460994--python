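# Methods

This note documents the models, parameter choices and known limitations of
`hicprox`. It is the place where genuinely open design decisions are
recorded with their rationale.

## Data model and conventions

All coordinates are 0-based half-open, including cytoBand input (UCSC
convention). The working resolution is a fixed bin size (default 1 Mb);
the last bin of each chromosome may be truncated. Regions are snapped to
whole bins (floor start, ceil end) before any bin-level computation: a
cytogenetic band "overlaps" exactly the set of bins it touches. Karyotype
band lookup is prefix-complete — `q34` covers `q34.1`, `q34.11`, never
`q3` → `q34` — by requiring the next character after the prefix to be `.`
or end-of-label.

Catalog filtering follows the standard exclusions for this analysis:
3-way records decompose into their three 2-way pairs, records with more
than three partners are rejected, whole-arm partners (band label exactly
`p` or `q`) are rejected, intra-chromosomal records are rejected, and
sequencing-derived breakpoints need at least three supporting reads. Every
rejection carries a reason code. Duplicate pairs are kept as records but
deduplicated on (region_a, region_b) for testing, so counts refer to
unique translocations.

Masking removes bins that overlap a centromeric (`acen`) band or have zero
total trans coverage; both reasons are recorded when they co-occur.

## Expected model and Hi-C score

The expected count controls for everything that multiplies a bin's
read-attraction roughly independently of its partner (coverage,
mappability, restriction-site density). Per chromosome pair, with unmasked
marginals `m_i` and total `T`:

    E(i,j) = m_i * m_j / T

which conserves the block total exactly (`sum E = sum O`, an identity the
tests check to 1e-9 relative). An optional linear smoothing filter
replaces each E by the mean of defined neighbors in a window (default 3,
odd), then renormalizes per pair; smoothing is applied to E only, never to
O. An iterative marginal-rebalancing variant (10 iterations, tolerance
1e-6) is available behind a flag for stronger bias removal but is off by
default — the marginal product is the model the rest of the analysis
assumes.

The score is `S = log2((O + c)/(E + c))` with pseudocount `c = 1.0` by
default. The pseudocount keeps zero-count bins finite and damps the
variance of low-coverage bins; `c = 0` is permitted only when every scored
count is positive. On pure-bias synthetic maps (counts Poisson(λ b_i b_j))
the score mean over large blocks is within ±0.05 of zero for λ ≥ 50 —
the bias cancels, up to the small negative Jensen offset of the log.

## Compartments

Per chromosome, the bins' trans score rows (against all unmasked bins on
other chromosomes) are correlated (Pearson) and the first principal
eigenvector of that correlation matrix is the compartment track, unit
norm, NaN on masked or constant rows. The sign is flipped so the track
correlates non-negatively with an orientation reference — gene content by
default, since the open compartment is the gene-rich one. A region's
compartment score is the mean PC1 over its unmasked bins; zero counts as
open (a fixed, measure-zero tie rule). Using trans rows rather than
cis-map correlation is a deliberate choice: the package's data model is
trans-only, and trans correlation recovers the same genome-scale
partition; planted A/B blocks with multipliers AA 1.4 / BB 1.2 / AB 0.7
are recovered at ≥ 90% sign agreement from λ = 30 counts.

## Proximity score and permutation nulls

The proximity score averages S over the full 2-D block of bin pairs
(region_a bins × region_b bins) — not two 1-D profiles — and reports how
many bin pairs were used and how many masked. Undefined scores (no usable
bin pair) propagate as explicit missing values and are excluded, with a
count, from summaries. Dataset summaries use a normal-approximation 95% CI
(mean ± 1.96·SEM); the CI construction is a package choice.

Four null constructions preserve the observed chromosome pairings and
region sizes (in whole bins):

1. both regions re-placed uniformly on their own chromosomes;
2. one region fixed, partner re-placed on the partner's own chromosome;
3. one region fixed, partner re-placed uniformly over all placements on
   any other chromosome;
4. one region fixed, partner drawn from the catalog's own partner regions
   not on the fixed chromosome, keeping the drawn region's size and
   position.

A candidate placement is valid when fewer than 50% of its bins are masked
(configurable); with compartment control (methods 1–3) a re-placed region
must also match the compartment sign of the region it replaces. Draws are
implemented as uniform choice over the enumerated set of valid placements,
which is distributionally identical to rejection sampling and lets the
engine vectorize; placement frequencies match the uniform-over-valid
oracle on masked toy genomes.

In methods 2–4 the fixed partner is chosen uniformly at random **once per
pair** (seeded), not per draw. This matters: the observed pair is
exchangeable with its null draws only if all draws come from one
conditional distribution; mixing "fix A" and "fix B" draws within a pair's
null set miscalibrates the rank and visibly inflates the KS distance of
null p-values from uniform. With per-pair fixing, p-values are uniform
under the null (measured KS ≈ 0.02–0.03 at 2,000 pairs for all methods,
with and without compartment control).

p-values are add-one, `(k+1)/(N+1)`, with ties counted against
significance, so a permutation p is never zero; `<0.001` is the display
convention for k = 0 at N = 1000. The group test permutes every pair
independently within each of the N replicate catalogs and compares the
observed mean against replicate means; Student's t and Wilcoxon rank-sum
p-values between observed and pooled permuted statistics are reported
alongside to monitor whether outliers drive a result. Per-pair p-values
are Benjamini–Hochberg corrected (hand-authored step-up, tested against
statsmodels), significant at q < 0.05.

Auxiliary comparisons: tissue-group score comparison uses the rank-sum
test with normal approximation and tie correction, without continuity
correction (identical groups give exactly p = 1); recurrence analysis
reports the Spearman correlation of report counts with proximity scores
and a regression-slope t-test on the ranks of permutation p-values vs
counts (the specific test for the latter relation is a package choice).

## Fine-mapping

The caller assumes an *unbalanced* event: one derivative chromosome, so
reads fill a single quadrant from the breakpoint with contact frequency
decaying along both axes. Pipeline: (1) maximal 1 Mb bin per chromosome
pair — when normalizing, the expected value is computed leave-one-out,
`E' = (m_i − O_ij)(m_j − O_ij)/T`, because a concentrated rearrangement
inflates its own marginals and would otherwise cap its own enrichment;
(2) all reads in the 3 Mb × 3 Mb window centered on that bin (bin ± 1 Mb,
clipped at chromosome ends); (3) corner detection at 50 kb; (4) 1 kb × 1 kb
refinement inside the corner bin when it holds ≥ 20 reads.

Corner detection scores each orientation by quadrant *enrichment*:
`clip(frac_in_quadrant − quadrant_area_share + 1/4, 0, 1)`, computed over
reads outside the corner bin itself (corner-bin reads are
orientation-ambiguous at 50 kb). Uniform reads score ≈ 0.25 whatever the
corner position; a perfect one-quadrant signal scores ≈ 1. A call
requires signature ≥ 0.6, a nearly empty diagonally opposite quadrant
(≤ 20% of non-corner reads — a balanced event fills it with its second
cloud), and both marginal profiles decaying away from the corner
(Spearman ≤ −0.5 vs distance). The corner is made "corner-most": after
orientation is fixed, it steps one bin against the opening direction when
that neighbor holds ≥ max(5, 10% of peak) reads, which resolves the
off-by-one that otherwise occurs when a breakpoint sits within a few kb of
a 50-kb bin boundary. Genome-wide scanning flags a pair's maximal bin when
it exceeds mean + 8 SD of the pair's unmasked counts; at that threshold
background-only maps (λ = 5) are flagged in < 5% of runs while planted
2,000-read events are always found.

Thresholds (min 200 window reads, min 20 refinement reads, z = 8,
signature 0.6, opposite ≤ 0.2) are configuration knobs whose defaults are
justified by the recovery/specificity simulations in the test suite.

## Synthetic data

The generator emits every input the pipeline reads — cytoband table,
contact triplets, read pairs, karyotype and breakpoint catalogs, gene BED,
truth YAML — deterministically from one seed.

* Counts: `O(i,j) ~ Poisson(λ · b_i · b_j · m_comp · f_hot)` per trans bin
  pair, with `b ~ LogNormal(0, σ)` (default σ = 0.3, λ = 50 — rates at
  which the analysis operates comfortably above the pseudocount),
  block-structured A/B labels (geometric block lengths, mean 10 bins) with
  multipliers AA 1.4, BB 1.2, AB 0.7, and hotspots placed on *named band
  pairs* (band-aligned blocks mirror the analysis model, where the
  proximity hotspot spans the translocating band pair) with fold 2.
* Cytobands: one two-sided `acen` centromere per chromosome and named
  p/q bands (default 5 Mb) whose regions round-trip exactly through the
  band parser; numbered arm bands start at 12 so the acen `p11.1`/`q11.1`
  never collide with prefix lookups.
* Translocation reads: from a breakpoint `(x0, y0)` with orientation signs
  `(s_x, s_y)`, a read sits at `(x0 + s_x d_1, y0 + s_y d_2)` where the
  total distance `d_1 + d_2` follows a truncated power law
  `(s + δ)^(−α)` on [0, 1.4 Mb] (closed-form inverse-CDF sampling; uniform
  split between axes). Defaults α = 1 (the classic ~1/s cis contact decay
  an unbalanced fusion converts into trans signal) and δ = 1 kb to avoid
  the singularity.
* Catalogs: `n_true` band pairs drawn from hotspots, `n_null` uniform
  inter-chromosomal band pairs, emitted both as karyotype notation and as
  breakpoint records (positions at band midpoints; the breakpoint view
  snaps to single bins, so it is *contained in*, not equal to, the band
  view). Gene intervals cover 60% of A bins and 15% of B bins, anchoring
  the eigenvector sign.

What the generator does **not** emulate: restriction-fragment structure
(reads are position-continuous, while real resolution is limited by
HindIII site density), cis contact maps and their distance decay,
copy-number alterations, mappability holes beyond whole-bin masking, and
inter-sample heterogeneity. Passing tests therefore demonstrate the
statistical machinery — bias cancellation, calibration, power, recovery —
under the stated generative model, not performance on any particular real
dataset.

## Problem sizes and numerical choices

Validation studies run on 4 × 100-bin chromosomes (calibration, power),
3 × 100-bin (compartments), 2 × 30-bin (fine-mapping, 100 seeds) and a
2 × 6-bin toy for exact enumeration — sizes chosen so each study completes
in seconds while leaving the measured quantities far from their
thresholds. Eigenvectors come from the dense symmetric solver; block means
use exact prefix-sum arithmetic; permutation determinism is bit-exact for
a fixed seed and configuration. Degenerate inputs fail loudly: constant
correlation rows are dropped with a warning (all-constant raises), empty
regions, zero-total chromosome pairs, and invalid p-values raise typed
errors rather than returning silent zeros.

## Limitations

* The expected model corrects per-bin multiplicative bias only; it is not
  a fragment-level probabilistic bias model, and scores on real data
  retain whatever bias is not multiplicative at bin scale.
* Method 4's null is only as rich as the catalog itself; for small
  catalogs its p-values are coarse.
* The compartment track is a single genome-scale eigenvector;
  sub-compartments and cis-based variants are out of scope.
* The fine-mapper targets unbalanced events; balanced translocations are
  deliberately rejected (two-cloud patterns), not called.
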