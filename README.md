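# hicprox

Trans-chromosomal Hi-C proximity analysis of translocation partner
selection: normalized contact scoring of region pairs, permutation
significance testing of translocation catalogs, A/B chromatin-compartment
control, and hierarchical fine-mapping of existing rearrangements from
read-level Hi-C data — with a synthetic-data generator so the whole
pipeline runs and validates without any external download.

## The scientific problem

Chromosomal translocations join segments of two different chromosomes. If
loci that are spatially proximal in the nucleus are more likely to be
joined when DNA breaks are mis-repaired (the contact-first model), then
translocation partners observed in disease genomes should show elevated
Hi-C contact frequency *before* any rearrangement. Testing this requires
(i) a contact measure that is robust to per-bin coverage and mappability
biases, (ii) a null model for "random region pairs that look like the
observed ones", and (iii) care with confounders such as chromosome-pair
preferences and open/closed chromatin.

The package is aimed at computational genomicists analyzing binned trans
Hi-C contact maps (1 Mb working resolution) together with translocation
catalogs given either as cytogenetic band pairs (karyotype notation, e.g.
`t(9;22)(q34;q11)`) or as sequenced breakpoints.

## Model and statistics

**Hi-C score.** For trans bins *i, j* with observed count *O(i,j)*, the
expected count under coverage bias alone is the marginal product
*E(i,j) = m_i m_j / T* over unmasked bins of the chromosome pair
(optionally passed through a linear smoothing filter and renormalized).
The score is the variance-stabilized log-ratio

    S(i,j) = log2( (O(i,j) + c) / (E(i,j) + c) ),   c = 1 by default.

Bins overlapping centromeres or with zero coverage are masked throughout.

**Proximity score.** For a translocation with partner regions *A, B*, the
proximity score is the mean of *S* over all unmasked 1-Mb bin pairs in the
block *A x B*.

**Permutation tests.** Each catalog is compared against 1,000 randomized
catalogs preserving chromosome pairings and region sizes, under four null
constructions (both regions re-placed; one fixed, partner re-placed on its
own chromosome; on any other chromosome; or drawn from the catalog's own
partner set), each optionally restricted to regions of the same chromatin
compartment sign. p-values use the add-one estimator (k+1)/(N+1) with ties
counted against significance; per-translocation p-values are
Benjamini–Hochberg corrected.

**Compartments.** Per chromosome, the first principal eigenvector of the
Pearson correlation matrix of trans score rows partitions bins into open
(positive, gene-rich) and closed compartments; the sign is anchored to
gene content.

**Fine-mapping.** An unbalanced translocation fills one quadrant of the
read-level contact map from its breakpoint. The caller finds the maximal
1 Mb x 1 Mb bin of a chromosome pair, collects reads in the 3 Mb x 3 Mb
window around it, scores the four corner orientations at 50 kb by quadrant
enrichment (with marginal-decay and opposite-quadrant checks), and refines
to 1 kb x 1 kb when coverage allows.

## Worked example

```sh
python examples/02_proximity_permutation.py
```

prints, for a synthetic catalog of 30 band pairs planted in x2 proximity
hotspots plus 30 random band pairs:

```
catalog: 60 pairs (30 planted, 30 random)
mean proximity score: +0.400 [+0.264, +0.536] (95% CI)
permuted mean: -0.070  group permutation p: <0.001  rank-sum p: 2.3e-13
individually significant (BH q < 0.05): 29 — of which planted: 28
```

The catalog's mean Hi-C score (+0.40) sits far above the mean of 1,000
size- and chromosome-matched random catalogs (−0.07): the planted spatial
proximity is detected at the group level (p < 0.001), and 28 of the 30
planted pairs are individually significant after FDR correction with only
one false positive. The other examples cover scoring (`01`), compartment
recovery (`03`) and breakpoint fine-mapping (`04`); each prints the
numbers it computes and what they mean.

A `hicprox` command-line tool wraps the same library for file-based runs:

```sh
hicprox simulate --out-dir data --seed 5
hicprox analyze  --in-dir data --out-dir report --seed 3 --method 1
hicprox finemap  --in-dir data --out-dir calls
```

`analyze` writes the mask, score triplets, compartment track, per-pair
proximity TSV, group/individual test TSVs and a one-row summary table
(mean score, permuted mean, permutation and rank-sum p, individually
significant count, catalog coverage fractions).

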