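"""Score a translocation catalog and test it against permutation nulls.

Simulates a catalog of 30 band pairs planted in x2 proximity hotspots plus
30 random band pairs, computes each pair's proximity score (mean Hi-C score
over its bin block), and runs the group and per-translocation permutation
tests under Method 1 (both regions re-placed on their own chromosomes).
"""

import numpy as np

from hicprox import (
    CompartmentTrack, PermutationConfig, PermutationEngine,
    build_mask, expected_trans, group_test, hic_score, individual_test,
    proximity_score, summarize_dataset,
)
from hicprox.permutation import gene_bin_coverage
from hicprox.simulate import SimConfig, simulate_dataset

cfg = SimConfig(
    n_chroms=4, chrom_length=100_000_000, base_rate=50.0, bias_sigma=0.3,
    n_hotspots=6, hotspot_fold=2.0, n_true=30, n_null=30, rng_seed=1,
)
ds = simulate_dataset(cfg)
mask = build_mask(ds.contact_map, ds.bands)
scores = hic_score(ds.contact_map, expected_trans(ds.contact_map, mask), mask)
gene_cov = gene_bin_coverage(ds.genes, ds.scheme)
comp = CompartmentTrack.from_scores(
    scores, {c: gene_cov[c] for c in ds.assembly.names}
)
engine = PermutationEngine(scores, mask, comp, gene_cov)

pairs = ds.catalog_pairs()
labels = np.array(ds.truth.catalog_labels)
results = [proximity_score(p, scores) for p in pairs]
summary = summarize_dataset(results)

pcfg = PermutationConfig(method=1, n_perms=1000, rng_seed=2)
gres = group_test(pairs, engine, pcfg)
ires = individual_test(pairs, engine, pcfg)

print(f"catalog: {len(pairs)} pairs "
      f"({(labels == 'true').sum()} planted, {(labels == 'null').sum()} random)")
print(f"mean proximity score: {summary.mean_score:+.3f} "
      f"[{summary.ci95_low:+.3f}, {summary.ci95_high:+.3f}] (95% CI)")
print(f"permuted mean: {np.mean(gres.null_means):+.3f}  "
      f"group permutation p: {gres.format_p()}  rank-sum p: {gres.rank_sum_p:.2g}")
sig = ires.significant
print(f"individually significant (BH q < 0.05): {sig.sum()} "
      f"— of which planted: {(sig & (labels == 'true')).sum()}")
print("The group p compares the observed catalog mean against 1000 "
      "re-placed catalogs; small p = partners sit closer in the nucleus "
      "than matched random regions.")
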