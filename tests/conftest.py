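"""Shared fixtures: toy genomes, a null (structure-free) simulated dataset,
and a planted-hotspot dataset, with the derived score maps and engines."""

import pytest

from hicprox import (
    CompartmentTrack,
    PermutationEngine,
    build_mask,
    expected_trans,
    hic_score,
)
from hicprox.permutation import gene_bin_coverage
from hicprox.regions import (
    BinScheme,
    CytoBand,
    GenomeAssembly,
    GenomicRegion,
    TranslocationPair,
)
from hicprox.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def toy_assembly():
    return GenomeAssembly(("chr1", "chr2"), (10_000_000, 10_000_000))


@pytest.fixture(scope="session")
def toy_scheme(toy_assembly):
    return BinScheme(toy_assembly, 1_000_000)


@pytest.fixture(scope="session")
def toy_bands():
    # chr1: q34.1 [10,20) Mb-scaled down to the 10-Mb toy; use kb-scale bands
    return [
        CytoBand("chr1", 0, 2_000_000, "p12", "gneg"),
        CytoBand("chr1", 2_000_000, 4_000_000, "p11", "gpos50"),
        CytoBand("chr1", 4_000_000, 5_000_000, "q11.1", "acen"),
        CytoBand("chr1", 5_000_000, 7_000_000, "q34.1", "gneg"),
        CytoBand("chr1", 7_000_000, 10_000_000, "q34.2", "gpos50"),
        CytoBand("chr2", 0, 4_000_000, "p13", "gneg"),
        CytoBand("chr2", 4_000_000, 5_000_000, "q11.1", "acen"),
        CytoBand("chr2", 5_000_000, 10_000_000, "q22", "gneg"),
    ]


def _derive(ds):
    mask = build_mask(ds.contact_map, ds.bands)
    model = expected_trans(ds.contact_map, mask)
    scores = hic_score(ds.contact_map, model, mask)
    gene_cov = gene_bin_coverage(ds.genes, ds.scheme)
    comp = CompartmentTrack.from_scores(
        scores, {c: gene_cov[c] for c in ds.assembly.names}
    )
    engine = PermutationEngine(scores, mask, comp, gene_cov)
    return {
        "ds": ds, "mask": mask, "model": model, "scores": scores,
        "gene_cov": gene_cov, "compartments": comp, "engine": engine,
    }


@pytest.fixture(scope="session")
def null_setup():
    """Structure-free map: biases only, no hotspots (the calibration model)."""
    cfg = SimConfig(
        n_chroms=4, chrom_length=100_000_000, base_rate=50.0,
        bias_sigma=0.3, n_hotspots=0, rng_seed=11,
    )
    return _derive(simulate_dataset(cfg))


@pytest.fixture(scope="session")
def bias_only_setup():
    """Pure coverage-bias map: no compartments, no hotspots. The marginal
    product removes all structure, so scores center on zero."""
    cfg = SimConfig(
        n_chroms=4, chrom_length=100_000_000, base_rate=50.0,
        bias_sigma=0.3, use_compartments=False, n_hotspots=0, rng_seed=17,
    )
    return _derive(simulate_dataset(cfg))


@pytest.fixture(scope="session")
def planted_setup():
    """Map with x2 hotspots and a labelled catalog placed in them."""
    cfg = SimConfig(
        n_chroms=4, chrom_length=100_000_000, base_rate=50.0,
        bias_sigma=0.3, n_hotspots=6, hotspot_fold=2.0,
        n_true=30, n_null=30, rng_seed=21,
    )
    return _derive(simulate_dataset(cfg))


def random_catalog(engine, scheme, n, rng, min_w=2, max_w=8):
    """Uniform random valid inter-chromosomal pairs (the calibration null)."""
    names = scheme.assembly.names
    bs = scheme.bin_size
    out = []
    for _ in range(n):
        i, j = sorted(rng.choice(len(names), 2, replace=False))
        c1, c2 = names[i], names[j]
        w1 = int(rng.integers(min_w, max_w + 1))
        w2 = int(rng.integers(min_w, max_w + 1))
        v1 = engine.valid_starts(c1, w1)
        v2 = engine.valid_starts(c2, w2)
        s1 = int(v1[rng.integers(v1.size)])
        s2 = int(v2[rng.integers(v2.size)])
        out.append(TranslocationPair(
            GenomicRegion(c1, s1 * bs, (s1 + w1) * bs),
            GenomicRegion(c2, s2 * bs, (s2 + w2) * bs),
        ))
    return out
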