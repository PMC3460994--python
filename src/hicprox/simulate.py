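"""Synthetic Hi-C inputs with known ground truth.

The generator emulates the statistical structure the analysis assumes:

  * trans contact counts O_ij ~ Poisson(lambda * b_i * b_j * m_comp * f_hot),
    with multiplicative per-bin biases b ~ LogNormal(0, bias_sigma)
    subsuming coverage/mappability/restriction-site effects, block-structured
    A/B compartment multipliers, and multi-megabase proximity hotspots;
  * read-level unbalanced-translocation signatures: reads fill one quadrant
    from a breakpoint with a truncated power-law decay of the total genomic
    distance to the corner;
  * cytoband tables with one centromere (acen) block per chromosome and
    named p/q sub-bands recoverable by band lookup;
  * labelled translocation catalogs (true pairs in hotspots, null pairs
    uniform) in both karyotype notation and breakpoint TSV form;
  * gene annotations whose density tracks the open (A) compartment, giving
    the compartment eigenvector a principled sign anchor.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError
from .contacts import RawContactMap
from .regions import (
    BinScheme,
    CytoBand,
    GenomeAssembly,
    GenomicRegion,
    TranslocationPair,
    band_to_region,
)


@dataclass
class SimConfig:
    n_chroms: int = 4
    chrom_length: int = 100_000_000
    bin_size: int = 1_000_000
    base_rate: float = 50.0          # lambda: expected reads per unbiased bin pair
    bias_sigma: float = 0.3          # log-normal SD of per-bin bias
    compartment_block_mean: float = 10.0  # mean block length in bins
    m_aa: float = 1.4
    m_bb: float = 1.2
    m_ab: float = 0.7
    use_compartments: bool = True
    hotspot_fold: float = 2.0
    n_hotspots: int = 0
    hotspot_width_bins: int = 5
    n_true: int = 0                  # catalog pairs placed in hotspots
    n_null: int = 0                  # catalog pairs placed uniformly
    band_width_bins: int = 5         # cytoband width
    # translocation read simulation
    decay_alpha: float = 1.0
    decay_delta: float = 1_000.0     # bp offset avoiding the power-law singularity
    translocation_reads: int = 2_000
    background_read_rate: float = 0.0  # uniform trans reads per bin pair
    gene_frac_a: float = 0.6         # gene density in A bins
    gene_frac_b: float = 0.15
    rng_seed: int = 0

    def __post_init__(self):
        if self.base_rate < 0 or self.hotspot_fold <= 0 or self.decay_alpha <= 0:
            raise ValidationError("rates/folds/alpha must be positive")
        if min(self.m_aa, self.m_bb, self.m_ab) <= 0:
            raise ValidationError("compartment multipliers must be positive")


@dataclass
class SimTruth:
    biases: dict[str, np.ndarray]
    compartment_labels: dict[str, np.ndarray]   # 'A' / 'B' per bin
    hotspots: list[dict]                        # chrom pair + bin ranges + fold
    breakpoints: list[dict]                     # planted read-level events
    catalog_labels: list[str]                   # 'true' / 'null' per catalog row


def simulate_genome(config: SimConfig) -> tuple[GenomeAssembly, list[CytoBand]]:
    """Assembly plus a cytoband table: per chromosome, p-arm bands p13..p11,
    a two-band acen centromere at the middle, then q-arm bands q11..;
    alternating gneg/gpos stains."""
    names = tuple(f"chr{i + 1}" for i in range(config.n_chroms))
    assembly = GenomeAssembly(names, tuple([config.chrom_length] * config.n_chroms))
    bands: list[CytoBand] = []
    bw = config.band_width_bins * config.bin_size
    for chrom in names:
        L = config.chrom_length
        mid = (L // 2 // config.bin_size) * config.bin_size
        acen_half = config.bin_size  # one bin on each side of the center
        # p arm: from mid-acen down to 0, named p12, p13, ... outward
        # (p11.x is reserved for the acen band so prefix lookups stay unique)
        pos = mid - acen_half
        idx = 12
        p_bands = []
        while pos > 0:
            start = max(0, pos - bw)
            p_bands.append((start, pos, f"p{idx}"))
            pos = start
            idx += 1
        for k, (s, e, name) in enumerate(p_bands):
            stain = "gneg" if k % 2 == 0 else "gpos50"
            bands.append(CytoBand(chrom, s, e, name, stain))
        bands.append(CytoBand(chrom, mid - acen_half, mid, "p11.1", "acen"))
        bands.append(CytoBand(chrom, mid, mid + acen_half, "q11.1", "acen"))
        pos = mid + acen_half
        idx = 12  # q11.1 is the acen band; numbered bands continue at q12
        while pos < L:
            end = min(L, pos + bw)
            stain = "gneg" if idx % 2 == 0 else "gpos50"
            bands.append(CytoBand(chrom, pos, end, f"q{idx}", stain))
            pos = end
            idx += 1
    bands.sort(key=lambda b: (b.chrom, b.start))
    return assembly, bands


def cytoband_text(bands: list[CytoBand]) -> str:
    return "".join(
        f"{b.chrom}\t{b.start}\t{b.end}\t{b.name}\t{b.stain}\n" for b in bands
    )


def draw_biases(config: SimConfig, scheme: BinScheme, rng) -> dict[str, np.ndarray]:
    return {
        c: np.exp(rng.normal(0.0, config.bias_sigma, scheme.n_bins(c)))
        for c in scheme.assembly.names
    }


def draw_compartments(config: SimConfig, scheme: BinScheme, rng) -> dict[str, np.ndarray]:
    """Alternating A/B blocks with geometric block lengths."""
    labels = {}
    for c in scheme.assembly.names:
        n = scheme.n_bins(c)
        lab = np.empty(n, dtype="<U1")
        cur = "A" if rng.integers(2) == 0 else "B"
        i = 0
        while i < n:
            ln = 1 + rng.geometric(1.0 / config.compartment_block_mean)
            lab[i : i + ln] = cur
            cur = "B" if cur == "A" else "A"
            i += ln
        labels[c] = lab
    return labels


def place_hotspots(
    config: SimConfig, scheme: BinScheme, bands: list[CytoBand], rng
) -> list[dict]:
    """Random trans hotspots, each a pair of named (non-acen) cytogenetic
    bands whose full bin block gets the fold multiplier. Band-aligned blocks
    mirror the analysis model, where the proximity hotspot spans the
    translocating band pair."""
    names = scheme.assembly.names
    by_chrom: dict[str, list[CytoBand]] = {}
    for b in bands:
        if b.stain != "acen":
            by_chrom.setdefault(b.chrom, []).append(b)
    hotspots = []
    bs = scheme.bin_size
    for _ in range(config.n_hotspots):
        i, j = sorted(rng.choice(len(names), size=2, replace=False))
        c1, c2 = names[i], names[j]
        b1 = by_chrom[c1][int(rng.integers(len(by_chrom[c1])))]
        b2 = by_chrom[c2][int(rng.integers(len(by_chrom[c2])))]
        hotspots.append({
            "chrom1": c1, "band1": b1.name,
            "bins1": (b1.start // bs, -(-b1.end // bs)),
            "chrom2": c2, "band2": b2.name,
            "bins2": (b2.start // bs, -(-b2.end // bs)),
            "fold": config.hotspot_fold,
        })
    return hotspots


def simulate_trans_map(
    config: SimConfig,
    scheme: BinScheme,
    biases: dict[str, np.ndarray],
    labels: dict[str, np.ndarray] | None,
    hotspots: list[dict],
    rng,
) -> RawContactMap:
    """O_ij ~ Poisson(lambda b_i b_j m_comp f_hot) independently per trans
    bin pair."""
    cmap = RawContactMap(scheme)
    names = scheme.assembly.names
    mult = {
        ("A", "A"): config.m_aa, ("B", "B"): config.m_bb,
        ("A", "B"): config.m_ab, ("B", "A"): config.m_ab,
    }
    for ii in range(len(names)):
        for jj in range(ii + 1, len(names)):
            c1, c2 = names[ii], names[jj]
            lam = config.base_rate * np.outer(biases[c1], biases[c2])
            if labels is not None:
                comp = np.array([
                    [mult[(a, b)] for b in labels[c2]] for a in labels[c1]
                ])
                lam = lam * comp
            for h in hotspots:
                if (h["chrom1"], h["chrom2"]) == (c1, c2):
                    r, c = h["bins1"], h["bins2"]
                    lam[r[0]:r[1], c[0]:c[1]] *= h["fold"]
                elif (h["chrom1"], h["chrom2"]) == (c2, c1):
                    r, c = h["bins2"], h["bins1"]
                    lam[r[0]:r[1], c[0]:c[1]] *= h["fold"]
            counts = rng.poisson(lam)
            block = cmap._ensure((ii, jj))
            block += counts
    return cmap


def sample_decay_distances(
    n: int, span: float, alpha: float, delta: float, rng
) -> np.ndarray:
    """Total distances s with density proportional to (s + delta)^(-alpha)
    on [0, span], by closed-form inverse-CDF sampling."""
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        return delta * ((span + delta) / delta) ** u - delta
    a1 = 1.0 - alpha
    lo, hi = delta ** a1, (span + delta) ** a1
    return (lo + u * (hi - lo)) ** (1.0 / a1) - delta


def simulate_translocation_reads(
    breakpoint: tuple[str, int, str, int],
    orientation: str,
    n_reads: int,
    rng,
    *,
    alpha: float = 1.0,
    delta: float = 1_000.0,
    span: float = 1_400_000.0,
    chrom_lengths: dict[str, int] | None = None,
) -> list[tuple[str, int, str, int]]:
    """Read pairs filling one quadrant from the breakpoint corner with the
    sum of the two distances following a truncated power law.

    orientation '+-' means reads at (x0 + d1, y0 - d2); the distance sum
    d1 + d2 has density ~ (s + delta)^(-alpha) on [0, span], split uniformly
    between the two axes."""
    c1, x0, c2, y0 = breakpoint
    s1 = 1 if orientation[0] == "+" else -1
    s2 = 1 if orientation[1] == "+" else -1
    s = sample_decay_distances(n_reads, span, alpha, delta, rng)
    u = rng.random(n_reads)
    d1, d2 = s * u, s * (1 - u)
    x = x0 + s1 * d1
    y = y0 + s2 * d2
    if chrom_lengths is not None:
        x = np.clip(x, 0, chrom_lengths[c1] - 1)
        y = np.clip(y, 0, chrom_lengths[c2] - 1)
    return [
        (c1, int(xi), c2, int(yi)) for xi, yi in zip(x, y)
    ]


def simulate_background_reads(
    config: SimConfig, scheme: BinScheme, rng
) -> list[tuple[str, int, str, int]]:
    """Uniform trans read pairs, ``background_read_rate`` per bin pair."""
    out = []
    names = scheme.assembly.names
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            c1, c2 = names[i], names[j]
            n = rng.poisson(
                config.background_read_rate
                * scheme.n_bins(c1) * scheme.n_bins(c2)
            )
            x = rng.integers(0, scheme.assembly.length(c1), size=n)
            y = rng.integers(0, scheme.assembly.length(c2), size=n)
            out.extend((c1, int(a), c2, int(b)) for a, b in zip(x, y))
    return out


def _band_center(region: GenomicRegion) -> int:
    return (region.start + region.end) // 2


def simulate_catalog(
    config: SimConfig,
    scheme: BinScheme,
    bands: list[CytoBand],
    hotspots: list[dict],
    rng,
) -> tuple[list[dict], list[str]]:
    """Catalog rows: n_true pairs on hotspot band pairs, n_null pairs on
    uniformly random inter-chromosomal band pairs.

    Each row carries the karyotype notation, the two band regions, a
    breakpoint position at each band's midpoint, and metadata. Returns
    (rows, labels)."""
    if config.n_true > 0 and not hotspots:
        raise ValidationError("n_true > 0 requires hotspots")
    named = [
        b for b in bands
        if b.stain != "acen"
    ]
    by_chrom: dict[str, list[CytoBand]] = {}
    for b in named:
        by_chrom.setdefault(b.chrom, []).append(b)

    def bands_in_bins(chrom: str, bin_range: tuple[int, int]) -> list[CytoBand]:
        lo = bin_range[0] * scheme.bin_size
        hi = bin_range[1] * scheme.bin_size
        return [b for b in by_chrom[chrom] if b.start < hi and b.end > lo]

    rows, labels = [], []

    def emit(c1, band1, c2, band2, label):
        i1, i2 = scheme.assembly.index(c1), scheme.assembly.index(c2)
        if i1 > i2:
            c1, band1, c2, band2 = c2, band2, c1, band1
        r1 = band_to_region(c1, band1.name, bands)
        r2 = band_to_region(c2, band2.name, bands)
        notation = (
            f"t({c1.removeprefix('chr')};{c2.removeprefix('chr')})"
            f"({band1.name};{band2.name})"
        )
        rows.append({
            "notation": notation,
            "region_a": r1, "region_b": r2,
            "pos_a": _band_center(r1), "pos_b": _band_center(r2),
            "tissue_class": "blood" if label == "true" else "non_blood",
            "recurrence_count": int(rng.integers(1, 20)),
        })
        labels.append(label)

    def band_by_name(chrom: str, name: str) -> CytoBand:
        for b in by_chrom[chrom]:
            if b.name == name:
                return b
        raise ValidationError(f"hotspot band {name} not found on {chrom}")

    for k in range(config.n_true):
        h = hotspots[int(rng.integers(len(hotspots)))]
        if "band1" in h:
            b1 = band_by_name(h["chrom1"], h["band1"])
            b2 = band_by_name(h["chrom2"], h["band2"])
        else:
            cand1 = bands_in_bins(h["chrom1"], h["bins1"])
            cand2 = bands_in_bins(h["chrom2"], h["bins2"])
            if not cand1 or not cand2:
                raise ValidationError("hotspot overlaps no named band")
            b1 = cand1[int(rng.integers(len(cand1)))]
            b2 = cand2[int(rng.integers(len(cand2)))]
        emit(h["chrom1"], b1, h["chrom2"], b2, "true")

    names = scheme.assembly.names
    for k in range(config.n_null):
        i, j = sorted(rng.choice(len(names), size=2, replace=False))
        c1, c2 = names[i], names[j]
        b1 = by_chrom[c1][int(rng.integers(len(by_chrom[c1])))]
        b2 = by_chrom[c2][int(rng.integers(len(by_chrom[c2])))]
        emit(c1, b1, c2, b2, "null")
    return rows, labels


def simulate_genes(
    config: SimConfig,
    scheme: BinScheme,
    labels: dict[str, np.ndarray] | None,
    rng,
) -> list[tuple[str, int, int]]:
    """One gene interval per bin, covering gene_frac_a of A bins and
    gene_frac_b of B bins (all bins use gene_frac_a when no compartments)."""
    genes = []
    bs = scheme.bin_size
    for chrom in scheme.assembly.names:
        for b in range(scheme.n_bins(chrom)):
            lab = labels[chrom][b] if labels is not None else "A"
            frac = config.gene_frac_a if lab == "A" else config.gene_frac_b
            width = int(frac * bs)
            if width == 0:
                continue
            start = b * bs + int(rng.integers(0, bs - width + 1))
            genes.append((chrom, start, start + width))
    return genes


@dataclass
class SimulatedDataset:
    config: SimConfig
    assembly: GenomeAssembly
    scheme: BinScheme
    bands: list[CytoBand]
    contact_map: RawContactMap
    genes: list[tuple[str, int, int]]
    catalog_rows: list[dict]
    reads: list[tuple[str, int, str, int]]
    truth: SimTruth

    def catalog_pairs(self) -> list[TranslocationPair]:
        pairs = []
        for row, label in zip(self.catalog_rows, self.truth.catalog_labels):
            pairs.append(TranslocationPair(
                row["region_a"], row["region_b"], "synthetic",
                row["tissue_class"], row["recurrence_count"], row["notation"],
            ))
        return pairs


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate every pipeline input from one config and seed."""
    rng = np.random.default_rng(config.rng_seed)
    assembly, bands = simulate_genome(config)
    scheme = BinScheme(assembly, config.bin_size)
    biases = draw_biases(config, scheme, rng)
    labels = draw_compartments(config, scheme, rng) if config.use_compartments else None
    hotspots = place_hotspots(config, scheme, bands, rng)
    cmap = simulate_trans_map(config, scheme, biases, labels, hotspots, rng)
    genes = simulate_genes(config, scheme, labels, rng)
    rows, cat_labels = simulate_catalog(config, scheme, bands, hotspots, rng)
    reads = simulate_background_reads(config, scheme, rng)
    truth = SimTruth(
        biases=biases,
        compartment_labels=labels if labels is not None else {},
        hotspots=hotspots,
        breakpoints=[],
        catalog_labels=cat_labels,
    )
    return SimulatedDataset(
        config, assembly, scheme, bands, cmap, genes, rows, reads, truth
    )


# ---------------------------------------------------------------------------
# file emission


def write_dataset(ds: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write every input file kind under ``out_dir``; returns the paths."""
    from .contacts import write_triplets

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["cytoband"] = out / "cytoBand.txt"
    paths["cytoband"].write_text(cytoband_text(ds.bands))

    paths["chrom_sizes"] = out / "chrom.sizes"
    paths["chrom_sizes"].write_text("".join(
        f"{n}\t{l}\n" for n, l in zip(ds.assembly.names, ds.assembly.lengths)
    ))

    paths["contacts"] = out / "contacts.tsv"
    with open(paths["contacts"], "w") as fh:
        fh.write("# chrom1\tstart1\tchrom2\tstart2\tcount\n")
        write_triplets(ds.contact_map, fh)

    paths["genes"] = out / "genes.bed"
    paths["genes"].write_text("".join(
        f"{c}\t{s}\t{e}\tgene_{i}\n" for i, (c, s, e) in enumerate(ds.genes)
    ))

    paths["karyotypes"] = out / "catalog_karyotype.tsv"
    with open(paths["karyotypes"], "w") as fh:
        fh.write("notation\tdataset_id\ttissue_class\trecurrence_count\n")
        for row in ds.catalog_rows:
            fh.write(
                f"{row['notation']}\tsynthetic\t{row['tissue_class']}\t"
                f"{row['recurrence_count']}\n"
            )

    paths["breakpoints"] = out / "catalog_breakpoints.tsv"
    with open(paths["breakpoints"], "w") as fh:
        fh.write("chrom1\tpos1\tchrom2\tpos2\tsupporting_reads\tdataset_id\n")
        for row in ds.catalog_rows:
            fh.write(
                f"{row['region_a'].chrom}\t{row['pos_a']}\t"
                f"{row['region_b'].chrom}\t{row['pos_b']}\t5\tsynthetic\n"
            )

    paths["reads"] = out / "reads.tsv"
    paths["reads"].write_text("".join(
        f"{c1}\t{p1}\t{c2}\t{p2}\n" for c1, p1, c2, p2 in ds.reads
    ))

    paths["truth"] = out / "truth.yaml"
    truth = {
        "seed": ds.config.rng_seed,
        "catalog_labels": ds.truth.catalog_labels,
        "hotspots": [
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in h.items()}
            for h in ds.truth.hotspots
        ],
        "compartment_labels": {
            c: "".join(v) for c, v in ds.truth.compartment_labels.items()
        },
        "biases": {
            c: [float(x) for x in v] for c, v in ds.truth.biases.items()
        },
    }
    paths["truth"].write_text(yaml.safe_dump(truth, sort_keys=True))
    return paths
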