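"""Genome bookkeeping: assemblies, bin schemes, cytogenetic bands, catalogs.

All coordinates are 0-based half-open, including cytoBand input (the UCSC
convention). Regions are snapped to whole bins (floor start, ceil end) before
any bin-level computation, matching an analysis that operates on the set of
1-Mb bins overlapping a chromosomal band.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

import numpy as np

from .errors import LookupError_, ParseError, ValidationError

# ---------------------------------------------------------------------------
# assemblies and bin schemes


@dataclass(frozen=True)
class GenomeAssembly:
    """An ordered set of chromosomes with lengths in base pairs."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self):
        if len(self.names) != len(set(self.names)):
            raise ValidationError("chromosome names must be unique")
        if len(self.names) != len(self.lengths):
            raise ValidationError("names and lengths differ in length")
        if any(l <= 0 for l in self.lengths):
            raise ValidationError("chromosome lengths must be positive")

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    def index(self, chrom: str) -> int:
        try:
            return self.names.index(chrom)
        except ValueError:
            raise LookupError_(f"unknown chromosome {chrom!r}") from None

    def length(self, chrom: str) -> int:
        return self.lengths[self.index(chrom)]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names


class BinScheme:
    """Fixed-width binning of an assembly; the last bin of a chromosome may be
    truncated. Global bin indices concatenate chromosomes in assembly order."""

    def __init__(self, assembly: GenomeAssembly, bin_size: int = 1_000_000):
        if bin_size <= 0:
            raise ValidationError("bin_size must be positive")
        self.assembly = assembly
        self.bin_size = int(bin_size)
        self._n_bins = tuple(
            int(-(-l // self.bin_size)) for l in assembly.lengths
        )
        self._offsets = tuple(
            int(x) for x in np.concatenate([[0], np.cumsum(self._n_bins)[:-1]])
        )

    @property
    def total_bins(self) -> int:
        return sum(self._n_bins)

    def n_bins(self, chrom: str) -> int:
        return self._n_bins[self.assembly.index(chrom)]

    def offset(self, chrom: str) -> int:
        return self._offsets[self.assembly.index(chrom)]

    def bin_of(self, chrom: str, pos: int) -> int:
        """Local (per-chromosome) bin ordinal containing ``pos``."""
        if not 0 <= pos < self.assembly.length(chrom):
            raise ValidationError(
                f"position {pos} outside {chrom} "
                f"(length {self.assembly.length(chrom)})"
            )
        return pos // self.bin_size

    def global_index(self, chrom: str, pos: int) -> int:
        return self.offset(chrom) + self.bin_of(chrom, pos)

    def bin_region(self, chrom: str, local_bin: int) -> "GenomicRegion":
        start = local_bin * self.bin_size
        end = min(start + self.bin_size, self.assembly.length(chrom))
        return GenomicRegion(chrom, start, end)

    def chrom_of_global(self, gidx: int) -> tuple[str, int]:
        """Map a global bin index back to (chrom, local ordinal)."""
        for name, off, n in zip(self.assembly.names, self._offsets, self._n_bins):
            if off <= gidx < off + n:
                return name, gidx - off
        raise ValidationError(f"global bin index {gidx} out of range")

    def snap(self, region: "GenomicRegion") -> "GenomicRegion":
        """Expand a region to whole-bin boundaries (floor start, ceil end)."""
        start = (region.start // self.bin_size) * self.bin_size
        end = min(
            -(-region.end // self.bin_size) * self.bin_size,
            self.assembly.length(region.chrom),
        )
        return GenomicRegion(region.chrom, start, end)

    def region_bins(self, region: "GenomicRegion") -> np.ndarray:
        """Local bin ordinals overlapped by the region."""
        first = region.start // self.bin_size
        last = -(-region.end // self.bin_size)
        return np.arange(first, min(last, self.n_bins(region.chrom)))

    def region_global_bins(self, region: "GenomicRegion") -> np.ndarray:
        return self.region_bins(region) + self.offset(region.chrom)


@dataclass(frozen=True, order=True)
class GenomicRegion:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid region {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# cytogenetic bands


@dataclass(frozen=True)
class CytoBand:
    chrom: str
    start: int
    end: int
    name: str
    stain: str

    @property
    def is_centromere(self) -> bool:
        return self.stain == "acen"


def parse_cytoband(stream: TextIO | Iterable[str]) -> list[CytoBand]:
    """Parse UCSC cytoBand text (5 tab-separated columns, 0-based half-open).

    Bands are validated to be non-overlapping within each chromosome and are
    returned sorted by (chrom, start).
    """
    bands: list[CytoBand] = []
    for i, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 5:
            raise ParseError(f"expected 5 tab-separated columns, got {len(cols)}", i)
        chrom, start_s, end_s, name, stain = cols
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(f"non-integer coordinates {start_s!r}/{end_s!r}", i)
        if not 0 <= start < end:
            raise ParseError(f"invalid interval [{start}, {end})", i)
        bands.append(CytoBand(chrom, start, end, name, stain))
    bands.sort(key=lambda b: (b.chrom, b.start))
    prev: CytoBand | None = None
    for b in bands:
        if prev is not None and prev.chrom == b.chrom and b.start < prev.end:
            raise ValidationError(
                f"overlapping bands {prev.name} and {b.name} on {b.chrom}"
            )
        prev = b
    return bands


def _band_matches(name: str, label: str) -> bool:
    # Prefix-complete match: "q34" matches q34, q34.1, q34.11 but never q3 -> q34.
    if name == label:
        return True
    return name.startswith(label) and name[len(label)] == "."


def band_to_region(
    chrom: str, band_label: str, bands: Sequence[CytoBand]
) -> GenomicRegion:
    """Union (min start, max end) of all bands on ``chrom`` matching the label
    exactly or extending it by sub-band digits ("q34" covers q34.1, q34.11...)."""
    hits = [
        b for b in bands if b.chrom == chrom and _band_matches(b.name, band_label)
    ]
    if not hits:
        raise LookupError_(f"no band matching {band_label!r} on {chrom}")
    return GenomicRegion(
        chrom, min(b.start for b in hits), max(b.end for b in hits)
    )


# ---------------------------------------------------------------------------
# translocation catalogs


@dataclass(frozen=True)
class TranslocationPair:
    """Two inter-chromosomal partner regions with catalog metadata."""

    region_a: GenomicRegion
    region_b: GenomicRegion
    dataset_id: str = ""
    tissue_class: str = "unspecified"
    recurrence_count: int = 0
    source_label: str = ""

    def __post_init__(self):
        if self.region_a.chrom == self.region_b.chrom:
            raise ValidationError("translocation pairs must be inter-chromosomal")
        if self.recurrence_count < 0:
            raise ValidationError("recurrence_count must be non-negative")

    def canonical(self, assembly: GenomeAssembly) -> "TranslocationPair":
        """Order regions so the lower-index chromosome comes first."""
        ia = assembly.index(self.region_a.chrom)
        ib = assembly.index(self.region_b.chrom)
        if ia <= ib:
            return self
        return TranslocationPair(
            self.region_b, self.region_a, self.dataset_id,
            self.tissue_class, self.recurrence_count, self.source_label,
        )


@dataclass(frozen=True)
class Rejection:
    source_label: str
    reason: str  # whole_arm | too_many_partners | intra_chromosomal | low_support


_KARYOTYPE_RE = re.compile(
    r"^t\(([^)]+)\)\(([^)]+)\)$"
)
_BAND_LABEL_RE = re.compile(r"^[pq](?:\d+(?:\.\d+)?)?$")


def parse_karyotype(
    notation: str,
    bands: Sequence[CytoBand],
    *,
    chrom_prefix: str = "chr",
) -> tuple[list[tuple[GenomicRegion, GenomicRegion]], str | None]:
    """Decompose a karyotype record ``t(c1;c2[;c3])(b1;b2[;b3])`` into
    region pairs.

    Returns (pairs, rejection_reason). A 2-way record yields one pair; a 3-way
    record yields its three 2-way pairs. Records with >3 partners, whole-arm
    band labels (bare "p"/"q"), or two partners on the same chromosome are
    rejected with a reason code rather than silently dropped.
    """
    m = _KARYOTYPE_RE.match(notation.strip())
    if m is None:
        raise ParseError(f"unparseable karyotype notation {notation!r}")
    chroms = [c.strip() for c in m.group(1).split(";")]
    labels = [b.strip() for b in m.group(2).split(";")]
    if len(chroms) != len(labels):
        raise ParseError(
            f"{notation!r}: {len(chroms)} chromosomes but {len(labels)} bands"
        )
    if len(chroms) < 2:
        raise ParseError(f"{notation!r}: need at least two partners")
    if len(chroms) > 3:
        return [], "too_many_partners"
    for lab in labels:
        if not _BAND_LABEL_RE.match(lab):
            raise ParseError(f"{notation!r}: bad band label {lab!r}")
        if lab in ("p", "q"):
            return [], "whole_arm"
    if len(set(chroms)) != len(chroms):
        return [], "intra_chromosomal"

    band_chroms = {b.chrom for b in bands}
    regions = []
    for c, lab in zip(chroms, labels):
        full = c if c in band_chroms else chrom_prefix + c
        regions.append(band_to_region(full, lab, bands))
    pairs = [
        (regions[i], regions[j])
        for i in range(len(regions))
        for j in range(i + 1, len(regions))
    ]
    return pairs, None


def read_karyotype_catalog(
    stream: TextIO | Iterable[str],
    bands: Sequence[CytoBand],
    assembly: GenomeAssembly,
) -> tuple[list[TranslocationPair], list[Rejection]]:
    """Read a TSV catalog with columns
    notation, dataset_id, tissue_class, recurrence_count (header optional)."""
    pairs: list[TranslocationPair] = []
    rejections: list[Rejection] = []
    for i, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if cols[0] == "notation":
            continue
        if len(cols) != 4:
            raise ParseError("expected 4 columns (notation, dataset_id, "
                             f"tissue_class, recurrence_count), got {len(cols)}", i)
        notation, dataset_id, tissue, rec = cols
        region_pairs, reason = parse_karyotype(notation, bands)
        if reason is not None:
            rejections.append(Rejection(notation, reason))
            continue
        for ra, rb in region_pairs:
            pairs.append(
                TranslocationPair(
                    ra, rb, dataset_id, tissue, int(rec), notation
                ).canonical(assembly)
            )
    return pairs, rejections


def breakpoints_to_pairs(
    records: Iterable[Sequence],
    scheme: BinScheme,
    *,
    min_supporting_reads: int = 3,
) -> tuple[list[TranslocationPair], list[Rejection]]:
    """Map breakpoint records (chrom1, pos1, chrom2, pos2, supporting_reads
    [, dataset_id]) to pairs of the 1-bin regions containing each position.

    Records with fewer than ``min_supporting_reads`` supporting reads and
    intra-chromosomal records are dropped with a reason code.
    """
    pairs: list[TranslocationPair] = []
    rejections: list[Rejection] = []
    for rec in records:
        chrom1, pos1, chrom2, pos2, reads = (
            rec[0], int(rec[1]), rec[2], int(rec[3]), int(rec[4])
        )
        dataset_id = str(rec[5]) if len(rec) > 5 else ""
        label = f"{chrom1}:{pos1}-{chrom2}:{pos2}"
        if reads < min_supporting_reads:
            rejections.append(Rejection(label, "low_support"))
            continue
        if chrom1 == chrom2:
            rejections.append(Rejection(label, "intra_chromosomal"))
            continue
        ra = scheme.bin_region(chrom1, scheme.bin_of(chrom1, pos1))
        rb = scheme.bin_region(chrom2, scheme.bin_of(chrom2, pos2))
        pairs.append(
            TranslocationPair(
                ra, rb, dataset_id, "unspecified", 0, label
            ).canonical(scheme.assembly)
        )
    return pairs, rejections


def read_breakpoint_catalog(
    stream: TextIO | Iterable[str], scheme: BinScheme, **kwargs
) -> tuple[list[TranslocationPair], list[Rejection]]:
    """Read a breakpoint TSV (chrom1, pos1, chrom2, pos2, supporting_reads,
    dataset_id); header row optional."""
    records = []
    for i, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if cols[0] == "chrom1" and not cols[1].lstrip("-").isdigit():
            continue  # header row
        if len(cols) < 5:
            raise ParseError(f"expected >=5 columns, got {len(cols)}", i)
        records.append(cols)
    return breakpoints_to_pairs(records, scheme, **kwargs)


def unique_pairs(pairs: Sequence[TranslocationPair]) -> list[TranslocationPair]:
    """Deduplicate on (region_a, region_b), keeping first occurrence."""
    seen: set[tuple] = set()
    out = []
    for p in pairs:
        key = (p.region_a, p.region_b)
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


# ---------------------------------------------------------------------------
# masking


class MaskTrack:
    """Set of masked global bin indices with per-bin reasons
    ({"centromere", "no_coverage"})."""

    def __init__(self, scheme: BinScheme):
        self.scheme = scheme
        self.masked = np.zeros(scheme.total_bins, dtype=bool)
        self.reasons: dict[int, set[str]] = {}

    def add(self, gidx: int, reason: str) -> None:
        if not 0 <= gidx < self.scheme.total_bins:
            raise ValidationError(f"bin index {gidx} outside scheme")
        self.masked[gidx] = True
        self.reasons.setdefault(int(gidx), set()).add(reason)

    def is_masked(self, gidx: int) -> bool:
        return bool(self.masked[gidx])

    def chrom_mask(self, chrom: str) -> np.ndarray:
        off = self.scheme.offset(chrom)
        return self.masked[off : off + self.scheme.n_bins(chrom)]

    @property
    def n_masked(self) -> int:
        return int(self.masked.sum())

    def to_tsv(self, stream: TextIO) -> None:
        for gidx in sorted(self.reasons):
            chrom, local = self.scheme.chrom_of_global(gidx)
            r = self.scheme.bin_region(chrom, local)
            stream.write(
                f"{chrom}\t{r.start}\t{r.end}\t{','.join(sorted(self.reasons[gidx]))}\n"
            )


def build_mask(contact_map, bands: Sequence[CytoBand]) -> MaskTrack:
    """Mask bins overlapping centromeric ("acen") bands and bins with zero
    total coverage across the whole dataset."""
    scheme = contact_map.scheme
    mask = MaskTrack(scheme)
    for b in bands:
        if not b.is_centromere or b.chrom not in scheme.assembly:
            continue
        for g in scheme.region_global_bins(GenomicRegion(b.chrom, b.start, b.end)):
            mask.add(int(g), "centromere")
    marg = contact_map.global_marginal()
    for g in np.nonzero(marg == 0)[0]:
        mask.add(int(g), "no_coverage")
    return mask


# ---------------------------------------------------------------------------
# gene content and coverage summaries


def gene_content(
    region: GenomicRegion, genes: Iterable[tuple[int, int]] | Iterable
) -> float:
    """Fraction of the region's bases covered by the union of transcript
    intervals (overlaps counted once). Intervals may be (start, end) tuples or
    objects with .start/.end; only those on the region's chromosome should be
    passed, or (chrom, start, end) triples which are filtered."""
    if len(region) == 0:
        raise ValidationError("empty region")
    ivals = []
    for g in genes:
        if hasattr(g, "start"):
            chrom, s, e = getattr(g, "chrom", region.chrom), g.start, g.end
        elif len(g) == 3:
            chrom, s, e = g
        else:
            chrom, (s, e) = region.chrom, g
        if chrom != region.chrom:
            continue
        s, e = max(int(s), region.start), min(int(e), region.end)
        if s < e:
            ivals.append((s, e))
    if not ivals:
        return 0.0
    ivals.sort()
    covered = 0
    cur_s, cur_e = ivals[0]
    for s, e in ivals[1:]:
        if s > cur_e:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s
    return covered / len(region)


def read_bed3(stream: TextIO | Iterable[str]) -> list[tuple[str, int, int]]:
    """Read BED3+ gene annotations; only chrom/start/end are used."""
    out = []
    for i, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise ParseError(f"expected >=3 BED columns, got {len(cols)}", i)
        out.append((cols[0], int(cols[1]), int(cols[2])))
    return out


def dataset_coverage(
    pairs: Sequence[TranslocationPair],
    scheme: BinScheme,
    mask: MaskTrack | None = None,
) -> dict[str, float]:
    """Genome fraction covered by the union of all catalog regions, and the
    fraction of unmasked trans bin pairs covered by any pair's region-a x
    region-b block."""
    if not pairs:
        raise ValidationError("empty catalog")
    # genome fraction: union of region base intervals per chromosome
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in pairs:
        for r in (p.region_a, p.region_b):
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    covered = 0
    for ivals in by_chrom.values():
        ivals.sort()
        cur_s, cur_e = ivals[0]
        for s, e in ivals[1:]:
            if s > cur_e:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        covered += cur_e - cur_s
    genome_fraction = covered / scheme.assembly.total_length

    masked = mask.masked if mask is not None else np.zeros(
        scheme.total_bins, dtype=bool
    )
    unmasked_per_chrom = [
        int((~masked[scheme.offset(c) : scheme.offset(c) + scheme.n_bins(c)]).sum())
        for c in scheme.assembly.names
    ]
    total_trans = 0
    for i in range(len(unmasked_per_chrom)):
        for j in range(i + 1, len(unmasked_per_chrom)):
            total_trans += unmasked_per_chrom[i] * unmasked_per_chrom[j]
    covered_pairs: set[tuple[int, int]] = set()
    for p in pairs:
        ga = [g for g in scheme.region_global_bins(p.region_a) if not masked[g]]
        gb = [g for g in scheme.region_global_bins(p.region_b) if not masked[g]]
        for a in ga:
            for b in gb:
                covered_pairs.add((min(a, b), max(a, b)))
    trans_bin_fraction = len(covered_pairs) / total_trans if total_trans else 0.0
    return {
        "genome_fraction": genome_fraction,
        "trans_bin_fraction": trans_bin_fraction,
    }
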