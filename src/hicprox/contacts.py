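"""Binned trans contact maps, the per-bin expected model, and the Hi-C score.

The Hi-C score of a trans bin pair is log2((O + c) / (E + c)): the observed
count O over the count E expected from the two bins' coverage alone, with a
pseudocount c guarding zero counts. E is a marginal-product model computed
per chromosome pair (E_ij = m_i m_j / T over unmasked bins), optionally
passed through a linear smoothing filter and renormalized so the expected
total matches the observed total exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np
from scipy.signal import convolve2d

from .errors import ParseError, ValidationError
from .regions import BinScheme, MaskTrack


class RawContactMap:
    """Per-chromosome-pair matrices of non-negative trans contact counts.

    A pair is stored once under canonical chromosome order (assembly order);
    queries in either orientation return the appropriately transposed block.
    """

    def __init__(self, scheme: BinScheme):
        self.scheme = scheme
        self._blocks: dict[tuple[int, int], np.ndarray] = {}

    # -- storage -----------------------------------------------------------

    def _canonical(self, chrom1: str, chrom2: str) -> tuple[int, int, bool]:
        i1 = self.scheme.assembly.index(chrom1)
        i2 = self.scheme.assembly.index(chrom2)
        if i1 == i2:
            raise ValidationError("trans map holds inter-chromosomal pairs only")
        return (i1, i2, False) if i1 < i2 else (i2, i1, True)

    def _ensure(self, key: tuple[int, int]) -> np.ndarray:
        if key not in self._blocks:
            names = self.scheme.assembly.names
            self._blocks[key] = np.zeros(
                (self.scheme.n_bins(names[key[0]]), self.scheme.n_bins(names[key[1]])),
                dtype=np.int64,
            )
        return self._blocks[key]

    def add_count(
        self, chrom1: str, bin1: int, chrom2: str, bin2: int, count: int
    ) -> None:
        if count < 0:
            raise ValidationError("counts must be non-negative")
        i1, i2, swapped = self._canonical(chrom1, chrom2)
        block = self._ensure((i1, i2))
        r, c = (bin2, bin1) if swapped else (bin1, bin2)
        if not (0 <= r < block.shape[0] and 0 <= c < block.shape[1]):
            raise ValidationError(
                f"bin ({bin1},{bin2}) outside {chrom1}x{chrom2} block"
            )
        block[r, c] += count

    def block(self, chrom1: str, chrom2: str) -> np.ndarray:
        """Counts oriented as (chrom1 bins, chrom2 bins); zeros if untouched."""
        i1, i2, swapped = self._canonical(chrom1, chrom2)
        b = self._ensure((i1, i2))
        return b.T if swapped else b

    @property
    def chrom_pairs(self) -> list[tuple[str, str]]:
        names = self.scheme.assembly.names
        return [(names[i], names[j]) for i, j in sorted(self._blocks)]

    def all_chrom_pairs(self) -> list[tuple[str, str]]:
        """Every inter-chromosomal pair of the assembly, canonical order."""
        names = self.scheme.assembly.names
        return [
            (names[i], names[j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]

    def global_marginal(self) -> np.ndarray:
        """Per-global-bin total counts over all trans partners."""
        marg = np.zeros(self.scheme.total_bins, dtype=np.int64)
        names = self.scheme.assembly.names
        for (i, j), block in self._blocks.items():
            marg[self.scheme.offset(names[i]) : self.scheme.offset(names[i])
                 + block.shape[0]] += block.sum(axis=1)
            marg[self.scheme.offset(names[j]) : self.scheme.offset(names[j])
                 + block.shape[1]] += block.sum(axis=0)
        return marg

    @property
    def total_count(self) -> int:
        return int(sum(b.sum() for b in self._blocks.values()))


def read_triplets(stream: TextIO | Iterable[str], scheme: BinScheme) -> RawContactMap:
    """Read sparse triplet contact text: chrom1, start1, chrom2, start2, count
    (tab-separated; "#" comments). Duplicate triplets accumulate."""
    cmap = RawContactMap(scheme)
    for i, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 5:
            raise ParseError(f"expected 5 columns, got {len(cols)}", i)
        chrom1, s1, chrom2, s2, cnt = cols
        start1, start2, count = int(s1), int(s2), int(cnt)
        if count < 0:
            raise ParseError(f"negative count {count}", i)
        if start1 % scheme.bin_size or start2 % scheme.bin_size:
            raise ParseError(
                f"start not aligned to bin size {scheme.bin_size}", i
            )
        cmap.add_count(
            chrom1, scheme.bin_of(chrom1, start1),
            chrom2, scheme.bin_of(chrom2, start2), count,
        )
    return cmap


def write_triplets(cmap: RawContactMap, stream: TextIO) -> None:
    bs = cmap.scheme.bin_size
    for c1, c2 in cmap.chrom_pairs:
        block = cmap.block(c1, c2)
        for r, c in zip(*np.nonzero(block)):
            stream.write(
                f"{c1}\t{r * bs}\t{c2}\t{c * bs}\t{int(block[r, c])}\n"
            )


def bin_read_pairs(
    reads: Iterable[Sequence],
    scheme: BinScheme,
    *,
    chrom_filter: tuple[str, str] | None = None,
) -> RawContactMap:
    """Bin read-pair records (chrom1, pos1, chrom2, pos2, ...) into a count
    map at the scheme's resolution. Each pair increments exactly one bin pair;
    intra-chromosomal pairs are skipped (the map is trans-only)."""
    cmap = RawContactMap(scheme)
    for idx, rec in enumerate(reads):
        chrom1, pos1, chrom2, pos2 = rec[0], int(rec[1]), rec[2], int(rec[3])
        if chrom1 == chrom2:
            continue
        if chrom_filter is not None and {chrom1, chrom2} != set(chrom_filter):
            continue
        try:
            b1 = scheme.bin_of(chrom1, pos1)
            b2 = scheme.bin_of(chrom2, pos2)
        except ValidationError as e:
            raise ValidationError(f"read record {idx}: {e}") from None
        cmap.add_count(chrom1, b1, chrom2, b2, 1)
    return cmap


def read_pairs_file(stream: TextIO | Iterable[str]) -> list[tuple[str, int, str, int]]:
    """Read read-pair text (chrom1, pos1, chrom2, pos2 [, strands...])."""
    out = []
    for i, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 4:
            raise ParseError(f"expected >=4 columns, got {len(cols)}", i)
        out.append((cols[0], int(cols[1]), cols[2], int(cols[3])))
    return out


# ---------------------------------------------------------------------------
# expected model


@dataclass
class ExpectedModel:
    """Expected counts per chromosome pair on unmasked bins (NaN elsewhere)."""

    scheme: BinScheme
    blocks: dict[tuple[str, str], np.ndarray]
    provenance: str  # marginal-product | smoothed | iterative
    uncomputable: set[tuple[str, str]] = field(default_factory=set)

    def block(self, chrom1: str, chrom2: str) -> np.ndarray:
        if (chrom1, chrom2) in self.blocks:
            return self.blocks[(chrom1, chrom2)]
        if (chrom2, chrom1) in self.blocks:
            return self.blocks[(chrom2, chrom1)].T
        raise ValidationError(f"no expected block for {chrom1} x {chrom2}")


def expected_trans(
    cmap: RawContactMap,
    mask: MaskTrack | None = None,
    *,
    iterative: bool = False,
    n_iter: int = 10,
    tol: float = 1e-6,
) -> ExpectedModel:
    """Marginal-product expected model per chromosome pair.

    With unmasked marginals m_i = sum_j O_ij and total T, E_ij = m_i m_j / T,
    which removes per-bin coverage/mappability bias and conserves the block
    total exactly. ``iterative=True`` alternates marginal rebalancing instead
    (a stronger correction; off by default). Pairs with T = 0 are flagged
    uncomputable and behave as masked downstream.
    """
    blocks: dict[tuple[str, str], np.ndarray] = {}
    uncomputable: set[tuple[str, str]] = set()
    for c1, c2 in cmap.all_chrom_pairs():
        O = cmap.block(c1, c2).astype(float)
        valid_r = ~mask.chrom_mask(c1) if mask is not None else np.ones(
            O.shape[0], dtype=bool
        )
        valid_c = ~mask.chrom_mask(c2) if mask is not None else np.ones(
            O.shape[1], dtype=bool
        )
        E = np.full(O.shape, np.nan)
        Ov = O[np.ix_(valid_r, valid_c)]
        T = Ov.sum()
        if Ov.size == 0 or T == 0:
            uncomputable.add((c1, c2))
            blocks[(c1, c2)] = E
            continue
        if not iterative:
            m_r = Ov.sum(axis=1)
            m_c = Ov.sum(axis=0)
            Ev = np.outer(m_r, m_c) / T
        else:
            # alternate row/column rebalancing toward the observed marginals
            m_r, m_c = Ov.sum(axis=1), Ov.sum(axis=0)
            Ev = np.full(Ov.shape, T / Ov.size)
            for _ in range(n_iter):
                rs = Ev.sum(axis=1)
                Ev *= np.where(rs > 0, m_r / np.where(rs > 0, rs, 1), 1)[:, None]
                cs = Ev.sum(axis=0)
                Ev *= np.where(cs > 0, m_c / np.where(cs > 0, cs, 1), 1)[None, :]
                if (np.abs(Ev.sum(axis=1) - m_r).max() < tol * max(T, 1)):
                    break
            Ev *= T / Ev.sum()
        E[np.ix_(valid_r, valid_c)] = Ev
        blocks[(c1, c2)] = E
    return ExpectedModel(
        cmap.scheme, blocks,
        "iterative" if iterative else "marginal-product", uncomputable,
    )


def smooth_expected(
    model: ExpectedModel,
    cmap: RawContactMap,
    window: int = 3,
) -> ExpectedModel:
    """Replace each expected value by the mean of defined values in its
    window x window neighborhood (masked cells excluded from the mean), then
    rescale each chromosome pair so the expected total equals the observed
    total again."""
    if window < 1 or window % 2 == 0:
        raise ValidationError("smoothing window must be odd and >= 1")
    kernel = np.ones((window, window))
    blocks: dict[tuple[str, str], np.ndarray] = {}
    for (c1, c2), E in model.blocks.items():
        if (c1, c2) in model.uncomputable or window == 1:
            blocks[(c1, c2)] = E.copy()
            continue
        valid = ~np.isnan(E)
        filled = np.where(valid, E, 0.0)
        num = convolve2d(filled, kernel, mode="same")
        den = convolve2d(valid.astype(float), kernel, mode="same")
        S = np.full(E.shape, np.nan)
        S[valid] = num[valid] / den[valid]
        O = cmap.block(c1, c2).astype(float)
        total_o = O[valid].sum()
        total_s = np.nansum(S)
        if total_s > 0:
            S *= total_o / total_s
        blocks[(c1, c2)] = S
    return ExpectedModel(model.scheme, blocks, "smoothed", set(model.uncomputable))


# ---------------------------------------------------------------------------
# Hi-C score


@dataclass
class HiCScoreMap:
    """log2((O + c)/(E + c)) per trans bin pair; NaN on masked bins."""

    scheme: BinScheme
    blocks: dict[tuple[str, str], np.ndarray]
    pseudocount: float
    mask: MaskTrack | None = None

    def block(self, chrom1: str, chrom2: str) -> np.ndarray:
        if (chrom1, chrom2) in self.blocks:
            return self.blocks[(chrom1, chrom2)]
        if (chrom2, chrom1) in self.blocks:
            return self.blocks[(chrom2, chrom1)].T
        raise ValidationError(f"no score block for {chrom1} x {chrom2}")

    def score(self, chrom1: str, bin1: int, chrom2: str, bin2: int) -> float:
        return float(self.block(chrom1, chrom2)[bin1, bin2])

    def to_triplets(self, stream: TextIO) -> None:
        bs = self.scheme.bin_size
        for (c1, c2), block in sorted(self.blocks.items()):
            for r, c in zip(*np.nonzero(~np.isnan(block))):
                stream.write(
                    f"{c1}\t{r * bs}\t{c2}\t{c * bs}\t{block[r, c]:.6g}\n"
                )


def hic_score(
    cmap: RawContactMap,
    model: ExpectedModel,
    mask: MaskTrack | None = None,
    pseudocount: float = 1.0,
) -> HiCScoreMap:
    """The Hi-C score S_ij = log2((O_ij + c)/(E_ij + c)) on unmasked bins.

    c = 0 is allowed only when every scored O is strictly positive (the log
    is otherwise undefined)."""
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    blocks: dict[tuple[str, str], np.ndarray] = {}
    for (c1, c2), E in model.blocks.items():
        O = cmap.block(c1, c2).astype(float)
        S = np.full(E.shape, np.nan)
        valid = ~np.isnan(E)
        if pseudocount == 0 and np.any(O[valid] == 0):
            raise ValidationError(
                "pseudocount 0 with zero observed counts: score undefined"
            )
        S[valid] = np.log2(
            (O[valid] + pseudocount) / (E[valid] + pseudocount)
        )
        blocks[(c1, c2)] = S
    return HiCScoreMap(cmap.scheme, blocks, pseudocount, mask)
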