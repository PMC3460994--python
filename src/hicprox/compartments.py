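"""A/B chromatin compartment assignment from trans Hi-C score correlation.

For each chromosome, the rows of its bins against all unmasked bins on other
chromosomes are correlated (Pearson); the first principal eigenvector of that
correlation matrix partitions bins into the open (positive) and closed
(negative) compartments. The eigenvector sign is anchored so that it
correlates non-negatively with an orientation reference — gene content by
default, since the open compartment is the gene-rich one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import UndefinedScoreError, ValidationError
from .contacts import HiCScoreMap
from .regions import BinScheme, GenomicRegion


def compartment_pc1(
    scores: HiCScoreMap,
    chrom: str,
    orientation_track: np.ndarray | None = None,
) -> np.ndarray:
    """First principal eigenvector of the chromosome's trans-row correlation
    matrix, unit-norm, sign-anchored to ``orientation_track``.

    Returns a vector over all bins of the chromosome, NaN at masked or
    degenerate (constant-row) bins.

    orientation_track: per-bin reference values for the chromosome (length =
    bin count); the output satisfies corr(PC1, track) >= 0 over defined bins.
    """
    scheme = scores.scheme
    n = scheme.n_bins(chrom)
    others = [c for c in scheme.assembly.names if c != chrom]
    if not others:
        raise ValidationError("compartment PC1 needs at least two chromosomes")
    rows = np.hstack([scores.block(chrom, oc) for oc in others])  # n x (trans bins)

    col_ok = ~np.isnan(rows).all(axis=0)
    rows = rows[:, col_ok]
    row_ok = ~np.isnan(rows).any(axis=1)
    idx = np.nonzero(row_ok)[0]
    if idx.size < 3:
        raise ValidationError(
            f"{chrom}: fewer than 3 unmasked bins for PC1"
        )
    X = rows[idx]
    sd = X.std(axis=1)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"{chrom}: dropping {int(const.sum())} constant score rows from PCA",
            stacklevel=2,
        )
        idx = idx[~const]
        X = X[~const]
    if X.shape[0] < 3:
        raise ValidationError(f"{chrom}: degenerate correlation matrix")

    C = np.corrcoef(X)
    if np.allclose(C, 1.0):
        # a single block (all rows identical up to scale) carries no
        # compartment contrast: the correlation matrix is rank one
        raise ValidationError(f"{chrom}: degenerate correlation matrix")
    eigvals, eigvecs = np.linalg.eigh(C)
    v = eigvecs[:, -1]
    v = v / np.linalg.norm(v)

    out = np.full(n, np.nan)
    out[idx] = v
    if orientation_track is not None:
        ref = np.asarray(orientation_track, dtype=float)
        if ref.shape[0] != n:
            raise ValidationError("orientation track length mismatch")
        both = ~np.isnan(out) & ~np.isnan(ref)
        if both.sum() >= 2 and np.std(ref[both]) > 0 and np.std(out[both]) > 0:
            r = np.corrcoef(out[both], ref[both])[0, 1]
            if r < 0:
                out = -out
    return out


@dataclass
class CompartmentTrack:
    """Oriented PC1 value per 1-Mb bin, per chromosome (NaN where undefined)."""

    scheme: BinScheme
    values: dict[str, np.ndarray]
    orientation_reference: str = "gene_content"

    @classmethod
    def from_scores(
        cls,
        scores: HiCScoreMap,
        orientation_tracks: dict[str, np.ndarray] | None = None,
        reference_name: str = "gene_content",
    ) -> "CompartmentTrack":
        values = {}
        for chrom in scores.scheme.assembly.names:
            track = (
                orientation_tracks.get(chrom)
                if orientation_tracks is not None
                else None
            )
            values[chrom] = compartment_pc1(scores, chrom, track)
        return cls(scores.scheme, values, reference_name)

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.values[chrom]

    def region_score(self, region: GenomicRegion) -> float:
        """Mean PC1 over the region's unmasked overlapping bins; raises if
        the region overlaps no defined bin (undefined, not zero)."""
        vals = self.values[region.chrom][self.scheme.region_bins(region)]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise UndefinedScoreError(
                f"no defined compartment bins in {region.chrom}:"
                f"{region.start}-{region.end}"
            )
        return float(vals.mean())

    def to_bedgraph(self, stream) -> None:
        bs = self.scheme.bin_size
        for chrom in self.scheme.assembly.names:
            for i, v in enumerate(self.values[chrom]):
                if not np.isnan(v):
                    end = min((i + 1) * bs, self.scheme.assembly.length(chrom))
                    stream.write(f"{chrom}\t{i * bs}\t{end}\t{v:.6g}\n")


def region_compartment_score(region: GenomicRegion, track: CompartmentTrack) -> float:
    return track.region_score(region)


def compartment_sign(score: float) -> str:
    """"open" for positive (and exactly zero, the fixed tie rule), "closed"
    for negative."""
    if np.isnan(score):
        raise UndefinedScoreError("compartment sign of an undefined score")
    return "open" if score >= 0 else "closed"
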