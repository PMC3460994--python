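"""Proximity scoring: the mean Hi-C score over a translocation's bin block.

The proximity score of a translocation is the mean score S(i, j) over every
pair (i, j) of unmasked 1-Mb bins with i overlapping one partner region and
j the other — the full 2-D block, so a pair of 3-bin and 4-bin bands averages
up to 12 values. Masked bin pairs are excluded and counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import UndefinedScoreError, ValidationError
from .compartments import CompartmentTrack
from .contacts import HiCScoreMap
from .regions import TranslocationPair, gene_content


@dataclass
class ProximityResult:
    pair: TranslocationPair
    proximity_score: float  # NaN when undefined
    n_bin_pairs_used: int
    n_bin_pairs_masked: int

    @property
    def defined(self) -> bool:
        return self.n_bin_pairs_used > 0 and not np.isnan(self.proximity_score)


def proximity_score(pair: TranslocationPair, scores: HiCScoreMap) -> ProximityResult:
    """Mean score over the region_a x region_b block of unmasked bin pairs."""
    scheme = scores.scheme
    ra, rb = pair.region_a, pair.region_b
    bins_a = scheme.region_bins(ra)
    bins_b = scheme.region_bins(rb)
    block = scores.block(ra.chrom, rb.chrom)[np.ix_(bins_a, bins_b)]
    valid = ~np.isnan(block)
    n_used = int(valid.sum())
    n_masked = int(block.size - n_used)
    if n_used == 0:
        return ProximityResult(pair, float("nan"), 0, n_masked)
    return ProximityResult(pair, float(block[valid].mean()), n_used, n_masked)


@dataclass
class DatasetSummary:
    dataset_id: str
    n_pairs: int
    mean_score: float
    ci95_low: float
    ci95_high: float
    n_undefined: int = 0


def summarize_dataset(
    results: Sequence[ProximityResult], dataset_id: str = ""
) -> DatasetSummary:
    """Mean proximity score with a normal-approximation 95% CI
    (mean +/- 1.96 SEM). Undefined scores are excluded and counted."""
    defined = [r.proximity_score for r in results if r.defined]
    n_undef = len(results) - len(defined)
    if len(defined) < 2:
        raise ValidationError("need >= 2 defined scores to summarize")
    arr = np.array(defined)
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size))
    return DatasetSummary(
        dataset_id, arr.size, mean, mean - 1.96 * sem, mean + 1.96 * sem, n_undef
    )


def feature_score(
    pair: TranslocationPair,
    feature: str,
    *,
    genes: Sequence | None = None,
    compartments: CompartmentTrack | None = None,
) -> float:
    """Mean of a per-region feature over the pair's two regions.

    feature "gene_content" needs ``genes`` (intervals); "compartment" needs a
    ``compartments`` track. Raises UndefinedScoreError if either region's
    feature is undefined.
    """
    if feature == "gene_content":
        if genes is None:
            raise ValidationError("gene_content feature needs gene intervals")
        vals = [gene_content(r, genes) for r in (pair.region_a, pair.region_b)]
    elif feature == "compartment":
        if compartments is None:
            raise ValidationError("compartment feature needs a CompartmentTrack")
        vals = [
            compartments.region_score(r) for r in (pair.region_a, pair.region_b)
        ]
    else:
        raise ValidationError(f"unknown feature {feature!r}")
    return float(np.mean(vals))


def results_to_tsv(results: Sequence[ProximityResult], stream) -> None:
    stream.write(
        "dataset_id\tsource_label\tchromA\tstartA\tendA\tchromB\tstartB\tendB\t"
        "proximity_score\tn_bin_pairs_used\tn_bin_pairs_masked\n"
    )
    for r in results:
        a, b = r.pair.region_a, r.pair.region_b
        score = f"{r.proximity_score:.6g}" if r.defined else "NA"
        stream.write(
            f"{r.pair.dataset_id}\t{r.pair.source_label}\t"
            f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t"
            f"{score}\t{r.n_bin_pairs_used}\t{r.n_bin_pairs_masked}\n"
        )
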