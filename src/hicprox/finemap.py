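"""Hierarchical fine-mapping of unbalanced translocations from Hi-C reads.

An unbalanced translocation fuses two chromosome arms, so reads from the
derivative chromosome fill exactly one quadrant of the trans contact map
around the breakpoint, with signal decaying away from the breakpoint corner
along both chromosomes. The procedure:

  1. find the 1 Mb x 1 Mb bin with the highest (normalized) read count for a
     chromosome pair;
  2. collect all reads in the 3 Mb x 3 Mb window around it and bin at 50 kb;
  3. score the four candidate orientations by the quadrant enrichment (over
     the uniform expectation) each opens from the count-argmax corner bin;
     a call needs enrichment signature >= 0.6 (uniform reads give ~0.25), a
     nearly empty opposite quadrant (balanced events fill it), and marginal
     profiles that decay away from the corner (Spearman <= -0.5);
  4. when the corner 50-kb bin holds enough reads, refine to the argmax
     1 kb x 1 kb bin inside it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import NoSignalError
from .contacts import ExpectedModel, RawContactMap
from .regions import MaskTrack

ORIENTATIONS = ("++", "+-", "-+", "--")


@dataclass
class BreakpointCall:
    chrom_pair: tuple[str, str]
    coarse_bin: tuple[int, int]  # 1-Mb local bin ordinals
    corner_bin_50kb: tuple[int, int] | None  # genomic 50-kb bin ordinals
    refined_bin_1kb: tuple[int, int] | None
    orientation: str | None
    signature_score: float
    window_read_count: int
    corner_read_count: int
    status: str  # called | no_signature | insufficient_coverage | sparse_refinement


def max_trans_bin(
    cmap: RawContactMap,
    chrom_pair: tuple[str, str],
    expected: ExpectedModel | None = None,
    pseudocount: float | None = None,
) -> tuple[int, int]:
    """The 1-Mb bin pair with the highest (normalized, if an expected model
    is given) read count; ties go to the lowest (bin_i, bin_j).

    When normalizing, each bin's expected value is computed leave-one-out
    from the coverage marginals, E'_ij = (m_i - O_ij)(m_j - O_ij) / T: a
    concentrated rearrangement would otherwise inflate its own marginals and
    cap its own enrichment near one. The expected model's mask (NaN cells)
    is honored; the pseudocount guards near-zero expected values."""
    c1, c2 = chrom_pair
    O = cmap.block(c1, c2).astype(float)
    if O.sum() == 0:
        raise NoSignalError(f"no reads on {c1} x {c2}")
    if expected is not None:
        defined = ~np.isnan(expected.block(c1, c2))
        m_r = np.where(defined, O, 0.0).sum(axis=1, keepdims=True)
        m_c = np.where(defined, O, 0.0).sum(axis=0, keepdims=True)
        T = np.where(defined, O, 0.0).sum()
        E_loo = np.clip(m_r - O, 0, None) * np.clip(m_c - O, 0, None) / T
        c = 1.0 if pseudocount is None else max(pseudocount, 1e-9)
        score = np.where(defined, (O + c) / (E_loo + c), -np.inf)
    else:
        score = O
    flat = int(np.argmax(score))  # C order: first maximum = lexicographic tie rule
    return flat // O.shape[1], flat % O.shape[1]


def window_reads(
    reads: Sequence[tuple[str, int, str, int]],
    chrom_pair: tuple[str, str],
    center_bin: tuple[int, int],
    bin_size: int = 1_000_000,
    window_span: int = 3_000_000,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[list[tuple[int, int]], tuple[int, int]]:
    """Reads with both ends inside the window_span x window_span window
    centered on the coarse bin (the bin plus (span - bin_size)/2 on each
    side, clipped at chromosome ends).

    Returns (list of (pos1, pos2) oriented as chrom_pair, window origin
    (start1, start2))."""
    c1, c2 = chrom_pair
    pad = (window_span - bin_size) // 2
    w1 = center_bin[0] * bin_size - pad
    w2 = center_bin[1] * bin_size - pad
    w1, w2 = max(w1, 0), max(w2, 0)
    e1, e2 = w1 + window_span, w2 + window_span
    if chrom_lengths is not None:
        e1 = min(e1, chrom_lengths[c1])
        e2 = min(e2, chrom_lengths[c2])
    out = []
    for r in reads:
        if r[0] == c1 and r[2] == c2:
            p1, p2 = int(r[1]), int(r[3])
        elif r[0] == c2 and r[2] == c1:
            p1, p2 = int(r[3]), int(r[1])
        else:
            continue
        if w1 <= p1 < e1 and w2 <= p2 < e2:
            out.append((p1, p2))
    return out, (w1, w2)


def corner_detect(
    window: Sequence[tuple[int, int]],
    *,
    fine_bin: int = 50_000,
    min_window_reads: int = 200,
    min_signature: float = 0.6,
    max_decay_spearman: float = -0.5,
    max_opposite_fraction: float = 0.2,
    window_bounds: tuple[tuple[int, int], tuple[int, int]] | None = None,
) -> dict:
    """Corner-signature detection on window reads binned at ``fine_bin``.

    The candidate corner is the count-argmax fine bin. For each orientation,
    the raw quadrant fraction is the share of window reads in the quadrant
    that orientation opens from the corner (corner bin inclusive; '+' opens
    toward increasing coordinates). The signature score recenters that
    fraction by the quadrant's share of the window area, so that uniform
    reads score ~0.25 whatever the corner position and a perfect
    one-quadrant signal scores ~1:

        signature = clip(frac_in_quadrant - quadrant_area_fraction + 1/4,
                         0, 1)

    decay_ok additionally requires both marginal profiles, moving away from
    the corner along the open directions, to correlate
    <= ``max_decay_spearman`` with distance (Spearman). A call needs
    signature >= ``min_signature`` and decay_ok.

    window_bounds: ((x0, x1), (y0, y1)) genomic extent of the searched
    window (half-open); defaults to the read bounding box.

    Returns a dict with orientation, corner_bin (genomic fine-bin ordinals),
    signature_score, decay_ok, called, n_reads.
    """
    n = len(window)
    if n < min_window_reads:
        return {
            "called": False, "status": "insufficient_coverage",
            "n_reads": n, "orientation": None, "corner_bin": None,
            "signature_score": float("nan"), "decay_ok": False,
        }
    pts = np.asarray(window, dtype=np.int64)
    b1 = pts[:, 0] // fine_bin
    b2 = pts[:, 1] // fine_bin
    if window_bounds is not None:
        (x0, x1), (y0, y1) = window_bounds
        lo1, hi1 = x0 // fine_bin, (x1 - 1) // fine_bin
        lo2, hi2 = y0 // fine_bin, (y1 - 1) // fine_bin
    else:
        lo1, hi1 = int(b1.min()), int(b1.max())
        lo2, hi2 = int(b2.min()), int(b2.max())
    n1, n2 = hi1 - lo1 + 1, hi2 - lo2 + 1

    # count-argmax fine bin, lexicographic tie-break
    keys = b1 * (hi2 + 1) + b2
    uniq, counts = np.unique(keys, return_counts=True)
    best = uniq[counts == counts.max()].min()
    corner = (int(best // (hi2 + 1)), int(best % (hi2 + 1)))
    peak_count = int(counts.max())
    count_of = dict(zip(
        ((int(k // (hi2 + 1)), int(k % (hi2 + 1))) for k in uniq),
        (int(c) for c in counts),
    ))

    def evaluate(at):
        # reads inside the corner bin itself are orientation-ambiguous at
        # this resolution (a balanced event shares the bin between opposite
        # quadrants), so quadrant fractions are taken over the other reads
        in_corner = (b1 == at[0]) & (b2 == at[1])
        use = ~in_corner if int((~in_corner).sum()) >= 20 else np.ones(n, bool)
        fracs, sigs = {}, {}
        for orient in ORIENTATIONS:
            s1 = 1 if orient[0] == "+" else -1
            s2 = 1 if orient[1] == "+" else -1
            in_q = ((b1 - at[0]) * s1 >= 0) & ((b2 - at[1]) * s2 >= 0)
            fracs[orient] = float(in_q[use].mean())
            open1 = (hi1 - at[0] + 1) if s1 > 0 else (at[0] - lo1 + 1)
            open2 = (hi2 - at[1] + 1) if s2 > 0 else (at[1] - lo2 + 1)
            area = (open1 / n1) * (open2 / n2)
            sigs[orient] = float(np.clip(fracs[orient] - area + 0.25, 0.0, 1.0))
        best_o = max(ORIENTATIONS, key=lambda o: sigs[o])
        return best_o, fracs, sigs

    # first pass fixes the orientation; the corner is then made corner-most:
    # when the breakpoint sits near a bin boundary the count argmax lands one
    # bin into the signal, so step one bin against the opening direction if
    # that neighbor still holds a meaningful share of the peak
    orient0, _, _ = evaluate(corner)
    s1 = 1 if orient0[0] == "+" else -1
    s2 = 1 if orient0[1] == "+" else -1
    min_edge = max(5, int(0.1 * peak_count))
    cx, cy = corner
    if lo1 <= cx - s1 <= hi1 and count_of.get((cx - s1, cy), 0) >= min_edge:
        cx -= s1
    if lo2 <= cy - s2 <= hi2 and count_of.get((cx, cy - s2), 0) >= min_edge:
        cy -= s2
    corner = (cx, cy)
    corner_count = count_of.get(corner, 0)

    best_orient, fracs, sigs = evaluate(corner)
    best_sig = sigs[best_orient]
    # exclusivity: an unbalanced event leaves the diagonally opposite
    # quadrant nearly empty; a balanced one fills it with the second cloud
    flip = {"+": "-", "-": "+"}
    opposite = flip[best_orient[0]] + flip[best_orient[1]]
    opposite_frac = fracs[opposite]

    decay_ok = _marginals_decay(
        b1, b2, corner, best_orient, max_decay_spearman
    )
    called = (
        best_sig >= min_signature
        and opposite_frac <= max_opposite_fraction
        and decay_ok
    )
    return {
        "called": called,
        "status": "called" if called else "no_signature",
        "orientation": best_orient,
        "corner_bin": corner,
        "signature_score": best_sig,
        "opposite_fraction": opposite_frac,
        "decay_ok": decay_ok,
        "n_reads": n,
        "corner_read_count": corner_count,
    }


def _marginals_decay(b1, b2, corner, orient, max_rho) -> bool:
    """Spearman(profile, distance) <= max_rho on both axes, within the
    winning quadrant, moving away from the corner."""
    s1 = 1 if orient[0] == "+" else -1
    s2 = 1 if orient[1] == "+" else -1
    in_q = ((b1 - corner[0]) * s1 >= 0) & ((b2 - corner[1]) * s2 >= 0)
    for vals, c, s in ((b1[in_q], corner[0], s1), (b2[in_q], corner[1], s2)):
        d = (vals - c) * s  # distance in fine bins, >= 0
        if d.size == 0:
            return False
        profile = np.bincount(d)
        if profile.size < 3:
            return False
        rho = stats.spearmanr(np.arange(profile.size), profile).statistic
        if not (rho <= max_rho):
            return False
    return True


def refine_1kb(
    window: Sequence[tuple[int, int]],
    corner_bin: tuple[int, int],
    *,
    fine_bin: int = 50_000,
    refine_bin: int = 1_000,
    min_refine_reads: int = 20,
) -> tuple[tuple[int, int] | None, str]:
    """Argmax 1-kb bin pair inside the corner 50-kb bin, if it holds at
    least ``min_refine_reads`` reads; otherwise (None, "sparse")."""
    pts = np.asarray(window, dtype=np.int64).reshape(-1, 2)
    in_corner = (pts[:, 0] // fine_bin == corner_bin[0]) & (
        pts[:, 1] // fine_bin == corner_bin[1]
    )
    sub = pts[in_corner]
    if sub.shape[0] < min_refine_reads:
        return None, "sparse"
    r1 = sub[:, 0] // refine_bin
    r2 = sub[:, 1] // refine_bin
    width = int(r2.max()) + 1
    keys = r1 * width + r2
    uniq, counts = np.unique(keys, return_counts=True)
    best = uniq[counts == counts.max()].min()
    return (int(best // width), int(best % width)), "refined"


def scan_genome(
    cmap: RawContactMap,
    mask: MaskTrack | None = None,
    z_threshold: float = 8.0,
) -> list[dict]:
    """Flag, per chromosome pair, the maximal 1-Mb bin when its count exceeds
    mean + z * SD of the pair's unmasked counts. Sorted by decreasing z."""
    hits = []
    for c1, c2 in cmap.chrom_pairs:
        O = cmap.block(c1, c2).astype(float)
        if mask is not None:
            vr = ~mask.chrom_mask(c1)
            vc = ~mask.chrom_mask(c2)
            vals = O[np.ix_(vr, vc)]
        else:
            vals = O
        if vals.size == 0 or vals.sum() == 0:
            continue
        mu, sd = vals.mean(), vals.std()
        if sd == 0:
            continue
        flat = int(np.argmax(O))
        bin_pair = (flat // O.shape[1], flat % O.shape[1])
        z = (O[bin_pair] - mu) / sd
        if z > z_threshold:
            hits.append({
                "chrom_pair": (c1, c2),
                "coarse_bin": bin_pair,
                "z": float(z),
                "count": int(O[bin_pair]),
            })
    hits.sort(key=lambda h: -h["z"])
    return hits


def finemap_pair(
    reads: Sequence[tuple[str, int, str, int]],
    cmap: RawContactMap,
    chrom_pair: tuple[str, str],
    *,
    expected: ExpectedModel | None = None,
    fine_bin: int = 50_000,
    refine_bin: int = 1_000,
    window_span: int = 3_000_000,
    min_window_reads: int = 200,
    min_refine_reads: int = 20,
    min_signature: float = 0.6,
) -> BreakpointCall:
    """Full hierarchical fine-mapping of one chromosome pair."""
    scheme = cmap.scheme
    coarse = max_trans_bin(cmap, chrom_pair, expected)
    lengths = {
        c: scheme.assembly.length(c) for c in chrom_pair
    }
    win, origin = window_reads(
        reads, chrom_pair, coarse,
        bin_size=scheme.bin_size, window_span=window_span,
        chrom_lengths=lengths,
    )
    bounds = (
        (origin[0], min(origin[0] + window_span, lengths[chrom_pair[0]])),
        (origin[1], min(origin[1] + window_span, lengths[chrom_pair[1]])),
    )
    det = corner_detect(
        win, fine_bin=fine_bin, min_window_reads=min_window_reads,
        min_signature=min_signature, window_bounds=bounds,
    )
    if not det["called"]:
        return BreakpointCall(
            chrom_pair, coarse, det.get("corner_bin"), None,
            det.get("orientation"), det.get("signature_score", float("nan")),
            det["n_reads"], det.get("corner_read_count", 0), det["status"],
        )
    refined, refine_status = refine_1kb(
        win, det["corner_bin"], fine_bin=fine_bin,
        refine_bin=refine_bin, min_refine_reads=min_refine_reads,
    )
    status = "called" if refine_status == "refined" else "sparse_refinement"
    return BreakpointCall(
        chrom_pair, coarse, det["corner_bin"], refined, det["orientation"],
        det["signature_score"], det["n_reads"], det["corner_read_count"],
        status,
    )


def calls_to_bedpe(calls: Iterable[BreakpointCall], stream, fine_bin=50_000) -> None:
    stream.write(
        "chrom1\tstart1\tend1\tchrom2\tstart2\tend2\torientation\t"
        "signature_score\twindow_reads\tcorner_reads\trefinement_status\n"
    )
    for c in calls:
        if c.corner_bin_50kb is not None:
            s1 = c.corner_bin_50kb[0] * fine_bin
            s2 = c.corner_bin_50kb[1] * fine_bin
            e1, e2 = s1 + fine_bin, s2 + fine_bin
        else:
            s1 = c.coarse_bin[0] * 1_000_000
            s2 = c.coarse_bin[1] * 1_000_000
            e1, e2 = s1 + 1_000_000, s2 + 1_000_000
        sig = "NA" if np.isnan(c.signature_score) else f"{c.signature_score:.4f}"
        stream.write(
            f"{c.chrom_pair[0]}\t{s1}\t{e1}\t{c.chrom_pair[1]}\t{s2}\t{e2}\t"
            f"{c.orientation or 'NA'}\t{sig}\t{c.window_read_count}\t"
            f"{c.corner_read_count}\t{c.status}\n"
        )
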