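"""Permutation null models for translocation catalogs.

Four null constructions, each preserving the sizes (in whole bins at the
analysis resolution) of the true regions:

  Method 1 - both regions re-placed uniformly on their own chromosomes
             (controls chromosome-pair-level association biases);
  Method 2 - one region fixed, the partner re-placed on the partner's own
             chromosome (controls promiscuity of the fixed region on that
             chromosome);
  Method 3 - one region fixed, the partner re-placed uniformly over all
             placements on any other chromosome;
  Method 4 - one region fixed, the partner drawn from the catalog's own set
             of partner regions not on the fixed region's chromosome,
             keeping the drawn region's own size and position.

A candidate placement is valid when fewer than ``validity_threshold`` (50%
by default) of its bins are masked. With compartment control (Methods 1-3),
a re-placed region must additionally carry the same compartment sign as the
region it replaces. Draws are uniform over the set of valid placements.

p-values use the add-one estimator (k + 1)/(N + 1) with ties counted
against significance ("exceeds" means >=), so a reported p is never zero;
k = 0 at N = 1000 prints as "<0.001".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DrawFailureError, ValidationError
from .compartments import CompartmentTrack
from .contacts import HiCScoreMap
from .regions import (
    BinScheme,
    GenomicRegion,
    MaskTrack,
    TranslocationPair,
    gene_content,
)
from .proximity import proximity_score


@dataclass
class PermutationConfig:
    method: int = 1
    n_perms: int = 1000
    compartment_control: bool = False
    validity_threshold: float = 0.5
    max_attempts: int = 1000
    rng_seed: int = 0
    statistic: str = "proximity"  # proximity | gene_content | compartment

    def __post_init__(self):
        if self.method not in (1, 2, 3, 4):
            raise ValidationError("method must be 1, 2, 3 or 4")
        if self.n_perms < 1:
            raise ValidationError("n_perms must be >= 1")
        if not 0 < self.validity_threshold <= 1:
            raise ValidationError("validity_threshold must be in (0, 1]")
        if self.compartment_control and self.method == 4:
            raise ValidationError(
                "compartment control applies to methods 1-3 only"
            )


def gene_bin_coverage(
    genes: Sequence[tuple[str, int, int]], scheme: BinScheme
) -> dict[str, np.ndarray]:
    """Per-bin bases covered by the union of gene intervals, per chromosome."""
    out: dict[str, np.ndarray] = {}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in genes:
        if chrom in scheme.assembly:
            by_chrom.setdefault(chrom, []).append((int(s), int(e)))
    for chrom in scheme.assembly.names:
        cov = np.zeros(scheme.n_bins(chrom))
        ivals = sorted(by_chrom.get(chrom, []))
        merged: list[list[int]] = []
        for s, e in ivals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        bs = scheme.bin_size
        L = scheme.assembly.length(chrom)
        for s, e in merged:
            e = min(e, L)
            b0, b1 = s // bs, (e - 1) // bs
            for b in range(b0, b1 + 1):
                cov[b] += min(e, (b + 1) * bs) - max(s, b * bs)
        out[chrom] = cov
    return out


class PermutationEngine:
    """Caches prefix-sum tables over a score map so that permuted-pair
    statistics are O(1) per draw and drawing is uniform over enumerated
    valid placements."""

    def __init__(
        self,
        scores: HiCScoreMap,
        mask: MaskTrack | None = None,
        compartments: CompartmentTrack | None = None,
        gene_coverage: dict[str, np.ndarray] | None = None,
    ):
        self.scores = scores
        self.scheme = scores.scheme
        self.names = self.scheme.assembly.names
        mask = mask if mask is not None else scores.mask

        # bin-level mask per chromosome (True = masked)
        self._masked: dict[str, np.ndarray] = {}
        for chrom in self.names:
            if mask is not None:
                self._masked[chrom] = mask.chrom_mask(chrom).copy()
            else:
                # a bin with no defined score against any partner is unusable
                others = [c for c in self.names if c != chrom]
                if others:
                    rows = np.hstack([scores.block(chrom, oc) for oc in others])
                    self._masked[chrom] = np.isnan(rows).all(axis=1)
                else:
                    self._masked[chrom] = np.zeros(
                        self.scheme.n_bins(chrom), dtype=bool
                    )
        self._masked_prefix = {
            c: np.concatenate([[0], np.cumsum(m.astype(np.int64))])
            for c, m in self._masked.items()
        }

        # 2-D prefix sums of filled scores and of validity counts
        self._psum: dict[tuple[str, str], np.ndarray] = {}
        self._pcnt: dict[tuple[str, str], np.ndarray] = {}
        for key, block in scores.blocks.items():
            valid = ~np.isnan(block)
            filled = np.where(valid, block, 0.0)
            self._psum[key] = np.pad(filled, ((1, 0), (1, 0))).cumsum(0).cumsum(1)
            self._pcnt[key] = (
                np.pad(valid.astype(np.float64), ((1, 0), (1, 0))).cumsum(0).cumsum(1)
            )

        # optional per-bin feature tracks (prefix sums, NaN-aware for PC1)
        self.compartments = compartments
        self._pc1_prefix: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if compartments is not None:
            for chrom in self.names:
                v = compartments.chrom_values(chrom)
                ok = ~np.isnan(v)
                self._pc1_prefix[chrom] = (
                    np.concatenate([[0.0], np.cumsum(np.where(ok, v, 0.0))]),
                    np.concatenate([[0], np.cumsum(ok.astype(np.int64))]),
                )
        self.gene_coverage = gene_coverage
        self._gene_prefix: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if gene_coverage is not None:
            bs = self.scheme.bin_size
            for chrom in self.names:
                cov = gene_coverage[chrom]
                lengths = np.full(len(cov), bs, dtype=np.int64)
                lengths[-1] = self.scheme.assembly.length(chrom) - (len(cov) - 1) * bs
                self._gene_prefix[chrom] = (
                    np.concatenate([[0.0], np.cumsum(cov)]),
                    np.concatenate([[0], np.cumsum(lengths)]),
                )

        self._valid_cache: dict[tuple, np.ndarray] = {}

    # -- vectorized primitives --------------------------------------------

    def block_means(self, ca: str, sa, wa, cb: str, sb, wb) -> np.ndarray:
        """Mean score over [sa, sa+wa) x [sb, sb+wb) blocks of the ca x cb
        score matrix; all of sa/wa/sb/wb may be arrays (broadcast).
        NaN where no unmasked bin pair exists."""
        if (ca, cb) in self._psum:
            P, C = self._psum[(ca, cb)], self._pcnt[(ca, cb)]
            r0, r1 = np.asarray(sa), np.asarray(sa) + np.asarray(wa)
            c0, c1 = np.asarray(sb), np.asarray(sb) + np.asarray(wb)
        elif (cb, ca) in self._psum:
            P, C = self._psum[(cb, ca)], self._pcnt[(cb, ca)]
            r0, r1 = np.asarray(sb), np.asarray(sb) + np.asarray(wb)
            c0, c1 = np.asarray(sa), np.asarray(sa) + np.asarray(wa)
        else:
            raise ValidationError(f"no score block for {ca} x {cb}")
        tot = P[r1, c1] - P[r0, c1] - P[r1, c0] + P[r0, c0]
        cnt = C[r1, c1] - C[r0, c1] - C[r1, c0] + C[r0, c0]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)

    def masked_in_window(self, chrom: str, s, w) -> np.ndarray:
        p = self._masked_prefix[chrom]
        s = np.asarray(s)
        return p[s + np.asarray(w)] - p[s]

    def region_pc1_mean(self, chrom: str, s, w) -> np.ndarray:
        if chrom not in self._pc1_prefix:
            raise ValidationError("engine built without a compartment track")
        tot, cnt = self._pc1_prefix[chrom]
        s = np.asarray(s)
        t = tot[s + np.asarray(w)] - tot[s]
        c = cnt[s + np.asarray(w)] - cnt[s]
        with np.errstate(invalid="ignore"):
            return np.where(c > 0, t / np.maximum(c, 1), np.nan)

    def region_gene_content(self, chrom: str, s, w) -> np.ndarray:
        if chrom not in self._gene_prefix:
            raise ValidationError("engine built without gene coverage")
        cov, ln = self._gene_prefix[chrom]
        s = np.asarray(s)
        return (cov[s + np.asarray(w)] - cov[s]) / (
            ln[s + np.asarray(w)] - ln[s]
        )

    # -- placement enumeration --------------------------------------------

    def valid_starts(
        self,
        chrom: str,
        width: int,
        threshold: float = 0.5,
        sign: str | None = None,
    ) -> np.ndarray:
        """All local start bins where a ``width``-bin region is valid:
        fewer than ``threshold`` of its bins masked, and (if ``sign`` given)
        region compartment sign equal to ``sign``."""
        key = (chrom, width, threshold, sign)
        if key in self._valid_cache:
            return self._valid_cache[key]
        n = self.scheme.n_bins(chrom)
        if width > n:
            starts = np.array([], dtype=np.int64)
        else:
            s = np.arange(n - width + 1)
            ok = self.masked_in_window(chrom, s, width) < threshold * width
            if sign is not None:
                pc1 = self.region_pc1_mean(chrom, s, width)
                want_open = sign == "open"
                ok &= ~np.isnan(pc1) & ((pc1 >= 0) == want_open)
            starts = s[ok]
        self._valid_cache[key] = starts
        return starts

    def region_sign(self, region: GenomicRegion) -> str:
        if self.compartments is None:
            raise ValidationError("engine built without a compartment track")
        return "open" if self.compartments.region_score(region) >= 0 else "closed"

    # -- statistics --------------------------------------------------------

    def _placement(self, region: GenomicRegion) -> tuple[str, int, int]:
        bins = self.scheme.region_bins(region)
        return region.chrom, int(bins[0]), int(len(bins))

    def pair_statistic(self, pair: TranslocationPair, statistic: str = "proximity"):
        ca, sa, wa = self._placement(pair.region_a)
        cb, sb, wb = self._placement(pair.region_b)
        if statistic == "proximity":
            return float(self.block_means(ca, sa, wa, cb, sb, wb))
        if statistic == "gene_content":
            return float(
                (self.region_gene_content(ca, sa, wa)
                 + self.region_gene_content(cb, sb, wb)) / 2
            )
        if statistic == "compartment":
            return float(
                (self.region_pc1_mean(ca, sa, wa)
                 + self.region_pc1_mean(cb, sb, wb)) / 2
            )
        raise ValidationError(f"unknown statistic {statistic!r}")

    def _region_stats(self, chrom: str, s, w, statistic: str) -> np.ndarray:
        if statistic == "gene_content":
            return self.region_gene_content(chrom, s, w)
        if statistic == "compartment":
            return self.region_pc1_mean(chrom, s, w)
        raise ValidationError(f"unknown per-region statistic {statistic!r}")

    # -- drawing -----------------------------------------------------------

    def _choose(self, starts: np.ndarray, n: int, rng, what: str) -> np.ndarray:
        if starts.size == 0:
            raise DrawFailureError(f"no valid placement for {what}")
        return starts[rng.integers(starts.size, size=n)]

    def _draw_placements(
        self,
        pair: TranslocationPair,
        config: PermutationConfig,
        n: int,
        rng: np.random.Generator,
        partner_pool: Sequence[TranslocationPair] | None = None,
    ):
        """Draw n permuted placements for ``pair``.

        Returns six arrays (chrom index, start, width for each side); side
        one is region_a's replacement (Method 1) or the fixed region
        (Methods 2-4)."""
        thr = config.validity_threshold
        ca, sa0, wa = self._placement(pair.region_a)
        cb, sb0, wb = self._placement(pair.region_b)
        ia, ib = self.names.index(ca), self.names.index(cb)
        control = config.compartment_control
        sign_a = self.region_sign(pair.region_a) if control else None
        sign_b = self.region_sign(pair.region_b) if control else None

        c1 = np.empty(n, dtype=np.int64); s1 = np.empty(n, dtype=np.int64)
        w1 = np.empty(n, dtype=np.int64)
        c2 = np.empty(n, dtype=np.int64); s2 = np.empty(n, dtype=np.int64)
        w2 = np.empty(n, dtype=np.int64)

        if config.method == 1:
            c1[:], w1[:] = ia, wa
            c2[:], w2[:] = ib, wb
            s1[:] = self._choose(
                self.valid_starts(ca, wa, thr, sign_a), n, rng, f"{ca} width {wa}"
            )
            s2[:] = self._choose(
                self.valid_starts(cb, wb, thr, sign_b), n, rng, f"{cb} width {wb}"
            )
            return c1, s1, w1, c2, s2, w2

        # Methods 2-4: fix one side, chosen uniformly at random once per pair.
        # Fixing per pair (not per draw) keeps the observed statistic
        # exchangeable with its null draws: every draw of the pair's null set
        # comes from the same conditional distribution as the observed pair,
        # so null p-values are uniform. Mixing the fixed side within a pair's
        # draws would mix two conditionals and miscalibrate the rank.
        fix_a = np.full(n, bool(rng.integers(2)))
        for fixed_is_a in (True, False):
            sel = fix_a if fixed_is_a else ~fix_a
            m = int(sel.sum())
            if m == 0:
                continue
            fc, fs, fw = (ia, sa0, wa) if fixed_is_a else (ib, sb0, wb)
            mc_name, mw, msign = (
                (cb, wb, sign_b) if fixed_is_a else (ca, wa, sign_a)
            )
            c1[sel], s1[sel], w1[sel] = fc, fs, fw
            if config.method == 2:
                c2[sel] = self.names.index(mc_name)
                w2[sel] = mw
                s2[sel] = self._choose(
                    self.valid_starts(mc_name, mw, thr, msign), m, rng,
                    f"{mc_name} width {mw}",
                )
            elif config.method == 3:
                pool_c, pool_s = [], []
                fixed_name = self.names[fc]
                for oc in self.names:
                    if oc == fixed_name:
                        continue
                    vs = self.valid_starts(oc, mw, thr, msign)
                    pool_c.append(np.full(vs.size, self.names.index(oc)))
                    pool_s.append(vs)
                pool_c = np.concatenate(pool_c) if pool_c else np.array([], int)
                pool_s = np.concatenate(pool_s) if pool_s else np.array([], int)
                if pool_s.size == 0:
                    raise DrawFailureError(
                        f"no valid width-{mw} placement off {fixed_name}"
                    )
                pick = rng.integers(pool_s.size, size=m)
                c2[sel], s2[sel], w2[sel] = pool_c[pick], pool_s[pick], mw
            else:  # method 4
                if partner_pool is None:
                    raise ValidationError("method 4 needs a partner_pool")
                pc, ps, pw = self._pool_arrays(partner_pool, thr)
                allowed = np.nonzero(pc != fc)[0]
                if allowed.size == 0:
                    raise DrawFailureError(
                        f"partner pool has no region off {self.names[fc]}"
                    )
                pick = allowed[rng.integers(allowed.size, size=m)]
                c2[sel], s2[sel], w2[sel] = pc[pick], ps[pick], pw[pick]
        return c1, s1, w1, c2, s2, w2

    def _pool_arrays(self, pool: Sequence[TranslocationPair], threshold: float):
        key = ("__pool__", id(pool), threshold)
        if key not in self._valid_cache:
            cs, ss, ws = [], [], []
            for p in pool:
                for r in (p.region_a, p.region_b):
                    c, s, w = self._placement(r)
                    if self.masked_in_window(c, s, w) < threshold * w:
                        cs.append(self.names.index(c)); ss.append(s); ws.append(w)
            if not cs:
                raise DrawFailureError("partner pool entirely invalid under mask")
            self._valid_cache[key] = (
                np.array(cs, dtype=np.int64),
                np.array(ss, dtype=np.int64),
                np.array(ws, dtype=np.int64),
            )
        return self._valid_cache[key]

    def permuted_statistics(
        self,
        pair: TranslocationPair,
        config: PermutationConfig,
        rng: np.random.Generator,
        n: int | None = None,
        partner_pool: Sequence[TranslocationPair] | None = None,
    ) -> np.ndarray:
        """Statistics of ``n`` (default config.n_perms) permuted versions of
        ``pair`` under the configured null."""
        n = config.n_perms if n is None else n
        c1, s1, w1, c2, s2, w2 = self._draw_placements(
            pair, config, n, rng, partner_pool
        )
        out = np.empty(n)
        keys = c1 * len(self.names) + c2
        for k in np.unique(keys):
            sel = keys == k
            na, nb = self.names[int(k) // len(self.names)], self.names[int(k) % len(self.names)]
            if config.statistic == "proximity":
                out[sel] = self.block_means(
                    na, s1[sel], w1[sel], nb, s2[sel], w2[sel]
                )
            else:
                out[sel] = (
                    self._region_stats(na, s1[sel], w1[sel], config.statistic)
                    + self._region_stats(nb, s2[sel], w2[sel], config.statistic)
                ) / 2
        return out

    def draw_permuted_pair(
        self,
        pair: TranslocationPair,
        config: PermutationConfig,
        rng: np.random.Generator,
        partner_pool: Sequence[TranslocationPair] | None = None,
    ) -> TranslocationPair:
        """One permuted pair under the configured null construction."""
        c1, s1, w1, c2, s2, w2 = self._draw_placements(
            pair, config, 1, rng, partner_pool
        )
        bs = self.scheme.bin_size
        regions = []
        for ci, si, wi in ((c1[0], s1[0], w1[0]), (c2[0], s2[0], w2[0])):
            chrom = self.names[int(ci)]
            start = int(si) * bs
            end = min(int(si + wi) * bs, self.scheme.assembly.length(chrom))
            regions.append(GenomicRegion(chrom, start, end))
        return TranslocationPair(
            regions[0], regions[1], pair.dataset_id, pair.tissue_class,
            pair.recurrence_count, pair.source_label,
        ).canonical(self.scheme.assembly)


# ---------------------------------------------------------------------------
# tests


@dataclass
class GroupTestResult:
    observed_mean: float
    null_means: np.ndarray
    p_value: float
    t_test_p: float
    rank_sum_p: float
    n_pairs: int
    n_undefined: int = 0

    def format_p(self) -> str:
        n = len(self.null_means)
        return "<0.001" if self.p_value <= 1 / (n + 1) and n >= 999 else (
            f"{self.p_value:.4g}"
        )


@dataclass
class IndividualTestResult:
    pairs: list[TranslocationPair]
    observed: np.ndarray
    p_values: np.ndarray
    bh_q: np.ndarray
    significant: np.ndarray  # bool, q < 0.05

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


def _observed_stats(pairs, engine, config):
    obs = np.array(
        [engine.pair_statistic(p, config.statistic) for p in pairs]
    )
    return obs


def group_test(
    pairs: Sequence[TranslocationPair],
    engine: PermutationEngine,
    config: PermutationConfig,
    partner_pool: Sequence[TranslocationPair] | None = None,
) -> GroupTestResult:
    """Dataset-level permutation test: each replicate permutes every pair
    independently and records the replicate mean; p is the add-one fraction
    of replicate means >= the observed mean. Student's t and Wilcoxon
    rank-sum p-values between observed and pooled permuted per-pair
    statistics are reported alongside to monitor outlier-driven signal."""
    if config.method == 4 and partner_pool is None:
        partner_pool = list(pairs)
    obs = _observed_stats(pairs, engine, config)
    defined = ~np.isnan(obs)
    if defined.sum() < 2:
        raise ValidationError("need >= 2 pairs with a defined statistic")
    rng = np.random.default_rng(config.rng_seed)
    null = np.empty((int(defined.sum()), config.n_perms))
    row = 0
    for p, ok in zip(pairs, defined):
        if not ok:
            continue
        null[row] = engine.permuted_statistics(
            p, config, rng, partner_pool=partner_pool
        )
        row += 1
    null_means = np.nanmean(null, axis=0)
    observed_mean = float(obs[defined].mean())
    k = int(np.sum(null_means >= observed_mean))
    p_value = (k + 1) / (config.n_perms + 1)
    pooled = null[~np.isnan(null)]
    t_p = float(stats.ttest_ind(obs[defined], pooled, equal_var=False).pvalue)
    rs_p = _ranksum_p(obs[defined], pooled)
    return GroupTestResult(
        observed_mean, null_means, p_value, t_p, rs_p,
        int(defined.sum()), int((~defined).sum()),
    )


def individual_test(
    pairs: Sequence[TranslocationPair],
    engine: PermutationEngine,
    config: PermutationConfig,
    partner_pool: Sequence[TranslocationPair] | None = None,
    fdr: float = 0.05,
) -> IndividualTestResult:
    """Per-translocation permutation p (add-one, >= convention),
    BH-corrected across the defined pairs; significant at q < ``fdr``."""
    if config.method == 4 and partner_pool is None:
        partner_pool = list(pairs)
    obs = _observed_stats(pairs, engine, config)
    rng = np.random.default_rng(config.rng_seed)
    pvals = np.full(len(pairs), np.nan)
    for i, p in enumerate(pairs):
        null = engine.permuted_statistics(p, config, rng, partner_pool=partner_pool)
        if np.isnan(obs[i]):
            continue
        k = int(np.sum(null >= obs[i]))
        pvals[i] = (k + 1) / (config.n_perms + 1)
    defined = ~np.isnan(pvals)
    q = np.full(len(pairs), np.nan)
    if defined.any():
        q[defined] = bh_adjust(pvals[defined])
    significant = np.where(defined, q < fdr, False)
    return IndividualTestResult(list(pairs), obs, pvals, q, significant)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving relative to the
    input; monotone and capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p, normal approximation with tie
    correction (no continuity correction, so identical groups give 1.0)."""
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return float(res.pvalue)


def tissue_comparison(
    scores_group1: Sequence[float], scores_group2: Sequence[float]
) -> dict:
    """Compare proximity-score distributions between two tissue groups
    (e.g. blood vs non-blood malignancies)."""
    a = np.asarray([s for s in scores_group1 if not np.isnan(s)], dtype=float)
    b = np.asarray([s for s in scores_group2 if not np.isnan(s)], dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs >= 2 defined scores")
    if np.ptp(np.concatenate([a, b])) == 0:
        raise ValidationError("degenerate groups (all values identical)")
    return {
        "rank_sum_p": _ranksum_p(a, b),
        "median_1": float(np.median(a)),
        "median_2": float(np.median(b)),
    }


def recurrence_correlation(
    recurrence_counts: Sequence[int],
    proximity_scores: Sequence[float],
    permutation_pvals: Sequence[float] | None = None,
) -> dict:
    """Spearman correlation between how often a translocation is reported and
    (a) its proximity score, (b) its permutation p-value.

    Returns rho/p for the score relation and, when p-values are supplied, the
    t-test p of the regression slope of p-value ranks on count ranks."""
    counts = np.asarray(recurrence_counts, dtype=float)
    scores = np.asarray(proximity_scores, dtype=float)
    ok = ~np.isnan(scores) & (counts >= 1)
    if ok.sum() < 3:
        raise ValidationError("need >= 3 pairs with counts >= 1")
    if np.ptp(counts[ok]) == 0 or np.ptp(scores[ok]) == 0:
        raise ValidationError("constant inputs: correlation undefined")
    rho, p = stats.spearmanr(counts[ok], scores[ok])
    out = {"rho_score": float(rho), "p_score": float(p)}
    if permutation_pvals is not None:
        pv = np.asarray(permutation_pvals, dtype=float)
        ok2 = ok & ~np.isnan(pv)
        if ok2.sum() >= 3 and np.ptp(pv[ok2]) > 0:
            lr = stats.linregress(
                stats.rankdata(counts[ok2]), stats.rankdata(pv[ok2])
            )
            out["slope_t_p_pvalue_vs_count"] = float(lr.pvalue)
        else:
            out["slope_t_p_pvalue_vs_count"] = float("nan")
    return out
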