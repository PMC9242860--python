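"""Permutation-based empirical inference: region-screen empirical
p-values, TSS-window proximity enrichment, interval-overlap Fisher tests
and identifier set overlaps.

Empirical p-values always carry the add-one correction
p = (1 + #{null at least as extreme}) / (1 + N), so p = 0 is impossible
and the floor is 1/(N+1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenomicInterval, GuideLibrary, CountMatrix
from .scoring import (
    FoldChangeTable,
    ScoreConfig,
    _region_construct_profile,
    region_scores_from_profile,
)

logger = logging.getLogger(__name__)


@dataclass
class PermConfig:
    n_perm: int = 10_000
    seed: int = 0
    side: str = "less"  # "less" = depletion, "greater" = enrichment

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.side not in ("less", "greater"):
            raise ValueError(f"side must be less/greater, got {self.side!r}")


@dataclass
class RegionTestResult:
    target_id: str
    observed: float
    empirical_p: float
    n_perm: int
    null_mean: float
    null_sd: float
    q_value: float = float("nan")
    per_unit_scores: dict[str, float] = field(default_factory=dict)


@dataclass
class EnrichmentResult:
    observed_count: int
    empirical_p: float
    n_perm: int
    null_mean: float
    null_sd: float
    window_bp: int


def empirical_p(
    observed: float, null_values: Sequence[float] | np.ndarray, side: str = "less"
) -> float:
    """Add-one-corrected empirical p-value of ``observed`` against a
    permutation null."""
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("null_values must be non-empty")
    if side == "less":
        hits = int(np.sum(null <= observed))
    elif side == "greater":
        hits = int(np.sum(null >= observed))
    else:
        raise ValueError(f"side must be less/greater, got {side!r}")
    return (1 + hits) / (1 + null.size)


def _permuted_region_stats(
    profile: np.ndarray,
    region_sizes: Sequence[int],
    m: int,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null matrix (n_perm x n_regions) of combined region statistics under
    random reassignment of constructs to region labels.

    ``profile`` is the (n_constructs x n_groups) matrix of per-group
    centered log2fc averages for region-targeting constructs only.
    """
    n_constructs, n_groups = profile.shape
    sizes = np.asarray(region_sizes)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    n_regions = len(sizes)
    out = np.empty((n_perm, n_regions))
    equal = sizes.min() == sizes.max()
    if equal:
        c = int(sizes[0])
        k = min(m, c)
        for p in range(n_perm):
            shuffled = profile[rng.permutation(n_constructs)]
            blocks = shuffled.reshape(n_regions, c, n_groups)
            part = np.partition(blocks, k - 1, axis=1)[:, :k, :]
            out[p] = part.mean(axis=(1, 2))
    else:
        for p in range(n_perm):
            shuffled = profile[rng.permutation(n_constructs)]
            for r in range(n_regions):
                block = shuffled[offsets[r]:offsets[r + 1]]
                k = min(m, block.shape[0])
                part = np.partition(block, k - 1, axis=0)[:k]
                out[p, r] = part.mean(axis=0).mean()
    return out


def region_screen_test(
    fc: FoldChangeTable,
    library: GuideLibrary,
    cm: CountMatrix,
    cfg: ScoreConfig | None = None,
    perm: PermConfig | None = None,
) -> list[RegionTestResult]:
    """Region depletion statistics with permutation empirical p-values.

    The null reassigns region-targeting constructs to region labels,
    preserving each region's construct count, and recomputes the combined
    statistic; each region's observed score is ranked within its own
    label's null draws. Benjamini-Hochberg q-values are reported as a
    convenience column.
    """
    cfg = cfg or ScoreConfig()
    perm = perm or PermConfig()
    if perm.n_perm < 100:
        warnings.warn(
            f"n_perm={perm.n_perm} gives coarse p-value granularity", stacklevel=2
        )

    region_constructs = library.targets("region")
    if len(region_constructs) < 2:
        raise ValueError("region permutation test needs >= 2 region targets")

    group_ids = sorted({cm.samples[s].group_id for s in cm.endpoint_samples})
    profile_df = _region_construct_profile(fc, cm.samples, group_ids)
    observed = region_scores_from_profile(profile_df, region_constructs, cfg.m_region)

    # constructs ordered region-block-wise for the permutation machinery
    ordered_ids = [
        c for ids in region_constructs.values() for c in ids if c in profile_df.index
    ]
    sizes = [
        sum(1 for c in ids if c in profile_df.index)
        for ids in region_constructs.values()
    ]
    rng = np.random.default_rng(perm.seed)
    null = _permuted_region_stats(
        profile_df.loc[ordered_ids].to_numpy(), sizes, cfg.m_region, perm.n_perm, rng
    )

    results = []
    pvals = []
    for r, score in enumerate(observed):
        p = empirical_p(score.score, null[:, r], perm.side)
        pvals.append(p)
        results.append(
            RegionTestResult(
                target_id=score.target_id,
                observed=score.score,
                empirical_p=p,
                n_perm=perm.n_perm,
                null_mean=float(null[:, r].mean()),
                null_sd=float(null[:, r].std(ddof=1)) if perm.n_perm > 1 else 0.0,
                per_unit_scores=score.per_unit_scores,
            )
        )
    for res, q in zip(results, benjamini_hochberg(pvals)):
        res.q_value = q
    return results


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


# ---------------------------------------------------------------------------
# TSS-window proximity enrichment
# ---------------------------------------------------------------------------


def _window_hit_count(
    peaks: Sequence[GenomicInterval],
    tss_all: Mapping[str, tuple[str, int]],
    gene_set: Iterable[str],
    window_bp: int,
) -> int:
    """Peaks intersecting the +/- window around >=1 gene's TSS, each peak
    counted once. Window is [tss - w, tss + w + 1): inclusive of both
    endpoints."""
    genes = list(gene_set)
    count = 0
    for peak in peaks:
        for g in genes:
            chrom, pos = tss_all[g]
            if peak.chrom != chrom:
                continue
            lo = max(0, pos - window_bp)
            hi = pos + window_bp + 1
            if peak.start < hi and peak.end > lo:
                count += 1
                break
    return count


def tss_window_enrichment(
    peaks: Sequence[GenomicInterval],
    tss_all: Mapping[str, tuple[str, int]],
    gene_set: Sequence[str],
    window_bp: int = 500_000,
    perm: PermConfig | None = None,
) -> EnrichmentResult:
    """Count peaks within ``window_bp`` of any TSS of ``gene_set`` and test
    the count against a null of equally sized gene sets drawn uniformly
    without replacement from ``tss_all``."""
    perm = perm or PermConfig(n_perm=1000, side="greater")
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    missing = [g for g in gene_set if g not in tss_all]
    if missing:
        raise KeyError(f"genes missing a TSS: {missing}")

    observed = _window_hit_count(peaks, tss_all, gene_set, window_bp)
    all_genes = np.array(list(tss_all))
    rng = np.random.default_rng(perm.seed)
    null = np.empty(perm.n_perm)
    for i in range(perm.n_perm):
        draw = rng.choice(all_genes, size=len(gene_set), replace=False)
        null[i] = _window_hit_count(peaks, tss_all, draw, window_bp)
    p = empirical_p(observed, null, side="greater")
    return EnrichmentResult(
        observed_count=observed,
        empirical_p=p,
        n_perm=perm.n_perm,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if perm.n_perm > 1 else 0.0,
        window_bp=window_bp,
    )


# ---------------------------------------------------------------------------
# Interval-set overlap (Fisher) and identifier set overlap
# ---------------------------------------------------------------------------


def _member_flags(
    subset: Sequence[GenomicInterval],
    universe: Sequence[GenomicInterval],
    mode: str,
) -> np.ndarray:
    if mode == "identity":
        keys = {(iv.chrom, iv.start, iv.end) for iv in subset}
        return np.array([(u.chrom, u.start, u.end) in keys for u in universe])
    if mode == "intersect":
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in subset:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        return np.array(
            [
                any(u.overlaps(iv) for iv in by_chrom.get(u.chrom, ()))
                for u in universe
            ]
        )
    raise ValueError(f"membership mode must be identity/intersect, got {mode!r}")


@dataclass
class FisherOverlapResult:
    table: tuple[int, int, int, int]  # (both, A only, B only, neither)
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    zero_cell_corrected: bool = False
    degenerate: bool = False


def interval_overlap_fisher(
    set_a: Sequence[GenomicInterval],
    set_b: Sequence[GenomicInterval],
    universe: Sequence[GenomicInterval],
    mode: str = "identity",
) -> FisherOverlapResult:
    """2x2 enrichment test of two interval sets over a universe.

    Returns the sample odds ratio ad/bc, a Woolf logit 95% CI (with
    Haldane-Anscombe 0.5 correction on zero cells, flagged), and a
    one-sided Fisher exact p for enrichment.
    """
    in_a = _member_flags(set_a, universe, mode)
    in_b = _member_flags(set_b, universe, mode)
    a = int(np.sum(in_a & in_b))
    b = int(np.sum(in_a & ~in_b))
    c = int(np.sum(~in_a & in_b))
    d = int(np.sum(~in_a & ~in_b))

    degenerate = (a + b == len(universe) and c == d == 0) or (a + b == 0) or (
        a + c == 0
    )
    zero_cell = 0 in (a, b, c, d)
    if zero_cell:
        af, bf, cf, df = (x + 0.5 for x in (a, b, c, d))
    else:
        af, bf, cf, df = float(a), float(b), float(c), float(d)
    odds_ratio = (a * d) / (b * c) if b * c > 0 else (af * df) / (bf * cf)
    se = np.sqrt(1 / af + 1 / bf + 1 / cf + 1 / df)
    log_or = np.log((af * df) / (bf * cf))
    z = stats.norm.ppf(0.975)
    ci_low, ci_high = np.exp(log_or - z * se), np.exp(log_or + z * se)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return FisherOverlapResult(
        table=(a, b, c, d),
        odds_ratio=float(odds_ratio),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=float(p),
        zero_cell_corrected=zero_cell,
        degenerate=degenerate,
    )


def canonical_id(identifier: str) -> str:
    """Identifier normalizer for set overlap: strip whitespace, uppercase."""
    return identifier.strip().upper()


def set_overlap(
    list_a: Iterable[str], list_b: Iterable[str]
) -> tuple[int, int, int]:
    """(|A|, |B|, |A intersect B|) after canonicalization and dedup."""
    a = {canonical_id(x) for x in list_a if x and x.strip()}
    b = {canonical_id(x) for x in list_b if x and x.strip()}
    return len(a), len(b), len(a & b)


def peak_cobinding_fraction(
    peaks_a: Sequence[GenomicInterval],
    peaks_b: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> float:
    """Fraction of ``peaks_a`` intersecting >=1 interval of ``peaks_b``."""
    if not peaks_a:
        raise ValueError("peaks_a is empty; co-binding fraction undefined")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in peaks_b:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for spans in by_chrom.values():
        spans.sort()
    n_hit = 0
    for a in peaks_a:
        spans = by_chrom.get(a.chrom, [])
        # spans sorted by start; early exit once starts pass a.end
        for start, end in spans:
            if start >= a.end - min_overlap + 1:
                break
            if min(a.end, end) - max(a.start, start) >= min_overlap:
                n_hit += 1
                break
    return n_hit / len(peaks_a)


def region_results_to_frame(results: list[RegionTestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "target_id": r.target_id,
            "score": r.observed,
            "empirical_p": r.empirical_p,
            "q_value": r.q_value,
            "n_perm": r.n_perm,
            "null_mean": r.null_mean,
            "null_sd": r.null_sd,
        }
        for unit, val in r.per_unit_scores.items():
            row[f"score_{unit}"] = val
        rows.append(row)
    return pd.DataFrame(rows)
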