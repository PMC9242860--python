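"""Time-course target-gene filtering and peak-to-gene proximity linking.

A gene passes the sustained-downregulation filter when it is
significantly downregulated at every required timepoint; candidate
regulatory peaks are then linked to passing genes within a symmetric TSS
window (default +/- 500 kb).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .io import GenomicInterval

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TimecoursePoint:
    gene: str
    timepoint_h: float
    log2fc: float
    padj: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.padj <= 1.0:
            raise ValueError(f"{self.gene}@{self.timepoint_h}h: padj must be in [0,1]")


@dataclass
class FilterConfig:
    lfc_max: float = 0.0  # log2fc must be strictly below this
    padj_max: float = 0.05
    required_timepoints: tuple[float, ...] = (32.0, 72.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.padj_max <= 1.0:
            raise ValueError("padj_max must be in (0, 1]")
        if not self.required_timepoints:
            raise ValueError("required_timepoints must be non-empty")


def sustained_downregulation_filter(
    points: Sequence[TimecoursePoint], cfg: FilterConfig | None = None
) -> set[str]:
    """Genes with log2fc < lfc_max and padj <= padj_max at every required
    timepoint. Genes missing a required timepoint are excluded with a
    warning."""
    cfg = cfg or FilterConfig()
    by_gene: dict[str, dict[float, TimecoursePoint]] = {}
    for p in points:
        by_gene.setdefault(p.gene, {})[p.timepoint_h] = p

    required = set(cfg.required_timepoints)
    retained: set[str] = set()
    n_missing = 0
    for gene, tp_map in by_gene.items():
        missing = required - set(tp_map)
        if missing:
            n_missing += 1
            continue
        if all(
            tp_map[t].log2fc < cfg.lfc_max and tp_map[t].padj <= cfg.padj_max
            for t in required
        ):
            retained.add(gene)
    if n_missing:
        logger.warning(
            "%d genes missing a required timepoint were excluded", n_missing
        )
    return retained


def link_peaks_to_genes(
    peaks: Sequence[GenomicInterval],
    tss_all: Mapping[str, tuple[str, int]],
    gene_set: Sequence[str],
    window_bp: int = 500_000,
) -> pd.DataFrame:
    """Every (peak, gene) pair where the peak intersects the +/- window
    around the gene's TSS (window inclusive of both endpoints).

    Columns: peak_chrom/start/end/name, gene, distance (TSS to peak
    midpoint, signed by genomic orientation). The deduplicated peak
    count for headline reporting is ``n_linked_peaks`` in ``.attrs``.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    missing = [g for g in gene_set if g not in tss_all]
    if missing:
        raise KeyError(f"genes missing a TSS: {missing}")

    rows = []
    linked_peaks: set[int] = set()
    for i, peak in enumerate(peaks):
        for gene in gene_set:
            chrom, pos = tss_all[gene]
            if peak.chrom != chrom:
                continue
            lo = max(0, pos - window_bp)
            hi = pos + window_bp + 1
            if peak.start < hi and peak.end > lo:
                rows.append(
                    {
                        "peak_chrom": peak.chrom,
                        "peak_start": peak.start,
                        "peak_end": peak.end,
                        "peak_name": peak.name or f"peak_{i}",
                        "gene": gene,
                        "distance": peak.midpoint - pos,
                    }
                )
                linked_peaks.add(i)
    df = pd.DataFrame(
        rows,
        columns=[
            "peak_chrom", "peak_start", "peak_end", "peak_name", "gene", "distance",
        ],
    )
    df.attrs["n_linked_peaks"] = len(linked_peaks)
    return df


def read_timecourse_table(path: str | Path) -> list[TimecoursePoint]:
    """TSV columns: gene, timepoint, log2fc, padj."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "timepoint", "log2fc", "padj"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing timecourse columns {sorted(missing)}")
    return [
        TimecoursePoint(
            gene=str(r.gene),
            timepoint_h=float(r.timepoint),
            log2fc=float(r.log2fc),
            padj=float(r.padj),
        )
        for r in df.itertuples(index=False)
    ]


def write_timecourse_table(
    points: Sequence[TimecoursePoint], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "gene": p.gene,
                "timepoint": p.timepoint_h,
                "log2fc": p.log2fc,
                "padj": p.padj,
            }
            for p in points
        ]
    ).to_csv(path, sep="\t", index=False)
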