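"""Dropout-screen scoring: abundance normalization, per-construct fold
changes, control centering, and ranked-mean target scores.

Gene-level scores average the ``k`` most depleted constructs per gene
(default k=3); region-level scores average the ``m`` most depleted
constructs per region (default m=2) after averaging each construct over
the tumours of a group. Scores are signed log2 values: negative means
depleted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix, GuideLibrary

logger = logging.getLogger(__name__)


@dataclass
class ScoreConfig:
    pseudocount: float = 0.5
    k_gene: int = 3
    m_region: int = 2
    control_center: str = "median"  # or "mean"
    fc_space: str = "linear_then_log"  # or "mean_of_logs"
    per_unit_center: bool = False  # region scoring: average per unit, not per group

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.k_gene < 1 or self.m_region < 1:
            raise ValueError("k_gene and m_region must be >= 1")
        if self.control_center not in ("median", "mean"):
            raise ValueError(f"unknown control_center {self.control_center!r}")
        if self.fc_space not in ("linear_then_log", "mean_of_logs"):
            raise ValueError(f"unknown fc_space {self.fc_space!r}")


@dataclass
class FoldChangeTable:
    """Per (construct, endpoint sample) log2 fold changes vs. reference."""

    log2fc: pd.DataFrame  # constructs x endpoint samples
    reference_of: dict[str, str]  # endpoint sample -> reference sample
    centered: bool = False

    @property
    def linear_fc(self) -> pd.DataFrame:
        return 2.0 ** self.log2fc


@dataclass
class TargetScore:
    target_id: str
    score: float
    per_unit_scores: dict[str, float] = field(default_factory=dict)
    n_constructs_used: int = 0


def normalize_counts(cm: CountMatrix, cfg: ScoreConfig | None = None) -> pd.DataFrame:
    """Counts-per-million with a pseudocount: per sample,
    a_i = (c_i + pc) / sum_j (c_j + pc) * 1e6."""
    cfg = cfg or ScoreConfig()
    counts = cm.counts.astype(float) + cfg.pseudocount
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"samples with zero total adjusted counts: {bad}")
    return counts / totals * 1e6


def guide_log2fc(abundances: pd.DataFrame, cm: CountMatrix) -> FoldChangeTable:
    """log2(endpoint abundance / paired reference abundance) per construct."""
    endpoints = cm.endpoint_samples
    if not endpoints:
        raise ValueError("count matrix has no endpoint samples")
    reference_of = {s: cm.samples[s].reference for s in endpoints}
    cols = {}
    for s in endpoints:
        ref = abundances[reference_of[s]]
        if (ref <= 0).any():
            raise RuntimeError("zero reference abundance despite pseudocount")
        cols[s] = np.log2(abundances[s] / ref)
    return FoldChangeTable(
        log2fc=pd.DataFrame(cols, index=abundances.index),
        reference_of=reference_of,
    )


def control_center(
    fc: FoldChangeTable, library: GuideLibrary, cfg: ScoreConfig | None = None
) -> FoldChangeTable:
    """Subtract the per-sample center (median by default) of the
    non-targeting-control log2 fold changes from every construct."""
    cfg = cfg or ScoreConfig()
    ctrl_ids = [c.construct_id for c in library.by_class("nontargeting_control")]
    ctrl_ids = [c for c in ctrl_ids if c in fc.log2fc.index]
    if not ctrl_ids:
        raise ValueError(
            "no non-targeting controls with counts; pass the uncentered table "
            "onward explicitly if centering is not wanted"
        )
    ctrl = fc.log2fc.loc[ctrl_ids]
    center = ctrl.median(axis=0) if cfg.control_center == "median" else ctrl.mean(axis=0)
    return FoldChangeTable(
        log2fc=fc.log2fc - center,
        reference_of=dict(fc.reference_of),
        centered=True,
    )


def _top_k_mean(values: pd.Series, k: int, fc_space: str) -> tuple[float, int]:
    """Mean of the k most-depleted values; ties broken by construct id.

    Input values are centered log2 fold changes. Under
    ``linear_then_log`` the result is log2(mean(2**values[topk])); under
    ``mean_of_logs`` it is mean(values[topk]).
    """
    ordered = values.sort_index().sort_values(kind="stable")
    k_used = min(k, len(ordered))
    top = ordered.iloc[:k_used]
    if fc_space == "linear_then_log":
        return float(np.log2(np.mean(2.0 ** top.values))), k_used
    return float(np.mean(top.values)), k_used


def gene_sensitivity_score(
    fc: FoldChangeTable, library: GuideLibrary, cfg: ScoreConfig | None = None
) -> list[TargetScore]:
    """Per gene: log2 of the mean fold change of the k most depleted
    constructs, computed per replicate (endpoint sample) and averaged."""
    cfg = cfg or ScoreConfig()
    results: list[TargetScore] = []
    for gene, construct_ids in library.targets("gene").items():
        present = [c for c in construct_ids if c in fc.log2fc.index]
        if not present:
            logger.warning("gene %s has no constructs with counts; skipped", gene)
            continue
        per_rep: dict[str, float] = {}
        n_used = 0
        for sample in fc.log2fc.columns:
            score, n_used = _top_k_mean(
                fc.log2fc.loc[present, sample], cfg.k_gene, cfg.fc_space
            )
            per_rep[sample] = score
        results.append(
            TargetScore(
                target_id=gene,
                score=float(np.mean(list(per_rep.values()))),
                per_unit_scores=per_rep,
                n_constructs_used=n_used,
            )
        )
    return results


def _region_construct_profile(
    fc: FoldChangeTable, cm_samples, group_ids: list[str]
) -> pd.DataFrame:
    """Per-construct log2fc averaged across each group's endpoint samples:
    constructs x groups."""
    cols = {}
    for gid in group_ids:
        members = [s for s in fc.log2fc.columns if cm_samples[s].group_id == gid]
        if not members:
            raise ValueError(f"group {gid!r} has no endpoint samples")
        cols[gid] = fc.log2fc[members].mean(axis=1)
    return pd.DataFrame(cols, index=fc.log2fc.index)


def region_scores_from_profile(
    profile: pd.DataFrame,
    region_constructs: dict[str, list[str]],
    m: int,
    fc_space: str = "mean_of_logs",
) -> list[TargetScore]:
    """Region scores from a constructs x groups profile of centered log2fc:
    per group the mean of the m lowest construct averages, then the mean
    over groups."""
    results = []
    for region, construct_ids in region_constructs.items():
        present = [c for c in construct_ids if c in profile.index]
        if not present:
            logger.warning("region %s has no constructs with counts; skipped", region)
            continue
        per_group: dict[str, float] = {}
        n_used = 0
        for gid in profile.columns:
            score, n_used = _top_k_mean(profile.loc[present, gid], m, fc_space)
            per_group[gid] = score
        results.append(
            TargetScore(
                target_id=region,
                score=float(np.mean(list(per_group.values()))),
                per_unit_scores=per_group,
                n_constructs_used=n_used,
            )
        )
    return results


def region_depletion_score(
    fc: FoldChangeTable,
    library: GuideLibrary,
    cm: CountMatrix,
    cfg: ScoreConfig | None = None,
) -> list[TargetScore]:
    """Per region: average each construct over a group's tumours, take the
    mean of the m most depleted construct averages per group, then
    average the per-group scores.

    With ``cfg.per_unit_center`` each endpoint sample (tumour) is treated
    as its own group.
    """
    cfg = cfg or ScoreConfig()
    if cfg.per_unit_center:
        group_ids = sorted({cm.samples[s].unit_id for s in cm.endpoint_samples})
        samples = {
            s: type(cm.samples[s])(
                sample_id=s,
                role=cm.samples[s].role,
                unit_id=cm.samples[s].unit_id,
                group_id=cm.samples[s].unit_id,
                reference=cm.samples[s].reference,
            )
            for s in cm.counts.columns
        }
    else:
        group_ids = sorted({cm.samples[s].group_id for s in cm.endpoint_samples})
        samples = cm.samples
    profile = _region_construct_profile(fc, samples, group_ids)
    # region depletion averages in log2 space (the per-group construct
    # averages are themselves log2 values); fc_space applies to gene scores
    return region_scores_from_profile(
        profile, library.targets("region"), cfg.m_region, "mean_of_logs"
    )


def scores_to_frame(scores: list[TargetScore]) -> pd.DataFrame:
    """Tidy result table: target_id, score, n_constructs_used, plus one
    ``score_<unit>`` column per replicate/group."""
    rows = []
    for s in scores:
        row = {
            "target_id": s.target_id,
            "score": s.score,
            "n_constructs_used": s.n_constructs_used,
        }
        for unit, val in s.per_unit_scores.items():
            row[f"score_{unit}"] = val
        rows.append(row)
    return pd.DataFrame(rows)
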