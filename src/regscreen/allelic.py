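"""Allele-specific ratio computation and normalization.

IP signals are normalized to their input control and expression signals
to genomic DNA, in odds-ratio form by default so the statistic inverts
exactly under allele relabelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

CONTEXTS = frozenset({"ip", "input", "rna", "gdna"})


@dataclass(frozen=True)
class AllelicMeasurement:
    label: str
    allele1_signal: float
    allele2_signal: float
    context: str  # ip | input | rna | gdna
    condition: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.allele1_signal < 0 or self.allele2_signal < 0:
            raise ValueError(f"{self.label}: allele signals must be >= 0")
        if self.allele1_signal + self.allele2_signal <= 0:
            raise ValueError(f"{self.label}: both allele signals are zero")
        if self.context not in CONTEXTS:
            raise ValueError(f"{self.label}: unknown context {self.context!r}")

    def swapped(self) -> "AllelicMeasurement":
        return AllelicMeasurement(
            label=self.label,
            allele1_signal=self.allele2_signal,
            allele2_signal=self.allele1_signal,
            context=self.context,
            condition=self.condition,
            replicate=self.replicate,
        )


def allele_fraction(m: AllelicMeasurement) -> float:
    """allele1 / (allele1 + allele2); 0 or 1 signals a monoallelic call."""
    return m.allele1_signal / (m.allele1_signal + m.allele2_signal)


def normalize_to_reference(
    sample: AllelicMeasurement,
    reference: AllelicMeasurement,
    mode: str = "odds",
) -> float:
    """Sample allelic bias relative to a reference (input or gDNA).

    ``odds`` (default): (f_s / (1 - f_s)) / (f_r / (1 - f_r)) — symmetric
    under allele relabelling (r -> 1/r). ``fraction``: f_s / f_r.
    A value of 1 means no bias beyond the reference.
    """
    f_ref = allele_fraction(reference)
    if f_ref <= 0.0 or f_ref >= 1.0:
        raise ValueError(
            f"reference {reference.label} is monoallelic (fraction {f_ref}); "
            "uninformative for normalization"
        )
    f_s = allele_fraction(sample)
    if mode == "odds":
        if f_s >= 1.0:
            return float("inf")
        return (f_s / (1 - f_s)) / (f_ref / (1 - f_ref))
    if mode == "fraction":
        return f_s / f_ref
    raise ValueError(f"mode must be odds/fraction, got {mode!r}")


def _mean_se(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    return float(arr.mean()), se


def knockdown_allelic_shift(
    treated: Sequence[AllelicMeasurement],
    control: Sequence[AllelicMeasurement],
    reference: AllelicMeasurement | None = None,
) -> dict:
    """Per-allele fold change of treated over control, with an
    allele-selectivity index.

    Each measurement's per-allele signals are first divided by the
    reference's (gDNA) allele signals when a reference is given. Folds
    are ratios of condition means; selectivity = fold_allele1 /
    fold_allele2 (< 1 means allele 1 is preferentially lost).
    """
    if not treated or not control:
        raise ValueError("both conditions need >= 1 measurement")
    contexts = {m.context for m in treated} | {m.context for m in control}
    if len(contexts) > 1:
        raise ValueError(f"conditions span multiple contexts: {sorted(contexts)}")

    if reference is not None:
        if reference.allele1_signal <= 0 or reference.allele2_signal <= 0:
            raise ValueError("reference must have positive signal for both alleles")
        norm = (reference.allele1_signal, reference.allele2_signal)
    else:
        norm = (1.0, 1.0)

    def signals(ms: Sequence[AllelicMeasurement], allele: int) -> list[float]:
        attr = "allele1_signal" if allele == 1 else "allele2_signal"
        return [getattr(m, attr) / norm[allele - 1] for m in ms]

    out: dict = {}
    folds = []
    for allele in (1, 2):
        t_mean, t_se = _mean_se(signals(treated, allele))
        c_mean, c_se = _mean_se(signals(control, allele))
        if c_mean == 0:
            raise ValueError(f"control mean for allele {allele} is zero")
        fold = t_mean / c_mean
        folds.append(fold)
        out[f"fold_allele{allele}"] = fold
        out[f"treated_mean_allele{allele}"] = t_mean
        out[f"treated_se_allele{allele}"] = t_se
        out[f"control_mean_allele{allele}"] = c_mean
        out[f"control_se_allele{allele}"] = c_se
    out["selectivity"] = folds[0] / folds[1] if folds[1] != 0 else float("inf")
    return out


# ---------------------------------------------------------------------------
# TSV interface
# ---------------------------------------------------------------------------

_COLUMNS = ("label", "context", "condition", "allele1", "allele2", "replicate")


def read_allelic_table(path: str | Path) -> list[AllelicMeasurement]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing allelic columns {sorted(missing)}")
    return [
        AllelicMeasurement(
            label=str(r.label),
            allele1_signal=float(r.allele1),
            allele2_signal=float(r.allele2),
            context=str(r.context),
            condition="" if pd.isna(r.condition) else str(r.condition),
            replicate=int(r.replicate),
        )
        for r in df.itertuples(index=False)
    ]


def write_allelic_table(
    measurements: Sequence[AllelicMeasurement], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "label": m.label,
                "context": m.context,
                "condition": m.condition,
                "allele1": m.allele1_signal,
                "allele2": m.allele2_signal,
                "replicate": m.replicate,
            }
            for m in measurements
        ]
    ).to_csv(path, sep="\t", index=False)
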