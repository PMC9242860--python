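"""Readers and writers for screen count tables, guide libraries, BED
intervals and position weight matrices, plus the domain types they
canonicalize into.

All genomic coordinates are 0-based, half-open (BED convention)
throughout; any 1-based display is formatting only.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TARGET_CLASSES = frozenset(
    {"gene", "region", "nontargeting_control", "essential_control"}
)

DNA_ALPHABET = frozenset("ACGT")
BASES = ("A", "C", "G", "T")
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class MetadataError(ValueError):
    """Raised when sample metadata is inconsistent with the count table."""


class ValidationError(ValueError):
    """Raised when a parsed object violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval (0-based start, exclusive end)."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval", min_overlap: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        return (
            min(self.end, other.end) - max(self.start, other.start) >= min_overlap
        )


@dataclass(frozen=True)
class GuideConstruct:
    """A screen construct carrying one or two protospacers."""

    construct_id: str
    protospacers: tuple[str, ...]
    target_id: str
    target_class: str

    def __post_init__(self) -> None:
        if self.target_class not in TARGET_CLASSES:
            raise ValidationError(
                f"unknown target_class {self.target_class!r} for "
                f"{self.construct_id}"
            )
        if not 1 <= len(self.protospacers) <= 2:
            raise ValidationError(
                f"{self.construct_id}: expected 1-2 protospacers, "
                f"got {len(self.protospacers)}"
            )
        for ps in self.protospacers:
            if not ps or set(ps) - DNA_ALPHABET:
                raise ValidationError(
                    f"{self.construct_id}: protospacer {ps!r} not over ACGT"
                )
        is_ntc = self.target_class == "nontargeting_control"
        if is_ntc and self.target_id:
            raise ValidationError(
                f"{self.construct_id}: nontargeting_control must have empty target_id"
            )
        if not is_ntc and not self.target_id:
            raise ValidationError(
                f"{self.construct_id}: target_id required for class "
                f"{self.target_class}"
            )


@dataclass
class GuideLibrary:
    constructs: list[GuideConstruct]
    region_coords: dict[str, GenomicInterval] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.construct_id for c in self.constructs]
        dupes = {i for i in ids if ids.count(i) > 1} if len(set(ids)) != len(ids) else set()
        if dupes:
            raise ValidationError(f"duplicate construct ids: {sorted(dupes)}")

    @property
    def construct_ids(self) -> list[str]:
        return [c.construct_id for c in self.constructs]

    def by_class(self, target_class: str) -> list[GuideConstruct]:
        return [c for c in self.constructs if c.target_class == target_class]

    def targets(self, target_class: str) -> dict[str, list[str]]:
        """Mapping target_id -> construct ids for one class, insertion order."""
        out: dict[str, list[str]] = {}
        for c in self.constructs:
            if c.target_class == target_class:
                out.setdefault(c.target_id, []).append(c.construct_id)
        return out

    def class_tally(self) -> dict[str, int]:
        tally = {cls: 0 for cls in sorted(TARGET_CLASSES)}
        for c in self.constructs:
            tally[c.target_class] += 1
        return tally


@dataclass
class SampleMeta:
    sample_id: str
    role: str  # "reference" | "endpoint"
    unit_id: str
    group_id: str
    reference: str | None = None  # sample_id of the paired reference

    def __post_init__(self) -> None:
        if self.role not in ("reference", "endpoint"):
            raise MetadataError(
                f"sample {self.sample_id}: role must be reference/endpoint, "
                f"got {self.role!r}"
            )


@dataclass
class CountMatrix:
    """Nonnegative integer construct x sample counts with sample roles."""

    counts: pd.DataFrame  # index: construct ids, columns: sample ids
    samples: dict[str, SampleMeta]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValidationError("counts must be nonnegative")
        missing = set(self.counts.columns) - set(self.samples)
        if missing:
            raise MetadataError(f"samples without metadata: {sorted(missing)}")
        for sid in self.counts.columns:
            meta = self.samples[sid]
            if meta.role == "endpoint":
                if meta.reference is None or meta.reference not in self.counts.columns:
                    raise MetadataError(
                        f"endpoint sample {sid} has unresolvable reference "
                        f"{meta.reference!r}"
                    )

    @property
    def construct_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def endpoint_samples(self) -> list[str]:
        return [s for s in self.counts.columns if self.samples[s].role == "endpoint"]

    @property
    def reference_samples(self) -> list[str]:
        return [s for s in self.counts.columns if self.samples[s].role == "reference"]


@dataclass
class PWM:
    """Position probability matrix over (A, C, G, T) with a background."""

    probs: np.ndarray  # shape (L, 4)
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    name: str = "motif"
    pseudoweight: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValidationError("PWM probs must be an L x 4 matrix")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("PWM rows must sum to 1")
        if (self.probs <= 0).any():
            raise ValidationError("PWM entries must be > 0 (apply a pseudoweight)")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValidationError("background must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def max_score(self) -> float:
        """Best achievable log2-odds score in bits."""
        return float(
            np.log2(self.probs / self.background[None, :]).max(axis=1).sum()
        )

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------


def read_sample_meta(path: str | Path) -> dict[str, SampleMeta]:
    """Read the sidecar sample-metadata TSV.

    Columns: sample_id, role, unit_id, group_id, reference (empty for
    reference samples).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "role", "unit_id", "group_id"}
    missing = required - set(df.columns)
    if missing:
        raise MetadataError(f"{path}: missing metadata columns {sorted(missing)}")
    out: dict[str, SampleMeta] = {}
    for row in df.itertuples(index=False):
        ref = getattr(row, "reference", "") or None
        out[row.sample_id] = SampleMeta(
            sample_id=row.sample_id,
            role=row.role,
            unit_id=row.unit_id,
            group_id=row.group_id,
            reference=ref,
        )
    return out


def read_count_table(
    path: str | Path,
    library: GuideLibrary,
    sample_meta: str | Path | Mapping[str, SampleMeta] | None = None,
) -> CountMatrix:
    """Read a construct x sample count TSV into a validated CountMatrix.

    The header row carries sample ids; the first column carries construct
    ids. Constructs present in the library but absent from the file are
    zero-filled with a warning; constructs absent from the library are an
    error. ``sample_meta`` is either a parsed mapping, a path to the
    sidecar TSV, or None to use ``<path stem>.samples.tsv``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)

    unknown = set(df.index) - set(library.construct_ids)
    if unknown:
        raise FormatError(
            f"{path}: constructs not in library: {sorted(unknown)}"
        )
    for col in df.columns:
        series = df[col]
        if not np.issubdtype(series.dtype, np.number):
            bad = series[pd.to_numeric(series, errors="coerce").isna()]
            loc = f"{bad.index[0]},{col}" if len(bad) else col
            raise FormatError(f"{path}: non-numeric count at {loc}")
        frac = series != np.floor(series)
        if frac.any():
            raise FormatError(
                f"{path}: non-integer count at {frac.idxmax()},{col}"
            )
        if (series < 0).any():
            raise FormatError(
                f"{path}: negative count at {(series < 0).idxmax()},{col}"
            )

    absent = [c for c in library.construct_ids if c not in df.index]
    if absent:
        logger.warning(
            "%s: %d library constructs missing from count file, zero-filled: %s",
            path, len(absent), absent[:10],
        )
    df = df.reindex(library.construct_ids, fill_value=0).astype(np.int64)

    if sample_meta is None:
        sample_meta = path.parent / (path.stem + ".samples.tsv")
    if isinstance(sample_meta, (str, Path)):
        samples = read_sample_meta(sample_meta)
    else:
        samples = dict(sample_meta)
    return CountMatrix(counts=df, samples=samples)


def write_count_table(cm: CountMatrix, path: str | Path) -> None:
    path = Path(path)
    cm.counts.to_csv(path, sep="\t", index_label="construct_id")
    meta = pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "role": m.role,
                "unit_id": m.unit_id,
                "group_id": m.group_id,
                "reference": m.reference or "",
            }
            for m in cm.samples.values()
        ]
    )
    meta.to_csv(path.parent / (path.stem + ".samples.tsv"), sep="\t", index=False)


# ---------------------------------------------------------------------------
# Guide libraries
# ---------------------------------------------------------------------------

_LIB_COLUMNS = ("construct_id", "protospacer_1", "target_id", "target_class")


def read_library(path: str | Path) -> GuideLibrary:
    """Read a guide-library TSV.

    Required columns: construct_id, protospacer_1, target_id,
    target_class. Optional: protospacer_2 and region chrom/start/end for
    region targets.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(_LIB_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing library columns {sorted(missing)}")

    constructs: list[GuideConstruct] = []
    region_coords: dict[str, GenomicInterval] = {}
    for row in df.itertuples(index=False):
        spacers = [row.protospacer_1.upper()]
        ps2 = getattr(row, "protospacer_2", "")
        if ps2:
            spacers.append(ps2.upper())
        constructs.append(
            GuideConstruct(
                construct_id=row.construct_id,
                protospacers=tuple(spacers),
                target_id=row.target_id,
                target_class=row.target_class,
            )
        )
        chrom = getattr(row, "chrom", "")
        if chrom and row.target_class == "region":
            region_coords[row.target_id] = GenomicInterval(
                chrom=chrom,
                start=int(getattr(row, "start")),
                end=int(getattr(row, "end")),
                name=row.target_id,
            )

    lib = GuideLibrary(constructs=constructs, region_coords=region_coords)
    logger.info("%s: per-class construct counts %s", path, lib.class_tally())
    return lib


def write_library(library: GuideLibrary, path: str | Path) -> None:
    rows = []
    for c in library.constructs:
        coords = library.region_coords.get(c.target_id)
        rows.append(
            {
                "construct_id": c.construct_id,
                "protospacer_1": c.protospacers[0],
                "protospacer_2": c.protospacers[1] if len(c.protospacers) > 1 else "",
                "target_id": c.target_id,
                "target_class": c.target_class,
                "chrom": coords.chrom if coords else "",
                "start": coords.start if coords else "",
                "end": coords.end if coords else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Intervals (BED)
# ---------------------------------------------------------------------------


def read_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ into intervals, preserving file order and coordinates."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 else None
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, name=name, strand=strand)
                )
            except ValidationError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_intervals(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    scores: Sequence[float] | None = None,
) -> None:
    """Write BED3/BED6. BED6 is emitted when any name/strand/score is set."""
    intervals = list(intervals)
    bed6 = scores is not None or any(
        iv.name is not None or iv.strand is not None for iv in intervals
    )
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if bed6:
                score = 0 if scores is None else scores[i]
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{score}\t{iv.strand or '.'}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_tss_table(path: str | Path) -> dict[str, tuple[str, int]]:
    """Read a TSS TSV (gene, chrom, position[, strand]) -> gene -> (chrom, pos)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    return {r.gene: (r.chrom, int(r.position)) for r in df.itertuples(index=False)}


def write_tss_table(tss: Mapping[str, tuple[str, int]], path: str | Path) -> None:
    rows = [{"gene": g, "chrom": c, "position": p} for g, (c, p) in tss.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PWMs (JASPAR / MEME)
# ---------------------------------------------------------------------------


def _counts_to_probs(counts: np.ndarray, pseudoweight: float) -> np.ndarray:
    """Counts -> probabilities, adding ``pseudoweight`` of each position's
    total to every cell before normalizing."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0  # all-zero position becomes uniform
    padded = counts + pseudoweight * totals
    return padded / padded.sum(axis=1, keepdims=True)


_JASPAR_ROW = re.compile(r"^\s*([ACGT])\s*\[?\s*([\d.\s]+?)\s*\]?\s*$")


def _parse_jaspar(text: str, pseudoweight: float) -> list[PWM]:
    pwms: list[PWM] = []
    name = "motif"
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        nonlocal rows, name
        if rows:
            if set(rows) != set(BASES):
                raise FormatError(f"JASPAR motif {name!r}: need A/C/G/T rows")
            lengths = {len(v) for v in rows.values()}
            if len(lengths) != 1:
                raise FormatError(f"JASPAR motif {name!r}: ragged rows")
            counts = np.array([rows[b] for b in BASES]).T  # L x 4
            pwms.append(
                PWM(
                    probs=_counts_to_probs(counts, pseudoweight),
                    name=name,
                    pseudoweight=pseudoweight,
                )
            )
        rows = {}

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].split()[0] if line[1:].split() else "motif"
            continue
        m = _JASPAR_ROW.match(line)
        if not m:
            raise FormatError(f"unparseable JASPAR line: {line!r}")
        try:
            rows[m.group(1)] = [float(x) for x in m.group(2).split()]
        except ValueError as exc:
            raise FormatError(f"non-numeric JASPAR value in: {line!r}") from exc
    flush()
    if not pwms:
        raise FormatError("no motifs found in JASPAR input")
    return pwms


def _parse_meme(text: str, pseudoweight: float) -> list[PWM]:
    pwms: list[PWM] = []
    background = np.full(4, 0.25)
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            toks = lines[i].split()
            bg = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks) - 1, 2)}
            background = np.array([bg.get(b, 0.25) for b in BASES])
            background = background / background.sum()
        elif line.startswith("MOTIF"):
            parts = line.split()
            name = parts[1] if len(parts) > 1 else "motif"
            # advance to the letter-probability header
            while i < len(lines) and "letter-probability matrix" not in lines[i]:
                i += 1
            if i == len(lines):
                raise FormatError(f"MEME motif {name!r}: no probability matrix")
            rows = []
            i += 1
            while i < len(lines):
                toks = lines[i].split()
                if len(toks) != 4:
                    break
                try:
                    rows.append([float(t) for t in toks])
                except ValueError:
                    break
                i += 1
            if not rows:
                raise FormatError(f"MEME motif {name!r}: empty matrix")
            probs = np.asarray(rows)
            if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-3):
                raise FormatError(f"MEME motif {name!r}: rows do not sum to 1")
            # mix toward uniform so every entry is strictly positive
            probs = (probs + pseudoweight * 0.25) / (1.0 + pseudoweight)
            pwms.append(
                PWM(probs=probs, background=background, name=name,
                    pseudoweight=pseudoweight)
            )
            continue
        i += 1
    if not pwms:
        raise FormatError("no motifs found in MEME input")
    return pwms


def read_pwm(
    path: str | Path, dialect: str = "jaspar", pseudoweight: float = 0.01
) -> list[PWM]:
    """Read PWMs from a JASPAR raw-count or MEME minimal file.

    Counts are converted to probabilities with a fractional pseudoweight
    (default 0.01 of each position's total per cell); background defaults
    to uniform unless the file specifies one.
    """
    text = Path(path).read_text()
    if dialect == "jaspar":
        return _parse_jaspar(text, pseudoweight)
    if dialect == "meme":
        return _parse_meme(text, pseudoweight)
    raise ValueError(f"unknown PWM dialect {dialect!r}")


def write_pwm(pwms: Sequence[PWM], path: str | Path) -> None:
    """Write PWMs as JASPAR-style probability matrices (bracket format)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            for bi, base in enumerate(BASES):
                vals = " ".join(f"{v:.10g}" for v in pwm.probs[:, bi])
                fh.write(f"{base} [ {vals} ]\n")
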