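"""PWM scanning, per-position information content, allele-aware motif
scoring and two-motif geometry (orientation + spacing) statistics.

Scores are log2-odds in bits: sum over motif positions of
log2(p(base) / background(base)). Scanning covers both strands; windows
containing N are skipped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import BASES, BASE_INDEX, PWM, GenomicInterval

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

ORIENTATIONS = ("tandem_AB", "tandem_BA", "convergent", "divergent")


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    start: int  # 0-based
    end: int  # exclusive
    strand: str  # "+" or "-"
    score: float  # log2-odds bits


@dataclass(frozen=True)
class PairGeometry:
    hit_a: MotifHit
    hit_b: MotifHit
    orientation: str
    spacing_bp: int  # edge-to-edge; negative = overlap


def information_content(pwm: PWM) -> tuple[np.ndarray, list[str]]:
    """Per-position relative-entropy information in bits against the
    background, plus the argmax base per position.

    IC_j = sum_b p_jb * log2(p_jb / bg_b).
    """
    ic = (pwm.probs * np.log2(pwm.probs / pwm.background[None, :])).sum(axis=1)
    argmax = [BASES[i] for i in pwm.probs.argmax(axis=1)]
    return ic, argmax


def _encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else -> 4."""
    table = np.full(256, 4, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def scan(
    pwm: PWM,
    sequence: str,
    threshold_bits: float | None = None,
    sequence_id: str = "seq",
    threshold_fraction: float = 0.8,
) -> list[MotifHit]:
    """Score every window on both strands; return hits at or above the
    threshold, sorted by (start, strand).

    With ``threshold_bits`` unset the threshold is ``threshold_fraction``
    of the PWM's maximal achievable score. Minus-strand windows are
    scored on the reverse complement; reported coordinates stay on the
    forward strand.
    """
    L = len(pwm)
    n = len(sequence)
    if n < L:
        return []
    if threshold_bits is None:
        threshold_bits = threshold_fraction * pwm.max_score

    lods = np.log2(pwm.probs / pwm.background[None, :])  # L x 4
    # minus strand: reverse-complement the matrix instead of the sequence
    lods_rc = lods[::-1, [3, 2, 1, 0]]

    enc = _encode(sequence)
    n_win = n - L + 1
    # windows x L view of the encoded sequence
    idx = np.arange(n_win)[:, None] + np.arange(L)[None, :]
    windows = enc[idx]
    valid = ~(windows == 4).any(axis=1)

    hits: list[MotifHit] = []
    for strand, mat in (("+", lods), ("-", lods_rc)):
        safe = np.where(windows == 4, 0, windows)
        scores = mat[np.arange(L)[None, :], safe].sum(axis=1)
        for pos in np.nonzero(valid & (scores >= threshold_bits))[0]:
            hits.append(
                MotifHit(
                    sequence_id=sequence_id,
                    start=int(pos),
                    end=int(pos) + L,
                    strand=strand,
                    score=float(scores[pos]),
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def score_window(pwm: PWM, window: str, strand: str = "+") -> float:
    """Log2-odds score of one window (used as an independent per-hit check)."""
    if strand == "-":
        window = reverse_complement(window)
    total = 0.0
    for j, base in enumerate(window.upper()):
        bi = BASE_INDEX[base]
        total += float(np.log2(pwm.probs[j, bi] / pwm.background[bi]))
    return total


def allele_delta_score(
    pwm: PWM,
    sequence: str,
    hit: MotifHit,
    offset_in_motif: int,
    ref_base: str,
    alt_base: str,
) -> tuple[float, float, float]:
    """(score_ref, score_alt, delta) for swapping one base inside a hit.

    ``offset_in_motif`` indexes motif positions (0-based, in motif
    orientation). For minus-strand hits the supplied genomic bases are
    complemented before matrix lookup. Positive delta means the
    reference base is favoured.
    """
    if not 0 <= offset_in_motif < len(pwm):
        raise ValueError(
            f"offset_in_motif {offset_in_motif} outside motif of length {len(pwm)}"
        )
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    for b in (ref_base, alt_base):
        if b not in BASE_INDEX:
            raise ValueError(f"invalid base {b!r}")

    window = sequence[hit.start:hit.end]
    base_score = score_window(pwm, window, hit.strand)

    if hit.strand == "-":
        ref_eff, alt_eff = COMPLEMENT[ref_base], COMPLEMENT[alt_base]
    else:
        ref_eff, alt_eff = ref_base, alt_base
    j = offset_in_motif
    lod = lambda b: float(
        np.log2(pwm.probs[j, BASE_INDEX[b]] / pwm.background[BASE_INDEX[b]])
    )
    # current base in motif orientation at position j
    if hit.strand == "-":
        cur = COMPLEMENT[window[len(pwm) - 1 - j].upper()]
    else:
        cur = window[j].upper()
    score_ref = base_score - lod(cur) + lod(ref_eff)
    score_alt = base_score - lod(cur) + lod(alt_eff)
    return score_ref, score_alt, score_ref - score_alt


def classify_pair(hit_a: MotifHit, hit_b: MotifHit) -> tuple[str, int]:
    """Orientation class and edge-to-edge spacing of an A-B hit pair.

    Orientation depends only on the two strands and genomic order:
    same strand -> tandem (AB if A comes first in reading direction);
    opposite strands -> convergent when the upstream hit points at the
    downstream one, divergent when they face away. Spacing is
    start(downstream) - end(upstream); negative means overlap.
    """
    if hit_a.start <= hit_b.start:
        upstream, downstream = hit_a, hit_b
    else:
        upstream, downstream = hit_b, hit_a
    spacing = downstream.start - upstream.end

    if hit_a.strand == hit_b.strand:
        if hit_a.strand == "+":
            orientation = "tandem_AB" if hit_a.start <= hit_b.start else "tandem_BA"
        else:
            orientation = "tandem_AB" if hit_a.start >= hit_b.start else "tandem_BA"
    else:
        orientation = "convergent" if upstream.strand == "+" else "divergent"
    return orientation, spacing


def pair_geometry(
    hits_a: Sequence[MotifHit],
    hits_b: Sequence[MotifHit],
    max_span_bp: int = 1000,
    recurrent_min_count: int = 2,
    close_spacing_bp: int = 10,
) -> tuple[list[PairGeometry], dict]:
    """All same-sequence A-B hit pairs within ``max_span_bp``, classified
    by orientation and spacing.

    The summary reports per-orientation counts, the (orientation,
    spacing) histogram, configurations recurring at least
    ``recurrent_min_count`` times, and the count of pairs within the
    close-spacing band.
    """
    by_seq: dict[str, list[MotifHit]] = {}
    for h in hits_b:
        by_seq.setdefault(h.sequence_id, []).append(h)

    pairs: list[PairGeometry] = []
    for a in hits_a:
        for b in by_seq.get(a.sequence_id, ()):
            span = max(a.end, b.end) - min(a.start, b.start)
            if span > max_span_bp:
                continue
            orientation, spacing = classify_pair(a, b)
            pairs.append(PairGeometry(a, b, orientation, spacing))

    histogram = Counter((p.orientation, p.spacing_bp) for p in pairs)
    summary = {
        "n_pairs": len(pairs),
        "orientation_counts": dict(
            Counter(p.orientation for p in pairs)
        ),
        "histogram": dict(histogram),
        "mode": max(histogram, key=histogram.get) if histogram else None,
        "recurrent": [
            cfg for cfg, n in histogram.items() if n >= recurrent_min_count
        ],
        "n_close_spacing": sum(
            1 for p in pairs if 0 <= p.spacing_bp <= close_spacing_bp
        ),
        "n_overlapping": sum(1 for p in pairs if p.spacing_bp < 0),
    }
    return pairs, summary


def hits_to_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sequence_id": h.sequence_id,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "score_bits": h.score,
            }
            for h in hits
        ]
    )


def hits_to_intervals(hits: Sequence[MotifHit]) -> list[GenomicInterval]:
    return [
        GenomicInterval(h.sequence_id, h.start, h.end, name=None, strand=h.strand)
        for h in hits
    ]


def pairs_to_frame(pairs: Sequence[PairGeometry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sequence_id": p.hit_a.sequence_id,
                "a_start": p.hit_a.start,
                "a_strand": p.hit_a.strand,
                "b_start": p.hit_b.start,
                "b_strand": p.hit_b.strand,
                "orientation": p.orientation,
                "spacing_bp": p.spacing_bp,
            }
            for p in pairs
        ]
    )
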