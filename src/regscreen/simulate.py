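"""Synthetic-data generators for the whole pipeline: pooled dropout
screens with transplantation bottlenecks and overdispersed sequencing,
genome annotations with planted TSS-proximal peaks, sequences with
planted motif pairs, and allelic count tables.

Every generator is a pure function of (config, seed); a shared seed
expands into named per-component substreams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import (
    BASES,
    CountMatrix,
    GenomicInterval,
    GuideConstruct,
    GuideLibrary,
    PWM,
    SampleMeta,
)
from .motifs import reverse_complement

import pandas as pd


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic named substream of a global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------------------
# Pooled dropout screen
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    n_genes: int = 0
    n_regions: int = 50
    constructs_per_target: int = 4
    n_controls_nontargeting: int = 10
    n_controls_essential: int = 8
    plasmid_sigma: float = 1.0  # SD of log2 plasmid abundance
    efficacy_a: float = 5.0  # Beta(a, b) per-construct efficacy
    efficacy_b: float = 1.0
    fitness_effects: dict[str, float] = field(default_factory=dict)
    essential_fitness: float = -1.0  # per doubling
    n_doublings: float = 10.0
    bottleneck_size: int = 100_000  # founder cells per tumour
    n_units_per_group: int = 5
    n_groups: int = 2
    sequencing_depth: int = 1_000_000
    overdispersion: float = 10.0  # negative-binomial size parameter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing_depth must be > 0")
        if self.bottleneck_size < 1:
            raise ValueError("bottleneck_size must be >= 1")
        if min(self.n_genes, self.n_regions, self.n_controls_nontargeting,
               self.n_controls_essential) < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class TruthTable:
    fitness: dict[str, float]  # target_id -> fitness effect per doubling
    efficacy: dict[str, float]  # construct_id -> efficacy in [0, 1]


def _random_protospacer(rng: np.random.Generator, length: int = 20) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def _nb_counts(
    mean: np.ndarray, size: float, rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial draws via gamma-Poisson mixing."""
    mean = np.maximum(mean, 1e-12)
    lam = rng.gamma(shape=size, scale=mean / size)
    return rng.poisson(lam)


def simulate_screen(cfg: SimConfig) -> tuple[GuideLibrary, CountMatrix, TruthTable]:
    """Simulate a pooled dropout screen.

    Reference counts are multinomial over a log-normal plasmid pool. Each
    endpoint unit (tumour) draws a multinomial founder population of
    ``bottleneck_size`` cells, grows every construct by
    2^(n_doublings x efficacy x fitness), and is sequenced with
    negative-binomial noise at ``sequencing_depth``.
    """
    rng_lib = substream(cfg.seed, "library")

    constructs: list[GuideConstruct] = []
    fitness: dict[str, float] = {}

    def add(target_id: str, target_class: str, n: int, tandem: bool) -> None:
        for i in range(n):
            cid = f"{target_id}_c{i + 1}" if target_id else f"ntc_{len(constructs) + 1:04d}"
            spacers = (_random_protospacer(rng_lib),)
            if tandem:
                spacers = spacers + (_random_protospacer(rng_lib),)
            constructs.append(
                GuideConstruct(
                    construct_id=cid,
                    protospacers=spacers,
                    target_id=target_id,
                    target_class=target_class,
                )
            )

    for g in range(cfg.n_genes):
        tid = f"gene_{g + 1:04d}"
        add(tid, "gene", cfg.constructs_per_target, tandem=False)
        fitness[tid] = cfg.fitness_effects.get(tid, 0.0)
    for r in range(cfg.n_regions):
        tid = f"region_{r + 1:04d}"
        add(tid, "region", cfg.constructs_per_target, tandem=True)
        fitness[tid] = cfg.fitness_effects.get(tid, 0.0)
    for e in range(cfg.n_controls_essential):
        tid = f"essential_{e + 1:04d}"
        add(tid, "essential_control", 1, tandem=False)
        fitness[tid] = cfg.fitness_effects.get(tid, cfg.essential_fitness)
    add("", "nontargeting_control", cfg.n_controls_nontargeting, tandem=False)

    library = GuideLibrary(constructs=constructs)
    ids = library.construct_ids
    n = len(ids)
    if n == 0:
        raise ValueError("empty library")

    rng_pool = substream(cfg.seed, "plasmid")
    plasmid = 2.0 ** rng_pool.normal(0.0, cfg.plasmid_sigma, size=n)
    plasmid /= plasmid.sum()

    rng_eff = substream(cfg.seed, "efficacy")
    efficacy = rng_eff.beta(cfg.efficacy_a, cfg.efficacy_b, size=n)
    fitness_by_construct = np.array(
        [fitness.get(c.target_id, 0.0) for c in constructs]
    )
    growth = 2.0 ** (cfg.n_doublings * efficacy * fitness_by_construct)

    counts: dict[str, np.ndarray] = {}
    samples: dict[str, SampleMeta] = {}

    rng_ref = substream(cfg.seed, "reference")
    counts["plasmid"] = rng_ref.multinomial(cfg.sequencing_depth, plasmid)
    samples["plasmid"] = SampleMeta(
        sample_id="plasmid", role="reference", unit_id="plasmid", group_id="pool"
    )

    rng_units = substream(cfg.seed, "units")
    for g in range(cfg.n_groups):
        group_id = f"group_{g + 1}"
        for u in range(cfg.n_units_per_group):
            sid = f"tumour_g{g + 1}_u{u + 1:02d}"
            founder = rng_units.multinomial(cfg.bottleneck_size, plasmid)
            grown = founder * growth
            total = grown.sum()
            if total == 0:
                grown = np.ones(n)
                total = float(n)
            mean = grown / total * cfg.sequencing_depth
            counts[sid] = _nb_counts(mean, cfg.overdispersion, rng_units)
            samples[sid] = SampleMeta(
                sample_id=sid,
                role="endpoint",
                unit_id=sid,
                group_id=group_id,
                reference="plasmid",
            )

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=ids).astype(np.int64),
        samples=samples,
    )
    truth = TruthTable(
        fitness=fitness, efficacy=dict(zip(ids, efficacy.tolist()))
    )
    return library, cm, truth


# ---------------------------------------------------------------------------
# Genome annotation with planted TSS-proximal peaks
# ---------------------------------------------------------------------------


def simulate_genome_annotation(
    n_genes: int,
    n_peaks: int,
    chrom_lengths: Mapping[str, int],
    gene_set_size: int,
    enrichment: float = 0.0,
    window_bp: int = 500_000,
    peak_width: int = 400,
    seed: int = 0,
) -> tuple[dict[str, tuple[str, int]], list[GenomicInterval], list[str]]:
    """TSS table, peak list and designated gene set, with a fraction
    ``enrichment`` of peaks planted within the window of designated
    genes and the remainder uniform over the genome."""
    if not 0.0 <= enrichment <= 1.0:
        raise ValueError("enrichment must be in [0, 1]")
    if gene_set_size > n_genes:
        raise ValueError("gene_set_size exceeds n_genes")
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    if (lengths < peak_width + 1).any():
        raise ValueError("chromosomes too short for requested peak width")
    rng = substream(seed, "annotation")

    tss: dict[str, tuple[str, int]] = {}
    for i in range(n_genes):
        ci = rng.integers(len(chroms))
        pos = int(rng.integers(0, chrom_lengths[chroms[ci]]))
        tss[f"gene_{i + 1:05d}"] = (chroms[ci], pos)

    gene_set = list(rng.choice(sorted(tss), size=gene_set_size, replace=False))

    n_planted = int(round(enrichment * n_peaks))
    peaks: list[GenomicInterval] = []
    for i in range(n_peaks):
        if i < n_planted:
            gene = gene_set[rng.integers(len(gene_set))]
            chrom, pos = tss[gene]
            lo = max(0, pos - window_bp)
            hi = min(chrom_lengths[chrom] - peak_width, pos + window_bp)
            if hi <= lo:
                raise ValueError(f"cannot place a planted peak near {gene}")
            start = int(rng.integers(lo, hi))
        else:
            ci = rng.integers(len(chroms))
            chrom = chroms[ci]
            start = int(rng.integers(0, chrom_lengths[chrom] - peak_width))
        peaks.append(
            GenomicInterval(chrom, start, start + peak_width, name=f"peak_{i + 1:05d}")
        )
    return tss, peaks, gene_set


# ---------------------------------------------------------------------------
# Sequences with planted motif pairs
# ---------------------------------------------------------------------------

_PLANT_STRANDS = {
    # strand of (A, B) with A placed genomically first
    "tandem_AB": ("+", "+"),
    "tandem_BA": ("-", "-"),
    "convergent": ("+", "-"),
    "divergent": ("-", "+"),
}


def _sample_site(pwm: PWM, rng: np.random.Generator) -> str:
    return "".join(
        BASES[rng.choice(4, p=row)] for row in pwm.probs
    )


def simulate_sequences_with_motifs(
    pwm_a: PWM,
    pwm_b: PWM,
    orientation: str,
    spacing_bp: int,
    n_sequences: int,
    seq_length: int,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    plant: bool = True,
) -> tuple[list[tuple[str, str]], list[dict]]:
    """Sequences with one planted A-B motif pair each at the requested
    orientation and edge-to-edge spacing (A genomically first), at a
    random offset; remainder i.i.d. background. Returns (records,
    truth), records as (id, sequence). ``plant=False`` gives
    background-only sequences."""
    if orientation not in _PLANT_STRANDS:
        raise ValueError(f"unknown orientation {orientation!r}")
    span = len(pwm_a) + spacing_bp + len(pwm_b)
    if plant and (spacing_bp < 0 or span > seq_length):
        raise ValueError(
            f"geometry infeasible: span {span} vs sequence length {seq_length}"
        )
    bg = np.asarray(background, dtype=float)
    bg = bg / bg.sum()
    rng = substream(seed, "sequences")
    strand_a, strand_b = _PLANT_STRANDS[orientation]

    records: list[tuple[str, str]] = []
    truth: list[dict] = []
    for i in range(n_sequences):
        seq = list("".join(BASES[j] for j in rng.choice(4, size=seq_length, p=bg)))
        entry: dict = {"sequence_id": f"seq_{i + 1:04d}", "planted": plant}
        if plant:
            offset = int(rng.integers(0, seq_length - span + 1))
            site_a = _sample_site(pwm_a, rng)
            site_b = _sample_site(pwm_b, rng)
            ins_a = site_a if strand_a == "+" else reverse_complement(site_a)
            ins_b = site_b if strand_b == "+" else reverse_complement(site_b)
            a_start = offset
            b_start = offset + len(pwm_a) + spacing_bp
            seq[a_start:a_start + len(pwm_a)] = ins_a
            seq[b_start:b_start + len(pwm_b)] = ins_b
            entry.update(
                a_start=a_start, a_strand=strand_a,
                b_start=b_start, b_strand=strand_b,
                orientation=orientation, spacing_bp=spacing_bp,
            )
        records.append((entry["sequence_id"], "".join(seq)))
        truth.append(entry)
    return records, truth


def write_fasta(records: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# Allelic counts
# ---------------------------------------------------------------------------


def simulate_allelic_counts(
    true_selectivity: float,
    depth: int,
    n_replicates: int,
    seed: int = 0,
    contexts: tuple[str, str] = ("rna", "gdna"),
    baseline_fraction: float = 0.5,
):
    """Binomial allele-count draws for a knockdown experiment.

    The reference context (gDNA/input) and the control condition sample
    the baseline allele fraction; the treated condition scales allele 1
    by ``true_selectivity`` before renormalizing. Returns a list of
    AllelicMeasurement matching the allelic TSV schema.
    """
    from .allelic import AllelicMeasurement

    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 < baseline_fraction < 1.0:
        raise ValueError("baseline_fraction must be in (0, 1)")
    assay_ctx, ref_ctx = contexts
    s = true_selectivity
    f_treated = (s * baseline_fraction) / (s * baseline_fraction + (1 - baseline_fraction))
    rng = substream(seed, "allelic")

    out = []

    def draw(label: str, context: str, condition: str, frac: float, rep: int):
        a1 = int(rng.binomial(depth, frac))
        out.append(
            AllelicMeasurement(
                label=label,
                allele1_signal=float(a1),
                allele2_signal=float(depth - a1),
                context=context,
                condition=condition,
                replicate=rep,
            )
        )

    for rep in range(1, n_replicates + 1):
        draw(f"{ref_ctx}_r{rep}", ref_ctx, "", baseline_fraction, rep)
        draw(f"{assay_ctx}_control_r{rep}", assay_ctx, "control", baseline_fraction, rep)
        draw(f"{assay_ctx}_treated_r{rep}", assay_ctx, "treated", f_treated, rep)
    return out
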