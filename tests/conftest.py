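import numpy as np
import pandas as pd
import pytest

from regscreen.io import (
    CountMatrix,
    GuideConstruct,
    GuideLibrary,
    PWM,
    SampleMeta,
)


def make_library(
    n_regions=3,
    constructs_per_region=2,
    n_genes=1,
    constructs_per_gene=4,
    n_ntc=2,
    n_essential=1,
):
    constructs = []
    for r in range(n_regions):
        for c in range(constructs_per_region):
            constructs.append(
                GuideConstruct(
                    f"region_{r + 1}_c{c + 1}",
                    ("ACGTACGTACGTACGTACGT", "TGCATGCATGCATGCATGCA"),
                    f"region_{r + 1}",
                    "region",
                )
            )
    for g in range(n_genes):
        for c in range(constructs_per_gene):
            constructs.append(
                GuideConstruct(
                    f"gene_{g + 1}_c{c + 1}",
                    ("ACGTACGTACGTACGTACGT",),
                    f"gene_{g + 1}",
                    "gene",
                )
            )
    for i in range(n_ntc):
        constructs.append(
            GuideConstruct(f"ntc_{i + 1}", ("ACGTACGTACGTACGTACGT",), "", "nontargeting_control")
        )
    for i in range(n_essential):
        constructs.append(
            GuideConstruct(
                f"ess_{i + 1}", ("ACGTACGTACGTACGTACGT",), f"essential_{i + 1}",
                "essential_control",
            )
        )
    return GuideLibrary(constructs=constructs)


def make_count_matrix(library, counts_by_sample, roles=None, groups=None, refs=None):
    """Build a CountMatrix from {sample_id: sequence of counts}."""
    samples = {}
    sample_ids = list(counts_by_sample)
    roles = roles or {
        s: ("reference" if s == sample_ids[0] else "endpoint") for s in sample_ids
    }
    ref_default = sample_ids[0]
    for s in sample_ids:
        samples[s] = SampleMeta(
            sample_id=s,
            role=roles[s],
            unit_id=s,
            group_id=(groups or {}).get(s, "group_1"),
            reference=(refs or {}).get(s, ref_default if roles[s] == "endpoint" else None),
        )
    counts = pd.DataFrame(
        {s: np.asarray(v, dtype=np.int64) for s, v in counts_by_sample.items()},
        index=library.construct_ids,
    )
    return CountMatrix(counts=counts, samples=samples)


def sharp_pwm(consensus: str, p: float = 0.91, name: str = "motif") -> PWM:
    from regscreen.io import BASE_INDEX

    rows = []
    for base in consensus:
        row = [(1 - p) / 3] * 4
        row[BASE_INDEX[base]] = p
        rows.append(row)
    return PWM(probs=np.asarray(rows), name=name)


@pytest.fixture
def toy_library():
    return make_library()


@pytest.fixture
def pwm_acgt():
    return sharp_pwm("ACGT", name="acgt")
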