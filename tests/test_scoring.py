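import itertools
import math

import numpy as np
import pandas as pd
import pytest

from regscreen import scoring
from regscreen.scoring import (
    FoldChangeTable,
    ScoreConfig,
    control_center,
    gene_sensitivity_score,
    guide_log2fc,
    normalize_counts,
    region_depletion_score,
)

from conftest import make_count_matrix, make_library


def _fc_table(log2fc: dict, index, centered=True):
    return FoldChangeTable(
        log2fc=pd.DataFrame(log2fc, index=index),
        reference_of={s: "plasmid" for s in log2fc},
        centered=centered,
    )


class TestNormalize:
    def test_symmetric(self):
        lib = make_library(n_regions=1, constructs_per_region=2, n_genes=0,
                           n_ntc=0, n_essential=0)
        cm = make_count_matrix(lib, {"s": [1, 1]}, roles={"s": "reference"})
        ab = normalize_counts(cm, ScoreConfig(pseudocount=0.5))
        assert np.allclose(ab["s"], [500_000, 500_000])

    def test_hand_arithmetic(self):
        lib = make_library(n_regions=1, constructs_per_region=2, n_genes=0,
                           n_ntc=0, n_essential=0)
        cm = make_count_matrix(lib, {"s": [3, 1]}, roles={"s": "reference"})
        ab = normalize_counts(cm, ScoreConfig(pseudocount=0.5))
        # (3.5/5, 1.5/5) x 1e6
        assert np.allclose(ab["s"], [700_000, 300_000])

    def test_all_zero_sample_uniform(self):
        lib = make_library(n_regions=1, constructs_per_region=4, n_genes=0,
                           n_ntc=0, n_essential=0)
        cm = make_count_matrix(lib, {"s": [0, 0, 0, 0]}, roles={"s": "reference"})
        ab = normalize_counts(cm, ScoreConfig(pseudocount=0.5))
        assert np.allclose(ab["s"], 250_000)

    def test_columns_sum_to_million(self, toy_library):
        rng = np.random.default_rng(0)
        cm = make_count_matrix(
            toy_library,
            {"a": rng.integers(0, 100, len(toy_library.constructs)),
             "b": rng.integers(0, 100, len(toy_library.constructs))},
            roles={"a": "reference", "b": "endpoint"}, refs={"b": "a"},
        )
        ab = normalize_counts(cm)
        assert np.allclose(ab.sum(axis=0), 1e6, atol=1e-6)


class TestFoldChange:
    def _cm(self, ref, end):
        lib = make_library(n_regions=1, constructs_per_region=len(ref), n_genes=0,
                           n_ntc=0, n_essential=0)
        return lib, make_count_matrix(lib, {"plasmid": ref, "t1": end})

    def test_equal_abundance_zero(self):
        _, cm = self._cm([10, 10], [10, 10])
        fc = guide_log2fc(normalize_counts(cm), cm)
        assert np.allclose(fc.log2fc["t1"], 0.0)

    def test_double_is_one(self):
        # construct at twice its reference *proportion*
        lib = make_library(n_regions=1, constructs_per_region=2, n_genes=0,
                           n_ntc=0, n_essential=0)
        ab = pd.DataFrame(
            {"plasmid": [350_000.0, 650_000.0], "t1": [700_000.0, 300_000.0]},
            index=lib.construct_ids,
        )
        cm = make_count_matrix(lib, {"plasmid": [1, 1], "t1": [1, 1]})
        fc = guide_log2fc(ab, cm)
        assert fc.log2fc.loc[lib.construct_ids[0], "t1"] == pytest.approx(1.0)

    def test_halved_is_minus_one(self):
        lib = make_library(n_regions=1, constructs_per_region=2, n_genes=0,
                           n_ntc=0, n_essential=0)
        ab = pd.DataFrame(
            {"plasmid": [700_000.0, 300_000.0], "t1": [350_000.0, 650_000.0]},
            index=lib.construct_ids,
        )
        cm = make_count_matrix(lib, {"plasmid": [1, 1], "t1": [1, 1]})
        fc = guide_log2fc(ab, cm)
        assert fc.log2fc.loc[lib.construct_ids[0], "t1"] == pytest.approx(-1.0)

    def test_linear_log_consistency(self):
        _, cm = self._cm([5, 20, 80], [80, 20, 5])
        fc = guide_log2fc(normalize_counts(cm), cm)
        assert np.allclose(np.log2(fc.linear_fc), fc.log2fc, atol=1e-12)


class TestControlCenter:
    def test_subtraction(self):
        lib = make_library(n_regions=0, n_genes=1, constructs_per_gene=1,
                           n_ntc=2, n_essential=0)
        fc = _fc_table({"t1": [-1.4, -0.4, -0.4]}, lib.construct_ids, centered=False)
        out = control_center(fc, lib)
        assert out.log2fc.loc["gene_1_c1", "t1"] == pytest.approx(-1.0)
        assert np.allclose(out.log2fc.loc[["ntc_1", "ntc_2"], "t1"], 0.0)

    def test_identity_when_centered(self):
        lib = make_library(n_regions=0, n_genes=1, constructs_per_gene=1,
                           n_ntc=3, n_essential=0)
        fc = _fc_table({"t1": [0.7, -0.5, 0.0, 0.5]}, lib.construct_ids, centered=False)
        out = control_center(fc, lib)
        pd.testing.assert_frame_equal(out.log2fc, fc.log2fc)

    def test_single_control_maps_to_zero(self):
        lib = make_library(n_regions=0, n_genes=1, constructs_per_gene=1,
                           n_ntc=1, n_essential=0)
        fc = _fc_table({"t1": [1.3, 0.77]}, lib.construct_ids, centered=False)
        out = control_center(fc, lib)
        assert out.log2fc.loc["ntc_1", "t1"] == 0.0

    def test_no_controls_instructive_error(self):
        lib = make_library(n_regions=0, n_genes=1, constructs_per_gene=1,
                           n_ntc=0, n_essential=0)
        fc = _fc_table({"t1": [0.0]}, lib.construct_ids, centered=False)
        with pytest.raises(ValueError, match="centering"):
            control_center(fc, lib)


class TestGeneScore:
    def test_hand_arithmetic(self):
        # centered linear FCs (0.25, 0.5, 1.0, 2.0), k=3
        lib = make_library(n_regions=0, n_genes=1, constructs_per_gene=4,
                           n_ntc=0, n_essential=0)
        fc = _fc_table({"rep1": np.log2([0.25, 0.5, 1.0, 2.0])}, lib.construct_ids)
        (score,) = gene_sensitivity_score(fc, lib, ScoreConfig(k_gene=3))
        assert score.score == pytest.approx(math.log2((0.25 + 0.5 + 1.0) / 3))
        assert score.score == pytest.approx(-0.778, abs=5e-4)
        assert score.n_constructs_used == 3

    def test_all_neutral_zero(self):
        lib = make_library(n_regions=0, n_genes=1, constructs_per_gene=4,
                           n_ntc=0, n_essential=0)
        fc = _fc_table({"rep1": np.zeros(4)}, lib.construct_ids)
        (score,) = gene_sensitivity_score(fc, lib)
        assert score.score == 0.0

    def test_default_k_is_three(self):
        assert ScoreConfig().k_gene == 3

    def test_replicates_averaged(self):
        lib = make_library(n_regions=0, n_genes=1, constructs_per_gene=3,
                           n_ntc=0, n_essential=0)
        fc = _fc_table(
            {"rep1": [-1.0, -1.0, -1.0], "rep2": [-3.0, -3.0, -3.0]},
            lib.construct_ids,
        )
        (score,) = gene_sensitivity_score(fc, lib)
        assert score.per_unit_scores["rep1"] == pytest.approx(-1.0)
        assert score.per_unit_scores["rep2"] == pytest.approx(-3.0)
        assert score.score == pytest.approx(-2.0)

    def test_fewer_than_k_uses_all(self):
        lib = make_library(n_regions=0, n_genes=1, constructs_per_gene=2,
                           n_ntc=0, n_essential=0)
        fc = _fc_table({"rep1": [-2.0, 0.0]}, lib.construct_ids)
        (score,) = gene_sensitivity_score(fc, lib, ScoreConfig(k_gene=3))
        assert score.n_constructs_used == 2

    def test_fc_space_agreement_when_equal(self):
        lib = make_library(n_regions=0, n_genes=1, constructs_per_gene=4,
                           n_ntc=0, n_essential=0)
        fc = _fc_table({"rep1": np.full(4, -1.7)}, lib.construct_ids)
        (a,) = gene_sensitivity_score(fc, lib, ScoreConfig(fc_space="linear_then_log"))
        (b,) = gene_sensitivity_score(fc, lib, ScoreConfig(fc_space="mean_of_logs"))
        assert a.score == pytest.approx(b.score, abs=1e-12)


class TestRegionScore:
    def _score(self, per_group_values, m=2):
        """per_group_values: {group_id: list of per-construct log2fc}."""
        n = len(next(iter(per_group_values.values())))
        lib = make_library(n_regions=1, constructs_per_region=n, n_genes=0,
                           n_ntc=0, n_essential=0)
        counts = {"plasmid": np.ones(n, dtype=int)}
        groups = {}
        fc_cols = {}
        for gid, vals in per_group_values.items():
            sid = f"t_{gid}"
            counts[sid] = np.ones(n, dtype=int)
            groups[sid] = gid
            fc_cols[sid] = vals
        cm = make_count_matrix(lib, counts, groups=groups)
        fc = _fc_table(fc_cols, lib.construct_ids)
        return region_depletion_score(fc, lib, cm, ScoreConfig(m_region=m))

    def test_mean_of_two_lowest(self):
        (score,) = self._score({"g1": [-3.0, -2.0, -0.5]})
        assert score.score == pytest.approx(-2.5)

    def test_all_zero(self):
        (score,) = self._score({"g1": [0.0, 0.0, 0.0]})
        assert score.score == 0.0

    def test_group_mean(self):
        (score,) = self._score({"g1": [-2.0, -2.0], "g2": [-3.0, -3.0]})
        assert score.per_unit_scores == {
            "g1": pytest.approx(-2.0), "g2": pytest.approx(-3.0)
        }
        assert score.score == pytest.approx(-2.5)

    def test_units_averaged_within_group(self):
        lib = make_library(n_regions=1, constructs_per_region=2, n_genes=0,
                           n_ntc=0, n_essential=0)
        cm = make_count_matrix(
            lib,
            {"plasmid": [1, 1], "u1": [1, 1], "u2": [1, 1]},
            groups={"u1": "g1", "u2": "g1"},
        )
        fc = _fc_table({"u1": [-1.0, -5.0], "u2": [-3.0, -1.0]}, lib.construct_ids)
        (score,) = region_depletion_score(fc, lib, cm, ScoreConfig(m_region=2))
        # per-construct group averages: (-2, -3) -> mean -2.5
        assert score.score == pytest.approx(-2.5)

    def test_empty_group_rejected(self, toy_library):
        cm = make_count_matrix(
            toy_library,
            {"plasmid": np.ones(len(toy_library.constructs), dtype=int)},
        )
        fc = _fc_table({}, toy_library.construct_ids)
        fc.log2fc = pd.DataFrame(index=toy_library.construct_ids)
        with pytest.raises(ValueError):
            scoring._region_construct_profile(fc, cm.samples, ["missing_group"])


class TestProperties:
    def test_scale_invariance(self, toy_library):
        rng = np.random.default_rng(7)
        n = len(toy_library.constructs)
        base = rng.integers(50, 500, n)
        end = rng.integers(50, 500, n)
        cm1 = make_count_matrix(toy_library, {"plasmid": base, "t1": end})
        cm2 = make_count_matrix(toy_library, {"plasmid": base * 10, "t1": end * 10})
        cfg1 = ScoreConfig(pseudocount=0.5)
        cfg2 = ScoreConfig(pseudocount=5.0)  # scaled with the counts
        fc1 = guide_log2fc(normalize_counts(cm1, cfg1), cm1)
        fc2 = guide_log2fc(normalize_counts(cm2, cfg2), cm2)
        assert np.allclose(fc1.log2fc.values, fc2.log2fc.values, atol=1e-12)

    def test_top_k_equals_exhaustive_enumeration(self):
        rng = np.random.default_rng(11)
        for trial in range(20):
            n = int(rng.integers(1, 9))
            k = int(rng.integers(1, 5))
            vals = rng.normal(size=n)
            lib = make_library(n_regions=0, n_genes=1, constructs_per_gene=n,
                               n_ntc=0, n_essential=0)
            fc = _fc_table({"rep1": vals}, lib.construct_ids)
            (score,) = gene_sensitivity_score(fc, lib, ScoreConfig(k_gene=k))
            k_eff = min(k, n)
            best = min(
                np.log2(np.mean(2.0 ** np.asarray(sub)))
                for sub in itertools.combinations(vals, k_eff)
            )
            assert score.score == pytest.approx(best, abs=1e-12)

    def test_monotonicity_in_endpoint_count(self):
        lib = make_library(n_regions=0, n_genes=1, constructs_per_gene=3,
                           n_ntc=1, n_essential=0)
        rng = np.random.default_rng(3)
        base = rng.integers(100, 1000, 4)
        end = rng.integers(100, 1000, 4)
        scores = []
        for dec in (0, 50, 99):
            end_mod = end.copy()
            end_mod[0] = max(1, end_mod[0] - dec)
            cm = make_count_matrix(lib, {"plasmid": base, "t1": end_mod})
            fc = control_center(guide_log2fc(normalize_counts(cm), cm), lib)
            (s,) = gene_sensitivity_score(fc, lib)
            scores.append(s.score)
        assert scores[0] >= scores[1] >= scores[2]

    def test_tie_break_is_deterministic(self):
        lib = make_library(n_regions=0, n_genes=1, constructs_per_gene=4,
                           n_ntc=0, n_essential=0)
        fc = _fc_table({"rep1": [-1.0, -1.0, -1.0, -1.0]}, lib.construct_ids)
        runs = {
            gene_sensitivity_score(fc, lib, ScoreConfig(k_gene=2))[0].score
            for _ in range(5)
        }
        assert len(runs) == 1
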