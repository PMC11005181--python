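import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chromlink import motifs as mt
from chromlink.simulate import generate_motif_lists
from conftest import expr_from_linear


def motif_list(names, scores=None, consensus="ACGTAC", origin="tf"):
    n = len(names)
    return pd.DataFrame(
        {
            "motif": names,
            "score": scores if scores is not None else np.arange(n, 0, -1, dtype=float),
            "consensus": consensus,
            "origin_gene": origin,
        }
    )


class TestQuartileRanks:
    def test_four_items_get_each_quartile(self):
        assert list(mt.quartile_ranks(4)) == [1, 2, 3, 4]

    def test_five_items_split_2_1_1_1(self):
        ranks = mt.quartile_ranks(5)
        sizes = [int((ranks == q).sum()) for q in (1, 2, 3, 4)]
        assert sizes == [2, 1, 1, 1]

    def test_invariant_under_monotone_score_transform(self):
        names = [f"m{i}" for i in range(7)]
        scores = np.array([9.0, 7.0, 5.5, 4.0, 3.0, 2.0, 1.0])
        union = sorted(names)
        v1 = mt.build_vector(motif_list(names, scores), union)
        v2 = mt.build_vector(motif_list(names, np.exp(scores)), union)
        assert np.array_equal(v1, v2)


class TestBuildVector:
    def test_absent_motif_scores_zero(self):
        union = ["a", "b", "c"]
        vec = mt.build_vector(motif_list(["a", "c"]), union)
        assert vec[union.index("b")] == 0
        assert vec[union.index("a")] > 0

    def test_motif_outside_union_rejected(self):
        with pytest.raises(ValueError):
            mt.build_vector(motif_list(["a", "zzz"]), ["a", "b"])


class TestRmse:
    def test_identical_vectors_zero(self):
        assert mt.rmse_similarity([1, 2, 3, 4], [1, 2, 3, 4]) == 0.0

    def test_constant_offset_two(self):
        assert mt.rmse_similarity([1, 1, 1, 1], [3, 3, 3, 3]) == pytest.approx(2.0)

    def test_hand_evaluated_mixed_vector(self):
        assert mt.rmse_similarity([1, 0], [0, 2]) == pytest.approx(np.sqrt(5 / 2))

    @given(
        data=st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=4),
                st.integers(min_value=0, max_value=4),
                st.integers(min_value=0, max_value=4),
            ),
            min_size=2,
            max_size=8,
        )
    )
    @settings(max_examples=150, derandomize=True)
    def test_metric_axioms(self, data):
        a = np.array([t[0] for t in data], dtype=float)
        b = np.array([t[1] for t in data], dtype=float)
        c = np.array([t[2] for t in data], dtype=float)
        dab = mt.rmse_similarity(a, b)
        assert dab == pytest.approx(mt.rmse_similarity(b, a))
        assert mt.rmse_similarity(a, a) == 0.0
        assert dab <= mt.rmse_similarity(a, c) + mt.rmse_similarity(c, b) + 1e-9


class TestMotifFeatures:
    def test_homopolymer(self):
        f = mt.motif_features_one("m", "AAAA")
        assert f.px["A"] == 1.0
        assert f.entropy == 0.0

    def test_acgt_dinucleotides(self):
        f = mt.motif_features_one("m", "ACGT")
        assert f.pxy["AC"] == pytest.approx(1 / 3)
        assert f.pxy["CG"] == pytest.approx(1 / 3)
        assert f.pxy["GT"] == pytest.approx(1 / 3)
        assert f.entropy == pytest.approx(np.log2(3))

    def test_gaga_repeat(self):
        f = mt.motif_features_one("m", "GAGA")
        assert f.pxy["GA"] == pytest.approx(2 / 3)
        assert f.pxy["AG"] == pytest.approx(1 / 3)
        assert f.entropy == pytest.approx(0.9182958, abs=1e-6)

    def test_iupac_fractional_counting(self):
        f = mt.motif_features_one("m", "RR")
        assert f.px["A"] == pytest.approx(0.5)
        assert f.px["G"] == pytest.approx(0.5)
        assert sum(f.pxy.values()) == pytest.approx(1.0)

    @given(st.text(alphabet="ACGT", min_size=2, max_size=15))
    @settings(max_examples=150, derandomize=True)
    def test_probability_and_entropy_bounds(self, seq):
        f = mt.motif_features_one("m", seq)
        assert sum(f.px.values()) == pytest.approx(1.0)
        assert sum(f.pxy.values()) == pytest.approx(1.0)
        assert 0 <= f.entropy <= min(4.0, np.log2(len(seq) - 1) if len(seq) > 2 else 4.0) + 1e-9


class TestFilterByExpression:
    def test_non_expressed_origin_dropped_and_classes_attached(self):
        expr = expr_from_linear(
            {"tf_on": (8, 8, 8), "tf_off": (0.25, 0.25, 0.25)}
        )
        classes = pd.DataFrame(
            {"gene_id": ["tf_on", "tf_off"], "class_label": ["SEG", "unclassified"]}
        )
        entries = motif_list(["a", "b"], origin="tf_on")
        entries.loc[1, "origin_gene"] = "tf_off"
        out = mt.filter_by_expression(entries, expr, classes)
        assert list(out["motif"]) == ["a"]
        assert out.loc[0, "origin_class"] == "SEG"

    def test_planted_nonexpressed_fraction_is_dropped(self, dataset):
        expr = dataset["expression"]
        kept_fracs = []
        for df in dataset["motif_lists"].values():
            out = mt.filter_by_expression(df, expr)
            kept_fracs.append(len(out) / len(df))
        dropped = 1 - np.mean(kept_fracs)
        assert dropped == pytest.approx(0.25, abs=0.10)


class TestGroupSimilarity:
    def build(self, lists):
        vectors, union = mt.build_vectors(lists)
        groups = {
            name: ("SEG" if name.startswith("SEG") else "DEG")
            + ("_enh" if "enhancer" in name else "_pro")
            for name in vectors.columns
        }
        return vectors, groups

    def test_identical_vectors_give_zero_gap(self):
        base = motif_list([f"m{i}" for i in range(8)])
        lists = {name: base.copy() for name in
                 ("DEG_ect_enhancer", "DEG_end_enhancer", "SEG_enhancer", "SEG_promoter")}
        vectors, groups = self.build(lists)
        res = mt.group_similarity(vectors, groups, n_perm=100, seed=0)
        assert res["gap"] == 0.0
        assert res["report"].p_value > 0.5

    def test_disjoint_grammars_put_between_above_within(self):
        deg = [f"d{i}" for i in range(8)]
        seg = [f"s{i}" for i in range(8)]
        lists = {
            "DEG_ect_enhancer": motif_list(deg),
            "DEG_end_enhancer": motif_list(deg),
            "SEG_enhancer": motif_list(seg),
            "SEG_promoter": motif_list(seg),
        }
        vectors, _ = mt.build_vectors(lists)
        groups = {n: "SEG" if n.startswith("SEG") else "DEG" for n in vectors.columns}
        res = mt.group_similarity(vectors, groups, n_perm=200, seed=0)
        within = [v for k, v in res["medians"].items()
                  if k.split("~")[0] == k.split("~")[1]]
        between = [v for k, v in res["medians"].items()
                   if k.split("~")[0] != k.split("~")[1]]
        assert min(between) > max(within)

    def test_planted_grammar_structure_detected(self, dataset):
        lists = dataset["motif_lists"]
        vectors, groups = self.build(lists)
        res = mt.group_similarity(vectors, groups, n_perm=300, seed=0)
        assert res["gap"] > 0
        assert res["report"].p_value < 0.05


class TestGcStratifiedPermutation:
    def test_singleton_strata_make_null_degenerate(self):
        lists = {
            "DEG_ect_enhancer": motif_list(["a", "b"]),
            "DEG_end_enhancer": motif_list(["a", "b"]),
            "SEG_enhancer": motif_list(["c", "d"]),
            "SEG_promoter": motif_list(["c", "d"]),
        }
        vectors, union = mt.build_vectors(lists)
        groups = {n: ("SEG" if n.startswith("SEG") else "DEG") for n in vectors.columns}
        gc = pd.Series([0.1, 0.4, 0.6, 0.9], index=union)
        report = mt.gc_stratified_permutation(vectors, groups, gc, n_perm=50, seed=0)
        assert report.p_value == pytest.approx(1.0)

    def test_planted_structure_survives_gc_stratification(self, dataset):
        lists = dataset["motif_lists"]
        vectors, union = mt.build_vectors(lists)
        groups = {
            n: ("SEG" if n.startswith("SEG") else "DEG")
            + ("_enh" if "enhancer" in n else "_pro")
            for n in vectors.columns
        }
        gc = pd.Series(
            {
                m: mt.consensus_gc(c)
                for df in lists.values()
                for m, c in zip(df["motif"], df["consensus"])
            }
        ).reindex(union)
        report = mt.gc_stratified_permutation(vectors, groups, gc, n_perm=200, seed=0)
        assert report.p_value < 0.05


class TestMotifGenerator:
    def test_zero_overlap_gives_disjoint_support(self):
        lists = generate_motif_lists(n_motifs=20, overlap_fraction=0.0, seed=0)
        deg = set(lists["DEG_ect_enhancer"]["motif"])
        seg = set(lists["SEG_enhancer"]["motif"])
        assert not deg & seg

    def test_full_overlap_makes_identical_grammars(self):
        lists = generate_motif_lists(n_motifs=20, overlap_fraction=1.0, seed=0)
        pool = set()
        for df in lists.values():
            pool |= set(df["motif"])
        # one shared grammar: every motif reachable from both groups
        assert len(pool) <= 25

    def test_gc_split_separates_consensus_composition(self):
        lists = generate_motif_lists(n_motifs=30, overlap_fraction=0.0, gc_split=0.9, seed=0)
        seg_gc = np.mean([mt.consensus_gc(c) for c in lists["SEG_enhancer"]["consensus"]])
        deg_gc = np.mean([mt.consensus_gc(c) for c in lists["DEG_ect_enhancer"]["consensus"]])
        assert seg_gc > deg_gc + 0.1

    def test_infeasible_overlap_rejected(self):
        with pytest.raises(ValueError):
            generate_motif_lists(n_motifs=20, overlap_fraction=1.5, seed=0)


class TestSignatures:
    def test_signature_sets_and_feature_comparison(self, dataset):
        lists = dataset["motif_lists"]
        sigs = mt.signature_motifs(lists)
        assert sigs["DEG"] and sigs["SEG"]
        consensus = {
            m: c for df in lists.values() for m, c in zip(df["motif"], df["consensus"])
        }
        feats = {
            side: mt.motif_features(
                pd.DataFrame(
                    {"motif": sorted(ids), "consensus": [consensus[m] for m in sorted(ids)]}
                )
            )
            for side, ids in sigs.items()
        }
        table = mt.compare_feature_groups(feats["DEG"], feats["SEG"])
        assert set(table["feature"]) == {"entropy", "Pa", "length"}
        assert np.isfinite(table["mannwhitney_p"]).all()
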