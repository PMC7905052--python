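"""Alignment cascade, local-name confirmation, alignment table I/O."""

import numpy as np
import pytest

from ontofuse import FusionConfig, align, build_name_matrix, run_fusion
from ontofuse.align import (NAME, NON_MATCHED, STRUCTURE, local_name_mean,
                            read_alignment_table, write_alignment_table)
from ontofuse.core import extract_subgraph
from ontofuse.names import NameMatrix
from ontofuse.structure import StructMatrix

from conftest import build_graph


def matrices_for(A, B, s_entries, t_entries, t_rows, t_cols):
    rows, cols = tuple(A.class_ids), tuple(B.class_ids)
    S = np.zeros((len(rows), len(cols)))
    for (a, b), v in s_entries.items():
        S[rows.index(a), cols.index(b)] = v
    T = np.zeros((len(t_rows), len(t_cols)))
    for (a, b), v in t_entries.items():
        T[t_rows.index(a), t_cols.index(b)] = v
    return (NameMatrix(rows, cols, S),
            StructMatrix(tuple(t_rows), tuple(t_cols), T))


class TestCascade:
    def test_identical_ontologies_all_name_matched(self, fixture_pair):
        A, _, _ = fixture_pair
        res = run_fusion(A, A, FusionConfig())
        counts = res.alignment.counts()
        assert counts[NAME] == len(A)
        assert counts[STRUCTURE] == counts[NON_MATCHED] == 0
        assert all((a, b) in res.alignment.matched_pairs
                   for a, b in zip(A.class_ids, A.class_ids))

    def test_all_zero_scores_everything_non_matched(self):
        A = build_graph([("a1", "a2")])
        B = build_graph([("b1", "b2")])
        S, T = matrices_for(A, B, {}, {}, A.class_ids, B.class_ids)
        al = align(A, B, S, T, FusionConfig())
        assert al.counts()[NON_MATCHED] == 2 and not al.matched_pairs

    def test_structure_match_via_cascade(self):
        # S below theta_N, T above theta_T, local names similar enough
        A = build_graph([("a1", "a2"), ("a2", "a3")],
                        labels={"a1": "alpha", "a2": "beta", "a3": "gamma"})
        B = build_graph([("b1", "b2"), ("b2", "b3")],
                        labels={"b1": "alphq", "b2": "betq", "b3": "gammq"})
        cfg = FusionConfig(W=2, theta_T=0.7, theta_LN=0.5)
        S = build_name_matrix(A, B, cfg)
        assert S.values.max() <= 0.85  # nothing name-matches
        _, T = matrices_for(A, B, {}, {("a2", "b2"): 0.9},
                            A.class_ids, B.class_ids)
        al = align(A, B, S, T, cfg)
        rec = next(r for r in al.records if r.native_id == "a2")
        assert rec.match_type == STRUCTURE
        assert rec.translated_label == "betq"
        assert rec.structure_score == pytest.approx(0.9)

    def test_structure_match_blocked_by_local_name(self):
        A = build_graph([("a1", "a2")], labels={"a1": "xxxx", "a2": "yyyy"})
        B = build_graph([("b1", "b2")], labels={"b1": "pppp", "b2": "qqqq"})
        cfg = FusionConfig(W=2, theta_T=0.5, theta_LN=0.7)
        S = build_name_matrix(A, B, cfg)
        _, T = matrices_for(A, B, {}, {("a1", "b1"): 0.95},
                            A.class_ids, B.class_ids)
        al = align(A, B, S, T, cfg)
        assert al.counts()[NON_MATCHED] == 2

    def test_name_tie_broken_by_smallest_b_id(self):
        A = build_graph([], extra_nodes=["a1"], labels={"a1": "same"})
        B = build_graph([], extra_nodes=["b2", "b1"],
                        labels={"b2": "same", "b1": "same"})
        S = build_name_matrix(A, B, FusionConfig())
        al = align(A, B, S, None, FusionConfig())
        assert al.matched_pairs == {("a1", "b1")}

    def test_many_to_one_allowed(self):
        B = build_graph([], extra_nodes=["b1"], labels={"b1": "target"})
        A = build_graph([], extra_nodes=["a1", "a2"],
                        labels={"a1": "target", "a2": "target"})
        S = build_name_matrix(A, B, FusionConfig())
        al = align(A, B, S, None, FusionConfig())
        assert al.matched_pairs == {("a1", "b1"), ("a2", "b1")}


class TestThresholdMonotonicity:
    def test_raising_thresholds_never_adds_matches(self, small_pair):
        A, B = small_pair.onto_a, small_pair.onto_b
        name_counts, struct_counts = [], []
        for theta in (0.6, 0.75, 0.9):
            cfg = FusionConfig(theta_N=theta)
            res = run_fusion(A, B, cfg)
            name_counts.append(res.alignment.counts()[NAME])
        assert name_counts == sorted(name_counts, reverse=True)
        for theta in (0.4, 0.6, 0.8):
            cfg = FusionConfig(theta_LN=theta)
            res = run_fusion(A, B, cfg)
            struct_counts.append(res.alignment.counts()[STRUCTURE])
        assert struct_counts == sorted(struct_counts, reverse=True)


class TestLocalNameMean:
    def test_identical_subgraphs_mean_one(self, fixture_pair):
        A, _, _ = fixture_pair
        cfg = FusionConfig()
        S = build_name_matrix(A, A, cfg)
        node = A.class_ids[5]
        sub = extract_subgraph(A, node, cfg.W)
        assert local_name_mean(sub, sub, S) == pytest.approx(1.0)

    def test_hand_mean(self):
        A = build_graph([("a1", "a2")])
        B = build_graph([("b1", "b2")])
        S = NameMatrix(tuple(A.class_ids), tuple(B.class_ids),
                       np.array([[1.0, 0.2], [0.5, 0.1]]))
        sa = extract_subgraph(A, "a1", 1)
        sb = extract_subgraph(B, "b1", 1)
        assert local_name_mean(sa, sb, S) == pytest.approx((1.0 + 0.5) / 2)


class TestAlignmentTable:
    def test_round_trip_counts_and_format(self, tmp_path, small_pair):
        res = run_fusion(small_pair.onto_a, small_pair.onto_b,
                         FusionConfig())
        path = tmp_path / "al.tsv"
        write_alignment_table(res.alignment, str(path))
        rows = read_alignment_table(str(path))
        assert len(rows) == len(small_pair.onto_a)
        counts = res.alignment.counts()
        got = {t: sum(r["match_type"] == t for r in rows)
               for t in (NAME, STRUCTURE, NON_MATCHED)}
        assert got == counts
        for r in rows:
            if r["match_type"] == NON_MATCHED:
                assert r["translated_label"] == ""
            # scores printed with 4 decimals
            assert len(r["name_score"].split(".")[1]) == 4
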