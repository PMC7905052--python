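"""Alignment cascade: combine name and structure mapping into matches.

For each class *i* of ontology A the best name-mapping candidate *j* is
taken; if ``S(i,j) > theta_N`` the pair is a *Name* match.  Otherwise the
best structure-mapping candidate among the name-unmatched classes of B is
considered: it becomes a *Structure* match when ``T(i,j) >= theta_T`` and
the local name comparison confirms it — the mean of each subgraph node's
best label similarity against the partner subgraph must exceed
``theta_LN``.  Everything else is *Non-matched*.  Matching is greedy
per-A-class; several A classes may share one B partner.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np

from .core import OntologyGraph, Subgraph, extract_subgraph
from .names import NameMatrix
from .onto_io import FusionConfig
from .structure import StructMatrix

logger = logging.getLogger(__name__)

NAME = "Name"
STRUCTURE = "Structure"
NON_MATCHED = "Non-matched"


@dataclass(frozen=True)
class AlignmentRecord:
    native_id: str
    native_label: str
    translated_label: str
    name_score: float
    structure_score: float
    match_type: str


@dataclass
class Alignment:
    """One record per class of A plus the set of matched (A-id, B-id) pairs."""

    records: list[AlignmentRecord]
    matched_pairs: set[tuple[str, str]]
    pair_info: dict[tuple[str, str], tuple[str, float]] = field(
        default_factory=dict)

    def counts(self) -> dict[str, int]:
        out = {NAME: 0, STRUCTURE: 0, NON_MATCHED: 0}
        for rec in self.records:
            out[rec.match_type] += 1
        return out


def _best_column(row: np.ndarray, col_ids: tuple[str, ...]) -> tuple[int, float]:
    """Index and value of the row maximum; ties go to the smallest col id."""
    mx = float(row.max())
    cand = np.flatnonzero(row == mx)
    if cand.size == 1:
        return int(cand[0]), mx
    best = min(cand, key=lambda c: col_ids[c])
    return int(best), mx


def name_matched_sets(S: NameMatrix, theta_N: float
                      ) -> tuple[dict[str, str], set[str]]:
    """Greedy per-A-class name assignment above ``theta_N``.

    Returns the A-id -> B-id assignment and the set of B ids claimed by at
    least one A class.  The complementary classes on each side are the
    generator nodes for structure mapping.
    """
    assigned: dict[str, str] = {}
    used_b: set[str] = set()
    for pos, a_id in enumerate(S.row_ids):
        j, score = _best_column(S.values[pos], S.col_ids)
        if score > theta_N:
            b_id = S.col_ids[j]
            assigned[a_id] = b_id
            used_b.add(b_id)
    return assigned, used_b


def local_name_mean(sub_a: Subgraph, sub_b: Subgraph, S: NameMatrix) -> float:
    """Mean of each A-subgraph node's best name score against B's subgraph."""
    idx_a = [S.row_index[k] for k in sub_a.node_order]
    idx_b = [S.col_index[l] for l in sub_b.node_order]
    block = S.values[np.ix_(idx_a, idx_b)]
    return float(block.max(axis=1).mean())


def local_name_confirm(sub_a: Subgraph, sub_b: Subgraph, S: NameMatrix,
                       theta_LN: float) -> bool:
    return local_name_mean(sub_a, sub_b, S) > theta_LN


def align(A: OntologyGraph, B: OntologyGraph, S: NameMatrix,
          T: StructMatrix | None, cfg: FusionConfig) -> Alignment:
    """Run the full decision cascade and produce the alignment table.

    ``T`` may be ``None`` (or empty) to disable structure matching, in
    which case every name-unmatched class is reported Non-matched.
    """
    assigned, _ = name_matched_sets(S, cfg.theta_N)
    records: list[AlignmentRecord] = []
    pairs: set[tuple[str, str]] = set()
    info: dict[tuple[str, str], tuple[str, float]] = {}

    sub_cache_a: dict[str, Subgraph] = {}
    sub_cache_b: dict[str, Subgraph] = {}

    def sub_of(cache, onto, node):
        if node not in cache:
            cache[node] = extract_subgraph(onto, node, cfg.W)
        return cache[node]

    for pos, a_id in enumerate(S.row_ids):
        label = A.get(a_id).label
        _, name_score = _best_column(S.values[pos], S.col_ids)
        if a_id in assigned:
            b_id = assigned[a_id]
            records.append(AlignmentRecord(a_id, label, B.get(b_id).label,
                                           name_score, 0.0, NAME))
            pairs.add((a_id, b_id))
            info[(a_id, b_id)] = (NAME, name_score)
            continue
        struct_score = 0.0
        matched_b: str | None = None
        if T is not None and a_id in T.row_index and len(T.col_ids):
            row = T.values[T.row_index[a_id]]
            mx = float(row.max())
            struct_score = mx
            if mx >= cfg.theta_T:
                # all columns attaining the maximum, smallest id first;
                # the first candidate surviving local-name confirmation wins
                ties = sorted(np.flatnonzero(row == mx),
                              key=lambda c: T.col_ids[c])
                sa = sub_of(sub_cache_a, A, a_id)
                for c in ties:
                    b_id = T.col_ids[c]
                    sb = sub_of(sub_cache_b, B, b_id)
                    if local_name_confirm(sa, sb, S, cfg.theta_LN):
                        matched_b = b_id
                        break
        if matched_b is not None:
            records.append(AlignmentRecord(a_id, label,
                                           B.get(matched_b).label,
                                           name_score, struct_score,
                                           STRUCTURE))
            pairs.add((a_id, matched_b))
            info[(a_id, matched_b)] = (STRUCTURE, struct_score)
        else:
            records.append(AlignmentRecord(a_id, label, "", name_score,
                                           struct_score, NON_MATCHED))
    return Alignment(records=records, matched_pairs=pairs, pair_info=info)


def write_alignment_table(al: Alignment, path: str) -> None:
    """Write the five-column alignment report as TSV.

    Columns: native label in A, translated label from B (empty when
    unmatched), name score, structure score, assignment type.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["native_label", "translated_label", "name_score",
                    "structure_score", "match_type"])
        for rec in al.records:
            w.writerow([rec.native_label, rec.translated_label,
                        f"{rec.name_score:.4f}",
                        f"{rec.structure_score:.4f}", rec.match_type])


def read_alignment_table(path: str) -> list[dict[str, str]]:
    """Parse an alignment TSV back into row dicts (round-trip checks)."""
    with open(path, newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))
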