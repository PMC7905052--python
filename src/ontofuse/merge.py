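"""Ontology merging: fuse B into A along an alignment.

Matched B classes are translated to their A partners (their labels and
synonyms become synonyms of the partner); unmatched B classes are appended
under fresh deterministic ids; every B relation is re-expressed in merged
ids and added once, duplicates removed in first-seen order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .align import Alignment, NAME, STRUCTURE
from .core import OntologyError, OntologyGraph

logger = logging.getLogger(__name__)


@dataclass
class MergeResult:
    merged: OntologyGraph
    n_name_matches: int
    n_structure_matches: int
    n_added_classes: int
    n_added_relations: int
    provenance: dict[str, str]          # class id -> "A" | "B" | "both"
    n_classes_a: int
    n_classes_b: int
    n_matched_b: int                    # distinct B classes matched
    n_synonym_pairs: int                # matched (A, B) pairs


def _fresh_id(existing: set[str], counter: int, prefix: str = "B:"
              ) -> tuple[str, int]:
    while True:
        cid = f"{prefix}{counter:04d}"
        if cid not in existing:
            return cid, counter + 1
        counter += 1


def merge(A: OntologyGraph, B: OntologyGraph, al: Alignment) -> MergeResult:
    """Fuse ``B`` into ``A`` using the computed alignment.

    When several A classes match one B class, the B class's relations
    attach to the single best-scoring A partner (ties broken by
    lexicographic id); replicating them onto every partner would invent
    relations with no counterpart in either input.
    """
    for a_id, b_id in al.matched_pairs:
        if a_id not in A or b_id not in B:
            raise OntologyError(
                f"alignment references unknown classes: ({a_id!r}, {b_id!r})")

    # best A partner per matched B class
    partner: dict[str, tuple[float, str]] = {}
    for (a_id, b_id), (_, score) in sorted(al.pair_info.items()):
        cur = partner.get(b_id)
        if cur is None or score > cur[0]:
            partner[b_id] = (score, a_id)
    b_to_a = {b: a for b, (_, a) in partner.items()}

    merged = A.copy(name=f"{A.name}+{B.name}" if A.name or B.name else "")
    provenance = {a_id: "A" for a_id in A.class_ids}

    # translate matched B classes: labels/synonyms fold into the partner
    for b_id, a_id in b_to_a.items():
        provenance[a_id] = "both"
        target = merged.get(a_id)
        for name in B.get(b_id).all_names():
            if name != target.label and name not in target.synonyms:
                target.synonyms.append(name)

    # append unmatched B classes with fresh deterministic ids
    id_map: dict[str, str] = dict(b_to_a)
    existing = set(merged.class_ids)
    counter = 1
    for cls in B.classes:
        if cls.id in b_to_a:
            continue
        new_id, counter = _fresh_id(existing, counter)
        existing.add(new_id)
        merged.add_class(new_id, cls.label, list(cls.synonyms))
        provenance[new_id] = "B"
        id_map[cls.id] = new_id

    # re-express every B relation in merged ids; de-duplicate
    n_added_relations = 0
    for p, c in B.edges:
        mp, mc = id_map[p], id_map[c]
        if mp == mc:
            logger.debug("edge %r -> %r collapsed to a self-loop; dropped",
                         p, c)
            continue
        if merged.add_edge(mp, mc):
            n_added_relations += 1

    counts = al.counts()
    n_added_classes = len(merged) - len(A)
    return MergeResult(
        merged=merged,
        n_name_matches=counts[NAME],
        n_structure_matches=counts[STRUCTURE],
        n_added_classes=n_added_classes,
        n_added_relations=n_added_relations,
        provenance=provenance,
        n_classes_a=len(A),
        n_classes_b=len(B),
        n_matched_b=len(b_to_a),
        n_synonym_pairs=len(al.matched_pairs),
    )


def merge_stats(res: MergeResult) -> dict:
    """Summary statistics of a merge (exact integers + 1-decimal percents)."""
    n_a, n_b = res.n_classes_a, res.n_classes_b
    n_matches = res.n_name_matches + res.n_structure_matches

    def pct(x: float, whole: float) -> float:
        return round(100.0 * x / whole, 1) if whole else 0.0

    return {
        "classes_a": n_a,
        "classes_b": n_b,
        "classes_merged": len(res.merged),
        "relations_merged": res.merged.n_edges,
        "added_classes": res.n_added_classes,
        "added_relations": res.n_added_relations,
        "added_classes_pct_of_a": pct(res.n_added_classes, n_a),
        "matched_b_classes": res.n_matched_b,
        "matched_b_pct_of_b": pct(res.n_matched_b, n_b),
        "synonym_pairs": res.n_synonym_pairs,
        "name_matches": res.n_name_matches,
        "structure_matches": res.n_structure_matches,
        "name_match_pct": pct(res.n_name_matches, n_matches),
        "structure_match_pct": pct(res.n_structure_matches, n_matches),
    }
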