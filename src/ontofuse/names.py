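"""Name mapping: scaled Levenshtein similarity over class labels.

The name mapping matrix ``S^AB`` holds, for every class *i* of ontology A
and *j* of ontology B, the similarity

    S(i,j) = 1 - lev(label_i, label_j) / max(|label_i|, |label_j|)

which lies in [0, 1] and equals 1 exactly for identical strings.  With
synonym matching enabled, every pairing of the two classes' name lists
(label + synonyms) is scored and the maximum is kept.

The edit distance itself is the classic dynamic programme; bulk matrix
construction is routed through ``edlib`` when available (identical values,
C speed) and falls back to the in-package DP otherwise.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field

import numpy as np

from .core import OntologyGraph
from .onto_io import FusionConfig

logger = logging.getLogger(__name__)

try:  # optional accelerated backend for bulk distances
    import edlib as _edlib
except ImportError:  # pragma: no cover - environment without edlib
    _edlib = None


def levenshtein(a: str, b: str) -> int:
    """Classic edit distance (insertions + deletions + substitutions)."""
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        append = cur.append
        for j, cb in enumerate(b, start=1):
            append(min(prev[j] + 1,            # deletion
                       cur[j - 1] + 1,         # insertion
                       prev[j - 1] + (ca != cb)))  # substitution
        prev = cur
    return prev[-1]


def _fast_lev(a: str, b: str) -> int:
    if a == b:
        return 0
    if _edlib is not None:
        try:
            return _edlib.align(a, b, task="distance")["editDistance"]
        except Exception:  # >256-symbol alphabets etc.
            pass
    return levenshtein(a, b)


def name_similarity(a: str, b: str) -> float:
    """Scaled Levenshtein similarity in [0, 1]; two empty strings score 1."""
    if not a and not b:
        logger.debug("name_similarity on two empty strings; defined as 1.0")
        return 1.0
    return 1.0 - _fast_lev(a, b) / max(len(a), len(b))


def synonym_similarity(names_a: list[str], names_b: list[str]) -> float:
    """Best pairwise similarity between two name lists (labels included)."""
    return max(name_similarity(a, b) for a in names_a for b in names_b)


@dataclass
class NameMatrix:
    """Dense a x b similarity matrix with id-indexed rows and columns."""

    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    values: np.ndarray
    row_index: dict[str, int] = field(init=False, repr=False)
    col_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("matrix shape does not match index lengths")
        self.row_index = {i: p for p, i in enumerate(self.row_ids)}
        self.col_index = {j: p for p, j in enumerate(self.col_ids)}

    def sim(self, a_id: str, b_id: str) -> float:
        return float(self.values[self.row_index[a_id],
                                 self.col_index[b_id]])

    def to_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t" + "\t".join(self.col_ids) + "\n")
            for rid, row in zip(self.row_ids, self.values):
                fh.write(rid + "\t"
                         + "\t".join(f"{v:.6f}" for v in row) + "\n")


def _names_of(onto: OntologyGraph, use_synonyms: bool) -> list[list[str]]:
    out = []
    for cls in onto.classes:
        label = unicodedata.normalize("NFC", cls.label)
        if not label:
            logger.warning("class %r has an empty label; using its id",
                           cls.id)
            label = cls.id
        names = [label]
        if use_synonyms:
            names += [unicodedata.normalize("NFC", s) for s in cls.synonyms
                      if s]
        out.append(names)
    return out


def build_name_matrix(A: OntologyGraph, B: OntologyGraph,
                      cfg: FusionConfig | None = None) -> NameMatrix:
    """Build the full name mapping matrix ``S^AB``.

    The matrix is materialised densely: local name matching later averages
    arbitrary entries, so every pair is needed.
    """
    cfg = cfg or FusionConfig()
    if len(A) == 0 or len(B) == 0:
        raise ValueError("both ontologies must be non-empty")
    names_a = _names_of(A, cfg.use_synonyms)
    names_b = _names_of(B, cfg.use_synonyms)
    values = np.zeros((len(names_a), len(names_b)), dtype=np.float64)
    for i, la in enumerate(names_a):
        row = values[i]
        for j, lb in enumerate(names_b):
            best = 0.0
            for a in la:
                for b in lb:
                    if a == b:
                        best = 1.0
                        break
                    s = 1.0 - _fast_lev(a, b) / max(len(a), len(b))
                    if s > best:
                        best = s
                if best == 1.0:
                    break
            row[j] = best
    return NameMatrix(tuple(A.class_ids), tuple(B.class_ids), values)
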