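"""End-to-end fusion pipeline: preprocess -> S -> T -> align -> merge."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

from .align import Alignment, align, name_matched_sets
from .core import OntologyGraph
from .merge import MergeResult, merge
from .names import NameMatrix, build_name_matrix
from .onto_io import FusionConfig
from .preprocess import normalize_graph_labels
from .structure import StructMatrix, build_structure_matrix

logger = logging.getLogger(__name__)


@dataclass
class FusionResult:
    alignment: Alignment
    merge: MergeResult
    name_matrix: NameMatrix
    struct_matrix: StructMatrix | None
    elapsed: dict[str, float]


def run_fusion(A: OntologyGraph, B: OntologyGraph,
               cfg: FusionConfig | None = None, threads: int = 1,
               normalize: bool = True, structure: bool = True
               ) -> FusionResult:
    """Align and merge ``B`` into ``A`` under the configuration.

    ``normalize`` applies label preconditioning (lowercase plus the
    configured strip characters and stop words) to working copies of both
    ontologies.  ``structure=False`` restricts matching to names only.
    """
    cfg = cfg or FusionConfig()
    elapsed: dict[str, float] = {}

    t0 = time.perf_counter()
    A, B = A.copy(), B.copy()
    if normalize:
        normalize_graph_labels(A, cfg.strip_chars, cfg.stop_words)
        normalize_graph_labels(B, cfg.strip_chars, cfg.stop_words)
    elapsed["preprocess"] = time.perf_counter() - t0
    logger.info("inputs: %d classes / %d relations vs %d classes / %d "
                "relations", len(A), A.n_edges, len(B), B.n_edges)

    t0 = time.perf_counter()
    S = build_name_matrix(A, B, cfg)
    elapsed["name_matrix"] = time.perf_counter() - t0
    logger.info("name matrix %dx%d built in %.2fs", *S.values.shape,
                elapsed["name_matrix"])

    T: StructMatrix | None = None
    if structure:
        assigned, used_b = name_matched_sets(S, cfg.theta_N)
        unmatched_a = [i for i in A.class_ids if i not in assigned]
        unmatched_b = [j for j in B.class_ids if j not in used_b]
        t0 = time.perf_counter()
        T = build_structure_matrix(A, B, unmatched_a, unmatched_b, cfg,
                                   S=S, threads=threads)
        elapsed["structure_matrix"] = time.perf_counter() - t0
        logger.info("structure matrix %dx%d (%s) built in %.2fs",
                    len(T.row_ids), len(T.col_ids), cfg.metric,
                    elapsed["structure_matrix"])

    t0 = time.perf_counter()
    al = align(A, B, S, T, cfg)
    elapsed["align"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    res = merge(A, B, al)
    elapsed["merge"] = time.perf_counter() - t0
    counts = al.counts()
    logger.info("alignment: %(Name)d name / %(Structure)d structure / "
                "%(Non-matched)d non-matched", counts)
    logger.info("merged ontology: %d classes, %d relations",
                len(res.merged), res.merged.n_edges)
    return FusionResult(alignment=al, merge=res, name_matrix=S,
                        struct_matrix=T, elapsed=elapsed)
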