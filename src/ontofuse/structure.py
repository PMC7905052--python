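"""Structure mapping: subgraph similarity between name-unmatched classes.

Classes the name mapping leaves unassigned ("generator nodes") are compared
through the window-``W`` subgraphs around them.  Five metrics are offered:

* **cosine / euclidean / pearson** — vectorial convolution: each adjacency
  row of the shorter-dimension matrix is slid across each row of the longer
  one at all ``nc = |a - b| + 1`` offsets, each offset scored by the vector
  metric, and the per-row-pair maximum kept.  The per-row maxima are reduced
  to one subgraph score by averaging row-wise and column-wise means, which
  makes the score symmetric and penalises size mismatch.
* **constraint** — trusts the name mapping: every subgraph node pair with
  name similarity above ``theta_N`` contributes a proximity weight
  ``c = W + 1 - s`` (``s`` = shortest path to the generator); the summed
  weights are normalised by the maximum attainable sum.
* **blondel** — the iterative mutually-reinforcing vertex similarity of
  Blondel et al., run on the two subgraph adjacency matrices and read out
  at the generators' positions.

All metrics return values in [0, 1].
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import (OntologyGraph, Subgraph, adjacency_matrix,
                   extract_subgraph, shortest_path_to_generator)
from .names import NameMatrix
from .onto_io import FusionConfig

logger = logging.getLogger(__name__)

VECTOR_METRICS = ("cosine", "euclidean", "pearson")


@dataclass(frozen=True)
class ConvolutionResult:
    """All per-slide similarities of one row pair, and their maximum."""

    nc: int
    scores: tuple[float, ...]
    best: float


def _metric_scores(short: np.ndarray, windows: np.ndarray, metric: str
                   ) -> np.ndarray:
    """Score every (short-row, window) combination with one vector metric.

    ``short``  has shape (s, m); ``windows`` has shape (t, nc, m).
    Returns an (s, t, nc) array of similarities in [0, 1].
    """
    short = short.astype(np.float64, copy=False)
    windows = windows.astype(np.float64, copy=False)
    m = short.shape[1]
    dots = np.einsum("sm,tnm->stn", short, windows)
    if metric == "cosine":
        ns = np.linalg.norm(short, axis=1)                 # (s,)
        nw = np.linalg.norm(windows, axis=2)               # (t, nc)
        denom = ns[:, None, None] * nw[None, :, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = np.where(denom > 0, dots / np.where(denom > 0, denom, 1.0),
                           0.0)
        both_zero = (ns[:, None, None] == 0) & (nw[None, :, :] == 0)
        sim = np.where(both_zero, 1.0, sim)
    elif metric == "euclidean":
        ns2 = np.einsum("sm,sm->s", short, short)
        nw2 = np.einsum("tnm,tnm->tn", windows, windows)
        d2 = ns2[:, None, None] + nw2[None, :, :] - 2.0 * dots
        dist = np.sqrt(np.clip(d2, 0.0, None))
        sim = 1.0 - dist / np.sqrt(m)
    elif metric == "pearson":
        sc = short - short.mean(axis=1, keepdims=True)
        wc = windows - windows.mean(axis=2, keepdims=True)
        cov = np.einsum("sm,tnm->stn", sc, wc) / m
        vs = short.var(axis=1)
        vw = windows.var(axis=2)
        denom = np.sqrt(vs[:, None, None] * vw[None, :, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0),
                           0.0)
        # zero-variance windows: undefined correlation; identical constant
        # vectors count as 1, anything else as 0
        zs = vs[:, None, None] == 0
        zw = vw[None, :, :] == 0
        const_equal = short[:, None, None, 0] == windows[None, :, :, 0]
        sim = np.where(zs & zw, np.where(const_equal, 1.0, 0.0), sim)
        sim = np.where(zs ^ zw, 0.0, sim)
    else:
        raise ValueError(f"unknown vector metric: {metric!r}")
    return np.clip(sim, 0.0, 1.0)


def row_convolution(row_a, row_b, metric: str = "cosine"
                    ) -> ConvolutionResult:
    """Slide the shorter row over the longer one at every offset.

    ``nc = |len_a - len_b| + 1`` similarities are computed with the chosen
    metric and the maximum is selected.
    """
    ra = np.asarray(row_a, dtype=np.float64)
    rb = np.asarray(row_b, dtype=np.float64)
    if ra.size == 0 or rb.size == 0:
        raise ValueError("rows must be non-empty")
    short, long_ = (ra, rb) if ra.size <= rb.size else (rb, ra)
    windows = sliding_window_view(long_, short.size)       # (nc, m)
    sim = _metric_scores(short[None, :], windows[None, :, :], metric)[0, 0]
    return ConvolutionResult(nc=sim.size, scores=tuple(float(v) for v in sim),
                             best=float(sim.max()))


def _pair_best_matrix(adj_a: np.ndarray, adj_b: np.ndarray, metric: str
                      ) -> np.ndarray:
    """Per-row-pair best convolution scores, shape (a, b)."""
    a, b = adj_a.shape[0], adj_b.shape[0]
    if a <= b:
        short_rows, long_rows, transpose = adj_a, adj_b, False
    else:
        short_rows, long_rows, transpose = adj_b, adj_a, True
    windows = sliding_window_view(long_rows, short_rows.shape[1], axis=1)
    best = _metric_scores(short_rows, windows, metric).max(axis=2)
    return best.T if transpose else best


def vectorial_similarity(sub_a: Subgraph, sub_b: Subgraph,
                         metric: str = "cosine") -> float:
    """Convolutional vectorial similarity between two subgraphs.

    Per-row best scores are aggregated symmetrically: the mean of row
    maxima and the mean of column maxima are averaged, so the score is
    invariant under exchanging the two subgraphs and reaches 1.0 for
    identical subgraphs in identical node order.
    """
    bits_a = adjacency_matrix(sub_a).bits
    bits_b = adjacency_matrix(sub_b).bits
    # only structure-bearing rows enter the aggregation: an all-zero row
    # carries no edges, and counting its trivial agreement with all-zero
    # windows would score edgeless regions as perfect matches
    nz_a = bits_a.any(axis=1)
    nz_b = bits_b.any(axis=1)
    if not nz_a.any() and not nz_b.any():
        # both subgraphs edgeless: extraction only yields this for
        # single-node windows, which are structurally identical
        return 1.0
    if not nz_a.any() or not nz_b.any():
        return 0.0
    p = _pair_best_matrix(bits_a, bits_b, metric)
    score = 0.5 * (p[nz_a].max(axis=1).mean() + p[:, nz_b].max(axis=0).mean())
    return float(np.clip(score, 0.0, 1.0))


def constraint_similarity(sub_a: Subgraph, sub_b: Subgraph, S: NameMatrix,
                          theta_N: float, W: int) -> float:
    """Proximity-weighted count of name matches between two subgraphs.

    Requires at least one node of the A-side subgraph to name-match a node
    of the B-side subgraph (similarity strictly above ``theta_N``);
    otherwise the score is 0.  Each matched node k contributes
    ``c_k = W + 1 - s_k`` with ``s_k`` its shortest path to the generator.
    The accumulated constraint is normalised by the maximum attainable sum
    (all of ``min(|A_W|, |B_W|) - 1`` non-generator nodes matched at
    distance 1, i.e. ``(min - 1) * W``) and capped at 1.
    """
    if W < 1:
        raise ValueError("W must be >= 1")
    idx_a = [S.row_index[k] for k in sub_a.node_order]
    idx_b = [S.col_index[l] for l in sub_b.node_order]
    block = S.values[np.ix_(idx_a, idx_b)]
    matched = block.max(axis=1) > theta_N
    if not matched.any():
        return 0.0
    total = 0.0
    for pos, k in enumerate(sub_a.node_order):
        if matched[pos]:
            total += W + 1 - shortest_path_to_generator(sub_a, k)
    denom = (min(len(sub_a.members), len(sub_b.members)) - 1) * W
    if denom <= 0:
        return 1.0
    return float(min(total / denom, 1.0))


def blondel_similarity(sub_a: Subgraph, sub_b: Subgraph, tol: float = 1e-6,
                       max_iter: int = 100) -> float:
    """Convolutional Blondel vertex similarity between two subgraphs.

    Iterates ``T <- (B T A^t + B^t T A) / ||.||_F`` from an all-ones
    matrix, checking convergence only at even steps (the iteration is
    2-periodic in general), and returns the entry pairing the two
    generator nodes.  If both subgraphs are edgeless the update is
    identically zero: two single nodes count as identical (1.0), anything
    else as 0.0.
    """
    if max_iter < 2 or max_iter % 2:
        raise ValueError("max_iter must be an even integer >= 2")
    A = adjacency_matrix(sub_a).bits.astype(np.float64)
    B = adjacency_matrix(sub_b).bits.astype(np.float64)
    if not A.any() or not B.any():
        if len(sub_a.members) == 1 and len(sub_b.members) == 1:
            return 1.0
        logger.debug("edgeless subgraph in Blondel similarity; score 0")
        return 0.0
    T = np.ones((B.shape[0], A.shape[0]))
    prev_even = T
    for k in range(1, max_iter + 1):
        M = B @ T @ A.T + B.T @ T @ A
        norm = np.linalg.norm(M)
        if norm == 0.0:
            logger.debug("Blondel iteration collapsed to zero; score 0")
            return 0.0
        T = M / norm
        if k % 2 == 0:
            if np.linalg.norm(T - prev_even) < tol:
                break
            prev_even = T
    # generators sit first in each node order
    return float(np.clip(T[0, 0], 0.0, 1.0))


@dataclass
class StructMatrix:
    """Structure mapping matrix over the name-unmatched generator nodes."""

    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    values: np.ndarray
    row_index: dict[str, int] = field(init=False, repr=False)
    col_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
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


def pair_similarity(sub_a: Subgraph, sub_b: Subgraph, metric: str,
                    S: NameMatrix | None = None,
                    cfg: FusionConfig | None = None) -> float:
    """Similarity of one subgraph pair under the configured metric."""
    if metric in VECTOR_METRICS:
        return vectorial_similarity(sub_a, sub_b, metric)
    if metric == "constraint":
        if S is None or cfg is None:
            raise ValueError("constraint metric needs the name matrix "
                             "and configuration")
        return constraint_similarity(sub_a, sub_b, S, cfg.theta_N, cfg.W)
    if metric == "blondel":
        return blondel_similarity(sub_a, sub_b)
    raise ValueError(f"unknown metric: {metric!r}")


def _row_worker(args) -> np.ndarray:
    sub_a, subs_b, metric, S, cfg = args
    return np.array([pair_similarity(sub_a, sb, metric, S, cfg)
                     for sb in subs_b])


def build_structure_matrix(A: OntologyGraph, B: OntologyGraph,
                           unmatched_a: list[str], unmatched_b: list[str],
                           cfg: FusionConfig, S: NameMatrix | None = None,
                           threads: int = 1) -> StructMatrix:
    """Build ``T^AB`` over the name-unmatched classes of A and B.

    Entries are independent; with ``threads > 1`` rows are computed in a
    process pool with an order-preserving map, so results are identical to
    serial execution.
    """
    rows, cols = tuple(unmatched_a), tuple(unmatched_b)
    if not rows or not cols:
        logger.info("no unmatched classes on one side; structure matrix "
                    "is empty and merging degenerates to name-only")
        return StructMatrix(rows, cols,
                            np.zeros((len(rows), len(cols))))
    subs_a = [extract_subgraph(A, i, cfg.W) for i in rows]
    subs_b = [extract_subgraph(B, j, cfg.W) for j in cols]
    need_S = cfg.metric == "constraint"
    S_arg = S if need_S else None
    cfg_arg = cfg if need_S else None
    tasks = [(sa, subs_b, cfg.metric, S_arg, cfg_arg) for sa in subs_a]
    if threads > 1 and len(tasks) > 1:
        with ProcessPoolExecutor(max_workers=threads) as pool:
            out = list(pool.map(_row_worker, tasks, chunksize=8))
    else:
        out = [_row_worker(t) for t in tasks]
    values = np.vstack(out) if out else np.zeros((0, len(cols)))
    return StructMatrix(rows, cols, values)
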