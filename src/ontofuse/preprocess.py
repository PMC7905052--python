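"""Automatic ontology editor: scripted repair and label preconditioning.

Real ontologies arrive ill-formed — disconnected branches, duplicated
classes from parallel human/mouse annotation, decorative punctuation and
filler words ("cell", "cells", "human") that drown the string similarity.
An edit script, applied strictly in order before alignment, repairs them:

* ``select(pattern)`` — keep only classes whose label or a synonym contains
  the pattern (case-insensitive substring), with induced edges;
* ``deselect(pattern)`` — remove matching classes and incident edges;
* ``connect(parent, child)`` — add one relation between named classes;
* ``merge_classes(keep, absorb)`` — collapse two classes into the first,
  unioning synonyms and edges (the absorbed label becomes a synonym);
* ``normalize_labels(strip_chars, stop_words)`` — label preconditioning.

Script files use one operation per line, tab-separated:
``op<TAB>arg1<TAB>arg2``.  For ``normalize_labels`` arg1 is a contiguous
run of characters to strip and arg2 a comma-separated stop-word list.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .core import ClassNotFoundError, OntologyError, OntologyGraph

logger = logging.getLogger(__name__)

_OPS = ("select", "deselect", "connect", "merge_classes", "normalize_labels")


@dataclass(frozen=True)
class EditOp:
    op: str
    args: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise OntologyError(f"unknown edit operation: {self.op!r}")


EditScript = list[EditOp]


def normalize_label(s: str, strip_chars: list[str] | str = (),
                    stop_words: list[str] = ()) -> str:
    """Lowercase, strip punctuation characters, drop stop words.

    Strip characters are replaced by a single space (never deleted in
    place: "yolk-sac" becomes "yolk sac", not "yolksac") and stop words are
    removed as whole tokens only, so "cell" never bites into "cellular".
    Whitespace runs collapse; the result is trimmed.  Idempotent.
    """
    out = s.lower()
    for ch in strip_chars:
        out = out.replace(ch.lower(), " ")
    stops = {w.lower() for w in stop_words}
    tokens = [t for t in out.split() if t not in stops]
    return " ".join(tokens)


def parse_edit_script(text: str) -> EditScript:
    """Parse edit-script text (one tab-separated operation per line)."""
    script: EditScript = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        op, args = parts[0].strip(), tuple(p.strip() for p in parts[1:])
        try:
            script.append(EditOp(op, args))
        except OntologyError as exc:
            raise OntologyError(f"edit script line {lineno}: {exc}") from exc
    return script


def read_edit_script(path: str) -> EditScript:
    with open(path, encoding="utf-8") as fh:
        return parse_edit_script(fh.read())


def _matches(onto: OntologyGraph, pattern: str) -> set[str]:
    pat = pattern.lower()
    hits = set()
    for cls in onto.classes:
        if any(pat in name.lower() for name in cls.all_names()):
            hits.add(cls.id)
    return hits


def _find_by_name(onto: OntologyGraph, name: str) -> str:
    low = name.lower()
    for cls in onto.classes:
        if cls.label.lower() == low or cls.id == name:
            return cls.id
    raise ClassNotFoundError(f"no class named {name!r}")


def _keep_only(onto: OntologyGraph, keep: set[str]) -> OntologyGraph:
    out = OntologyGraph(name=onto.name)
    for cls in onto.classes:
        if cls.id in keep:
            out.add_class(cls.id, cls.label, list(cls.synonyms))
    for p, c in onto.edges:
        if p in keep and c in keep:
            out.add_edge(p, c)
    return out


def apply_edit_script(onto: OntologyGraph, script: EditScript
                      ) -> OntologyGraph:
    """Apply the edit operations in order; the input graph is not mutated."""
    cur = onto.copy()
    for op in script:
        if op.op == "select":
            hits = _matches(cur, op.args[0])
            if not hits:
                logger.warning("select(%r) matched no classes; "
                               "empty ontology returned", op.args[0])
            cur = _keep_only(cur, hits)
        elif op.op == "deselect":
            hits = _matches(cur, op.args[0])
            cur = _keep_only(cur, set(cur.class_ids) - hits)
        elif op.op == "connect":
            parent = _find_by_name(cur, op.args[0])
            child = _find_by_name(cur, op.args[1])
            cur.add_edge(parent, child)
        elif op.op == "merge_classes":
            keep = _find_by_name(cur, op.args[0])
            absorb = _find_by_name(cur, op.args[1])
            if keep == absorb:
                continue
            kc, ac = cur.get(keep), cur.get(absorb)
            for name in ac.all_names():
                if name != kc.label and name not in kc.synonyms:
                    kc.synonyms.append(name)
            in_edges = [(p, keep) for p in cur.parents(absorb)]
            out_edges = [(keep, c) for c in cur.children(absorb)]
            cur.remove_class(absorb)
            for p, c in in_edges + out_edges:
                if p != c and p in cur and c in cur:
                    cur.add_edge(p, c)  # self-loops/dups dropped by add_edge
        elif op.op == "normalize_labels":
            strip = op.args[0] if len(op.args) > 0 else ""
            stops = ([w.strip() for w in op.args[1].split(",") if w.strip()]
                     if len(op.args) > 1 else [])
            normalize_graph_labels(cur, list(strip), stops)
    return cur


def normalize_graph_labels(onto: OntologyGraph,
                           strip_chars: list[str] = (),
                           stop_words: list[str] = ()) -> None:
    """Normalise every label and synonym in place (empty results flagged)."""
    for cls in onto.classes:
        label = normalize_label(cls.label, strip_chars, stop_words)
        if not label:
            logger.warning("label of %r normalised to empty; keeping raw",
                           cls.id)
            label = cls.label.lower().strip()
        syns = []
        for s in cls.synonyms:
            ns = normalize_label(s, strip_chars, stop_words)
            if ns and ns != label and ns not in syns:
                syns.append(ns)
        cls.label, cls.synonyms = label, syns


_WS_RE = re.compile(r"\s+")
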