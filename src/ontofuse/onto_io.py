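"""Readers and writers for ontology files, plus run configuration.

Supported inputs: an OWL (RDF/XML) subset — class declarations with
``rdfs:label``, exact-synonym annotation properties and named-class
``rdfs:subClassOf`` axioms — and two-column parent/child tables, either as
the first sheet of an ODS spreadsheet or as a tabulated text file.  The
merged ontology is written back as RDF/XML that round-trips through
:func:`read_owl`.

The configuration file is a flat UTF-8 ``key = value`` dialect with ``#``
comments; lists are comma-separated.
"""

from __future__ import annotations

import csv
import logging
import math
import zipfile
from dataclasses import dataclass, field
from urllib.parse import quote

from lxml import etree
from rdflib import Graph as RdfGraph
from rdflib import Literal, Namespace, RDF, RDFS, URIRef
from rdflib.namespace import OWL
from rdflib.term import BNode

from .core import OntologyError, OntologyGraph

logger = logging.getLogger(__name__)

OBO_IN_OWL = Namespace("http://www.geneontology.org/formats/oboInOwl#")

#: annotation properties accepted as exact synonyms on read
DEFAULT_SYNONYM_PROPERTIES = (
    str(OBO_IN_OWL.hasExactSynonym),
    "http://www.ebi.ac.uk/efo/alternative_term",
    "http://purl.obolibrary.org/obo/IAO_0000118",
)

BASE_IRI = "http://ontofuse.local/onto#"

VALID_METRICS = ("cosine", "euclidean", "pearson", "constraint", "blondel")


@dataclass
class FusionConfig:
    """Alignment parameters: window length ``W`` and the threshold vector
    theta = {theta_N (name), theta_T (structure), theta_LN (local name)}.

    Defaults follow the optimised values for cell-ontology fusion:
    W=4, theta_N=0.85, theta_LN=0.7.  theta_T has no canonical default and
    is set to 0.7, aligned with theta_LN; override per run.
    """

    W: int = 4
    theta_N: float = 0.85
    theta_T: float = 0.7
    theta_LN: float = 0.7
    metric: str = "cosine"
    use_synonyms: bool = True
    stop_words: list[str] = field(default_factory=list)
    strip_chars: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.W < 1:
            raise OntologyError(f"W must be >= 1, got {self.W}")
        for key in ("theta_N", "theta_T", "theta_LN"):
            v = getattr(self, key)
            if not (isinstance(v, (int, float)) and math.isfinite(v)
                    and 0.0 <= v <= 1.0):
                raise OntologyError(
                    f"{key} must lie in [0, 1], got {v!r}")
        if self.metric not in VALID_METRICS:
            raise OntologyError(
                f"metric must be one of {VALID_METRICS}, got {self.metric!r}")

    def to_dict(self) -> dict:
        return {
            "W": self.W, "theta_N": self.theta_N, "theta_T": self.theta_T,
            "theta_LN": self.theta_LN, "metric": self.metric,
            "use_synonyms": self.use_synonyms,
            "stop_words": list(self.stop_words),
            "strip_chars": list(self.strip_chars),
        }


# ---------------------------------------------------------------------------
# OWL reading
# ---------------------------------------------------------------------------

def _fragment(iri: str) -> str:
    for sep in ("#", "/"):
        if sep in iri:
            frag = iri.rsplit(sep, 1)[1]
            if frag:
                return frag
    return iri


def read_owl(path: str, synonym_properties: tuple[str, ...] =
             DEFAULT_SYNONYM_PROPERTIES, name: str | None = None
             ) -> OntologyGraph:
    """Parse an OWL (RDF/XML) file into an :class:`OntologyGraph`.

    One class per ``owl:Class`` declaration; label from ``rdfs:label``
    (fallback: the IRI fragment); synonyms from the accepted exact-synonym
    annotation properties.  One edge per named-class subclass axiom,
    oriented parent->child.  Anonymous/restriction superclasses are ignored
    (counted and logged); classes referenced in a subclass axiom but never
    declared are auto-created with the IRI fragment as label.
    """
    rg = RdfGraph()
    try:
        rg.parse(path)
    except Exception as exc:  # rdflib raises parser-specific errors
        raise OntologyError(f"cannot parse OWL file {path!r}: {exc}") from exc

    onto = OntologyGraph(name=name if name is not None else str(path))
    syn_props = [URIRef(p) for p in synonym_properties]

    declared = [s for s in rg.subjects(RDF.type, OWL.Class)
                if isinstance(s, URIRef)]
    for subj in declared:
        if onto.has_class(str(subj)):
            continue
        label = next((str(o) for o in rg.objects(subj, RDFS.label)), None)
        if not label:
            label = _fragment(str(subj))
        synonyms = []
        for prop in syn_props:
            synonyms.extend(str(o) for o in rg.objects(subj, prop))
        onto.add_class(str(subj), label, synonyms)

    n_anonymous = 0
    for child, _, parent in rg.triples((None, RDFS.subClassOf, None)):
        if isinstance(parent, BNode) or not isinstance(child, URIRef):
            n_anonymous += 1
            continue
        for iri in (str(parent), str(child)):
            if not onto.has_class(iri):
                logger.warning("undeclared class %s auto-created", iri)
                onto.add_class(iri, _fragment(iri))
        onto.add_edge(str(parent), str(child))
    if n_anonymous:
        logger.info("ignored %d anonymous/restriction superclass axioms",
                    n_anonymous)
    return onto


# ---------------------------------------------------------------------------
# OWL writing
# ---------------------------------------------------------------------------

def _iri_for(cid: str) -> URIRef:
    if cid.startswith(("http://", "https://", "urn:")):
        return URIRef(cid)
    return URIRef(BASE_IRI + quote(cid, safe=""))


def write_owl(onto: OntologyGraph, path: str,
              provenance: dict[str, str] | None = None) -> None:
    """Serialise ``onto`` as RDF/XML.

    Class ids that are not already IRIs are minted deterministic IRIs under
    a fixed base namespace, so the output re-parses to a graph isomorphic
    to ``onto`` (same labels, synonyms and edges, ids renamed).  Optional
    ``provenance`` tags (class id -> source) are written as
    ``rdfs:comment`` annotations.
    """
    rg = RdfGraph()
    rg.bind("owl", OWL)
    rg.bind("oboInOwl", OBO_IN_OWL)
    for cls in onto.classes:
        iri = _iri_for(cls.id)
        rg.add((iri, RDF.type, OWL.Class))
        rg.add((iri, RDFS.label, Literal(cls.label)))
        for syn in cls.synonyms:
            rg.add((iri, OBO_IN_OWL.hasExactSynonym, Literal(syn)))
        if provenance and cls.id in provenance:
            rg.add((iri, RDFS.comment,
                    Literal(f"source:{provenance[cls.id]}")))
    for parent, child in onto.edges:
        rg.add((_iri_for(child), RDFS.subClassOf, _iri_for(parent)))
    rg.serialize(destination=path, format="xml")


# ---------------------------------------------------------------------------
# Two-column tables
# ---------------------------------------------------------------------------

_ODS_NS = {
    "table": "urn:oasis:names:tc:opendocument:xmlns:table:1.0",
    "text": "urn:oasis:names:tc:opendocument:xmlns:text:1.0",
}


def _read_ods_rows(path: str) -> list[list[str]]:
    """Minimal first-sheet reader for flat ODS spreadsheets.

    No installed library reads ODS, and only plain string cells of the
    first sheet are needed, so the content.xml table is walked directly.
    """
    with zipfile.ZipFile(path) as zf:
        content = zf.read("content.xml")
    root = etree.fromstring(content)
    tables = root.findall(".//table:table", _ODS_NS)
    if not tables:
        raise OntologyError(f"no sheet found in ODS file {path!r}")
    rows: list[list[str]] = []
    for row in tables[0].findall("table:table-row", _ODS_NS):
        cells: list[str] = []
        for cell in row.findall("table:table-cell", _ODS_NS):
            repeat = int(cell.get(
                f"{{{_ODS_NS['table']}}}number-columns-repeated", "1"))
            text = "".join(cell.itertext())
            # cap pathological trailing repeats on empty cells
            cells.extend([text] * min(repeat, 16))
        while cells and cells[-1] == "":
            cells.pop()
        if cells:
            rows.append(cells)
    return rows


def _read_tsv_rows(path: str) -> list[list[str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        return [row for row in csv.reader(fh, delimiter="\t") if row]


def read_two_column(path: str, dialect: str = "tsv",
                    synonym_separator: str = "|",
                    name: str | None = None) -> OntologyGraph:
    """Read a parent/child edge table into an :class:`OntologyGraph`.

    ``dialect`` is ``"tsv"`` (tab-separated text) or ``"ods-sheet"`` (first
    sheet of an ODS spreadsheet).  Classes are the union of both columns
    keyed by name (id = name); one edge per row, duplicates collapsed.  A
    cell may carry synonyms as ``label|syn1|syn2`` (separator
    configurable); rows with an empty cell are skipped with a warning.
    """
    if dialect == "ods-sheet":
        rows = _read_ods_rows(path)
    elif dialect == "tsv":
        rows = _read_tsv_rows(path)
    else:
        raise OntologyError(f"unknown two-column dialect: {dialect!r}")
    if not rows:
        raise OntologyError(f"no data rows in {path!r}")
    if max(len(r) for r in rows) < 2:
        raise OntologyError(
            f"{path!r} is single-column; two columns (parent, child) needed")

    onto = OntologyGraph(name=name if name is not None else str(path))

    def ensure(cell: str) -> str:
        parts = [p.strip() for p in cell.split(synonym_separator)]
        label, synonyms = parts[0], [p for p in parts[1:] if p]
        if not onto.has_class(label):
            onto.add_class(label, label, synonyms)
        elif synonyms:
            cls = onto.get(label)
            for s in synonyms:
                if s != cls.label and s not in cls.synonyms:
                    cls.synonyms.append(s)
        return label

    for i, row in enumerate(rows, start=1):
        cells = [c.strip() for c in row[:2]] + [""] * (2 - len(row))
        if not cells[0] or not cells[1]:
            logger.warning("row %d of %r has an empty cell; skipped", i, path)
            continue
        parent, child = ensure(cells[0]), ensure(cells[1])
        if parent == child:
            logger.warning("row %d of %r is a self-relation; skipped", i, path)
            continue
        onto.add_edge(parent, child)
    return onto


def write_two_column(onto: OntologyGraph, path: str) -> None:
    """Dump the edge list as a two-column TSV (debugging/interchange)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        for parent, child in onto.edges:
            w.writerow([parent, child])


# ---------------------------------------------------------------------------
# Configuration file
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "W": int,
    "theta_N": float,
    "theta_T": float,
    "theta_LN": float,
    "metric": str,
    "use_synonyms": bool,
    "stop_words": list,
    "strip_chars": list,
}

_TRUE = {"true", "yes", "on", "1"}
_FALSE = {"false", "no", "off", "0"}


def read_config(path: str) -> FusionConfig:
    """Parse a ``key = value`` configuration file into a FusionConfig.

    Unknown keys are warned about and ignored; missing keys take their
    defaults; out-of-range values raise with the key name and bounds.
    """
    values: dict[str, object] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise OntologyError(
                    f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, val = (part.strip() for part in line.partition("="))
            if key not in _CONFIG_KEYS:
                logger.warning("%s:%d: unknown config key %r ignored",
                               path, lineno, key)
                continue
            kind = _CONFIG_KEYS[key]
            try:
                if kind is int:
                    values[key] = int(val)
                elif kind is float:
                    values[key] = float(val)
                elif kind is bool:
                    low = val.lower()
                    if low in _TRUE:
                        values[key] = True
                    elif low in _FALSE:
                        values[key] = False
                    else:
                        raise ValueError(val)
                elif kind is list:
                    values[key] = [tok.strip() for tok in val.split(",")
                                   if tok.strip()]
                else:
                    values[key] = val
            except ValueError as exc:
                raise OntologyError(
                    f"{path}:{lineno}: bad value for {key}: {val!r}") from exc
    return FusionConfig(**values)
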