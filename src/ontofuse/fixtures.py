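"""Packaged demonstration ontologies.

A small synthetic ontology pair (~60 classes, generated by
:mod:`ontofuse.synthetic` at a fixed seed) with its ground-truth
reference alignment, shipped so the full pipeline can be demonstrated and
tested without external downloads.
"""

from __future__ import annotations

from importlib import resources

from .core import OntologyGraph
from .evaluate import Pair, read_reference
from .onto_io import read_owl

FIXTURE_SEED = 20210211
FIXTURE_N = 60


def _data_path(name: str):
    return resources.files("ontofuse") / "data" / name


def fixture_paths() -> dict[str, str]:
    return {key: str(_data_path(name)) for key, name in (
        ("a", "synthetic_fixture_a.owl"),
        ("b", "synthetic_fixture_b.owl"),
        ("truth", "synthetic_fixture_truth.tsv"),
    )}


def load_fixture_pair() -> tuple[OntologyGraph, OntologyGraph, set[Pair]]:
    """Load the packaged synthetic pair and its reference alignment.

    The reference pairs are expressed in the OWL IRIs the readers produce,
    so they compare directly with pipeline output.
    """
    paths = fixture_paths()
    return (read_owl(paths["a"], name="fixture-A"),
            read_owl(paths["b"], name="fixture-B"),
            read_reference(paths["truth"]))
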