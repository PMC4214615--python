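import pandas as pd
import pytest

from ontonet import (
    AnnotationStore,
    EntityTable,
    OntologyDAG,
    Term,
    annotations_from_pairs,
    propagate,
)


@pytest.fixture
def chain_dag() -> OntologyDAG:
    """A <- B <- C (C is the leaf; edges run child -> parent)."""
    terms = [Term("A", "alpha"), Term("B", "beta"), Term("C", "gamma")]
    return OntologyDAG(terms, [("B", "A"), ("C", "B")])


@pytest.fixture
def diamond_dag() -> OntologyDAG:
    """A <- {B, C} <- D."""
    terms = [Term(t, f"term {t}") for t in "ABCD"]
    return OntologyDAG(terms, [("B", "A"), ("C", "A"), ("D", "B"), ("D", "C")])


def make_entities(ids) -> EntityTable:
    return EntityTable(
        pd.DataFrame(
            {"id": list(ids), "symbol": [e.upper() for e in ids],
             "description": ["" for _ in ids]}
        )
    )


def make_store(pairs, entity_ids) -> AnnotationStore:
    return annotations_from_pairs(pairs, list(entity_ids))


def make_propagated(pairs, entity_ids, dag) -> AnnotationStore:
    return propagate(make_store(pairs, entity_ids), dag)


@pytest.fixture
def tsv_writer(tmp_path):
    """Write a TSV file under tmp_path and return its path."""

    def write(name: str, frame: pd.DataFrame):
        path = tmp_path / name
        frame.to_csv(path, sep="\t", index=False)
        return path

    return write
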