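"""Graph export, packaged toy datasets, and run configuration.

All graph-like results — ontology sub-DAGs, similarity networks, contact
networks — export to three plain-text formats: GraphML (via networkx), DOT
(a minimal writer, since no DOT library is pre-installed alongside the
package) and a weighted edge-list TSV whose export→import round trip is
exact.  A small registry of generated toy datasets stands in for a
downloadable data backend; every registered object satisfies its type's
invariants.  ``RunConfig`` serialises a CLI run (flags, seed, worker
count) to YAML/JSON and back, and every CLI command writes a machine-
readable manifest so identical manifests imply identical outputs.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .ontology import (
    AnnotationStore,
    EntityTable,
    OntologyDAG,
    Term,
    annotations_from_pairs,
)
from .rwr import ContactNetwork
from .similarity import SimilarityNetwork

logger = logging.getLogger("ontonet")

EXPORT_FORMATS = ("graphml", "dot", "edgelist")


class ConfigError(ValueError):
    pass


def setup_logging(level: str = "INFO") -> None:
    """Route package logs to stderr (data goes to files only)."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())


# ---------------------------------------------------------------------------
# graph export
# ---------------------------------------------------------------------------


def _as_networkx(graph) -> nx.Graph | nx.DiGraph:
    if isinstance(graph, (nx.Graph, nx.DiGraph)):
        return graph
    if isinstance(graph, (OntologyDAG, SimilarityNetwork, ContactNetwork)):
        return graph.to_networkx()
    raise ConfigError(f"cannot export object of type {type(graph).__name__}")


def _write_dot(g: nx.Graph | nx.DiGraph, path: Path) -> None:
    directed = g.is_directed()
    lines = ["digraph G {" if directed else "graph G {"]
    arrow = "->" if directed else "--"
    for n, data in g.nodes(data=True):
        attrs = ", ".join(f'{k}="{v}"' for k, v in sorted(data.items()))
        lines.append(f'  "{n}" [{attrs}];' if attrs else f'  "{n}";')
    for u, v, data in g.edges(data=True):
        attrs = ", ".join(f'{k}="{v_}"' for k, v_ in sorted(data.items()))
        lines.append(f'  "{u}" {arrow} "{v}" [{attrs}];' if attrs else f'  "{u}" {arrow} "{v}";')
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")


def _write_edgelist(g: nx.Graph | nx.DiGraph, path: Path) -> None:
    rows = [
        # repr() is the shortest round-trip float representation
        {"source": u, "target": v, "weight": repr(float(data.get("weight", 1.0)))}
        for u, v, data in g.edges(data=True)
    ]
    frame = pd.DataFrame(rows, columns=["source", "target", "weight"])
    frame = frame.sort_values(["source", "target"]).reset_index(drop=True)
    with open(path, "w") as fh:
        fh.write(f"# nodes\t{','.join(str(n) for n in g.nodes)}\n")
        fh.write(f"# directed\t{int(g.is_directed())}\n")
        frame.to_csv(fh, sep="\t", index=False)


def export_graph(graph, path: str | Path, fmt: str = "graphml") -> Path:
    """Export a DAG / similarity network / contact network to a text format.

    Node attributes (name, p-values, IC) and edge weights are preserved in
    GraphML and DOT; the edge-list TSV keeps node list and weights so that
    :func:`import_edgelist` reproduces the graph exactly.
    """
    g = _as_networkx(graph)
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "dot":
        _write_dot(g, path)
    elif fmt == "edgelist":
        _write_edgelist(g, path)
    else:
        raise ConfigError(f"unknown export format {fmt!r}; choose from {EXPORT_FORMATS}")
    return path


def import_edgelist(path: str | Path) -> nx.Graph | nx.DiGraph:
    """Read a graph written by ``export_graph(..., fmt='edgelist')``."""
    path = Path(path)
    with open(path) as fh:
        header1 = fh.readline().rstrip("\n").split("\t")
        header2 = fh.readline().rstrip("\n").split("\t")
        if header1[0] != "# nodes" or header2[0] != "# directed":
            raise ConfigError(f"{path} is not an ontonet edge list")
        nodes = header1[1].split(",") if len(header1) > 1 and header1[1] else []
        directed = bool(int(header2[1]))
        # weight stays textual: Python's float() is correctly rounded,
        # keeping the export->import round trip bit-exact
        frame = pd.read_csv(fh, sep="\t", dtype={"source": str, "target": str, "weight": str})
    g = nx.DiGraph() if directed else nx.Graph()
    g.add_nodes_from(nodes)
    for row in frame.itertuples(index=False):
        g.add_edge(row.source, row.target, weight=float(row.weight))
    return g


def read_network(path: str | Path) -> SimilarityNetwork:
    """Load a similarity network from an edge-list TSV or GraphML file."""
    path = Path(path)
    if path.suffix == ".graphml":
        g = nx.read_graphml(path)
        g = nx.Graph(g)
    else:
        g = import_edgelist(path)
        if g.is_directed():
            g = g.to_undirected()
    return SimilarityNetwork(g, {"source": str(path)})


# ---------------------------------------------------------------------------
# packaged toy datasets
# ---------------------------------------------------------------------------


def _toy_chain() -> OntologyDAG:
    terms = [Term("A", "alpha"), Term("B", "beta"), Term("C", "gamma", alt_ids=frozenset({"C_alt"}))]
    return OntologyDAG(terms, [("B", "A"), ("C", "B")])


def _toy_diamond() -> OntologyDAG:
    terms = [Term(t, f"term {t}") for t in "ABCD"]
    return OntologyDAG(terms, [("B", "A"), ("C", "A"), ("D", "B"), ("D", "C")])


def _toy_entities() -> EntityTable:
    ids = [f"d{i}" for i in range(1, 6)]
    return EntityTable(
        pd.DataFrame({"id": ids, "symbol": [e.upper() for e in ids],
                      "description": [f"toy entity {e}" for e in ids]})
    )


def _toy_annotations() -> AnnotationStore:
    pairs = [("d1", "C"), ("d2", "B"), ("d3", "C"), ("d4", "A"), ("d5", "B")]
    return annotations_from_pairs(pairs, [f"d{i}" for i in range(1, 6)])


_REGISTRY: dict[str, Callable] = {
    "toy_chain": _toy_chain,
    "toy_diamond": _toy_diamond,
    "toy_entities": _toy_entities,
    "toy_annotations": _toy_annotations,
}


def list_registered() -> list[str]:
    return sorted(_REGISTRY)


def load_registered(name: str):
    """Return a packaged toy dataset by name.

    Objects are rebuilt on every call, so callers may mutate them freely.
    """
    if name not in _REGISTRY:
        raise KeyError(f"unknown dataset {name!r}; available: {', '.join(list_registered())}")
    return _REGISTRY[name]()


# ---------------------------------------------------------------------------
# run configuration and manifests
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Serialisable record of one CLI run."""

    command: str = ""
    params: dict = field(default_factory=dict)
    seed: int = 0
    workers: int = 1
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "params": dict(sorted(self.params.items())),
            "seed": self.seed,
            "workers": self.workers,
            "log_level": self.log_level,
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=True)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        data = (
            json.loads(path.read_text())
            if path.suffix == ".json"
            else yaml.safe_load(path.read_text())
        )
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls(
            command=data.get("command", ""),
            params=dict(data.get("params", {})),
            seed=int(data.get("seed", 0)),
            workers=int(data.get("workers", 1)),
            log_level=str(data.get("log_level", "INFO")),
        )


def write_manifest(config: RunConfig, out_path: str | Path) -> Path:
    """Write the machine-readable run manifest next to an output file."""
    import numpy
    import scipy

    manifest = {
        "config": config.to_dict(),
        "versions": {
            "ontonet": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "networkx": nx.__version__,
            "pandas": pd.__version__,
        },
    }
    path = Path(str(out_path) + ".manifest.json")
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
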