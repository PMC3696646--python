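"""GO-based classification of proteins as extracellular / cell surface / other.

A protein is classified *extracellular* when annotated with GO:0005576
(extracellular region) or GO:0005615 (extracellular space), and *cell surface*
when annotated with GO:0005886 (plasma membrane) or GO:0009986 (cell surface)
but with neither extracellular term — extracellular takes precedence when both
match. By default only direct annotations are matched, reflecting retrieval
from a curated association set; optionally each protein's term set is first
closed over is_a/part_of ancestors in a supplied ontology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "EXTRACELLULAR_TERMS",
    "CELL_SURFACE_TERMS",
    "Ontology",
    "ClassifiedProtein",
    "classify",
    "annotation_map",
]

logger = logging.getLogger(__name__)

EXTRACELLULAR_TERMS = frozenset({"GO:0005576", "GO:0005615"})
CELL_SURFACE_TERMS = frozenset({"GO:0005886", "GO:0009986"})


class Ontology:
    """A lightweight acyclic is_a/part_of parent graph over GO terms."""

    def __init__(self, parents: Mapping[str, set[str]], names: Mapping[str, str] | None = None):
        self._graph = nx.DiGraph()
        self._graph.add_nodes_from(parents)
        for child, ps in parents.items():
            for p in ps:
                self._graph.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(self._graph):
            cycle = nx.find_cycle(self._graph)
            raise ValueError(f"ontology parent graph is cyclic: {cycle}")
        self.names = dict(names or {})
        self._ancestors = lru_cache(maxsize=None)(self._ancestors_uncached)

    def __contains__(self, term: str) -> bool:
        return term in self._graph

    def _ancestors_uncached(self, term: str) -> frozenset[str]:
        return frozenset(nx.descendants(self._graph, term))  # edges point child -> parent

    def ancestors(self, term: str) -> frozenset[str]:
        """All transitive parents of ``term`` (not including the term itself)."""
        if term not in self._graph:
            raise KeyError(term)
        return self._ancestors(term)


def annotation_map(annotations: pd.DataFrame) -> dict[str, set[str]]:
    """Collapse an annotation table to symbol -> set of GO ids."""
    out: dict[str, set[str]] = {}
    for row in annotations.itertuples(index=False):
        out.setdefault(row.gene_symbol, set()).add(row.go_id)
    return out


@dataclass(frozen=True)
class ClassifiedProtein:
    symbol: str
    go_terms: frozenset[str]
    cls: str  # extracellular | cell_surface | other


def classify(
    symbols: Iterable[str],
    annotations: pd.DataFrame | Mapping[str, set[str]],
    ontology: Ontology | None = None,
    propagate: bool = False,
) -> list[ClassifiedProtein]:
    """Classify each symbol from its GO annotations.

    With ``propagate=True`` (requires ``ontology``) each protein's annotation
    set is closed over ancestors before matching, so e.g. a term nested under
    extracellular region also triggers the extracellular class; propagation
    can only add classifications, never remove them. Annotated terms unknown
    to the ontology are ignored for propagation with a warning (their direct
    match still counts).
    """
    if propagate and ontology is None:
        raise ValueError("propagate=True requires an ontology")
    ann = annotations if isinstance(annotations, Mapping) else annotation_map(annotations)

    out: list[ClassifiedProtein] = []
    warned: set[str] = set()
    for symbol in symbols:
        terms = set(ann.get(symbol, set()))
        effective = set(terms)
        if propagate and ontology is not None:
            for t in terms:
                if t in ontology:
                    effective |= ontology.ancestors(t)
                elif t not in warned:
                    logger.warning("GO id %s not in ontology; skipped for propagation", t)
                    warned.add(t)
        if effective & EXTRACELLULAR_TERMS:
            cls = "extracellular"
        elif effective & CELL_SURFACE_TERMS:
            cls = "cell_surface"
        else:
            cls = "other"
        out.append(ClassifiedProtein(symbol, frozenset(terms), cls))
    return out


def class_filter(classified: Iterable[ClassifiedProtein], classes: set[str]) -> frozenset[str]:
    """Symbols whose class is in ``classes`` (e.g. {extracellular, cell_surface})."""
    return frozenset(c.symbol for c in classified if c.cls in classes)
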