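"""OBO ontology parsing, hierarchy distances, concept vectors and Wang similarity.

An ontology here is a directed acyclic ``is_a`` graph of concepts.  Each
concept carries one preferred label and zero or more synonyms.  Concepts are
embedded into an N-dimensional space (N = number of concepts) where the
vector of a concept has weight ``decay ** d`` on itself (d = 0) and on each
of its ancestors (d = minimum number of is_a steps), and 0 elsewhere.
"""

from __future__ import annotations

import re
from collections import deque
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping

import networkx as nx
import numpy as np

from conceptnorm.errors import FormatError, OntologyError

__all__ = [
    "Concept",
    "Ontology",
    "ConceptVectorSpace",
    "parse_obo",
    "ancestor_distances",
    "build_concept_vectors",
    "wang_similarity",
]

# Default edge contribution for Wang similarity; the value attached to
# is_a edges in Wang et al.'s original definition.
DEFAULT_EDGE_CONTRIBUTION = 0.8


@dataclass
class Concept:
    """One ontology term: identifier, labels and is_a parents."""

    id: str
    preferred_label: str
    synonyms: list[str] = field(default_factory=list)
    parents: set[str] = field(default_factory=set)

    def labels(self) -> list[str]:
        """Preferred label followed by synonyms."""
        return [self.preferred_label, *self.synonyms]


class Ontology:
    """A set of concepts forming an acyclic is_a hierarchy.

    Parameters
    ----------
    concepts
        Iterable of :class:`Concept`.  Parent references must resolve and the
        graph must be acyclic; violations raise :class:`OntologyError`.
    alt_ids
        Optional mapping of alternative identifiers to canonical concept ids
        (from OBO ``alt_id`` lines), used by :meth:`resolve`.
    """

    def __init__(
        self,
        concepts: Iterable[Concept],
        alt_ids: Mapping[str, str] | None = None,
    ) -> None:
        self.concepts: dict[str, Concept] = {}
        for c in concepts:
            if c.id in self.concepts:
                raise OntologyError(f"duplicate concept id {c.id!r}")
            if not c.preferred_label:
                raise OntologyError(f"concept {c.id!r} has an empty label")
            self.concepts[c.id] = c
        self.alt_ids: dict[str, str] = dict(alt_ids or {})

        for c in self.concepts.values():
            for p in c.parents:
                if p not in self.concepts:
                    raise OntologyError(
                        f"concept {c.id!r} has is_a to unknown id {p!r}"
                    )

        graph = nx.DiGraph()
        graph.add_nodes_from(self.concepts)
        for c in self.concepts.values():
            for p in c.parents:
                graph.add_edge(c.id, p)  # child -> parent
        try:
            cycle = nx.find_cycle(graph)
        except nx.NetworkXNoCycle:
            pass
        else:
            path = " -> ".join(edge[0] for edge in cycle)
            raise OntologyError(f"cycle in is_a graph: {path}")
        self._graph = graph
        self.roots: set[str] = {
            cid for cid, c in self.concepts.items() if not c.parents
        }
        if self.concepts and not self.roots:
            raise OntologyError("ontology has no root concept")

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def __iter__(self) -> Iterator[str]:
        return iter(self.concepts)

    def resolve(self, concept_id: str) -> str:
        """Map an id (possibly an alt_id) to its canonical concept id."""
        if concept_id in self.concepts:
            return concept_id
        if concept_id in self.alt_ids:
            return self.alt_ids[concept_id]
        raise OntologyError(f"unknown concept id {concept_id!r}")

    def children(self, concept_id: str) -> set[str]:
        """Direct children (concepts having ``concept_id`` as a parent)."""
        return set(self._graph.predecessors(concept_id))

    def ancestors(self, concept_id: str) -> set[str]:
        """All proper ancestors reachable over is_a edges."""
        if concept_id not in self.concepts:
            raise OntologyError(f"unknown concept id {concept_id!r}")
        return set(nx.descendants(self._graph, concept_id))

    def descendants(self, concept_id: str) -> set[str]:
        """All proper descendants."""
        if concept_id not in self.concepts:
            raise OntologyError(f"unknown concept id {concept_id!r}")
        return set(nx.ancestors(self._graph, concept_id))


# ---------------------------------------------------------------------------
# OBO parsing

_SYNONYM_RE = re.compile(r'^"(.*?)"')


def parse_obo(stream: IO[str] | str) -> Ontology:
    """Parse an OBO 1.2/1.4 flat file into an :class:`Ontology`.

    Reads ``[Term]`` stanzas with ``id``, ``name``, ``synonym``, ``is_a``,
    ``alt_id`` and ``is_obsolete`` fields.  Obsolete terms are dropped; their
    ids never enter the graph.  ``alt_id`` lines are recorded so annotation
    readers can map stale identifiers to the canonical concept.

    Parameters
    ----------
    stream
        A text file object or the OBO document as a string.

    Raises
    ------
    FormatError
        On a stanza without ``id`` or ``name``.
    OntologyError
        On a cyclic is_a graph or an is_a target that does not exist.
    """
    if isinstance(stream, str):
        lines: Iterable[str] = stream.splitlines()
    else:
        lines = stream

    concepts: list[Concept] = []
    alt_ids: dict[str, str] = {}
    stanza: dict[str, list[str]] | None = None
    stanza_type = ""

    def flush() -> None:
        if stanza is None or stanza_type != "Term":
            return
        if stanza.get("is_obsolete", ["false"])[0].startswith("true"):
            return
        if "id" not in stanza:
            raise FormatError("[Term] stanza without an id")
        cid = stanza["id"][0]
        if "name" not in stanza:
            raise FormatError(f"term {cid!r} has no name")
        synonyms = []
        for raw in stanza.get("synonym", []):
            m = _SYNONYM_RE.match(raw)
            if m:
                synonyms.append(m.group(1))
        parents = {v.split("!")[0].strip() for v in stanza.get("is_a", [])}
        concepts.append(
            Concept(
                id=cid,
                preferred_label=stanza["name"][0],
                synonyms=synonyms,
                parents=parents,
            )
        )
        for alt in stanza.get("alt_id", []):
            alt_ids[alt] = cid

    for raw_line in lines:
        line = raw_line.strip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("["):
            flush()
            stanza_type = line.strip("[]")
            stanza = {}
            continue
        if stanza is None:
            continue  # header clauses (format-version etc.)
        key, _, value = line.partition(":")
        stanza.setdefault(key.strip(), []).append(value.strip())
    flush()

    return Ontology(concepts, alt_ids=alt_ids)


# ---------------------------------------------------------------------------
# Hierarchy distances and concept vectors


def ancestor_distances(ontology: Ontology, concept: str) -> dict[str, int]:
    """Minimum is_a step counts from ``concept`` to itself and each ancestor.

    The concept itself is at distance 0.  On a DAG with several upward paths
    to the same ancestor, the minimum step count is used.
    """
    if concept not in ontology:
        raise OntologyError(f"unknown concept id {concept!r}")
    dist = {concept: 0}
    queue = deque([concept])
    while queue:
        cur = queue.popleft()
        for parent in ontology.concepts[cur].parents:
            if parent not in dist:
                dist[parent] = dist[cur] + 1
                queue.append(parent)
    return dist


@dataclass
class ConceptVectorSpace:
    """Hierarchy-encoded concept vectors with a fixed concept/dimension order.

    ``vectors[i]`` is the vector of concept ``concept_ids[i]``; its non-zero
    dimensions are exactly the concept itself (weight 1) and its ancestors
    (weight ``decay ** distance``).
    """

    concept_ids: list[str]
    vectors: np.ndarray  # (N, N) float64
    decay: float

    def __post_init__(self) -> None:
        self.index: dict[str, int] = {
            cid: i for i, cid in enumerate(self.concept_ids)
        }

    @property
    def n_concepts(self) -> int:
        return len(self.concept_ids)

    def vector(self, concept_id: str) -> np.ndarray:
        return self.vectors[self.index[concept_id]]


def build_concept_vectors(
    ontology: Ontology, decay: float
) -> ConceptVectorSpace:
    """Build decay-weighted concept vectors for every concept.

    The weight of concept i on dimension j is ``decay ** d(i, j)`` where d is
    the minimum number of is_a steps from i up to ancestor j (0 for i itself,
    with ``0 ** 0 == 1``); dimensions outside the ancestor closure are 0.
    ``decay=0`` therefore yields the identity matrix and ``decay=1`` gives
    every ancestor the same weight as the concept.
    """
    if not 0.0 <= decay <= 1.0:
        raise ValueError(f"decay must lie in [0, 1], got {decay}")
    concept_ids = sorted(ontology.concepts)
    index = {cid: i for i, cid in enumerate(concept_ids)}
    n = len(concept_ids)
    vectors = np.zeros((n, n), dtype=np.float64)
    for cid in concept_ids:
        i = index[cid]
        for anc, d in ancestor_distances(ontology, cid).items():
            vectors[i, index[anc]] = 1.0 if d == 0 else decay**d
    return ConceptVectorSpace(concept_ids, vectors, decay)


# ---------------------------------------------------------------------------
# Wang semantic similarity


def _s_values(
    ontology: Ontology, concept: str, edge_contribution: float
) -> dict[str, float]:
    """S-value of every term in the ancestor closure of ``concept``.

    S(concept) = 1; S propagates upward, multiplied by the edge contribution
    at each is_a step, keeping the maximum over all downward paths.
    """
    dist = ancestor_distances(ontology, concept)
    s = {concept: 1.0}
    # Processing closure members in order of increasing distance guarantees
    # every contributing child is finalized before its parents.
    for cur in sorted(dist, key=dist.get):
        for parent in ontology.concepts[cur].parents:
            cand = s[cur] * edge_contribution
            if cand > s.get(parent, 0.0):
                s[parent] = cand
    return s


def wang_similarity(
    ontology: Ontology,
    a: str,
    b: str,
    edge_contribution: float = DEFAULT_EDGE_CONTRIBUTION,
) -> float:
    """Wang et al.'s hierarchy-aware semantic similarity between two concepts.

    Equals 1 when ``a == b``, is symmetric, and decreases toward 0 as the
    concepts grow farther apart in the is_a graph.

    Parameters
    ----------
    edge_contribution
        Per-edge decay of the S-value, in (0, 1).
    """
    if not 0.0 < edge_contribution < 1.0:
        raise ValueError(
            f"edge_contribution must lie in (0, 1), got {edge_contribution}"
        )
    s_a = _s_values(ontology, a, edge_contribution)
    if a == b:
        return 1.0  # definitionally exact; avoids float summation noise
    s_b = _s_values(ontology, b, edge_contribution)
    shared = set(s_a) & set(s_b)
    numer = sum(s_a[t] + s_b[t] for t in shared)
    denom = sum(s_a.values()) + sum(s_b.values())
    return numer / denom
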