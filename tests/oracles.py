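"""Independent brute-force oracles used to validate the package.

Everything here is deliberately written as straight-line, enumeration-based
code with no reuse of the package's internals beyond the plain data types,
so the two routes stay independent.
"""

from __future__ import annotations

import numpy as np

from conceptnorm.ontology import Concept, Ontology


def random_dag_ontology(rng: np.random.Generator, n_concepts: int, p_extra: float = 0.15) -> Ontology:
    """Random DAG: node i may point to any earlier node, guaranteeing acyclicity."""
    concepts = []
    ids = [f"T:{i:03d}" for i in range(n_concepts)]
    for i, cid in enumerate(ids):
        parents: set[str] = set()
        if i > 0:
            parents.add(ids[int(rng.integers(i))])
            for j in range(i):
                if rng.random() < p_extra / max(i, 1):
                    parents.add(ids[j])
        concepts.append(Concept(id=cid, preferred_label=f"label {i}", parents=parents))
    return Ontology(concepts)


def random_tree_ontology(rng: np.random.Generator, n_concepts: int) -> Ontology:
    concepts = []
    ids = [f"T:{i:03d}" for i in range(n_concepts)]
    for i, cid in enumerate(ids):
        parents = {ids[int(rng.integers(i))]} if i > 0 else set()
        concepts.append(Concept(id=cid, preferred_label=f"label {i}", parents=parents))
    return Ontology(concepts)


def enumerate_upward_paths(ontology: Ontology, start: str) -> list[list[str]]:
    """Every upward is_a path from ``start`` (inclusive) to any ancestor."""
    paths = [[start]]
    out = [[start]]
    while paths:
        path = paths.pop()
        for parent in ontology.concepts[path[-1]].parents:
            extended = path + [parent]
            out.append(extended)
            paths.append(extended)
    return out


def brute_min_distances(ontology: Ontology, start: str) -> dict[str, int]:
    """Min upward step count per reachable ancestor, by full path enumeration."""
    best: dict[str, int] = {}
    for path in enumerate_upward_paths(ontology, start):
        node, steps = path[-1], len(path) - 1
        if node not in best or steps < best[node]:
            best[node] = steps
    return best


def brute_concept_vectors(ontology: Ontology, decay: float) -> tuple[list[str], np.ndarray]:
    """decay^(min path length) per (concept, ancestor) pair, 0^0 := 1."""
    ids = sorted(ontology.concepts)
    index = {cid: i for i, cid in enumerate(ids)}
    vectors = np.zeros((len(ids), len(ids)))
    for cid in ids:
        for anc, d in brute_min_distances(ontology, cid).items():
            vectors[index[cid], index[anc]] = 1.0 if d == 0 else decay**d
    return ids, vectors


def brute_wang(ontology: Ontology, a: str, b: str, w: float) -> float:
    """Wang similarity via exhaustive upward-path S-value maximization."""

    def s_values(concept: str) -> dict[str, float]:
        s: dict[str, float] = {}
        for path in enumerate_upward_paths(ontology, concept):
            node, steps = path[-1], len(path) - 1
            value = w**steps
            if value > s.get(node, 0.0):
                s[node] = value
        return s

    s_a, s_b = s_values(a), s_values(b)
    shared = set(s_a) & set(s_b)
    return sum(s_a[t] + s_b[t] for t in shared) / (
        sum(s_a.values()) + sum(s_b.values())
    )


# ---------------------------------------------------------------------------
# straight-line forward passes


def loop_slfnn(x: np.ndarray, mask: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-example loops: masked token average then dense layer."""
    n_out = W.shape[0]
    out = np.zeros((x.shape[0], n_out))
    for i in range(x.shape[0]):
        real = [x[i, t] for t in range(x.shape[1]) if mask[i, t]]
        mean = np.mean(real, axis=0) if real else np.zeros(x.shape[2])
        for k in range(n_out):
            out[i, k] = float(np.dot(W[k], mean)) + b[k]
    return out


def loop_cnn(
    x: np.ndarray,
    mask: np.ndarray,
    F: np.ndarray,
    c: np.ndarray,
    filter_size: int,
    slope: float,
) -> np.ndarray:
    """Per-example loops: convolution, masked max-pool, leaky ReLU."""
    n_filters = F.shape[0]
    out = np.zeros((x.shape[0], n_filters))
    for i in range(x.shape[0]):
        n_tokens = int(mask[i].sum())
        positions = list(range(max(n_tokens - filter_size + 1, 0))) or [0]
        for k in range(n_filters):
            scores = []
            for t in positions:
                acc = c[k]
                for f in range(filter_size):
                    acc += float(np.dot(F[k, f], x[i, t + f]))
                scores.append(acc)
            z = max(scores)
            out[i, k] = z if z > 0 else slope * z
    return out


def loop_cnorm(x, mask, W, b, F, c, filter_size, slope) -> np.ndarray:
    o1 = loop_slfnn(x, mask, W, b)
    o2 = loop_cnn(x, mask, F, c, filter_size, slope)
    return 0.5 * (o1 + o2)
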