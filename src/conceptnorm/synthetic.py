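"""Download-free synthetic fixtures: ontologies, embeddings and corpora.

The generators emulate the structure of a few-shot normalization benchmark:
a hierarchy of concepts with distinctive vocabularies and hierarchical
lexical overlap, word embeddings clustered by concept (so normalization is
learnable by construction), and standoff-annotated documents with a
controllable fraction of zero-shot concepts that never occur in the
training split.

Everything is deterministic for a fixed seed and writes the same OBO /
word2vec-text / standoff formats the real pipeline reads.
"""

from __future__ import annotations

import json
import string
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from conceptnorm.ontology import Concept, Ontology
from conceptnorm.text import EmbeddingTable

__all__ = [
    "SyntheticSpec",
    "StandoffDoc",
    "SyntheticCorpus",
    "generate_ontology",
    "generate_embeddings",
    "generate_corpus",
    "write_obo",
]

VARIATION_OPS = (
    "synonym_swap",
    "suffix_inflection",
    "token_dropout",
    "modifier_insertion",
)

_MODIFIERS = ("fresh", "small", "novel", "raw", "wild", "local")
_SUFFIXES = ("s", "ic", "al")

_SENTENCE_PREFIX = "Samples were isolated from "
_SENTENCE_SUFFIX = " during the survey. "


@dataclass
class SyntheticSpec:
    """Knobs of the fixture generator."""

    n_concepts: int = 50
    branching: float = 2.5
    vocab_per_concept: int = 2
    embedding_dim: int = 20
    n_mentions: int = 200
    examples_per_concept_dist: tuple[float, float] = (2.0, 1.0)
    zero_shot_fraction: float = 0.0
    variation_ops: tuple[str, ...] = ()
    variation_rate: float = 0.5
    parent_token_prob: float = 0.25
    embedding_noise: float = 0.1
    mentions_per_document: int = 10
    entity_type: str = "Habitat"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_concepts < 1 or self.vocab_per_concept < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.zero_shot_fraction <= 1.0:
            raise ValueError("zero_shot_fraction must lie in [0, 1]")
        unknown = set(self.variation_ops) - set(VARIATION_OPS)
        if unknown:
            raise ValueError(f"unknown variation ops: {sorted(unknown)}")


@dataclass
class StandoffDoc:
    """One document with its .txt / .a1 / .a2 contents."""

    document_id: str
    text: str
    a1: str
    a2: str

    def write(self, directory: Path) -> None:
        directory.mkdir(parents=True, exist_ok=True)
        (directory / f"{self.document_id}.txt").write_text(self.text, encoding="utf-8")
        (directory / f"{self.document_id}.a1").write_text(self.a1, encoding="utf-8")
        (directory / f"{self.document_id}.a2").write_text(self.a2, encoding="utf-8")


@dataclass
class SyntheticCorpus:
    """Train/dev/test standoff splits plus the sampled zero-shot concept set."""

    splits: dict[str, list[StandoffDoc]]
    zero_shot_concepts: set[str]
    spec: SyntheticSpec

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        for split, docs in self.splits.items():
            for doc in docs:
                doc.write(directory / split)
        manifest = {
            "spec": {**asdict(self.spec)},
            "zero_shot_concepts": sorted(self.zero_shot_concepts),
            "n_documents": {s: len(d) for s, d in self.splits.items()},
        }
        (directory / "manifest.json").write_text(
            json.dumps(manifest, indent=2), encoding="utf-8"
        )


def _make_words(rng: np.random.Generator, count: int, used: set[str]) -> list[str]:
    words = []
    letters = np.array(list(string.ascii_lowercase))
    while len(words) < count:
        length = int(rng.integers(5, 9))
        word = "".join(rng.choice(letters, size=length))
        if word not in used:
            used.add(word)
            words.append(word)
    return words


def generate_ontology(spec: SyntheticSpec) -> Ontology:
    """Random single-root is_a tree with hierarchically overlapping labels.

    Each concept owns ``vocab_per_concept`` distinctive tokens; its label is
    those tokens, prefixed half the time by the parent's head token to give
    parent/child lexical overlap.  Concepts carry 0-2 synonyms built from
    permutations of their own tokens.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_concepts
    width = max(4, len(str(n)))
    ids = [f"SYN:{i:0{width}d}" for i in range(n)]

    parents: dict[str, set[str]] = {ids[0]: set()}
    # level-wise tree growth: each parent takes ~Poisson(branching) children
    frontier = [ids[0]]
    next_child = 1
    while next_child < n:
        new_frontier = []
        for parent in frontier:
            if next_child >= n:
                break
            k = max(1, int(rng.poisson(spec.branching)))
            for _ in range(k):
                if next_child >= n:
                    break
                cid = ids[next_child]
                parents[cid] = {parent}
                new_frontier.append(cid)
                next_child += 1
        frontier = new_frontier or [ids[0]]

    used: set[str] = set()
    vocab = {cid: _make_words(rng, spec.vocab_per_concept, used) for cid in ids}

    concepts = []
    for cid in ids:
        own = vocab[cid]
        tokens = list(own)
        parent_ids = parents[cid]
        if parent_ids and rng.random() < spec.parent_token_prob:
            head = vocab[next(iter(parent_ids))][0]
            tokens = [head, *tokens]
        label = " ".join(tokens)
        synonyms = []
        n_syn = int(rng.integers(0, 3))
        for _ in range(n_syn):
            perm = list(rng.permutation(own))
            syn = " ".join(perm)
            if syn != label and syn not in synonyms:
                synonyms.append(syn)
        concepts.append(
            Concept(id=cid, preferred_label=label, synonyms=synonyms, parents=set(parent_ids))
        )
    return Ontology(concepts)


def _concept_vocab(ontology: Ontology) -> dict[str, list[str]]:
    """Tokens grouped by the concept that introduced them (first occurrence)."""
    owner: dict[str, str] = {}
    for cid in sorted(ontology.concepts):
        for label in ontology.concepts[cid].labels():
            for token in label.lower().split():
                owner.setdefault(token, cid)
    grouped: dict[str, list[str]] = {}
    for token, cid in owner.items():
        grouped.setdefault(cid, []).append(token)
    return grouped


def generate_embeddings(
    ontology: Ontology, dim: int = 20, seed: int = 0, noise: float = 0.1
) -> EmbeddingTable:
    """Unit-norm embeddings clustered around one direction per concept.

    Tokens of the same concept end up with high pairwise cosine (>= 0.8 for
    the default noise level), unrelated concepts near-orthogonal in
    expectation, so the normalization task is learnable by construction.
    """
    if dim < 2:
        raise ValueError("embedding dimension must be >= 2")
    rng = np.random.default_rng(seed)
    grouped = sorted(_concept_vocab(ontology).items())
    centers = _spread_directions(rng, len(grouped), dim)
    vectors: dict[str, np.ndarray] = {}
    for (cid, tokens), center in zip(grouped, centers):
        for token in sorted(tokens):
            vec = center + noise * rng.standard_normal(dim)
            vectors[token] = vec / np.linalg.norm(vec)
    return EmbeddingTable(dimension=dim, vectors=vectors, unit_normalized=True)


def _spread_directions(rng: np.random.Generator, n: int, dim: int) -> np.ndarray:
    """n unit vectors pushed toward minimal pairwise correlation.

    Plain i.i.d. directions leave chance near-duplicates when n > dim; a few
    repulsion steps drive the Gram matrix toward the identity so distinct
    concepts stay distinguishable.
    """
    c = rng.standard_normal((n, dim))
    c /= np.linalg.norm(c, axis=1, keepdims=True)
    for _ in range(200):
        gram = c @ c.T
        np.fill_diagonal(gram, 0.0)
        c -= 0.05 * gram @ c
        c /= np.linalg.norm(c, axis=1, keepdims=True)
    return c


def _vary(
    surface: str,
    concept: Concept,
    ops: tuple[str, ...],
    rate: float,
    rng: np.random.Generator,
) -> str:
    for op in ops:
        if rng.random() >= rate:
            continue
        tokens = surface.split()
        if op == "synonym_swap":
            labels = [l for l in concept.labels() if l != surface]
            if labels:
                surface = labels[int(rng.integers(len(labels)))]
        elif op == "suffix_inflection":
            tokens[-1] += _SUFFIXES[int(rng.integers(len(_SUFFIXES)))]
            surface = " ".join(tokens)
        elif op == "token_dropout":
            if len(tokens) > 1:
                tokens.pop(int(rng.integers(len(tokens))))
                surface = " ".join(tokens)
        elif op == "modifier_insertion":
            mod = _MODIFIERS[int(rng.integers(len(_MODIFIERS)))]
            surface = f"{mod} {surface}"
    return surface


def _build_docs(
    targets: list[tuple[str, str]],
    split: str,
    spec: SyntheticSpec,
) -> list[StandoffDoc]:
    """Pack (concept id, surface) pairs into standoff documents."""
    docs = []
    per_doc = spec.mentions_per_document
    for d, start in enumerate(range(0, len(targets), per_doc)):
        chunk = targets[start : start + per_doc]
        doc_id = f"{split}-{d:04d}"
        text_parts: list[str] = []
        a1_lines: list[str] = []
        a2_lines: list[str] = []
        offset = 0
        for i, (cid, surface) in enumerate(chunk, start=1):
            begin = offset + len(_SENTENCE_PREFIX)
            end = begin + len(surface)
            sentence = _SENTENCE_PREFIX + surface + _SENTENCE_SUFFIX
            text_parts.append(sentence)
            offset += len(sentence)
            a1_lines.append(f"T{i}\t{spec.entity_type} {begin} {end}\t{surface}")
            a2_lines.append(
                f"N{i}\tOntoBiotope Annotation:T{i} Referent:{cid}"
            )
        docs.append(
            StandoffDoc(
                document_id=doc_id,
                text="".join(text_parts),
                a1="\n".join(a1_lines) + "\n",
                a2="\n".join(a2_lines) + "\n",
            )
        )
    return docs


def generate_corpus(ontology: Ontology, spec: SyntheticSpec) -> SyntheticCorpus:
    """Sample an annotated corpus with few-shot/zero-shot structure.

    A ``zero_shot_fraction`` share of concepts is barred from the training
    split.  Training mention counts per remaining concept are drawn from
    ``examples_per_concept_dist``; the dev and test splits each hold about
    20% of ``n_mentions``, sampled uniformly over all concepts.  Mention
    surfaces start from a concept label and pass through the configured
    variation operators.
    """
    rng = np.random.default_rng(spec.seed + 1)
    ids = sorted(ontology.concepts)
    n_zero = int(round(spec.zero_shot_fraction * len(ids)))
    zero_shot = set(rng.choice(ids, size=n_zero, replace=False)) if n_zero else set()
    trainable = [cid for cid in ids if cid not in zero_shot]

    mean, sd = spec.examples_per_concept_dist

    def realize(cid: str) -> tuple[str, str]:
        concept = ontology.concepts[cid]
        labels = concept.labels()
        surface = labels[int(rng.integers(len(labels)))]
        surface = _vary(surface, concept, spec.variation_ops, spec.variation_rate, rng)
        return cid, surface

    train_targets: list[tuple[str, str]] = []
    for cid in trainable:
        k = int(round(rng.normal(mean, sd)))
        for _ in range(max(0, k)):
            train_targets.append(realize(cid))
    order = rng.permutation(len(train_targets))
    train_targets = [train_targets[i] for i in order]

    n_eval = max(1, int(round(0.2 * spec.n_mentions)))
    dev_targets = [realize(ids[int(i)]) for i in rng.integers(len(ids), size=n_eval)]
    test_targets = [realize(ids[int(i)]) for i in rng.integers(len(ids), size=n_eval)]

    return SyntheticCorpus(
        splits={
            "train": _build_docs(train_targets, "train", spec),
            "dev": _build_docs(dev_targets, "dev", spec),
            "test": _build_docs(test_targets, "test", spec),
        },
        zero_shot_concepts=zero_shot,
        spec=spec,
    )


def write_obo(ontology: Ontology, path: str | Path) -> None:
    """Serialize an ontology as an OBO 1.2 flat file."""
    lines = ["format-version: 1.2", ""]
    for cid in sorted(ontology.concepts):
        c = ontology.concepts[cid]
        lines.append("[Term]")
        lines.append(f"id: {c.id}")
        lines.append(f"name: {c.preferred_label}")
        for syn in c.synonyms:
            lines.append(f'synonym: "{syn}" EXACT []')
        for parent in sorted(c.parents):
            lines.append(f"is_a: {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")
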