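"""BioNLP-ST standoff annotation I/O and training-set assembly.

Entities live in ``.a1`` files (``Tn<TAB>Type start end[;start end]*<TAB>
surface``), normalizations in ``.a2`` files (``Nn<TAB>Resource
Annotation:Tk Referent:CONCEPT``).  Offsets are 0-based, end-exclusive
character offsets into the UTF-8 ``.txt`` document.

Weak supervision turns every ontology label (and optionally synonym) into a
training example normalized with its own concept, guaranteeing that each
concept is covered at least once.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from conceptnorm.errors import FormatError, ValidationError
from conceptnorm.ontology import Ontology
from conceptnorm.text import tokenize_filter

__all__ = [
    "Mention",
    "GoldNormalization",
    "TrainingExample",
    "read_standoff",
    "read_standoff_dir",
    "labels_as_examples",
    "assemble_training",
    "write_predictions",
]

logger = logging.getLogger(__name__)

DEFAULT_RESOURCE_NAME = "OntoBiotope"


@dataclass
class Mention:
    """One annotated entity occurrence in a document."""

    mention_id: str
    document_id: str
    entity_type: str
    spans: list[tuple[int, int]]
    surface: str

    @property
    def key(self) -> tuple[str, str]:
        return (self.document_id, self.mention_id)


@dataclass
class GoldNormalization:
    """Reference concept id(s) for one mention."""

    mention_id: str
    document_id: str
    concept_ids: set[str]


@dataclass
class TrainingExample:
    """A (token list, target concept) pair with its provenance."""

    tokens: list[str]
    target_concept: str
    provenance: str  # "gold" or "weak"
    mention_id: str | None = None
    document_id: str | None = None


_A1_RE = re.compile(r"^(T\d+)\t(\S+) ([\d ;]+)\t(.*)$")
_A2_RE = re.compile(
    r"^(N\d+)\t(\S+) Annotation:(T\d+) Referent:(\S+)\s*$"
)


def read_standoff(
    txt: str,
    a1: str,
    a2: str = "",
    document_id: str = "doc",
    entity_types: Sequence[str] | None = None,
) -> tuple[list[Mention], list[GoldNormalization]]:
    """Parse one document's standoff annotation into mentions and referents.

    Parameters
    ----------
    txt
        Raw document text.
    a1
        Entity lines; discontinuous spans (``start end;start end``) are
        supported and their fragments joined by single spaces.
    a2
        Normalization lines; repeated lines for the same mention accumulate
        into a multi-concept reference.
    entity_types
        If given, only mentions of these types are returned.

    Raises
    ------
    FormatError
        On malformed offsets or an ``.a2`` line referring to an absent
        mention.
    """
    mentions: dict[str, Mention] = {}
    for lineno, line in enumerate(a1.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith("T"):
            continue  # ignore other annotation kinds
        m = _A1_RE.match(line)
        if m is None:
            raise FormatError(f"{document_id}.a1:{lineno}: malformed entity line {line!r}")
        tid, etype, offsets, surface = m.groups()
        spans: list[tuple[int, int]] = []
        for frag in offsets.split(";"):
            parts = frag.split()
            if len(parts) != 2:
                raise FormatError(
                    f"{document_id}.a1:{lineno}: malformed offsets {offsets!r}"
                )
            start, end = int(parts[0]), int(parts[1])
            if not (0 <= start < end <= len(txt)):
                raise FormatError(
                    f"{document_id}.a1:{lineno}: offsets {start} {end} out of "
                    f"range or inverted (document length {len(txt)})"
                )
            spans.append((start, end))
        expected = " ".join(txt[s:e] for s, e in spans)
        if surface != expected:
            logger.warning(
                "%s %s: surface %r differs from document text %r",
                document_id,
                tid,
                surface,
                expected,
            )
        mentions[tid] = Mention(
            mention_id=tid,
            document_id=document_id,
            entity_type=etype,
            spans=spans,
            surface=expected,
        )

    gold: dict[str, GoldNormalization] = {}
    for lineno, line in enumerate(a2.splitlines(), start=1):
        if not line.strip() or not line.startswith("N"):
            continue
        m = _A2_RE.match(line)
        if m is None:
            raise FormatError(
                f"{document_id}.a2:{lineno}: malformed normalization line {line!r}"
            )
        _, _, tid, concept = m.groups()
        if tid not in mentions:
            raise FormatError(
                f"{document_id}.a2:{lineno}: reference to absent mention {tid!r}"
            )
        if tid in gold:
            gold[tid].concept_ids.add(concept)
        else:
            gold[tid] = GoldNormalization(
                mention_id=tid, document_id=document_id, concept_ids={concept}
            )

    if entity_types is not None:
        wanted = set(entity_types)
        mentions = {
            tid: m for tid, m in mentions.items() if m.entity_type in wanted
        }
        gold = {tid: g for tid, g in gold.items() if tid in mentions}

    return list(mentions.values()), list(gold.values())


def read_standoff_dir(
    directory: str | Path,
    entity_types: Sequence[str] | None = None,
) -> tuple[list[Mention], list[GoldNormalization]]:
    """Read every ``.txt``/``.a1``[/``.a2``] triple in a directory."""
    directory = Path(directory)
    mentions: list[Mention] = []
    gold: list[GoldNormalization] = []
    txt_files = sorted(directory.glob("*.txt"))
    if not txt_files:
        raise ValidationError(f"no .txt documents found in {directory}")
    for txt_path in txt_files:
        doc_id = txt_path.stem
        a1_path = txt_path.with_suffix(".a1")
        if not a1_path.exists():
            logger.warning("document %s has no .a1 file; skipped", doc_id)
            continue
        a2_path = txt_path.with_suffix(".a2")
        ms, gs = read_standoff(
            txt_path.read_text(encoding="utf-8"),
            a1_path.read_text(encoding="utf-8"),
            a2_path.read_text(encoding="utf-8") if a2_path.exists() else "",
            document_id=doc_id,
            entity_types=entity_types,
        )
        mentions.extend(ms)
        gold.extend(gs)
    return mentions, gold


def labels_as_examples(
    ontology: Ontology,
    include_synonyms: bool = True,
    stopwords: frozenset[str] | set[str] = frozenset(),
) -> list[TrainingExample]:
    """Weak-supervision examples: each concept label is a mention of itself.

    One example per preferred label, plus one per synonym when
    ``include_synonyms``; every concept is covered at least once.
    """
    examples: list[TrainingExample] = []
    for cid in sorted(ontology.concepts):
        concept = ontology.concepts[cid]
        labels = concept.labels() if include_synonyms else [concept.preferred_label]
        for label in labels:
            examples.append(
                TrainingExample(
                    tokens=tokenize_filter(label, stopwords),
                    target_concept=cid,
                    provenance="weak",
                )
            )
    return examples


def assemble_training(
    mentions: Sequence[Mention],
    gold: Sequence[GoldNormalization],
    ontology: Ontology,
    mode: str = "standard+weak",
    include_synonyms: bool = True,
    stopwords: frozenset[str] | set[str] = frozenset(),
) -> list[TrainingExample]:
    """Expand gold annotations (and optionally ontology labels) into examples.

    A mention with several reference concepts becomes one example per
    concept.  Mentions left with no token after filtering are dropped from
    training with a warning.  In ``standard+weak`` mode the label examples
    are appended after the gold ones; order is deterministic.

    Raises
    ------
    ValidationError
        If a gold concept id cannot be resolved in the ontology.
    """
    if mode not in {"standard", "standard+weak"}:
        raise ValueError(f"unknown training mode {mode!r}")
    by_key = {m.key: m for m in mentions}
    examples: list[TrainingExample] = []
    unresolved: list[str] = []
    for g in sorted(gold, key=lambda g: (g.document_id, g.mention_id)):
        mention = by_key.get((g.document_id, g.mention_id))
        if mention is None:
            continue
        tokens = tokenize_filter(mention.surface, stopwords)
        if not tokens:
            logger.warning(
                "mention %s/%s is empty after filtering; dropped from training",
                g.document_id,
                g.mention_id,
            )
            continue
        for concept in sorted(g.concept_ids):
            try:
                canonical = ontology.resolve(concept)
            except Exception:
                unresolved.append(concept)
                continue
            examples.append(
                TrainingExample(
                    tokens=tokens,
                    target_concept=canonical,
                    provenance="gold",
                    mention_id=g.mention_id,
                    document_id=g.document_id,
                )
            )
    if unresolved:
        raise ValidationError(
            "gold concepts not resolvable in the ontology: "
            + ", ".join(sorted(set(unresolved)))
        )
    if mode == "standard+weak":
        examples.extend(
            labels_as_examples(ontology, include_synonyms, stopwords)
        )
    return examples


def write_predictions(
    predictions: Iterable,
    resource_name: str = DEFAULT_RESOURCE_NAME,
) -> str:
    """Serialize predictions as sequentially numbered ``.a2`` N lines.

    Each prediction needs ``mention_id`` and ``concept_id`` attributes (see
    :class:`conceptnorm.decode.Prediction`).
    """
    lines = []
    for i, pred in enumerate(predictions, start=1):
        lines.append(
            f"N{i}\t{resource_name} Annotation:{pred.mention_id} "
            f"Referent:{pred.concept_id}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
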