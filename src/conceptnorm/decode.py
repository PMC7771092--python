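"""Turn model output vectors into concept predictions.

Decoding is cosine nearest-neighbor search over the concept-vector space.
The sieve combiner keeps a primary model's predictions above a confidence
threshold and defers the remaining mentions to a fallback model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from conceptnorm.ontology import ConceptVectorSpace

__all__ = ["Prediction", "nearest_concept", "decode_batch", "sieve_combine"]

logger = logging.getLogger(__name__)


@dataclass
class Prediction:
    """One (mention, concept) decision with its cosine confidence."""

    mention_id: str
    concept_id: str
    confidence: float
    source: str  # slfnn | cnn | cnorm | sieve
    document_id: str = ""
    flagged: bool = False


def nearest_concept(
    output: np.ndarray, space: ConceptVectorSpace
) -> tuple[str, float]:
    """Concept whose vector has the highest cosine with ``output``.

    Ties break toward the lexicographically smallest concept id (the space
    is stored in sorted id order, so the first argmax wins).  A zero output
    vector cannot be oriented; the fallback is the lexicographically
    smallest root-like concept — here the first concept of the space — with
    confidence 0.

    Raises
    ------
    ValueError
        On an output dimension different from the space's N.
    """
    output = np.asarray(output, dtype=np.float64)
    if output.shape != (space.n_concepts,):
        raise ValueError(
            f"output has shape {output.shape}, expected ({space.n_concepts},)"
        )
    norm = float(np.linalg.norm(output))
    if norm == 0.0:
        logger.warning("zero output vector; falling back to %s", space.concept_ids[0])
        return space.concept_ids[0], 0.0
    cos = (space.vectors @ output) / (
        np.linalg.norm(space.vectors, axis=1) * norm
    )
    best = int(np.argmax(cos))
    return space.concept_ids[best], float(cos[best])


def decode_batch(
    outputs: np.ndarray,
    mention_ids: Sequence[str],
    space: ConceptVectorSpace,
    source: str,
    document_ids: Sequence[str] | None = None,
) -> list[Prediction]:
    """Nearest-concept decoding for a batch of output vectors."""
    if len(outputs) != len(mention_ids):
        raise ValueError("outputs and mention_ids must align")
    preds = []
    for i, (vec, mid) in enumerate(zip(outputs, mention_ids)):
        cid, cos = nearest_concept(vec, space)
        preds.append(
            Prediction(
                mention_id=mid,
                concept_id=cid,
                confidence=cos,
                source=source,
                document_id=document_ids[i] if document_ids else "",
                flagged=cos == 0.0 and not np.any(vec),
            )
        )
    return preds


def sieve_combine(
    primary: Sequence[Prediction],
    fallback: Sequence[Prediction],
    threshold: float,
) -> list[Prediction]:
    """Keep primary predictions with confidence strictly above the threshold.

    Mentions whose primary confidence is ``<= threshold`` take the fallback
    model's prediction instead.  Both lists must cover exactly the same
    mentions; the output order follows ``primary``.
    """
    def key(p: Prediction) -> tuple[str, str]:
        return (p.document_id, p.mention_id)

    fb = {key(p): p for p in fallback}
    if {key(p) for p in primary} != set(fb):
        only_primary = {key(p) for p in primary} - set(fb)
        only_fallback = set(fb) - {key(p) for p in primary}
        raise ValueError(
            "primary and fallback cover different mentions: "
            f"primary-only={sorted(only_primary)}, "
            f"fallback-only={sorted(only_fallback)}"
        )
    combined = []
    kept = 0
    for p in primary:
        chosen = p if p.confidence > threshold else fb[key(p)]
        kept += chosen is p
        combined.append(
            Prediction(
                mention_id=p.mention_id,
                concept_id=chosen.concept_id,
                confidence=chosen.confidence,
                source="sieve",
                document_id=p.document_id,
                flagged=chosen.flagged,
            )
        )
    logger.info(
        "sieve kept %d primary predictions, passed %d to fallback",
        kept,
        len(combined) - kept,
    )
    return combined
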