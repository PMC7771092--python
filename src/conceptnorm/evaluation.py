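"""Scoring prediction sets against gold normalizations.

Two metrics, both averaged over mentions: the strict exact score (1 if the
predicted concept is a reference concept, else 0) and the Wang similarity
score (hierarchy-aware, 1 for an exact match and decaying toward 0 with
graph distance).  Errors are additionally classified by their relation to
the gold concepts on the is_a graph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from conceptnorm.decode import Prediction
from conceptnorm.errors import ValidationError
from conceptnorm.ontology import (
    DEFAULT_EDGE_CONTRIBUTION,
    Ontology,
    ancestor_distances,
    wang_similarity,
)

__all__ = ["EvaluationReport", "strict_score", "wang_score", "evaluate"]

TYPOLOGY = ("correct", "overgeneralization", "overspecification", "partial", "off_path")


@dataclass
class MentionResult:
    mention_id: str
    document_id: str
    predicted: str
    gold: list[str]
    strict: float
    wang: float
    typology: str
    graph_distance: int | None = None


@dataclass
class EvaluationReport:
    n_mentions: int
    strict_mean: float
    wang_mean: float
    per_mention: list[MentionResult]
    error_typology: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_mentions": self.n_mentions,
                "strict_mean": self.strict_mean,
                "wang_mean": self.wang_mean,
                "error_typology": self.error_typology,
            },
            indent=2,
        )

    def to_tsv(self) -> str:
        lines = ["mention_id\tdocument_id\tpredicted\tgold\tstrict\twang\ttypology"]
        for r in self.per_mention:
            lines.append(
                f"{r.mention_id}\t{r.document_id}\t{r.predicted}\t"
                f"{','.join(r.gold)}\t{r.strict}\t{r.wang:.6f}\t{r.typology}"
            )
        return "\n".join(lines) + "\n"


def strict_score(predicted: str, gold: set[str] | Sequence[str], ontology: Ontology) -> float:
    """1.0 iff the predicted concept is one of the reference concepts."""
    predicted = ontology.resolve(predicted)
    gold_resolved = {ontology.resolve(g) for g in gold}
    return 1.0 if predicted in gold_resolved else 0.0


def wang_score(
    predicted: str,
    gold: set[str] | Sequence[str],
    ontology: Ontology,
    edge_contribution: float = DEFAULT_EDGE_CONTRIBUTION,
) -> float:
    """Best Wang similarity between the prediction and any reference concept."""
    predicted = ontology.resolve(predicted)
    return max(
        wang_similarity(ontology, predicted, ontology.resolve(g), edge_contribution)
        for g in gold
    )


def _classify(
    predicted: str, gold: set[str], ontology: Ontology
) -> tuple[str, int | None]:
    """Assign an error type and, for on-path errors, the graph distance."""
    if predicted in gold:
        return "correct", 0
    for g in sorted(gold):
        dist = ancestor_distances(ontology, g)
        if predicted in dist and dist[predicted] > 0:
            return "overgeneralization", dist[predicted]
    for g in sorted(gold):
        dist = ancestor_distances(ontology, predicted)
        if g in dist and dist[g] > 0:
            return "overspecification", dist[g]
    if len(gold) > 1:
        # reachable only under scoring conventions stricter than membership
        return "partial", None
    return "off_path", None


def evaluate(
    predictions: Sequence[Prediction],
    gold: Mapping[tuple[str, str], set[str]] | Sequence,
    ontology: Ontology,
    edge_contribution: float = DEFAULT_EDGE_CONTRIBUTION,
) -> EvaluationReport:
    """Score a prediction set against gold normalizations.

    Parameters
    ----------
    predictions
        One :class:`Prediction` per gold mention.
    gold
        Either a mapping ``(document_id, mention_id) -> set of concept ids``
        or a sequence of :class:`conceptnorm.corpus_io.GoldNormalization`.

    Raises
    ------
    ValidationError
        If some gold mention has no prediction.
    """
    if not isinstance(gold, Mapping):
        gold = {
            (g.document_id, g.mention_id): set(g.concept_ids) for g in gold
        }
    by_key = {(p.document_id, p.mention_id): p for p in predictions}
    missing = sorted(set(gold) - set(by_key))
    if missing:
        raise ValidationError(
            f"gold mentions without a prediction: {missing}"
        )

    results: list[MentionResult] = []
    typology = {t: 0 for t in TYPOLOGY}
    for key in sorted(gold):
        pred = by_key[key]
        refs = {ontology.resolve(g) for g in gold[key]}
        predicted = ontology.resolve(pred.concept_id)
        strict = strict_score(predicted, refs, ontology)
        wang = wang_score(predicted, refs, ontology, edge_contribution)
        kind, dist = _classify(predicted, refs, ontology)
        typology[kind] += 1
        results.append(
            MentionResult(
                mention_id=pred.mention_id,
                document_id=pred.document_id,
                predicted=predicted,
                gold=sorted(refs),
                strict=strict,
                wang=wang,
                typology=kind,
                graph_distance=dist,
            )
        )
    n = len(results)
    return EvaluationReport(
        n_mentions=n,
        strict_mean=sum(r.strict for r in results) / n if n else 0.0,
        wang_mean=sum(r.wang for r in results) / n if n else 0.0,
        per_mention=results,
        error_typology=typology,
    )
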