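"""Event canonicalization, generalization and network interpretation.

This module turns nested biomolecular event structures into objects that
can be aggregated across a whole bibliome:

* :func:`canonicalize` collapses small lexical variants of gene symbols
  ("Esr-1" → "esr1") by lower-casing and stripping non-alphanumerics;
* :func:`generalization_key` groups events that share a type and
  equivalent arguments, at the canonical-string or the normalized-
  identifier level;
* :func:`flatten_to_relations` converts a nested event into typed,
  directed pairwise agent→target relations (the network interpretation);
* :class:`EventIndex` aggregates occurrence counts and maximum
  confidences over a corpus, the evidence base for the re-ranking and
  machine-learned conversion features.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .standoff import Document, EntityAnnotation, EventAnnotation

__all__ = [
    "CanonicalizationError",
    "CoarseEventType",
    "PairwiseRelation",
    "GeneralizationKey",
    "EventIndex",
    "REGULATION_LAYERS",
    "GENE_ENTITY_TYPES",
    "canonicalize",
    "generalization_key",
    "flatten_to_relations",
    "build_event_index",
]


class CanonicalizationError(ValueError):
    """Symbol has no alphanumeric characters left after stripping."""


_NON_ALNUM = re.compile(r"[^a-z0-9]+")

#: Regulation-family event types and the polarity layer they contribute.
REGULATION_LAYERS = {
    "Regulation": "Unspecified",
    "Positive_regulation": "Positive",
    "Negative_regulation": "Negative",
}

#: Coarse base assigned to non-regulation event types.
_BASE_OF_TYPE = {
    "Binding": "Binding",
    "Transcription": "Transcription",
    "Gene_expression": "GeneExpression",
}

#: Entity types treated as gene/gene-product mentions when flattening.
GENE_ENTITY_TYPES = frozenset(
    {"Gene", "Protein", "Operon", "PolymeraseComplex", "ProteinComplex", "GGP"}
)


def canonicalize(symbol: str) -> str:
    """Lower-case ``symbol`` and strip non-alphanumeric characters.

    Idempotent; raises :class:`CanonicalizationError` when nothing is left.
    """
    result = _NON_ALNUM.sub("", symbol.lower())
    if not result:
        raise CanonicalizationError(f"symbol {symbol!r} has no alphanumeric characters")
    return result


@dataclass(frozen=True)
class CoarseEventType:
    """Regulatory polarity layer plus mechanistic base of an event.

    ``regulatory_layer`` is one of ``None``/``Unspecified``/``Positive``/
    ``Negative`` (the string ``"None"`` means no regulation wraps the
    base event); ``base`` is ``Binding``, ``Transcription``,
    ``GeneExpression`` or ``Other``.
    """

    regulatory_layer: str
    base: str

    LAYERS = ("None", "Unspecified", "Positive", "Negative")
    BASES = ("Binding", "Transcription", "GeneExpression", "Other")

    def __post_init__(self) -> None:
        if self.regulatory_layer not in self.LAYERS:
            raise ValueError(f"unknown layer {self.regulatory_layer!r}")
        if self.base not in self.BASES:
            raise ValueError(f"unknown base {self.base!r}")
        if self.base == "Binding" and self.regulatory_layer != "None":
            raise ValueError("Binding base cannot carry a regulatory layer")

    def __str__(self) -> str:  # compact form used in feature names
        return f"{self.regulatory_layer}:{self.base}"


def compose_layers(outer: str, inner: str) -> str:
    """Polarity algebra for nested regulations.

    Sign multiplication: Negative∘Negative = Positive, mixed = Negative;
    Unspecified absorbs everything; composing with "None" is identity.
    """
    if inner == "None":
        return outer
    if outer == "None":
        return inner
    if "Unspecified" in (outer, inner):
        return "Unspecified"
    return "Positive" if outer == inner else "Negative"


@dataclass(frozen=True)
class PairwiseRelation:
    """A directed agent→target relation extracted from one event."""

    agent: str  # canonical symbol
    target: str
    coarse_type: CoarseEventType
    confidence: float
    source_doc: str
    source_event: str
    negated: bool = False
    agent_entity_type: str | None = None
    target_entity_type: str | None = None
    agent_id: str | None = None  # standardized gene id, filled by symbol matching
    target_id: str | None = None

    def __post_init__(self) -> None:
        if not self.agent or not self.target:
            raise ValueError("agent and target symbols must be non-empty")
        if not (0.0 < self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside (0, 1]")


@dataclass(frozen=True)
class GeneralizationKey:
    """Equivalence-class key for events across documents.

    ``level`` is ``"canonical"`` (arguments keyed by canonicalized surface
    symbol) or ``"normalized_id"`` (keyed by standardized gene id).
    Arguments form a multiset, so argument order never matters.
    """

    level: str
    event_type: str
    argument_keys: tuple[tuple[str, str], ...]  # sorted (role, symbol-or-id)

    def __post_init__(self) -> None:
        if self.level not in ("canonical", "normalized_id"):
            raise ValueError(f"unknown generalization level {self.level!r}")


class GeneralizationError(KeyError):
    """A leaf argument lacks the identifier required by the level."""


def _leaf_arg_key(
    ref: EntityAnnotation | EventAnnotation,
    level: str,
    symbol_table: dict[str, str] | None,
) -> str:
    """Key for a single entity argument at the requested level."""
    assert isinstance(ref, EntityAnnotation)
    canon = canonicalize(ref.symbol)
    if level == "canonical":
        return canon
    if symbol_table is None or canon not in symbol_table:
        raise GeneralizationError(f"no standardized id for symbol {ref.symbol!r}")
    return symbol_table[canon]


def generalization_key(
    event: EventAnnotation,
    level: str = "canonical",
    symbol_table: dict[str, str] | None = None,
) -> GeneralizationKey:
    """Deterministic grouping key for ``event`` at ``level``.

    Entity arguments are keyed by role plus canonical symbol (or
    standardized id); nested event arguments contribute their own key,
    rendered as a string, so structurally equivalent nestings coincide.
    ``symbol_table`` maps canonical symbols to standardized ids and is
    required at the ``normalized_id`` level.
    """
    arg_keys: list[tuple[str, str]] = []
    for arg in event.arguments:
        if arg.is_event:
            sub = generalization_key(arg.ref, level, symbol_table)
            rendered = f"{sub.event_type}({','.join('%s=%s' % rk for rk in sub.argument_keys)})"
            arg_keys.append((arg.role, rendered))
        else:
            arg_keys.append((arg.role, _leaf_arg_key(arg.ref, level, symbol_table)))
    return GeneralizationKey(level, event.event_type, tuple(sorted(arg_keys)))


# ---------------------------------------------------------------------------
# Network interpretation
# ---------------------------------------------------------------------------

def _gene_entity(ref) -> EntityAnnotation | None:
    if isinstance(ref, EntityAnnotation) and ref.entity_type in GENE_ENTITY_TYPES:
        return ref
    return None


def _descend_theme(
    event: EventAnnotation, layer: str, confidence: float, negated: bool
) -> list[tuple[EntityAnnotation, str, str, float, bool]]:
    """Follow Theme chains down to leaf gene targets.

    Returns ``(target_entity, layer, base, confidence, negated)`` tuples,
    where ``layer`` composes the polarities of all traversed regulations
    and ``confidence``/``negated`` fold min/OR along the chain.
    """
    out = []
    for theme in event.themes():
        if theme.is_event:
            inner: EventAnnotation = theme.ref
            conf = min(confidence, inner.confidence)
            neg = negated or inner.negated
            if inner.event_type in REGULATION_LAYERS:
                inner_layer = compose_layers(layer, REGULATION_LAYERS[inner.event_type])
                out.extend(_descend_theme(inner, inner_layer, conf, neg))
            elif inner.event_type in ("Transcription", "Gene_expression"):
                base = _BASE_OF_TYPE[inner.event_type]
                for sub in inner.themes():
                    ent = _gene_entity(sub.ref)
                    if ent is not None:
                        out.append((ent, layer, base, conf, neg))
            # other nested types (e.g. nested Binding) are not interpreted
        else:
            ent = _gene_entity(theme.ref)
            if ent is not None:
                out.append((ent, layer, "Other", confidence, negated))
    return out


def flatten_to_relations(event: EventAnnotation, doc_id: str = "") -> list[PairwiseRelation]:
    """Convert a nested event into pairwise agent→target relations.

    Rules:

    * a Binding with two or more gene/protein Themes yields one relation
      per unordered Theme pair, in both orientations, with coarse type
      ``(None, Binding)`` — orientation is resolved downstream by the
      entity-type filter;
    * a regulation-family event with a gene Cause yields relations from
      the Cause to every leaf gene target reached by following Theme
      chains through nested regulations (polarities composed by sign
      multiplication) and through nested Transcription/Gene_expression
      events (which set the mechanistic base);
    * events with neither a Binding Theme pair nor a gene Cause yield
      nothing.

    Relation confidence is the minimum along the event chain; negation
    propagates by logical OR.  At most one relation is emitted per
    distinct (agent, target, coarse type) triple.
    """
    relations: list[PairwiseRelation] = []

    def add(agent: EntityAnnotation, target: EntityAnnotation,
            coarse: CoarseEventType, conf: float, neg: bool) -> None:
        relations.append(
            PairwiseRelation(
                agent=canonicalize(agent.symbol),
                target=canonicalize(target.symbol),
                coarse_type=coarse,
                confidence=conf,
                source_doc=doc_id,
                source_event=event.id,
                negated=neg,
                agent_entity_type=agent.entity_type,
                target_entity_type=target.entity_type,
            )
        )

    if event.event_type == "Binding":
        genes = [e for a in event.themes() if (e := _gene_entity(a.ref)) is not None]
        coarse = CoarseEventType("None", "Binding")
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                add(genes[i], genes[j], coarse, event.confidence, event.negated)
                add(genes[j], genes[i], coarse, event.confidence, event.negated)
    elif event.event_type in REGULATION_LAYERS:
        causes = [e for a in event.causes() if (e := _gene_entity(a.ref)) is not None]
        if causes:
            layer = REGULATION_LAYERS[event.event_type]
            leaves = _descend_theme(event, layer, event.confidence, event.negated)
            for cause in causes:
                for target, lay, base, conf, neg in leaves:
                    add(cause, target, CoarseEventType(lay, base), conf, neg)

    # at most one relation per (agent, target) pair: keep the highest
    # confidence path (first emission wins ties), OR the negation flags
    best: dict[tuple[str, str], PairwiseRelation] = {}
    for rel in relations:
        key = (rel.agent, rel.target)
        prev = best.get(key)
        if prev is None:
            best[key] = rel
        else:
            winner = rel if rel.confidence > prev.confidence else prev
            neg = rel.negated or prev.negated
            if winner.negated != neg:
                winner = PairwiseRelation(
                    agent=winner.agent, target=winner.target,
                    coarse_type=winner.coarse_type, confidence=winner.confidence,
                    source_doc=winner.source_doc, source_event=winner.source_event,
                    negated=neg, agent_entity_type=winner.agent_entity_type,
                    target_entity_type=winner.target_entity_type,
                )
            best[key] = winner
    return list(best.values())


# ---------------------------------------------------------------------------
# Bibliome-wide aggregation
# ---------------------------------------------------------------------------

@dataclass
class EventIndex:
    """Bibliome-wide aggregation of event occurrences.

    Keyed three ways: by generalization key (count, max confidence), by
    (event type, single argument key) for partial matches, and by
    directed canonical pair plus coarse type for the network level.
    """

    key_counts: dict[GeneralizationKey, int] = field(default_factory=dict)
    key_max_conf: dict[GeneralizationKey, float] = field(default_factory=dict)
    pair_counts: dict[tuple[str, str, CoarseEventType], int] = field(default_factory=dict)
    pair_max_conf: dict[tuple[str, str, CoarseEventType], float] = field(default_factory=dict)
    # (level, event_type, (role, arg-key)) -> occurrence count
    partial_counts: dict[tuple[str, str, tuple[str, str]], int] = field(default_factory=dict)

    def add_event(
        self,
        event: EventAnnotation,
        doc_id: str,
        symbol_table: dict[str, str] | None = None,
        levels: tuple[str, ...] = ("canonical", "normalized_id"),
    ) -> None:
        for level in levels:
            try:
                key = generalization_key(event, level, symbol_table)
            except (KeyError, CanonicalizationError):
                continue  # e.g. no standardized id at the normalized level
            self.key_counts[key] = self.key_counts.get(key, 0) + 1
            self.key_max_conf[key] = max(
                self.key_max_conf.get(key, 0.0), event.confidence
            )
            for arg_key in set(key.argument_keys):
                pk = (level, key.event_type, arg_key)
                self.partial_counts[pk] = self.partial_counts.get(pk, 0) + 1
        for rel in flatten_to_relations(event, doc_id):
            pair = (rel.agent, rel.target, rel.coarse_type)
            self.pair_counts[pair] = self.pair_counts.get(pair, 0) + 1
            self.pair_max_conf[pair] = max(
                self.pair_max_conf.get(pair, 0.0), rel.confidence
            )

    # -- lookups ----------------------------------------------------------
    def key_stats(self, key: GeneralizationKey) -> tuple[int, float]:
        return self.key_counts.get(key, 0), self.key_max_conf.get(key, 0.0)

    def partial_match_count(self, key: GeneralizationKey) -> int:
        """Occurrences sharing the event type and ≥1 equivalent argument.

        Computed by inclusion over single-argument postings with overlap
        correction against the stored per-key argument multisets.
        """
        candidates: dict[GeneralizationKey, int] = {}
        for other, count in self.key_counts.items():
            if other.level != key.level or other.event_type != key.event_type:
                continue
            if set(other.argument_keys) & set(key.argument_keys):
                candidates[other] = count
        return sum(candidates.values())

    def pair_stats(self, agent: str, target: str,
                   coarse: CoarseEventType | None = None) -> tuple[int, float]:
        """Count and max confidence for a directed pair (all types or one)."""
        if coarse is not None:
            pair = (agent, target, coarse)
            return self.pair_counts.get(pair, 0), self.pair_max_conf.get(pair, 0.0)
        count, max_conf = 0, 0.0
        for (a, t, _), c in self.pair_counts.items():
            if a == agent and t == target:
                count += c
        for (a, t, _), m in self.pair_max_conf.items():
            if a == agent and t == target:
                max_conf = max(max_conf, m)
        return count, max_conf

    def directed_pairs(self) -> set[tuple[str, str]]:
        return {(a, t) for (a, t, _) in self.pair_counts}


def build_event_index(
    documents: list[Document],
    symbol_table: dict[str, str] | None = None,
    levels: tuple[str, ...] = ("canonical", "normalized_id"),
) -> EventIndex:
    """Aggregate counts and maximum confidences over a corpus.

    ``symbol_table`` (canonical symbol → standardized id) enables the
    normalized-identifier generalization; events whose arguments lack an
    id simply contribute nothing at that level.
    """
    index = EventIndex()
    for doc in documents:
        for event in doc.events:
            index.add_event(event, doc.doc_id, symbol_table, levels)
    return index
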