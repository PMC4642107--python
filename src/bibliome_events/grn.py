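"""Gene regulatory network construction from pairwise event relations.

Implements the rule-based conversion of coarse event types to the five
regulatory-network interaction types, the entity-type compatibility
filter, the Binding→Transcription refactoring, and the one-edge-per-pair
selection rules — plus a machine-learned alternative in which a separate
RBF-kernel SVM per interaction type learns the mapping from bibliome
count/confidence features, combinable with the rule filters (hybrid) or
run end to end (ml_full).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .events import CoarseEventType, EventIndex, PairwiseRelation, build_event_index, flatten_to_relations
from .standoff import Document, GRN_TYPES

__all__ = [
    "GRNInteraction",
    "MLConversionConfig",
    "PairFeatureVector",
    "restrict_documents",
    "match_symbols",
    "map_type_rule",
    "filter_entity_types",
    "refactor_binding",
    "select_edges",
    "convert_rule_based",
    "convert_unfiltered",
    "conversion_candidates",
    "build_pair_features",
    "collect_candidate_pairs",
    "label_pairs_from_gold",
    "train_type_classifiers",
    "convert_ml",
]


@dataclass(frozen=True)
class GRNInteraction:
    """A typed, directed network edge between standardized gene ids."""

    agent_id: str
    target_id: str
    grn_type: str
    confidence: float
    agent_entity_type: str | None = None
    target_entity_type: str | None = None

    def __post_init__(self) -> None:
        if self.grn_type not in GRN_TYPES:
            raise ValueError(f"unknown interaction type {self.grn_type!r}")


# ---------------------------------------------------------------------------
# Rule-based pipeline stages
# ---------------------------------------------------------------------------

def restrict_documents(
    relations: list[PairwiseRelation], doc_ids: set[str] | str
) -> list[PairwiseRelation]:
    """Keep only relations from the given documents; ``"all"`` is identity."""
    if doc_ids == "all":
        return list(relations)
    return [r for r in relations if r.source_doc in doc_ids]


def match_symbols(
    relations: list[PairwiseRelation], symbol_table: dict[str, str]
) -> list[PairwiseRelation]:
    """Resolve canonical symbols to standardized gene identifiers.

    ``symbol_table`` maps canonicalized surface symbols to ids (the gold
    symbol table is canonicalized on load).  Relations whose agent or
    target cannot be resolved are dropped: symbols never seen in the
    gold data cannot take part in the network.
    """
    out = []
    for rel in relations:
        agent_id = symbol_table.get(rel.agent)
        target_id = symbol_table.get(rel.target)
        if agent_id is None or target_id is None:
            continue
        out.append(replace(rel, agent_id=agent_id, target_id=target_id))
    return out


def map_type_rule(coarse: CoarseEventType) -> str | None:
    """Rule-based mapping of a coarse event type to a network type.

    Rows are applied top-down; "regulation of transcription/expression"
    outranks the bare polarity rows, so e.g. a positive regulation of
    Transcription maps to Transcription, not Activation.
    """
    layer, base = coarse.regulatory_layer, coarse.base
    if layer == "None" and base == "Binding":
        return "Binding"
    if layer != "None" and base in ("Transcription", "GeneExpression"):
        return "Transcription"
    if layer == "Positive":
        return "Activation"
    if layer == "Negative":
        return "Inhibition"
    if layer == "Unspecified":
        return "Regulation"
    return None  # plain non-Binding event: no network interpretation


#: Allowed (target, agent) entity types per network type.
_ALLOWED_TARGETS = {
    "Binding": frozenset({"Protein"}),
    "Transcription": frozenset({"Protein", "PolymeraseComplex"}),
    "Regulation": frozenset({"Protein", "PolymeraseComplex"}),
    "Activation": frozenset({"Protein", "PolymeraseComplex"}),
    "Inhibition": frozenset({"Protein", "PolymeraseComplex"}),
}
_ALLOWED_AGENTS = {
    "Binding": frozenset({"Gene"}),
    "Transcription": frozenset({"Gene", "Operon"}),
    "Regulation": frozenset({"Gene", "Operon", "Protein", "ProteinComplex"}),
    "Activation": frozenset({"Gene", "Operon", "Protein", "ProteinComplex"}),
    "Inhibition": frozenset({"Gene", "Operon", "Protein", "ProteinComplex"}),
}


def filter_entity_types(interaction: GRNInteraction) -> bool:
    """Entity-type compatibility filter; ``True`` means keep.

    A Binding must link a Gene agent to a Protein target (excluding
    protein–protein interactions); Transcription requires a Gene/Operon
    agent; the regulatory types additionally admit Protein and
    ProteinComplex agents.
    """
    if interaction.agent_entity_type is None or interaction.target_entity_type is None:
        raise ValueError(
            f"interaction {interaction.agent_id}->{interaction.target_id} "
            "lacks entity types required by the filter"
        )
    return (
        interaction.target_entity_type in _ALLOWED_TARGETS[interaction.grn_type]
        and interaction.agent_entity_type in _ALLOWED_AGENTS[interaction.grn_type]
    )


def refactor_binding(interactions: list[GRNInteraction]) -> list[GRNInteraction]:
    """Re-type every surviving Binding edge as Transcription.

    Binding events align more often with transcription-factor/promoter
    relations than with the network's Binding type; the refactoring runs
    only after entity-type filtering so the Binding-specific type
    constraints have already applied.
    """
    return [
        replace(i, grn_type="Transcription") if i.grn_type == "Binding" else i
        for i in interactions
    ]


def select_edges(interactions: list[GRNInteraction]) -> list[GRNInteraction]:
    """Reduce to at most one edge per ordered (agent, target) pair.

    Sequential rules per pair: (a) drop Regulation when a more specific
    type is present; (b) on an Activation/Inhibition contradiction keep
    the higher-confidence one; (c) keep mechanism edges (Transcription,
    Binding) only when no regulatory edge remains; (d) break residual
    ties by confidence, then lexicographic type order.
    """
    by_pair: dict[tuple[str, str], list[GRNInteraction]] = {}
    for inter in interactions:
        by_pair.setdefault((inter.agent_id, inter.target_id), []).append(inter)

    out: list[GRNInteraction] = []
    for _, group in sorted(by_pair.items()):
        types = {g.grn_type for g in group}
        # (a) specificity: Regulation loses to any more specific type
        if "Regulation" in types and types & {"Activation", "Inhibition", "Transcription", "Binding"}:
            group = [g for g in group if g.grn_type != "Regulation"]
        # (b) contradiction: keep the higher-confidence polarity
        types = {g.grn_type for g in group}
        if "Activation" in types and "Inhibition" in types:
            act = max((g for g in group if g.grn_type == "Activation"), key=lambda g: g.confidence)
            inh = max((g for g in group if g.grn_type == "Inhibition"), key=lambda g: g.confidence)
            loser = "Inhibition" if act.confidence >= inh.confidence else "Activation"
            group = [g for g in group if g.grn_type != loser]
        # (c) mechanism suppression
        types = {g.grn_type for g in group}
        if types & {"Transcription", "Binding"} and types & {"Activation", "Inhibition", "Regulation"}:
            group = [g for g in group if g.grn_type not in ("Transcription", "Binding")]
        # (d) residual tie-break: confidence desc, then type lexicographic
        winner = sorted(group, key=lambda g: (-g.confidence, g.grn_type))[0]
        out.append(winner)
    return out


def _convert(
    documents: list[Document],
    symbol_table: dict[str, str],
    doc_restriction: set[str] | str,
    drop_negated: bool,
    apply_entity_filter: bool,
) -> list[GRNInteraction]:
    interactions = conversion_candidates(
        documents, symbol_table, doc_restriction, drop_negated
    )
    if apply_entity_filter:
        interactions = [i for i in interactions if filter_entity_types(i)]
    interactions = refactor_binding(interactions)
    return select_edges(interactions)


def conversion_candidates(
    documents: list[Document],
    symbol_table: dict[str, str],
    doc_restriction: set[str] | str = "all",
    drop_negated: bool = False,
) -> list[GRNInteraction]:
    """Typed interaction candidates before filtering and edge selection.

    The per-relation output of flatten → restrict → match → type-map,
    exposed so the entity-type filter can be studied as a pure filter
    (its output is always a subset of this list).
    """
    from .events import canonicalize

    canon_table = {canonicalize(k): v for k, v in symbol_table.items()}
    relations: list[PairwiseRelation] = []
    for doc in documents:
        for event in doc.events:
            relations.extend(flatten_to_relations(event, doc.doc_id))
    relations = restrict_documents(relations, doc_restriction)
    if drop_negated:
        relations = [r for r in relations if not r.negated]
    relations = match_symbols(relations, canon_table)
    out = []
    for rel in relations:
        grn_type = map_type_rule(rel.coarse_type)
        if grn_type is None:
            continue
        out.append(
            GRNInteraction(
                agent_id=rel.agent_id, target_id=rel.target_id,
                grn_type=grn_type, confidence=rel.confidence,
                agent_entity_type=rel.agent_entity_type,
                target_entity_type=rel.target_entity_type,
            )
        )
    return out


def convert_rule_based(
    documents: list[Document],
    symbol_table: dict[str, str],
    doc_restriction: set[str] | str = "all",
    drop_negated: bool = False,
) -> list[GRNInteraction]:
    """End-to-end rule-based network conversion.

    Pipeline: flatten events → restrict documents → (optionally drop
    negated relations) → resolve symbols → map types → entity-type
    filter → Binding refactoring → edge selection.  ``symbol_table``
    maps surface symbols (canonicalized internally) to standardized ids.
    """
    return _convert(documents, symbol_table, doc_restriction, drop_negated, True)


def convert_unfiltered(
    documents: list[Document],
    symbol_table: dict[str, str],
    doc_restriction: set[str] | str = "all",
    drop_negated: bool = False,
) -> list[GRNInteraction]:
    """Type conversion without the entity-type filter (ablation arm)."""
    return _convert(documents, symbol_table, doc_restriction, drop_negated, False)


# ---------------------------------------------------------------------------
# Machine-learned conversion
# ---------------------------------------------------------------------------

_DEFAULT_C_GRID = [2.0 ** k for k in range(-5, 16, 2)]
_DEFAULT_GAMMA_GRID = [2.0 ** k for k in range(-15, 4, 2)]


@dataclass
class MLConversionConfig:
    """Configuration of the per-type SVM conversion."""

    C_grid: list[float] = field(default_factory=lambda: list(_DEFAULT_C_GRID))
    gamma_grid: list[float] = field(default_factory=lambda: list(_DEFAULT_GAMMA_GRID))
    n_folds: int = 5
    include_entity_type_features: bool = False
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not self.C_grid or not self.gamma_grid:
            raise ValueError("parameter grids must be non-empty")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


_COARSE_TYPES = [
    CoarseEventType(layer, base)
    for layer in CoarseEventType.LAYERS
    for base in CoarseEventType.BASES
    if not (base == "Binding" and layer != "None")
]

_ENTITY_TYPE_ORDER = [
    "Gene", "Protein", "Operon", "PolymeraseComplex", "ProteinComplex", "GGP", "Other",
]


@dataclass
class PairFeatureVector:
    """Bibliome features for one directed agent→target pair."""

    counts: dict[CoarseEventType, int]
    total_count: int
    reverse_counts: dict[CoarseEventType, int]
    reverse_total: int
    max_conf: dict[CoarseEventType, float]
    overall_max_conf: float
    reverse_max_conf: float
    reverse_dominates: bool
    agent_entity_type: str | None = None
    target_entity_type: str | None = None

    def to_array(self, include_entity_types: bool) -> np.ndarray:
        vals: list[float] = []
        for ct in _COARSE_TYPES:
            vals.append(self.counts.get(ct, 0))
        vals.append(self.total_count)
        for ct in _COARSE_TYPES:
            vals.append(self.reverse_counts.get(ct, 0))
        vals.append(self.reverse_total)
        for ct in _COARSE_TYPES:
            vals.append(self.max_conf.get(ct, 0.0))
        vals.append(self.overall_max_conf)
        vals.append(self.reverse_max_conf)
        vals.append(1.0 if self.reverse_dominates else 0.0)
        if include_entity_types:
            for et in _ENTITY_TYPE_ORDER:
                vals.append(1.0 if self.agent_entity_type == et else 0.0)
            for et in _ENTITY_TYPE_ORDER:
                vals.append(1.0 if self.target_entity_type == et else 0.0)
        return np.asarray(vals, dtype=float)


def build_pair_features(
    pair: tuple[str, str],
    event_index: EventIndex,
    entity_types: tuple[str | None, str | None] = (None, None),
) -> PairFeatureVector:
    """Assemble count/confidence features for a directed pair.

    Five feature classes: per-type and total forward counts, reverse
    counts, per-type and overall forward max confidence, reverse max
    confidence, and a flag marking reverse dominance; optionally the
    agent/target entity types as categorical extras.  Raises when the
    pair has no forward event at all.
    """
    agent, target = pair
    counts, max_conf = {}, {}
    total = 0
    for ct in _COARSE_TYPES:
        c, m = event_index.pair_stats(agent, target, ct)
        if c:
            counts[ct] = c
            max_conf[ct] = m
            total += c
    if total == 0:
        raise ValueError(f"pair {pair} has no forward event in the index")
    rev_counts = {}
    rev_total = 0
    for ct in _COARSE_TYPES:
        c, _ = event_index.pair_stats(target, agent, ct)
        if c:
            rev_counts[ct] = c
            rev_total += c
    _, fwd_max = event_index.pair_stats(agent, target)
    _, rev_max = event_index.pair_stats(target, agent)
    return PairFeatureVector(
        counts=counts, total_count=total,
        reverse_counts=rev_counts, reverse_total=rev_total,
        max_conf=max_conf, overall_max_conf=fwd_max,
        reverse_max_conf=rev_max,
        reverse_dominates=rev_max > fwd_max,
        agent_entity_type=entity_types[0],
        target_entity_type=entity_types[1],
    )


@dataclass
class TypeClassifier:
    """Binary decision model for one network interaction type."""

    grn_type: str
    model: object | None  # fitted sklearn pipeline-like, or None
    constant: bool = False
    constant_value: bool = False
    best_params: dict | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.constant:
            return np.full(len(X), self.constant_value, dtype=bool)
        scaler, svc = self.model
        return svc.predict(scaler.transform(X)).astype(bool)


def train_type_classifiers(
    pairs: list[PairFeatureVector],
    labels: dict[str, np.ndarray],
    config: MLConversionConfig,
) -> dict[str, TypeClassifier]:
    """Train one RBF-SVM per interaction type with grid-searched (C, γ).

    ``labels`` maps each network type to a boolean array aligned with
    ``pairs``.  Grid search maximizes mean F-score under stratified
    cross-validation; types without enough examples of both classes for
    the folds are trained at default parameters (with a warning), and
    single-class types collapse to constant predictors.
    """
    X = np.stack([p.to_array(config.include_entity_type_features) for p in pairs])
    out: dict[str, TypeClassifier] = {}
    for grn_type in GRN_TYPES:
        y = np.asarray(labels.get(grn_type, np.zeros(len(pairs), dtype=bool)), dtype=bool)
        n_pos, n_neg = int(y.sum()), int((~y).sum())
        if n_pos == 0 or n_neg == 0:
            out[grn_type] = TypeClassifier(
                grn_type, None, constant=True, constant_value=n_pos > 0
            )
            continue
        scaler = StandardScaler().fit(X)
        Xs = scaler.transform(X)
        if min(n_pos, n_neg) < config.n_folds:
            warnings.warn(
                f"type {grn_type}: too few examples for {config.n_folds}-fold "
                "grid search; training at default parameters"
            )
            svc = SVC(kernel="rbf", random_state=config.random_seed).fit(Xs, y)
            out[grn_type] = TypeClassifier(grn_type, (scaler, svc))
            continue
        cv = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True, random_state=config.random_seed
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            search = GridSearchCV(
                SVC(kernel="rbf", random_state=config.random_seed),
                {"C": config.C_grid, "gamma": config.gamma_grid},
                scoring="f1", cv=cv, n_jobs=1,
            )
            search.fit(Xs, y)
        out[grn_type] = TypeClassifier(
            grn_type, (scaler, search.best_estimator_), best_params=dict(search.best_params_)
        )
    return out


def convert_ml(
    documents: list[Document],
    symbol_table: dict[str, str],
    classifiers: dict[str, TypeClassifier],
    mode: str = "hybrid",
    config: MLConversionConfig | None = None,
) -> list[GRNInteraction]:
    """Machine-learned network conversion.

    Candidate pairs are all directed standardized-id pairs with at least
    one forward event; each positively classified type yields a candidate
    edge whose confidence is the pair's forward maximum confidence.
    ``hybrid`` then applies the rule-based entity-type filter, Binding
    refactoring and edge selection; ``ml_full`` relies on the entity-type
    features inside the classifiers and applies edge selection only.
    """
    if mode not in ("hybrid", "ml_full"):
        raise ValueError(f"unknown mode {mode!r}")
    config = config or MLConversionConfig()
    if mode == "ml_full" and not config.include_entity_type_features:
        raise ValueError("ml_full requires classifiers trained with entity-type features")

    pairs, feats = collect_candidate_pairs(documents, symbol_table)
    if not pairs:
        return []
    candidates: list[GRNInteraction] = []
    X = np.stack([f.to_array(config.include_entity_type_features) for f in feats])
    for grn_type, clf in classifiers.items():
        pred = clf.predict(X)
        for (pair, feat), keep in zip(zip(pairs, feats), pred):
            if not keep:
                continue
            candidates.append(
                GRNInteraction(
                    agent_id=pair[0], target_id=pair[1], grn_type=grn_type,
                    confidence=feat.overall_max_conf,
                    agent_entity_type=feat.agent_entity_type,
                    target_entity_type=feat.target_entity_type,
                )
            )
    if mode == "hybrid":
        candidates = [c for c in candidates if filter_entity_types(c)]
        candidates = refactor_binding(candidates)
    return select_edges(candidates)


def collect_candidate_pairs(
    documents: list[Document], symbol_table: dict[str, str]
) -> tuple[list[tuple[str, str]], list[PairFeatureVector]]:
    """Directed id pairs with ≥1 forward event, plus their features.

    The index is built over the given documents with symbols resolved
    through the (canonicalized) gold symbol table; each pair's entity
    types are the modal agent/target entity types over its relations.
    """
    from .events import canonicalize

    canon_table = {canonicalize(k): v for k, v in symbol_table.items()}
    index = EventIndex()
    etype_votes: dict[tuple[str, str], dict[tuple[str, str], int]] = {}
    for doc in documents:
        for event in doc.events:
            index.add_event(event, doc.doc_id, canon_table, levels=("canonical",))
            for rel in flatten_to_relations(event, doc.doc_id):
                votes = etype_votes.setdefault((rel.agent, rel.target), {})
                key = (rel.agent_entity_type, rel.target_entity_type)
                votes[key] = votes.get(key, 0) + 1

    pairs: list[tuple[str, str]] = []
    feats: list[PairFeatureVector] = []
    for agent_c, target_c in sorted(index.directed_pairs()):
        agent_id = canon_table.get(agent_c)
        target_id = canon_table.get(target_c)
        if agent_id is None or target_id is None:
            continue
        votes = etype_votes.get((agent_c, target_c), {})
        etypes = max(sorted(votes), key=lambda k: votes[k]) if votes else (None, None)
        feat = build_pair_features((agent_c, target_c), index, etypes)
        pairs.append((agent_id, target_id))
        feats.append(feat)
    return pairs, feats


def label_pairs_from_gold(
    pairs: list[tuple[str, str]],
    gold: list,
) -> dict[str, np.ndarray]:
    """Per-type boolean label arrays for training the type classifiers."""
    gold_map = {(g.agent_id, g.target_id): g.interaction_type for g in gold}
    labels: dict[str, np.ndarray] = {}
    for grn_type in GRN_TYPES:
        labels[grn_type] = np.array(
            [gold_map.get(p) == grn_type for p in pairs], dtype=bool
        )
    return labels
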