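"""Per-sentence re-ranking and threshold regression of event predictions.

The re-ranker assigns each candidate event a score meaningful only
relative to the other candidates in the same sentence (its query set);
a separately learned regressor then predicts, per sentence, the score
threshold below which candidates are discarded.  Oracle harnesses bound
the attainable gain: the best-case oracle picks the per-sentence
F-maximizing threshold with gold access, the worst-case oracle does the
same but may not filter sentences containing only false positives, and
a random-ranking baseline quantifies how much of the gain comes from
the oracle rather than the ranker.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC, LinearSVR

from .events import (
    EventIndex,
    GeneralizationError,
    CanonicalizationError,
    flatten_to_relations,
    generalization_key,
)
from .standoff import Document, EventAnnotation, TextSpan

__all__ = [
    "CandidateEvent",
    "SentenceQuerySet",
    "RerankConfig",
    "RankingModel",
    "ThresholdRegressor",
    "label_candidates",
    "extract_event_features",
    "sentence_features",
    "train_ranker",
    "score_events",
    "threshold_target",
    "train_threshold_regressor",
    "apply_filter",
    "oracle_thresholds",
    "random_rank_baseline",
    "prf_from_query_sets",
    "sentence_f_score",
    "is_multi_argument",
]

#: Event-type groups used for per-category reporting.
EVENT_TYPE_GROUPS = {
    "Simple": frozenset({"Gene_expression", "Transcription", "Localization"}),
    "Protein_mod": frozenset(
        {"Phosphorylation", "Protein_modification", "Ubiquitination",
         "Acetylation", "Deacetylation"}
    ),
    "Binding": frozenset({"Binding"}),
    "Regulation": frozenset(
        {"Regulation", "Positive_regulation", "Negative_regulation"}
    ),
}


def event_type_group(event_type: str) -> str:
    for group, members in EVENT_TYPE_GROUPS.items():
        if event_type in members:
            return group
    return "Other"


@dataclass
class CandidateEvent:
    """A predicted event with its correctness label and ranking score."""

    event: EventAnnotation
    base_confidence: float
    label: str = "unknown"  # tp | fp | unknown
    rank_score: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in ("tp", "fp", "unknown"):
            raise ValueError(f"bad label {self.label!r}")


@dataclass
class SentenceQuerySet:
    """All candidate events of one sentence — the ranking unit."""

    doc_id: str
    sentence_span: TextSpan
    candidates: list[CandidateEvent]

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValueError("query set must contain at least one candidate")

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.candidates]


@dataclass
class RerankConfig:
    """Knobs of the re-ranking stage.

    ``fallback_offset`` is the margin added above (below) the highest
    (lowest) score for all-false-positive (all-true-positive) training
    sentences; ``n_random_runs`` is the number of randomized-ranking
    repetitions averaged in the baseline.
    """

    fallback_offset: float = 0.2
    n_random_runs: int = 10
    random_seed: int = 0
    generalization_levels: tuple[str, ...] = ("canonical", "normalized_id")
    feature_groups: tuple[str, ...] = ("event", "sentence", "bibliome")

    def __post_init__(self) -> None:
        if self.fallback_offset <= 0:
            raise ValueError("fallback_offset must be positive")
        if self.n_random_runs < 1:
            raise ValueError("n_random_runs must be >= 1")


# ---------------------------------------------------------------------------
# Labeling predictions against gold
# ---------------------------------------------------------------------------

def _event_signature(ev: EventAnnotation, tolerance: int = 0):
    """Recursive structural signature used for gold matching."""
    args = []
    for arg in ev.arguments:
        if arg.is_event:
            args.append((arg.role, "E", _event_signature(arg.ref, tolerance)))
        else:
            ref = arg.ref
            args.append((arg.role, "T", (ref.entity_type, ref.span.start, ref.span.end)))
    return (ev.event_type, ev.trigger.start, ev.trigger.end, tuple(sorted(args)))


def _signatures_match(a, b, tolerance: int) -> bool:
    if tolerance == 0:
        return a == b
    ta, sa, ea, args_a = a
    tb, sb, eb, args_b = b
    if ta != tb or abs(sa - sb) > tolerance or abs(ea - eb) > tolerance:
        return False
    if len(args_a) != len(args_b):
        return False
    remaining = list(args_b)
    for arg in args_a:
        hit = None
        for cand in remaining:
            if arg[0] != cand[0] or arg[1] != cand[1]:
                continue
            if arg[1] == "E":
                if _signatures_match(arg[2], cand[2], tolerance):
                    hit = cand
                    break
            else:
                et_a, s_a, e_a = arg[2]
                et_b, s_b, e_b = cand[2]
                if et_a == et_b and abs(s_a - s_b) <= tolerance and abs(e_a - e_b) <= tolerance:
                    hit = cand
                    break
        if hit is None:
            return False
        remaining.remove(hit)
    return True


def label_candidates(
    predicted: list[EventAnnotation],
    gold: list[EventAnnotation],
    span_tolerance: int = 0,
) -> list[CandidateEvent]:
    """Label predictions tp/fp by recursive structural match against gold.

    A prediction is a true positive when a gold event has the same type,
    the same trigger span (within ``span_tolerance`` characters) and an
    equal argument multiset (entity arguments by span and type, event
    arguments recursively).  Each gold event absorbs at most one
    prediction; predictions compete greedily by confidence, ties broken
    by document order.
    """
    gold_sigs = [_event_signature(g) for g in gold]
    taken = [False] * len(gold)
    order = sorted(
        range(len(predicted)),
        key=lambda i: (-predicted[i].confidence, i),
    )
    labels = ["fp"] * len(predicted)
    for i in order:
        sig = _event_signature(predicted[i])
        for j, gsig in enumerate(gold_sigs):
            if taken[j]:
                continue
            if _signatures_match(sig, gsig, span_tolerance):
                taken[j] = True
                labels[i] = "tp"
                break
    return [
        CandidateEvent(event=ev, base_confidence=ev.confidence, label=lab)
        for ev, lab in zip(predicted, labels)
    ]


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

def _root_to_leaf_paths(ev: EventAnnotation, prefix: str = "") -> list[str]:
    """Role/type paths from the root trigger to each argument leaf."""
    base = f"{prefix}{ev.event_type}"
    paths = []
    for arg in ev.arguments:
        if arg.is_event:
            paths.extend(_root_to_leaf_paths(arg.ref, f"{base}>{arg.role}>"))
        else:
            paths.append(f"{base}>{arg.role}>{arg.ref.entity_type}")
    return paths


def is_multi_argument(ev: EventAnnotation) -> bool:
    return len(ev.arguments) >= 2


def extract_event_features(
    candidate: CandidateEvent,
    query_set: SentenceQuerySet,
    event_index: EventIndex,
    symbol_table: dict[str, str] | None = None,
    config: RerankConfig | None = None,
) -> dict[str, float]:
    """Feature dictionary for one candidate event.

    Three groups, individually switchable via ``config.feature_groups``:

    * ``event`` — base confidence, event type, argument count and the
      root-to-leaf structural paths as categorical indicators;
    * ``sentence`` — number of co-candidates and confidence statistics
      and type histogram over the other events in the sentence;
    * ``bibliome`` — per generalization level: exact-key occurrence
      count and max confidence, partial-match count (same type, ≥1
      shared argument), and pairwise network-level count/confidence for
      the candidate's flattened relations.
    """
    config = config or RerankConfig()
    ev = candidate.event
    feats: dict[str, float] = {}

    if "event" in config.feature_groups:
        feats["ev:base_confidence"] = candidate.base_confidence
        feats[f"ev:type={ev.event_type}"] = 1.0
        feats["ev:n_args"] = float(len(ev.arguments))
        feats["ev:multi_arg"] = 1.0 if is_multi_argument(ev) else 0.0
        for path in _root_to_leaf_paths(ev):
            feats[f"ev:path={path}"] = 1.0

    if "sentence" in config.feature_groups:
        others = [c for c in query_set.candidates if c is not candidate]
        feats["sent:n_others"] = float(len(others))
        if others:
            confs = [c.base_confidence for c in others]
            feats["sent:mean_conf"] = float(np.mean(confs))
            feats["sent:max_conf"] = float(np.max(confs))
            feats["sent:min_conf"] = float(np.min(confs))
            for c in others:
                key = f"sent:type={c.event.event_type}"
                feats[key] = feats.get(key, 0.0) + 1.0

    if "bibliome" in config.feature_groups:
        for level in config.generalization_levels:
            try:
                key = generalization_key(ev, level, symbol_table)
            except (GeneralizationError, CanonicalizationError, KeyError):
                continue
            count, max_conf = event_index.key_stats(key)
            feats[f"bib:{level}:count"] = float(count)
            feats[f"bib:{level}:max_conf"] = max_conf
            feats[f"bib:{level}:partial"] = float(event_index.partial_match_count(key))
        pair_count, pair_conf = 0.0, 0.0
        for rel in flatten_to_relations(ev, query_set.doc_id):
            c, m = event_index.pair_stats(rel.agent, rel.target)
            pair_count += c
            pair_conf = max(pair_conf, m)
        feats["bib:pair_count"] = pair_count
        feats["bib:pair_max_conf"] = pair_conf
    return feats


def sentence_features(query_set: SentenceQuerySet) -> dict[str, float]:
    """Sentence-level features for the threshold regressor.

    Candidate count, ranking-score statistics (mean/min/max/spread),
    base-confidence statistics and the event-type histogram.
    """
    scores = [c.rank_score for c in query_set.candidates]
    confs = [c.base_confidence for c in query_set.candidates]
    feats = {
        "n_candidates": float(len(scores)),
        "score_mean": float(np.mean(scores)),
        "score_min": float(np.min(scores)),
        "score_max": float(np.max(scores)),
        "score_spread": float(np.max(scores) - np.min(scores)),
        "conf_mean": float(np.mean(confs)),
        "conf_min": float(np.min(confs)),
        "conf_max": float(np.max(confs)),
    }
    for c in query_set.candidates:
        key = f"type={c.event.event_type}"
        feats[key] = feats.get(key, 0.0) + 1.0
    return feats


# ---------------------------------------------------------------------------
# Ranker
# ---------------------------------------------------------------------------

@dataclass
class RankingModel:
    """Linear scoring model trained on within-sentence preference pairs."""

    vectorizer: DictVectorizer
    scaler: StandardScaler
    weights: np.ndarray
    config: RerankConfig
    symbol_table: dict[str, str] | None = None

    def score(self, feats: dict[str, float]) -> float:
        x = self.vectorizer.transform([feats]).toarray()
        return float(self.scaler.transform(x)[0] @ self.weights)


def train_ranker(
    query_sets: list[SentenceQuerySet],
    event_index: EventIndex,
    config: RerankConfig | None = None,
    symbol_table: dict[str, str] | None = None,
) -> RankingModel:
    """Train the pairwise large-margin ranker.

    Reduction of ranking-SVM training to binary classification: for each
    training sentence, every (tp, fp) candidate pair contributes the
    feature difference as a training point (both orientations), so the
    learned direction orders true positives above false positives within
    a sentence.  Preferences are never formed across sentences.
    """
    config = config or RerankConfig()
    featdicts: list[list[dict[str, float]]] = []
    for qs in query_sets:
        featdicts.append(
            [extract_event_features(c, qs, event_index, symbol_table, config)
             for c in qs.candidates]
        )
    vectorizer = DictVectorizer(sparse=True)
    all_feats = [f for fs in featdicts for f in fs]
    scaler = StandardScaler().fit(vectorizer.fit_transform(all_feats).toarray())

    diffs, targets = [], []
    for qs, fs in zip(query_sets, featdicts):
        X = scaler.transform(vectorizer.transform(fs).toarray())
        for i, ci in enumerate(qs.candidates):
            for j, cj in enumerate(qs.candidates):
                if ci.label == "tp" and cj.label == "fp":
                    diffs.append(X[i] - X[j])
                    targets.append(1)
                    diffs.append(X[j] - X[i])
                    targets.append(-1)
    if not diffs:
        raise ValueError(
            "no mixed query set: training requires at least one sentence "
            "with both tp and fp candidates"
        )
    svm = LinearSVC(
        C=1.0, fit_intercept=False, random_state=config.random_seed,
        max_iter=20000, dual="auto", tol=1e-6,
    )
    svm.fit(np.asarray(diffs), np.asarray(targets))
    return RankingModel(vectorizer, scaler, svm.coef_.ravel().copy(), config, symbol_table)


def score_events(
    model: RankingModel,
    query_set: SentenceQuerySet,
    event_index: EventIndex,
) -> SentenceQuerySet:
    """Assign ranking scores; comparable only within the query set."""
    scored = []
    for c in query_set.candidates:
        feats = extract_event_features(
            c, query_set, event_index, model.symbol_table, model.config
        )
        scored.append(replace(c, rank_score=model.score(feats)))
    return SentenceQuerySet(query_set.doc_id, query_set.sentence_span, scored)


# ---------------------------------------------------------------------------
# Thresholds
# ---------------------------------------------------------------------------

def sentence_f_score(retained_labels: list[str], total_tp: int) -> float:
    """Per-sentence F-score of a retention decision.

    Retained tp count as true positives, retained fp as false positives,
    removed tp as false negatives.  An empty retained set scores 1 when
    the sentence had no true positives at all, else 0.
    """
    tp = sum(1 for lab in retained_labels if lab == "tp")
    fp = sum(1 for lab in retained_labels if lab == "fp")
    fn = total_tp - tp
    if tp + fp == 0:
        return 1.0 if total_tp == 0 else 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def _best_cut(query_set: SentenceQuerySet) -> tuple[int, float]:
    """Retention size maximizing per-sentence F over score-ordered cuts.

    Candidates are ordered by descending score; cut k retains the top k.
    Ties in F prefer the larger retained set.  Returns (k, best F).
    """
    order = sorted(
        query_set.candidates, key=lambda c: -c.rank_score
    )
    total_tp = sum(1 for c in query_set.candidates if c.label == "tp")
    best_k, best_f = 0, sentence_f_score([], total_tp)
    for k in range(1, len(order) + 1):
        f = sentence_f_score([c.label for c in order[:k]], total_tp)
        if f >= best_f:  # ties -> larger retained set
            best_k, best_f = k, f
    return best_k, best_f


def threshold_target(
    query_set: SentenceQuerySet, config: RerankConfig | None = None
) -> float:
    """Regression target: the per-sentence filtering threshold.

    For a sentence with both labels, the score of the lowest-ranked
    event in the retention set that maximizes the sentence F-score
    (exhaustive search over the score-ordered cut points).  Sentences
    with only false positives get the maximum score plus the fallback
    offset; sentences with only true positives the minimum score minus
    it.
    """
    config = config or RerankConfig()
    labels = set(query_set.labels)
    scores = [c.rank_score for c in query_set.candidates]
    if labels == {"fp"}:
        return max(scores) + config.fallback_offset
    if labels == {"tp"}:
        return min(scores) - config.fallback_offset
    k, _ = _best_cut(query_set)
    order = sorted(query_set.candidates, key=lambda c: -c.rank_score)
    assert k >= 1  # a mixed sentence always benefits from retaining its top tp
    return order[k - 1].rank_score


@dataclass
class ThresholdRegressor:
    """Linear large-margin regressor over sentence-level features."""

    vectorizer: DictVectorizer
    scaler: StandardScaler | None
    model: LinearSVR | None
    constant_value: float | None = None

    def predict(self, query_set: SentenceQuerySet) -> float:
        if self.constant_value is not None:
            return self.constant_value
        x = self.vectorizer.transform([sentence_features(query_set)])
        return float(self.model.predict(self.scaler.transform(x))[0])


def train_threshold_regressor(
    query_sets: list[SentenceQuerySet],
    config: RerankConfig | None = None,
    targets: list[float] | None = None,
) -> ThresholdRegressor:
    """Fit the per-sentence threshold regressor on scored, labeled sentences.

    ``targets`` defaults to :func:`threshold_target` per query set.
    """
    config = config or RerankConfig()
    if len(query_sets) < 2:
        raise ValueError("need at least two training sentences")
    if targets is None:
        targets = [threshold_target(qs, config) for qs in query_sets]
    targets = np.asarray(targets, dtype=float)
    vectorizer = DictVectorizer(sparse=False)
    X = vectorizer.fit_transform([sentence_features(qs) for qs in query_sets])
    if np.allclose(targets, targets[0]):
        return ThresholdRegressor(vectorizer, None, None, constant_value=float(targets[0]))
    scaler = StandardScaler().fit(X)
    model = LinearSVR(
        epsilon=0.0, C=100.0, loss="squared_epsilon_insensitive",
        dual=False, random_state=config.random_seed, max_iter=50000, tol=1e-10,
    )
    model.fit(scaler.transform(X), targets)
    return ThresholdRegressor(vectorizer, scaler, model)


def apply_filter(
    query_set: SentenceQuerySet, threshold: float
) -> list[CandidateEvent]:
    """Remove candidates scoring below the threshold, then cascade.

    After thresholding, any retained event one of whose event-valued
    arguments was removed is removed too, recursively, so the retained
    set is always structurally valid.
    """
    retained = [c for c in query_set.candidates if c.rank_score >= threshold]
    removed_ids = {
        c.event.id for c in query_set.candidates if c.rank_score < threshold
    }
    changed = True
    while changed:
        changed = False
        for c in list(retained):
            for arg in c.event.arguments:
                if arg.is_event and arg.ref.id in removed_ids:
                    retained.remove(c)
                    removed_ids.add(c.event.id)
                    changed = True
                    break
    return retained


# ---------------------------------------------------------------------------
# Oracles and baselines
# ---------------------------------------------------------------------------

def oracle_thresholds(
    query_sets: list[SentenceQuerySet],
    mode: str = "best",
    config: RerankConfig | None = None,
) -> list[float]:
    """Per-sentence oracle thresholds (gold access).

    ``best``: the per-sentence F-maximizing threshold everywhere; for
    all-false-positive sentences this removes everything.  ``worst``:
    identical, except all-false-positive sentences may not be filtered
    (threshold below every score).
    """
    if mode not in ("best", "worst"):
        raise ValueError(f"unknown oracle mode {mode!r}")
    config = config or RerankConfig()
    thresholds = []
    for qs in query_sets:
        labels = set(qs.labels)
        scores = [c.rank_score for c in qs.candidates]
        if labels == {"fp"}:
            if mode == "best":
                thresholds.append(max(scores) + config.fallback_offset)
            else:
                thresholds.append(min(scores) - config.fallback_offset)
            continue
        if labels == {"tp"}:
            thresholds.append(min(scores) - config.fallback_offset)
            continue
        k, _ = _best_cut(qs)
        order = sorted(qs.candidates, key=lambda c: -c.rank_score)
        thresholds.append(order[k - 1].rank_score)
    return thresholds


def prf_from_query_sets(
    query_sets: list[SentenceQuerySet],
    retained_sets: list[list[CandidateEvent]],
    total_gold: int | None = None,
) -> tuple[float, float, float]:
    """Corpus-level precision/recall/F of a filtering decision.

    ``total_gold`` defaults to the number of tp-labeled candidates (every
    gold event that was predicted); pass a larger value to account for
    gold events the upstream extractor missed entirely.
    """
    tp = sum(1 for kept in retained_sets for c in kept if c.label == "tp")
    fp = sum(1 for kept in retained_sets for c in kept if c.label == "fp")
    if total_gold is None:
        total_gold = sum(1 for qs in query_sets for c in qs.candidates if c.label == "tp")
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / total_gold if total_gold else 1.0
    f = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return precision, recall, f


def random_rank_baseline(
    query_sets: list[SentenceQuerySet],
    config: RerankConfig | None = None,
    total_gold: int | None = None,
) -> tuple[float, float, float]:
    """Worst-case oracle under randomized rankings, averaged over runs.

    Each run replaces every candidate's score by an independent uniform
    draw, applies the worst-case oracle thresholds and collects P/R/F;
    the averages over ``config.n_random_runs`` runs are returned.
    """
    config = config or RerankConfig()
    if not query_sets:
        raise ValueError("no query sets given")
    rng = np.random.default_rng(config.random_seed)
    metrics = []
    for _ in range(config.n_random_runs):
        shuffled = []
        for qs in query_sets:
            cands = [replace(c, rank_score=float(rng.random())) for c in qs.candidates]
            shuffled.append(SentenceQuerySet(qs.doc_id, qs.sentence_span, cands))
        thresholds = oracle_thresholds(shuffled, "worst", config)
        retained = [apply_filter(qs, t) for qs, t in zip(shuffled, thresholds)]
        metrics.append(prf_from_query_sets(shuffled, retained, total_gold))
    arr = np.asarray(metrics)
    return tuple(float(v) for v in arr.mean(axis=0))
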