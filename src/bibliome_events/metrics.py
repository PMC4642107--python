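"""Network- and event-level scoring.

Networks are scored with precision/recall/F and the Slot Error Rate
SER = (substitutions + insertions + deletions) / |gold|, where slots are
ordered (agent, target) pairs.  In *strict* mode a predicted edge on a
gold pair must also carry the gold interaction type to count as a match
(a type mismatch is a substitution); *relaxed* mode ignores the type.
Official shared-task scorers may weight substitutions differently, so
numbers produced here are internally consistent but not byte-compatible
with hosted evaluation services.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .grn import GRNInteraction
from .rerank import event_type_group, label_candidates
from .standoff import EventAnnotation, GoldRelationRecord

__all__ = ["NetworkScore", "EventScore", "score_network", "score_events"]


@dataclass(frozen=True)
class NetworkScore:
    matches: int
    substitutions: int
    insertions: int
    deletions: int
    precision: float
    recall: float
    f_score: float
    ser: float


@dataclass(frozen=True)
class EventScore:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_score: float
    per_group: dict[str, tuple[int, int, int]] = field(default_factory=dict)


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    f = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return precision, recall, f


def score_network(
    predicted: list[GRNInteraction],
    gold: list[GoldRelationRecord],
    mode: str = "strict",
) -> NetworkScore:
    """Score a predicted network against a gold one.

    Pairing is on the ordered (agent_id, target_id) slot.  A gold edge is
    a match when a predicted edge exists on its pair with the same type
    (strict) or regardless of type (relaxed); a substitution when a
    predicted edge exists but only with a different type (strict only);
    a deletion otherwise.  Predicted edges on pairs absent from gold are
    insertions.  If several predictions share one pair (which edge
    selection normally prevents) the highest-confidence one is paired
    and the rest count as insertions.
    """
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"unknown mode {mode!r}")
    if not gold:
        raise ValueError("SER is undefined for an empty gold network")

    pred_by_pair: dict[tuple[str, str], GRNInteraction] = {}
    insertions = 0
    for p in sorted(predicted, key=lambda p: -p.confidence):
        pair = (p.agent_id, p.target_id)
        if pair in pred_by_pair:
            insertions += 1  # surplus prediction on an already-paired slot
        else:
            pred_by_pair[pair] = p

    matches = substitutions = deletions = 0
    gold_pairs = set()
    for g in gold:
        pair = (g.agent_id, g.target_id)
        gold_pairs.add(pair)
        p = pred_by_pair.get(pair)
        if p is None:
            deletions += 1
        elif mode == "relaxed" or p.grn_type == g.interaction_type:
            matches += 1
        else:
            substitutions += 1
    insertions += sum(1 for pair in pred_by_pair if pair not in gold_pairs)

    n_gold = len(gold)
    precision = matches / len(predicted) if predicted else 1.0
    recall = matches / n_gold
    f = (
        2 * precision * recall / (precision + recall)
        if (precision + recall)
        else 0.0
    )
    ser = (substitutions + insertions + deletions) / n_gold
    return NetworkScore(matches, substitutions, insertions, deletions,
                        precision, recall, f, ser)


def score_events(
    predicted: dict[str, list[EventAnnotation]],
    gold: dict[str, list[EventAnnotation]],
    span_tolerance: int = 0,
) -> EventScore:
    """Score predicted events against gold per document, with groups.

    ``predicted``/``gold`` map doc ids to event lists.  Matching uses the
    recursive structural criterion of the re-ranking labeler; the
    per-group breakdown keys each event by its type group (Simple,
    Protein_mod, Binding, Regulation, Other).
    """
    tp = fp = fn = 0
    per_group: dict[str, list[int]] = {}

    def bump(group: str, slot: int) -> None:
        per_group.setdefault(group, [0, 0, 0])[slot] += 1

    for doc_id in sorted(set(predicted) | set(gold)):
        preds = predicted.get(doc_id, [])
        golds = gold.get(doc_id, [])
        cands = label_candidates(preds, golds, span_tolerance)
        matched_gold = sum(1 for c in cands if c.label == "tp")
        for c in cands:
            group = event_type_group(c.event.event_type)
            if c.label == "tp":
                tp += 1
                bump(group, 0)
            else:
                fp += 1
                bump(group, 1)
        # unmatched gold events are false negatives
        doc_fn = len(golds) - matched_gold
        fn += doc_fn
        # attribute fns to groups by re-running the greedy match bookkeeping
        if doc_fn:
            matched_sigs = _matched_gold_indices(preds, golds, span_tolerance)
            for j, g in enumerate(golds):
                if j not in matched_sigs:
                    bump(event_type_group(g.event_type), 2)

    precision, recall, f = _prf(tp, fp, fn)
    groups = {g: tuple(v) for g, v in per_group.items()}
    return EventScore(tp, fp, fn, precision, recall, f, groups)


def _matched_gold_indices(preds, golds, span_tolerance):
    """Indices of gold events absorbed by the greedy matching."""
    from .rerank import _event_signature, _signatures_match

    taken: set[int] = set()
    order = sorted(range(len(preds)), key=lambda i: (-preds[i].confidence, i))
    for i in order:
        sig = _event_signature(preds[i])
        for j, g in enumerate(golds):
            if j in taken:
                continue
            if _signatures_match(sig, _event_signature(g), span_tolerance):
                taken.add(j)
                break
    return taken
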