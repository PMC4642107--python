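"""Re-ranking: labeling, features, ranking, thresholds, oracles."""

import numpy as np
import pytest

from bibliome_events.events import EventIndex, build_event_index, canonicalize
from bibliome_events.rerank import (
    CandidateEvent,
    RerankConfig,
    SentenceQuerySet,
    apply_filter,
    extract_event_features,
    label_candidates,
    oracle_thresholds,
    prf_from_query_sets,
    random_rank_baseline,
    score_events,
    sentence_f_score,
    threshold_target,
    train_ranker,
    train_threshold_regressor,
)
from bibliome_events.simulate import GeneratorConfig, generate, make_labeled_querysets
from bibliome_events.standoff import (
    EntityAnnotation,
    EventAnnotation,
    EventArgument,
    TextSpan,
)


def _ent(eid, symbol, etype="Protein", start=0):
    return EntityAnnotation(eid, etype, TextSpan(start, start + len(symbol), symbol))


def _event(eid, etype="Binding", trig=(10, 15, "binds"), args=None, conf=0.9):
    args = args or (EventArgument("Theme", _ent("T1", "sigB")),)
    return EventAnnotation(eid, etype, TextSpan(*trig), tuple(args), confidence=conf)


class TestLabelCandidates:
    def test_identical_prediction_is_tp(self):
        gold = _event("G1")
        pred = _event("P1", conf=0.5)
        assert label_candidates([pred], [gold])[0].label == "tp"

    def test_wrong_event_type_is_fp(self):
        gold = _event("G1", "Gene_expression", trig=(10, 15, "binds"))
        pred = _event("P1", "Binding", trig=(10, 15, "binds"))
        assert label_candidates([pred], [gold])[0].label == "fp"

    def test_one_gold_absorbs_one_of_two_identical_predictions(self):
        gold = _event("G1")
        preds = [_event("P1", conf=0.3), _event("P2", conf=0.8)]
        labels = [c.label for c in label_candidates(preds, [gold])]
        assert sorted(labels) == ["fp", "tp"]
        # greedy by confidence: the higher-confidence twin wins
        assert labels == ["fp", "tp"]

    def test_nested_arguments_matched_recursively(self):
        inner_g = _event("GI", "Transcription", trig=(20, 22, "tx"))
        gold = _event("G1", "Positive_regulation", trig=(0, 4, "acts"),
                      args=(EventArgument("Theme", inner_g),))
        inner_p = _event("PI", "Transcription", trig=(20, 22, "tx"))
        pred_good = _event("P1", "Positive_regulation", trig=(0, 4, "acts"),
                           args=(EventArgument("Theme", inner_p),))
        inner_bad = _event("PB", "Gene_expression", trig=(20, 22, "tx"))
        pred_bad = _event("P2", "Positive_regulation", trig=(0, 4, "acts"),
                          args=(EventArgument("Theme", inner_bad),))
        labels = label_candidates([pred_good, pred_bad], [gold, inner_g])
        assert labels[0].label == "tp"
        assert labels[1].label == "fp"

    def test_span_tolerance(self):
        gold = _event("G1", trig=(10, 15, "binds"))
        pred = _event("P1", trig=(11, 16, "inds "))
        assert label_candidates([pred], [gold])[0].label == "fp"
        assert label_candidates([pred], [gold], span_tolerance=2)[0].label == "tp"


def _qs(cands, doc_id="d"):
    return SentenceQuerySet(doc_id, TextSpan(0, 50, "x" * 50), cands)


def _cand(score, label, conf=0.5, eid="E1", etype="Binding", event=None):
    ev = event or _event(eid, etype, conf=conf)
    return CandidateEvent(event=ev, base_confidence=conf, label=label,
                          rank_score=score)


class TestFeatures:
    def test_empty_index_gives_zero_bibliome_counts(self):
        cand = _cand(0.0, "unknown")
        feats = extract_event_features(cand, _qs([cand]), EventIndex())
        assert feats["bib:canonical:count"] == 0.0
        assert feats["bib:pair_count"] == 0.0

    def test_sole_candidate_has_no_co_candidates(self):
        cand = _cand(0.0, "unknown")
        feats = extract_event_features(cand, _qs([cand]), EventIndex())
        assert feats["sent:n_others"] == 0.0
        assert "sent:mean_conf" not in feats

    def test_exact_key_stats_surface(self):
        from bibliome_events.standoff import Document

        ev = _event("E1", conf=0.9)
        docs = [Document("d", "x" * 40, [], [
            _event(f"E{i}", conf=c) for i, c in enumerate((0.2, 0.9, 0.5, 0.7, 0.1))
        ], [])]
        index = build_event_index(docs)
        cand = _cand(0.0, "unknown", event=ev)
        feats = extract_event_features(cand, _qs([cand]), index)
        assert feats["bib:canonical:count"] == 5.0
        assert feats["bib:canonical:max_conf"] == pytest.approx(0.9)


class TestThresholdTarget:
    def test_mixed_sentence_cuts_at_last_retained(self):
        qs = _qs([_cand(0.9, "tp"), _cand(0.1, "fp")])
        assert threshold_target(qs) == pytest.approx(0.9)

    def test_all_fp_fallback(self):
        qs = _qs([_cand(0.3, "fp"), _cand(0.1, "fp")])
        assert threshold_target(qs) == pytest.approx(0.5)

    def test_all_tp_fallback(self):
        qs = _qs([_cand(0.1, "tp"), _cand(0.6, "tp")])
        assert threshold_target(qs) == pytest.approx(-0.1)

    def test_agrees_with_exhaustive_search(self):
        """Independent oracle: try every candidate score as threshold."""
        rng = np.random.default_rng(3)
        for _ in range(300):
            n = int(rng.integers(2, 11))
            labels = ["tp" if rng.random() < 0.5 else "fp" for _ in range(n)]
            if len(set(labels)) < 2:
                continue
            scores = rng.normal(size=n)
            qs = _qs([_cand(float(s), l) for s, l in zip(scores, labels)])
            total_tp = labels.count("tp")

            def f_at(threshold):
                kept = [l for s, l in zip(scores, labels) if s >= threshold]
                return sentence_f_score(kept, total_tp)

            candidates = sorted(set(scores))
            best_f = max([f_at(t) for t in candidates] + [f_at(max(scores) + 1)])
            chosen = threshold_target(qs)
            assert f_at(chosen) == pytest.approx(best_f)
            # the chosen threshold is an attained score (mixed sentence)
            assert any(np.isclose(chosen, s) for s in scores)


class TestApplyFilter:
    def test_threshold_below_all_is_identity(self):
        qs = _qs([_cand(0.5, "tp"), _cand(0.2, "fp")])
        assert len(apply_filter(qs, -10)) == 2

    def test_threshold_above_all_removes_everything(self):
        qs = _qs([_cand(0.5, "tp"), _cand(0.2, "fp")])
        assert apply_filter(qs, 10) == []

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(11)
        cands = [_cand(float(s), "tp") for s in rng.normal(size=8)]
        qs = _qs(cands)
        sizes = [len(apply_filter(qs, t)) for t in np.linspace(-3, 3, 25)]
        assert sizes == sorted(sizes, reverse=True)

    def test_cascade_removes_parent_of_removed_theme(self):
        inner = _event("EI", "Transcription", trig=(20, 22, "tx"))
        outer = _event("EO", "Positive_regulation", trig=(0, 4, "acts"),
                       args=(EventArgument("Theme", inner),))
        c_in = CandidateEvent(inner, 0.9, "tp", rank_score=0.1)
        c_out = CandidateEvent(outer, 0.9, "tp", rank_score=0.9)
        kept = apply_filter(_qs([c_in, c_out]), 0.5)
        assert kept == []  # inner removed by score, outer cascaded


@pytest.fixture(scope="module")
def trained():
    config = GeneratorConfig(seed=5, n_genes=12, n_edges=24, n_docs=12,
                             mentions_per_edge=3, sentences_per_doc=14)
    docs, truth = generate(config)
    canon = {canonicalize(k): v for k, v in truth.symbol_table.items()}
    index = build_event_index(docs, canon)
    query_sets = make_labeled_querysets(docs, truth)
    rc = RerankConfig(random_seed=5)
    model = train_ranker(query_sets, index, rc, canon)
    scored = [score_events(model, qs, index) for qs in query_sets]
    return model, scored, index, query_sets, rc


class TestRankerAndRegressor:
    def test_training_needs_a_mixed_sentence(self):
        qs = _qs([_cand(0.0, "tp")])
        with pytest.raises(ValueError, match="mixed"):
            train_ranker([qs], EventIndex())

    def test_ranker_orders_most_mixed_sentences_correctly(self, trained):
        _, scored, *_ = trained
        good = bad = 0
        for qs in scored:
            tps = [c.rank_score for c in qs.candidates if c.label == "tp"]
            fps = [c.rank_score for c in qs.candidates if c.label == "fp"]
            if tps and fps:
                if min(tps) > max(fps):
                    good += 1
                else:
                    bad += 1
        assert good > bad

    def test_ranker_is_seed_deterministic(self, trained):
        model, _, index, query_sets, rc = trained
        again = train_ranker(query_sets, index, rc, model.symbol_table)
        assert np.allclose(model.weights, again.weights)

    def test_scoring_is_deterministic(self, trained):
        model, scored, index, query_sets, _ = trained
        rescored = [score_events(model, qs, index) for qs in query_sets]
        for a, b in zip(scored, rescored):
            assert [c.rank_score for c in a.candidates] == \
                   [c.rank_score for c in b.candidates]

    def test_regressor_recovers_linear_target(self):
        """Exact linear fit: targets linear in the sentence features."""
        rng = np.random.default_rng(2)
        query_sets = []
        for _ in range(40):
            n = int(rng.integers(1, 5))
            cands = [_cand(float(rng.normal()), "unknown",
                           conf=float(rng.uniform(0.1, 1.0))) for _ in range(n)]
            query_sets.append(_qs(cands))
        from bibliome_events.rerank import sentence_features

        weights = {"score_mean": 0.7, "n_candidates": -0.15, "conf_max": 0.4}
        targets = [
            sum(weights.get(k, 0.0) * v for k, v in sentence_features(qs).items()) + 0.25
            for qs in query_sets
        ]
        reg = train_threshold_regressor(query_sets, RerankConfig(random_seed=0),
                                        targets=targets)
        preds = [reg.predict(qs) for qs in query_sets]
        assert np.allclose(preds, targets, atol=1e-3)

    def test_constant_targets_give_constant_regressor(self):
        qs1 = _qs([_cand(0.3, "fp"), _cand(0.1, "fp")])
        qs2 = _qs([_cand(0.3, "fp"), _cand(0.1, "fp")])
        reg = train_threshold_regressor([qs1, qs2])
        assert reg.constant_value == pytest.approx(0.5)


class TestOracles:
    def test_all_fp_sentence_best_removes_worst_retains(self):
        qs = _qs([_cand(0.4, "fp"), _cand(0.1, "fp")])
        best = oracle_thresholds([qs], "best")[0]
        worst = oracle_thresholds([qs], "worst")[0]
        assert apply_filter(qs, best) == []
        assert len(apply_filter(qs, worst)) == 2

    def test_mixed_separable_sentence_oracles_agree(self):
        qs = _qs([_cand(0.9, "tp"), _cand(0.1, "fp")])
        assert oracle_thresholds([qs], "best") == oracle_thresholds([qs], "worst")

    def test_best_f_at_least_worst_f(self, noisy_corpus):
        docs, truth = noisy_corpus
        rng = np.random.default_rng(0)
        query_sets = []
        for qs in make_labeled_querysets(docs, truth):
            cands = [CandidateEvent(c.event, c.base_confidence, c.label,
                                    rank_score=float(rng.normal()))
                     for c in qs.candidates]
            query_sets.append(SentenceQuerySet(qs.doc_id, qs.sentence_span, cands))
        bf = prf_from_query_sets(query_sets, [
            apply_filter(q, t) for q, t in zip(query_sets,
                                               oracle_thresholds(query_sets, "best"))
        ])[2]
        wf = prf_from_query_sets(query_sets, [
            apply_filter(q, t) for q, t in zip(query_sets,
                                               oracle_thresholds(query_sets, "worst"))
        ])[2]
        assert bf >= wf

    def test_random_baseline_reproducible(self, noisy_corpus):
        docs, truth = noisy_corpus
        query_sets = make_labeled_querysets(docs, truth)
        config = RerankConfig(random_seed=9, n_random_runs=3)
        assert random_rank_baseline(query_sets, config) == \
            random_rank_baseline(query_sets, config)

    def test_empty_query_set_list_rejected(self):
        with pytest.raises(ValueError):
            random_rank_baseline([])
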