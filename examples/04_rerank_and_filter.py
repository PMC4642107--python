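"""Re-rank event predictions per sentence and filter false positives.

A pairwise-ranking linear SVM scores each candidate event inside its
sentence using event, sentence-context and bibliome-wide features; a
linear regressor then predicts a per-sentence score threshold.  Oracle
thresholds (per-sentence F-maximizing cutoffs with gold access) bound
what the ranker could achieve: best case may empty all-false-positive
sentences, worst case may not.
"""

from dataclasses import replace

from bibliome_events.events import build_event_index, canonicalize
from bibliome_events.rerank import (
    RerankConfig, apply_filter, oracle_thresholds, prf_from_query_sets,
    random_rank_baseline, score_events, train_ranker, train_threshold_regressor,
)
from bibliome_events.simulate import GeneratorConfig, generate, make_labeled_querysets

config = GeneratorConfig(seed=1)
train_docs, train_truth = generate(replace(config, seed=3))
eval_docs, eval_truth = generate(replace(config, seed=4))
canon = lambda t: {canonicalize(k): v for k, v in t.items()}

train_index = build_event_index(train_docs, canon(train_truth.symbol_table))
eval_index = build_event_index(eval_docs, canon(eval_truth.symbol_table))
train_qs = make_labeled_querysets(train_docs, train_truth)
eval_qs = make_labeled_querysets(eval_docs, eval_truth)

rc = RerankConfig(random_seed=1)
model = train_ranker(train_qs, train_index, rc, canon(train_truth.symbol_table))
regressor = train_threshold_regressor(
    [score_events(model, q, train_index) for q in train_qs], rc)
scored = [score_events(model, q, eval_index) for q in eval_qs]


def report(name, retained):
    p, r, f = prf_from_query_sets(scored, retained)
    print(f"{name:28s} P {100*p:5.1f}  R {100*r:5.1f}  F {100*f:5.1f}")


report("unfiltered baseline", [list(q.candidates) for q in scored])
report("ranker + regressed threshold",
       [apply_filter(q, regressor.predict(q)) for q in scored])
for mode in ("best", "worst"):
    thresholds = oracle_thresholds(scored, mode, rc)
    report(f"{mode}-case oracle",
           [apply_filter(q, t) for q, t in zip(scored, thresholds)])
p, r, f = random_rank_baseline(scored, rc)
print(f"{'worst-case oracle (random)':28s} P {100*p:5.1f}  R {100*r:5.1f}  F {100*f:5.1f}")
# The learned system trades recall for precision; the oracle rows bound
# how much of the remaining gap is attributable to threshold regression.
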