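"""Learn the event-type -> network-type mapping with per-type SVMs.

One RBF-kernel SVM per interaction type is trained on bibliome count
and confidence features of each gene pair, with (C, gamma) grid-searched
under 5-fold cross-validation.  Combined with the rule-based entity
filter (the hybrid system) it reproduces the rule-based network on
held-out documents from the same generator.
"""

import warnings

from bibliome_events.grn import (
    MLConversionConfig,
    collect_candidate_pairs,
    convert_ml,
    convert_rule_based,
    label_pairs_from_gold,
    train_type_classifiers,
)
from bibliome_events.simulate import GeneratorConfig, generate

train_docs, train_truth = generate(GeneratorConfig.zero_noise(
    seed=1, n_genes=40, n_edges=140, n_docs=80, mentions_per_edge=5))
held_docs, held_truth = generate(GeneratorConfig.zero_noise(seed=2))

pairs, feats = collect_candidate_pairs(train_docs, train_truth.symbol_table)
labels = label_pairs_from_gold(pairs, train_truth.planted)
config = MLConversionConfig(random_seed=1)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    classifiers = train_type_classifiers(feats, labels, config)

for grn_type, clf in classifiers.items():
    status = "constant (no positives)" if clf.constant else f"best {clf.best_params}"
    print(f"{grn_type:14s} {status}")

ml_net = convert_ml(held_docs, held_truth.symbol_table, classifiers, "hybrid", config)
rule_net = convert_rule_based(held_docs, held_truth.symbol_table)
ml_set = {(i.agent_id, i.target_id, i.grn_type) for i in ml_net}
rule_set = {(i.agent_id, i.target_id, i.grn_type) for i in rule_net}
print(f"\nheld-out edges: ml {len(ml_set)}, rule-based {len(rule_set)}, "
      f"identical: {ml_set == rule_set}")
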