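"""Convert a noisy synthetic bibliome into a typed regulatory network.

Shows the rule-based conversion pipeline (type mapping, entity-type
filtering, Binding refactoring, one-edge-per-pair selection) and the
effect of the entity-type filter on strict precision and the Slot
Error Rate (SER = (substitutions + insertions + deletions) / |gold|;
below 1 is useful, 0 is perfect).
"""

from bibliome_events.grn import convert_rule_based, convert_unfiltered
from bibliome_events.metrics import score_network
from bibliome_events.simulate import GeneratorConfig, generate

docs, truth = generate(GeneratorConfig(seed=1))

for label, convert in (("type conversion only  ", convert_unfiltered),
                       ("with entity filtering ", convert_rule_based)):
    network = convert(docs, truth.symbol_table)
    score = score_network(network, truth.planted, "strict")
    print(f"{label}: {len(network):3d} edges  "
          f"P {score.precision:.3f}  R {score.recall:.3f}  SER {score.ser:.3f}")

# Entity-type filtering removes edges whose agent/target entity types are
# implausible for the interaction (e.g. protein-protein Bindings), which
# raises precision and drives SER toward zero without losing true edges.
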