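"""Generate a synthetic bibliome and inspect what it contains.

A planted regulatory network of 12 genes is realized as template
sentences carrying nested event annotations; 30% of all events are
injected false positives whose confidences are drawn from a lower Beta
distribution than the correct events'.
"""

from collections import Counter

from bibliome_events.simulate import GeneratorConfig, generate

config = GeneratorConfig(seed=1, n_genes=12, n_edges=24, n_docs=12,
                         mentions_per_edge=3, sentences_per_doc=14)
docs, truth = generate(config)

n_events = sum(len(d.events) for d in docs)
labels = Counter(truth.labels.values())
print(f"documents:        {len(docs)}")
print(f"planted edges:    {len(truth.planted)}")
print(f"events:           {n_events} "
      f"({labels['tp']} correct, {labels['fp']} false positives)")
print(f"planted types:    {Counter(g.interaction_type for g in truth.planted)}")

doc = docs[0]
print(f"\nfirst sentence of {doc.doc_id}: {doc.sentence_spans[0].text!r}")
ev = doc.events[0]
print(f"first event: {ev.event_type} trigger={ev.trigger.text!r} "
      f"confidence={ev.confidence:.2f} "
      f"label={truth.labels[(doc.doc_id, ev.id)]}")
# The event's arguments show the nesting: a regulation whose Theme may
# itself be a Transcription event over the target gene.
for arg in ev.arguments:
    kind = arg.ref.event_type if arg.is_event else arg.ref.entity_type
    print(f"  {arg.role}: {kind}")
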