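"""Seeded synthetic bibliome generator.

Generates a corpus of template-text documents carrying nested event
annotations around a planted, typed gene regulatory network, so that
every other module can be exercised end to end without any external
corpus.  The generator emulates the structural and statistical features
that matter downstream — nested event structures, per-event confidence
scores correlated with correctness, lexical gene-symbol variants,
injected false-positive events with a configurable type-confusion
process — while making no attempt at linguistic realism (each sentence
is a short template clause; one sentence per text line).

Every planted edge is realized by one or more mentions whose event
structure converts back to the edge's network type under the rule-based
pipeline, and whose entity types satisfy the entity-type filter; with
all noise rates at zero, the rule-based conversion therefore recovers
the planted network exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rerank import CandidateEvent, SentenceQuerySet, label_candidates
from .standoff import (
    Document,
    EntityAnnotation,
    EventAnnotation,
    EventArgument,
    GoldRelationRecord,
    TextSpan,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "GeneratorConfigError",
    "COARSE_MENU",
    "generate",
    "make_labeled_querysets",
]


class GeneratorConfigError(ValueError):
    """Unsatisfiable or invalid generator configuration."""


#: Realizable coarse event types, the axis of the type-confusion matrix.
COARSE_MENU = (
    "None:Binding",
    "Positive:Other", "Negative:Other", "Unspecified:Other",
    "Positive:Transcription", "Negative:Transcription", "Unspecified:Transcription",
    "Positive:GeneExpression", "Negative:GeneExpression", "Unspecified:GeneExpression",
)


def _default_type_distribution() -> dict[str, float]:
    # Binding mass is zero by default: the conversion pipeline refactors
    # every Binding edge to Transcription, so a planted Binding edge could
    # never be recovered strictly.  Binding STRUCTURES still occur as one
    # realization of Transcription edges.
    return {
        "Transcription": 0.35,
        "Activation": 0.30,
        "Inhibition": 0.20,
        "Regulation": 0.15,
        "Binding": 0.0,
    }


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic bibliome.

    ``fp_rate`` is the expected fraction of all generated events that
    are injected false positives; ``type_confusion`` is a row-stochastic
    matrix over :data:`COARSE_MENU` applied when realizing them.
    ``conf_correct``/``conf_incorrect`` are Beta parameters for the
    confidence of correct vs incorrect events — the defaults Beta(5, 2)
    vs Beta(2, 5) give the correctness/confidence correlation the
    re-ranker exploits.  ``variant_rate`` is the chance a mention uses a
    non-base lexical variant of its gene symbol; ``unmatched_symbol_rate``
    the chance it uses a symbol absent from the gold symbol table.
    """

    n_genes: int = 30
    n_edges: int = 60
    n_docs: int = 40
    sentences_per_doc: int = 12
    mentions_per_edge: int = 4
    type_distribution: dict[str, float] = field(default_factory=_default_type_distribution)
    fp_rate: float = 0.3
    type_confusion: np.ndarray | None = None  # default: uniform rows
    conf_correct: tuple[float, float] = (5.0, 2.0)
    conf_incorrect: tuple[float, float] = (2.0, 5.0)
    variant_rate: float = 0.2
    unmatched_symbol_rate: float = 0.05
    plant_requirement_rate: float = 0.0
    fp_same_sentence_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_edges, self.n_docs,
               self.sentences_per_doc, self.mentions_per_edge) < 1:
            raise GeneratorConfigError("size parameters must be positive")
        if self.n_edges > self.n_genes * (self.n_genes - 1):
            raise GeneratorConfigError("n_edges exceeds the number of ordered gene pairs")
        total = sum(self.type_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise GeneratorConfigError("type_distribution must sum to 1")
        if not (0 <= self.fp_rate < 1):
            raise GeneratorConfigError("fp_rate must be in [0, 1)")
        for pair in (self.conf_correct, self.conf_incorrect):
            if min(pair) <= 0:
                raise GeneratorConfigError("Beta parameters must be positive")
        if self.type_confusion is not None:
            m = np.asarray(self.type_confusion, dtype=float)
            if m.shape != (len(COARSE_MENU), len(COARSE_MENU)):
                raise GeneratorConfigError("type_confusion has the wrong shape")
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
                raise GeneratorConfigError("type_confusion rows must sum to 1")

    @classmethod
    def zero_noise(cls, **overrides) -> "GeneratorConfig":
        """Conditions under which the planted network is exactly recoverable."""
        params = dict(fp_rate=0.0, variant_rate=0.0, unmatched_symbol_rate=0.0)
        params.update(overrides)
        return cls(**params)


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated corpus."""

    planted: list[GoldRelationRecord]
    symbol_table: dict[str, str]  # surface -> standardized id
    labels: dict[tuple[str, str], str]  # (doc_id, event_id) -> tp | fp
    gold_events: dict[str, list[EventAnnotation]]  # doc_id -> true events


# ---------------------------------------------------------------------------
# Gene vocabulary
# ---------------------------------------------------------------------------

def _gene_lexicon(n_genes: int) -> tuple[list[str], list[list[str]], dict[str, str]]:
    """Standardized ids, surface variant pools, and the symbol table."""
    ids, variants = [], []
    table: dict[str, str] = {}
    for i in range(n_genes):
        stem = f"{chr(ord('A') + i % 26)}{i // 26}"
        gid = f"g{i:03d}"
        pool = [f"Sg{stem}", f"sg{stem}", f"Sg-{stem}", f"sigma{stem}"]
        ids.append(gid)
        variants.append(pool)
        for surface in pool:
            table[surface] = gid
    return ids, variants, table


# ---------------------------------------------------------------------------
# Clause realization
# ---------------------------------------------------------------------------

@dataclass
class _Clause:
    """One template clause: text plus relative-offset annotations."""

    text: str
    # (key, rel_start, rel_end, surface, entity_type) for entity mentions
    mentions: list[tuple[str, int, int, str, str]]
    # (local_event_key, event_type, trig_rel_start, trig_rel_end, trig_text,
    #  [(role, ref_key)]) -- ref_key names a mention or another event key
    events: list[tuple[str, str, int, int, str, list[tuple[str, str]]]]
    label: str  # tp | fp, applied to every event of the clause


def _assemble(parts) -> tuple[str, dict[str, tuple[int, int, str]]]:
    """Concatenate text parts, recording offsets of named spans."""
    text = ""
    spans: dict[str, tuple[int, int, str]] = {}
    for part in parts:
        if isinstance(part, str):
            text += part
        else:
            key, chunk = part
            spans[key] = (len(text), len(text) + len(chunk), chunk)
            text += chunk
    return text, spans


_LAYER_VERBS = {
    "Positive_regulation": "activates",
    "Negative_regulation": "inhibits",
    "Regulation": "regulates",
}
_LAYER_OF_COARSE = {
    "Positive": "Positive_regulation",
    "Negative": "Negative_regulation",
    "Unspecified": "Regulation",
}
_INNER_NOUNS = {
    "Transcription": "transcription",
    "Gene_expression": "expression",
    "Positive_regulation": "activation",
    "Negative_regulation": "repression",
}


def _clause_direct(reg_type: str, a: tuple[str, str], b: tuple[str, str],
                   label: str) -> _Clause:
    """``A <verb> B.`` — a single regulation event with entity Theme."""
    a_sym, a_et = a
    b_sym, b_et = b
    verb = _LAYER_VERBS[reg_type]
    text, spans = _assemble([
        ("A", a_sym), " ", ("V", verb), " ", ("B", b_sym), ".",
    ])
    return _Clause(
        text=text,
        mentions=[("A", *spans["A"], a_et), ("B", *spans["B"], b_et)],
        events=[("E", reg_type, *spans["V"], [("Theme", "B"), ("Cause", "A")])],
        label=label,
    )


def _clause_nested(outer_type: str, inner_type: str, a: tuple[str, str],
                   b: tuple[str, str], label: str) -> _Clause:
    """``A <verb> the <noun> of B.`` — regulation over a nested event."""
    a_sym, a_et = a
    b_sym, b_et = b
    verb = _LAYER_VERBS[outer_type]
    noun = _INNER_NOUNS[inner_type]
    text, spans = _assemble([
        ("A", a_sym), " ", ("V", verb), " the ", ("N", noun),
        " of ", ("B", b_sym), ".",
    ])
    return _Clause(
        text=text,
        mentions=[("A", *spans["A"], a_et), ("B", *spans["B"], b_et)],
        events=[
            ("Ein", inner_type, *spans["N"], [("Theme", "B")]),
            ("E", outer_type, *spans["V"], [("Theme", "Ein"), ("Cause", "A")]),
        ],
        label=label,
    )


def _clause_binding(a: tuple[str, str], b: tuple[str, str], label: str) -> _Clause:
    """``B binds the A promoter.`` — Binding with two entity Themes."""
    a_sym, a_et = a
    b_sym, b_et = b
    text, spans = _assemble([
        ("B", b_sym), " ", ("V", "binds"), " the ", ("A", a_sym), " promoter.",
    ])
    return _Clause(
        text=text,
        mentions=[("B", *spans["B"], b_et), ("A", *spans["A"], a_et)],
        events=[("E", "Binding", *spans["V"], [("Theme", "B"), ("Theme", "A")])],
        label=label,
    )


def _clause_plain(a: tuple[str, str], b: tuple[str, str]) -> _Clause:
    """A mention sentence with no extractable event structure."""
    a_sym, a_et = a
    b_sym, b_et = b
    text, spans = _assemble([
        ("A", a_sym), " is required together with ", ("B", b_sym), ".",
    ])
    return _Clause(
        text=text,
        mentions=[("A", *spans["A"], a_et), ("B", *spans["B"], b_et)],
        events=[],
        label="tp",
    )


_ALL_ENTITY_TYPES = (
    "Gene", "Protein", "Operon", "PolymeraseComplex", "ProteinComplex", "GGP", "Other",
)


def _realize_true_mention(rng: np.random.Generator, grn_type: str) -> "callable":
    """Pick a realization whose conversion yields ``grn_type`` again.

    Returns a function (agent, target) -> _Clause; entity types are
    chosen to satisfy the entity-type filter for the realized structure.
    """
    def reg_agent_et() -> str:
        return str(rng.choice(["Gene", "Operon", "Protein", "ProteinComplex"],
                              p=[0.5, 0.15, 0.25, 0.1]))

    def reg_target_et() -> str:
        return str(rng.choice(["Protein", "PolymeraseComplex"], p=[0.85, 0.15]))

    if grn_type == "Transcription":
        kind = rng.choice(["reg_tx", "reg_gx", "binding"], p=[0.45, 0.25, 0.3])
        if kind == "binding":
            def build(a_sym, b_sym):
                return _clause_binding((a_sym, "Gene"), (b_sym, "Protein"), "tp")
            return build
        inner = "Transcription" if kind == "reg_tx" else "Gene_expression"
        outer = _LAYER_OF_COARSE[rng.choice(["Positive", "Negative", "Unspecified"])]
        agent_et = str(rng.choice(["Gene", "Operon"], p=[0.8, 0.2]))
        target_et = reg_target_et()

        def build(a_sym, b_sym):
            return _clause_nested(outer, inner, (a_sym, agent_et), (b_sym, target_et), "tp")
        return build

    if grn_type == "Binding":
        def build(a_sym, b_sym):
            return _clause_binding((a_sym, "Gene"), (b_sym, "Protein"), "tp")
        return build

    agent_et, target_et = reg_agent_et(), reg_target_et()
    if grn_type == "Activation":
        if rng.random() < 0.3:  # double negative composes to Positive
            def build(a_sym, b_sym):
                return _clause_nested("Negative_regulation", "Negative_regulation",
                                      (a_sym, agent_et), (b_sym, target_et), "tp")
            return build

        def build(a_sym, b_sym):
            return _clause_direct("Positive_regulation",
                                  (a_sym, agent_et), (b_sym, target_et), "tp")
        return build
    if grn_type == "Inhibition":
        if rng.random() < 0.3:  # positive regulation of a repression
            def build(a_sym, b_sym):
                return _clause_nested("Positive_regulation", "Negative_regulation",
                                      (a_sym, agent_et), (b_sym, target_et), "tp")
            return build

        def build(a_sym, b_sym):
            return _clause_direct("Negative_regulation",
                                  (a_sym, agent_et), (b_sym, target_et), "tp")
        return build
    # Regulation
    def build(a_sym, b_sym):
        return _clause_direct("Regulation", (a_sym, agent_et), (b_sym, target_et), "tp")
    return build


def _realize_fp(rng: np.random.Generator, coarse: str,
                a_sym: str, b_sym: str) -> _Clause:
    """Realize a false-positive event of the given coarse type."""
    a = (a_sym, str(rng.choice(_ALL_ENTITY_TYPES)))
    b = (b_sym, str(rng.choice(_ALL_ENTITY_TYPES)))
    layer, base = coarse.split(":")
    if base == "Binding":
        return _clause_binding(a, b, "fp")
    outer = _LAYER_OF_COARSE[layer]
    if base == "Other":
        return _clause_direct(outer, a, b, "fp")
    inner = "Transcription" if base == "Transcription" else "Gene_expression"
    return _clause_nested(outer, inner, a, b, "fp")


# ---------------------------------------------------------------------------
# Corpus assembly
# ---------------------------------------------------------------------------

def generate(config: GeneratorConfig) -> tuple[list[Document], SyntheticTruth]:
    """Generate a corpus and its ground truth, reproducibly by seed."""
    rng = np.random.default_rng(config.seed)
    gene_ids, gene_variants, symbol_table = _gene_lexicon(config.n_genes)

    # ---- planted network -------------------------------------------------
    n_pairs = config.n_genes * (config.n_genes - 1)
    pair_idx = rng.choice(n_pairs, size=config.n_edges, replace=False)
    types = list(config.type_distribution)
    probs = np.array([config.type_distribution[t] for t in types])
    planted: list[GoldRelationRecord] = []
    edges: list[tuple[int, int, str]] = []
    for k in sorted(int(x) for x in pair_idx):
        i, j = divmod(k, config.n_genes - 1)
        j = j if j < i else j + 1  # skip the diagonal
        if config.plant_requirement_rate and rng.random() < config.plant_requirement_rate:
            grn_type = "Requirement"
        else:
            grn_type = str(rng.choice(types, p=probs))
        planted.append(GoldRelationRecord(gene_ids[i], gene_ids[j], grn_type))
        edges.append((i, j, grn_type))

    # ---- surface symbol choice -------------------------------------------
    unk_counter = [0]

    def surface(gene: int) -> str:
        if config.unmatched_symbol_rate and rng.random() < config.unmatched_symbol_rate:
            unk_counter[0] += 1
            return f"Unk{unk_counter[0]}"
        pool = gene_variants[gene]
        if config.variant_rate and rng.random() < config.variant_rate:
            return str(rng.choice(pool[1:]))
        return pool[0]

    # ---- true mentions ----------------------------------------------------
    sentences: list[list[tuple[_Clause, float]]] = []  # clause + event confidence draw
    def conf(correct: bool) -> float:
        a, b = config.conf_correct if correct else config.conf_incorrect
        x = float(rng.beta(a, b))
        return min(max(x, 1e-6), 1.0)

    for (i, j, grn_type) in edges:
        for _ in range(config.mentions_per_edge):
            if grn_type == "Requirement":
                clause = _clause_plain((surface(i), "Gene"), (surface(j), "Protein"))
            else:
                build = _realize_true_mention(rng, grn_type)
                clause = build(surface(i), surface(j))
            sentences.append([(clause, conf(True))])

    # ---- false positives --------------------------------------------------
    n_true_events = sum(len(cl.events) for sent in sentences for cl, _ in sent)
    if config.fp_rate > 0:
        lam = n_true_events * config.fp_rate / (1.0 - config.fp_rate)
        n_fp = int(rng.poisson(lam))
    else:
        n_fp = 0
    confusion = (
        np.asarray(config.type_confusion, dtype=float)
        if config.type_confusion is not None
        else np.full((len(COARSE_MENU), len(COARSE_MENU)), 1.0 / len(COARSE_MENU))
    )
    fp_budget = n_fp
    while fp_budget > 0:
        intended = int(rng.integers(len(COARSE_MENU)))
        realized = int(rng.choice(len(COARSE_MENU), p=confusion[intended]))
        gi = int(rng.integers(config.n_genes))
        gj = int(rng.integers(config.n_genes - 1))
        gj = gj if gj < gi else gj + 1
        clause = _realize_fp(rng, COARSE_MENU[realized], surface(gi), surface(gj))
        fp_budget -= len(clause.events)
        if config.fp_same_sentence_rate and rng.random() < config.fp_same_sentence_rate and sentences:
            host = int(rng.integers(len(sentences)))
            sentences[host].append((clause, conf(False)))
        else:
            sentences.append([(clause, conf(False))])

    # ---- pack sentences into documents ------------------------------------
    capacity = config.n_docs * config.sentences_per_doc
    if len(sentences) > capacity:
        raise GeneratorConfigError(
            f"{len(sentences)} sentences exceed capacity "
            f"{config.n_docs} docs x {config.sentences_per_doc} sentences"
        )
    order = rng.permutation(len(sentences))
    doc_sentences: list[list[list[tuple[_Clause, float]]]] = [
        [] for _ in range(config.n_docs)
    ]
    for pos, sent_idx in enumerate(order):
        doc_sentences[pos % config.n_docs].append(sentences[int(sent_idx)])

    docs: list[Document] = []
    labels: dict[tuple[str, str], str] = {}
    gold_events: dict[str, list[EventAnnotation]] = {}
    for d, sent_list in enumerate(doc_sentences):
        doc_id = f"{90000000 + d}"
        doc = _assemble_document(doc_id, sent_list)
        docs.append(doc)
        gold_events[doc_id] = []
        for ev in doc.events:
            labels[(doc_id, ev.id)] = ev._label  # attached in assembly
            if ev._label == "tp":
                gold_events[doc_id].append(ev)
        doc.validate()
    truth = SyntheticTruth(planted, symbol_table, labels, gold_events)
    return docs, truth


def _assemble_document(
    doc_id: str, sent_list: list[list[tuple[_Clause, float]]]
) -> Document:
    """Lay out clauses into lines and materialize annotations."""
    text_lines: list[str] = []
    entities: list[EntityAnnotation] = []
    events: list[EventAnnotation] = []
    t_counter, e_counter = [0], [0]
    offset = 0

    for sent in sent_list:
        line_parts: list[str] = []
        clause_offsets: list[int] = []
        pos = offset
        for c_idx, (clause, _) in enumerate(sent):
            if c_idx > 0:
                pos += len(" ; ")
            clause_offsets.append(pos)
            line_parts.append(clause.text)
            pos += len(clause.text)
        line = " ; ".join(line_parts)
        text_lines.append(line)

        for (clause, confidence), base in zip(sent, clause_offsets):
            local_refs: dict[str, object] = {}
            for key, rs, re_, surf, etype in clause.mentions:
                t_counter[0] += 1
                ent = EntityAnnotation(
                    id=f"T{t_counter[0]}", entity_type=etype,
                    span=TextSpan(base + rs, base + re_, surf),
                )
                entities.append(ent)
                local_refs[key] = ent
            for key, ev_type, rs, re_, trig, args in clause.events:
                e_counter[0] += 1
                built_args = tuple(
                    EventArgument(role, local_refs[ref_key]) for role, ref_key in args
                )
                ev = EventAnnotation(
                    id=f"E{e_counter[0]}", event_type=ev_type,
                    trigger=TextSpan(base + rs, base + re_, trig),
                    arguments=built_args, confidence=confidence,
                )
                object.__setattr__(ev, "_label", clause.label)
                events.append(ev)
                local_refs[key] = ev
        offset += len(line) + 1  # newline

    text = "\n".join(text_lines)
    if text_lines:
        text += "\n"
    spans = []
    pos = 0
    for line in text_lines:
        spans.append(TextSpan(pos, pos + len(line), line))
        pos += len(line) + 1
    return Document(doc_id, text, entities, events, spans)


def make_labeled_querysets(
    corpus: list[Document], truth: SyntheticTruth
) -> list[SentenceQuerySet]:
    """Group each document's events into per-sentence labeled query sets."""
    query_sets: list[SentenceQuerySet] = []
    for doc in corpus:
        by_sentence: dict[TextSpan, list[CandidateEvent]] = {}
        for ev in doc.events:
            sent = doc.sentence_of(ev.trigger)
            if sent is None:
                continue
            label = truth.labels.get((doc.doc_id, ev.id), "unknown")
            by_sentence.setdefault(sent, []).append(
                CandidateEvent(event=ev, base_confidence=ev.confidence, label=label)
            )
        for sent in sorted(by_sentence, key=lambda s: s.start):
            query_sets.append(SentenceQuerySet(doc.doc_id, sent, by_sentence[sent]))
    return query_sets


def relabel_querysets_against_gold(
    corpus: list[Document], truth: SyntheticTruth
) -> list[SentenceQuerySet]:
    """Query sets labeled via the structural matcher instead of the truth map.

    Used as a cross-check: labels must agree with the generator's own
    bookkeeping on every document.
    """
    query_sets: list[SentenceQuerySet] = []
    for doc in corpus:
        cands = label_candidates(doc.events, truth.gold_events.get(doc.doc_id, []))
        by_sentence: dict[TextSpan, list[CandidateEvent]] = {}
        for cand in cands:
            sent = doc.sentence_of(cand.event.trigger)
            if sent is not None:
                by_sentence.setdefault(sent, []).append(cand)
        for sent in sorted(by_sentence, key=lambda s: s.start):
            query_sets.append(SentenceQuerySet(doc.doc_id, sent, by_sentence[sent]))
    return query_sets
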