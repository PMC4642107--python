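"""BioNLP-ST standoff annotation IO.

Reads and writes the standoff triplet used by the shared-task corpora --
``.txt`` (document text), ``.a1`` (entity annotations) and ``.a2``
(event triggers and events) -- plus three small sidecar/tabular formats
native to this toolkit:

* a confidence sidecar TSV (``event_id<TAB>confidence<TAB>negated``),
  because standard ``.a2`` carries no confidence field;
* a network TSV (``agent_id<TAB>target_id<TAB>type[<TAB>confidence]``)
  used both for gold regulatory networks and for predicted ones;
* a symbol table TSV mapping surface gene symbols to standardized gene
  identifiers.

Offsets are 0-based and end-exclusive; the document text is a flat
character sequence.  Every parsed span is verified against the document
text, and all writers round-trip bit-exactly through their readers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

__all__ = [
    "TextSpan",
    "EntityAnnotation",
    "EventArgument",
    "EventAnnotation",
    "Document",
    "GoldRelationRecord",
    "StandoffParseError",
    "StandoffIntegrityError",
    "ENTITY_TYPES",
    "GRN_TYPES",
    "parse_a1",
    "parse_a2",
    "write_a1",
    "write_a2",
    "read_confidence_sidecar",
    "write_confidence_sidecar",
    "read_network_tsv",
    "write_network_tsv",
    "read_symbol_table",
    "write_symbol_table",
    "read_document",
    "write_document",
    "read_corpus",
    "write_corpus",
]

#: Entity vocabulary consumed by the entity-type filter.
ENTITY_TYPES = frozenset(
    {"Gene", "Protein", "Operon", "PolymeraseComplex", "ProteinComplex", "GGP", "Other"}
)

#: Closed vocabulary of regulatory-network interaction types.
GRN_TYPES = ("Binding", "Transcription", "Regulation", "Activation", "Inhibition")


class StandoffParseError(ValueError):
    """A line does not conform to the standoff grammar."""


class StandoffIntegrityError(ValueError):
    """Annotations are well-formed but internally inconsistent."""


@dataclass(frozen=True, order=True)
class TextSpan:
    """A character span ``[start, end)`` together with its surface text."""

    start: int
    end: int
    text: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise StandoffIntegrityError(
                f"invalid span [{self.start}, {self.end}): need 0 <= start < end"
            )
        if len(self.text) != self.end - self.start:
            raise StandoffIntegrityError(
                f"span text {self.text!r} has length {len(self.text)}, "
                f"expected {self.end - self.start}"
            )

    def contains(self, other: "TextSpan") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass(frozen=True)
class EntityAnnotation:
    """A typed text-bound entity mention (``T``-line in ``.a1``)."""

    id: str
    entity_type: str
    span: TextSpan

    def __post_init__(self) -> None:
        if self.entity_type not in ENTITY_TYPES:
            raise StandoffIntegrityError(
                f"unknown entity type {self.entity_type!r} for {self.id}"
            )

    @property
    def symbol(self) -> str:
        return self.span.text


@dataclass(frozen=True)
class EventArgument:
    """A role-labelled event argument: an entity or a nested event."""

    role: str  # "Theme" or "Cause"
    ref: "EntityAnnotation | EventAnnotation"

    @property
    def is_event(self) -> bool:
        return isinstance(self.ref, EventAnnotation)


@dataclass(frozen=True)
class EventAnnotation:
    """A typed trigger with role-labelled, possibly nested arguments."""

    id: str
    event_type: str
    trigger: TextSpan
    arguments: tuple[EventArgument, ...]
    confidence: float = 1.0
    negated: bool = False

    def __post_init__(self) -> None:
        if not any(a.role == "Theme" for a in self.arguments):
            raise StandoffIntegrityError(f"event {self.id} has no Theme argument")
        if not (0.0 < self.confidence <= 1.0):
            raise StandoffIntegrityError(
                f"event {self.id}: confidence {self.confidence} outside (0, 1]"
            )

    def themes(self) -> tuple[EventArgument, ...]:
        return tuple(a for a in self.arguments if a.role == "Theme")

    def causes(self) -> tuple[EventArgument, ...]:
        return tuple(a for a in self.arguments if a.role == "Cause")


@dataclass(frozen=True)
class GoldRelationRecord:
    """A typed agent→target edge of a gold or predicted network."""

    agent_id: str
    target_id: str
    interaction_type: str
    confidence: float | None = None

    def __post_init__(self) -> None:
        # Requirement appears in gold data of the task but is never produced
        # by the converter; it is accepted here so evaluation can count it.
        if self.interaction_type not in GRN_TYPES + ("Requirement",):
            raise StandoffIntegrityError(
                f"unknown interaction type {self.interaction_type!r}"
            )


@dataclass
class Document:
    """A document with its text, entities, events and sentence spans."""

    doc_id: str
    text: str
    entities: list[EntityAnnotation] = field(default_factory=list)
    events: list[EventAnnotation] = field(default_factory=list)
    sentence_spans: list[TextSpan] = field(default_factory=list)

    def validate(self) -> None:
        """Check span/sentence integrity; raise StandoffIntegrityError."""
        seen: set[str] = set()
        for ent in self.entities:
            if ent.id in seen:
                raise StandoffIntegrityError(f"duplicate annotation id {ent.id}")
            seen.add(ent.id)
            _check_span(ent.span, self.text)
        for ev in self.events:
            _check_span(ev.trigger, self.text)
        prev_end = -1
        for sent in self.sentence_spans:
            if sent.start < prev_end:
                raise StandoffIntegrityError("sentence spans overlap or are unordered")
            prev_end = sent.end
            _check_span(sent, self.text)
        if self.sentence_spans:
            for ev in self.events:
                if self.sentence_of(ev.trigger) is None:
                    raise StandoffIntegrityError(
                        f"trigger of {ev.id} crosses sentence boundaries"
                    )

    def sentence_of(self, span: TextSpan) -> TextSpan | None:
        """The unique sentence span containing ``span``, if any."""
        for sent in self.sentence_spans:
            if sent.contains(span):
                return sent
        return None


def _check_span(span: TextSpan, text: str) -> None:
    if span.end > len(text):
        raise StandoffIntegrityError(f"span [{span.start}, {span.end}) beyond document end")
    actual = text[span.start : span.end]
    if actual != span.text:
        raise StandoffIntegrityError(
            f"span text mismatch at [{span.start}, {span.end}): "
            f"annotation says {span.text!r}, document has {actual!r}"
        )


# ---------------------------------------------------------------------------
# .a1 / .a2
# ---------------------------------------------------------------------------

def _parse_t_line(lineno: int, line: str) -> tuple[str, str, TextSpan]:
    parts = line.split("\t")
    if len(parts) != 3:
        raise StandoffParseError(f"line {lineno}: expected 3 tab-separated fields: {line!r}")
    tid, typeloc, surface = parts
    loc = typeloc.split(" ")
    if len(loc) != 3:
        raise StandoffParseError(f"line {lineno}: expected 'Type Start End': {typeloc!r}")
    ann_type, s, e = loc
    try:
        start, end = int(s), int(e)
    except ValueError as exc:
        raise StandoffParseError(f"line {lineno}: non-integer offsets in {typeloc!r}") from exc
    return tid, ann_type, TextSpan(start, end, surface)


def parse_a1(raw_text: str, document_text: str) -> list[EntityAnnotation]:
    """Parse ``.a1`` entity lines, verifying every span against the text."""
    entities: list[EntityAnnotation] = []
    seen: set[str] = set()
    for lineno, line in enumerate(raw_text.splitlines(), start=1):
        if not line.strip():
            continue
        tid, etype, span = _parse_t_line(lineno, line)
        if tid in seen:
            raise StandoffIntegrityError(f"line {lineno}: duplicate id {tid}")
        seen.add(tid)
        _check_span(span, document_text)
        entities.append(EntityAnnotation(id=tid, entity_type=etype, span=span))
    return entities


def parse_a2(
    raw_text: str,
    entities: list[EntityAnnotation],
    document_text: str,
    confidences: dict[str, tuple[float, bool]] | None = None,
) -> list[EventAnnotation]:
    """Parse ``.a2`` trigger and event lines into resolved event structures.

    ``confidences`` maps event ids to ``(confidence, negated)`` pairs from the
    sidecar; absent entries default to ``(1.0, False)``.
    """
    triggers: dict[str, tuple[str, TextSpan]] = {}
    raw_events: dict[str, tuple[int, str, str, list[tuple[str, str]]]] = {}
    order: list[str] = []
    for lineno, line in enumerate(raw_text.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("T"):
            tid, etype, span = _parse_t_line(lineno, line)
            _check_span(span, document_text)
            triggers[tid] = (etype, span)
        elif line.startswith("E"):
            parts = line.split("\t")
            if len(parts) != 2:
                raise StandoffParseError(f"line {lineno}: malformed event line {line!r}")
            eid, body = parts
            tokens = body.split(" ")
            head = tokens[0].split(":")
            if len(head) != 2:
                raise StandoffParseError(f"line {lineno}: malformed event head {tokens[0]!r}")
            ev_type, trig_id = head
            args: list[tuple[str, str]] = []
            for tok in tokens[1:]:
                if not tok:
                    continue
                rc = tok.split(":")
                if len(rc) != 2:
                    raise StandoffParseError(f"line {lineno}: malformed argument {tok!r}")
                role = rc[0].rstrip("0123456789")  # Theme2 -> Theme
                args.append((role, rc[1]))
            if eid in raw_events:
                raise StandoffIntegrityError(f"line {lineno}: duplicate event id {eid}")
            raw_events[eid] = (lineno, ev_type, trig_id, args)
            order.append(eid)
        else:
            raise StandoffParseError(f"line {lineno}: unrecognised line {line!r}")

    entity_by_id = {e.id: e for e in entities}
    confidences = confidences or {}
    resolved: dict[str, EventAnnotation] = {}
    resolving: set[str] = set()

    def resolve(eid: str) -> EventAnnotation:
        if eid in resolved:
            return resolved[eid]
        if eid in resolving:
            raise StandoffIntegrityError(f"event reference cycle through {eid}")
        resolving.add(eid)
        lineno, ev_type, trig_id, args = raw_events[eid]
        if trig_id not in triggers:
            raise StandoffIntegrityError(f"line {lineno}: unknown trigger {trig_id}")
        trig_type, trig_span = triggers[trig_id]
        if trig_type != ev_type:
            raise StandoffIntegrityError(
                f"line {lineno}: event type {ev_type} != trigger type {trig_type}"
            )
        built: list[EventArgument] = []
        for role, ref in args:
            if ref in entity_by_id:
                built.append(EventArgument(role, entity_by_id[ref]))
            elif ref in raw_events:
                built.append(EventArgument(role, resolve(ref)))
            else:
                raise StandoffIntegrityError(f"line {lineno}: unresolved reference {ref}")
        conf, neg = confidences.get(eid, (1.0, False))
        ev = EventAnnotation(
            id=eid, event_type=ev_type, trigger=trig_span,
            arguments=tuple(built), confidence=conf, negated=neg,
        )
        resolving.discard(eid)
        resolved[eid] = ev
        return ev

    return [resolve(eid) for eid in order]


def write_a1(entities: list[EntityAnnotation]) -> str:
    lines = [
        f"{e.id}\t{e.entity_type} {e.span.start} {e.span.end}\t{e.span.text}"
        for e in entities
    ]
    return "".join(line + "\n" for line in lines)


def write_a2(events: list[EventAnnotation]) -> str:
    """Serialize events to ``.a2`` text; inverse of :func:`parse_a2`.

    Trigger lines are emitted before the events that use them, one trigger
    per event (triggers are not shared on output); identifiers are kept.
    """
    out: list[str] = []
    written_trig: dict[str, str] = {}  # event id -> trigger id
    next_t = [1]

    def trig_id_for(ev: EventAnnotation) -> str:
        if ev.id not in written_trig:
            tid = f"TR{next_t[0]}"
            next_t[0] += 1
            written_trig[ev.id] = tid
            out.append(
                f"{tid}\t{ev.event_type} {ev.trigger.start} {ev.trigger.end}\t{ev.trigger.text}"
            )
        return written_trig[ev.id]

    emitted: set[str] = set()

    def emit(ev: EventAnnotation) -> None:
        if ev.id in emitted:
            return
        for arg in ev.arguments:
            if isinstance(arg.ref, EventAnnotation):
                emit(arg.ref)
        tid = trig_id_for(ev)
        args = " ".join(
            f"{arg.role}:{arg.ref.id}" for arg in ev.arguments
        )
        out.append(f"{ev.id}\t{ev.event_type}:{tid} {args}".rstrip())
        emitted.add(ev.id)

    for ev in events:
        emit(ev)
    return "".join(line + "\n" for line in out)


# ---------------------------------------------------------------------------
# Sidecars and tables
# ---------------------------------------------------------------------------

def read_confidence_sidecar(raw_text: str) -> dict[str, tuple[float, bool]]:
    """Parse ``event_id<TAB>confidence<TAB>negated`` lines."""
    out: dict[str, tuple[float, bool]] = {}
    for lineno, line in enumerate(raw_text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise StandoffParseError(f"line {lineno}: expected 3 fields: {line!r}")
        eid, conf, neg = parts
        if neg not in ("0", "1"):
            raise StandoffParseError(f"line {lineno}: negated flag must be 0 or 1")
        out[eid] = (float(conf), neg == "1")
    return out


def write_confidence_sidecar(events: list[EventAnnotation]) -> str:
    lines = [
        f"{ev.id}\t{ev.confidence!r}\t{1 if ev.negated else 0}" for ev in events
    ]
    return "".join(line + "\n" for line in lines)


def read_network_tsv(raw_text: str) -> list[GoldRelationRecord]:
    records: list[GoldRelationRecord] = []
    for lineno, line in enumerate(raw_text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) not in (3, 4):
            raise StandoffParseError(f"line {lineno}: expected 3-4 fields: {line!r}")
        conf = float(parts[3]) if len(parts) == 4 else None
        try:
            rec = GoldRelationRecord(parts[0], parts[1], parts[2], conf)
        except StandoffIntegrityError as exc:
            raise StandoffIntegrityError(f"line {lineno}: {exc}") from exc
        records.append(rec)
    return records


def write_network_tsv(records: list[GoldRelationRecord]) -> str:
    lines = []
    for r in records:
        base = f"{r.agent_id}\t{r.target_id}\t{r.interaction_type}"
        if r.confidence is not None:
            base += f"\t{r.confidence!r}"
        lines.append(base)
    return "".join(line + "\n" for line in lines)


def read_symbol_table(raw_text: str) -> dict[str, str]:
    """Parse ``surface_symbol<TAB>standardized_id`` lines."""
    table: dict[str, str] = {}
    for lineno, line in enumerate(raw_text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise StandoffParseError(f"line {lineno}: expected 2 fields: {line!r}")
        table[parts[0]] = parts[1]
    return table


def write_symbol_table(table: dict[str, str]) -> str:
    return "".join(f"{k}\t{v}\n" for k, v in table.items())


# ---------------------------------------------------------------------------
# Corpus directories
# ---------------------------------------------------------------------------

def _sentence_spans_from_lines(text: str) -> list[TextSpan]:
    spans = []
    pos = 0
    for line in text.split("\n"):
        if line:
            spans.append(TextSpan(pos, pos + len(line), line))
        pos += len(line) + 1
    return spans


def read_document(directory: str, doc_id: str) -> Document:
    """Read ``doc_id.{txt,a1,a2}`` (+ optional sidecars) from a directory.

    Sentence spans come from a ``.sent`` sidecar of ``start<TAB>end`` lines
    when present, otherwise one sentence per text line.
    """
    def slurp(ext: str) -> str | None:
        path = os.path.join(directory, f"{doc_id}.{ext}")
        if not os.path.exists(path):
            return None
        with open(path, encoding="utf-8", newline="") as fh:
            return fh.read()

    text = slurp("txt")
    if text is None:
        raise FileNotFoundError(f"{doc_id}.txt not found in {directory}")
    entities = parse_a1(slurp("a1") or "", text)
    conf_raw = slurp("conf")
    confidences = read_confidence_sidecar(conf_raw) if conf_raw else None
    events = parse_a2(slurp("a2") or "", entities, text, confidences)
    sent_raw = slurp("sent")
    if sent_raw:
        spans = []
        for line in sent_raw.splitlines():
            if not line.strip():
                continue
            s, e = line.split("\t")
            spans.append(TextSpan(int(s), int(e), text[int(s):int(e)]))
    else:
        spans = _sentence_spans_from_lines(text)
    doc = Document(doc_id, text, entities, events, spans)
    doc.validate()
    return doc


def write_document(directory: str, doc: Document) -> None:
    os.makedirs(directory, exist_ok=True)

    def spit(ext: str, content: str) -> None:
        with open(os.path.join(directory, f"{doc.doc_id}.{ext}"), "w",
                  encoding="utf-8", newline="") as fh:
            fh.write(content)

    spit("txt", doc.text)
    spit("a1", write_a1(doc.entities))
    spit("a2", write_a2(doc.events))
    spit("conf", write_confidence_sidecar(doc.events))


def read_corpus(directory: str) -> list[Document]:
    doc_ids = sorted(
        fn[:-4] for fn in os.listdir(directory) if fn.endswith(".txt")
    )
    return [read_document(directory, did) for did in doc_ids]


def write_corpus(directory: str, docs: list[Document]) -> None:
    for doc in docs:
        write_document(directory, doc)
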