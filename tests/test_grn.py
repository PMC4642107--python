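"""Rule-based network conversion: type mapping, filtering, edge selection."""

import itertools

import numpy as np
import pytest

from bibliome_events.events import CoarseEventType, PairwiseRelation
from bibliome_events.grn import (
    GRNInteraction,
    conversion_candidates,
    convert_rule_based,
    filter_entity_types,
    map_type_rule,
    match_symbols,
    refactor_binding,
    restrict_documents,
    select_edges,
)
from bibliome_events.metrics import score_network
from bibliome_events.standoff import GRN_TYPES

ALL_COARSE = [
    CoarseEventType(layer, base)
    for layer in CoarseEventType.LAYERS
    for base in CoarseEventType.BASES
    if not (base == "Binding" and layer != "None")
]


class TestMapTypeRule:
    @pytest.mark.parametrize("coarse, expected", [
        (("None", "Binding"), "Binding"),
        (("Positive", "Transcription"), "Transcription"),
        (("Negative", "Transcription"), "Transcription"),
        (("Unspecified", "Transcription"), "Transcription"),
        (("Positive", "GeneExpression"), "Transcription"),
        (("Negative", "GeneExpression"), "Transcription"),
        (("Unspecified", "GeneExpression"), "Transcription"),
        (("Positive", "Other"), "Activation"),
        (("Negative", "Other"), "Inhibition"),
        (("Unspecified", "Other"), "Regulation"),
        (("None", "Other"), None),
        (("None", "Transcription"), None),
        (("None", "GeneExpression"), None),
    ])
    def test_rule_rows(self, coarse, expected):
        assert map_type_rule(CoarseEventType(*coarse)) == expected

    def test_total_and_deterministic(self):
        for coarse in ALL_COARSE:
            first = map_type_rule(coarse)
            assert first == map_type_rule(coarse)
            assert first in (None,) + GRN_TYPES


ENTITY_TYPES = ["Gene", "Protein", "Operon", "PolymeraseComplex",
                "ProteinComplex", "GGP", "Other"]


def _inter(grn_type, agent_et, target_et, conf=0.9, agent="gA", target="gB"):
    return GRNInteraction(agent, target, grn_type, conf,
                          agent_entity_type=agent_et, target_entity_type=target_et)


class TestEntityTypeFilter:
    @pytest.mark.parametrize("grn_type, agent_et, target_et, keep", [
        ("Binding", "Gene", "Protein", True),
        ("Binding", "Protein", "Protein", False),
        ("Binding", "Gene", "Gene", False),
        ("Transcription", "Gene", "Protein", True),
        ("Transcription", "Operon", "PolymeraseComplex", True),
        ("Transcription", "Protein", "Protein", False),
        ("Activation", "Operon", "PolymeraseComplex", True),
        ("Activation", "Protein", "Protein", True),
        ("Regulation", "ProteinComplex", "Protein", True),
        ("Inhibition", "GGP", "Protein", False),
        ("Regulation", "Gene", "Gene", False),
    ])
    def test_rule_rows(self, grn_type, agent_et, target_et, keep):
        assert filter_entity_types(_inter(grn_type, agent_et, target_et)) is keep

    def test_exhaustive_against_declared_tables(self):
        """Full enumeration equals the declared target/agent tables."""
        allowed = {
            "Binding": ({"Protein"}, {"Gene"}),
            "Transcription": ({"Protein", "PolymeraseComplex"}, {"Gene", "Operon"}),
            "Regulation": ({"Protein", "PolymeraseComplex"},
                           {"Gene", "Operon", "Protein", "ProteinComplex"}),
            "Activation": ({"Protein", "PolymeraseComplex"},
                           {"Gene", "Operon", "Protein", "ProteinComplex"}),
            "Inhibition": ({"Protein", "PolymeraseComplex"},
                           {"Gene", "Operon", "Protein", "ProteinComplex"}),
        }
        for grn_type, (targets, agents) in allowed.items():
            for agent_et, target_et in itertools.product(ENTITY_TYPES, repeat=2):
                expected = target_et in targets and agent_et in agents
                assert filter_entity_types(_inter(grn_type, agent_et, target_et)) is expected

    def test_missing_entity_type_errors(self):
        with pytest.raises(ValueError, match="entity types"):
            filter_entity_types(GRNInteraction("a", "b", "Binding", 0.5))


class TestRefactorBinding:
    def test_binding_becomes_transcription(self):
        out = refactor_binding([_inter("Binding", "Gene", "Protein")])
        assert out[0].grn_type == "Transcription"

    def test_others_untouched_and_empty_ok(self):
        assert refactor_binding([]) == []
        inter = _inter("Activation", "Gene", "Protein")
        assert refactor_binding([inter]) == [inter]


def select_edges_oracle(interactions):
    """Brute-force reference: test every candidate of a pair as the
    proposed winner and keep the one no rule eliminates and none of the
    other surviving candidates dominates."""

    def eliminated(cand, group):
        types = {g.grn_type for g in group}
        if cand.grn_type == "Regulation" and types & {
            "Activation", "Inhibition", "Transcription", "Binding"
        }:
            return True
        after_a = [g for g in group
                   if not (g.grn_type == "Regulation" and types & {
                       "Activation", "Inhibition", "Transcription", "Binding"})]
        types_a = {g.grn_type for g in after_a}
        if {"Activation", "Inhibition"} <= types_a:
            best_act = max(g.confidence for g in after_a if g.grn_type == "Activation")
            best_inh = max(g.confidence for g in after_a if g.grn_type == "Inhibition")
            losing = "Inhibition" if best_act >= best_inh else "Activation"
            if cand.grn_type == losing:
                return True
            after_a = [g for g in after_a if g.grn_type != losing]
        types_b = {g.grn_type for g in after_a}
        if cand.grn_type in ("Transcription", "Binding") and types_b & {
            "Activation", "Inhibition", "Regulation"
        }:
            return True
        return False

    def dominates(x, y):
        return x.confidence > y.confidence or (
            x.confidence == y.confidence and x.grn_type < y.grn_type
        )

    pairs = {}
    for i in interactions:
        pairs.setdefault((i.agent_id, i.target_id), []).append(i)
    chosen = []
    for group in pairs.values():
        winners = [
            cand for cand in group
            if not eliminated(cand, group)
            and not any(
                dominates(o, cand)
                for o in group if not eliminated(o, group)
            )
        ]
        assert winners, "some candidate must survive"
        chosen.append(winners[0])  # equals share (confidence, type)
    return chosen


class TestSelectEdges:
    def test_transcription_beats_regulation(self):
        out = select_edges([
            _inter("Transcription", "Gene", "Protein", 0.5),
            _inter("Regulation", "Gene", "Protein", 0.9),
        ])
        assert [i.grn_type for i in out] == ["Transcription"]

    def test_contradiction_resolved_by_confidence(self):
        out = select_edges([
            _inter("Activation", "Gene", "Protein", 0.9),
            _inter("Inhibition", "Gene", "Protein", 0.4),
        ])
        assert [i.grn_type for i in out] == ["Activation"]

    def test_mechanism_suppressed_by_regulatory(self):
        out = select_edges([
            _inter("Transcription", "Gene", "Protein", 0.99),
            _inter("Activation", "Gene", "Protein", 0.2),
        ])
        assert [i.grn_type for i in out] == ["Activation"]

    def test_one_edge_per_pair_and_invariants_random(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            interactions = []
            for pair_idx in range(rng.integers(1, 4)):
                agent, target = f"a{pair_idx}", f"t{pair_idx}"
                for _ in range(rng.integers(1, 7)):
                    interactions.append(_inter(
                        str(rng.choice(GRN_TYPES)),
                        "Gene", "Protein",
                        float(rng.choice([0.1, 0.3, 0.5, 0.5, 0.9])),
                        agent, target,
                    ))
            out = select_edges(interactions)
            pairs = [(i.agent_id, i.target_id) for i in out]
            assert len(pairs) == len(set(pairs))
            for (a, t) in set(pairs):
                group_types = {i.grn_type for i in out
                               if (i.agent_id, i.target_id) == (a, t)}
                assert not ({"Activation", "Inhibition"} <= group_types)
            # agreement with the independent oracle
            oracle = select_edges_oracle(interactions)
            assert {(i.agent_id, i.target_id, i.grn_type, i.confidence) for i in out} \
                == {(i.agent_id, i.target_id, i.grn_type, i.confidence) for i in oracle}


def _rel(doc, agent="siga", target="sigb", coarse=("Positive", "Other")):
    return PairwiseRelation(
        agent=agent, target=target, coarse_type=CoarseEventType(*coarse),
        confidence=0.8, source_doc=doc, source_event="E1",
        agent_entity_type="Gene", target_entity_type="Protein",
    )


class TestRestrictAndMatch:
    def test_restrict_all_is_identity(self):
        rels = [_rel("d1"), _rel("d2")]
        assert restrict_documents(rels, "all") == rels

    def test_restrict_filters_by_doc(self):
        rels = [_rel("d1"), _rel("d2"), _rel("d3"), _rel("d2"), _rel("d9")]
        kept = restrict_documents(rels, {"d2"})
        assert len(kept) == 2 and all(r.source_doc == "d2" for r in kept)

    def test_restrict_empty_set(self):
        assert restrict_documents([_rel("d1")], set()) == []

    def test_match_resolves_and_drops(self):
        rels = [_rel("d1", "sigmab", "katx"), _rel("d1", "nope", "katx")]
        out = match_symbols(rels, {"sigmab": "sigB", "katx": "katX"})
        assert len(out) == 1
        assert (out[0].agent_id, out[0].target_id) == ("sigB", "katX")

    def test_variants_collapse_to_one_id(self):
        rels = [_rel("d1", "sigmab", "katx"), _rel("d1", "sigb", "katx")]
        out = match_symbols(rels, {"sigmab": "sigB", "sigb": "sigB", "katx": "katX"})
        assert {r.agent_id for r in out} == {"sigB"}


class TestConvertRuleBased:
    def test_zero_noise_recovers_planted_network(self, zero_noise_corpus):
        docs, truth = zero_noise_corpus
        network = convert_rule_based(docs, truth.symbol_table)
        predicted = {(i.agent_id, i.target_id, i.grn_type) for i in network}
        planted = {(g.agent_id, g.target_id, g.interaction_type) for g in truth.planted}
        assert predicted == planted
        assert score_network(network, truth.planted, "strict").ser == 0.0

    def test_empty_corpus_gives_empty_network(self, zero_noise_corpus):
        _, truth = zero_noise_corpus
        assert convert_rule_based([], truth.symbol_table) == []

    def test_unmatched_symbols_give_empty_network(self, zero_noise_corpus):
        docs, _ = zero_noise_corpus
        assert convert_rule_based(docs, {"unrelated": "x"}) == []

    def test_entity_filter_is_a_pure_filter(self, noisy_corpus):
        """Filtered candidates are a subset: recall can never increase."""
        docs, truth = noisy_corpus
        cands = conversion_candidates(docs, truth.symbol_table)
        kept = [i for i in cands if filter_entity_types(i)]
        assert len(kept) <= len(cands)
        gold = {(g.agent_id, g.target_id, g.interaction_type) for g in truth.planted}

        def hits(items):
            return {(i.agent_id, i.target_id, i.grn_type) for i in items} & gold

        assert hits(kept) <= hits(cands)
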