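"""Classifier contracts: the hit filter's window/span rules, rank ceilings
and lineage consensus, clade rescue, and the self-contained search."""

import numpy as np
import pytest

from metabias import (
    Hit,
    SequenceRecord,
    UltrametricTree,
    clade_rescue,
    consensus_taxonomy,
    filter_hits,
    naive_search,
)
from metabias.taxonomy_assign import Assignment, classify


def hit(ident, lineage=("Annelida", "Nerillidae", "Nerilla sp."), span=150, q="q1"):
    return Hit(query=q, lineage=lineage, pct_identity=ident, span=span)


class TestFilterHits:
    def test_identity_window(self):
        hits = [hit(98.0), hit(97.6), hit(97.4)]
        kept = filter_hits(hits)
        assert [h.pct_identity for h in kept] == [98.0, 97.6]

    def test_short_top_hit_excluded_and_top_recomputed(self):
        hits = [hit(99.0, span=100), hit(97.0), hit(96.6)]
        kept = filter_hits(hits)
        assert [h.pct_identity for h in kept] == [97.0, 96.6]

    def test_span_exactly_at_limit_excluded(self):
        assert filter_hits([hit(98.0, span=120)]) == []

    def test_top_five_kept(self):
        hits = [hit(98.0 - 0.05 * i) for i in range(6)]
        assert len(filter_hits(hits)) == 5

    def test_empty(self):
        assert filter_hits([]) == []


class TestConsensus:
    def test_species_level_unanimous(self):
        a = consensus_taxonomy([hit(98.2)] * 5)
        assert (a.rank, a.label) == ("species", "Nerilla sp.")
        assert a.basis == "consensus"

    def test_family_ceiling_without_family_agreement(self):
        hits = [hit(95.0, ("Annelida", "Nerillidae", None)),
                hit(94.8, ("Annelida", "Saccocirridae", None))]
        a = consensus_taxonomy(hits)
        assert (a.rank, a.label) == ("phylum", "Annelida")

    def test_below_all_thresholds_unassigned(self):
        a = consensus_taxonomy([hit(89.9)])
        assert a.rank == "unassigned"
        assert a.label == ""

    def test_phylum_disagreement_unassigned(self):
        hits = [hit(98.0, ("Annelida", "F1", "s1")),
                hit(98.0, ("Mollusca", "F2", "s2"))]
        assert consensus_taxonomy(hits).rank == "unassigned"

    def test_ceiling_caps_depth(self):
        # agreement to species but only family-grade identity
        a = consensus_taxonomy([hit(95.0)] * 3)
        assert a.rank == "family"
        assert a.label == "Nerillidae"

    def test_boundary_identities_are_strict(self):
        assert consensus_taxonomy([hit(97.0)]).rank == "family"
        assert consensus_taxonomy([hit(93.0)]).rank == "phylum"
        assert consensus_taxonomy([hit(90.0)]).rank == "unassigned"


class TestMonotonicity:
    def _random_hits(self, rng):
        phyla = ["Annelida", "Mollusca"]
        hits = []
        top = rng.uniform(88, 100)
        for i in range(rng.integers(1, 7)):
            ph = rng.choice(phyla)
            lineage = (ph, f"{ph}_f{rng.integers(2)}", f"{ph}_s{rng.integers(2)}")
            hits.append(Hit(query="q", lineage=lineage,
                            pct_identity=float(np.clip(top - rng.uniform(0, 2), 0, 100)),
                            span=int(rng.integers(100, 200))))
        return sorted(hits, key=lambda h: -h.pct_identity)

    RANK_DEPTH = {"unassigned": 0, "phylum": 1, "family": 2, "species": 3}

    def test_raising_thresholds_never_deepens(self, rng):
        for _ in range(300):
            hits = self._random_hits(rng)
            kept = filter_hits(hits)
            lo = consensus_taxonomy(kept, thresholds=(97.0, 93.0, 90.0))
            hi = consensus_taxonomy(kept, thresholds=(98.0, 95.0, 92.0))
            assert self.RANK_DEPTH[hi.rank] <= self.RANK_DEPTH[lo.rank]

    def test_widening_window_never_deepens(self, rng):
        for _ in range(300):
            hits = self._random_hits(rng)
            narrow = consensus_taxonomy(filter_hits(hits, top_window=0.5))
            wide = consensus_taxonomy(filter_hits(hits, top_window=2.0))
            assert self.RANK_DEPTH[wide.rank] <= self.RANK_DEPTH[narrow.rank]


def _rescue_tree():
    # a 0.99-supported clade of five Annelida plus the query tip q
    return UltrametricTree.from_newick(
        "(((q:1,(a1:0.8,(a2:0.6,(a3:0.4,(a4:0.2,a5:0.2):0.2):0.2):0.2):0.2)"
        "0.99:1,m1:2):1,m2:3);")


def _assignments(labels):
    out = []
    for tip, phylum in labels.items():
        if phylum is None:
            out.append(Assignment(query=tip, rank="unassigned", label="",
                                  basis="consensus"))
        else:
            out.append(Assignment(query=tip, rank="phylum", label=phylum,
                                  basis="consensus", lineage=(phylum, None, None)))
    return out


class TestCladeRescue:
    def test_rescued_inside_pure_supported_clade(self):
        tree = _rescue_tree()
        labels = {"q": None, "m1": "Mollusca", "m2": "Mollusca",
                  **{f"a{i}": "Annelida" for i in range(1, 6)}}
        out = {a.query: a for a in clade_rescue(tree, _assignments(labels))}
        assert out["q"].rank == "phylum"
        assert out["q"].label == "Annelida"
        assert out["q"].basis == "clade_rescue"

    def test_four_neighbours_insufficient(self):
        tree = UltrametricTree.from_newick(
            "(((q:1,(a1:0.8,(a2:0.6,(a3:0.4,a4:0.4):0.2):0.2):0.2)0.99:1,m1:2):1,m2:3);")
        labels = {"q": None, "m1": "Mollusca", "m2": "Mollusca",
                  **{f"a{i}": "Annelida" for i in range(1, 5)}}
        out = {a.query: a for a in clade_rescue(tree, _assignments(labels))}
        assert out["q"].rank == "unassigned"

    def test_mixed_phyla_block_rescue(self):
        tree = _rescue_tree()
        labels = {"q": None, "m1": "Mollusca", "m2": "Mollusca",
                  **{f"a{i}": "Annelida" for i in range(1, 5)}, "a5": "Mollusca"}
        out = {a.query: a for a in clade_rescue(tree, _assignments(labels))}
        assert out["q"].rank == "unassigned"

    def test_unsupported_clade_blocks_rescue(self):
        tree = UltrametricTree.from_newick(
            "(((q:1,(a1:0.8,(a2:0.6,(a3:0.4,(a4:0.2,a5:0.2):0.2):0.2):0.2):0.2)"
            "0.60:1,m1:2):1,m2:3);")
        labels = {"q": None, "m1": "Mollusca", "m2": "Mollusca",
                  **{f"a{i}": "Annelida" for i in range(1, 6)}}
        out = {a.query: a for a in clade_rescue(tree, _assignments(labels))}
        assert out["q"].rank == "unassigned"

    def test_assigned_tips_never_changed(self):
        tree = _rescue_tree()
        labels = {"q": None, "m1": "Mollusca", "m2": "Mollusca",
                  **{f"a{i}": "Annelida" for i in range(1, 6)}}
        before = _assignments(labels)
        after = {a.query: a for a in clade_rescue(tree, before)}
        assert after["m1"].label == "Mollusca"
        assert after["a1"].basis == "consensus"

    def test_invariant_to_assignment_order(self):
        tree = _rescue_tree()
        labels = {"q": None, "m1": "Mollusca", "m2": "Mollusca",
                  **{f"a{i}": "Annelida" for i in range(1, 6)}}
        fwd = clade_rescue(tree, _assignments(labels))
        rev = clade_rescue(tree, list(reversed(_assignments(labels))))
        assert {a.query: (a.rank, a.label) for a in fwd} == \
            {a.query: (a.rank, a.label) for a in rev}

    def test_missing_tip_raises(self):
        tree = _rescue_tree()
        bad = [Assignment(query="nope", rank="unassigned", label="", basis="consensus")]
        with pytest.raises(ValueError):
            clade_rescue(tree, bad)


class TestNaiveSearch:
    def _refs(self):
        seqs = ["ACGTTGCA" * 20, "TTGGCCAA" * 20, "ACACGTGT" * 20]
        return [
            SequenceRecord(id=f"ref{i}", seq=s, phylum=f"P{i}", species=f"sp{i}")
            for i, s in enumerate(seqs)
        ]

    def test_identical_reference_first(self):
        refs = self._refs()
        q = SequenceRecord(id="q", seq=refs[1].seq)
        hits = naive_search([q], refs)["q"]
        assert hits[0].pct_identity == pytest.approx(100.0)
        assert hits[0].species == "sp1"

    def test_k_larger_than_reference_count(self):
        refs = self._refs()
        q = SequenceRecord(id="q", seq=refs[0].seq)
        assert len(naive_search([q], refs, k=10)["q"]) == 3

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            naive_search([SequenceRecord(id="q", seq="ACGT")], [])

    def test_pipeline_recovers_species_for_clean_queries(self):
        refs = self._refs()
        queries = [SequenceRecord(id=f"q{i}", seq=r.seq) for i, r in enumerate(refs)]
        table = naive_search(queries, refs)
        assignments = classify(table)
        for i, a in enumerate(assignments):
            assert a.rank == "species"
            assert a.label == f"sp{i}"
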