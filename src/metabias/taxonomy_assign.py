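"""Consensus taxonomy from ranked similarity hits, plus phylogenetic rescue.

The classifier mirrors a common metabarcoding practice: retain the top-k
hits within a small identity window of the best hit (after discarding short
alignments), cap the assignable rank by the best hit's identity (>97%
species, >93% family, >90% phylum), and report the deepest rank at which
every retained hit agrees.  Sequences left unassigned can be rescued to
phylum level when they fall inside a well-supported clade of at least
``min_clade`` consistently-labelled sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .delimitation import _get_aligner, percent_identity
from .io_formats import Hit, HitTable, SequenceRecord, UltrametricTree

logger = logging.getLogger("metabias")

RANKS = ("phylum", "family", "species")  # shallow -> deep


@dataclass
class Assignment:
    """A taxonomic assignment for one query.

    ``rank`` is the achieved rank; ``label`` the name at that rank (empty
    iff unassigned); ``lineage`` retains the agreed prefix up to ``rank``
    so downstream steps (clade rescue, per-phylum reports) can recover the
    phylum of deep assignments.
    """

    query: str
    rank: str  # species | family | phylum | unassigned
    label: str
    basis: str  # consensus | clade_rescue
    lineage: tuple[str | None, str | None, str | None] = (None, None, None)

    def __post_init__(self) -> None:
        if (self.rank == "unassigned") != (self.label == ""):
            raise ValueError("rank 'unassigned' iff label empty")

    @property
    def assigned(self) -> bool:
        return self.rank != "unassigned"

    @property
    def phylum(self) -> str | None:
        return self.lineage[0]


def filter_hits(hits: Sequence[Hit], top_window: float = 0.5,
                min_span: int = 120, k: int = 5) -> list[Hit]:
    """Filter a ranked hit list: span first, then the identity window.

    Hits with alignment span <= ``min_span`` are discarded; the top hit is
    then the best surviving identity, and hits more than ``top_window``
    identity points below it are dropped; at most ``k`` hits are kept.
    """
    spanned = [h for h in hits if h.span > min_span]
    if not spanned:
        return []
    top = max(h.pct_identity for h in spanned)
    windowed = [h for h in spanned if h.pct_identity >= top - top_window]
    return windowed[:k]


def _rank_ceiling(best_identity: float,
                  thresholds: tuple[float, float, float]) -> int:
    """Depth (0-3) of the deepest rank allowed by the best-hit identity.
    Comparisons are strict, matching the >97 / >93 / >90 wording."""
    species_t, family_t, phylum_t = thresholds
    if best_identity > species_t:
        return 3
    if best_identity > family_t:
        return 2
    if best_identity > phylum_t:
        return 1
    return 0


def consensus_taxonomy(filtered_hits: Sequence[Hit],
                       thresholds: tuple[float, float, float] = (97.0, 93.0, 90.0),
                       query: str | None = None) -> Assignment:
    """Best consensus taxonomy of pre-filtered hits.

    The achieved rank is the deepest level, capped by the identity ceiling,
    at which all retained hits share a non-missing name (a lowest-common-
    lineage-prefix rule, independent of hit order).  No agreement even at
    phylum level yields an unassigned result.
    """
    qname = query if query is not None else (filtered_hits[0].query if filtered_hits else "")
    if not filtered_hits:
        return Assignment(query=qname, rank="unassigned", label="", basis="consensus")
    ceiling = _rank_ceiling(filtered_hits[0].pct_identity
                            if len(filtered_hits) == 1
                            else max(h.pct_identity for h in filtered_hits),
                            thresholds)
    agreed: list[str] = []
    for depth in range(3):
        names = {h.lineage[depth] for h in filtered_hits}
        if len(names) == 1 and None not in names:
            agreed.append(names.pop())
        else:
            break
    depth = min(ceiling, len(agreed))
    if depth == 0:
        return Assignment(query=qname, rank="unassigned", label="", basis="consensus")
    lineage = tuple(agreed[:depth]) + (None,) * (3 - depth)
    return Assignment(query=qname, rank=RANKS[depth - 1], label=agreed[depth - 1],
                      basis="consensus", lineage=lineage)  # type: ignore[arg-type]


def classify(hits: HitTable, top_window: float = 0.5, min_span: int = 120,
             k: int = 5,
             thresholds: tuple[float, float, float] = (97.0, 93.0, 90.0),
             ) -> list[Assignment]:
    """Filter + consensus for every query in a hit table."""
    return [
        consensus_taxonomy(filter_hits(qhits, top_window, min_span, k),
                           thresholds, query=query)
        for query, qhits in hits.items()
    ]


def clade_rescue(tree: UltrametricTree, assignments: Sequence[Assignment],
                 min_clade: int = 5, support_min: float = 0.95) -> list[Assignment]:
    """Rescue unassigned tips to phylum level via supported clades.

    For each unassigned tip, the smallest ancestral clade with support >=
    ``support_min`` is examined; if it contains at least ``min_clade`` other
    tips, all of them assigned and all of one phylum, the tip inherits that
    phylum (basis ``clade_rescue``).  Assigned tips are never changed, and
    rescued labels do not feed later rescues.
    """
    tip_nodes = {leaf.taxon.label: leaf for leaf in tree.tree.leaf_node_iter()}
    by_query = {a.query: a for a in assignments}
    for a in assignments:
        if a.query not in tip_nodes:
            raise ValueError(f"query {a.query!r} is not a tip of the tree")

    leaf_cache: dict[int, list[str]] = {}

    def leaves_under(node) -> list[str]:
        key = id(node)
        if key not in leaf_cache:
            leaf_cache[key] = [l.taxon.label for l in node.leaf_iter()]
        return leaf_cache[key]

    out: list[Assignment] = []
    for a in assignments:
        if a.assigned:
            out.append(a)
            continue
        node = tip_nodes[a.query].parent_node
        clade = None
        while node is not None:
            support = tree.node_support(node)
            if support is not None and support >= support_min:
                clade = node
                break
            node = node.parent_node
        rescued = None
        if clade is not None:
            others = [t for t in leaves_under(clade) if t != a.query]
            if len(others) >= min_clade:
                labels = {by_query[t].phylum if t in by_query else None
                          for t in others}
                phyla = {p for p in labels}
                if None not in phyla and len(phyla) == 1:
                    phylum = phyla.pop()
                    rescued = Assignment(
                        query=a.query, rank="phylum", label=phylum,
                        basis="clade_rescue", lineage=(phylum, None, None),
                    )
        out.append(rescued if rescued is not None else a)
    return out


def _identity_and_span(a: str, b: str) -> tuple[float, int]:
    if a == b:
        return 1.0, len(a)
    alignment = _get_aligner().align(a, b)[0]
    c = alignment.counts()
    total = c.identities + c.mismatches + c.gaps
    return c.identities / total, total


def naive_search(query_seqs: Sequence[SequenceRecord],
                 reference_seqs: Sequence[SequenceRecord],
                 k: int = 5,
                 lineages: Mapping[str, tuple[str | None, str | None, str | None]] | None = None,
                 ) -> HitTable:
    """Exhaustive top-k similarity search against a labelled reference set.

    A self-contained stand-in for an external similarity search on synthetic
    runs: every query is globally aligned to every reference and the top-k
    references by identity are reported (ties broken by reference id), with
    span equal to the aligned length.  Reference lineages come from
    ``lineages`` or are derived from the records' phylum/species labels
    (using the phylum name as a pseudo-family, since the synthetic taxonomy
    has no family level).
    """
    if not reference_seqs:
        raise ValueError("empty reference set")
    if lineages is None:
        lineages = {
            r.id: (r.phylum, f"{r.phylum}_fam" if r.phylum else None, r.species)
            for r in reference_seqs
        }
    table: HitTable = {}
    for q in query_seqs:
        scored = []
        for ref in reference_seqs:
            ident, span = _identity_and_span(q.seq, ref.seq)
            scored.append((ident, ref.id, span))
        scored.sort(key=lambda t: (-t[0], t[1]))
        table[q.id] = [
            Hit(query=q.id, lineage=lineages[ref_id],
                pct_identity=round(ident * 100.0, 6), span=span)
            for ident, ref_id, span in scored[:k]
        ]
    return table


def write_assignments(assignments: Sequence[Assignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("query\trank\tlabel\tbasis\n")
        for a in assignments:
            fh.write(f"{a.query}\t{a.rank}\t{a.label}\t{a.basis}\n")
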