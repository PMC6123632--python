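"""Taxonomic-unit delimitation: sequence variants, greedy OTUs, GMYC entities.

Three unit definitions are implemented over the same inputs:

* :func:`dereplicate_and_denoise` - exact dereplication followed by an
  abundance-ratio merge rule, yielding denoised sequence variants;
* :func:`cluster_greedy` - greedy centroid clustering at a percent-identity
  threshold (99% by default), yielding OTUs/eOTUs;
* :func:`gmyc_single_threshold` - the single-threshold GMYC model, delimiting
  evolutionary independent entities on an ultrametric gene tree by fitting a
  between-species pure-birth process above a threshold time and independent
  within-species coalescent processes below it.

All three are deterministic given input order and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io_formats import SequenceRecord, UltrametricTree
from .synthetic_data import reverse_complement

logger = logging.getLogger("metabias")

POOLED_SITE = "all"


@dataclass
class UnitSet:
    """The result of one delimitation method.

    ``units`` maps unit id to member sequence ids (a partition of the
    retained input ids); ``site_counts`` is a units x sites integer matrix;
    ``unit_phyla`` optionally labels units for per-phylum comparisons.
    """

    method: str
    units: dict[str, list[str]]
    site_counts: pd.DataFrame
    unit_phyla: dict[str, str] | None = None

    def incidence(self):
        from .io_formats import IncidenceMatrix

        return IncidenceMatrix((self.site_counts >= 1).astype(int))

    @property
    def n_units(self) -> int:
        return len(self.units)


def build_unitset(method: str, partition: Mapping[str, Sequence[str]],
                  records: Sequence[SequenceRecord] | None = None,
                  unit_phyla: Mapping[str, str] | None = None) -> UnitSet:
    """Assemble a UnitSet from a unit -> member-ids partition, accumulating
    per-site counts from the member records (missing sites pool into 'all')."""
    by_id = {r.id: r for r in records} if records else {}
    sites: list[str] = []
    rows: dict[str, dict[str, int]] = {}
    for unit, members in partition.items():
        row: dict[str, int] = {}
        for mid in members:
            rec = by_id.get(mid)
            site = rec.site if rec is not None and rec.site else POOLED_SITE
            weight = rec.abundance if rec is not None and rec.abundance else 1
            row[site] = row.get(site, 0) + weight
            if site not in sites:
                sites.append(site)
        rows[unit] = row
    counts = pd.DataFrame(
        [[rows[u].get(s, 0) for s in sites] for u in partition],
        index=list(partition), columns=sites, dtype=int,
    )
    return UnitSet(method=method,
                   units={u: list(m) for u, m in partition.items()},
                   site_counts=counts,
                   unit_phyla=dict(unit_phyla) if unit_phyla else None)


def richness_by_site(unitset: UnitSet) -> pd.Series:
    """Number of units present (count >= 1) at each site."""
    return (unitset.site_counts >= 1).sum(axis=0)


# ---------------------------------------------------------------------------
# pairwise identity
# ---------------------------------------------------------------------------

_aligner = None


def _get_aligner():
    global _aligner
    if _aligner is None:
        from Bio.Align import PairwiseAligner

        a = PairwiseAligner()
        a.mode = "global"
        a.match_score = 1
        a.mismatch_score = -1
        a.open_gap_score = -2
        a.extend_gap_score = -2
        _aligner = a
    return _aligner


def percent_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / aligned columns.

    Needleman-Wunsch with match 1 / mismatch -1 / gap -2; the denominator
    counts every aligned column (gap-base columns included; gap-gap columns
    cannot arise in a pairwise alignment).  Returns a fraction in [0, 1].
    """
    if not a or not b:
        raise ValueError("percent_identity requires non-empty sequences")
    if a == b:
        return 1.0
    alignment = _get_aligner().align(a, b)[0]
    counts = alignment.counts()
    total = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / total


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# sequence variants (dereplicate + denoise)
# ---------------------------------------------------------------------------

def dereplicate_and_denoise(reads: Sequence[SequenceRecord],
                            min_abundance: int = 2,
                            max_err_links: int = 1) -> UnitSet:
    """Denoise equal-length reads into sequence variants.

    Exact dereplication first; then any unique sequence with abundance below
    ``min_abundance`` that lies within ``max_err_links`` substitutions of a
    >= 10x-more-abundant sequence is merged into it (an abundance-ratio
    stand-in for a learned error model); remaining low-abundance sequences
    are dropped.  Per-site counts are preserved through merging.
    """
    if not reads:
        return build_unitset("sv", {})
    lengths = {len(r.seq) for r in reads}
    if len(lengths) > 1:
        raise ValueError(
            f"reads have unequal lengths {sorted(lengths)}; trim to a common "
            "length before denoising"
        )

    class _Uniq:
        __slots__ = ("seq", "members", "abundance")

        def __init__(self, seq: str):
            self.seq = seq
            self.members: list[str] = []
            self.abundance = 0

    uniq: dict[str, _Uniq] = {}
    weight = {r.id: (r.abundance or 1) for r in reads}
    for rec in reads:
        u = uniq.setdefault(rec.seq, _Uniq(rec.seq))
        u.members.append(rec.id)
        u.abundance += weight[rec.id]

    entries = sorted(uniq.values(), key=lambda u: (-u.abundance, u.members[0]))
    low = [u for u in entries if u.abundance < min_abundance]
    # merge quietest first so chains resolve toward the abundant end
    for u in sorted(low, key=lambda u: (u.abundance, u.members[0])):
        partners = [
            v for v in entries
            if v is not u and v.abundance >= 10 * u.abundance
            and _hamming(u.seq, v.seq) <= max_err_links
        ]
        if partners:
            target = max(partners, key=lambda v: (v.abundance, v.members[0]))
            target.members.extend(u.members)
            target.abundance += u.abundance
            u.abundance = 0
            u.members = []

    kept = [u for u in entries if u.members and u.abundance >= min_abundance]
    kept.sort(key=lambda u: (-u.abundance, u.members[0]))
    partition = {min(u.members): u.members for u in kept}
    by_id = {r.id: r for r in reads}
    records = [by_id[mid] for u in kept for mid in u.members]
    return build_unitset("sv", partition, records)


# ---------------------------------------------------------------------------
# greedy centroid clustering (OTU / eOTU)
# ---------------------------------------------------------------------------

def cluster_greedy(seqs: Sequence[SequenceRecord],
                   identity_threshold: float = 0.99,
                   method: str = "otu") -> UnitSet:
    """Greedy centroid clustering at a percent-identity threshold.

    Sequences are processed by decreasing abundance (ties broken by
    lexicographic id) and joined to the first centroid reaching the
    threshold; reverse-strand matches are allowed.  Unmatched sequences
    found new centroids.
    """
    if not 0.5 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0.5, 1]")
    if not seqs:
        return build_unitset(method, {})

    order = sorted(seqs, key=lambda r: (-(r.abundance or 1), r.id))
    centroids: list[SequenceRecord] = []
    partition: dict[str, list[str]] = {}
    for rec in order:
        rc = reverse_complement(rec.seq)
        assigned = False
        for cen in centroids:
            ident = percent_identity(rec.seq, cen.seq)
            if ident < identity_threshold:
                ident = max(ident, percent_identity(rc, cen.seq))
            if ident >= identity_threshold:
                partition[cen.id].append(rec.id)
                assigned = True
                break
        if not assigned:
            centroids.append(rec)
            partition[rec.id] = [rec.id]
    return build_unitset(method, partition, list(seqs))


def cluster_reads(reads: Sequence[SequenceRecord],
                  identity_threshold: float = 0.99,
                  method: str = "eotu") -> UnitSet:
    """Dereplicate reads exactly, cluster the unique sequences greedily
    (abundance-weighted), and expand clusters back to the original reads.

    Equivalent to :func:`cluster_greedy` on the full read set but avoids
    aligning duplicate sequences repeatedly.
    """
    if not reads:
        return build_unitset(method, {})
    uniq: dict[str, list[str]] = {}
    weight = {r.id: (r.abundance or 1) for r in reads}
    for rec in reads:
        uniq.setdefault(rec.seq, []).append(rec.id)
    reps = [
        SequenceRecord(id=min(ids), seq=seq,
                       abundance=sum(weight[i] for i in ids))
        for seq, ids in uniq.items()
    ]
    rep_units = cluster_greedy(reps, identity_threshold, method)
    members_of_rep = {min(ids): ids for seq, ids in uniq.items()}
    expanded = {
        unit: [rid for rep_id in rep_ids for rid in members_of_rep[rep_id]]
        for unit, rep_ids in rep_units.units.items()
    }
    return build_unitset(method, expanded, reads)


# ---------------------------------------------------------------------------
# GMYC single-threshold species delimitation
# ---------------------------------------------------------------------------

@dataclass
class GmycFit:
    """A fitted single-threshold GMYC model.

    ``threshold_time`` is measured back from the present (tips at 0);
    entities are the tip sets of the subtrees whose stem edge crosses the
    threshold, singletons included.  ``p_value`` is from a chi-square test
    of the mixed model against the single-process null (df = 2, one rate
    parameter and the threshold).
    """

    threshold_time: float
    n_entities: int
    logL_mixed: float
    logL_null: float
    LR: float
    p_value: float
    entities: list[frozenset[str]] = field(default_factory=list)


def _mixed_loglik(T: float, node_ages: list[tuple[float, object]],
                  subtree_ages: dict, tip_count: int) -> tuple[float, int]:
    """Log-likelihood of the single-threshold mixed model at threshold T,
    and the implied number of entities (edges crossing T).

    Every internode interval of the reconstructed tree is an exponential
    waiting time under the combined branching intensity
    b(t) = lambda * n_sp(t) + lambda_c * sum_j n_j(t) (n_j(t) - 1) / 2,
    where n_sp is the number of species-level lineages (all lineages above
    T; the constant number of clusters below T, i.e. speciation remains
    censored down to the present) and n_j counts the lineages of cluster j
    (zero coalescent intensity above T).  The two rates are maximized
    numerically; the final interval down to the present is censored.
    """
    ages_desc = sorted((a for a, _ in node_ages), reverse=True)
    root_age = ages_desc[0]
    clusters = [
        (internal_ages, n_tips)
        for _, internal_ages, n_tips in _clusters_below(T, subtree_ages)
    ]
    n_entities = len(clusters)

    def n_lineages(t: float) -> int:
        return 1 + sum(1 for a in ages_desc if a > t)

    def coal_sum(t: float) -> float:
        total = 0.0
        for internal_ages, n_tips in clusters:
            nj = 1 + sum(1 for a in internal_ages if a > t)
            total += nj * (nj - 1) / 2.0
        return total

    boundaries = sorted(set(ages_desc) | {0.0} | ({T} if 0.0 < T < root_age else set()),
                        reverse=True)
    A1 = 0.0
    A2 = 0.0
    seg_above: dict[float, tuple[float, float]] = {}  # lower boundary -> (s, c)
    for hi, lo in zip(boundaries, boundaries[1:]):
        mid = 0.5 * (hi + lo)
        s = float(n_lineages(mid)) if mid >= T else float(n_entities)
        c = coal_sum(mid) if mid < T else 0.0
        A1 += s * (hi - lo)
        A2 += c * (hi - lo)
        seg_above[lo] = (s, c)

    events = np.array([[*seg_above[a]] for a in ages_desc[1:]])  # root excluded
    s_e, c_e = events[:, 0], events[:, 1]
    n_ev = len(s_e)

    def negloglik(log_rates: np.ndarray) -> float:
        lam1, lam2 = np.exp(log_rates)
        rates = lam1 * s_e + lam2 * c_e
        return -(np.sum(np.log(rates)) - lam1 * A1 - lam2 * A2)

    if A2 == 0.0 or not np.any(c_e > 0):
        # no coalescent signal: closed-form pure-birth MLE
        lam1 = n_ev / A1
        logL = n_ev * np.log(lam1) + float(np.sum(np.log(s_e))) - n_ev
        return logL, n_entities

    from scipy.optimize import minimize

    x0 = np.log([max(n_ev / A1, 1e-8), max(n_ev / A2, 1e-8)])
    best = None
    for start in (x0, x0 + np.log([0.1, 10.0]), x0 + np.log([10.0, 0.1])):
        res = minimize(negloglik, start, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    return -best.fun, n_entities


def _clusters_below(T: float, subtree_ages: dict):
    """Yield (root age, sorted internal ages, tip count) for every maximal
    subtree whose stem crosses T (parent older than T, node at or below)."""
    for node, (age, parent_age, internal_ages, n_tips) in subtree_ages.items():
        if age <= T and (parent_age is None or parent_age > T):
            yield age, [a for a in internal_ages if a <= T], n_tips


def gmyc_single_threshold(tree: UltrametricTree, seed: int = 0) -> GmycFit:
    """Fit the single-threshold GMYC model and delimit entities.

    Candidate thresholds are the midpoints between consecutive distinct
    branching times plus the present (T = 0, at which the mixed model
    reduces exactly to the single pure-birth null, so LR >= 0 always).
    One between-species and one within-species rate are profiled out; the
    likelihood-ratio test uses chi-square with 2 degrees of freedom.
    Tied node heights are broken by a tiny seeded jitter.
    """
    if not tree.is_ultrametric:
        raise ValueError("GMYC requires an ultrametric tree")
    tips = tree.tip_labels()
    n = len(tips)
    if n < 3:
        raise ValueError("GMYC requires at least 3 tips")

    ages_map = tree.node_ages()
    internal = [(max(a, 0.0), node) for node, a in ages_map.items()
                if not node.is_leaf()]
    heights = np.array([a for a, _ in internal])
    if len(np.unique(np.round(heights, 12))) < len(heights):
        rng = np.random.default_rng(seed)
        scale = 1e-9 * max(tree.height, 1.0)
        jitter = dict(zip([id(nd) for _, nd in internal],
                          rng.uniform(0, scale, size=len(internal))))
        internal = [(a + jitter[id(nd)], nd) for a, nd in internal]
        logger.debug("GMYC: tied node heights perturbed by seeded jitter")
    age_by_node = {id(nd): a for a, nd in internal}

    # per-node summaries for cluster extraction
    subtree_ages: dict = {}
    leaf_sets: dict[int, frozenset[str]] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            leaf_sets[id(node)] = frozenset([node.taxon.label])
            subtree_ages[node] = (0.0, _parent_age(node, age_by_node), [], 1)
        else:
            children = node.child_nodes()
            members = frozenset().union(*(leaf_sets[id(c)] for c in children))
            leaf_sets[id(node)] = members
            own = age_by_node[id(node)]
            internal_ages = sorted(
                [a for c in children for a in subtree_ages[c][2]] + [own]
            )
            subtree_ages[node] = (
                own, _parent_age(node, age_by_node), internal_ages, len(members)
            )

    node_ages = sorted(internal, key=lambda x: x[0])
    distinct = sorted(set(a for a, _ in node_ages))
    candidates = [0.0]
    grid = [0.0] + distinct
    for lo, hi in zip(grid, grid[1:]):
        candidates.append(0.5 * (lo + hi))

    best_T, best_logL, best_n = 0.0, -np.inf, n
    null_logL = None
    for T in candidates:
        logL, n_ent = _mixed_loglik(T, node_ages, subtree_ages, n)
        if T == 0.0:
            null_logL = logL
        if logL > best_logL + 1e-12:
            best_T, best_logL, best_n = T, logL, n_ent

    assert null_logL is not None
    LR = max(0.0, 2.0 * (best_logL - null_logL))
    entities = [
        leaf_sets[id(node)]
        for node, (age, parent_age, _, _) in subtree_ages.items()
        if age <= best_T and (parent_age is None or parent_age > best_T)
    ]
    entities.sort(key=lambda s: sorted(s)[0])
    return GmycFit(
        threshold_time=best_T,
        n_entities=best_n,
        logL_mixed=best_logL,
        logL_null=null_logL,
        LR=LR,
        p_value=float(chi2.sf(LR, df=2)),
        entities=entities,
    )


def _parent_age(node, age_by_node) -> float | None:
    parent = node.parent_node
    if parent is None:
        return None
    return age_by_node[id(parent)]


def gmyc_unitset(fit: GmycFit, records: Sequence[SequenceRecord] | None = None) -> UnitSet:
    """Convert GMYC entities into a UnitSet (unit ids from the first tip)."""
    partition = {sorted(ent)[0]: sorted(ent) for ent in fit.entities}
    return build_unitset("entity", partition, records)
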