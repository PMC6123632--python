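"""Synthetic communities with the generative structure the study design assumes.

The generator produces (a) a species phylogeny with Yule (pure-birth)
between-species branching and Kingman-coalescent within-species branching,
(b) 18S-like amplicons with two variable regions of unequal Jukes-Cantor
substitution rates flanked by conserved primer motifs, (c) multi-site
incidence with phylum- and method-specific detection probabilities, and
(d) reads with i.i.d. substitution errors and Poisson depth.  Everything is
bit-reproducible given (parameters, seed), and a :class:`SyntheticTruth`
object exactly explains every emitted read id.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import IncidenceMatrix, SequenceRecord, UltrametricTree

# Printed primer sets: EukF/SR7 amplify the V1-V2 region from single
# specimens; Illumina_Euk_1391f/EukBr amplify the V9 region for metabarcoding.
V1V2_FWD = "AACCTGGTTGATCCTGCCAGT"
V1V2_REV = "GTTCAACTACGAGCTTTTTAA"
V9_FWD = "GTACACACCGCCCGTC"
V9_REV = "TGATCCTTCTGCAGGTTCACCTAC"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class RegionSpec:
    """One variable region: length, substitution rate, flanking primers.

    Rates are substitutions/site per unit of tree time; primers are perfectly
    conserved (rate 0) in simulation, mirroring their role as conserved
    annealing sites.
    """

    name: str
    length: int
    rate: float
    fwd_primer: str
    rev_primer: str

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("region length must be positive")
        if self.rate < 0:
            raise ValueError("substitution rate must be >= 0")


def default_regions(v1v2_rate: float = 0.1, v9_rate: float = 0.3) -> list[RegionSpec]:
    """The two-marker layout: a ~300 bp V1-V2-like region and a 130 bp
    V9-like region, the V9 rate higher by default (3x)."""
    return [
        RegionSpec("V1V2", length=300, rate=v1v2_rate,
                   fwd_primer=V1V2_FWD, rev_primer=V1V2_REV),
        RegionSpec("V9", length=130, rate=v9_rate,
                   fwd_primer=V9_FWD, rev_primer=V9_REV),
    ]


@dataclass
class DetectionModel:
    """Per-(phylum, method) detection probabilities plus read-generation noise.

    ``detection`` maps ``(phylum, method)`` to a probability; missing pairs
    fall back to ``default_p``.  The per-phylum values shipped anywhere in
    this package are illustrative: the study design motivates their structure
    (phyla respond unevenly to the survey method) but prints no numbers.
    """

    methods: tuple[str, ...]
    detection: dict[tuple[str, str], float] = field(default_factory=dict)
    default_p: float = 1.0
    read_depth_mean: float = 20.0
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        for key, p in self.detection.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"detection probability for {key} outside [0, 1]")
        if not 0.0 <= self.default_p <= 1.0:
            raise ValueError("default_p outside [0, 1]")
        if self.read_depth_mean <= 0:
            raise ValueError("read_depth_mean must be > 0")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate outside [0, 0.1]")

    def p(self, phylum: str, method: str) -> float:
        return self.detection.get((phylum, method), self.default_p)


# ---------------------------------------------------------------------------
# tree simulation (lightweight node structs -> newick -> UltrametricTree)
# ---------------------------------------------------------------------------

class _SimNode:
    __slots__ = ("name", "length", "children")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = length
        self.children: list[_SimNode] = []

    def newick(self) -> str:
        if self.children:
            inner = ",".join(c.newick() for c in self.children)
            return f"({inner}):{self.length:.12g}"
        return f"{self.name}:{self.length:.12g}"


def _finish(root: _SimNode) -> UltrametricTree:
    body = root.newick()
    # strip the root's own zero-length edge
    body = body.rsplit(":", 1)[0] if not root.children else f"({','.join(c.newick() for c in root.children)})"
    return UltrametricTree.from_newick(body + ";")


def simulate_yule_tree(n_species: int, birth_rate: float, seed: int | np.random.Generator) -> UltrametricTree:
    """Simulate a pure-birth (Yule) species tree with ``n_species`` tips.

    Starting from the root split (two lineages), waiting times while ``k``
    lineages exist are Exp(birth_rate * k); after the (n-1)-th split one
    further Exp(birth_rate * n) interval runs to the present, so the expected
    root height is sum_{k=2..n} 1/(birth_rate * k).
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    if n_species == 1:
        return UltrametricTree.from_newick("sp1:0;")

    root = _SimNode()
    active: list[tuple[_SimNode, float]] = []  # (node, birth time)
    for _ in range(2):
        child = _SimNode()
        root.children.append(child)
        active.append((child, 0.0))
    t = 0.0
    k = 2
    while k < n_species:
        t += rng.exponential(1.0 / (birth_rate * k))
        idx = int(rng.integers(len(active)))
        node, born = active.pop(idx)
        node.length = t - born
        for _ in range(2):
            child = _SimNode()
            node.children.append(child)
            active.append((child, t))
        k += 1
    t_end = t + rng.exponential(1.0 / (birth_rate * n_species))
    for i, (node, born) in enumerate(active):
        node.length = t_end - born
    # name tips in traversal order
    counter = [0]

    def _name(node: _SimNode) -> None:
        if not node.children:
            counter[0] += 1
            node.name = f"sp{counter[0]}"
        for c in node.children:
            _name(c)

    _name(root)
    return _finish(root)


def _copy_dendropy(tree: UltrametricTree) -> _SimNode:
    def convert(node) -> _SimNode:
        out = _SimNode(
            name=node.taxon.label if node.is_leaf() else None,
            length=node.edge.length or 0.0,
        )
        out.children = [convert(c) for c in node.child_nodes()]
        return out

    root = convert(tree.tree.seed_node)
    root.length = 0.0
    return root


def _coalescent_subtree(species: str, n: int, theta: float, max_height: float,
                        rng: np.random.Generator, retries: int = 100) -> tuple[_SimNode, float]:
    """Kingman coalescent of ``n`` lineages; total height must stay below
    ``max_height`` (the species' terminal branch), resampling a bounded
    number of times before giving up."""
    for _ in range(retries):
        heights = []
        h = 0.0
        for j in range(n, 1, -1):
            h += rng.exponential(theta / (j * (j - 1) / 2.0))
            heights.append(h)
        if not heights or heights[-1] < max_height:
            break
    else:
        raise RuntimeError(
            f"coalescent height for {species} exceeded its terminal branch "
            f"({max_height:.4g}) in {retries} attempts; reduce theta"
        )
    lineages: list[tuple[_SimNode, float]] = [
        (_SimNode(name=f"{species}_t{j + 1}"), 0.0) for j in range(n)
    ]
    for h_event in heights:
        i = int(rng.integers(len(lineages)))
        a, a_start = lineages.pop(i)
        j = int(rng.integers(len(lineages)))
        b, b_start = lineages.pop(j)
        a.length = h_event - a_start
        b.length = h_event - b_start
        parent = _SimNode()
        parent.children = [a, b]
        lineages.append((parent, h_event))
    root, root_start = lineages[0]
    return root, root_start  # root_start == total height (0 for n == 1)


def graft_coalescent_tips(species_tree: UltrametricTree, within_species_n: int,
                          theta: float, seed: int | np.random.Generator) -> UltrametricTree:
    """Replace every species tip by a coalescent subtree of its individuals.

    Each species tip becomes the MRCA of ``within_species_n`` tips named
    ``<species>_t<j>``; the within-species tree height is constrained below
    the species' terminal branch so the grafted tree stays ultrametric and
    every within-species MRCA is younger than every between-species node
    whenever theta is small relative to the species-tree heights.
    """
    if within_species_n < 1:
        raise ValueError("within_species_n must be >= 1")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    root = _copy_dendropy(species_tree)

    def graft(node: _SimNode) -> _SimNode:
        if not node.children:
            sub, height = _coalescent_subtree(
                node.name, within_species_n, theta, node.length, rng
            )
            sub.length = node.length - height
            return sub
        node.children = [graft(c) for c in node.children]
        return node

    root = graft(root)
    if not root.children:  # single-species tree
        tree = UltrametricTree.from_newick(root.newick() + ";")
    else:
        tree = _finish(root)
    return tree


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def _jc_mutate(seq: np.ndarray, rate: float, t: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor evolution: site changes with prob 3/4(1 - exp(-4rt/3)),
    and a changed site picks one of the three other bases uniformly."""
    if rate == 0.0 or t == 0.0:
        return seq.copy()
    p_change = 0.75 * (1.0 - np.exp(-4.0 * rate * t / 3.0))
    hit = rng.random(seq.shape[0]) < p_change
    out = seq.copy()
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 4
    return out


def species_of_tip(tip_label: str) -> str:
    """Tip labels are ``<species>_t<j>`` (grafted trees) or bare species names."""
    head, sep, tail = tip_label.rpartition("_t")
    if sep and tail.isdigit():
        return head
    return tip_label


def evolve_sequences(tree: UltrametricTree, regions: Sequence[RegionSpec],
                     seed: int | np.random.Generator) -> list[SequenceRecord]:
    """Evolve region sequences down the tree and emit per-tip amplicons.

    The emitted sequence is ``fwd + region + revcomp(rev)`` concatenated over
    regions, i.e. the forward genomic strand with the reverse primer site
    appearing as its reverse complement.  Primers are identical across tips.
    """
    if not regions:
        raise ValueError("at least one region required")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    root_state = {r.name: rng.integers(0, 4, size=r.length).astype(np.uint8)
                  for r in regions}
    dtree = tree.tree
    states: dict[int, dict[str, np.ndarray]] = {id(dtree.seed_node): root_state}
    records: list[SequenceRecord] = []
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            continue
        parent_state = states[id(node.parent_node)]
        t = node.edge.length or 0.0
        state = {r.name: _jc_mutate(parent_state[r.name], r.rate, t, rng)
                 for r in regions}
        states[id(node)] = state
        if node.is_leaf():
            parts = []
            for r in regions:
                region_seq = bytes(_BASES[state[r.name]]).decode()
                parts.append(r.fwd_primer + region_seq + reverse_complement(r.rev_primer))
            label = node.taxon.label
            records.append(SequenceRecord(id=label, seq="".join(parts),
                                          species=species_of_tip(label)))
    return records


def assign_phyla(species: Sequence[str], phyla: Sequence[str]) -> dict[str, str]:
    """Deterministically partition species into contiguous phylum blocks."""
    if not phyla:
        raise ValueError("need at least one phylum")
    blocks = np.array_split(np.arange(len(species)), len(phyla))
    out: dict[str, str] = {}
    for phylum, idx in zip(phyla, blocks):
        for i in idx:
            out[species[int(i)]] = phylum
    return out


# ---------------------------------------------------------------------------
# survey simulation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Ground truth for one simulated survey: the species set with phylum
    labels, the true incidence, and a map explaining every emitted read."""

    species: list[str]
    phylum_of: dict[str, str]
    incidence_true: IncidenceMatrix
    read_truth: dict[str, dict[str, str]]  # read id -> {species, site, method}
    tree_newick: str
    params: dict

    def to_json(self, path: str | Path) -> None:
        payload = {
            "species": self.species,
            "phylum_of": self.phylum_of,
            "incidence_true": {
                "units": self.incidence_true.units,
                "sites": self.incidence_true.sites,
                "cells": self.incidence_true.data.to_numpy().tolist(),
            },
            "read_truth": self.read_truth,
            "tree_newick": self.tree_newick,
            "params": self.params,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        inc = payload["incidence_true"]
        matrix = IncidenceMatrix(pd.DataFrame(
            inc["cells"], index=inc["units"], columns=inc["sites"]
        ))
        return cls(
            species=payload["species"],
            phylum_of=payload["phylum_of"],
            incidence_true=matrix,
            read_truth=payload["read_truth"],
            tree_newick=payload["tree_newick"],
            params=payload["params"],
        )


def _with_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate == 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    acgt = np.array([65, 67, 71, 84], dtype=np.uint8)
    idx = np.searchsorted(acgt, arr)
    hit = rng.random(arr.shape[0]) < error_rate
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum()))
        idx[hit] = (idx[hit] + shift) % 4
        arr = acgt[idx]
    return arr.tobytes().decode()


def simulate_survey(truth_tree: UltrametricTree, sequences: Sequence[SequenceRecord],
                    n_sites: int, occupancy_prob: float, detection: DetectionModel,
                    seed: int | np.random.Generator,
                    phylum_of: Mapping[str, str] | None = None,
                    ) -> tuple[IncidenceMatrix, dict[str, list[SequenceRecord]], SyntheticTruth]:
    """Simulate a multi-site incidence survey observed by several methods.

    True incidence is Bernoulli(occupancy_prob) per species x site with at
    least one occupied site per species.  A present species is detected by a
    method with its (phylum, method) probability; detections yield
    1 + Poisson(read_depth_mean - 1) reads copied from a random individual
    amplicon of that species, with i.i.d. substitution errors.
    """
    if n_sites < 2:
        raise ValueError("n_sites must be >= 2")
    if not 0.0 < occupancy_prob <= 1.0:
        raise ValueError("occupancy_prob must be in (0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    by_species: dict[str, list[SequenceRecord]] = {}
    for rec in sequences:
        sp = rec.species or species_of_tip(rec.id)
        by_species.setdefault(sp, []).append(rec)
    species = list(by_species)

    if phylum_of is None:
        phylum_of = {rec.species or species_of_tip(rec.id): rec.phylum
                     for rec in sequences if rec.phylum is not None}
        if len(phylum_of) < len(species):
            phylum_of = {sp: "P1" for sp in species}
    phylum_of = dict(phylum_of)

    sites = [f"site{j + 1:02d}" for j in range(n_sites)]
    cells = np.zeros((len(species), n_sites), dtype=int)
    for i in range(len(species)):
        row = (rng.random(n_sites) < occupancy_prob).astype(int)
        while row.sum() == 0:
            row = (rng.random(n_sites) < occupancy_prob).astype(int)
        cells[i] = row
    incidence = IncidenceMatrix(pd.DataFrame(cells, index=species, columns=sites))

    depth_shift = max(detection.read_depth_mean - 1.0, 0.0)
    observed: dict[str, list[SequenceRecord]] = {m: [] for m in detection.methods}
    read_truth: dict[str, dict[str, str]] = {}
    for method in detection.methods:
        for j, site in enumerate(sites):
            for i, sp in enumerate(species):
                if cells[i, j] == 0:
                    continue
                if rng.random() >= detection.p(phylum_of[sp], method):
                    continue
                depth = 1 + int(rng.poisson(depth_shift))
                pool = by_species[sp]
                for k in range(depth):
                    template = pool[int(rng.integers(len(pool)))]
                    read_id = f"{method}_{site}_{sp}_r{k + 1}"
                    observed[method].append(SequenceRecord(
                        id=read_id,
                        seq=_with_errors(template.seq, detection.error_rate, rng),
                        phylum=phylum_of[sp],
                        species=sp,
                        site=site,
                    ))
                    read_truth[read_id] = {"species": sp, "site": site, "method": method}

    truth = SyntheticTruth(
        species=species,
        phylum_of=phylum_of,
        incidence_true=incidence,
        read_truth=read_truth,
        tree_newick=truth_tree.to_newick(),
        params={
            "n_sites": n_sites,
            "occupancy_prob": occupancy_prob,
            "read_depth_mean": detection.read_depth_mean,
            "error_rate": detection.error_rate,
            "methods": list(detection.methods),
        },
    )
    return incidence, observed, truth
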