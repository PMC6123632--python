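"""Readers and writers for the formats the pipeline touches.

All downstream modules consume the in-memory types defined here
(:class:`SequenceRecord`, :class:`UltrametricTree`, :class:`IncidenceMatrix`,
:class:`HitTable`) and never open files themselves.  FASTA carries optional
in-band metadata as whitespace-separated ``key=value`` tokens in the
description line (``phylum=``, ``species=``, ``site=``, ``abundance=``);
unknown keys are ignored.  Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import dendropy
import pandas as pd
import yaml

logger = logging.getLogger("metabias")

_VALID_BASES = frozenset("ACGTN")
_META_KEYS = ("phylum", "species", "site", "abundance")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SequenceRecord:
    """One identified amplicon or environmental read.

    ``phylum``/``species`` are truth labels for synthetic data or
    classifications for real data; ``site`` and ``abundance`` carry survey
    provenance.  ``seq`` is an uppercase string over {A, C, G, T, N}.
    """

    id: str
    seq: str
    phylum: str | None = None
    species: str | None = None
    site: str | None = None
    abundance: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record id must be non-empty")
        self.seq = self.seq.upper()
        if len(self.seq) < 1:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - _VALID_BASES
        if bad:
            raise FormatError(
                f"record {self.id!r}: invalid bases {sorted(bad)!r}"
            )
        if self.abundance is not None:
            self.abundance = int(self.abundance)
            if self.abundance < 1:
                raise FormatError(
                    f"record {self.id!r}: abundance must be >= 1"
                )


def _format_header(rec: SequenceRecord) -> str:
    parts = [rec.id]
    for key in _META_KEYS:
        val = getattr(rec, key)
        if val is not None:
            parts.append(f"{key}={val}")
    return " ".join(parts)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, in file order.

    Description-line tokens of the form ``key=value`` populate the metadata
    fields; other tokens are ignored.  Duplicate ids are an error; an empty
    file yields an empty list.
    """
    from Bio import SeqIO

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio_rec in SeqIO.parse(str(path), "fasta"):
        if bio_rec.id in seen:
            raise FormatError(f"duplicate sequence id {bio_rec.id!r} in {path}")
        seen.add(bio_rec.id)
        meta: dict[str, str] = {}
        for token in bio_rec.description.split()[1:]:
            if "=" in token:
                key, _, val = token.partition("=")
                if key in _META_KEYS:
                    meta[key] = val
        records.append(
            SequenceRecord(
                id=bio_rec.id,
                seq=str(bio_rec.seq),
                phylum=meta.get("phylum"),
                species=meta.get("species"),
                site=meta.get("site"),
                abundance=int(meta["abundance"]) if "abundance" in meta else None,
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns.

    Metadata fields are emitted as ``key=value`` tokens in a fixed order so
    that write -> read -> write is byte-identical.
    """
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{_format_header(rec)}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


@dataclass
class UltrametricTree:
    """A rooted tree with branch lengths, nominally time-calibrated.

    Wraps a :class:`dendropy.Tree`.  ``is_ultrametric`` records whether the
    tip-depth spread is within ``tolerance`` (relative to tree height);
    internal node labels parseable as floats are kept as support values.
    """

    tree: dendropy.Tree
    is_ultrametric: bool = True
    height: float = 0.0

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, rel_tolerance: float = 1e-6) -> "UltrametricTree":
        depths = _leaf_depths(tree)
        if depths:
            height = max(depths.values())
            spread = height - min(depths.values())
            ultra = spread <= rel_tolerance * max(height, 1e-300)
        else:  # pragma: no cover - dendropy trees always have >= 1 leaf
            height, ultra = 0.0, True
        return cls(tree=tree, is_ultrametric=ultra, height=height)

    @classmethod
    def from_newick(cls, newick: str, rel_tolerance: float = 1e-6) -> "UltrametricTree":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise FormatError(f"Newick parse error: {exc}") from exc
        return cls.from_dendropy(tree, rel_tolerance)

    # -- convenience accessors -------------------------------------------
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def node_support(self, node: dendropy.Node) -> float | None:
        if node.label is None:
            return None
        try:
            return float(node.label)
        except ValueError:
            return None

    def leaf_depths(self) -> dict[str, float]:
        return {k: v for k, v in _leaf_depths(self.tree).items()}

    def node_ages(self) -> dict[dendropy.Node, float]:
        """Age (time above the present) of every node; tips have age ~0."""
        ages: dict[dendropy.Node, float] = {}
        for node, depth in _node_depths(self.tree).items():
            ages[node] = self.height - depth
        return ages

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def clone(self) -> "UltrametricTree":
        return UltrametricTree.from_newick(self.to_newick())


def _node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0
        depths[node] = edge + (depths[parent] if parent is not None else 0.0)
    return depths


def _leaf_depths(tree: dendropy.Tree) -> dict[str, float]:
    depths = _node_depths(tree)
    return {n.taxon.label: d for n, d in depths.items() if n.is_leaf()}


def read_newick(path: str | Path, rel_tolerance: float = 1e-6) -> UltrametricTree:
    """Read a single rooted Newick tree; flags (not rejects) non-ultrametric input."""
    text = Path(path).read_text()
    tree = UltrametricTree.from_newick(text, rel_tolerance)
    if not tree.is_ultrametric:
        logger.warning("tree in %s is not ultrametric (tip depth spread exceeds tolerance)", path)
    return tree


def write_newick(tree: UltrametricTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


class IncidenceMatrix:
    """A binary units x sites occurrence table.

    The common currency of the richness estimators and the community
    comparisons.  ``q1``/``q2`` count units occurring in exactly one / two
    sites, following incidence-based estimator conventions.
    """

    def __init__(self, data: pd.DataFrame):
        values = data.to_numpy()
        bad = (values != 0) & (values != 1)
        if bad.any():
            i, j = [int(x[0]) for x in bad.nonzero()]
            raise FormatError(
                f"non-binary incidence cell at unit {data.index[i]!r}, "
                f"site {data.columns[j]!r}: {values[i, j]!r}"
            )
        self.data = data.astype(int)

    @property
    def units(self) -> list[str]:
        return list(self.data.index)

    @property
    def sites(self) -> list[str]:
        return list(self.data.columns)

    @property
    def m(self) -> int:
        """Number of sites."""
        return self.data.shape[1]

    @property
    def s_obs(self) -> int:
        return int((self.data.sum(axis=1) >= 1).sum())

    @property
    def q1(self) -> int:
        return int((self.data.sum(axis=1) == 1).sum())

    @property
    def q2(self) -> int:
        return int((self.data.sum(axis=1) == 2).sum())

    def site_unit_sets(self) -> dict[str, frozenset[str]]:
        return {
            site: frozenset(self.data.index[self.data[site] == 1])
            for site in self.data.columns
        }

    def __eq__(self, other: object) -> bool:
        return isinstance(other, IncidenceMatrix) and self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"IncidenceMatrix({len(self.units)} units x {self.m} sites)"


def read_incidence(path: str | Path) -> IncidenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = [str(c) for c in df.columns]
    return IncidenceMatrix(df)


def write_incidence(matrix: IncidenceMatrix, path: str | Path) -> None:
    out = matrix.data.copy()
    out.index.name = out.index.name or "unit"
    out.to_csv(path, sep="\t")


@dataclass
class Hit:
    """One similarity-search hit: query, 3-rank lineage, identity, span."""

    query: str
    lineage: tuple[str | None, str | None, str | None]  # phylum, family, species
    pct_identity: float
    span: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise FormatError(
                f"hit for {self.query!r}: pct_identity {self.pct_identity} "
                "outside [0, 100]"
            )
        phylum, family, species = self.lineage
        if species is not None and family is None:
            raise FormatError(
                f"hit for {self.query!r}: species without family in lineage"
            )
        if self.span < 0:
            raise FormatError(f"hit for {self.query!r}: negative span")

    @property
    def phylum(self) -> str | None:
        return self.lineage[0]

    @property
    def family(self) -> str | None:
        return self.lineage[1]

    @property
    def species(self) -> str | None:
        return self.lineage[2]


def parse_lineage(text: str) -> tuple[str | None, str | None, str | None]:
    """Parse ``phylum;family;species``; deeper lineages truncate to 3 ranks."""
    ranks = [r.strip() or None for r in text.split(";")]
    ranks = (ranks + [None, None, None])[:3]
    return (ranks[0], ranks[1], ranks[2])


HitTable = dict[str, list[Hit]]
"""Hits grouped per query, sorted by descending identity (stable on ties)."""


def read_hits(path: str | Path) -> HitTable:
    """Read a similarity-hit TSV (query, lineage, pct_identity, span).

    A header row naming the first column ``query`` is tolerated.  Hits are
    grouped per query and sorted by descending identity; ties keep file order.
    """
    rows: list[tuple[str, str, float, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() == "query":
                continue
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 tab-separated columns")
            try:
                ident = float(parts[2])
                span = int(float(parts[3]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            rows.append((parts[0], parts[1], ident, span))

    table: HitTable = {}
    for query, lineage_text, ident, span in rows:
        table.setdefault(query, []).append(
            Hit(query=query, lineage=parse_lineage(lineage_text),
                pct_identity=ident, span=span)
        )
    for query in table:
        table[query].sort(key=lambda h: -h.pct_identity)  # stable: ties keep file order
    return table


def write_hits(table: HitTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query\tsubject_lineage\tpct_identity\talign_span\n")
        for query in table:
            for hit in table[query]:
                lineage = ";".join(r for r in hit.lineage if r is not None)
                fh.write(f"{query}\t{lineage}\t{hit.pct_identity:g}\t{hit.span}\n")


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read a site covariate TSV (one row per site, first column the site id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate site id {dup!r} in covariate table")
    if df.index.isnull().any() or (df.index == "").any():
        raise FormatError("missing site key in covariate table")
    return df


def write_covariates(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = out.index.name or "site"
    out.to_csv(path, sep="\t")


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with the study's defaults.

    Identity/rank thresholds, the hit-filter window and span, and the
    clade-rescue size follow the printed analysis choices; permutation counts
    and the clade-support floor are package defaults (documented in the
    methods note).  The seed is always explicit.
    """

    cluster_identity: float = 0.99      # greedy clustering identity threshold
    rank_thresholds: tuple[float, float, float] = (97.0, 93.0, 90.0)
    top_window: float = 0.5             # %-identity window below the top hit
    min_span: int = 120                 # alignment span must exceed this (bp)
    top_k: int = 5                      # hits considered per query
    min_clade: int = 5                  # "at least five other sequences"
    support_min: float = 0.95           # clade support floor for rescue
    min_abundance: int = 2              # denoiser: retain threshold
    max_err_links: int = 1              # denoiser: substitution link radius
    n_perm: int = 999
    null_reps: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 < self.cluster_identity <= 1.0:
            raise ValueError("cluster_identity must be in (0.5, 1]")
        t = self.rank_thresholds
        if not (0 <= t[2] <= t[1] <= t[0] <= 100):
            raise ValueError("rank_thresholds must be descending within [0, 100]")
        if self.top_window < 0 or self.min_span < 0 or self.top_k < 1:
            raise ValueError("invalid hit-filter parameters")
        if not 0.0 <= self.support_min <= 1.0:
            raise ValueError("support_min must be in [0, 1]")
        if self.n_perm < 99 or self.null_reps < 1:
            raise ValueError("permutation counts too small")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "rank_thresholds" in raw:
            raw["rank_thresholds"] = tuple(raw["rank_thresholds"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["rank_thresholds"] = list(data["rank_thresholds"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def setup_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler()
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())
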