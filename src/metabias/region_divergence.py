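"""Primer location, variable-region extraction, and identity profiles.

Compares the information content of marker sub-regions (V1-V2 vs V9 of 18S
rRNA): primers are located by ungapped Hamming matching with IUPAC expansion
on both strands, the between-primer interval is extracted (primers excluded
by default), and per-group mean pairwise identity is computed per region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .delimitation import percent_identity
from .io_formats import SequenceRecord
from .synthetic_data import RegionSpec

logger = logging.getLogger("metabias")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_COMP = {
    "A": "T", "T": "A", "C": "G", "G": "C", "R": "Y", "Y": "R",
    "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}


def iupac_reverse_complement(primer: str) -> str:
    return "".join(_IUPAC_COMP[b] for b in reversed(primer.upper()))


@dataclass
class RegionHit:
    """A located region: 0-based half-open forward-strand coordinates."""

    seq_id: str
    region_name: str
    start: int
    end: int
    strand: str  # + or -
    fwd_mismatches: int
    rev_mismatches: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("require 0 <= start < end")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")


def _mismatch_profile(seq: str, primer: str) -> np.ndarray:
    """Mismatch count of the primer at every window start (IUPAC-aware;
    an N in the sequence matches any primer code)."""
    n, k = len(seq), len(primer)
    if n < k:
        return np.empty(0, dtype=int)
    seq_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(seq_arr, k)
    mism = np.zeros(windows.shape[0], dtype=int)
    for j, code in enumerate(primer.upper()):
        allowed = set(IUPAC[code]) | {"N"}
        ok = np.zeros(windows.shape[0], dtype=bool)
        for base in allowed:
            ok |= windows[:, j] == ord(base)
        mism += ~ok
    return mism


def _best_window(seq: str, primer: str, max_mismatch: int,
                 min_start: int = 0) -> tuple[int, int] | None:
    """Leftmost minimal-mismatch placement at or after ``min_start``."""
    mism = _mismatch_profile(seq, primer)
    if mism.size <= min_start:
        return None
    sub = mism[min_start:]
    best = int(sub.min())
    if best > max_mismatch:
        return None
    pos = min_start + int(np.argmin(sub))
    return pos, best


def _locate_forward(seq: str, fwd: str, rev: str,
                    max_mismatch: int) -> tuple[int, int, int, int] | None:
    """Locate fwd then revcomp(rev) downstream on the given strand; returns
    (start, end, fwd_mm, rev_mm) for the between-primer interval."""
    hit_f = _best_window(seq, fwd, max_mismatch)
    if hit_f is None:
        return None
    f_pos, f_mm = hit_f
    region_start = f_pos + len(fwd)
    rc_rev = iupac_reverse_complement(rev)
    hit_r = _best_window(seq, rc_rev, max_mismatch, min_start=region_start + 1)
    if hit_r is None:
        return None
    r_pos, r_mm = hit_r
    if r_pos <= region_start:
        return None
    return region_start, r_pos, f_mm, r_mm


def locate_primer_pair(seq: SequenceRecord | str, fwd_primer: str, rev_primer: str,
                       max_mismatch: int = 2, region_name: str = "",
                       seq_id: str | None = None) -> RegionHit | None:
    """Best placement of a primer pair on either strand, or None.

    The reverse primer is matched as its reverse complement downstream of
    the forward primer; minus-strand placements are reported in forward
    coordinates.  The returned interval is the region *between* the primers.
    """
    if isinstance(seq, SequenceRecord):
        seq_id = seq_id or seq.id
        text = seq.seq
    else:
        text = seq.upper()
        seq_id = seq_id or ""

    plus = _locate_forward(text, fwd_primer, rev_primer, max_mismatch)
    rc = _revcomp_seq(text)
    minus = _locate_forward(rc, fwd_primer, rev_primer, max_mismatch)

    candidates: list[tuple[int, RegionHit]] = []
    if plus is not None:
        s, e, fm, rm = plus
        candidates.append((fm + rm, RegionHit(seq_id, region_name, s, e, "+", fm, rm)))
    if minus is not None:
        s, e, fm, rm = minus
        L = len(text)
        candidates.append((fm + rm, RegionHit(seq_id, region_name, L - e, L - s, "-", fm, rm)))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (c[0], c[1].strand))  # ties prefer +
    return candidates[0][1]


def _revcomp_seq(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))


def extract_regions(seqs: Sequence[SequenceRecord],
                    region_specs: Sequence[RegionSpec],
                    max_mismatch: int = 2,
                    include_primers: bool = False,
                    ) -> dict[str, list[SequenceRecord]]:
    """Extract every region from every sequence that contains its primers.

    Minus-strand hits are reverse-complemented so all extracted regions are
    in primer orientation; sequences lacking a region are omitted from that
    region's list with a logged count.  ``include_primers=True`` keeps the
    primer sites, making extraction idempotent on its own output.
    """
    out: dict[str, list[SequenceRecord]] = {spec.name: [] for spec in region_specs}
    missing = {spec.name: 0 for spec in region_specs}
    for spec in region_specs:
        pad = len(spec.fwd_primer) if include_primers else 0
        pad_r = len(spec.rev_primer) if include_primers else 0
        for rec in seqs:
            hit = locate_primer_pair(rec, spec.fwd_primer, spec.rev_primer,
                                     max_mismatch, region_name=spec.name)
            if hit is None:
                missing[spec.name] += 1
                continue
            start = max(hit.start - pad, 0)
            end = min(hit.end + pad_r, len(rec.seq))
            fragment = rec.seq[start:end]
            if hit.strand == "-":
                fragment = _revcomp_seq(fragment)
            out[spec.name].append(SequenceRecord(
                id=rec.id, seq=fragment, phylum=rec.phylum,
                species=rec.species, site=rec.site, abundance=rec.abundance,
            ))
    for name, count in missing.items():
        if count:
            logger.info("extract_regions: %d sequence(s) lack region %s", count, name)
    return out


@dataclass
class RegionProfile:
    """group (phylum) -> region -> (n sequences, mean pairwise identity).

    The mean is over all unordered pairs within a group-region cell and is
    None when fewer than 2 sequences are available.
    """

    cells: dict[str, dict[str, tuple[int, float | None]]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group, regions in self.cells.items():
            for region, (n, ident) in regions.items():
                rows.append({"group": group, "region": region, "n": n,
                             "mean_identity": ident})
        return pd.DataFrame(rows)


def region_identity_profile(extracted: Mapping[str, Sequence[SequenceRecord]],
                            group_labels: Mapping[str, str]) -> RegionProfile:
    """Mean pairwise identity per group x region.

    ``group_labels`` maps sequence id to group (typically phylum); order of
    input sequences does not affect the means.
    """
    cells: dict[str, dict[str, tuple[int, float | None]]] = {}
    for region, records in extracted.items():
        by_group: dict[str, list[SequenceRecord]] = {}
        for rec in records:
            group = group_labels.get(rec.id, rec.phylum or "unknown")
            by_group.setdefault(group, []).append(rec)
        for group, members in by_group.items():
            n = len(members)
            if n < 2:
                ident = None
            else:
                pairs = [
                    percent_identity(members[i].seq, members[j].seq)
                    for i in range(n) for j in range(i + 1, n)
                ]
                ident = float(np.mean(pairs))
            cells.setdefault(group, {})[region] = (n, ident)
    return RegionProfile(cells=cells)
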