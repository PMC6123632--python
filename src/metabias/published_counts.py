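"""The study's printed per-phylum sample sizes and unit counts, as input data.

These are the per-phylum counts of specimens, 18S rRNA sequences, and units
under each delimitation method (morphotype, GMYC entity, OTU, eOTU, sequence
variant) for the seven focal meiofaunal phyla of the Panama survey.  They are
inputs to the aggregation checks: the pipeline's pooled-site aggregation must
reproduce the printed totals (835 specimens, 187 morphotypes, 116 entities,
211 OTUs, 547 eOTUs, 293 sequence variants) from these rows.
"""

from __future__ import annotations

import pandas as pd

from .delimitation import UnitSet, build_unitset

PHYLA = (
    "Annelida", "Gastrotricha", "Mollusca", "Nematoda",
    "Nemertea", "Platyhelminthes", "Xenacoelomorpha",
)

# columns: specimens, sequences_18s, morphotype, entity, otu, eotu, sv
_ROWS = {
    "Annelida":        (163, 133, 20, 23, 27, 178, 63),
    "Gastrotricha":    (133, 107, 37, 27, 38, 20, 12),
    "Mollusca":        (96, 81, 22, 6, 17, 36, 22),
    "Nematoda":        (108, 73, 37, 2, 37, 155, 89),
    "Nemertea":        (94, 83, 23, 9, 34, 12, 8),
    "Platyhelminthes": (208, 163, 38, 42, 48, 120, 87),
    "Xenacoelomorpha": (33, 28, 10, 7, 10, 26, 12),
}

UNIT_METHODS = ("morphotype", "entity", "otu", "eotu", "sv")


def per_phylum_counts() -> pd.DataFrame:
    """Per-phylum counts table (phyla as rows)."""
    return pd.DataFrame.from_dict(
        _ROWS, orient="index",
        columns=["specimens", "sequences_18s"] + list(UNIT_METHODS),
    ).loc[list(PHYLA)]


def pooled_unitsets() -> dict[str, UnitSet]:
    """One pooled-site UnitSet per method, with one unit per published unit.

    Unit ids are synthetic (``<phylum>_u<i>``); every unit is present at the
    single pooled site, so site richness equals the published total and the
    per-phylum breakdown is carried by ``unit_phyla``.
    """
    counts = per_phylum_counts()
    out: dict[str, UnitSet] = {}
    for method in UNIT_METHODS:
        partition: dict[str, list[str]] = {}
        phyla_map: dict[str, str] = {}
        for phylum in PHYLA:
            for i in range(int(counts.loc[phylum, method])):
                unit = f"{phylum}_u{i + 1}"
                partition[unit] = [unit]
                phyla_map[unit] = phylum
        out[method] = build_unitset(method, partition, unit_phyla=phyla_map)
    return out
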