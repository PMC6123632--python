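"""End-to-end study analyses over synthetic communities.

Each function runs one of the package's headline computations from scratch:
the pooled-site aggregation of the published per-phylum unit counts, GMYC
species recovery on simulated gene trees, PERMANOVA type-I calibration, the
phylum-specific metabarcoding-deficit emulation, and the V1-V2 vs V9
region-divergence ordering.  They are shared by the analysis drivers, the
acceptance script, and the test suite.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .community_stats import compare_methods, jaccard_matrix, permanova
from .delimitation import dereplicate_and_denoise, gmyc_single_threshold, richness_by_site
from .io_formats import IncidenceMatrix
from .published_counts import PHYLA, per_phylum_counts, pooled_unitsets
from .region_divergence import extract_regions, region_identity_profile
from .synthetic_data import (
    DetectionModel,
    assign_phyla,
    default_regions,
    evolve_sequences,
    graft_coalescent_tips,
    simulate_survey,
    simulate_yule_tree,
)

logger = logging.getLogger("metabias")

FOCAL_PHYLA = list(PHYLA)


def table1_totals() -> dict[str, int]:
    """Whole-survey totals recomputed by pooling the published per-phylum
    counts through the standard aggregation path (one pooled site)."""
    counts = per_phylum_counts()
    totals = {
        "specimens": int(counts["specimens"].sum()),
        "sequences_18s": int(counts["sequences_18s"].sum()),
    }
    for method, unitset in pooled_unitsets().items():
        totals[method] = int(richness_by_site(unitset).sum())
    return totals


def gmyc_recovery(n_reps: int = 50, seed: int = 0, n_species: int = 5,
                  tips_per_species: int = 4, theta_frac: float = 0.01
                  ) -> dict[str, float]:
    """Fraction of simulated gene trees on which single-threshold GMYC
    recovers the true species count.

    Simulations whose coalescent cannot fit a very short terminal branch are
    replaced by the next seed (the generative model rejects them).  Also
    reports whether the mixed model ever fell below the null.
    """
    correct = 0
    lr_ok = True
    done = 0
    draw = 0
    while done < n_reps:
        rep_seed = (seed * 1_000_003 + draw) % (2**31 - 1)
        draw += 1
        sp = simulate_yule_tree(n_species, 1.0, rep_seed)
        try:
            tree = graft_coalescent_tips(sp, tips_per_species,
                                         theta_frac * sp.height, rep_seed + 1)
        except RuntimeError:
            continue
        fit = gmyc_single_threshold(tree)
        correct += fit.n_entities == n_species
        lr_ok &= fit.logL_mixed >= fit.logL_null - 1e-6
        done += 1
    return {"rate": correct / n_reps, "n_correct": correct,
            "n_reps": n_reps, "lr_never_below_null": lr_ok}


def permanova_type1(n_datasets: int = 1000, n_perm: int = 199,
                    alpha: float = 0.05, seed: int = 0,
                    n_units: int = 15, n_sites: int = 10) -> dict[str, float]:
    """Type-I error of the PERMANOVA against a covariate independent of the
    community structure, over many null simulations."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_datasets):
        cells = (rng.random((n_units, n_sites)) < 0.4).astype(int)
        cells[:, 0] |= cells.sum(axis=1) == 0
        inc = IncidenceMatrix(pd.DataFrame(
            cells, index=[f"u{i}" for i in range(n_units)],
            columns=[f"s{j}" for j in range(n_sites)]))
        dist = jaccard_matrix(inc)
        cov = pd.DataFrame({"x": rng.normal(size=n_sites)}, index=dist.labels)
        res = permanova(dist, cov, ["x"], n_perm=n_perm,
                        seed=int(rng.integers(2**31 - 1)))
        rejections += res[0].p <= alpha
    return {"rate": rejections / n_datasets, "n_rejections": rejections,
            "n_datasets": n_datasets, "alpha": alpha}


def _survey_unitsets(observed, truth, min_abundance=2, max_err_links=1):
    """Denoise each method's reads into sequence-variant UnitSets with
    truth-derived phylum labels (majority over member reads)."""
    unitsets = {}
    all_sites = truth.incidence_true.sites
    for method, reads in observed.items():
        us = dereplicate_and_denoise(reads, min_abundance, max_err_links)
        phyla = {}
        for unit, members in us.units.items():
            counts: dict[str, int] = {}
            for mid in members:
                sp = truth.read_truth[mid]["species"]
                ph = truth.phylum_of[sp]
                counts[ph] = counts.get(ph, 0) + 1
            phyla[unit] = max(counts, key=lambda p: (counts[p], p))
        us.unit_phyla = phyla
        for site in all_sites:
            if site not in us.site_counts.columns:
                us.site_counts[site] = 0
        us.site_counts = us.site_counts[sorted(us.site_counts.columns)]
        unitsets[method] = us
    return unitsets


def bias_emulation(n_reps: int = 50, seed: int = 0, target: str = "Gastrotricha",
                   depressed_p: float = 0.3, baseline_p: float = 0.95,
                   n_sites: int = 19, species_per_phylum: int = 3,
                   occupancy: float = 0.6, read_depth: float = 3.0,
                   error_rate: float = 0.001, n_perm: int = 999
                   ) -> dict[str, float]:
    """End-to-end emulation of a phylum-specific metabarcoding deficit.

    Each replicate simulates a community over the seven focal phyla, surveys
    it with two methods in which only the target phylum's metabarcoding
    detection is depressed, denoises reads into sequence variants per method,
    and tests the per-phylum richness contrast (metabarcoding - specimen)
    with the site-stratified permutation test.  Reports how often the target
    phylum is flagged (negative contrast, p < 0.05).
    """
    n_species = species_per_phylum * len(FOCAL_PHYLA)
    methods = ("metabarcoding", "specimen")
    flagged = 0
    done = 0
    draw = 0
    while done < n_reps:
        rep_seed = (seed * 999_983 + draw) % (2**31 - 1)
        draw += 1
        sp_tree = simulate_yule_tree(n_species, 1.0, rep_seed)
        try:
            tree = graft_coalescent_tips(sp_tree, 1, 0.01 * sp_tree.height,
                                         rep_seed + 1)
        except RuntimeError:  # pragma: no cover - within_n=1 never rejects
            continue
        seqs = evolve_sequences(tree, default_regions(), rep_seed + 2)
        phyla = assign_phyla(sorted({r.species for r in seqs}), FOCAL_PHYLA)
        detection = DetectionModel(
            methods=methods,
            detection={(p, m): depressed_p
                       if (p == target and m == "metabarcoding") else baseline_p
                       for p in FOCAL_PHYLA for m in methods},
            read_depth_mean=read_depth,
            error_rate=error_rate,
        )
        _, observed, truth = simulate_survey(tree, seqs, n_sites, occupancy,
                                             detection, rep_seed + 3,
                                             phylum_of=phyla)
        unitsets = _survey_unitsets(observed, truth)
        report = compare_methods(unitsets, n_perm=n_perm, seed=rep_seed + 4)
        pc = report["phylum_contrasts"]
        row = pc[(pc["phylum"] == target)
                 & (pc["method_a"] == "metabarcoding")].iloc[0]
        flagged += (row["contrast"] < 0) and (row["p"] < 0.05)
        done += 1
    return {"rate": flagged / n_reps, "n_flagged": flagged, "n_reps": n_reps}


def region_ordering(n_seeds: int = 5, seed: int = 0, v1v2_rate: float = 0.1,
                    v9_rate: float = 0.3, species_per_phylum: int = 3
                    ) -> dict[str, float]:
    """Fraction of phylum x replicate cells in which the faster-evolving V9
    region shows lower mean pairwise identity than V1-V2."""
    n_species = species_per_phylum * len(FOCAL_PHYLA)
    ordered = 0
    cells = 0
    for i in range(n_seeds):
        rep_seed = (seed * 7_919 + i) % (2**31 - 1)
        sp_tree = simulate_yule_tree(n_species, 1.0, rep_seed)
        tree = graft_coalescent_tips(sp_tree, 2, 0.01 * sp_tree.height,
                                     rep_seed + 1)
        regions = default_regions(v1v2_rate=v1v2_rate, v9_rate=v9_rate)
        seqs = evolve_sequences(tree, regions, rep_seed + 2)
        phyla = assign_phyla(sorted({r.species for r in seqs}), FOCAL_PHYLA)
        labels = {r.id: phyla[r.species] for r in seqs}
        profile = region_identity_profile(extract_regions(seqs, regions), labels)
        for group, by_region in profile.cells.items():
            cells += 1
            ordered += by_region["V9"][1] < by_region["V1V2"][1]
    return {"fraction": ordered / cells, "n_ordered": ordered, "n_cells": cells}
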