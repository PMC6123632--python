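"""Beta-diversity, PERMANOVA, and the cross-method bias comparison harness.

The PERMANOVA follows the distance-partitioning definition (Gower-centered
squared distances, sequential Type-I sums of squares in the order terms are
given, pseudo-F per term, p-values from row-label permutation with the
observed statistic counted in numerator and denominator).  The cross-method
harness compares per-site richness between unit-delimitation methods with a
site-stratified sign-flip permutation test, Holm-corrected across contrasts,
optionally stratified by phylum.
"""

from __future__ import annotations

import itertools
import json
import logging

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .delimitation import UnitSet, richness_by_site
from .io_formats import IncidenceMatrix

logger = logging.getLogger("metabias")


@dataclass
class DistanceMatrix:
    """A symmetric site-by-site dissimilarity matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def jaccard_matrix(incidence: IncidenceMatrix) -> DistanceMatrix:
    """Pairwise Jaccard dissimilarity between sites: 1 - |A∩B| / |A∪B|.

    A pair of sites with no units at all has distance 0 by convention
    (flagged in the log).
    """
    if incidence.m < 2:
        raise ValueError("need at least 2 sites")
    X = incidence.data.to_numpy().T.astype(bool)  # sites x units
    empty = ~X.any(axis=1)
    if empty.any():
        logger.warning("jaccard_matrix: %d empty site(s); both-empty pairs get d=0",
                       int(empty.sum()))
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(X, metric="jaccard"))
    d = np.nan_to_num(d, nan=0.0)  # both-empty pairs
    return DistanceMatrix(labels=incidence.sites, values=d)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    term: str
    df: int
    ss: float
    pseudo_F: float
    R2: float
    p: float
    n_perm: int
    seed: int


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    n = d.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return j @ a @ j


def _design_blocks(covariates: pd.DataFrame, terms: Sequence[str]) -> list[np.ndarray]:
    blocks = []
    for term in terms:
        if term not in covariates.columns:
            raise ValueError(f"unknown covariate term {term!r}")
        col = covariates[term]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, drop_first=True).to_numpy(dtype=float)
            if dummies.shape[1] == 0:
                raise ValueError(f"constant covariate {term!r}")
            blocks.append(dummies)
        else:
            x = col.to_numpy(dtype=float)
            if np.ptp(x) == 0:
                raise ValueError(f"constant covariate {term!r}")
            blocks.append(x[:, None])
    return blocks


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X.T @ X) @ X.T


def permanova(dist: DistanceMatrix, covariates: pd.DataFrame,
              terms: Sequence[str], n_perm: int = 999, seed: int = 0,
              permutations: str = "randomized") -> list[PermanovaResult]:
    """Distance-based multivariate ANOVA with sequential sums of squares.

    Terms are fitted in the order given (Type-I), so term order matters.
    ``permutations='exact'`` enumerates all row permutations (n <= 8 sites)
    and computes exact p-values; otherwise ``n_perm`` random permutations
    are drawn and p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).  The last
    returned row is the residual (no test).
    """
    n = len(dist.labels)
    cov = covariates.loc[dist.labels]
    blocks = _design_blocks(cov, terms)
    G = _gower_center(dist.values)
    ss_total = float(np.trace(G))

    intercept = np.ones((n, 1))
    hats = []
    X = intercept
    for block in blocks:
        X = np.hstack([X, block])
        hats.append(_hat(X))
    df_terms = [b.shape[1] for b in blocks]
    df_resid = n - 1 - sum(df_terms)
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")

    def stats(Gmat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        upto = np.array([float(np.sum(H * Gmat)) for H in hats])
        ss = np.diff(np.concatenate([[0.0], upto]))
        ss_res = float(np.trace(Gmat)) - upto[-1]
        F = (ss / df_terms) / (ss_res / df_resid)
        return ss, F

    ss_obs, F_obs = stats(G)
    ss_res = ss_total - ss_obs.sum()

    if permutations == "exact":
        if n > 8:
            raise ValueError("exact enumeration limited to 8 sites")
        count = np.zeros(len(terms))
        total = 0
        for perm in itertools.permutations(range(n)):
            idx = np.array(perm)
            Fp = stats(G[np.ix_(idx, idx)])[1]
            count += Fp >= F_obs - 1e-12
            total += 1
        pvals = count / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(len(terms))
        for _ in range(n_perm):
            idx = rng.permutation(n)
            Fp = stats(G[np.ix_(idx, idx)])[1]
            count += Fp >= F_obs - 1e-12
        pvals = (1.0 + count) / (1.0 + n_perm)
        n_used = n_perm

    results = [
        PermanovaResult(term=t, df=df_terms[i], ss=float(ss_obs[i]),
                        pseudo_F=float(F_obs[i]), R2=float(ss_obs[i] / ss_total),
                        p=float(pvals[i]), n_perm=n_used, seed=seed)
        for i, t in enumerate(terms)
    ]
    results.append(PermanovaResult(
        term="Residual", df=df_resid, ss=float(ss_res),
        pseudo_F=float("nan"), R2=float(ss_res / ss_total),
        p=float("nan"), n_perm=n_used, seed=seed,
    ))
    return results


# ---------------------------------------------------------------------------
# cross-method comparison harness
# ---------------------------------------------------------------------------

def holm_correction(pvals: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    m = len(pvals)
    order = np.argsort(pvals)
    adjusted = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adjusted[i] = min(1.0, running)
    return adjusted.tolist()


def _stratified_contrast(diff: np.ndarray, n_perm: int,
                         rng: np.random.Generator) -> tuple[float, float]:
    """Two-sided site-stratified permutation test for a paired richness
    difference: swapping the two method labels within a site flips the sign
    of that site's difference."""
    obs = float(diff.mean())
    signs = rng.choice([-1.0, 1.0], size=(n_perm, diff.size))
    null = (signs * diff).mean(axis=1)
    count = int((np.abs(null) >= abs(obs) - 1e-12).sum())
    p = (1 + count) / (1 + n_perm)
    return obs, p


def _phylum_richness(unitset: UnitSet) -> pd.DataFrame:
    """Per-phylum unit richness by site (requires unit_phyla labels)."""
    present = (unitset.site_counts >= 1)
    phyla = pd.Series({u: unitset.unit_phyla.get(u, "unknown")
                       for u in unitset.site_counts.index})
    return present.groupby(phyla).sum()


def compare_methods(unitsets: Mapping[str, UnitSet],
                    covariates: pd.DataFrame | None = None,
                    terms: Sequence[str] | None = None,
                    n_perm: int = 999, seed: int = 0) -> dict:
    """Cross-method bias report over a shared site set.

    Produces the per-method richness table, pairwise method contrasts
    (site-stratified sign-flip tests, Holm-corrected), per-phylum contrasts
    when all unit sets carry phylum labels, and per-method Jaccard matrices
    (with PERMANOVA when covariates and terms are given).
    """
    if len(unitsets) < 2:
        raise ValueError("need at least 2 unit sets")
    methods = list(unitsets)
    site_sets = {m: tuple(sorted(u.site_counts.columns)) for m, u in unitsets.items()}
    if len(set(site_sets.values())) != 1:
        raise ValueError(f"site sets differ across methods: {site_sets}")
    sites = list(site_sets[methods[0]])

    richness = pd.DataFrame(
        {m: richness_by_site(u).reindex(sites).fillna(0).astype(int)
         for m, u in unitsets.items()}
    ).T  # methods x sites

    rng = np.random.default_rng(seed)
    rows = []
    for a, b in itertools.combinations(methods, 2):
        diff = (richness.loc[a] - richness.loc[b]).to_numpy(dtype=float)
        obs, p = _stratified_contrast(diff, n_perm, rng)
        rows.append({"method_a": a, "method_b": b, "phylum": "all",
                     "contrast": obs, "p": p})
    contrasts = pd.DataFrame(rows)
    contrasts["p_holm"] = holm_correction(contrasts["p"].tolist())

    phylum_contrasts = None
    if all(u.unit_phyla for u in unitsets.values()):
        per_phylum = {m: _phylum_richness(u).reindex(columns=sites).fillna(0)
                      for m, u in unitsets.items()}
        phyla = sorted(set().union(*(df.index for df in per_phylum.values())))
        rows = []
        for phylum in phyla:
            for a, b in itertools.combinations(methods, 2):
                ra = per_phylum[a].loc[phylum] if phylum in per_phylum[a].index \
                    else pd.Series(0, index=sites)
                rb = per_phylum[b].loc[phylum] if phylum in per_phylum[b].index \
                    else pd.Series(0, index=sites)
                diff = (ra - rb).to_numpy(dtype=float)
                obs, p = _stratified_contrast(diff, n_perm, rng)
                rows.append({"method_a": a, "method_b": b, "phylum": phylum,
                             "contrast": obs, "p": p})
        phylum_contrasts = pd.DataFrame(rows)
        phylum_contrasts["p_holm"] = holm_correction(phylum_contrasts["p"].tolist())

    jaccard: dict[str, DistanceMatrix] = {}
    permanova_results: dict[str, list[PermanovaResult]] = {}
    for m, u in unitsets.items():
        inc = IncidenceMatrix((u.site_counts[sites] >= 1).astype(int))
        jaccard[m] = jaccard_matrix(inc)
        if covariates is not None and terms:
            permanova_results[m] = permanova(
                jaccard[m], covariates, terms, n_perm=n_perm, seed=seed
            )

    return {
        "richness": richness,
        "contrasts": contrasts,
        "phylum_contrasts": phylum_contrasts,
        "jaccard": jaccard,
        "permanova": permanova_results,
    }


def write_report(report: dict, out_dir: str | Path) -> None:
    """Serialize a compare_methods report: report.tsv, report.json, and one
    jaccard_<method>.tsv per method."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = [report["contrasts"]]
    if report["phylum_contrasts"] is not None:
        tables.append(report["phylum_contrasts"])
    pd.concat(tables, ignore_index=True).to_csv(out / "report.tsv", sep="\t", index=False)
    payload = {
        "richness": {m: report["richness"].loc[m].to_dict()
                     for m in report["richness"].index},
        "contrasts": report["contrasts"].to_dict(orient="records"),
        "phylum_contrasts": (report["phylum_contrasts"].to_dict(orient="records")
                             if report["phylum_contrasts"] is not None else None),
        "permanova": {
            m: [vars(r) for r in res] for m, res in report["permanova"].items()
        },
    }
    (out / "report.json").write_text(json.dumps(payload, indent=1))
    for m, dm in report["jaccard"].items():
        dm.to_frame().to_csv(out / f"jaccard_{m}.tsv", sep="\t")
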