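"""Incidence-based richness estimators and phylogenetic diversity descriptors.

Richness: the classic Chao2 estimator and first-order jackknife, computed
from the counts of units occurring in exactly one (Q1) and two (Q2) sites.

Phylogeny: Faith's PD (total branch length of the minimal subtree spanning a
tip set, root edge excluded, PD of a single tip defined as 0), mean pairwise
distance (MPD), mean nearest-taxon distance (MNTD), and their standardized
effect sizes against a uniform tip-shuffling null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import IncidenceMatrix, UltrametricTree

logger = logging.getLogger("metabias")


def chao2(incidence: IncidenceMatrix) -> float:
    """Chao2 incidence-based richness estimate (>= S_obs).

    S_obs + ((m-1)/m) * Q1^2 / (2 Q2) when Q2 > 0; the bias-corrected form
    S_obs + ((m-1)/m) * Q1 (Q1 - 1) / 2 when Q2 = 0.
    """
    s, q1, q2, m = incidence.s_obs, incidence.q1, incidence.q2, incidence.m
    if m < 1:
        raise ValueError("need at least one site")
    factor = (m - 1) / m
    if q2 > 0:
        return s + factor * q1 * q1 / (2.0 * q2)
    logger.debug("chao2: Q2 = 0, using bias-corrected form")
    return s + factor * q1 * (q1 - 1) / 2.0


def jack1(incidence: IncidenceMatrix) -> float:
    """First-order jackknife richness estimate: S_obs + Q1 (m-1)/m."""
    m = incidence.m
    if m < 1:
        raise ValueError("need at least one site")
    return incidence.s_obs + incidence.q1 * (m - 1) / m


# ---------------------------------------------------------------------------
# phylogenetic descriptors
# ---------------------------------------------------------------------------

def _check_tips(tree: UltrametricTree, tip_set: Iterable[str]) -> list[str]:
    tips = list(dict.fromkeys(tip_set))
    known = set(tree.tip_labels())
    unknown = [t for t in tips if t not in known]
    if unknown:
        raise ValueError(f"tips not in tree: {unknown}")
    if not tips:
        raise ValueError("tip set must be non-empty")
    return tips


def faith_pd(tree: UltrametricTree, tip_set: Iterable[str]) -> float:
    """Faith's PD: branch length of the minimal subtree connecting the tips.

    Edges on the paths from the tips to their MRCA are summed; the MRCA's
    own stem and everything above it are excluded, so PD of a single tip
    is 0 by convention.
    """
    tips = set(_check_tips(tree, tip_set))
    k = len(tips)
    total = 0.0
    below: dict[int, int] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            count = 1 if node.taxon.label in tips else 0
        else:
            count = sum(below[id(c)] for c in node.child_nodes())
        below[id(node)] = count
        if 0 < count < k and node.edge.length:
            total += node.edge.length
    return total


def _patristic_matrix(tree: UltrametricTree) -> tuple[list[str], np.ndarray]:
    """All-pairs patristic distances, ordered by leaf iteration order."""
    pdm = tree.tree.phylogenetic_distance_matrix()
    labels = [leaf.taxon.label for leaf in tree.tree.leaf_node_iter()]
    taxa = {t.label: t for t in tree.tree.taxon_namespace}
    n = len(labels)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            dist[i, j] = dist[j, i] = d
    return labels, dist


def _mpd_from(dist: np.ndarray) -> float:
    n = dist.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(dist[iu].mean())


def _mntd_from(dist: np.ndarray) -> float:
    d = dist + np.diag(np.full(dist.shape[0], np.inf))
    return float(d.min(axis=1).mean())


def mpd(tree: UltrametricTree, tip_set: Iterable[str]) -> float:
    """Mean patristic distance over unordered tip pairs (needs >= 2 tips)."""
    tips = _check_tips(tree, tip_set)
    if len(tips) < 2:
        raise ValueError("mpd requires at least 2 tips")
    labels, dist = _patristic_matrix(tree)
    idx = [labels.index(t) for t in tips]
    return _mpd_from(dist[np.ix_(idx, idx)])


def mntd(tree: UltrametricTree, tip_set: Iterable[str]) -> float:
    """Mean distance from each tip to its nearest neighbour in the set."""
    tips = _check_tips(tree, tip_set)
    if len(tips) < 2:
        raise ValueError("mntd requires at least 2 tips")
    labels, dist = _patristic_matrix(tree)
    idx = [labels.index(t) for t in tips]
    return _mntd_from(dist[np.ix_(idx, idx)])


@dataclass
class PDResult:
    """Observed descriptors for one tip set plus SES against the tip-shuffle
    null.  ``degenerate`` flags a zero null standard deviation (e.g. the
    tip set is all tips), in which case the SES fields are NaN, never 0."""

    pd: float
    mpd: float
    mntd: float
    ses_mpd: float
    ses_mntd: float
    null_reps: int
    seed: int
    degenerate: bool = False


def ses(metric: str, tree: UltrametricTree, tip_set: Iterable[str],
        null_reps: int = 999, seed: int = 0) -> "PDResult":
    """Standardized effect size of ``metric`` ('mpd' or 'mntd'); see
    :func:`pd_descriptors`, which this wraps for a single metric."""
    if metric not in ("mpd", "mntd"):
        raise ValueError("metric must be 'mpd' or 'mntd'")
    return pd_descriptors(tree, tip_set, null_reps=null_reps, seed=seed)


def pd_descriptors(tree: UltrametricTree, tip_set: Iterable[str],
                   null_reps: int = 999, seed: int = 0) -> PDResult:
    """PD, MPD, MNTD and the SES of MPD/MNTD for one tip set.

    The null draws ``null_reps`` uniform tip sets of equal size without
    replacement from all tips ('taxa-labels' shuffling);
    ses = (observed - null mean) / null sd.  Deterministic given seed.
    """
    tips = _check_tips(tree, tip_set)
    if len(tips) < 2:
        raise ValueError("SES descriptors require at least 2 tips")
    labels, dist = _patristic_matrix(tree)
    idx = np.array([labels.index(t) for t in tips])
    sub = dist[np.ix_(idx, idx)]
    obs_mpd = _mpd_from(sub)
    obs_mntd = _mntd_from(sub)
    obs_pd = faith_pd(tree, tips)

    rng = np.random.default_rng(seed)
    n = len(labels)
    k = len(tips)
    null_mpd = np.empty(null_reps)
    null_mntd = np.empty(null_reps)
    for r in range(null_reps):
        draw = rng.choice(n, size=k, replace=False)
        d = dist[np.ix_(draw, draw)]
        null_mpd[r] = _mpd_from(d)
        null_mntd[r] = _mntd_from(d)

    sd_mpd = float(null_mpd.std(ddof=1))
    sd_mntd = float(null_mntd.std(ddof=1))
    # a null whose spread is at floating-point noise level is degenerate
    tol_mpd = 1e-9 * max(abs(null_mpd.mean()), 1e-300)
    tol_mntd = 1e-9 * max(abs(null_mntd.mean()), 1e-300)
    if sd_mpd <= tol_mpd:
        sd_mpd = 0.0
    if sd_mntd <= tol_mntd:
        sd_mntd = 0.0
    degenerate = sd_mpd == 0.0 or sd_mntd == 0.0
    if degenerate:
        logger.warning("SES null has zero variance; SES flagged undefined")
    return PDResult(
        pd=obs_pd,
        mpd=obs_mpd,
        mntd=obs_mntd,
        ses_mpd=(obs_mpd - null_mpd.mean()) / sd_mpd if sd_mpd > 0 else float("nan"),
        ses_mntd=(obs_mntd - null_mntd.mean()) / sd_mntd if sd_mntd > 0 else float("nan"),
        null_reps=null_reps,
        seed=seed,
        degenerate=degenerate,
    )
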