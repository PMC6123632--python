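"""Beta-diversity and PERMANOVA contracts: set-algebra Jaccard oracle,
adonis2-verified partitioning, exhaustive-permutation p-values, and the
cross-method contrast harness."""

import itertools

import numpy as np
import pandas as pd
import pytest

from metabias import (
    SequenceRecord,
    build_unitset,
    compare_methods,
    jaccard_matrix,
    permanova,
)
from metabias.community_stats import holm_correction
from conftest import make_incidence


class TestJaccard:
    def test_identical_sites(self):
        d = jaccard_matrix(make_incidence([[1, 1], [0, 0], [1, 1]]))
        assert d.values[0, 1] == 0.0

    def test_hand_count(self):
        # A={a,b,c}, B={b,c,d} -> 1 - 2/4 = 0.5
        d = jaccard_matrix(make_incidence([[1, 0], [1, 1], [1, 1], [0, 1]]))
        assert d.values[0, 1] == pytest.approx(0.5)

    def test_disjoint_sites(self):
        d = jaccard_matrix(make_incidence([[1, 0], [0, 1]]))
        assert d.values[0, 1] == 1.0

    def test_both_empty_convention(self):
        d = jaccard_matrix(make_incidence([[0, 0, 1]]))
        assert d.values[0, 1] == 0.0

    def test_set_algebra_oracle_exhaustive(self):
        # every binary matrix with <= 4 units x 3 sites
        for bits in range(2 ** 6):
            cells = np.array([[(bits >> (i * 3 + j)) & 1 for j in range(3)]
                              for i in range(2)])
            inc = make_incidence(cells)
            d = jaccard_matrix(inc)
            sets = inc.site_unit_sets()
            for i, si in enumerate(inc.sites):
                for j, sj in enumerate(inc.sites):
                    a, b = sets[si], sets[sj]
                    union = len(a | b)
                    expect = 0.0 if union == 0 else 1 - len(a & b) / union
                    assert d.values[i, j] == pytest.approx(expect)

    def test_triangle_inequality(self, rng):
        for _ in range(30):
            cells = (rng.random((6, 4)) < 0.5).astype(int)
            d = jaccard_matrix(make_incidence(cells)).values
            for i, j, k in itertools.permutations(range(4), 3):
                assert d[i, k] <= d[i, j] + d[j, k] + 1e-12


def _oracle_permanova_F(dvals, x):
    """Independent single-term pseudo-F from the raw definitions."""
    n = len(x)
    a = -0.5 * dvals ** 2
    G = a - a.mean(0) - a.mean(1)[:, None] + a.mean()
    X = np.column_stack([np.ones(n), x])
    H = X @ np.linalg.pinv(X.T @ X) @ X.T
    ss_model = np.trace(H @ G) - np.trace(G) / n * 0  # intercept-only trace
    H0 = np.full((n, n), 1.0 / n)
    ss_term = np.trace((H - H0) @ G)
    ss_res = np.trace((np.eye(n) - H) @ G)
    return (ss_term / 1) / (ss_res / (n - 2))


class TestPermanova:
    def test_matches_adonis2(self):
        # Frozen oracle: R vegan::adonis2(d ~ depth + grain, by="terms") on
        # this exact matrix gives SS (0.27384, 0.28666, 0.66752),
        # R2 (0.22299, 0.23343, 0.54357), F (1.2307, 1.2883).
        rng = np.random.default_rng(7)
        cells = (rng.random((10, 6)) < 0.5).astype(int)
        cells[:, 0] |= cells.sum(1) == 0
        d = jaccard_matrix(make_incidence(cells))
        cov = pd.DataFrame({"depth": rng.normal(size=6),
                            "grain": rng.normal(size=6)}, index=d.labels)
        res = permanova(d, cov, ["depth", "grain"], n_perm=99, seed=0)
        assert [round(r.ss, 5) for r in res] == [0.27384, 0.28666, 0.66752]
        assert [round(r.R2, 5) for r in res] == [0.22299, 0.23343, 0.54357]
        assert res[0].pseudo_F == pytest.approx(1.2307, abs=1e-4)
        assert res[1].pseudo_F == pytest.approx(1.2883, abs=1e-4)
        assert sum(r.R2 for r in res) == pytest.approx(1.0)

    def test_exact_enumeration_matches_bruteforce_oracle(self):
        dvals = np.array([
            [0.0, 0.3, 0.7, 0.9],
            [0.3, 0.0, 0.5, 0.8],
            [0.7, 0.5, 0.0, 0.4],
            [0.9, 0.8, 0.4, 0.0],
        ])
        from metabias import DistanceMatrix

        labels = ["s1", "s2", "s3", "s4"]
        d = DistanceMatrix(labels=labels, values=dvals)
        x = np.array([0.1, 0.5, 0.2, 0.9])
        cov = pd.DataFrame({"x": x}, index=labels)
        res = permanova(d, cov, ["x"], permutations="exact")
        F_obs = _oracle_permanova_F(dvals, x)
        assert res[0].pseudo_F == pytest.approx(F_obs)
        count = 0
        total = 0
        for perm in itertools.permutations(range(4)):
            idx = np.array(perm)
            count += _oracle_permanova_F(dvals[np.ix_(idx, idx)], x) >= F_obs - 1e-12
            total += 1
        assert res[0].p == pytest.approx(count / total)

    def test_invariant_to_site_relabeling(self, rng):
        cells = (rng.random((8, 6)) < 0.5).astype(int)
        cells[:, 0] |= cells.sum(1) == 0
        d = jaccard_matrix(make_incidence(cells))
        cov = pd.DataFrame({"x": rng.normal(size=6)}, index=d.labels)
        res1 = permanova(d, cov, ["x"], n_perm=199, seed=3)
        perm = rng.permutation(6)
        from metabias import DistanceMatrix

        d2 = DistanceMatrix(labels=[d.labels[i] for i in perm],
                            values=d.values[np.ix_(perm, perm)])
        res2 = permanova(d2, cov, ["x"], n_perm=199, seed=3)
        assert res2[0].pseudo_F == pytest.approx(res1[0].pseudo_F)
        assert res2[0].ss == pytest.approx(res1[0].ss)

    def test_constant_covariate_rejected(self):
        d = jaccard_matrix(make_incidence([[1, 0, 1], [0, 1, 1]]))
        cov = pd.DataFrame({"x": [1.0, 1.0, 1.0]}, index=d.labels)
        with pytest.raises(ValueError, match="x"):
            permanova(d, cov, ["x"], n_perm=99)

    def test_categorical_term(self):
        rng = np.random.default_rng(0)
        cells = (rng.random((10, 8)) < 0.5).astype(int)
        cells[:, 0] |= cells.sum(1) == 0
        d = jaccard_matrix(make_incidence(cells))
        cov = pd.DataFrame({"habitat": ["littoral"] * 4 + ["offshore"] * 4},
                           index=d.labels)
        res = permanova(d, cov, ["habitat"], n_perm=99, seed=0)
        assert res[0].df == 1
        assert 0 < res[0].p <= 1


def _unitsets_from_counts(counts_by_method, phyla=None):
    out = {}
    for method, counts in counts_by_method.items():
        recs = []
        partition = {}
        unit_phyla = {}
        for (unit, site), k in counts.items():
            rid = f"{method}_{unit}_{site}"
            recs.append(SequenceRecord(id=rid, seq="ACGT", site=site, abundance=k))
            partition.setdefault(unit, []).append(rid)
            if phyla:
                unit_phyla[unit] = phyla[unit]
        out[method] = build_unitset(method, partition, recs,
                                    unit_phyla=unit_phyla or None)
    return out


class TestCompareMethods:
    def test_identical_unitsets_give_null_contrasts(self):
        counts = {("u1", "s1"): 2, ("u1", "s2"): 1, ("u2", "s1"): 1}
        sets = _unitsets_from_counts({"a": counts, "b": dict(counts)})
        report = compare_methods(sets, n_perm=199, seed=0)
        row = report["contrasts"].iloc[0]
        assert row["contrast"] == 0.0
        assert row["p"] == 1.0

    def test_label_swap_negates_contrast(self):
        c1 = {("u1", "s1"): 1, ("u2", "s1"): 1, ("u1", "s2"): 1}
        c2 = {("u1", "s1"): 1, ("u1", "s2"): 1}
        ab = compare_methods(_unitsets_from_counts({"a": c1, "b": c2}),
                             n_perm=99, seed=1)
        ba = compare_methods(_unitsets_from_counts({"b": c2, "a": c1}),
                             n_perm=99, seed=1)
        assert ab["contrasts"].iloc[0]["contrast"] == \
            -ba["contrasts"].iloc[0]["contrast"]

    def test_site_mismatch_rejected(self):
        c1 = {("u1", "s1"): 1}
        c2 = {("u1", "s2"): 1}
        with pytest.raises(ValueError, match="site sets differ"):
            compare_methods(_unitsets_from_counts({"a": c1, "b": c2}))

    def test_per_phylum_contrasts_present_with_labels(self):
        phyla = {"u1": "Annelida", "u2": "Mollusca"}
        c1 = {("u1", "s1"): 1, ("u2", "s1"): 1, ("u1", "s2"): 1, ("u2", "s2"): 1}
        c2 = {("u1", "s1"): 1, ("u1", "s2"): 1}
        report = compare_methods(
            _unitsets_from_counts({"a": c1, "b": c2}, phyla=phyla),
            n_perm=99, seed=0)
        pc = report["phylum_contrasts"]
        assert set(pc["phylum"]) == {"Annelida", "Mollusca"}
        moll = pc[pc["phylum"] == "Mollusca"].iloc[0]
        assert moll["contrast"] == 1.0  # method b never sees Mollusca


def test_holm_correction_monotone_and_bounded():
    raw = [0.01, 0.04, 0.03, 0.5]
    adj = holm_correction(raw)
    assert all(0 <= p <= 1 for p in adj)
    order = np.argsort(raw)
    assert np.all(np.diff(np.array(adj)[order]) >= -1e-12)
    assert adj[0] == pytest.approx(0.04)
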