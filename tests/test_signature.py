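"""Knockdown-signature analysis: fold changes, overlap statistics, shared
signatures, correlation filtering, clustering and outcome association."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from survscreen import DegenerateError, ValidationError
from survscreen.signature import (
    GeneSet,
    cluster_outcome_association,
    cluster_samples,
    correlate_with_feature,
    fold_changes,
    overlap_test,
    select_by_fold_change,
    shared_signature,
)
from survscreen.synthetic import (
    KnockdownConfig,
    simulate_knockdown,
    simulate_signature_cohort,
)


def build_sets(kd_matrices, universe, pseudocount=0.01):
    sets = {}
    lines = sorted({ln for ln, _ in kd_matrices})
    sirnas = sorted({c for _, c in kd_matrices if c != "control"})
    for line in lines:
        ctrl = kd_matrices[(line, "control")].iloc[:, 0]
        for sirna in sirnas:
            ratios = fold_changes(kd_matrices[(line, sirna)].iloc[:, 0], ctrl, pseudocount)
            up, down = select_by_fold_change(ratios, universe_size=universe)
            sets[(line, sirna, "up")] = up
            sets[(line, sirna, "down")] = down
    return sets


class TestFoldChanges:
    def test_no_change_gives_unit_ratio(self):
        x = pd.Series([1.0, 2.0], index=["a", "b"])
        r = fold_changes(x, x)
        assert np.allclose(r, 1.0)
        up, down = select_by_fold_change(r)
        assert len(up) == 0 and len(down) == 0

    def test_boundary_is_inclusive_and_strict_below(self):
        kd = pd.Series([2.5], index=["g"])
        ctrl = pd.Series([2.0], index=["g"])
        r = fold_changes(kd, ctrl, pseudocount=0.01)
        assert r["g"] < 1.25  # 2.51/2.01 ~ 1.2488: below the cut
        up, _ = select_by_fold_change(r)
        assert "g" not in up.members
        # exactly 1.25 counts as up
        up2, _ = select_by_fold_change(pd.Series([1.25], index=["g"]))
        assert "g" in up2.members

    def test_pseudocount_converges_to_raw_ratio(self):
        kd = pd.Series([3.0], index=["g"])
        ctrl = pd.Series([2.0], index=["g"])
        for pc in (1e-3, 1e-6, 1e-9):
            assert abs(fold_changes(kd, ctrl, pc)["g"] - 1.5) < 2 * pc

    def test_planted_genes_selected_with_correct_sign(self):
        cfg = KnockdownConfig(n_genes=1000, n_affected=100, noise_sigma=0.02, seed=5)
        mats, truth = simulate_knockdown(cfg)
        ctrl = mats[("LINE1", "control")].iloc[:, 0]
        ratios = fold_changes(mats[("LINE1", "siRNA1")].iloc[:, 0], ctrl)
        up, down = select_by_fold_change(ratios)
        planted = set(truth.per_condition[("LINE1", "siRNA1")])
        correct = {g for g in planted
                   if (g in up.members and truth.directions[g] == 1)
                   or (g in down.members and truth.directions[g] == -1)}
        assert len(correct) >= 95

    def test_mismatched_genes_rejected(self):
        with pytest.raises(ValidationError):
            fold_changes(pd.Series([1.0], index=["a"]), pd.Series([1.0], index=["b"]))


class TestOverlapTest:
    def test_set_equal_to_universe_forces_overlap(self):
        u = 10
        a = GeneSet("a", frozenset(f"g{i}" for i in range(u)), u)
        b = GeneSet("b", frozenset(["g0", "g1"]), u)
        assert overlap_test(a, b).p_value == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        # universe of 10; enumerate all C(10,4) x C(10,5) draws
        u = 10
        genes = [f"g{i}" for i in range(u)]
        a = GeneSet("a", frozenset(genes[:4]), u)
        b = GeneSet("b", frozenset(genes[:4] + [genes[5]]), u)
        observed = len(a.members & b.members)
        total = hits = 0
        for xa in itertools.combinations(range(u), 4):
            for xb in itertools.combinations(range(u), 5):
                total += 1
                hits += len(set(xa) & set(xb)) >= observed
        res = overlap_test(a, b)
        assert res.overlap == observed == 4
        assert res.p_value == pytest.approx(hits / total, abs=1e-10)

    def test_disjoint_large_sets_near_one(self):
        u = 10000
        a = GeneSet("a", frozenset(f"g{i}" for i in range(100)), u)
        b = GeneSet("b", frozenset(f"g{i}" for i in range(200, 300)), u)
        assert overlap_test(a, b).p_value > 0.5


class TestSharedSignature:
    def test_identical_sets_pass_through(self):
        u = 50
        members = frozenset(["g1", "g2", "g3"])
        sets = {(l, s, "up"): GeneSet("x", members, u)
                for l in ("L1", "L2") for s in ("s1", "s2")}
        sets.update({(l, s, "down"): GeneSet("x", frozenset(), u)
                     for l in ("L1", "L2") for s in ("s1", "s2")})
        assert shared_signature(sets).members == members

    def test_one_empty_set_empties_direction(self):
        u = 50
        sets = {
            ("L1", "s1", "up"): GeneSet("x", frozenset(["g1"]), u),
            ("L2", "s1", "up"): GeneSet("x", frozenset(), u),
            ("L1", "s1", "down"): GeneSet("x", frozenset(["g9"]), u),
            ("L2", "s1", "down"): GeneSet("x", frozenset(["g9"]), u),
        }
        assert shared_signature(sets).members == frozenset(["g9"])

    def test_recovers_planted_shared_genes(self):
        cfg = KnockdownConfig(n_genes=1000, n_affected=100, shared_fraction=1.0,
                              noise_sigma=0.02, seed=9)
        mats, truth = simulate_knockdown(cfg)
        shared = shared_signature(build_sets(mats, cfg.n_genes))
        assert len(shared.members & set(truth.shared_genes)) >= 95

    def test_monotone_adding_constraints(self):
        cfg = KnockdownConfig(n_genes=400, n_affected=40, shared_fraction=0.5,
                              noise_sigma=0.05, seed=10)
        mats, _ = simulate_knockdown(cfg)
        sets = build_sets(mats, cfg.n_genes)
        subset = {k: v for k, v in sets.items() if k[0] == "LINE1"}
        assert shared_signature(sets).members <= shared_signature(subset).members

    def test_order_invariance(self):
        cfg = KnockdownConfig(n_genes=300, n_affected=30, seed=11)
        mats, _ = simulate_knockdown(cfg)
        sets = build_sets(mats, cfg.n_genes)
        reordered = dict(reversed(list(sets.items())))
        assert shared_signature(sets).members == shared_signature(reordered).members


class TestCorrelation:
    def test_exact_copy_included(self, rng):
        base = rng.lognormal(0, 1, 20)
        m = pd.DataFrame({"marker": base, "copy": base, "noise": rng.lognormal(0, 1, 20)}).T
        m.columns = [f"s{i}" for i in range(20)]
        gs = correlate_with_feature(m, "marker")
        assert "copy" in gs.members

    def test_independent_noise_excluded_at_large_n(self, rng):
        n = 466
        target = rng.lognormal(0, 1, n)
        rows = {"marker": target}
        rows.update({f"g{i}": rng.lognormal(0, 1, n) for i in range(50)})
        m = pd.DataFrame(rows).T
        gs = correlate_with_feature(m, "marker")
        # null r ~ N(0, 1/sqrt(466)): threshold 0.15 is ~3.2 sigma
        assert len(gs.members) <= 2

    def test_matches_textbook_formula(self, rng):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        y = np.array([2.0, 5.0, 1.0, 9.0, 4.0])
        m = pd.DataFrame({"f": x, "g": y}).T
        m.columns = [f"s{i}" for i in range(5)]
        r_hand = float(((x - x.mean()) * (y - y.mean())).sum()
                       / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        threshold = r_hand - 1e-12
        gs = correlate_with_feature(m, "f", r_threshold=threshold)
        assert "g" in gs.members
        gs2 = correlate_with_feature(m, "f", r_threshold=r_hand + 1e-9)
        assert "g" not in gs2.members

    def test_zero_variance_feature_fails(self):
        m = pd.DataFrame({"f": [1.0, 1.0, 1.0], "g": [1.0, 2.0, 3.0]}).T
        m.columns = ["a", "b", "c"]
        with pytest.raises(DegenerateError):
            correlate_with_feature(m, "f")


class TestClustering:
    def test_recovers_planted_groups_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        matrix, _, groups, _ = simulate_signature_cohort(n_samples=120, seed=3)
        assignment = cluster_samples(matrix, k=2)
        assert adjusted_rand_score(groups, assignment.labels) == 1.0

    def test_duplicate_sample_stays_with_its_twin(self):
        matrix, *_ = simulate_signature_cohort(n_samples=40, seed=4)
        dup = matrix.copy()
        dup["S_dup"] = dup.iloc[:, 0]
        assignment = cluster_samples(dup, k=2)
        labels = dict(zip(assignment.sample_ids, assignment.labels))
        assert labels["S_dup"] == labels[matrix.columns[0]]

    def test_linkage_heights_monotone(self):
        matrix, *_ = simulate_signature_cohort(n_samples=60, seed=5)
        z = cluster_samples(matrix, k=2).linkage_matrix
        assert np.all(np.diff(z[:, 2]) >= -1e-12)

    def test_affine_gene_rescaling_invariance(self):
        # Pearson on mean-centered log2 is invariant to per-gene scaling of
        # the log profile only; here we check multiplicative RPKM rescaling,
        # which shifts log2 rows by a constant removed by centering
        matrix, *_ = simulate_signature_cohort(n_samples=50, noise_sigma=0.3, seed=6)
        scaled = matrix.mul(np.exp2(np.arange(matrix.shape[0]) % 5), axis=0)
        a1 = cluster_samples(matrix, k=2, pseudocount=1e-9)
        a2 = cluster_samples(scaled, k=2, pseudocount=1e-9)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(a1.labels, a2.labels) == 1.0

    def test_constant_profile_rejected(self):
        m = pd.DataFrame(np.ones((3, 4)), columns=list("abcd"))
        with pytest.raises(ValidationError):
            cluster_samples(m, k=2)


class TestClusterOutcome:
    def test_fisher_matches_exhaustive_enumeration(self):
        from scipy.stats import fisher_exact

        # 2x2 table {{8,2},{1,9}}: enumerate all tables with fixed margins
        table = np.array([[8, 2], [1, 9]])
        r1, r2 = table.sum(1)
        c1 = table.sum(0)[0]
        n = table.sum()
        prob = {}
        for a in range(max(0, c1 - r2), min(r1, c1) + 1):
            prob[a] = (math.comb(r1, a) * math.comb(r2, c1 - a)) / math.comb(n, c1)
        p_obs = prob[8]
        expected = sum(p for p in prob.values() if p <= p_obs + 1e-12)
        assert fisher_exact(table)[1] == pytest.approx(expected, abs=1e-10)

    def test_signature_drives_survival_and_marker_enrichment(self):
        matrix, clinical, groups, marker = simulate_signature_cohort(n_samples=200, seed=12)
        assignment = cluster_samples(matrix, k=2)
        lr, fisher_p = cluster_outcome_association(assignment, clinical, marker)
        assert lr.p_value < 0.01
        assert fisher_p < 0.01

    def test_missing_survival_records_rejected(self):
        matrix, clinical, *_ = simulate_signature_cohort(n_samples=30, seed=13)
        assignment = cluster_samples(matrix, k=2)
        with pytest.raises(ValidationError):
            cluster_outcome_association(assignment, clinical.iloc[:10], np.ones(30, bool))
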