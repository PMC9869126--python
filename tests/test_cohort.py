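import itertools
import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import aneuwall as aw
from aneuwall.cohort import (EXCLUSIONS, bootstrap_auc_ci, empirical_auc,
                             reproduce_paper, spearman, tukey_outliers,
                             two_sample_test, youden_optimal_cutoff)


def brute_force_auc(pos, neg) -> float:
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def brute_force_spearman(x, y) -> float:
    """Classic rank-difference formula (valid without ties)."""
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    d2 = ((rx - ry) ** 2).sum()
    n = len(x)
    return 1 - 6 * d2 / (n * (n ** 2 - 1))


class TestTable:
    def test_shape_and_groups(self, table1):
        assert len(table1.records) == 48
        assert table1.group_sizes() == {"A": 20, "B": 17, "C": 11}

    def test_record_one_idelta(self, table1):
        rec = next(r for r in table1.records if r.id == 1)
        assert rec.I_delta == pytest.approx(8.719434105, rel=1e-9)
        assert rec.I_BA / rec.I_S == pytest.approx(8.719434105, rel=1e-6)

    def test_identity_holds_for_all_rows(self, table1):
        for r in table1.records:
            assert abs(r.I_delta - r.I_BA / r.I_S) / r.I_delta < 1e-6


class TestSpearman:
    def test_published_group_correlations(self, table1):
        expected = {"C": 0.900, "B": 0.745, "A": 0.241}
        for g, r_expected in expected.items():
            r = spearman(table1.values("I_S", groups={g}),
                         table1.values("volume", groups={g}))
            assert r == pytest.approx(r_expected, abs=0.0005)

    def test_matches_rank_formula_oracle(self, table1):
        for g in "ABC":
            x = table1.values("I_S", groups={g})
            y = table1.values("volume", groups={g})
            assert spearman(x, y) == pytest.approx(brute_force_spearman(x, y),
                                                   abs=1e-12)

    def test_monotone_pair_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman(x, np.exp(x)) == 1.0

    @given(st.lists(st.integers(-10_000, 10_000), min_size=5, max_size=30,
                    unique=True))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_invariant_under_monotone_transform(self, xs):
        # integer grid keeps exp() strictly monotone in floating point
        x = np.array(xs, dtype=float) / 100.0
        rng = np.random.default_rng(0)
        y = rng.normal(size=len(x))
        assert spearman(x, y) == pytest.approx(spearman(np.exp(x / 100), y), abs=1e-12)


class TestAUC:
    def test_published_translucency_aucs(self, table1):
        pos = table1.values("I_delta", {"B"}, EXCLUSIONS["idelta_translucency"].ids)
        neg = table1.values("I_delta", {"C"}, EXCLUSIONS["idelta_translucency"].ids)
        assert empirical_auc(pos, neg) == pytest.approx(0.927, abs=0.0005)
        pos = table1.values("I_BA", {"B"}, EXCLUSIONS["iba_translucency"].ids)
        neg = table1.values("I_BA", {"C"}, EXCLUSIONS["iba_translucency"].ids)
        assert empirical_auc(pos, neg) == pytest.approx(0.812, abs=0.0005)

    def test_matches_pair_counting_oracle_exactly(self, table1):
        cases = [
            (table1.values("I_delta", {"B"}), table1.values("I_delta", {"C"})),
            (table1.values("I_S", {"A"}), table1.values("I_S", {"B", "C"})),
            (np.array([1.0, 2.0, 2.0, 3.0]), np.array([2.0, 2.0, 0.5])),  # ties
        ]
        for pos, neg in cases:
            assert empirical_auc(pos, neg) == brute_force_auc(pos, neg)

    def test_degenerate_samples(self):
        assert empirical_auc([5, 6], [1, 2]) == 1.0
        assert empirical_auc([3, 3], [3, 3]) == 0.5

    def test_invariant_under_monotone_transforms(self, table1):
        pos = table1.values("I_delta", {"B"})
        neg = table1.values("I_delta", {"C"})
        base = empirical_auc(pos, neg)
        assert empirical_auc(np.log(pos), np.log(neg)) == base
        assert empirical_auc(pos ** 3, neg ** 3) == base


class TestYouden:
    @pytest.mark.parametrize("marker,pos_g,neg_g,excl,cutoff,sens,spec,j", [
        ("I_delta", {"B"}, {"C"}, "idelta_translucency", 2.0753, 1.000, 0.727, 0.727),
        ("I_delta", {"A"}, {"B", "C"}, "idelta_rupture", 4.3991, 0.5, 0.962, 0.462),
        ("I_BA", {"B"}, {"C"}, "iba_translucency", 6.4424, 1.000, 0.636, 0.636),
    ])
    def test_published_cutoffs(self, table1, marker, pos_g, neg_g, excl,
                               cutoff, sens, spec, j):
        ids = EXCLUSIONS[excl].ids
        res = youden_optimal_cutoff(table1.values(marker, pos_g, ids),
                                    table1.values(marker, neg_g, ids))
        assert res.cutoff == pytest.approx(cutoff, abs=0.0005)
        assert res.sensitivity == pytest.approx(sens, abs=0.0005)
        assert res.specificity == pytest.approx(spec, abs=0.0005)
        assert res.youden_j == pytest.approx(j, abs=0.0005)

    def test_reported_operating_point_recomputes(self, table1):
        pos = table1.values("I_delta", {"B"}, EXCLUSIONS["idelta_translucency"].ids)
        neg = table1.values("I_delta", {"C"}, EXCLUSIONS["idelta_translucency"].ids)
        res = youden_optimal_cutoff(pos, neg)
        assert res.sensitivity == float((pos >= res.cutoff).mean())
        assert res.specificity == float((neg < res.cutoff).mean())
        # cutoff is a midpoint of two consecutive distinct pooled values
        pooled = np.unique(np.concatenate([pos, neg]))
        mids = (pooled[:-1] + pooled[1:]) / 2
        assert np.any(np.isclose(mids, res.cutoff, rtol=0, atol=1e-12))


class TestTwoSampleTests:
    def test_ks_identical_and_disjoint(self):
        x = np.arange(10.0)
        z, p = two_sample_test(x, x, method="ks")
        assert z == 0.0 and p == pytest.approx(1.0)
        z, p = two_sample_test(x, x + 100.0, method="ks")
        assert z == pytest.approx(1.0 * np.sqrt(100 / 20))
        assert p < 1e-4

    def test_mann_whitney_close_to_exact_enumeration(self):
        x = np.array([1.2, 3.4, 2.2, 5.5, 0.1, 4.0])
        y = np.array([2.0, 6.0, 7.1, 3.3, 8.0, 9.9])
        _, p_approx = two_sample_test(x, y, method="mann-whitney")
        # exact permutation null of the U statistic at n1 = n2 = 6
        pooled = np.concatenate([x, y])
        n = len(x)

        def u_stat(idx):
            xs = pooled[list(idx)]
            ys = np.delete(pooled, list(idx))
            return sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)

        observed = u_stat(range(n))
        null = [u_stat(c) for c in itertools.combinations(range(12), n)]
        mean_u = len(x) * len(y) / 2
        p_exact = np.mean([abs(u - mean_u) >= abs(observed - mean_u) - 1e-12
                           for u in null])
        assert abs(p_approx - p_exact) < 0.01

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            two_sample_test([1, 2, 3], [1, 2, 3], method="t")


class TestTukey:
    def test_single_spike(self):
        assert list(tukey_outliers([1, 2, 3, 4, 100])) == [4]

    def test_all_equal(self):
        assert len(tukey_outliers([5, 5, 5, 5])) == 0

    def test_bundled_volumes_reported_not_asserted(self, table1, capsys):
        vols = table1.values("volume")
        flagged = {table1.records[i].id for i in tukey_outliers(vols)}
        published = {15, 17, 31, 34, 45}
        print(f"Tukey-flagged volume outliers: {sorted(flagged)}; "
              f"published exclusions: {sorted(published)}; "
              f"agreement: {sorted(flagged & published)}")
        assert flagged  # informative comparison only; the rule is unpublished


class TestBootstrap:
    def test_separated_samples_reach_one(self):
        lo, hi = bootstrap_auc_ci([5, 6, 7], [1, 2, 3], n_boot=200, seed=1)
        assert hi == 1.0

    def test_wider_level_nests(self, table1):
        pos = table1.values("I_delta", {"B"})
        neg = table1.values("I_delta", {"C"})
        lo90, hi90 = bootstrap_auc_ci(pos, neg, n_boot=500, seed=3, level=0.90)
        lo99, hi99 = bootstrap_auc_ci(pos, neg, n_boot=500, seed=3, level=0.99)
        assert lo99 <= lo90 <= hi90 <= hi99

    def test_seed_reproducible(self, table1):
        pos = table1.values("I_BA", {"B"})
        neg = table1.values("I_BA", {"C"})
        assert (bootstrap_auc_ci(pos, neg, n_boot=300, seed=11)
                == bootstrap_auc_ci(pos, neg, n_boot=300, seed=11))


class TestReproducePaper:
    def test_report_contents(self, table1):
        rep = reproduce_paper(table1, n_boot=200)
        assert rep["correlation_IS_volume"]["A"] == pytest.approx(0.241, abs=0.0005)
        assert rep["roc"]["iba_translucency"]["auc"] == pytest.approx(0.812, abs=0.0005)
        assert "not reproducible" in rep["roc"]["idelta_rupture"]["note"]
        assert rep["identity_max_rel_error"] < 1e-6

    def test_deterministic_json(self, table1):
        a = json.dumps(reproduce_paper(table1, n_boot=100), sort_keys=True)
        b = json.dumps(reproduce_paper(table1, n_boot=100), sort_keys=True)
        assert a == b
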