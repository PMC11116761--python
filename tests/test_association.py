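import itertools

import numpy as np
import pytest

from sociodep.association import (_fit_beta, _group_structure, _posterior_r,
                                  compute_sri, daily_swap_chain, mantel_test,
                                  permutation_test, social_differentiation)
from sociodep.sightings_io import Dataset

from conftest import null_association_dataset, sighting, two_clique_dataset


def brute_force_sri(groups):
    """Sighting-period SRI by dyad enumeration (independent oracle)."""
    ids = sorted(set().union(*groups))
    out = {}
    for a, b in itertools.combinations(ids, 2):
        x = sum(1 for g in groups if a in g and b in g)
        either = sum(1 for g in groups if a in g or b in g)
        out[(a, b)] = x / either if either else 0.0
    return ids, out


def ds_from_groups(groups, per_day=1):
    """One sighting per group; `per_day` groups share each calendar day."""
    out = []
    for k, g in enumerate(groups):
        out.append(sighting(f"s{k}", tuple(g), day=1 + k // per_day,
                            hour=8 + 2 * (k % per_day)))
    return Dataset(out)


class TestSRI:
    def test_always_together_is_one(self):
        am = compute_sri(ds_from_groups([{"A", "B"}, {"A", "B"}]))
        i, j = am.ids.index("A"), am.ids.index("B")
        assert am.sri[i, j] == 1.0

    def test_half_shared_periods(self):
        am = compute_sri(ds_from_groups([{"A", "B"}, {"A"}, {"B"}, {"A", "B"}]))
        i, j = am.ids.index("A"), am.ids.index("B")
        assert am.x[i, j] == 2 and am.d[i, j] == 4
        assert am.sri[i, j] == 0.5

    def test_never_together_is_zero(self):
        am = compute_sri(ds_from_groups([{"A"}, {"B"}, {"A"}]))
        i, j = am.ids.index("A"), am.ids.index("B")
        assert am.sri[i, j] == 0.0

    def test_matches_brute_force_on_random_groups(self):
        rng = np.random.default_rng(3)
        ids = list("ABCDEFGH")
        groups = [set(rng.choice(ids, size=rng.integers(1, 5), replace=False))
                  for _ in range(25)]
        am = compute_sri(ds_from_groups(groups))
        _, oracle = brute_force_sri(groups)
        for (a, b), v in oracle.items():
            assert am.sri[am.ids.index(a), am.ids.index(b)] == pytest.approx(v)

    def test_symmetric_in_unit_interval(self):
        am = compute_sri(null_association_dataset(1), "sighting")
        assert np.allclose(am.sri, am.sri.T)
        assert (am.sri >= 0).all() and (am.sri <= 1).all()
        assert np.all(am.d >= am.x)

    def test_day_period_counts_both_present_not_together(self):
        # A and B sighted the same day in different sightings
        ds = Dataset([sighting("s1", ("A",), day=1, hour=8),
                      sighting("s2", ("B",), day=1, hour=12),
                      sighting("s3", ("A", "B"), day=2)])
        am = compute_sri(ds, "day")
        i, j = am.ids.index("A"), am.ids.index("B")
        assert am.y_both_separate[i, j] == 1
        assert am.x[i, j] == 1 and am.d[i, j] == 2
        assert am.sri[i, j] == 0.5

    def test_unknown_period_rejected(self):
        with pytest.raises(ValueError):
            compute_sri(null_association_dataset(1), "week")


class TestPermutation:
    def test_chain_preserves_margins_per_step(self):
        ds = null_association_dataset(7)
        _, B, day_codes = _group_structure(ds)
        row0 = B.sum(axis=1).copy()
        col_by_day = {d: B[day_codes == d].sum(axis=0).copy()
                      for d in np.unique(day_codes)}
        rng = np.random.default_rng(0)
        for Bcur, _ in daily_swap_chain(B.copy(), day_codes, 50, 10, rng):
            assert (Bcur.sum(axis=1) == row0).all()
            for d, c in col_by_day.items():
                assert (Bcur[day_codes == d].sum(axis=0) == c).all()

    def test_seed_reproducible(self):
        ds = null_association_dataset(2)
        r1 = permutation_test(ds, "cv_sri", n_permutations=100, seed=42)
        r2 = permutation_test(ds, "cv_sri", n_permutations=100, seed=42)
        assert np.array_equal(r1.permuted, r2.permuted)
        assert r1.p_value == r2.p_value

    def test_detects_planted_cliques(self):
        res = permutation_test(two_clique_dataset(), "cv_sri",
                               n_permutations=500, seed=1)
        assert res.p_value < 0.05

    @pytest.mark.parametrize("stat", ["cv_sri", "sd_sri", "sd_nonzero_sri"])
    def test_all_statistics_run(self, stat):
        res = permutation_test(null_association_dataset(3), stat,
                               n_permutations=50, seed=0)
        assert 0.0 <= res.p_value <= 1.0
        assert res.permuted.size == 50

    def test_degenerate_when_nothing_swappable(self):
        # one group per day: no within-day pair of groups exists
        ds = Dataset([sighting(f"s{k}", ("A", "B"), day=k + 1)
                      for k in range(4)])
        with pytest.warns(UserWarning):
            res = permutation_test(ds, "cv_sri", n_permutations=20, seed=0)
        assert not res.testable and res.p_value == 1.0


class TestMantel:
    def test_identity_gives_r_one(self):
        am = compute_sri(null_association_dataset(5))
        res = mantel_test(am, am, n_permutations=50, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        am = compute_sri(null_association_dataset(5))
        import copy
        am2 = copy.deepcopy(am)
        am2.x = am.sri ** 3 * 100          # rank-preserving transform
        am2.d = np.full_like(am.d, 100.0)
        np.fill_diagonal(am2.d, 0.0)
        res = mantel_test(am, am2, n_permutations=50, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_requires_three_common_individuals(self):
        ds1 = ds_from_groups([{"A", "B"}, {"A"}])
        ds2 = ds_from_groups([{"A", "C"}, {"C"}])
        with pytest.raises(ValueError):
            mantel_test(compute_sri(ds1), compute_sri(ds2))

    def test_null_p_not_extreme_under_independence(self):
        rng = np.random.default_rng(0)
        am = compute_sri(null_association_dataset(8))
        import copy
        am2 = copy.deepcopy(am)
        r = rng.random(am.x.shape)
        r = (r + r.T) / 2
        am2.x = r * 50
        am2.d = np.full_like(am.d, 50.0)
        ps = []
        for seed in range(10):
            am3 = copy.deepcopy(am2)
            p = rng.permutation(am.n)
            am3.x = am2.x[np.ix_(p, p)]
            ps.append(mantel_test(am, am3, n_permutations=99, seed=seed).p_value)
        # under independence p should not pile up near 0
        assert np.mean(np.array(ps) < 0.05) <= 0.3


class TestSocialDifferentiation:
    def make_am(self, a, b, n_dyads, d, seed=0):
        """Beta-binomial dyads wrapped in a minimal AssociationMatrix."""
        from sociodep.association import AssociationMatrix
        rng = np.random.default_rng(seed)
        # build a symmetric container whose upper triangle holds the dyads
        n = int(np.ceil((1 + np.sqrt(1 + 8 * n_dyads)) / 2))
        X = np.zeros((n, n))
        D = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        m = iu[0].size
        p = rng.beta(a, b, size=m)
        xs = rng.binomial(d, p)
        X[iu] = xs
        D[iu] = d
        X += X.T
        D += D.T
        ids = [f"I{k}" for k in range(n)]
        return AssociationMatrix(ids, X, D, np.full(n, float(d)),
                                 np.zeros((n, n)), "sighting", d)

    def test_recovers_planted_cv(self):
        am = self.make_am(2, 2, 300, 100, seed=1)
        est = social_differentiation(am, seed=1, n_boot=0, n_sim=10)
        true_cv = np.sqrt(2 / (2 * 5))          # CV of Beta(2,2) = 0.447
        assert est.S == pytest.approx(true_cv, rel=0.15)
        assert est.power == pytest.approx(est.S ** 2 * est.H)

    def test_degenerate_flag_when_no_variation(self):
        from sociodep.association import AssociationMatrix
        n = 20
        X = np.full((n, n), 5000.0)
        D = np.full((n, n), 10000.0)
        np.fill_diagonal(X, 0.0)
        np.fill_diagonal(D, 0.0)
        am = AssociationMatrix([f"I{k}" for k in range(n)], X, D,
                               np.full(n, 1e4), np.zeros((n, n)), "sighting", 10000)
        est = social_differentiation(am, seed=0, n_boot=0, n_sim=5)
        assert est.S < 0.05 and est.degenerate

    def test_r_increases_with_denominator(self):
        rng = np.random.default_rng(0)
        rs = [_posterior_r(2.0, 2.0, np.full(300, d, dtype=float), rng, n_sim=20)
              for d in (5, 50, 500)]
        assert rs[0] < rs[1] < rs[2]

    def test_bootstrap_se_positive(self):
        am = self.make_am(2, 2, 100, 50, seed=2)
        est = social_differentiation(am, seed=0, n_boot=20, n_sim=5)
        assert est.se_S > 0

    def test_beta_fit_oracle(self):
        # ML fit recovers (a, b) of a large exact beta-binomial sample
        rng = np.random.default_rng(4)
        p = rng.beta(3.0, 5.0, size=4000)
        xs = rng.binomial(200, p)
        a, b = _fit_beta(xs.astype(float), np.full(4000, 200.0))
        assert a == pytest.approx(3.0, rel=0.2)
        assert b == pytest.approx(5.0, rel=0.2)
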