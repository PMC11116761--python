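import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import integrate, stats

from sociodep.occurrence_model import (aicc, build_occurrence_table,
                                       count_parameters, dedup_12h, diagnose,
                                       emmeans_units, fit_glmm, select_model)
from sociodep.social_units import Partition
from sociodep.synthetic_data import simulate_occurrence_records

from conftest import sighting


def part_of(mapping):
    return Partition(mapping, 0.3, 0.0, 1.0, 1, 0)


class TestDedup12h:
    part = part_of({"a1": "A", "a2": "A", "b1": "B"})

    def test_repeat_within_window_same_vessel_dropped(self):
        s = [sighting("s1", ("a1",), hour=0), sighting("s2", ("a2",), hour=6)]
        kept = dedup_12h(s, self.part)
        assert [k.sighting_id for k in kept] == ["s1"]

    def test_different_vessel_kept(self):
        s = [sighting("s1", ("a1",), hour=0, vessel="V1"),
             sighting("s2", ("a1",), hour=6, vessel="V2")]
        assert len(dedup_12h(s, self.part)) == 2

    def test_outside_window_kept_and_reanchored(self):
        s = [sighting("s1", ("a1",), hour=0), sighting("s2", ("a1",), hour=13),
             sighting("s3", ("a1",), hour=20)]
        kept = dedup_12h(s, self.part)
        # 13 h > 12 h re-anchors; 20 h is within 12 h of the new anchor
        assert [k.sighting_id for k in kept] == ["s1", "s2"]

    def test_kept_when_any_unit_is_new(self):
        s = [sighting("s1", ("a1",), hour=0),
             sighting("s2", ("a1", "b1"), hour=6)]
        kept = dedup_12h(s, self.part)
        assert [k.sighting_id for k in kept] == ["s1", "s2"]

    def test_never_drops_isolated_sightings(self):
        s = [sighting(f"s{k}", ("a1",), day=k + 1) for k in range(5)]
        assert len(dedup_12h(s, self.part)) == 5


class TestOccurrenceTable:
    def test_one_record_per_sighting_unit_pair(self):
        part = part_of({"a1": "A", "b1": "B"})
        ds_sightings = [sighting("s1", ("a1",), hour=0),
                        sighting("s2", ("b1",), day=2)]
        from sociodep.sightings_io import Dataset
        rec = build_occurrence_table(Dataset(ds_sightings), part)
        assert len(rec) == 4
        assert set(rec.columns) >= {"sighting_id", "unit", "present", "year",
                                    "month", "effort", "vessel_id"}
        present = rec.set_index(["sighting_id", "unit"]).present
        assert present[("s1", "A")] == 1 and present[("s1", "B")] == 0


class TestBookkeeping:
    @pytest.mark.parametrize("levels,nvar,expected", [
        ([], 1, 2),                    # null model
        ([18], 1, 19),                 # + year
        ([18, 12], 1, 30),             # + month
        ([18, 12, 17], 1, 46),         # + unit
        ([18, 12, 17], 3, 48),         # + nested random structure
    ])
    def test_parameter_counts(self, levels, nvar, expected):
        assert count_parameters(levels, nvar) == expected

    def test_aicc_identity_on_fit(self):
        rec, _ = simulate_occurrence_records(n_sightings=80, n_units=5, seed=0)
        fit = fit_glmm(rec, fixed_terms=("unit",))
        k, n, ll = fit.K, fit.n, fit.loglik
        assert fit.aicc == pytest.approx(
            -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1), abs=1e-10)

    def test_aicc_undefined_for_tiny_n(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)


class TestGLMMFit:
    def test_sigma_zero_limit_equals_plain_logistic(self):
        rec, _ = simulate_occurrence_records(n_sightings=250, n_units=6,
                                             effort_sigma=0.0, seed=1)
        fit = fit_glmm(rec, fixed_terms=("unit",), fixed_sigma2=1e-10)
        oracle = sm.GLM(fit.y, fit.X, family=sm.families.Binomial()).fit()
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-4)
        assert np.allclose(fit.params.to_numpy(), oracle.params, atol=1e-4)

    def test_loglik_matches_dense_quadrature(self):
        # pin the variance so the quadrature oracle is well conditioned
        rec, _ = simulate_occurrence_records(n_sightings=120, n_units=4,
                                             effort_sigma=0.5, seed=2)
        fit = fit_glmm(rec, fixed_terms=("unit",), fixed_sigma2=0.25)
        beta = fit.params.to_numpy()
        s2 = fit.sigma2["effort"]
        eta = fit.X @ beta
        codes = fit.z_codes["effort"]
        ll = 0.0
        for g in np.unique(codes):
            idx = codes == g
            yg, eg = fit.y[idx], eta[idx]

            def f(u):
                return np.exp(np.sum(yg * (eg + u) - np.logaddexp(0, eg + u))
                              ) * stats.norm.pdf(u, 0, np.sqrt(s2))

            val, _ = integrate.quad(f, -6 * np.sqrt(s2) - 2, 6 * np.sqrt(s2) + 2,
                                    limit=200)
            ll += np.log(val)
        assert fit.loglik == pytest.approx(ll, abs=1e-3)

    def test_r2_conditional_at_least_marginal(self):
        rec, _ = simulate_occurrence_records(n_sightings=150, n_units=5, seed=3)
        fit = fit_glmm(rec, fixed_terms=("unit",))
        assert 0 <= fit.r2_marginal <= fit.r2_conditional <= 1

    def test_multiple_random_terms_fit(self):
        rec, _ = simulate_occurrence_records(n_sightings=60, n_units=4, seed=4)
        fit = fit_glmm(rec, fixed_terms=("unit",),
                       random_terms=("effort", "sighting_id"))
        assert set(fit.sigma2) == {"effort", "sighting_id"}
        assert fit.K == 1 + 3 + 2

    def test_separation_warns(self):
        rec, _ = simulate_occurrence_records(n_sightings=40, n_units=3, seed=5)
        rec = rec.copy()
        rec["flag"] = np.where(rec.present == 1, "yes", "no")  # perfect predictor
        with pytest.warns(UserWarning, match="separation"):
            fit_glmm(rec, fixed_terms=("flag",), random_terms=())


class TestSelection:
    def test_forward_ladder_prefers_true_structure(self):
        rec, _ = simulate_occurrence_records(n_sightings=250, n_units=8,
                                             year_sd=0.0, month_sd=0.0, seed=6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ladder, fits = select_model(rec, nested_extension=None)
        # unit effects are strong by construction: full model wins on AICc
        assert ladder["rank"].iloc[-1] == 1
        # X2 column equals twice the LL difference of consecutive fits
        for k in range(1, len(fits)):
            assert ladder.X2.iloc[k] == pytest.approx(
                max(0.0, 2 * (fits[k].loglik - fits[k - 1].loglik)), abs=1e-8)
        assert ladder.wAICc.sum() == pytest.approx(1.0)

    def test_nested_extension_adds_two_variance_terms(self):
        rec, _ = simulate_occurrence_records(n_sightings=50, n_units=3, seed=7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ladder, fits = select_model(
                rec, candidate_order=("unit",),
                nested_extension=("sighting_id", "sighting_id:unit"))
        assert fits[-1].K == fits[-2].K + 2
        # the nested structure cannot lower the likelihood of the same model
        assert ladder.X2.iloc[-1] >= -1e-6


@pytest.fixture(scope="module")
def fitted():
    rec, _ = simulate_occurrence_records(n_sightings=250, n_units=6, seed=8)
    return fit_glmm(rec, fixed_terms=("unit",))


class TestDiagnostics:

    def test_well_specified_model_passes_checks(self, fitted):
        d = diagnose(fitted, n_sim=300, seed=0)
        assert 0.8 < d.dispersion_ratio < 1.2
        assert d.ks_p > 0.01
        assert 0.8 < d.zero_inflation_ratio < 1.2
        assert 1.5 < d.durbin_watson < 2.5
        for p in (d.dispersion_p, d.ks_p, d.outlier_p, d.zero_inflation_p,
                  d.durbin_watson_p):
            assert 0 <= p <= 1

    def test_collinear_design_flagged_by_gvif(self):
        rec, _ = simulate_occurrence_records(n_sightings=60, n_units=4, seed=9)
        rec = rec.copy()
        rec["unit_copy"] = rec["unit"]
        fit = fit_glmm(rec, fixed_terms=("unit", "unit_copy"))
        d = diagnose(fit, n_sim=50, seed=0)
        assert not np.isfinite(d.gvif["unit"]) or d.gvif["unit"] > 100


class TestEmmeans:
    def test_unit_only_model_recovers_empirical_frequencies(self):
        rec, _ = simulate_occurrence_records(n_sightings=200, n_units=6, seed=10)
        fit = fit_glmm(rec, fixed_terms=("unit",), random_terms=())
        emm = emmeans_units(fit).emmeans.set_index("unit")
        freq = rec.groupby("unit").present.mean()
        for u in freq.index:
            assert emm.loc[u, "prob"] == pytest.approx(freq[u], abs=1e-6)

    def test_interval_and_holm_invariants(self):
        rec, _ = simulate_occurrence_records(n_sightings=150, n_units=5, seed=11)
        fit = fit_glmm(rec)
        res = emmeans_units(fit)
        e = res.emmeans
        assert ((e.lo95 <= e.prob) & (e.prob <= e.hi95)).all()
        assert ((e.prob > 0) & (e.prob < 1)).all()
        c = res.contrasts
        assert (c.p_holm >= c.p - 1e-12).all()
        assert len(c) == 5 * 4 / 2

    def test_requires_unit_term(self):
        rec, _ = simulate_occurrence_records(n_sightings=50, n_units=3, seed=12)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sparse years may separate
            fit = fit_glmm(rec, fixed_terms=("year",))
        with pytest.raises(ValueError):
            emmeans_units(fit)

    def test_holm_adjustment_stepdown_arithmetic(self):
        # m=3 raw p-values .01/.02/.04 -> .03/.04/.04 after step-down
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([0.01, 0.02, 0.04], method="holm")[1]
        assert np.allclose(adj, [0.03, 0.04, 0.04])
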