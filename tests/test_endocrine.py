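import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from cogchange import endocrine as en
from cogchange.datatypes import Group, HormonePanel, SubjectRecord


def free_t_fixed_point(tt, shbg, constants=en.BindingConstants(), albumin=None, tol=1e-13):
    """Independent iterative mass-balance solver: start from FT = TT and
    repeatedly redistribute testosterone over SHBG and albumin binding."""
    if tt == 0:
        return 0.0
    if albumin is None:
        albumin = constants.albumin_default
    tt_m, shbg_m = tt * 1e-9, shbg * 1e-9
    alb = constants.k_albumin * albumin / constants.albumin_molar_mass
    ft = tt_m
    for _ in range(10_000):
        new = tt_m / (1.0 + alb + constants.k_shbg * shbg_m / (1.0 + constants.k_shbg * ft))
        if abs(new - ft) < tol * tt_m:
            ft = new
            break
        ft = new
    return ft * 1e9


class TestFreeTestosterone:
    def test_zero_total_gives_zero_free(self):
        assert en.free_testosterone(0.0, 40.0) == 0.0

    def test_no_binding_proteins_gives_total(self):
        assert en.free_testosterone(15.0, 0.0, albumin=0.0) == pytest.approx(15.0, rel=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            en.free_testosterone(-1.0, 40.0)
        with pytest.raises(ValueError):
            en.free_testosterone(15.0, -1.0)

    def test_cohort_mean_inputs_in_physiological_band(self):
        """At the cohort-mean total T and SHBG the free fraction is 1-4%."""
        ft = en.free_testosterone(15.87, 38.18)
        assert 0.01 * 15.87 <= ft <= 0.04 * 15.87
        assert ft == pytest.approx(free_t_fixed_point(15.87, 38.18), abs=1e-6)

    def test_matches_fixed_point_solver_on_grid(self):
        for tt in np.linspace(2, 40, 5):
            for shbg in np.linspace(5, 100, 5):
                assert en.free_testosterone(tt, shbg) == pytest.approx(
                    free_t_fixed_point(tt, shbg), abs=1e-6
                )

    @given(st.floats(0.5, 50), st.floats(1, 120))
    def test_monotonic_and_bounded(self, tt, shbg):
        ft = en.free_testosterone(tt, shbg)
        assert 0 <= ft <= tt
        assert en.free_testosterone(tt + 1, shbg) > ft  # increasing in total T
        assert en.free_testosterone(tt, shbg + 5) < ft  # decreasing in SHBG


def _subject(sid, group, t1, t2, **kwargs):
    return SubjectRecord(
        sid, group, age=40, premorbid_iq=10,
        hormones_t1=HormonePanel(**t1), hormones_t2=HormonePanel(**t2), **kwargs
    )


class TestDeltas:
    def test_equal_timepoints_give_zero(self):
        s = _subject("a", Group.PATIENT, {"shbg": 38.18}, {"shbg": 38.18})
        (rec,) = en.compute_deltas([s], ["shbg"])
        assert rec.delta == 0.0

    def test_shbg_rise_arithmetic(self):
        s = _subject("a", Group.PATIENT, {"shbg": 38.18}, {"shbg": 47.29})
        (rec,) = en.compute_deltas([s], ["shbg"])
        assert rec.delta == pytest.approx(9.11)

    def test_antisymmetry(self, rng):
        v1, v2 = rng.random(2) * 50
        fwd = _subject("a", Group.CONTROL, {"lh": v1}, {"lh": v2})
        rev = _subject("a", Group.CONTROL, {"lh": v2}, {"lh": v1})
        (d1,) = en.compute_deltas([fwd], ["lh"])
        (d2,) = en.compute_deltas([rev], ["lh"])
        assert d1.delta == -d2.delta

    def test_missing_timepoint_skipped(self):
        s = _subject("a", Group.PATIENT, {"shbg": 38.0}, {})
        assert en.compute_deltas([s], ["shbg"]) == []

    def test_summary_matches_brute_tally(self, default_cohort):
        _, subjects, _ = default_cohort
        recs = en.compute_deltas(subjects, ["shbg", "neutrophils"])
        summary = en.delta_summary(recs)
        for var in ("shbg", "neutrophils"):
            for group in ("patient", "control"):
                vals = [r.delta for r in recs
                        if r.variable_id == var and r.group.value == group]
                row = summary[(summary.variable == var) & (summary.group == group)]
                assert row["delta_mean"].iloc[0] == pytest.approx(np.mean(vals))
                assert row["n"].iloc[0] == len(vals)

    def test_patient_shbg_rises_and_neutrophils_fall(self, default_cohort):
        """The generator reproduces the study's endocrine signature: SHBG
        rising in patients but flat in controls, neutrophils falling."""
        _, subjects, _ = default_cohort
        summary = en.delta_summary(en.compute_deltas(subjects, ["shbg", "neutrophils"]))

        def mean_of(var, grp):
            m = summary[(summary.variable == var) & (summary.group == grp)]
            return m["delta_mean"].iloc[0]

        assert mean_of("shbg", "patient") > mean_of("shbg", "control")
        assert mean_of("neutrophils", "patient") < mean_of("neutrophils", "control")


class TestPredictChange:
    def test_exact_linear_relation_recovered(self, rng):
        x = rng.normal(0, 1, 40)
        (res,) = en.predict_change(2.0 * x, x)
        assert res.beta == pytest.approx(2.0, abs=1e-9)
        assert res.p < 1e-12

    def test_constant_predictor_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            en.predict_change(rng.normal(0, 1, 20), np.ones(20))

    def test_too_few_cases_rejected(self, rng):
        with pytest.raises(ValueError, match="complete cases"):
            en.predict_change(rng.normal(0, 1, 5), rng.normal(0, 1, 5))

    def test_null_predictor_p_uniform(self):
        rng = np.random.default_rng(3)
        ps = [
            en.predict_change(rng.normal(0, 1, 50), rng.normal(0, 1, 50))[0].p
            for _ in range(300)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    def test_group_interaction_followup_triggered(self, rng):
        n = 40
        g = np.r_[["patient"] * n, ["control"] * n]
        x = rng.normal(0, 1, 2 * n)
        y = np.where(g == "patient", -1.0 * x, 0.0 * x) + rng.normal(0, 0.3, 2 * n)
        results = en.predict_change(y, x, group=g)
        assert {r.group for r in results} == {"patient", "control"}
        pat = next(r for r in results if r.group == "patient")
        assert pat.beta < 0 and pat.p < 0.01
        assert pat.group_interaction_p is not None and pat.group_interaction_p < 0.01


class TestAdjustedModel:
    def test_shbg_driven_outcome_leaves_testosterone_null(self, rng):
        n = 2000
        t = rng.normal(16, 5, n)
        shbg = rng.normal(40, 15, n)
        cag = rng.normal(19, 2.6, n)
        y = 3.0 * shbg + rng.normal(0, 1, n)
        res = en.adjusted_testosterone_model(y, t, shbg, cag)
        assert abs(res.beta) < 0.05
        assert res.p > 1e-4

    def test_null_outcome_calibrated(self):
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(200):
            n = 40
            ps.append(
                en.adjusted_testosterone_model(
                    rng.normal(0, 1, n), rng.normal(16, 5, n),
                    rng.normal(40, 15, n), rng.normal(19, 2.6, n),
                ).p
            )
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    def test_too_few_cases_rejected(self, rng):
        with pytest.raises(ValueError):
            en.adjusted_testosterone_model(np.ones(4), np.arange(4.0),
                                           np.arange(4.0), np.arange(4.0))

    def test_collinear_predictors_warn(self, rng):
        n = 50
        t = rng.normal(16, 5, n)
        with pytest.warns(UserWarning, match="collinear"):
            res = en.adjusted_testosterone_model(
                rng.normal(0, 1, n), t, t * 2.0 + 1e-9 * rng.normal(size=n),
                rng.normal(19, 2.6, n),
            )
        assert res.collinearity_warning


class TestGenotypeEffects:
    def test_all_carriers_skipped(self, rng):
        out = en.genotype_effects(
            {"gcs_z": rng.normal(0, 1, 30)}, {"apoe": np.ones(30)}
        )
        assert out == []

    def test_designed_carrier_effect_detected(self, rng):
        flags = (rng.random(200) < 0.4).astype(float)
        y = 1.2 * flags + rng.normal(0, 1, 200)
        (res,) = en.genotype_effects({"gcs_z": y}, {"apoe": flags})
        assert res.beta == pytest.approx(1.2, abs=0.4)
        assert res.p < 1e-4

    def test_null_genotype_type_one_error_nominal(self):
        rng = np.random.default_rng(4)
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            flags = (rng.random(40) < 0.5).astype(float)
            if flags.sum() in (0, 40):
                continue
            (res,) = en.genotype_effects({"z": rng.normal(0, 1, 40)}, {"g": flags})
            hits += res.p < 0.05
        rate = hits / n_rep
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep)
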