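"""Feature ladder: rates, fits, yields, replicate statistics, corrections."""

import copy
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fermkit as fk
from fermkit import features as F
from fermkit.errors import FeatureError

from conftest import make_course


def _logistic(t, A, mu, lam):
    return A / (1 + np.exp(4 * mu / A * (lam - t) + 2))


class TestGradient:
    def test_linear_series_exact_everywhere(self, trial_id):
        rs = fk.gradient(make_course(trial_id, "product", [0, 1, 2], [0, 2, 4]))
        assert rs.rates.tolist() == [2.0, 2.0, 2.0]

    def test_nonuniform_quadratic_interior_exact(self, trial_id):
        rs = fk.gradient(make_course(trial_id, "product", [0, 1, 3], [0, 1, 9]))
        assert rs.rates.tolist() == [1.0, 2.0, 4.0]

    def test_missing_values_dropped_first(self, trial_id):
        rs = fk.gradient(
            make_course(trial_id, "product", [0, 1, 2, 3], [0, np.nan, 4, 6])
        )
        assert rs.times.tolist() == [0.0, 2.0, 3.0]
        assert rs.rates.tolist() == [2.0, 2.0, 2.0]

    def test_single_finite_point_errors(self, trial_id):
        with pytest.raises(FeatureError, match="insufficient"):
            fk.gradient(make_course(trial_id, "product", [0, 1], [1.0, np.nan]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        a=st.floats(-5, 5, allow_nan=False),
        b=st.floats(-5, 5, allow_nan=False),
    )
    def test_affine_exact_on_random_grids(self, a, b):
        tid = fk.parse_identifier("strain:A|media:M9")
        t = np.array([0.0, 0.7, 1.1, 2.9, 4.0])
        rs = fk.gradient(make_course(tid, "product", t, a * t + b))
        assert np.allclose(rs.rates, a, atol=1e-9)


class TestGrowthFits:
    def test_exponential_exact_recovery(self, trial_id):
        t = np.arange(0, 5.1, 0.5)
        course = make_course(trial_id, "biomass", t, 0.05 * np.exp(0.6 * t))
        fit = fk.fit_growth_model(course, "exponential")
        assert fit.params["mu"] == pytest.approx(0.6, abs=1e-6)
        assert fit.params["X0"] == pytest.approx(0.05, abs=1e-6)

    def test_constant_course_zero_mu(self, trial_id):
        fit = fk.fit_growth_model(
            make_course(trial_id, "biomass", [0, 1, 2, 3], [1.0] * 4), "exponential"
        )
        assert fit.params["mu"] == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_values_rejected(self, trial_id):
        with pytest.raises(FeatureError, match="positive"):
            fk.fit_growth_model(
                make_course(trial_id, "biomass", [0, 1, 2], [1.0, 0.0, 2.0]), "exponential"
            )

    def test_gen_logistic_noiseless_recovery(self, trial_id):
        t = np.arange(0, 24.1, 0.5)
        course = make_course(trial_id, "biomass", t, _logistic(t, 2.0, 0.5, 1.0))
        fit = fk.fit_growth_model(course, "gen_logistic")
        assert fit.params["A"] == pytest.approx(2.0, rel=1e-4)
        assert fit.params["mu_max"] == pytest.approx(0.5, rel=1e-4)
        assert fit.params["lam"] == pytest.approx(1.0, rel=1e-4)

    def test_richards5_noiseless_recovery(self, trial_id):
        t = np.arange(0, 24.1, 0.5)
        truth = {"A": 2.0, "mu_max": 0.5, "lam": 1.0, "nu": 1.0, "X0": 0.05}
        y = F._richards5_form(t, truth)
        fit = fk.fit_growth_model(make_course(trial_id, "biomass", t, y), "richards5")
        for k, v in truth.items():
            assert fit.params[k] == pytest.approx(v, rel=1e-3, abs=1e-3), k

    def test_noisy_logistic_mu_max_within_5pct(self, trial_id):
        t = np.arange(0, 24.1, 0.5)
        clean = _logistic(t, 2.0, 0.5, 1.0)
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = clean + rng.normal(0, 0.01, t.size)
            fit = fk.fit_growth_model(make_course(trial_id, "biomass", t, y), "gen_logistic")
            if abs(fit.params["mu_max"] - 0.5) / 0.5 <= 0.05:
                hits += 1
        assert hits >= 95

    def test_window_restricts_fit(self, trial_id):
        t = np.arange(0, 10.1, 0.5)
        y = 0.05 * np.exp(0.6 * t)
        y[t > 5] = y[t <= 5][-1]  # growth stops
        fit = fk.fit_growth_model(
            make_course(trial_id, "biomass", t, y), "exponential", window=(0, 5)
        )
        assert fit.params["mu"] == pytest.approx(0.6, abs=1e-9)

    def test_deterministic_refit(self, trial_id):
        t = np.arange(0, 24.1, 1.0)
        rng = np.random.default_rng(0)
        y = _logistic(t, 2.0, 0.5, 1.0) + rng.normal(0, 0.02, t.size)
        course = make_course(trial_id, "biomass", t, y)
        f1 = fk.fit_growth_model(course, "gen_logistic")
        f2 = fk.fit_growth_model(course, "gen_logistic")
        assert f1.params == f2.params

    def test_too_few_points_errors(self, trial_id):
        with pytest.raises(FeatureError, match="insufficient"):
            fk.fit_growth_model(
                make_course(trial_id, "biomass", [0, 1, 2, 3], [1, 2, 3, 4]), "gen_logistic"
            )


class TestYield:
    def test_endpoint_arithmetic(self, trial_id):
        S = make_course(trial_id, "substrate", [0, 10], [10, 4])
        P = make_course(trial_id, "product", [0, 10], [0, 3])
        assert fk.compute_yield(P, S).endpoint_yield == pytest.approx(0.5)

    def test_constant_product_zero_yield(self, trial_id):
        S = make_course(trial_id, "substrate", [0, 10], [10, 4])
        P = make_course(trial_id, "product", [0, 10], [1, 1])
        assert fk.compute_yield(P, S).endpoint_yield == 0.0

    def test_no_consumption_errors(self, trial_id):
        S = make_course(trial_id, "substrate", [0, 10], [10, 10])
        P = make_course(trial_id, "product", [0, 10], [0, 3])
        with pytest.raises(FeatureError, match="no substrate consumed"):
            fk.compute_yield(P, S)

    def test_synthetic_ground_truth_exact(self, clean_synthetic):
        e, truth = clean_synthetic
        single = e.replicates[0].singles[0]
        res = fk.compute_yield(single.courses["product"], single.courses["glucose"])
        assert res.endpoint_yield == pytest.approx(truth["Y_PS"], abs=1e-12)

    def test_cumulative_undefined_before_consumption(self, trial_id):
        S = make_course(trial_id, "substrate", [0, 1, 2], [10, 10, 5])
        P = make_course(trial_id, "product", [0, 1, 2], [0, 0, 2])
        res = fk.compute_yield(P, S)
        assert np.isnan(res.cumulative[0]) and np.isnan(res.cumulative[1])
        assert res.cumulative[2] == pytest.approx(0.4)


class TestSpecificRate:
    def test_constant_biomass_linear_product(self, trial_id):
        t = np.arange(0, 5.0)
        P = make_course(trial_id, "product", t, 1.0 * t, unit="g/L")
        X = make_course(trial_id, "biomass", t, np.full(t.size, 0.5), unit="gDW/L")
        q = fk.specific_rate(P, X)
        assert np.allclose(q.rates[1:-1], 2.0)

    def test_molar_mass_conversion(self, trial_id):
        t = np.arange(0, 5.0)
        P = make_course(trial_id, "product", t, 0.9 * t, unit="g/L")
        X = make_course(trial_id, "biomass", t, np.full(t.size, 0.5), unit="gDW/L")
        q = fk.specific_rate(P, X, molar_mass=90.0)
        assert np.allclose(q.rates, 20.0)
        assert q.unit == "mmol/gDW/h"

    def test_growth_rate_special_case(self, trial_id):
        t = np.arange(0, 5.01, 0.25)
        X = make_course(trial_id, "biomass", t, 0.05 * np.exp(0.6 * t), unit="gDW/L")
        mu = fk.specific_rate(X, X)
        assert np.allclose(mu.rates[1:-1], 0.6, rtol=0.01)

    def test_zero_biomass_rejected(self, trial_id):
        t = np.arange(0, 3.0)
        P = make_course(trial_id, "product", t, t)
        X = make_course(trial_id, "biomass", t, [0.5, 0.0, 0.5])
        with pytest.raises(FeatureError, match="biomass"):
            fk.specific_rate(P, X)


class TestNormalization:
    def test_pointwise_division(self, trial_id):
        sig = make_course(trial_id, "reporter", [0, 1], [1, 2], unit="AU")
        od = make_course(trial_id, "biomass", [0, 1], [0.5, 1.0], unit="OD")
        out = fk.normalize_to_biomass(sig, od)
        assert out.values.tolist() == [2.0, 2.0]
        assert out.unit == "AU/OD"

    def test_self_normalization_identity(self, trial_id):
        od = make_course(trial_id, "biomass", [0, 1, 2], [0.5, 1.0, 2.0])
        assert fk.normalize_to_biomass(od, od).values.tolist() == [1.0, 1.0, 1.0]

    def test_missing_propagates(self, trial_id):
        sig = make_course(trial_id, "reporter", [0, 1], [1, np.nan])
        od = make_course(trial_id, "biomass", [0, 1], [0.5, 1.0])
        out = fk.normalize_to_biomass(sig, od)
        assert out.values[0] == 2.0 and np.isnan(out.values[1])


class TestReplicateStatistics:
    def test_missing_data_worked_example(self, table1_experiment):
        stats = fk.replicate_statistics(table1_experiment.replicates[0])["OD600"]
        assert np.round(stats.mean, 2).tolist() == [0.5, 0.75, 1.03, 1.2]
        assert np.round(stats.std[:3], 2).tolist() == [0.1, 0.07, 0.15]
        assert np.isnan(stats.std[3])  # one observation left at t=6
        assert stats.n_obs.tolist() == [3, 2, 3, 1]

    def test_matches_brute_force_oracle(self, clean_synthetic):
        e, _ = clean_synthetic
        rep = e.replicates[0]
        stats = fk.replicate_statistics(rep)["OD600"]
        raw = np.array([s.courses["OD600"].values for s in rep.singles])
        assert np.allclose(stats.mean, raw.mean(axis=0))
        assert np.allclose(stats.std, raw.std(axis=0, ddof=1))

    def test_identical_replicates_zero_std(self, table1_experiment):
        rep = copy.deepcopy(table1_experiment.replicates[0])
        first = rep.singles[0].courses["OD600"].values
        for s in rep.singles:
            s.courses["OD600"].values = first.copy()
        stats = fk.replicate_statistics(rep)["OD600"]
        assert np.allclose(stats.std, 0.0)

    def test_single_replicate_mean_defined_std_not(self, table1_experiment):
        rep = copy.deepcopy(table1_experiment.replicates[0])
        rep.singles = rep.singles[:1]
        stats = fk.replicate_statistics(rep)["OD600"]
        assert np.array_equal(stats.mean, rep.singles[0].courses["OD600"].values,
                              equal_nan=True)
        assert np.all(np.isnan(stats.std))


def _scaled_replicates(base_rep, scales):
    rep = fk.ReplicateTrial(identifier=base_rep.identifier)
    template = base_rep.singles[0]
    for i, scale in enumerate(scales, 1):
        s = copy.deepcopy(template)
        s.identifier = replace(s.identifier, replicate_index=i)
        for c in s.courses.values():
            c.identifier = replace(c.identifier, replicate_index=i)
            c.values = c.values * scale
    # reattach in given order
        rep.singles.append(s)
    return rep


class TestOutliers:
    def test_scaled_replicate_flagged(self, table1_experiment):
        rep = _scaled_replicates(table1_experiment.replicates[0], [1.0, 1.0, 5.0])
        assert fk.detect_outlier_replicates(rep, "OD600", tau=0.5) == {3}

    def test_identical_replicates_unflagged(self, table1_experiment):
        rep = _scaled_replicates(table1_experiment.replicates[0], [1.0, 1.0, 1.0])
        assert fk.detect_outlier_replicates(rep, "OD600", tau=0.5) == set()

    def test_two_replicates_guard(self, table1_experiment):
        rep = _scaled_replicates(table1_experiment.replicates[0], [1.0, 5.0])
        assert fk.detect_outlier_replicates(rep, "OD600", tau=0.5) == set()

    def test_never_flags_more_than_n_minus_2(self, table1_experiment):
        rep = _scaled_replicates(table1_experiment.replicates[0], [1.0, 4.0, 9.0])
        flagged = fk.detect_outlier_replicates(rep, "OD600", tau=0.01)
        assert len(flagged) <= 1

    def test_permutation_invariant(self, table1_experiment):
        rep = _scaled_replicates(table1_experiment.replicates[0], [1.0, 1.0, 5.0])
        shuffled = fk.ReplicateTrial(identifier=rep.identifier,
                                     singles=[rep.singles[2], rep.singles[0], rep.singles[1]])
        assert (fk.detect_outlier_replicates(shuffled, "OD600", tau=0.5)
                == fk.detect_outlier_replicates(rep, "OD600", tau=0.5))

    def test_unknown_analyte_errors(self, table1_experiment):
        with pytest.raises(FeatureError, match="acetate"):
            fk.detect_outlier_replicates(table1_experiment.replicates[0], "acetate")


def _blank_experiment(trial_level=0.55, blank_level=0.05, blank_times=None, media="M9"):
    pts = []
    blank_times = blank_times or [0.0, 4.0]
    for rep in (1, 2):
        for t in (0.0, 2.0, 4.0):
            pts.append(fk.TimePoint(
                fk.parse_identifier(f"strain:A|media:{media}|rep:{rep}|time:{t}|analyte:OD600"),
                trial_level, "OD"))
    for t, v in zip(blank_times, [blank_level] * len(blank_times)):
        pts.append(fk.TimePoint(
            fk.parse_identifier(f"strain:blank|media:{media}|rep:1|time:{t}|analyte:OD600"),
            v, "OD"))
    return fk.assemble_experiment(pts, "blanked")


class TestBlanks:
    def test_constant_blank_recovers_signal(self):
        e = _blank_experiment()
        blank = next(r for r in e.replicates if r.identifier.is_blank)
        trial = next(r for r in e.replicates if not r.identifier.is_blank)
        corr = fk.subtract_blank(trial, blank)
        for s in corr.singles:
            assert np.allclose(s.courses["OD600"].values, 0.50)
        assert corr.blank_corrected

    def test_interpolated_blank(self):
        pts = [fk.TimePoint(fk.parse_identifier("strain:A|media:M9|rep:1|time:2|analyte:OD600"),
                            0.55, "OD")]
        for t, v in [(0.0, 0.0), (4.0, 0.2)]:
            pts.append(fk.TimePoint(
                fk.parse_identifier(f"strain:blank|media:M9|rep:1|time:{t}|analyte:OD600"),
                v, "OD"))
        e = fk.assemble_experiment(pts, "interp")
        blank = next(r for r in e.replicates if r.identifier.is_blank)
        trial = next(r for r in e.replicates if not r.identifier.is_blank)
        corr = fk.subtract_blank(trial, blank)
        assert corr.singles[0].courses["OD600"].values[0] == pytest.approx(0.45)

    def test_missing_analyte_left_uncorrected(self, caplog):
        e = _blank_experiment()
        trial = next(r for r in e.replicates if not r.identifier.is_blank)
        blank = next(r for r in e.replicates if r.identifier.is_blank)
        for s in blank.singles:
            s.courses = {"acetate": s.courses["OD600"]}
        with caplog.at_level("WARNING"):
            corr = fk.subtract_blank(trial, blank)
        assert np.allclose(corr.singles[0].courses["OD600"].values, 0.55)
        assert any("OD600" in r.message for r in caplog.records)

    def test_subtract_then_stats_commutes_on_complete_grids(self):
        e = _blank_experiment(blank_times=[0.0, 2.0, 4.0])
        blank = next(r for r in e.replicates if r.identifier.is_blank)
        trial = next(r for r in e.replicates if not r.identifier.is_blank)
        corr_stats = fk.replicate_statistics(fk.subtract_blank(trial, blank))["OD600"]
        raw_stats = fk.replicate_statistics(trial)["OD600"]
        blank_mean = fk.replicate_statistics(blank)["OD600"].mean
        assert np.allclose(corr_stats.mean, raw_stats.mean - blank_mean)

    def test_assign_blanks_by_media(self):
        pts = []
        for media in ("M9", "LB"):
            e = _blank_experiment(media=media)
        # build a combined 2-media experiment
        pts = []
        for media in ("M9", "LB"):
            for rep_s in (f"strain:A|media:{media}|rep:1|time:0|analyte:OD600",
                          f"strain:blank|media:{media}|rep:1|time:0|analyte:OD600"):
                pts.append(fk.TimePoint(fk.parse_identifier(rep_s), 0.5, "OD"))
        e = fk.assemble_experiment(pts, "two-media")
        mapping = fk.assign_blanks(e)
        assert len(mapping) == 2
        for key, blank_key in mapping.items():
            assert fk.parse_identifier(key).media == fk.parse_identifier(blank_key).media

    def test_no_blanks_empty_map(self, table1_experiment, caplog):
        with caplog.at_level("WARNING"):
            assert fk.assign_blanks(table1_experiment) == {}

    def test_tie_broken_lexicographically(self, caplog):
        pts = []
        for s in ("strain:A|media:M9|rep:1|time:0|analyte:OD600",
                  "strain:blank|media:M9|experiment:b1|rep:1|time:0|analyte:OD600",
                  "strain:blank|media:M9|experiment:a2|rep:1|time:0|analyte:OD600"):
            pts.append(fk.TimePoint(fk.parse_identifier(s), 0.5, "OD"))
        e = fk.assemble_experiment(pts, "tie")
        with caplog.at_level("WARNING"):
            mapping = fk.assign_blanks(e)
        (blank_key,) = set(mapping.values())
        assert "a2" in blank_key


class TestStages:
    def test_half_open_boundary_membership(self, trial_id):
        pts = [fk.TimePoint(
            fk.parse_identifier(f"strain:A|media:M9|rep:1|time:{t}|analyte:glucose"), v, "g/L")
            for t, v in [(0, 10), (2, 8), (4, 6), (6, 4), (8, 2)]]
        e = fk.assemble_experiment(pts, "staged")
        s1, s2 = fk.slice_stages(e, [0, 4, 8])
        assert s1.replicates[0].singles[0].courses["glucose"].times.tolist() == [0, 2]
        assert s2.replicates[0].singles[0].courses["glucose"].times.tolist() == [4, 6, 8]

    def test_two_phase_yield(self):
        # no production before t=8; Y_PS = 0.5 afterwards
        times = [0, 2, 4, 6, 8, 10, 12]
        S = [10, 10, 10, 10, 10, 8, 6]
        P = [0, 0, 0, 0, 0, 1, 2]
        pts = []
        for t, s, p in zip(times, S, P):
            for analyte, v in (("glucose", s), ("product", p)):
                pts.append(fk.TimePoint(fk.parse_identifier(
                    f"strain:A|media:M9|rep:1|time:{t}|analyte:{analyte}"), float(v), "g/L"))
        e = fk.assemble_experiment(pts, "phased")
        stage1, stage2 = fk.slice_stages(e, [0, 8, 12])
        s2 = stage2.replicates[0].singles[0]
        assert fk.compute_yield(s2.courses["product"], s2.courses["glucose"]).endpoint_yield \
            == pytest.approx(0.5)
        s1 = stage1.replicates[0].singles[0]
        with pytest.raises(FeatureError, match="no substrate consumed"):
            fk.compute_yield(s1.courses["product"], s1.courses["glucose"])

    def test_empty_stage_warns(self, table1_experiment, caplog):
        with caplog.at_level("WARNING"):
            stages = fk.slice_stages(table1_experiment, [0, 7, 100])
        assert stages[1].replicates == []

    def test_nonincreasing_boundaries_rejected(self, table1_experiment):
        with pytest.raises(FeatureError, match="increasing"):
            fk.slice_stages(table1_experiment, [0, 4, 4])


class TestRegistry:
    def test_core_features_registered(self):
        reg = fk.registered_features()
        assert reg["gradient"] == "analyte"
        assert reg["yield"] == "trial"
        assert reg["replicate_statistics"] == "replicate"
        assert reg["assign_blanks"] == "experiment"

    def test_unknown_feature_errors(self):
        with pytest.raises(FeatureError, match="unknown feature"):
            F.get_feature("nope")
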