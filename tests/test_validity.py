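import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from cagerank.ethogram import Behavior, BehaviorEvent
from cagerank.validity import (
    MEASURE_COLUMNS,
    convergent_regression,
    discriminant_model,
    ml_factor_analysis,
    pca,
    pearson_ci,
    residualize,
    response_logistic,
    select_extremes,
    standardize,
    subjects_per_variable,
    submission_response_scan,
)


class TestStandardize:
    def test_closed_form(self):
        z = standardize(pd.Series([1.0, 2.0, 3.0]))
        assert list(z) == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_error(self):
        with pytest.raises(ValueError, match="variance"):
            standardize(pd.Series([2.0, 2.0, 2.0]))

    def test_idempotent(self, rng):
        x = pd.Series(rng.normal(5, 3, size=30))
        z = standardize(x)
        assert list(standardize(z)) == pytest.approx(list(z))

    def test_missing_preserved(self):
        z = standardize(pd.Series([1.0, np.nan, 3.0, 5.0]))
        assert z.isna().tolist() == [False, True, False, False]


def _design_table(rng, n_cages=100, effect=0.0, noise=1.0):
    rows = []
    for c in range(n_cages):
        strain = "SJL" if c % 2 else "albinoB6"
        gs = 3 if c % 4 < 2 else 5
        shift = effect if strain == "SJL" else 0.0
        for m in range(2):
            rows.append(
                {
                    "cage_id": f"c{c}",
                    "strain": strain,
                    "group_size": gs,
                    "y": shift + rng.normal(0, noise),
                }
            )
    return pd.DataFrame(rows)


class TestResidualize:
    def test_strain_effect_removed(self, rng):
        df = _design_table(rng, n_cages=100, effect=2.0)
        out = residualize(df, ["y"])
        strain_ind = (df["strain"] == "SJL").astype(float)
        r = np.corrcoef(out["y"], strain_ind)[0, 1]
        assert abs(r) < 0.05

    def test_no_effect_residuals_near_centered(self, rng):
        df = _design_table(rng, n_cages=60, effect=0.0)
        out = residualize(df, ["y"])
        centered = df["y"] - df["y"].mean()
        r = np.corrcoef(out["y"], centered)[0, 1]
        assert r > 0.9

    def test_residual_mean_near_zero(self, rng):
        df = _design_table(rng, n_cages=40, effect=1.0)
        out = residualize(df, ["y"])
        assert abs(out["y"].mean()) < 0.05

    def test_fixed_mode(self, rng):
        df = _design_table(rng, n_cages=30, effect=1.0)
        out = residualize(df, ["y"], mode="fixed")
        # fixed-cage residuals are exactly within-cage deviations
        within = df["y"] - df.groupby("cage_id")["y"].transform("mean")
        scale = standardize(df["y"]).std() / df["y"].std()
        assert np.allclose(out["y"], within * scale, atol=1e-10)


class TestSelectExtremes:
    def test_one_dominant_one_subordinate_per_cage(self):
        df = pd.DataFrame(
            {
                "cage_id": ["c1"] * 3 + ["c2"] * 3,
                "mouse": list("ABCDEF"),
                "glicko_sub_net": [5.0, -3.0, 1.0, 0.0, 10.0, -10.0],
            }
        )
        sel = select_extremes(df)
        assert len(sel) == 4
        doms = sel[sel["role"] == "dominant"]["mouse"].tolist()
        subs = sel[sel["role"] == "subordinate"]["mouse"].tolist()
        assert doms == ["A", "E"]
        assert subs == ["B", "F"]


class TestSubjectsPerVariable:
    def test_ratio(self):
        df = pd.DataFrame(np.ones((36, 6)), columns=MEASURE_COLUMNS)
        assert subjects_per_variable(df, MEASURE_COLUMNS) == 6.0

    def test_missing_rows_excluded(self):
        df = pd.DataFrame(np.ones((40, 6)), columns=MEASURE_COLUMNS)
        df.loc[:3, "darcin"] = np.nan
        assert subjects_per_variable(df, MEASURE_COLUMNS) == 6.0


class TestPCA:
    def test_two_perfectly_correlated(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        res = pca(df)
        assert res.eigenvalues[0] == pytest.approx(2.0)
        assert res.eigenvalues[1] == pytest.approx(0.0, abs=1e-10)
        assert res.n_retained == 1

    def test_trace_conservation(self, rng):
        df = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        res = pca(df)
        assert res.eigenvalues.sum() == pytest.approx(4.0)

    def test_independent_normals_eigenvalues_near_one(self, rng):
        df = pd.DataFrame(rng.normal(size=(5000, 3)), columns=list("abc"))
        res = pca(df)
        assert np.all(np.abs(res.eigenvalues - 1.0) < 0.1)

    def test_constant_column_error(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10)})
        with pytest.raises(ValueError, match="constant"):
            pca(df)

    def test_fewer_rows_than_vars_warns(self, rng):
        df = pd.DataFrame(rng.normal(size=(3, 4)), columns=list("abcd"))
        with pytest.warns(UserWarning, match="rank"):
            pca(df)

    def test_scores_unit_variance(self, rng):
        df = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        res = pca(df)
        assert res.scores.std(ddof=1).iloc[0] == pytest.approx(1.0, abs=1e-6)


def two_block_table(rng, n=36, cross=0.0, noise=0.6):
    """Block 1: three tube rounds; block 2: darcin + preputial; PALS weakly
    with block 1.  ``cross`` couples the two latents."""
    l1 = rng.normal(size=n)
    l2 = cross * l1 + np.sqrt(1 - cross**2) * rng.normal(size=n)
    return pd.DataFrame(
        {
            "darcin": l2 + noise * rng.normal(size=n),
            "preputial_ratio": l2 + noise * rng.normal(size=n),
            "posterior_pals": 0.4 * l1 + rng.normal(size=n),
            "tube_r1": l1 + noise * rng.normal(size=n),
            "tube_r2": l1 + noise * rng.normal(size=n),
            "tube_r3": l1 + noise * rng.normal(size=n),
        }
    )


def blocks_separated(fa):
    L = fa.loadings.abs()
    thr = fa.loading_threshold
    if fa.n_factors < 2:
        return False
    f_dar = L.loc["darcin"].idxmax()
    others = [f for f in L.columns if f != f_dar]
    f_tube = others[0]
    ok_b2 = (L.loc[["darcin", "preputial_ratio"], f_dar] >= thr).all() and (
        L.loc[["darcin", "preputial_ratio"], f_tube] < thr
    ).all()
    tubes = ["tube_r1", "tube_r2", "tube_r3"]
    ok_b1 = (L.loc[tubes, f_tube] >= thr).all() and (L.loc[tubes, f_dar] < thr).all()
    return bool(ok_b1 and ok_b2)


class TestFactorAnalysis:
    def test_two_block_recovery_at_n36(self, rng):
        df = two_block_table(rng)
        fa = ml_factor_analysis(df)
        assert fa.n_factors == 2
        assert blocks_separated(fa)

    def test_varimax_preserves_communalities(self, rng):
        df = two_block_table(rng, n=200, noise=0.8)
        fa = ml_factor_analysis(df, n_factors=2)
        # compare against the unrotated ML fit
        from statsmodels.multivariate.factor import Factor

        Z = (df - df.mean()) / df.std(ddof=1)
        res = Factor(Z.to_numpy(), n_factor=2, method="ml").fit()
        unrot = np.asarray(res.loadings)[:, :2]
        h2_unrot = (unrot**2).sum(axis=1)
        h2_rot = (fa.loadings.to_numpy() ** 2).sum(axis=1)
        assert h2_rot == pytest.approx(h2_unrot, abs=1e-6)

    def test_single_factor_data_retains_one(self, rng):
        n = 200
        l1 = rng.normal(size=n)
        df = pd.DataFrame(
            {f"v{i}": l1 + 0.5 * rng.normal(size=n) for i in range(5)}
        )
        fa = ml_factor_analysis(df)
        assert fa.n_factors == 1

    def test_low_spv_warns(self, rng):
        df = two_block_table(rng, n=20)
        with pytest.warns(UserWarning, match="subjects-per-variable"):
            ml_factor_analysis(df)

    def test_membership_threshold(self, rng):
        df = two_block_table(rng)
        fa = ml_factor_analysis(df)
        for f, members in fa.membership.items():
            for v in members:
                assert abs(fa.loadings.loc[v, f]) >= 0.45


class TestConvergentRegression:
    def test_perfect_linear(self, rng):
        scores = pd.DataFrame(
            rng.normal(size=(30, 2)), columns=["factor1", "factor2"]
        )
        y = 2.0 * scores["factor2"] - 1.0 * scores["factor1"]
        res = convergent_regression(y, scores)
        assert res.attrs["r_squared"] == pytest.approx(1.0)

    def test_signal_detected_with_calibrated_power(self, rng):
        # beta sized for ~0.98 analytic power at n=36, alpha=0.05, which
        # leaves headroom for the t-test's heavier tails at this n
        n = 36
        beta = (stats.norm.ppf(0.975) + stats.norm.ppf(0.98)) / np.sqrt(n)
        hits = 0
        reps = 200
        for _ in range(reps):
            scores = pd.DataFrame(
                rng.normal(size=(n, 2)), columns=["factor1", "factor2"]
            )
            y = beta * scores["factor2"] + rng.normal(size=n)
            res = convergent_regression(pd.Series(y), scores)
            hits += res.loc["factor2", "p"] < 0.05
        assert hits / reps >= 0.90

    def test_type_i_error_calibrated(self, rng):
        n = 36
        reps = 500
        hits = 0
        for _ in range(reps):
            scores = pd.DataFrame(
                rng.normal(size=(n, 2)), columns=["factor1", "factor2"]
            )
            y = pd.Series(rng.normal(size=n))
            res = convergent_regression(y, scores)
            hits += res.loc["factor2", "p"] < 0.05
        rate = hits / reps
        mc_se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) <= 2.5 * mc_se

    def test_rank_deficiency_error(self, rng):
        scores = pd.DataFrame({"factor1": rng.normal(size=20)})
        scores["factor2"] = scores["factor1"]
        with pytest.raises(ValueError, match="rank"):
            convergent_regression(pd.Series(rng.normal(size=20)), scores)


def _disc_table(rng, n_cages=19, beta_distance=0.0):
    rows = []
    for c in range(n_cages):
        strain = "SJL" if c % 2 else "albinoB6"
        gs = 3 if c % 4 < 2 else 5
        for role in ("dom", "sub"):
            dist = rng.normal(2500, 400)
            rows.append(
                {
                    "cage_id": f"c{c}",
                    "strain": strain,
                    "group_size": gs,
                    "ofm_boli": rng.poisson(3),
                    "ofm_center_pct": rng.uniform(5, 25),
                    "ofm_distance_cm": dist,
                    "tube_pc": beta_distance * (dist - 2500) / 400
                    + rng.normal(),
                }
            )
    return pd.DataFrame(rows)


class TestDiscriminantModel:
    def test_null_rejection_rate_near_alpha(self, rng):
        reps = 150
        rejections = {t: 0 for t in ("ofm_boli", "ofm_center_pct", "ofm_distance_cm")}
        for _ in range(reps):
            res = discriminant_model(_disc_table(rng))
            for t in rejections:
                rejections[t] += res.loc[t, "p"] < 0.05
        for t, k in rejections.items():
            mc_se = np.sqrt(0.05 * 0.95 / reps)
            assert abs(k / reps - 0.05) <= 3 * mc_se, (t, k / reps)

    def test_coupled_distance_detected(self, rng):
        hits = 0
        reps = 50
        for _ in range(reps):
            res = discriminant_model(_disc_table(rng, beta_distance=1.0))
            hits += res.loc["ofm_distance_cm", "p"] < 0.05
        assert hits / reps >= 0.9

    def test_translation_invariance(self, rng):
        df = _disc_table(rng)
        res1 = discriminant_model(df)
        df2 = df.copy()
        df2["tube_pc"] = df2["tube_pc"] + 100.0
        res2 = discriminant_model(df2)
        assert np.allclose(res1["coef"], res2["coef"], atol=1e-6)


class TestPearsonCI:
    def test_identity(self, rng):
        x = rng.normal(size=20)
        assert pearson_ci(x, x)["r"] == pytest.approx(1.0)

    def test_negation(self, rng):
        x = rng.normal(size=20)
        assert pearson_ci(x, -x)["r"] == pytest.approx(-1.0)

    def test_ci_coverage(self, rng):
        rho = 0.79
        n = 96
        cover = 0
        reps = 1000
        for _ in range(reps):
            x = rng.normal(size=n)
            y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n)
            lo, hi = pearson_ci(x, y)["ci"]
            cover += lo <= rho <= hi
        assert abs(cover / reps - 0.95) < 0.02

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            pearson_ci([1, 1, 1, 1], [1, 2, 3, 4])

    def test_small_n_error(self):
        with pytest.raises(ValueError):
            pearson_ci([1, 2], [3, 4])


def inv(a, r, t, day=2):
    return BehaviorEvent(day, t, a, r, Behavior.INVESTIGATION)


def sub(a, r, t, day=2):
    return BehaviorEvent(day, t, a, r, Behavior.SUBMISSION)


class TestResponseScan:
    def test_within_window(self):
        [o] = submission_response_scan([inv("A", "B", 10.0), sub("B", "A", 13.0)])
        assert o.responded == 1

    def test_outside_window(self):
        [o] = submission_response_scan([inv("A", "B", 10.0), sub("B", "A", 16.0)])
        assert o.responded == 0

    def test_third_mouse_does_not_count(self):
        [o] = submission_response_scan([inv("A", "B", 10.0), sub("C", "A", 12.0)])
        assert o.responded == 0

    def test_boundary_inclusive(self):
        [o] = submission_response_scan([inv("A", "B", 10.0), sub("B", "A", 15.0)])
        assert o.responded == 1

    def test_cross_day_not_counted(self):
        [o] = submission_response_scan(
            [inv("A", "B", 86398.0, day=2), sub("B", "A", 1.0, day=7)]
        )
        assert o.responded == 0

    def test_count_equals_investigations(self, rng):
        events = []
        t = 0.0
        for _ in range(50):
            kind = rng.integers(3)
            a, b = ("A", "B") if rng.random() < 0.5 else ("B", "A")
            if kind == 0:
                events.append(inv(a, b, t))
            elif kind == 1:
                events.append(sub(a, b, t))
            else:
                events.append(BehaviorEvent(2, t, a, b, Behavior.ALLOGROOM))
            t += rng.uniform(0, 10)
        n_inv = sum(e.category is Behavior.INVESTIGATION for e in events)
        assert len(submission_response_scan(events)) == n_inv


class TestResponseLogistic:
    def _outcomes(self, rng, probs, n_per_cell=120):
        rows = []
        for (strain, day), p in probs.items():
            rows.append(
                pd.DataFrame(
                    {
                        "strain": strain,
                        "day": day,
                        "responded": rng.binomial(1, p, size=n_per_cell),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def test_threshold_is_0083(self, rng):
        df = self._outcomes(
            rng, {("A", 2): 0.3, ("A", 7): 0.3, ("B", 2): 0.3, ("B", 7): 0.3}
        )
        res = response_logistic(df)
        assert res["threshold"] == 0.0083

    def test_elevated_cell_detected(self, rng):
        probs = {("SJL", 2): 0.6, ("SJL", 7): 0.2, ("B6", 2): 0.2, ("B6", 7): 0.2}
        df = self._outcomes(rng, probs, n_per_cell=250)
        res = response_logistic(df)
        c = res["contrasts"]
        involving = c[
            (c["cell_a"] == "SJL:day2") | (c["cell_b"] == "SJL:day2")
        ]
        assert involving["significant"].all()
        others = c[
            (c["cell_a"] != "SJL:day2") & (c["cell_b"] != "SJL:day2")
        ]
        assert not others["significant"].any()

    def test_six_contrasts(self, rng):
        df = self._outcomes(
            rng, {("A", 2): 0.3, ("A", 7): 0.3, ("B", 2): 0.3, ("B", 7): 0.3}
        )
        assert len(response_logistic(df)["contrasts"]) == 6

    def test_separation_fallback_warns(self, rng):
        probs = {("A", 2): 0.0, ("A", 7): 0.3, ("B", 2): 0.3, ("B", 7): 0.3}
        df = self._outcomes(rng, probs, n_per_cell=30)
        with pytest.warns(UserWarning, match="separation"):
            res = response_logistic(df)
        assert np.isfinite(res["contrasts"]["z"]).all()

    def test_needs_two_levels(self, rng):
        df = self._outcomes(rng, {("A", 2): 0.3, ("A", 7): 0.3})
        with pytest.raises(ValueError):
            response_logistic(df)
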