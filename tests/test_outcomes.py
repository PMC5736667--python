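import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter

import methylsub as ms


def _competing(rng, n, h1, h2, hc=0.08):
    t1 = rng.exponential(1 / h1, n) if h1 > 0 else np.full(n, np.inf)
    t2 = rng.exponential(1 / h2, n) if h2 > 0 else np.full(n, np.inf)
    tc = rng.exponential(1 / hc, n) if hc > 0 else np.full(n, np.inf)
    T = np.minimum.reduce([t1, t2, tc])
    E = np.select([tc <= np.minimum(t1, t2), t1 <= t2], [0, 1], 2)
    return pd.DataFrame({"time": T, "event": E})


class TestKaplanMeier:
    def test_hand_product_limit(self):
        toy = pd.DataFrame({"time": [1, 2, 3, 4, 5], "event": [1, 1, 0, 1, 0]})
        km = ms.kaplan_meier(toy)
        assert km.survival_at(4.0) == pytest.approx(0.3)
        assert km.survival_at(0.5) == 1.0

    def test_no_events_flat_one(self):
        toy = pd.DataFrame({"time": [1, 2, 3], "event": [0, 0, 0]})
        km = ms.kaplan_meier(toy)
        assert km.survival_at(10.0) == 1.0

    def test_matches_lifelines_oracle(self, rng):
        df = _competing(rng, 80, 0.2, 0.0)
        df["event"] = (df["event"] != 0).astype(int)
        km = ms.kaplan_meier(df)
        kmf = KaplanMeierFitter().fit(df["time"], df["event"])
        for t in (0.5, 1.0, 3.0, 7.0):
            assert km.survival_at(t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-10
            )

    def test_ci_brackets_estimate(self, rng):
        df = _competing(rng, 60, 0.15, 0.0)
        df["event"] = (df["event"] != 0).astype(int)
        km = ms.kaplan_meier(df)
        lo, hi = km.ci_at(3.0)
        assert lo <= km.survival_at(3.0) <= hi

    def test_negative_times_rejected(self):
        with pytest.raises(ms.ValidationError):
            ms.kaplan_meier(pd.DataFrame({"time": [-1.0], "event": [1]}))


class TestLogrank:
    def test_duplicated_groups_null(self, rng):
        df = _competing(rng, 40, 0.2, 0.0)
        chi2, dof, p = ms.logrank_test({"a": df, "b": df.copy()})
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_power_under_hazard_ratio_three(self):
        rng = np.random.default_rng(0)
        rejections = 0
        n_sim = 100
        for _ in range(n_sim):
            a = _competing(rng, 200, 0.05, 0.0)
            b = _competing(rng, 200, 0.15, 0.0)
            _, _, p = ms.logrank_test({"a": a, "b": b})
            rejections += p < 0.05
        assert rejections / n_sim >= 0.8

    def test_null_calibration(self):
        rng = np.random.default_rng(1)
        rej = 0
        n_sim = 400
        for _ in range(n_sim):
            a = _competing(rng, 60, 0.1, 0.0)
            b = _competing(rng, 60, 0.1, 0.0)
            _, _, p = ms.logrank_test({"a": a, "b": b})
            rej += p < 0.05
        from scipy.stats import binom

        lo, hi = binom.interval(0.99, n_sim, 0.05)
        assert lo <= rej <= hi

    def test_no_events_warns_p_one(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0]})
        with pytest.warns(UserWarning):
            _, _, p = ms.logrank_test({"a": df, "b": df.copy()})
        assert p == 1.0


class TestCumulativeIncidence:
    def test_single_cause_equals_one_minus_km(self, rng):
        df = _competing(rng, 70, 0.2, 0.0)
        cif = ms.cumulative_incidence(df)
        km = ms.kaplan_meier(df)
        for t in (0.5, 2.0, 5.0):
            assert float(cif[1](t)) == pytest.approx(1 - km.survival_at(t), abs=1e-12)

    def test_additivity_identity(self, rng):
        for _ in range(5):
            df = _competing(rng, 120, 0.15, 0.07)
            cif = ms.cumulative_incidence(df)
            ts = np.unique(df.loc[df["event"] != 0, "time"])
            total = cif[1](ts) + cif[2](ts) + cif["km"](ts)
            assert np.abs(total - 1).max() < 1e-9

    def test_closed_form_large_sample(self):
        rng = np.random.default_rng(3)
        h1, h2 = 0.15, 0.05
        df = _competing(rng, 2000, h1, h2, hc=0.0)
        cif = ms.cumulative_incidence(df, cause=1)
        closed = h1 / (h1 + h2) * (1 - np.exp(-(h1 + h2) * 5))
        assert float(cif(5.0)) == pytest.approx(closed, abs=0.05)

    def test_cif_monotone_bounded(self, rng):
        df = _competing(rng, 90, 0.12, 0.06)
        cif = ms.cumulative_incidence(df)
        for c in (1, 2):
            v = cif[c].values
            assert (np.diff(v) >= -1e-12).all()
            assert v.max() <= 1.0 + 1e-12


class TestGraysTest:
    def test_identical_groups_null(self, rng):
        df = _competing(rng, 60, 0.15, 0.07)
        chi2, dof, p = ms.grays_test({"a": df, "b": df.copy()}, cause=1)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_reduces_to_logrank_without_competing_events(self, rng):
        a = _competing(rng, 100, 0.15, 0.0)
        b = _competing(rng, 100, 0.08, 0.0)
        g_chi2, _, _ = ms.grays_test({"a": a, "b": b}, cause=1)
        l_chi2, _, _ = ms.logrank_test({"a": a, "b": b})
        assert g_chi2 == pytest.approx(l_chi2, rel=1e-6)

    def test_detects_planted_subdistribution_difference(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(20):
            a = _competing(rng, 100, 0.04, 0.06)
            b = _competing(rng, 100, 0.16, 0.06)
            _, _, p = ms.grays_test({"a": a, "b": b}, cause=1)
            hits += p < 0.05
        assert hits >= 16  # power >= 0.8

    def test_three_groups_df(self, rng):
        dfs = {g: _competing(rng, 50, 0.1, 0.05) for g in "abc"}
        chi2, dof, p = ms.grays_test(dfs, cause=1)
        assert dof == 2
        assert 0 <= p <= 1

    def test_empty_group_rejected(self, rng):
        df = _competing(rng, 20, 0.1, 0.05)
        empty = df.iloc[:0]
        with pytest.raises(ms.ValidationError):
            ms.grays_test({"a": df, "b": empty})


class TestCauseSpecificCox:
    def test_grid_search_oracle_six_subjects(self):
        toy = pd.DataFrame(
            {
                "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "event": [1, 1, 0, 1, 1, 0],
                "x": [1, 0, 1, 1, 0, 0],
            }
        )
        res = ms.cause_specific_cox(toy, ["x"], cause=1)
        # brute force: maximize the partial likelihood on a grid
        def logpl(beta):
            total = 0.0
            for _, row in toy[toy["event"] == 1].iterrows():
                risk = toy[toy["time"] >= row["time"]]
                total += beta * row["x"] - np.log(
                    np.exp(beta * risk["x"]).sum()
                )
            return total

        grid = np.linspace(-3, 3, 6001)
        best = grid[np.argmax([logpl(b) for b in grid])]
        assert res.loc["x", "coef"] == pytest.approx(best, abs=2e-3)

    def test_independent_covariate_ci_coverage(self):
        rng = np.random.default_rng(6)
        covered = 0
        n_sim = 100
        for _ in range(n_sim):
            df = _competing(rng, 80, 0.15, 0.05)
            df["x"] = rng.integers(0, 2, len(df))
            res = ms.cause_specific_cox(df, ["x"], cause=1)
            covered += res.loc["x", "ci_lower"] <= 1 <= res.loc["x", "ci_upper"]
        assert covered / n_sim >= 0.87

    def test_recovers_planted_relative_risk(self):
        rng = np.random.default_rng(7)
        n = 500
        x = rng.integers(0, 2, n)
        h1 = 0.05 * np.exp(np.log(3) * x)
        t1 = rng.exponential(1 / h1)
        t2 = rng.exponential(1 / 0.04, n)
        tc = rng.exponential(1 / 0.05, n)
        T = np.minimum.reduce([t1, t2, tc])
        E = np.select([tc <= np.minimum(t1, t2), t1 <= t2], [0, 1], 2)
        df = pd.DataFrame({"time": T, "event": E, "x": x})
        res = ms.cause_specific_cox(df, ["x"], cause=1)
        assert res.loc["x", "rr"] == pytest.approx(3.0, rel=0.2)

    def test_too_few_events_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "x": [0, 1]})
        with pytest.raises(ms.ValidationError):
            ms.cause_specific_cox(df, ["x"], cause=1)


class TestRankAndContingency:
    def test_exact_enumeration_extreme(self):
        stat, p = ms.ranksum_test([1, 2, 3], [4, 5, 6])
        # 1/20 one-tailed, doubled
        assert p == pytest.approx(0.1)

    def test_identical_samples_exact_p_one(self):
        _, p = ms.ranksum_test([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert p == 1.0

    def test_all_tied_warns(self):
        with pytest.warns(UserWarning):
            _, p = ms.ranksum_test([2, 2, 2], [2, 2])
        assert p == 1.0

    def test_normal_approximation_close_to_exact(self, rng):
        from scipy.stats import mannwhitneyu

        for _ in range(10):
            x, y = rng.random(8), rng.random(8)
            _, p_pkg = ms.ranksum_test(x, y)  # exact path
            p_approx = mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic",
                use_continuity=True,
            ).pvalue
            assert abs(p_pkg - p_approx) <= 0.02

    def test_balanced_2x2_p_one(self):
        assert ms.contingency_test([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_perfect_association_hypergeometric(self):
        import math

        p = ms.contingency_test([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_chi_square_matches_textbook_formula(self):
        table = np.array([[10, 20], [15, 5], [5, 15]])
        p_pkg = ms.contingency_test(table)
        total = table.sum()
        expected = np.outer(table.sum(1), table.sum(0)) / total
        chi2 = ((table - expected) ** 2 / expected).sum()
        from scipy.stats import chi2 as chi2_dist

        assert p_pkg == pytest.approx(chi2_dist.sf(chi2, 2), rel=1e-9)

    def test_empty_margin_rejected(self):
        with pytest.raises(ms.ValidationError):
            ms.contingency_test([[0, 0], [1, 2]])


class TestAlterationBurden:
    def _mut(self):
        df = pd.DataFrame(
            [
                ("p1", "PTPN11", "snv"),
                ("p1", "NRAS", "snv"),
                ("p1", "EZH2", "loss"),
                ("p2", "KRAS", "snv"),
                ("p3", "SETBP1", "none"),
            ],
            columns=["patient", "gene", "alteration"],
        )
        pm = {"PTPN11": "RAS", "NRAS": "RAS", "EZH2": "PRC2",
              "KRAS": "RAS", "SETBP1": "other"}
        return ms.MutationMatrix(df, pm)

    def test_counts_and_multihit(self):
        groups = pd.Series({"p1": "HM", "p2": "LM", "p3": "LM"})
        res = ms.alteration_burden(self._mut(), groups)
        assert res["per_patient"].to_dict() == {"p1": 3, "p2": 1, "p3": 0}
        assert res["per_group_total"].to_dict() == {"HM": 3, "LM": 1}
        # p1 has 2 RAS-pathway events -> multi-hit
        assert res["multihit_fraction"]["HM"] == 1.0
        assert res["multihit_fraction"]["LM"] == 0.0

    def test_empty_matrix_all_zero(self):
        mut = ms.MutationMatrix(
            pd.DataFrame(columns=["patient", "gene", "alteration"]), {}
        )
        groups = pd.Series({"p1": "HM", "p2": "LM"})
        res = ms.alteration_burden(mut, groups)
        assert (res["per_patient"] == 0).all()

    def test_unmapped_patient_rejected(self):
        groups = pd.Series({"p1": "HM"})
        with pytest.raises(ms.ValidationError):
            ms.alteration_burden(self._mut(), groups)

    def test_totals_match_brute_force(self, rng):
        patients = [f"p{i}" for i in range(12)]
        genes = [f"G{j}" for j in range(6)]
        rows = []
        for _ in range(40):
            rows.append(
                (rng.choice(patients), rng.choice(genes),
                 rng.choice(["snv", "indel", "gain"]))
            )
        df = pd.DataFrame(rows, columns=["patient", "gene", "alteration"])
        pm = {g: "RAS" for g in genes}
        groups = pd.Series(
            {p: ("HM" if i % 2 else "LM") for i, p in enumerate(patients)}
        )
        res = ms.alteration_burden(ms.MutationMatrix(df, pm), groups)
        for p in patients:
            assert res["per_patient"][p] == (df["patient"] == p).sum()
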