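"""Statistics engine: oracles, printed-value checks, properties.

Independent oracles used here: scipy.stats.levene / f_oneway / ttest_ind,
a dense Simpson grid for the Bayes-factor integral, explicit loop-based
sums-of-squares for the split-plot ANOVA, pingouin.mixed_anova, and a
vectorized Monte-Carlo ANOVA for the power solver.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from thetaband import inferstats as ist

R = ist.DEFAULT_RSCALE


# --------------------------------------------------------------------------
# Levene


class TestLevene:
    def test_identical_deviation_multisets_give_zero(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = x + 10.0                      # same |deviations| about the mean
        stat, p = ist.levene_test([x, y])
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_detects_sd_ratio_4(self):
        rng = np.random.default_rng(15)
        x = rng.normal(0, 1.0, 33)
        y = rng.normal(0, 4.0, 33)
        _, p = ist.levene_test([x, y])
        assert p < 0.05

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(0, s, n) for s, n in ((1, 12), (2.5, 9), (0.5, 15))]
        stat, p = ist.levene_test(groups)
        o_stat, o_p = stats.levene(*groups, center="mean")
        assert stat == pytest.approx(o_stat, abs=1e-10)
        assert p == pytest.approx(o_p, abs=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            ist.levene_test([np.array([1.0]), np.array([1.0, 2.0])])


# --------------------------------------------------------------------------
# Welch df / Cohen's d


class TestWelchDf:
    def test_symmetric_limit(self):
        assert ist.welch_satterthwaite_df(2.0, 2.0, 20, 20) == pytest.approx(38.0)

    @pytest.mark.parametrize(
        "s1,s2,n1,n2,expected",
        [(1.77, 3.92, 33, 33, 44.58), (3.92, 0.33, 33, 33, 32.46)],
    )
    def test_published_fractional_dfs(self, s1, s2, n1, n2, expected):
        # printed SDs are rounded to 2 dp, hence the 0.15 tolerance
        assert ist.welch_satterthwaite_df(s1, s2, n1, n2) == pytest.approx(
            expected, abs=0.15
        )

    def test_zero_variances_rejected(self):
        with pytest.raises(ValueError):
            ist.welch_satterthwaite_df(0.0, 0.0, 5, 5)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    s1=st.floats(0.01, 10), s2=st.floats(0.01, 10),
    n1=st.integers(3, 100), n2=st.integers(3, 100),
)
def test_welch_df_never_exceeds_pooled(s1, s2, n1, n2):
    assert ist.welch_satterthwaite_df(s1, s2, n1, n2) <= n1 + n2 - 2 + 1e-9


class TestCohensD:
    @pytest.mark.parametrize(
        "t,expected", [(3.69, 0.91), (3.63, 0.89), (2.61, 0.64), (0.0, 0.0)]
    )
    def test_printed_pairs_33_per_group(self, t, expected):
        assert ist.cohens_d_from_t(t, 33, 33) == pytest.approx(expected, abs=0.005)

    def test_sign_follows_t(self):
        assert ist.cohens_d_from_t(-2.0, 10, 12) < 0


# --------------------------------------------------------------------------
# JZS Bayes factor


def _bf10_simpson(t, n1, n2, r=R, n_grid=200_001):
    """Dense-grid Simpson oracle on the log-g axis."""
    u = np.linspace(-30.0, 30.0, n_grid)
    g = np.exp(u)
    N = n1 * n2 / (n1 + n2)
    nu = n1 + n2 - 2
    like = (1 + N * g) ** -0.5 * (1 + t**2 / (nu * (1 + N * g))) ** (
        -(nu + 1) / 2
    )
    prior = (2 * np.pi) ** -0.5 * r * g**-1.5 * np.exp(-(r**2) / (2 * g))
    num = integrate.simpson(like * prior * g, x=u)
    return num / (1 + t**2 / nu) ** (-(nu + 1) / 2)


class TestJZSBayesFactor:
    @pytest.mark.parametrize(
        "t,published",
        [(3.69, 58.48), (0.23, 0.26), (3.63, 49.43), (-0.05, 0.25)],
    )
    def test_published_values(self, t, published):
        # 2% slack: the published values came from t rounded to 2 dp
        assert ist.jzs_bf10(t, 33, 33) == pytest.approx(published, rel=0.02)

    @pytest.mark.parametrize("t", [0.0, 0.5, 2.0, 4.5])
    def test_quadrature_matches_simpson_oracle(self, t):
        got = ist.jzs_bf10(t, 20, 25)
        assert got == pytest.approx(_bf10_simpson(t, 20, 25), rel=1e-6)

    def test_strictly_increasing_in_abs_t(self):
        ts = [0.0, 0.5, 1.0, 2.0, 3.0, 5.0]
        bfs = [ist.jzs_bf10(t, 33, 33) for t in ts]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))
        assert ist.jzs_bf10(-3.0, 33, 33) == pytest.approx(
            ist.jzs_bf10(3.0, 33, 33), rel=1e-9
        )

    def test_null_t_favours_h0(self):
        assert ist.jzs_bf10(0.0, 33, 33) < 1.0

    def test_vanishing_prior_scale_gives_unit_bf(self):
        assert ist.jzs_bf10(2.0, 33, 33, ist.BFPrior(1e-4)) == pytest.approx(
            1.0, abs=1e-3
        )

    def test_nonfinite_t_rejected(self):
        with pytest.raises(ValueError):
            ist.jzs_bf10(math.nan, 33, 33)


# --------------------------------------------------------------------------
# t-tests


class TestIndependentT:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r = ist.independent_t_test(x, x.copy())
        assert r.t == 0.0 and r.d == 0.0

    def test_pooled_matches_textbook_oracle(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([2.0, 4.0, 6.0])
        r = ist.independent_t_test(x, y)
        assert r.variant == "pooled"
        sp2 = (x.var(ddof=1) * 2 + y.var(ddof=1) * 2) / 4
        t_hand = (x.mean() - y.mean()) / math.sqrt(sp2 * (2 / 3))
        assert r.t == pytest.approx(t_hand, abs=1e-12)
        o = stats.ttest_ind(x, y)
        assert r.t == pytest.approx(o.statistic, abs=1e-12)
        assert r.p == pytest.approx(o.pvalue, abs=1e-12)

    def test_welch_branch_from_printed_summaries(self):
        """Omission counts: PC (0.91, 1.77) vs VR (3.00, 3.92), n = 33."""
        x = ist.samples_from_summary(0.91, 1.77, 33)
        y = ist.samples_from_summary(3.00, 3.92, 33)
        r = ist.independent_t_test(x, y)
        assert r.variant == "welch"
        assert r.t == pytest.approx(-2.79, abs=0.03)
        assert r.df == pytest.approx(44.58, abs=0.15)
        o = stats.ttest_ind(x, y, equal_var=False)
        assert r.t == pytest.approx(o.statistic, abs=1e-10)

    def test_samples_from_summary_exact_moments(self):
        s = ist.samples_from_summary(2.5, 1.3, 33)
        assert s.mean() == pytest.approx(2.5, abs=1e-12)
        assert s.std(ddof=1) == pytest.approx(1.3, abs=1e-12)


# --------------------------------------------------------------------------
# one-way ANOVA from summaries


class TestSummaryAnova:
    def test_equal_means_give_zero(self):
        gs = [ist.GroupSummary(g, 10, 5.0, 1.0) for g in "abc"]
        F, *_ = ist.anova_oneway_from_summary(gs)
        assert F == pytest.approx(0.0, abs=1e-12)

    def test_printed_omission_anova(self):
        gs = [
            ist.GroupSummary("PC", 33, 0.91, 1.77),
            ist.GroupSummary("VR", 33, 3.00, 3.92),
            ist.GroupSummary("RL", 33, 0.12, 0.33),
        ]
        F, df1, df2, p = ist.anova_oneway_from_summary(gs)
        assert (df1, df2) == (2, 96)
        assert F == pytest.approx(11.76, abs=0.1)
        assert p < 0.001

    def test_matches_full_data_anova(self):
        gs = [
            ist.GroupSummary("a", 12, 1.0, 0.8),
            ist.GroupSummary("b", 12, 1.5, 1.1),
            ist.GroupSummary("c", 12, 0.7, 0.9),
        ]
        F, _, _, _ = ist.anova_oneway_from_summary(gs)
        data = [ist.samples_from_summary(g.mean, g.sd, g.n) for g in gs]
        o = stats.f_oneway(*data)
        assert F == pytest.approx(o.statistic, abs=1e-9)


# --------------------------------------------------------------------------
# power solver


class TestPower:
    def test_study_specification_returns_98(self):
        assert ist.required_sample_size_oneway(ist.PowerSpec()) == 98

    def test_minimality(self):
        spec = ist.PowerSpec()
        n = ist.required_sample_size_oneway(spec)
        assert ist.power_oneway(n, spec) >= spec.power
        assert ist.power_oneway(n - 1, spec) < spec.power

    def test_monte_carlo_oracle(self):
        """Simulate the k=3 ANOVA at N=98 with the design noncentrality and
        compare empirical power with the noncentral-F value."""
        spec = ist.PowerSpec()
        N, reps = 98, 20_000
        sizes = (32, 33, 33)
        lam = spec.f2 * N
        pattern = np.array([-1.0, 0.0, 1.0])
        w = np.repeat(pattern, sizes)
        wbar = np.average(pattern, weights=sizes)
        c = math.sqrt(lam / np.sum(np.array(sizes) * (pattern - wbar) ** 2))
        mu = c * w
        rng = np.random.default_rng(808)
        X = mu + rng.standard_normal((reps, N))
        idx = np.repeat(np.arange(3), sizes)
        gm = np.stack([X[:, idx == g].mean(axis=1) for g in range(3)], axis=1)
        grand = X.mean(axis=1)
        ssb = np.sum(np.array(sizes) * (gm - grand[:, None]) ** 2, axis=1)
        ssw = np.sum(
            [
                ((X[:, idx == g] - gm[:, [g]]) ** 2).sum(axis=1)
                for g in range(3)
            ],
            axis=0,
        )
        F = (ssb / 2) / (ssw / (N - 3))
        fcrit = stats.f.ppf(0.95, 2, N - 3)
        assert (F > fcrit).mean() == pytest.approx(
            ist.power_oneway(N, spec), abs=0.01
        )

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ist.PowerSpec(power=1.0)


# --------------------------------------------------------------------------
# split-plot ANOVA


def _balanced_table(n_per_group=4, n_groups=3, windows=3, pres=None, seed=0,
                    group_shift=0.6, window_slope=0.4, pres_shift=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for gi in range(n_groups):
        for s in range(n_per_group):
            sid = f"g{gi}s{s}"
            base = rng.normal(gi * group_shift, 1.0)
            for w in range(windows):
                for p in pres or ["first"]:
                    rows.append(
                        dict(
                            subject=sid,
                            group=f"G{gi}",
                            window=f"w{w}",
                            presentation=p,
                            amplitude=base
                            + window_slope * w
                            + (pres_shift if p == "second" else 0.0)
                            + rng.normal(0, 0.5),
                        )
                    )
    return pd.DataFrame(rows)


def _oracle_split_plot(df):
    """Loop-based sums-of-squares for 1 between + 1 within factor."""
    subjects = sorted(df.subject.unique())
    windows = sorted(df.window.unique())
    groups = sorted(df.group.unique())
    a, n_subj = len(windows), len(subjects)
    cell = {
        (s, w): df[(df.subject == s) & (df.window == w)].amplitude.mean()
        for s in subjects
        for w in windows
    }
    g_of = {s: df[df.subject == s].group.iloc[0] for s in subjects}
    grand = np.mean(list(cell.values()))
    m_s = {s: np.mean([cell[s, w] for w in windows]) for s in subjects}
    m_g = {
        g: np.mean([m_s[s] for s in subjects if g_of[s] == g]) for g in groups
    }
    m_w = {w: np.mean([cell[s, w] for s in subjects]) for w in windows}
    m_gw = {
        (g, w): np.mean([cell[s, w] for s in subjects if g_of[s] == g])
        for g in groups
        for w in windows
    }
    n_per = n_subj // len(groups)
    ss_g = a * n_per * sum((m_g[g] - grand) ** 2 for g in groups)
    ss_s = a * sum((m_s[s] - m_g[g_of[s]]) ** 2 for s in subjects)
    ss_w = n_subj * sum((m_w[w] - grand) ** 2 for w in windows)
    ss_gw = n_per * sum(
        (m_gw[g, w] - m_g[g] - m_w[w] + grand) ** 2
        for g in groups
        for w in windows
    )
    ss_err = sum(
        (cell[s, w] - m_s[s] - m_gw[g_of[s], w] + m_g[g_of[s]]) ** 2
        for s in subjects
        for w in windows
    )
    return dict(group=ss_g, subj=ss_s, window=ss_w, inter=ss_gw, err=ss_err)


class TestMixedAnova:
    def test_two_level_within_sphericity_trivial(self):
        df = _balanced_table(windows=2)
        res = ist.mixed_anova(df, within=("window",))
        eff = res["window"]
        assert eff.gg_epsilon == 1.0
        assert eff.mauchly_p == 1.0
        assert not eff.corrected

    def test_matches_loop_oracle(self):
        df = _balanced_table(n_per_group=3, n_groups=2, windows=3, seed=5)
        res = ist.mixed_anova(df, within=("window",))
        o = _oracle_split_plot(df)
        assert res["group"].ss == pytest.approx(o["group"], abs=1e-9)
        assert res["window"].ss == pytest.approx(o["window"], abs=1e-9)
        assert res["window*group"].ss == pytest.approx(o["inter"], abs=1e-9)
        F_g = (o["group"] / 1) / (o["subj"] / 4)
        assert res["group"].F == pytest.approx(F_g, abs=1e-9)
        F_w = (o["window"] / 2) / (o["err"] / 8)
        assert res["window"].F == pytest.approx(F_w, abs=1e-9)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        df = _balanced_table(n_per_group=8, windows=3, seed=7)
        res = ist.mixed_anova(df, within=("window",))
        o = pg.mixed_anova(
            df, dv="amplitude", within="window", subject="subject",
            between="group",
        ).set_index("Source")
        for mine, theirs in [
            ("group", "group"), ("window", "window"),
            ("window*group", "Interaction"),
        ]:
            assert res[mine].F == pytest.approx(o.loc[theirs, "F"], rel=1e-9)
            assert res[mine].ss == pytest.approx(o.loc[theirs, "SS"], rel=1e-9)
            assert res[mine].partial_eta2 == pytest.approx(
                o.loc[theirs, "np2"], rel=1e-9
            )

    def test_between_f_equals_oneway_on_subject_means(self):
        df = _balanced_table(n_per_group=5, windows=3, seed=9)
        res = ist.mixed_anova(df, within=("window",))
        m = df.groupby(["subject", "group"], as_index=False).amplitude.mean()
        o = stats.f_oneway(
            *[m[m.group == g].amplitude.to_numpy() for g in sorted(m.group.unique())]
        )
        assert res["group"].F == pytest.approx(o.statistic, abs=1e-9)

    def test_ss_conservation(self):
        df = _balanced_table(n_per_group=4, windows=3, pres=["first", "second"],
                             seed=3)
        res = ist.mixed_anova(df, within=("presentation", "window"))
        # recompute error SS from effects and partial eta2 relations
        ss_effects = sum(e.ss for e in res.effects.values())
        errs = set()
        for e in res.effects.values():
            # SS_err recoverable from F: SS_err = SS * df2 / (F * df1)
            errs.add(round(e.ss * e.df2 / (e.F * e.df1), 9))
        assert ss_effects + sum(errs) == pytest.approx(res.ss_total, rel=1e-9)

    def test_epsilon_bounds(self):
        df = _balanced_table(n_per_group=6, windows=4, seed=11)
        res = ist.mixed_anova(df, within=("window",))
        eps = res["window"].gg_epsilon
        assert 1.0 / 3 - 1e-12 <= eps <= 1.0 + 1e-12

    def test_unbalanced_rejected(self):
        df = _balanced_table()
        df = df.iloc[:-1]
        with pytest.raises(ValueError, match="balanced"):
            ist.mixed_anova(df, within=("window",))

    def test_two_within_factor_effects_present(self):
        df = _balanced_table(n_per_group=4, windows=3, pres=["first", "second"],
                             seed=13)
        res = ist.mixed_anova(df, within=("presentation", "window"))
        assert set(res.effects) == {
            "group", "presentation", "presentation*group",
            "window", "window*group",
            "presentation*window", "presentation*window*group",
        }


class TestPresentationGate:
    def test_strong_presentation_effect_keeps_first_only(self):
        df = _balanced_table(n_per_group=6, windows=2,
                             pres=["first", "second"], pres_shift=2.0, seed=1)
        reduced, gate = ist.presentation_gate(df)
        assert gate["action"] == "first_only"
        assert set(reduced.presentation) == {"first"}

    def test_no_presentation_effect_averages(self):
        # null presentation effect; strict alpha avoids the ~alpha-level
        # false-trigger rate inherent to the gate itself
        df = _balanced_table(n_per_group=8, windows=2,
                             pres=["first", "second"], pres_shift=0.0, seed=21)
        reduced, gate = ist.presentation_gate(df, alpha=1e-6)
        assert gate["action"] == "averaged"
        assert len(reduced) == len(df) // 2
        # averaging preserved subject/window structure
        assert set(reduced.presentation) == {"mean"}


def test_jeffreys_grades():
    assert ist.jeffreys_grade(58.48) == "very strong"
    assert ist.jeffreys_grade(0.26) == "moderate"   # 1/0.26 ~ 3.8
    assert ist.jeffreys_grade(1.5) == "anecdotal"
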