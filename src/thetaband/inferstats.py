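"""Inferential statistics, implemented from first principles.

The module covers every statistic reported in the analysis design:

* balanced split-plot ("mixed") ANOVA with one between-subject factor and
  one or two within-subject factors, including Mauchly's sphericity test
  and the Greenhouse-Geisser correction;
* Levene-gated independent-samples t-tests (pooled vs Welch), Cohen's d,
  and the JZS default-prior Bayes factor (Cauchy scale sqrt(2)/2 on the
  standardized effect, evaluated by adaptive quadrature);
* a one-way ANOVA computable from printed group summaries (n, mean, SD);
* a noncentral-F a-priori power solver for the one-way omnibus test.

Only `scipy` distribution functions (F, t, chi-square, noncentral F) and
`numpy` linear algebra are used; no statistics package performs any test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats

__all__ = [
    "BFPrior",
    "PowerSpec",
    "GroupSummary",
    "TTestResult",
    "EffectResult",
    "MixedAnovaResult",
    "levene_test",
    "welch_satterthwaite_df",
    "cohens_d_from_t",
    "jzs_bf10",
    "independent_t_test",
    "samples_from_summary",
    "anova_oneway_from_summary",
    "power_oneway",
    "required_sample_size_oneway",
    "mixed_anova",
    "presentation_gate",
    "jeffreys_grade",
]

DEFAULT_RSCALE = math.sqrt(2.0) / 2.0


@dataclass(frozen=True)
class BFPrior:
    """JZS two-sample prior: Cauchy(scale=rscale) on the standardized
    effect, Jeffreys prior on the variance."""

    rscale: float = DEFAULT_RSCALE

    def __post_init__(self) -> None:
        if self.rscale <= 0:
            raise ValueError("rscale must be positive")


@dataclass(frozen=True)
class PowerSpec:
    """A-priori power specification for a k-group one-way ANOVA."""

    eta2: float = 0.14
    alpha: float = 0.05
    power: float = 0.95
    k_groups: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.eta2 < 1:
            raise ValueError("eta2 must be in (0, 1)")
        if not 0 < self.alpha < self.power < 1:
            raise ValueError("need 0 < alpha < power < 1")
        if self.k_groups < 2:
            raise ValueError("need at least 2 groups")

    @property
    def f2(self) -> float:
        """Cohen's f^2 = eta^2 / (1 - eta^2)."""
        return self.eta2 / (1.0 - self.eta2)


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group needs n >= 2")
        if self.sd < 0:
            raise ValueError("SD must be non-negative")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    d: float
    bf10: float
    variant: str                 # pooled | welch
    levene_stat: float
    levene_p: float


@dataclass(frozen=True)
class EffectResult:
    """One ANOVA effect with its error term."""

    name: str
    ss: float
    df1: float
    df2: float
    F: float
    p: float
    partial_eta2: float
    # sphericity diagnostics (within effects with > 2 levels only)
    mauchly_w: float | None = None
    mauchly_p: float | None = None
    gg_epsilon: float | None = None
    df1_gg: float | None = None
    df2_gg: float | None = None
    p_gg: float | None = None
    corrected: bool = False

    @property
    def p_reported(self) -> float:
        return self.p_gg if self.corrected else self.p


@dataclass(frozen=True)
class MixedAnovaResult:
    effects: dict[str, EffectResult]
    ss_total: float
    n_subjects: int
    table: pd.DataFrame = field(repr=False)

    def __getitem__(self, name: str) -> EffectResult:
        return self.effects[name]


# --------------------------------------------------------------------------
# t-test family


def levene_test(samples: list[np.ndarray]) -> tuple[float, float]:
    """Levene's test for equality of variances (mean-centred variant):
    one-way ANOVA on absolute deviations from the group means."""
    samples = [np.asarray(s, dtype=float) for s in samples]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs n >= 2")
    z = [np.abs(s - s.mean()) for s in samples]
    k = len(z)
    ns = np.array([len(g) for g in z])
    means = np.array([g.mean() for g in z])
    grand = np.concatenate(z).mean()
    ss_b = float(np.sum(ns * (means - grand) ** 2))
    ss_w = float(sum(np.sum((g - m) ** 2) for g, m in zip(z, means)))
    df1, df2 = k - 1, int(ns.sum()) - k
    if ss_w == 0:
        return (0.0, 1.0) if ss_b == 0 else (math.inf, 0.0)
    F = (ss_b / df1) / (ss_w / df2)
    return F, float(stats.f.sf(F, df1, df2))


def welch_satterthwaite_df(s1: float, s2: float, n1: int, n2: int) -> float:
    """Welch-Satterthwaite effective degrees of freedom."""
    v1, v2 = s1**2 / n1, s2**2 / n2
    if v1 + v2 == 0:
        raise ValueError("both samples have zero variance")
    return (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))


def cohens_d_from_t(t: float, n1: int, n2: int) -> float:
    """Cohen's d recovered from an independent-samples t statistic:
    d = t * sqrt(1/n1 + 1/n2)."""
    return t * math.sqrt(1.0 / n1 + 1.0 / n2)


def jzs_bf10(t: float, n1: int, n2: int, prior: BFPrior | None = None) -> float:
    """JZS Bayes factor BF10 for a two-sample design, from the t statistic.

    Following Rouder et al.'s default Bayesian t-test: the alternative puts
    a Cauchy(r) prior on the standardized effect, equivalent to a scale
    mixture over g ~ InverseGamma(1/2, r^2/2). The marginal likelihood
    ratio is

        BF10 = int_0^inf (1+N*g)^(-1/2) (1 + t^2/(nu (1+N*g)))^(-(nu+1)/2)
                        pi(g) dg  /  (1 + t^2/nu)^(-(nu+1)/2)

    with effective sample size N = n1 n2/(n1+n2) and nu = n1+n2-2. The
    integral is evaluated by adaptive quadrature on a log-g axis.
    """
    if not math.isfinite(t):
        raise ValueError("t must be finite")
    prior = prior or BFPrior()
    r = prior.rscale
    N = n1 * n2 / (n1 + n2)
    nu = n1 + n2 - 2

    def integrand_logg(u: float) -> float:
        g = math.exp(u)
        like = (1.0 + N * g) ** -0.5 * (
            1.0 + t**2 / (nu * (1.0 + N * g))
        ) ** (-(nu + 1) / 2.0)
        prior_g = (2.0 * math.pi) ** -0.5 * r * g**-1.5 * math.exp(
            -(r**2) / (2.0 * g)
        )
        return like * prior_g * g  # jacobian dg = g du

    num, _ = integrate.quad(
        integrand_logg, -35.0, 35.0, epsrel=1e-8, epsabs=0.0, limit=500
    )
    den = (1.0 + t**2 / nu) ** (-(nu + 1) / 2.0)
    return num / den


def independent_t_test(
    x: np.ndarray,
    y: np.ndarray,
    prior: BFPrior | None = None,
    levene_alpha: float = 0.05,
) -> TTestResult:
    """Two-sided independent-samples t-test with a Levene gate.

    If Levene's test rejects equality of variances at ``levene_alpha`` the
    Welch statistic with Satterthwaite df is reported, otherwise the
    pooled-variance Student statistic. Cohen's d and BF10 are derived from
    the resulting t.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need n >= 2")
    lev_stat, lev_p = levene_test([x, y])
    m1, m2 = x.mean(), y.mean()
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    if lev_p < levene_alpha:
        variant = "welch"
        se = math.sqrt(v1 / n1 + v2 / n2)
        df = welch_satterthwaite_df(math.sqrt(v1), math.sqrt(v2), n1, n2)
    else:
        variant = "pooled"
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = n1 + n2 - 2
    t = 0.0 if se == 0 and m1 == m2 else (m1 - m2) / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(
        t=t,
        df=df,
        p=p,
        d=cohens_d_from_t(t, n1, n2),
        bf10=jzs_bf10(t, n1, n2, prior),
        variant=variant,
        levene_stat=lev_stat,
        levene_p=lev_p,
    )


def samples_from_summary(mean: float, sd: float, n: int) -> np.ndarray:
    """Construct a sample of size ``n`` with exactly the given mean and SD
    (ddof=1), shaped like standard normal quantiles.

    Useful for re-running tests from printed summary statistics: any test
    that depends on the data only through (n, mean, SD) gives identical
    results on the realized sample.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    q = stats.norm.ppf((np.arange(n) + 0.5) / n)
    q = (q - q.mean()) / q.std(ddof=1)
    return mean + sd * q


def anova_oneway_from_summary(
    groups: list[GroupSummary],
) -> tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA computed from group (n, mean, SD).

    Returns ``(F, df1, df2, p)`` where MS_between uses the n-weighted
    squared mean deviations and MS_within pools the group variances.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups])
    sds = np.array([g.sd for g in groups])
    k = len(groups)
    grand = float(np.sum(ns * means) / ns.sum())
    ms_b = float(np.sum(ns * (means - grand) ** 2) / (k - 1))
    df2 = int(ns.sum()) - k
    ms_w = float(np.sum((ns - 1) * sds**2) / df2)
    F = ms_b / ms_w
    return F, k - 1, df2, float(stats.f.sf(F, k - 1, df2))


# --------------------------------------------------------------------------
# power analysis


def power_oneway(n_total: int, spec: PowerSpec) -> float:
    """Power of the one-way omnibus F test at total sample size ``n_total``
    under noncentrality lambda = f^2 * N."""
    df1 = spec.k_groups - 1
    df2 = n_total - spec.k_groups
    if df2 < 1:
        return 0.0
    fcrit = stats.f.ppf(1.0 - spec.alpha, df1, df2)
    return float(stats.ncf.sf(fcrit, df1, df2, spec.f2 * n_total))


def required_sample_size_oneway(spec: PowerSpec) -> int:
    """Smallest total N whose noncentral-F power reaches the target."""
    n = spec.k_groups + 1
    while power_oneway(n, spec) < spec.power:
        n += 1
        if n > 10_000_000:
            raise RuntimeError("no feasible sample size below 1e7")
    return n


# --------------------------------------------------------------------------
# split-plot (mixed) ANOVA


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (rows orthonormal, each
    orthogonal to the unit vector)."""
    basis = np.eye(k) - 1.0 / k
    q, _ = np.linalg.qr(basis[:, : k - 1])
    return q.T


def _sphericity(scores: np.ndarray, groups: np.ndarray,
                contrasts: np.ndarray) -> tuple[float, float, float]:
    """Mauchly W (+p) and Greenhouse-Geisser epsilon from subject-level
    scores (n_subjects x k cells), pooled within groups.

    Returns (W, p, epsilon); for a single contrast row sphericity is
    trivially satisfied (W = 1, p = 1, epsilon = 1).
    """
    n, k = scores.shape
    uniq = np.unique(groups)
    centred = np.empty_like(scores)
    for g in uniq:
        sel = groups == g
        centred[sel] = scores[sel] - scores[sel].mean(axis=0)
    d = n - len(uniq)                       # pooled df
    S = centred.T @ centred / d
    T = contrasts @ S @ contrasts.T
    p_rows = T.shape[0]
    eig = np.linalg.eigvalsh(T)
    eig = np.clip(eig, 0.0, None)
    eps = float(eig.sum() ** 2 / (p_rows * np.sum(eig**2)))
    if p_rows < 2:
        return 1.0, 1.0, 1.0
    mean_eig = eig.mean()
    if mean_eig <= 0:
        return 1.0, 1.0, eps
    W = float(np.prod(eig / mean_eig))
    chi2 = -(d - (2.0 * p_rows**2 + p_rows + 2.0) / (6.0 * p_rows)) * math.log(
        max(W, 1e-300)
    )
    df_chi = p_rows * (p_rows + 1) // 2 - 1
    p = float(stats.chi2.sf(chi2, df_chi))
    return W, p, eps


def _effect(name, ss, df1, ss_err, df2, *, sph=None, alpha=0.05) -> EffectResult:
    ms, ms_e = ss / df1, ss_err / df2
    F = ms / ms_e if ms_e > 0 else math.inf
    p = float(stats.f.sf(F, df1, df2))
    pe2 = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
    kw: dict = {}
    if sph is not None:
        W, p_m, eps = sph
        kw = dict(
            mauchly_w=W,
            mauchly_p=p_m,
            gg_epsilon=eps,
            df1_gg=df1 * eps,
            df2_gg=df2 * eps,
            p_gg=float(stats.f.sf(F, df1 * eps, df2 * eps)),
            corrected=p_m < alpha,
        )
    return EffectResult(name=name, ss=ss, df1=df1, df2=df2, F=F, p=p,
                        partial_eta2=pe2, **kw)


def mixed_anova(
    table: pd.DataFrame,
    dv: str = "amplitude",
    between: str = "group",
    within: tuple[str, ...] = ("window",),
    subject: str = "subject",
    mauchly_alpha: float = 0.05,
) -> MixedAnovaResult:
    """Balanced split-plot ANOVA with one between factor and 1-2 within
    factors.

    Between effects are tested against subjects-within-groups; each within
    effect (and its interaction with the between factor) against its own
    subject-by-factor interaction. For every within effect with more than
    two levels, Mauchly's test and the Greenhouse-Geisser epsilon are
    computed from the pooled covariance of within-level differences; the
    corrected p is reported when Mauchly's p < ``mauchly_alpha``.
    """
    if not 1 <= len(within) <= 2:
        raise ValueError("within must name 1 or 2 factors")
    cols = [subject, between, *within, dv]
    df = table[cols].copy()
    subjects = np.sort(df[subject].unique())
    n_subj = len(subjects)
    w_levels = [np.sort(df[w].unique()) for w in within]
    n_cells = int(np.prod([len(l) for l in w_levels]))
    # pivot to subjects x within-cells, validating balance
    wide = df.pivot_table(index=[subject, between], columns=list(within),
                          values=dv, aggfunc="mean", sort=True)
    if wide.isna().any().any() or len(wide) != n_subj:
        raise ValueError("design must be complete and balanced")
    counts = df.groupby([subject, *within], observed=True).size()
    if counts.nunique() != 1:
        raise ValueError("design must be complete and balanced")
    grp = wide.index.get_level_values(between).to_numpy()
    uniq_g, g_counts = np.unique(grp, return_counts=True)
    if len(set(g_counts)) != 1:
        raise ValueError("groups must have equal sizes")
    Y = wide.to_numpy()                        # (n_subj, n_cells)
    shape = tuple(len(l) for l in w_levels)
    n_g = len(uniq_g)
    n_per = g_counts[0]
    M = Y.mean()
    ss_total = float(np.sum((Y - M) ** 2))

    # --- between-subject stratum
    subj_means = Y.mean(axis=1)
    g_means = np.array([subj_means[grp == g].mean() for g in uniq_g])
    ss_G = n_cells * n_per * float(np.sum((g_means - M) ** 2))
    g_of_subj = np.array([g_means[list(uniq_g).index(g)] for g in grp])
    ss_S = n_cells * float(np.sum((subj_means - g_of_subj) ** 2))
    df_S = n_subj - n_g
    effects: dict[str, EffectResult] = {
        between: _effect(between, ss_G, n_g - 1, ss_S, df_S)
    }

    # cell arrays for within algebra: (n_subj, *shape)
    Yc = Y.reshape((n_subj, *shape))

    def marg(arr, keep_axes):
        """Mean over all within axes not in keep_axes (axes of Yc[1:])."""
        axes = tuple(i + 1 for i in range(len(shape)) if i not in keep_axes)
        return arr.mean(axis=axes) if axes else arr

    def group_mean(arr):
        return np.stack([arr[grp == g].mean(axis=0) for g in uniq_g])

    within_specs = []
    # single within factors
    for i, w in enumerate(within):
        a = shape[i]
        subj_w = marg(Yc, {i})                      # (n_subj, a)
        w_mean = subj_w.mean(axis=0)                # (a,)
        gw_mean = group_mean(subj_w)                # (n_g, a)
        ss_W = n_subj * np.prod([shape[j] for j in range(len(shape)) if j != i]) \
            * float(np.sum((w_mean - M) ** 2))
        inter = gw_mean - g_means[:, None] - w_mean[None, :] + M
        ss_WG = n_per * np.prod(
            [shape[j] for j in range(len(shape)) if j != i]
        ) * float(np.sum(inter**2))
        gw_of_subj = np.stack([gw_mean[list(uniq_g).index(g)] for g in grp])
        resid = subj_w - subj_means[:, None] - gw_of_subj + g_of_subj[:, None]
        ss_err = np.prod(
            [shape[j] for j in range(len(shape)) if j != i]
        ) * float(np.sum(resid**2))
        df1 = a - 1
        df_err = (a - 1) * df_S
        C = _orthonormal_contrasts(a)
        # k = 2 within levels: one contrast, sphericity holds exactly
        sph = _sphericity(subj_w, grp, C) if a > 2 else (1.0, 1.0, 1.0)
        effects[w] = _effect(w, ss_W, df1, ss_err, df_err, sph=sph,
                             alpha=mauchly_alpha)
        effects[f"{w}*{between}"] = _effect(
            f"{w}*{between}", ss_WG, df1 * (n_g - 1), ss_err, df_err,
            sph=sph, alpha=mauchly_alpha,
        )
        within_specs.append((i, ss_W, ss_WG, ss_err))

    if len(within) == 2:
        a, b = shape
        w1, w2 = within
        cell_mean = Yc.mean(axis=0)                 # (a, b)
        m1 = marg(Yc, {0}).mean(axis=0)             # (a,)
        m2 = marg(Yc, {1}).mean(axis=0)             # (b,)
        ab = cell_mean - m1[:, None] - m2[None, :] + M
        ss_AB = n_subj * float(np.sum(ab**2))
        g_cell = group_mean(Yc)                     # (n_g, a, b)
        g_m1 = group_mean(marg(Yc, {0}))            # (n_g, a)
        g_m2 = group_mean(marg(Yc, {1}))            # (n_g, b)
        abg = (
            g_cell
            - g_m1[:, :, None]
            - g_m2[:, None, :]
            + g_means[:, None, None]
            - ab[None, :, :]
        )
        ss_ABG = n_per * float(np.sum(abg**2))
        used = ss_G + ss_S + ss_AB + ss_ABG
        for _, ss_W, ss_WG, ss_err in within_specs:
            used += ss_W + ss_WG + ss_err
        ss_ABS = max(ss_total - used, 0.0)
        df_ab = (a - 1) * (b - 1)
        df_abs = df_ab * df_S
        C = np.kron(_orthonormal_contrasts(a), _orthonormal_contrasts(b))
        sph = (
            _sphericity(Yc.reshape(n_subj, -1), grp, C)
            if df_ab > 1
            else (1.0, 1.0, 1.0)
        )
        effects[f"{w1}*{w2}"] = _effect(
            f"{w1}*{w2}", ss_AB, df_ab, ss_ABS, df_abs, sph=sph,
            alpha=mauchly_alpha,
        )
        effects[f"{w1}*{w2}*{between}"] = _effect(
            f"{w1}*{w2}*{between}", ss_ABG, df_ab * (n_g - 1), ss_ABS, df_abs,
            sph=sph, alpha=mauchly_alpha,
        )

    out_rows = [
        {
            "effect": e.name,
            "SS": e.ss,
            "df1": e.df1,
            "df2": e.df2,
            "F": e.F,
            "p": e.p,
            "partial_eta2": e.partial_eta2,
            "GG_epsilon": e.gg_epsilon,
            "p_GG": e.p_gg,
            "corrected": e.corrected,
        }
        for e in effects.values()
    ]
    return MixedAnovaResult(
        effects=effects,
        ss_total=ss_total,
        n_subjects=n_subj,
        table=pd.DataFrame(out_rows),
    )


def presentation_gate(
    table: pd.DataFrame,
    dv: str = "amplitude",
    within: str = "window",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Decide how to treat the first/second-presentation factor.

    Runs the presentation x window x group mixed ANOVA; if the
    presentation main effect or any interaction involving it is significant
    at ``alpha``, downstream analysis keeps only first presentations,
    otherwise presentations are averaged.
    """
    res = mixed_anova(table, dv=dv, within=("presentation", within))
    pres_effects = [
        e for name, e in res.effects.items() if "presentation" in name
    ]
    triggered = any(e.p_reported < alpha for e in pres_effects)
    if triggered:
        reduced = table[table["presentation"] == "first"].copy()
        action = "first_only"
    else:
        keys = [c for c in table.columns if c not in ("presentation", dv)]
        reduced = (
            table.groupby(keys, as_index=False, observed=True, sort=False)[dv]
            .mean()
        )
        reduced["presentation"] = "mean"
        action = "averaged"
    gate = {
        "action": action,
        "effects": {
            e.name: {"F": e.F, "p": e.p_reported} for e in pres_effects
        },
    }
    return reduced, gate


def jeffreys_grade(bf10: float) -> str:
    """Evidence grade for the favoured hypothesis (thresholds 1/3/10/30/100
    on the favoured side's Bayes factor)."""
    b = bf10 if bf10 >= 1 else 1.0 / bf10 if bf10 > 0 else math.inf
    if b >= 100:
        return "extreme"
    if b >= 30:
        return "very strong"
    if b >= 10:
        return "strong"
    if b >= 3:
        return "moderate"
    return "anecdotal"
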