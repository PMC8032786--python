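"""Repeated-measures inference, effect sizes and Bayes factors.

The central design is a 3 (motivation: remember / control / forget) x 2
(memory accuracy: hit / miss) fully within-subject ANOVA.  Sphericity of
any effect with more than one numerator degree of freedom is checked with
Mauchly's test; when violated (p < .05) the Greenhouse-Geisser corrected
p-value is reported together with epsilon.  Post hoc paired t-tests over
the three motivation contrasts are Bonferroni-corrected (multiplier 3).

Effect sizes follow the convention used alongside F and t statistics in
this literature::

    Cohen's f = sqrt(df1 * F / df2)        Cohen's d = t / sqrt(n)

A-priori power for a two-sided paired t-test uses the noncentral t
distribution, and Bayes factors for t-tests are Jeffreys-Zellner-Siow
(JZS) BF10 values: the ratio of the marginal likelihood of t under a
Cauchy(0, r) prior on the standardized effect size (default r = sqrt(2)/2)
to its likelihood under the point null, evaluated by adaptive quadrature.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import integrate, stats

__all__ = [
    "cohen_f_from_F",
    "cohen_d_from_t",
    "paired_t_power",
    "jzs_bf10",
    "rm_anova_3x2",
    "rm_anova_oneway",
    "posthoc_motivation",
]


def cohen_f_from_F(F: float, df1: int, df2: int) -> float:
    """Cohen's f from an F statistic and its degrees of freedom."""
    if F < 0:
        raise ValueError("F must be non-negative")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return math.sqrt(df1 * F / df2)


def cohen_d_from_t(t: float, n: int) -> float:
    """Cohen's d for a paired contrast: t over the square root of n."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return t / math.sqrt(n)


def paired_t_power(n: int, d: float, alpha: float = 0.05) -> float:
    """Two-sided power of a paired t-test at effect size d (noncentral t)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    df = n - 1
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    ncp = d * math.sqrt(n)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def jzs_bf10(t: float, n: int, prior_scale: float = math.sqrt(2) / 2) -> float:
    """JZS Bayes factor BF10 for a one-sample / paired t statistic.

    BF10 = [ integral of nct(t; n-1, delta * sqrt(n)) over the
    Cauchy(0, prior_scale) prior on delta ] / t(t; n-1), computed with
    adaptive quadrature (relative tolerance 1e-8).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    df = n - 1
    sqrt_n = math.sqrt(n)

    def integrand(delta):
        return stats.cauchy.pdf(delta, 0.0, prior_scale) * \
            stats.nct.pdf(t, df, delta * sqrt_n)

    num, err = integrate.quad(integrand, -np.inf, np.inf,
                              epsrel=1e-8, epsabs=0, limit=200)
    if num <= 0 or not np.isfinite(num) or (num > 0 and err / num > 1e-6):
        raise ArithmeticError(
            f"JZS integration failed: value={num}, abs error={err}")
    return float(num / stats.t.pdf(t, df))


def _sphericity_p(wide: pd.DataFrame) -> float:
    """Mauchly p-value for a k-level within factor given a subjects x levels table."""
    long = wide.reset_index().melt(id_vars="participant_id",
                                   var_name="level", value_name="y")
    res = pg.sphericity(long, dv="y", within="level", subject="participant_id")
    return float(res.pval)


def rm_anova_3x2(cells: pd.DataFrame, dv: str = "mean_score",
                 subject: str = "participant_id",
                 factors: tuple[str, str] = ("motivation", "outcome"),
                 alpha: float = 0.05, gg_always: bool = False) -> pd.DataFrame:
    """Two-way fully within-subject ANOVA with sphericity handling.

    ``cells`` must hold one complete 3 x 2 cell table per participant
    (participants with empty cells are excluded upstream).  For each
    effect with df1 > 1 a Mauchly test decides whether the
    Greenhouse-Geisser corrected p-value is reported (``gg_always`` forces
    the correction on).  Cohen's f accompanies every effect.
    """
    f_a, f_b = factors
    counts = cells.groupby(subject, observed=True)[dv].count()
    n_levels = cells[f_a].nunique() * cells[f_b].nunique()
    if cells[dv].isna().any() or (counts != n_levels).any():
        raise ValueError("incomplete cell table: exclude participants with "
                         "missing cells before the ANOVA")
    aov = pg.rm_anova(data=cells, dv=dv, within=[f_a, f_b], subject=subject,
                      detailed=True)
    aov = aov.rename(columns={c: c.replace("-", "_") for c in aov.columns})

    # Mauchly tests: the 3-level factor on its marginal means, the
    # interaction on the per-level difference scores of the 2-level factor.
    spher_p = {}
    marg = (cells.groupby([subject, f_a], observed=True)[dv].mean()
            .unstack(f_a))
    spher_p[f_a] = _sphericity_p(marg)
    lv_b = sorted(cells[f_b].unique())
    if len(lv_b) == 2:
        wide = cells.pivot_table(index=subject, columns=[f_a, f_b], values=dv)
        diff = pd.DataFrame({a: wide[(a, lv_b[0])] - wide[(a, lv_b[1])]
                             for a in cells[f_a].unique()})
        spher_p[f"{f_a} * {f_b}"] = _sphericity_p(diff)

    rows = []
    for rec in aov.itertuples():
        effect = rec.Source
        df1, df2 = int(rec.ddof1), int(rec.ddof2)
        sp = spher_p.get(effect, np.nan)
        use_gg = df1 > 1 and (gg_always or (np.isfinite(sp) and sp < alpha))
        eps = getattr(rec, "eps", np.nan) if df1 > 1 else 1.0
        p = rec.p_GG_corr if use_gg else rec.p_unc
        rows.append({
            "effect": effect, "F": rec.F, "df1": df1, "df2": df2,
            "epsilon": float(eps) if np.isfinite(eps) else 1.0,
            "mauchly_p": sp, "gg_applied": bool(use_gg),
            "p": float(p), "p_uncorrected": float(rec.p_unc),
            "cohen_f": cohen_f_from_F(rec.F, df1, df2),
        })
    return pd.DataFrame(rows)


def rm_anova_oneway(data: pd.DataFrame, dv: str, within: str,
                    subject: str = "participant_id", alpha: float = 0.05,
                    gg_always: bool = False) -> pd.DataFrame:
    """One-way repeated-measures ANOVA with the same sphericity handling."""
    aov = pg.rm_anova(data=data, dv=dv, within=within, subject=subject,
                      correction=True, detailed=True)
    aov = aov.rename(columns={c: c.replace("-", "_") for c in aov.columns})
    rec = aov.iloc[0]
    df1, df2 = int(rec["DF"]), int(aov.iloc[1]["DF"])
    sp = float(rec.get("p_spher", np.nan))
    use_gg = df1 > 1 and (gg_always or (np.isfinite(sp) and sp < alpha))
    p = rec["p_GG_corr"] if use_gg else rec["p_unc"]
    return pd.DataFrame([{
        "effect": within, "F": rec["F"], "df1": df1, "df2": df2,
        "epsilon": float(rec.get("eps", 1.0)),
        "mauchly_p": sp, "gg_applied": bool(use_gg),
        "p": float(p), "p_uncorrected": float(rec["p_unc"]),
        "cohen_f": cohen_f_from_F(rec["F"], df1, df2),
    }])


def posthoc_motivation(data: pd.DataFrame, dv: str,
                       within: str = "motivation",
                       subject: str = "participant_id",
                       levels: tuple = ("remember", "control", "forget"),
                       prior_scale: float = math.sqrt(2) / 2) -> pd.DataFrame:
    """Bonferroni-corrected paired t-tests over the three motivation contrasts.

    Marginal means per participant (averaged over any other factor) are
    contrasted pairwise; each contrast reports t, df, the Bonferroni
    p-value (raw p times 3, capped at 1), Cohen's d and the JZS BF10.
    """
    marg = data.groupby([subject, within], observed=True)[dv].mean().unstack(within)
    rows = []
    pairs = [(levels[0], levels[1]), (levels[0], levels[2]),
             (levels[1], levels[2])]
    m = len(pairs)
    for a, b in pairs:
        paired = marg[[a, b]].dropna()
        n = len(paired)
        t, p_raw = stats.ttest_rel(paired[a], paired[b])
        rows.append({
            "contrast": f"{a} vs {b}", "n": n, "t": float(t), "df": n - 1,
            "p_raw": float(p_raw),
            "p_bonferroni": float(min(1.0, m * p_raw)),
            "cohen_d": cohen_d_from_t(float(t), n),
            "bf10": jzs_bf10(float(t), n, prior_scale),
        })
    return pd.DataFrame(rows)
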