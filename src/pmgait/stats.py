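"""Statistical stage: normality screen, mixed repeated-measures ANOVA,
Bonferroni post hoc tests, speed-stability correlations, a-priori power.

The design is a split-plot ANOVA: one between-subject factor (age group,
2 levels) crossed with one within-subject factor (speed condition, 8
levels), applied separately to each dependent variable (rVAR or LyE) and
each principal movement.  Within-subject terms are Greenhouse-Geisser
corrected; effect sizes are partial eta squared; observed power follows the
noncentral-F convention with lambda = F * df1 at the corrected degrees of
freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, ValidationError

LONG_COLUMNS = ("subject", "age_group", "condition", "pm", "metric", "value")


@dataclass
class AnovaResult:
    effect: str  # "age" (between) | "speed" (within) | "interaction"
    df1: float
    df2: float
    F: float
    p: float  # GG-corrected for within terms
    p_uncorrected: float
    partial_eta_sq: float
    observed_power: float
    epsilon_gg: float  # 1.0 for the between term


def _condition_sort(levels) -> list:
    def key(c):
        try:
            return (0, float(c), str(c))
        except (TypeError, ValueError):
            return (1, 0.0, str(c))
    return sorted(levels, key=key)


def _pivot_complete(table: pd.DataFrame, metric: str, pm: int):
    """Subject x condition wide matrix with listwise deletion.

    Returns (Y, groups, condition_levels, n_dropped).
    """
    sub = table[(table["metric"] == metric) & (table["pm"] == pm)]
    sub = sub.dropna(subset=["value"])
    if sub.empty:
        raise ValidationError(f"no data for metric={metric!r}, pm={pm}")
    levels = _condition_sort(sub["condition"].unique())
    wide = sub.pivot_table(index="subject", columns="condition",
                           values="value", aggfunc="mean")
    wide = wide.reindex(columns=levels)
    complete = wide.dropna(axis=0)
    n_dropped = wide.shape[0] - complete.shape[0]
    group_map = (sub.drop_duplicates("subject")
                 .set_index("subject")["age_group"])
    groups = group_map.reindex(complete.index).to_numpy()
    return complete.to_numpy(dtype=float), groups, levels, n_dropped


def greenhouse_geisser_epsilon(cov: np.ndarray) -> float:
    """GG epsilon from an L x L within-cell covariance matrix.

    Computed as tr(M)^2 / ((L-1) tr(M^2)) with M = C S C' for an
    orthonormal contrast basis C; bounded in [1/(L-1), 1].
    """
    L = cov.shape[0]
    if L < 2:
        raise ValidationError("need at least 2 within levels")
    # orthonormal basis of the contrast space (complement of the unit vector)
    c = np.linalg.qr(
        np.eye(L) - np.full((L, L), 1.0 / L)
    )[0][:, : L - 1]
    m = c.T @ cov @ c
    tr = np.trace(m)
    tr2 = np.trace(m @ m)
    if tr2 <= 0:
        raise DegenerateInputError("within-cell covariance has no variance")
    eps = tr**2 / ((L - 1) * tr2)
    return float(np.clip(eps, 1.0 / (L - 1), 1.0))


def _observed_power(F: float, df1: float, df2: float, alpha: float) -> float:
    if not np.isfinite(F) or df1 <= 0 or df2 <= 0:
        return np.nan
    lam = F * df1
    crit = sps.f.isf(alpha, df1, df2)
    return float(sps.ncf.sf(crit, df1, df2, lam))


def _one_way_rm_anova(Y: np.ndarray, alpha: float) -> list[AnovaResult]:
    """Single-group repeated-measures ANOVA (within effect only)."""
    n, L = Y.shape
    grand = Y.mean()
    ss_total = ((Y - grand) ** 2).sum()
    ss_subjects = L * ((Y.mean(axis=1) - grand) ** 2).sum()
    ss_b = n * ((Y.mean(axis=0) - grand) ** 2).sum()
    ss_err = ss_total - ss_subjects - ss_b
    df_b, df_err = float(L - 1), float((n - 1) * (L - 1))
    F = (ss_b / df_b) / (ss_err / df_err)
    eps = greenhouse_geisser_epsilon(np.cov(Y, rowvar=False, ddof=1))
    p_unc = float(sps.f.sf(F, df_b, df_err))
    df1c, df2c = eps * df_b, eps * df_err
    return [AnovaResult(
        effect="speed", df1=df1c, df2=df2c, F=float(F),
        p=float(sps.f.sf(F, df1c, df2c)), p_uncorrected=p_unc,
        partial_eta_sq=float(ss_b / (ss_b + ss_err)),
        observed_power=_observed_power(F, df1c, df2c, alpha),
        epsilon_gg=eps,
    )]


def split_plot_anova(Y: np.ndarray, groups: np.ndarray,
                     alpha: float = 0.05) -> list[AnovaResult]:
    """Mixed (split-plot) ANOVA on a complete subjects x levels matrix.

    ``Y`` is N x L (subjects by within levels); ``groups`` assigns each
    subject to one of two between-subject levels.  Returns the between
    ("age"), within ("speed") and interaction effects with
    Greenhouse-Geisser correction on the within terms.  With a single
    group level the design degenerates to a one-way repeated-measures
    ANOVA and only the within effect is returned.
    """
    Y = np.asarray(Y, dtype=float)
    n, L = Y.shape
    glabels = np.unique(groups)
    if len(glabels) not in (1, 2):
        raise ValidationError(
            f"expected 1 or 2 between-subject levels, got {len(glabels)}")
    if L < 2:
        raise ValidationError("within factor needs >= 2 levels")
    counts = np.array([(groups == g).sum() for g in glabels])
    if counts.min() < 2:
        raise ValidationError("need >= 2 subjects per between-subject group")
    if np.ptp(Y) == 0:
        raise DegenerateInputError("all observations identical")
    if len(glabels) == 1:
        return _one_way_rm_anova(Y, alpha)

    grand = Y.mean()
    ss_total = ((Y - grand) ** 2).sum()
    subj_means = Y.mean(axis=1)
    ss_subjects = L * ((subj_means - grand) ** 2).sum()
    ss_within_subj = ss_total - ss_subjects

    group_means = np.array([Y[groups == g].mean() for g in glabels])
    ss_a = L * (counts * (group_means - grand) ** 2).sum()
    ss_s_in_a = ss_subjects - ss_a

    cond_means = Y.mean(axis=0)
    ss_b = n * ((cond_means - grand) ** 2).sum()
    ss_ab = 0.0
    for g, cnt, gm in zip(glabels, counts, group_means):
        cell = Y[groups == g].mean(axis=0)
        ss_ab += cnt * ((cell - gm - cond_means + grand) ** 2).sum()
    ss_err_within = ss_within_subj - ss_b - ss_ab

    df_a, df_s = 1.0, float(n - 2)
    df_b = float(L - 1)
    df_ab = df_a * df_b
    df_err = df_s * df_b

    ms = lambda ss, df: ss / df  # noqa: E731
    F_a = ms(ss_a, df_a) / ms(ss_s_in_a, df_s)
    F_b = ms(ss_b, df_b) / ms(ss_err_within, df_err)
    F_ab = ms(ss_ab, df_ab) / ms(ss_err_within, df_err)

    # pooled within-group covariance of the L repeated measures
    pooled = np.zeros((L, L))
    for g, cnt in zip(glabels, counts):
        sub = Y[groups == g]
        pooled += (cnt - 1) * np.cov(sub, rowvar=False, ddof=1)
    pooled /= (n - 2)
    eps = greenhouse_geisser_epsilon(pooled)

    results = []
    p_a = float(sps.f.sf(F_a, df_a, df_s))
    results.append(AnovaResult(
        effect="age", df1=df_a, df2=df_s, F=float(F_a),
        p=p_a, p_uncorrected=p_a,
        partial_eta_sq=float(ss_a / (ss_a + ss_s_in_a)),
        observed_power=_observed_power(F_a, df_a, df_s, alpha),
        epsilon_gg=1.0,
    ))
    for name, F, ss_eff, df_eff in (
        ("speed", F_b, ss_b, df_b),
        ("interaction", F_ab, ss_ab, df_ab),
    ):
        p_unc = float(sps.f.sf(F, df_eff, df_err))
        df1c, df2c = eps * df_eff, eps * df_err
        p_gg = float(sps.f.sf(F, df1c, df2c))
        results.append(AnovaResult(
            effect=name, df1=df1c, df2=df2c, F=float(F),
            p=p_gg, p_uncorrected=p_unc,
            partial_eta_sq=float(ss_eff / (ss_eff + ss_err_within)),
            observed_power=_observed_power(F, df1c, df2c, alpha),
            epsilon_gg=eps,
        ))
    return results


def mixed_rm_anova(table: pd.DataFrame, metric: str, pm: int,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Mixed RM-ANOVA on one metric x PM slice of a long-format table."""
    Y, groups, levels, n_dropped = _pivot_complete(table, metric, pm)
    results = split_plot_anova(Y, groups, alpha=alpha)
    out = pd.DataFrame([vars(r) for r in results])
    out.insert(0, "pm", pm)
    out.insert(0, "metric", metric)
    out["n_subjects"] = Y.shape[0]
    out["n_dropped"] = n_dropped
    return out


def shapiro_wilk_screen(table: pd.DataFrame) -> pd.DataFrame:
    """Shapiro-Wilk W and p per (metric, pm, condition, age_group) cell.

    Advisory only: cells with fewer than 3 observations or zero variance
    are flagged and skipped, and no downstream branching depends on the
    outcome.
    """
    rows = []
    keys = ["metric", "pm", "condition", "age_group"]
    for key, cell in table.dropna(subset=["value"]).groupby(keys, sort=True):
        vals = cell["value"].to_numpy(dtype=float)
        row = dict(zip(keys, key))
        row.update(n=len(vals), W=np.nan, p=np.nan, flag="ok")
        if len(vals) < 3:
            row["flag"] = "skipped: n < 3"
        elif np.ptp(vals) == 0:
            row["flag"] = "degenerate: constant sample"
        else:
            w, p = sps.shapiro(vals)
            row.update(W=float(w), p=float(p))
        rows.append(row)
    return pd.DataFrame(rows, columns=keys + ["n", "W", "p", "flag"])


def bonferroni_posthoc(table: pd.DataFrame, metric: str, pm: int,
                       alpha_adj: float = 0.006) -> pd.DataFrame:
    """All pairwise paired t-tests across speed conditions.

    ``alpha_adj`` defaults to the conventional 0.05/8 = 0.006 used for this
    design; a flag at the all-pairs Bonferroni level 0.05/C(L,2) is also
    reported.  Degenerate pairs (zero difference variance) are flagged
    non-significant.
    """
    Y, _, levels, _ = _pivot_complete(table, metric, pm)
    L = len(levels)
    n_pairs = L * (L - 1) // 2
    alpha_allpairs = 0.05 / n_pairs
    rows = []
    for i in range(L):
        for j in range(i + 1, L):
            a, b = Y[:, i], Y[:, j]
            diff = a - b
            row = {
                "metric": metric, "pm": pm,
                "level_a": levels[i], "level_b": levels[j],
                "mean_diff": float(diff.mean()),
                "t": np.nan, "df": len(diff) - 1, "p": np.nan,
                "significant": False,
                "significant_allpairs": False,
                "alpha_adj": alpha_adj,
                "flag": "ok",
            }
            if len(diff) < 2:
                row["flag"] = "skipped: fewer than 2 complete pairs"
            elif np.ptp(diff) == 0:
                row["flag"] = "degenerate: identical paired samples"
            else:
                t, p = sps.ttest_rel(a, b)
                row.update(t=float(t), p=float(p),
                           significant=bool(p < alpha_adj),
                           significant_allpairs=bool(p < alpha_allpairs))
            rows.append(row)
    return pd.DataFrame(rows)


def speed_stability_correlations(lye_table: pd.DataFrame,
                                 speeds: pd.DataFrame | None = None
                                 ) -> pd.DataFrame:
    """Pearson r between LyE and walking speed, per condition x PM.

    Speeds come from a ``speed_m_s`` column of ``lye_table`` or from a
    separate (subject, condition, speed_m_s) table.  Correlations are
    across subjects within one speed condition, so they measure whether
    faster walkers (in absolute m/s, at the same relative speed) are more
    or less stable.
    """
    df = lye_table.copy()
    if speeds is not None:
        df = df.drop(columns=[c for c in ("speed_m_s",) if c in df], errors="ignore")
        df = df.merge(speeds, on=["subject", "condition"], how="left")
    if "speed_m_s" not in df.columns:
        raise ValidationError("no speed_m_s column or speeds table provided")
    rows = []
    for (cond, pm), cell in df.groupby(["condition", "pm"], sort=True):
        cell = cell.dropna(subset=["lye", "speed_m_s"])
        row = {"condition": cond, "pm": pm, "n": len(cell),
               "r": np.nan, "p": np.nan, "flag": "ok"}
        if len(cell) < 3:
            row["flag"] = "skipped: n < 3"
        elif (np.ptp(cell["lye"]) == 0 or np.ptp(cell["speed_m_s"]) == 0):
            row["flag"] = "undefined: zero variance"
        else:
            r, p = sps.pearsonr(cell["speed_m_s"], cell["lye"])
            row.update(r=float(r), p=float(p))
        rows.append(row)
    out = pd.DataFrame(rows, columns=["condition", "pm", "n", "r", "p", "flag"])
    key = out["condition"].map(lambda c: _condition_sort([c])[0])
    out = out.sort_values(["pm", "condition"],
                          key=lambda s: s.map(lambda v: (0, float(v))
                                              if str(v).replace(".", "").isdigit()
                                              else (1, str(v)))
                          if s.name == "condition" else s)
    return out.reset_index(drop=True)


def within_factor_power(n_total: int, effect_f: float = 0.25,
                        alpha: float = 0.05, n_groups: int = 2,
                        n_measures: int = 8, corr: float = 0.5,
                        epsilon: float = 1.0) -> float:
    """Power of the within-subject main effect at total sample size N.

    Noncentral-F convention for repeated measures:
    lambda = N f^2 m eps / (1 - rho), df1 = (m-1) eps,
    df2 = (N - groups)(m-1) eps.
    """
    df2 = (n_total - n_groups) * (n_measures - 1) * epsilon
    if df2 < 1:
        return 0.0
    lam = n_total * effect_f**2 * n_measures * epsilon / (1.0 - corr)
    df1 = (n_measures - 1) * epsilon
    crit = sps.f.isf(alpha, df1, df2)
    return float(sps.ncf.sf(crit, df1, df2, lam))


def required_sample_size(effect_f: float = 0.25, alpha: float = 0.05,
                         power: float = 0.95, n_groups: int = 2,
                         n_measures: int = 8, corr: float = 0.5,
                         epsilon: float = 1.0, balanced: bool = True,
                         max_n: int = 10**6) -> int:
    """Smallest total N whose within-factor power reaches ``power``.

    With ``balanced=True`` (default) N is constrained to multiples of
    ``n_groups``, matching the equal-group allocation of standard a-priori
    power software for between x within designs.
    """
    if effect_f <= 0:
        raise ValidationError("effect_f must be > 0")
    if not 0 < power < 1:
        raise ValidationError("power must be in (0, 1)")
    step = n_groups if balanced else 1
    n = n_groups if balanced else n_groups + 1
    while n <= max_n:
        if within_factor_power(n, effect_f, alpha, n_groups,
                               n_measures, corr, epsilon) >= power:
            return n
        n += step
    raise ValidationError(f"requested power unreachable below N={max_n}")
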