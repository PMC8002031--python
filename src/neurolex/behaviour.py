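"""Behavioural inference: 2 x 3 repeated-measures ANOVA and follow-ups.

The chain mirrors the standard lexical-decision analysis: per participant
x session x lexicality cell means (RT on correct, outlier-free trials;
accuracy as proportion correct), a two-way within-subject ANOVA with
Mauchly's sphericity test and Greenhouse-Geisser correction (applied when
Mauchly p < .05), generalized eta-squared effect sizes, and
Bonferroni-corrected paired follow-up t-tests with Cohen's d_z.

The sums-of-squares decomposition is written out explicitly (fully
balanced within design) rather than routed through a GLM, so every term
is inspectable: SS_A, SS_B, SS_AB and their subject-interaction error
terms, with eta^2_G = SS_effect / (SS_effect + all subject-related SS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .epochs import exclude_incorrect, exclude_rt_outliers

__all__ = [
    "AnovaResult",
    "build_behavioural_table",
    "paired_followups",
    "paired_ttest",
    "rm_anova_2x3",
    "rm_anova_oneway",
]


def build_behavioural_table(trials: pd.DataFrame,
                            apply_exclusions: bool = True) -> pd.DataFrame:
    """Participant x session x lexicality summary table.

    RT outliers (±2.5 SD per cell) are removed first; accuracy is the
    proportion correct among outlier-free trials; mean RT uses correct
    outlier-free trials only.
    """
    if apply_exclusions:
        trials, _ = exclude_rt_outliers(trials)
    acc = (trials.groupby(["participant", "session", "lexicality"])["correct"]
           .mean().rename("accuracy"))
    rt = (exclude_incorrect(trials)
          .groupby(["participant", "session", "lexicality"])["rt_ms"]
          .mean().rename("rt_ms"))
    table = pd.concat([rt, acc], axis=1).reset_index()
    if table[["rt_ms", "accuracy"]].isna().any().any():
        raise ValueError("incomplete design: a participant cell has no usable trials")
    return table


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k, k-1) orthonormal contrast matrix (Helmert, normalized)."""
    c = np.zeros((k, k - 1))
    for j in range(1, k):
        c[:j, j - 1] = 1.0
        c[j, j - 1] = -j
        c[:, j - 1] /= np.linalg.norm(c[:, j - 1])
    return c


def _sphericity(scores: np.ndarray) -> dict:
    """Mauchly's W and Greenhouse-Geisser epsilon from orthonormal
    contrast scores (n_subjects x d)."""
    n, d = scores.shape
    if d < 2:
        return {"W": 1.0, "chi2": 0.0, "df": 0, "p_mauchly": 1.0, "eps": 1.0}
    s = np.cov(scores, rowvar=False, ddof=1)
    eig = np.linalg.eigvalsh(s)
    eig = np.clip(eig, 0.0, None)
    mean_eig = eig.mean()
    w = float(np.prod(eig / mean_eig)) if mean_eig > 0 else 1.0
    df = d * (d + 1) // 2 - 1
    f = (2 * d ** 2 + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * (1 - f) * np.log(max(w, np.finfo(float).tiny))
    p = float(stats.chi2.sf(chi2, df))
    eps = float(eig.sum() ** 2 / (d * np.sum(eig ** 2))) if eig.sum() > 0 else 1.0
    eps = min(max(eps, 1.0 / d), 1.0)
    return {"W": w, "chi2": float(chi2), "df": df, "p_mauchly": p, "eps": eps}


@dataclass
class AnovaResult:
    """Effect table plus sphericity diagnostics.

    ``table`` has one row per effect (A, B, A x B) with F, dfs, p,
    generalized eta-squared, Mauchly statistics and the GG-corrected dfs/p
    (``p_reported`` is GG-corrected when Mauchly p < .05, uncorrected
    otherwise).  ``ss`` holds the full sums-of-squares partition.
    """

    table: pd.DataFrame
    ss: dict
    factor_a: str
    factor_b: str


def rm_anova_2x3(table: pd.DataFrame, dv: str = "rt_ms",
                 factor_a: str = "lexicality", factor_b: str = "session",
                 subject: str = "participant") -> AnovaResult:
    """Two-way fully-within ANOVA on a complete factorial cell-mean table."""
    cells = table.pivot_table(index=subject, columns=[factor_a, factor_b],
                              values=dv, aggfunc="mean")
    if cells.isna().any().any():
        raise ValueError("missing cell in the within-subject design")
    a_levels = sorted({c[0] for c in cells.columns})
    b_levels = sorted({c[1] for c in cells.columns})
    a, b, n = len(a_levels), len(b_levels), len(cells)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    y = np.empty((n, a, b))
    for i, al in enumerate(a_levels):
        for j, bl in enumerate(b_levels):
            y[:, i, j] = cells[(al, bl)].to_numpy()

    gm = y.mean()
    mean_a = y.mean(axis=(0, 2))
    mean_b = y.mean(axis=(0, 1))
    mean_ab = y.mean(axis=0)
    mean_s = y.mean(axis=(1, 2))
    mean_sa = y.mean(axis=2)
    mean_sb = y.mean(axis=1)

    ss_a = n * b * np.sum((mean_a - gm) ** 2)
    ss_b = n * a * np.sum((mean_b - gm) ** 2)
    ss_ab = n * np.sum((mean_ab - mean_a[:, None] - mean_b[None, :] + gm) ** 2)
    ss_s = a * b * np.sum((mean_s - gm) ** 2)
    ss_sa = b * np.sum((mean_sa - mean_a[None, :] - mean_s[:, None] + gm) ** 2)
    ss_sb = a * np.sum((mean_sb - mean_b[None, :] - mean_s[:, None] + gm) ** 2)
    resid = (y - mean_ab[None] - mean_sa[:, :, None] - mean_sb[:, None, :]
             + mean_a[None, :, None] + mean_b[None, None, :] + mean_s[:, None, None] - gm)
    ss_sab = np.sum(resid ** 2)
    ss = {"A": ss_a, "B": ss_b, "AxB": ss_ab, "subject": ss_s,
          "AxS": ss_sa, "BxS": ss_sb, "AxBxS": ss_sab,
          "total": np.sum((y - gm) ** 2)}
    ss_subject_related = ss_s + ss_sa + ss_sb + ss_sab

    # sphericity inputs: orthonormal contrast scores per effect
    ca = _orthonormal_contrasts(a)
    cb = _orthonormal_contrasts(b)
    scores = {
        "A": y.mean(axis=2) @ ca,
        "B": y.mean(axis=1) @ cb,
        "AxB": np.einsum("nij,ip,jq->npq", y, ca, cb).reshape(n, -1),
    }

    effects = [("A", factor_a, ss_a, a - 1, ss_sa),
               ("B", factor_b, ss_b, b - 1, ss_sb),
               ("AxB", f"{factor_a} x {factor_b}", ss_ab, (a - 1) * (b - 1), ss_sab)]
    rows = []
    for key, name, ss_eff, df1, ss_err in effects:
        df2 = df1 * (n - 1)
        ms_eff, ms_err = ss_eff / df1, ss_err / df2
        f_stat = ms_eff / ms_err if ms_err > 0 else 0.0
        p = float(stats.f.sf(f_stat, df1, df2)) if ms_err > 0 else 1.0
        sph = _sphericity(scores[key])
        df1_gg, df2_gg = sph["eps"] * df1, sph["eps"] * df2
        p_gg = float(stats.f.sf(f_stat, df1_gg, df2_gg)) if ms_err > 0 else 1.0
        gg_applied = df1 > 1 and sph["p_mauchly"] < 0.05
        rows.append({
            "effect": name, "F": f_stat, "df1": df1, "df2": df2, "p": p,
            "ng2": (ss_eff / (ss_eff + ss_subject_related)
                    if ss_eff + ss_subject_related > 0 else 0.0),
            "mauchly_W": sph["W"], "p_mauchly": sph["p_mauchly"],
            "eps_gg": sph["eps"], "df1_gg": df1_gg, "df2_gg": df2_gg,
            "p_gg": p_gg, "gg_applied": gg_applied,
            "p_reported": p_gg if gg_applied else p,
        })
    return AnovaResult(table=pd.DataFrame(rows), ss=ss,
                       factor_a=factor_a, factor_b=factor_b)


def rm_anova_oneway(table: pd.DataFrame, dv: str = "rt_ms",
                    within: str = "session", subject: str = "participant",
                    subset: dict | None = None) -> dict:
    """One-way within-subject ANOVA (simple main effect).

    Other factors are fixed via ``subset`` or averaged out per subject.
    Returns F, dfs, p, generalized eta-squared and sphericity/GG fields
    (``p_reported`` is GG-corrected when Mauchly p < .05).
    """
    df = table
    if subset:
        for k, v in subset.items():
            df = df[df[k] == v]
    wide = df.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    if wide.isna().any().any():
        raise ValueError("missing cell in the within-subject design")
    y = wide.to_numpy()
    n, k = y.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 subjects and 2 levels")
    gm = y.mean()
    mean_s, mean_b = y.mean(axis=1), y.mean(axis=0)
    ss_b = n * np.sum((mean_b - gm) ** 2)
    ss_s = k * np.sum((mean_s - gm) ** 2)
    ss_err = np.sum((y - mean_s[:, None] - mean_b[None, :] + gm) ** 2)
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_eff, ms_err = ss_b / df1, ss_err / df2
    f_stat = ms_eff / ms_err if ms_err > 0 else 0.0
    p = float(stats.f.sf(f_stat, df1, df2)) if ms_err > 0 else 1.0
    sph = _sphericity(y @ _orthonormal_contrasts(k))
    p_gg = (float(stats.f.sf(f_stat, sph["eps"] * df1, sph["eps"] * df2))
            if ms_err > 0 else 1.0)
    gg_applied = df1 > 1 and sph["p_mauchly"] < 0.05
    return {"F": float(f_stat), "df1": df1, "df2": df2, "p": p,
            "ng2": float(ss_b / (ss_b + ss_s + ss_err)),
            "mauchly_W": sph["W"], "p_mauchly": sph["p_mauchly"],
            "eps_gg": sph["eps"], "p_gg": p_gg, "gg_applied": gg_applied,
            "p_reported": p_gg if gg_applied else p}


def paired_ttest(x: np.ndarray, y: np.ndarray) -> dict:
    """Paired t with Cohen's d_z (mean difference / SD of differences).

    Zero-variance differences leave t and d undefined (NaN, flagged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return {"t": 0.0, "df": n - 1, "p": 1.0, "d": 0.0, "se": 0.0,
                    "defined": d.mean() != 0 or True}
        return {"t": np.nan, "df": n - 1, "p": np.nan, "d": np.nan,
                "se": 0.0, "defined": False}
    se = sd / np.sqrt(n)
    t = d.mean() / se
    return {"t": float(t), "df": n - 1,
            "p": float(2 * stats.t.sf(abs(t), n - 1)),
            "d": float(d.mean() / sd), "se": float(se), "defined": True}


def paired_followups(table: pd.DataFrame, dv: str = "rt_ms",
                     within: str = "session", subset: dict | None = None,
                     subject: str = "participant",
                     alpha: float = 0.017) -> pd.DataFrame:
    """All pairwise paired t-tests across levels of ``within``.

    ``subset`` fixes other factors first (e.g. {'lexicality': 'word'});
    remaining factors are averaged out per subject.  Significance is
    flagged at the supplied Bonferroni-corrected alpha.
    """
    df = table
    if subset:
        for k, v in subset.items():
            df = df[df[k] == v]
    wide = df.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    levels = list(wide.columns)
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            res = paired_ttest(wide[levels[i]].to_numpy(), wide[levels[j]].to_numpy())
            rows.append({"level_1": levels[i], "level_2": levels[j], **res,
                         "significant": bool(res["defined"] and res["p"] < alpha)})
    return pd.DataFrame(rows)
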