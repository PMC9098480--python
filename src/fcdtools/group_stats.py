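"""Region-wise group statistics for multi-condition regional profiles.

One-way repeated-measures ANOVA per region (subjects as the blocking
factor), Benjamini-Hochberg FDR across regions, Bonferroni-corrected paired
post-hocs, paired Cohen's d effect-size maps, behavioral correlations and
subgroup comparisons of condition differences.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ConditionDataset


def rm_anova(data: ConditionDataset, alpha: float = 0.05) -> pd.DataFrame:
    """One-way within-subject ANOVA per region.

    F = MS_condition / MS_(condition x subject) with df1 = C - 1 and
    df2 = (C - 1)(S - 1); sphericity is assumed (no Greenhouse-Geisser
    correction, so the printed df match the classical repeated-measures
    table); a GG epsilon diagnostic is included per region.  q-values are
    Benjamini-Hochberg across regions.
    """
    y = data.values
    if not np.all(np.isfinite(y)):
        bad = np.argwhere(~np.isfinite(y))[0]
        raise ValueError(
            f"missing cell at subject {bad[0]}, condition {bad[1]}, region {bad[2]}"
        )
    s, c, _ = y.shape
    grand = y.mean(axis=(0, 1))
    cond_mean = y.mean(axis=0)  # conditions x regions
    subj_mean = y.mean(axis=1)  # subjects x regions
    ss_cond = s * ((cond_mean - grand) ** 2).sum(axis=0)
    ss_subj = c * ((subj_mean - grand) ** 2).sum(axis=0)
    ss_total = ((y - grand) ** 2).sum(axis=(0, 1))
    ss_err = ss_total - ss_cond - ss_subj
    df1 = c - 1
    df2 = (c - 1) * (s - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    zero_cond = ss_cond <= 1e-12 * np.maximum(ss_total, np.finfo(float).tiny)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ms_err > 0, ms_cond / np.where(ms_err > 0, ms_err, 1.0), np.inf)
    f = np.where(zero_cond, 0.0, np.maximum(f, 0.0))  # no condition variance -> F = 0
    p = stats.f.sf(f, df1, df2)
    q, reject = bh_fdr(p, alpha=alpha)
    eps = _gg_epsilon(y)
    return pd.DataFrame(
        {
            "region_id": data.region_ids,
            "F": f,
            "df1": df1,
            "df2": df2,
            "p": p,
            "q": q,
            "significant": reject,
            "gg_epsilon": eps,
        }
    )


def _gg_epsilon(y: np.ndarray) -> np.ndarray:
    """Greenhouse-Geisser sphericity epsilon per region (diagnostic only)."""
    s, c, r = y.shape
    eps = np.empty(r)
    for j in range(r):
        centered = y[:, :, j] - y[:, :, j].mean(axis=0)
        cov = centered.T @ centered / (s - 1)
        mean_diag = np.trace(cov) / c
        mean_all = cov.mean()
        num = (c * (mean_diag - mean_all)) ** 2
        den = (c - 1) * ((cov**2).sum() - 2 * c * (cov.mean(axis=1) ** 2).sum() + c**2 * mean_all**2)
        eps[j] = 1.0 if den <= 0 else min(1.0, num / den)
    return eps


def bh_fdr(pvalues, alpha: float = 0.05):
    """Benjamini-Hochberg step-up FDR: q-values and rejection flags."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def posthoc_pairwise(data: ConditionDataset, regions=None) -> pd.DataFrame:
    """Paired two-sided t-tests per condition pair, Bonferroni-adjusted.

    ``regions`` selects region ids (default: all).  With C conditions the
    C(C-1)/2 pairwise p-values are multiplied by the number of pairs and
    capped at 1.  A pair whose within-subject differences have zero
    variance but a nonzero mean is reported with p = 0 and a degenerate
    flag; zero variance and zero mean gives p = 1.
    """
    if data.n_subjects < 2:
        raise ValueError("need at least 2 subjects for paired tests")
    region_idx = np.arange(data.n_regions)
    if regions is not None:
        lookup = {rid: i for i, rid in enumerate(data.region_ids)}
        region_idx = np.array([lookup[r] for r in regions])
    names = data.condition_names
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    rows = []
    for a, b in pairs:
        ia, ib = data.condition_index(a), data.condition_index(b)
        diff = data.values[:, ib, :] - data.values[:, ia, :]
        for j in region_idx:
            d = diff[:, j]
            degenerate = bool(np.isclose(d.std(ddof=1), 0.0))
            if degenerate:
                p_raw = 0.0 if abs(d.mean()) > 0 else 1.0
                t_stat = np.inf * np.sign(d.mean()) if abs(d.mean()) > 0 else 0.0
            else:
                t_stat, p_raw = stats.ttest_rel(data.values[:, ib, j], data.values[:, ia, j])
            rows.append(
                {
                    "region_id": data.region_ids[j],
                    "pair": f"{a} vs {b}",
                    "t": float(t_stat),
                    "p_raw": float(p_raw),
                    "p_bonferroni": float(min(1.0, p_raw * len(pairs))),
                    "direction": "increase" if d.mean() > 0 else ("decrease" if d.mean() < 0 else "none"),
                    "degenerate_variance": degenerate,
                }
            )
    return pd.DataFrame(rows)


def cohens_d_map(
    data: ConditionDataset, pair: tuple, variant: str = "paired_dz", cap: float = 1e6
) -> pd.DataFrame:
    """Per-region Cohen's d for one condition pair.

    ``paired_dz``: mean within-subject difference / SD of differences
    (sample SD, ddof = 1).  ``pooled``: mean difference / pooled SD of the
    two conditions.  Antisymmetric in the pair order.  Zero-SD regions are
    capped at +-``cap`` and flagged.
    """
    cond_a, cond_b = pair
    ia, ib = data.condition_index(cond_a), data.condition_index(cond_b)
    a = data.values[:, ia, :]
    b = data.values[:, ib, :]
    diff = b - a
    mean_diff = diff.mean(axis=0)
    if variant == "paired_dz":
        sd = diff.std(axis=0, ddof=1)
    elif variant == "pooled":
        sd = np.sqrt((a.var(axis=0, ddof=1) + b.var(axis=0, ddof=1)) / 2.0)
    else:
        raise ValueError(f"variant must be 'paired_dz' or 'pooled', got {variant!r}")
    degenerate = np.isclose(sd, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(degenerate, np.sign(mean_diff) * cap, mean_diff / np.where(degenerate, 1.0, sd))
    return pd.DataFrame(
        {
            "region_id": data.region_ids,
            "d": d,
            "pair": f"{cond_a} vs {cond_b}",
            "variant": variant,
            "degenerate_sd": degenerate,
        }
    )


def behavior_correlation(delta_profile: np.ndarray, delta_score: np.ndarray) -> pd.DataFrame:
    """Pearson r per region between subject-level regional change and a
    behavioral change score, with two-sided p from the t transform."""
    delta_profile = np.atleast_2d(np.asarray(delta_profile, dtype=float))
    delta_score = np.asarray(delta_score, dtype=float).ravel()
    n = delta_score.size
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if delta_profile.shape[0] != n:
        raise ValueError("delta_profile must be (subjects, regions)")
    rows = []
    score_degenerate = delta_score.std() == 0
    for j in range(delta_profile.shape[1]):
        x = delta_profile[:, j]
        if score_degenerate or x.std() == 0:
            rows.append({"region_index": j, "r": np.nan, "p": np.nan, "degenerate": True})
            continue
        r, p = stats.pearsonr(x, delta_score)
        rows.append({"region_index": j, "r": float(r), "p": float(p), "degenerate": False})
    return pd.DataFrame(rows)


def subgroup_difference(deltas: np.ndarray, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Welch two-sample comparison of condition-difference values per region.

    ``deltas`` is (subjects, regions); ``groups`` a binary label per
    subject (sex or genotype).  p-values are BH-FDR corrected across
    regions; zero-variance regions are flagged.
    """
    deltas = np.atleast_2d(np.asarray(deltas, dtype=float))
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"need exactly 2 groups, got {labels.tolist()}")
    g0 = deltas[groups == labels[0]]
    g1 = deltas[groups == labels[1]]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("each group needs at least 2 subjects")
    t_stat, p = stats.ttest_ind(g0, g1, axis=0, equal_var=False)
    degenerate = (g0.std(axis=0) == 0) & (g1.std(axis=0) == 0)
    p = np.where(degenerate, np.nan, p)
    finite = np.isfinite(p)
    q = np.full_like(p, np.nan, dtype=float)
    reject = np.zeros(p.size, dtype=bool)
    if finite.any():
        q[finite], reject[finite] = bh_fdr(p[finite], alpha=alpha)
    return pd.DataFrame(
        {
            "region_index": np.arange(deltas.shape[1]),
            "t": t_stat,
            "p": p,
            "q": q,
            "significant": reject,
            "degenerate_variance": degenerate,
        }
    )
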