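"""Inferential tests for the summary measures.

Paired/unpaired Student's t tests, one- and multi-factor repeated-measures
ANOVA, split-plot (mixed) ANOVA with one between-subjects factor, the
Greenhouse-Geisser sphericity correction, and Bonferroni adjustment of
post hoc p values.

The Greenhouse-Geisser epsilon is estimated from the eigenvalues of the
double-centered within-subject covariance,

    eps = (sum lambda_i)^2 / ((k - 1) * sum lambda_i^2),

equivalently from the covariance of orthonormal contrast scores, which is
how the multi-factor effects are handled here.  Following common practice
when the correction is applied unconditionally, numerator and denominator
degrees of freedom are both multiplied by eps before computing the
corrected p value; for two-level factors eps is identically 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    tails: int = 2


@dataclass
class AnovaResult:
    effect_name: str
    F: float
    df_num: float
    df_den: float
    epsilon_gg: float
    p_uncorrected: float
    p_gg: float
    ss_effect: float = float("nan")
    ss_error: float = float("nan")


class ZeroVarianceError(ValueError):
    """Raised when a test's error variance is exactly zero."""


def paired_t(x, y) -> TestResult:
    """Two-tailed paired Student's t test on per-subject differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D arrays, n >= 2")
    diff = x - y
    if np.all(diff == 0):
        # identical samples: no effect, trivially t = 0
        return TestResult(statistic=0.0, df=float(x.size - 1), p=1.0)
    if np.var(diff) == 0:
        raise ZeroVarianceError("paired differences have zero variance")
    res = sps.ttest_rel(x, y)
    return TestResult(statistic=float(res.statistic), df=float(x.size - 1),
                      p=float(res.pvalue))


def unpaired_t(x, y) -> TestResult:
    """Two-tailed unpaired (equal-variance) Student's t test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(x.size, y.size) < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(x) == 0 and np.var(y) == 0:
        raise ZeroVarianceError("both groups have zero variance")
    res = sps.ttest_ind(x, y)
    return TestResult(statistic=float(res.statistic),
                      df=float(x.size + y.size - 2), p=float(res.pvalue))


def _epsilon_from_covariance(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a k x k within-level covariance."""
    k = cov.shape[0]
    if k == 2:
        return 1.0
    centering = np.eye(k) - np.ones((k, k)) / k
    centered = centering @ cov @ centering
    lam = np.linalg.eigvalsh(centered)
    lam = np.clip(lam, 0.0, None)
    denom = (k - 1) * float(np.sum(lam**2))
    if denom == 0:
        raise ZeroVarianceError("degenerate (all-zero) covariance")
    eps = float(np.sum(lam)) ** 2 / denom
    return float(min(max(eps, 1.0 / (k - 1)), 1.0))


def gg_epsilon(data) -> float:
    """Greenhouse-Geisser epsilon for a subjects x levels data table."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need a 2-D subjects x levels table, n >= 2, k >= 2")
    cov = np.cov(data, rowvar=False, ddof=1)
    return _epsilon_from_covariance(np.atleast_2d(cov))


def _normalized_helmert(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (rows orthogonal to ones)."""
    h = np.zeros((k - 1, k))
    for i in range(k - 1):
        h[i, : i + 1] = 1.0
        h[i, i + 1] = -(i + 1.0)
        h[i] /= np.linalg.norm(h[i])
    return h


def _anova_from_scores(
    scores: np.ndarray, effect_name: str, apply_gg: bool
) -> AnovaResult:
    """Univariate RM-ANOVA of one effect from orthonormal contrast scores.

    ``scores`` is subjects x q (q = effect df).  SS_effect = n * ||mean||^2,
    SS_error = total squared deviation of scores from their mean; the GG
    epsilon comes from the score covariance.
    """
    n, q = scores.shape
    mean = scores.mean(axis=0)
    ss_effect = n * float(mean @ mean)
    resid = scores - mean
    ss_error = float(np.sum(resid**2))
    df_num = float(q)
    df_den = float((n - 1) * q)
    if ss_error == 0:
        raise ZeroVarianceError(f"zero residual variance for effect {effect_name}")
    F = (ss_effect / df_num) / (ss_error / df_den)
    if q == 1:
        eps = 1.0
    else:
        cov = np.cov(scores, rowvar=False, ddof=1)
        lam = np.clip(np.linalg.eigvalsh(np.atleast_2d(cov)), 0.0, None)
        eps = float(np.sum(lam)) ** 2 / (q * float(np.sum(lam**2)))
        eps = float(min(max(eps, 1.0 / q), 1.0))
    p_unc = float(sps.f.sf(F, df_num, df_den))
    p_gg = float(sps.f.sf(F, df_num * eps, df_den * eps))
    return AnovaResult(
        effect_name=effect_name,
        F=float(F),
        df_num=df_num * eps if apply_gg else df_num,
        df_den=df_den * eps if apply_gg else df_den,
        epsilon_gg=eps,
        p_uncorrected=p_unc,
        p_gg=p_gg if apply_gg else p_unc,
        ss_effect=ss_effect,
        ss_error=ss_error,
    )


def rm_anova(data, apply_gg: bool = True) -> AnovaResult:
    """One-way repeated-measures ANOVA on a subjects x levels table.

    Standard within-subject decomposition (condition, subject, residual
    sums of squares); the Greenhouse-Geisser correction multiplies both
    degrees of freedom by the estimated epsilon (identity for k = 2).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need a 2-D subjects x levels table, n >= 2, k >= 2")
    if np.isnan(data).any():
        raise ValueError("missing cells are not supported")
    scores = data @ _normalized_helmert(data.shape[1]).T
    return _anova_from_scores(scores, "condition", apply_gg)


def rm_anova_factorial(data, factor_names=None, apply_gg: bool = True) -> list:
    """Fully within-subject factorial RM-ANOVA (two or three factors).

    ``data`` has shape (n_subjects, k1, k2[, k3]); every main effect and
    interaction is tested against its own effect-by-subject error term via
    Kronecker products of orthonormal contrasts, with GG correction per
    effect.  Cells must be complete and balanced.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim < 3 or data.ndim > 4:
        raise ValueError("data must be subjects x k1 x k2 [x k3]")
    if np.isnan(data).any():
        raise ValueError("missing cells are not supported")
    n = data.shape[0]
    ks = data.shape[1:]
    names = list(factor_names) if factor_names else [
        f"F{i + 1}" for i in range(len(ks))
    ]
    if len(names) != len(ks):
        raise ValueError("factor_names length mismatch")
    flat = data.reshape(n, -1)

    results = []
    from itertools import combinations

    for r in range(1, len(ks) + 1):
        for subset in combinations(range(len(ks)), r):
            mats = [
                _normalized_helmert(k) if i in subset else
                np.ones((1, k)) / np.sqrt(k)
                for i, k in enumerate(ks)
            ]
            contrast = mats[0]
            for m in mats[1:]:
                contrast = np.kron(contrast, m)
            scores = flat @ contrast.T
            label = " x ".join(names[i] for i in subset)
            results.append(_anova_from_scores(scores, label, apply_gg))
    return results


def mixed_anova(data, groups, apply_gg: bool = True) -> list:
    """Split-plot ANOVA: one between-subjects factor, one within factor.

    ``data`` is subjects x levels; ``groups`` labels each subject's group
    (>= 2 subjects per group; unequal group sizes allowed).  Returns
    AnovaResults for the between (group) effect, the within effect, and
    the group x within interaction.  GG correction (from the pooled
    within-group covariance) applies to the within and interaction terms.
    """
    data = np.asarray(data, dtype=float)
    groups = np.asarray(groups)
    if data.ndim != 2 or data.shape[0] != groups.shape[0]:
        raise ValueError("data rows and groups must align")
    n, k = data.shape
    labels, counts = np.unique(groups, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every group needs >= 2 subjects")
    g = len(labels)

    grand = data.mean()
    subj_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    group_means = np.array([subj_means[groups == lab].mean() for lab in labels])
    cell_means = np.vstack([data[groups == lab].mean(axis=0) for lab in labels])

    ss_group = k * float(np.sum(counts * (group_means - grand) ** 2))
    ss_subj_within = k * float(
        sum(
            np.sum((subj_means[groups == lab] - gm) ** 2)
            for lab, gm in zip(labels, group_means)
        )
    )
    ss_within_total = float(np.sum((data - subj_means[:, None]) ** 2))
    ss_time = n * float(np.sum((col_means - grand) ** 2))
    inter_dev = (
        cell_means
        - group_means[:, None]
        - col_means[None, :]
        + grand
    )
    ss_inter = float(np.sum(counts[:, None] * inter_dev**2))
    ss_err_within = ss_within_total - ss_time - ss_inter

    df_group, df_subj = float(g - 1), float(n - g)
    df_time = float(k - 1)
    df_inter = float((g - 1) * (k - 1))
    df_err_w = float((n - g) * (k - 1))
    if ss_subj_within == 0 or ss_err_within <= 0:
        raise ZeroVarianceError("zero residual variance in split-plot decomposition")

    # pooled within-group covariance for the GG estimate
    pooled = np.zeros((k, k))
    for lab in labels:
        sub = data[groups == lab]
        pooled += (sub.shape[0] - 1) * np.cov(sub, rowvar=False, ddof=1)
    pooled /= n - g
    eps = _epsilon_from_covariance(pooled) if k > 2 else 1.0

    def _result(name, ss_eff, df_eff, ss_err, df_err, use_eps):
        F = (ss_eff / df_eff) / (ss_err / df_err)
        e = eps if use_eps else 1.0
        p_unc = float(sps.f.sf(F, df_eff, df_err))
        p_gg = float(sps.f.sf(F, df_eff * e, df_err * e))
        return AnovaResult(
            effect_name=name,
            F=float(F),
            df_num=df_eff * e if apply_gg else df_eff,
            df_den=df_err * e if apply_gg else df_err,
            epsilon_gg=e,
            p_uncorrected=p_unc,
            p_gg=p_gg if apply_gg else p_unc,
            ss_effect=ss_eff,
            ss_error=ss_err,
        )

    if g == 1:
        # degenerate single-group design: only the within effect is testable
        return [_result("within", ss_time, df_time, ss_err_within, df_err_w, True)]
    return [
        _result("group", ss_group, df_group, ss_subj_within, df_subj, False),
        _result("within", ss_time, df_time, ss_err_within, df_err_w, True),
        _result("group x within", ss_inter, df_inter, ss_err_within, df_err_w, True),
    ]


def bonferroni(p_values) -> list:
    """Bonferroni adjustment: p_adj = min(1, m * p)."""
    ps = list(p_values)
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p value {p} outside [0, 1]")
    m = len(ps)
    return [min(1.0, m * p) for p in ps]
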