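"""Cohort-level statistics: distributional checks, ANOVA with Bonferroni
pairwise tests, Pearson correlation, and ROC analysis with Youden's J.

The analysis plan for a three-group cohort (NC / MCI / CI): per variable,
a one-sample Kolmogorov-Smirnov test against the fitted normal per group
and Levene's test (mean-centered) for homogeneity; a one-way fixed-effects
ANOVA with three pairwise pooled-variance t-tests flagged at the
Bonferroni-corrected level alpha/3; Pearson correlations of each variable
with the cognitive score; and an empirical ROC with the operating
threshold chosen by Youden's J and a stratified-bootstrap percentile CI
for the AUC.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve

from .errors import DegenerateInputError, InvalidArgumentError

__all__ = [
    "PAIRWISE_COMPARISONS",
    "distribution_checks", "anova_bonferroni", "pearson", "roc_youden",
    "AnovaResult", "RocResult",
]

PAIRWISE_COMPARISONS = (("NC", "MCI"), ("NC", "CI"), ("MCI", "CI"))


def _as_groups(values: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {k: np.asarray(v, dtype=float) for k, v in values.items()}


def distribution_checks(values: dict[str, np.ndarray]) -> dict:
    """Normality and homogeneity p-values for per-group samples.

    Normality: one-sample Kolmogorov-Smirnov of each group against a
    normal with that group's sample mean and SD. Homogeneity: Levene's
    test (mean-centered) across groups.
    """
    groups = _as_groups(values)
    for name, x in groups.items():
        if x.size < 3:
            raise InvalidArgumentError(f"group {name!r} needs n >= 3")
        if np.std(x) == 0:
            raise DegenerateInputError(f"zero variance in group {name!r}")
    normality = {
        name: float(sps.kstest(x, "norm",
                               args=(x.mean(), x.std(ddof=1))).pvalue)
        for name, x in groups.items()
    }
    levene = sps.levene(*groups.values(), center="mean")
    return {"normality_p": normality, "levene_p": float(levene.pvalue)}


@dataclass
class AnovaResult:
    """One-way ANOVA with Bonferroni-corrected pairwise t-tests."""

    f: float
    p: float
    corrected_alpha: float
    pairwise: dict[tuple[str, str], dict] = field(default_factory=dict)


def anova_bonferroni(values: dict[str, np.ndarray],
                     family_alpha: float = 0.05,
                     welch: bool = False) -> AnovaResult:
    """One-way ANOVA plus the three pairwise comparisons.

    Pairwise tests are two-sided Student t with pooled variance (Welch by
    flag); a comparison is significant when its raw p-value is below
    family_alpha / 3 (0.0167 for the conventional 0.05).
    """
    groups = _as_groups(values)
    if len(groups) != 3:
        raise InvalidArgumentError("exactly three groups are required")
    for name, x in groups.items():
        if x.size < 2:
            raise InvalidArgumentError(f"group {name!r} needs n >= 2")
    f, p = sps.f_oneway(*groups.values())
    alpha_c = family_alpha / 3.0
    pairwise = {}
    for g1, g2 in PAIRWISE_COMPARISONS:
        if g1 not in groups or g2 not in groups:
            raise InvalidArgumentError(f"missing group {g1!r} or {g2!r}")
        t, pp = sps.ttest_ind(groups[g1], groups[g2], equal_var=not welch)
        pairwise[(g1, g2)] = {"t": float(t), "p": float(pp),
                              "significant": bool(pp < alpha_c)}
    return AnovaResult(float(f), float(p), alpha_c, pairwise)


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidArgumentError("need equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("constant input to correlation")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class RocResult:
    """ROC with Youden-optimal operating point and bootstrap AUC CI."""

    auc: float
    ci_low: float
    ci_high: float
    threshold: float
    sensitivity: float
    specificity: float


def _roc_points(scores: np.ndarray, labels: np.ndarray):
    """Empirical ROC over all distinct thresholds (higher score = positive)."""
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    return fpr, tpr, thr


def _auc_and_youden(scores: np.ndarray, labels: np.ndarray):
    fpr, tpr, thr = _roc_points(scores, labels)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = j.max()
    # tie-break: among equal J, prefer the point with higher sensitivity
    cand = np.flatnonzero(np.isclose(j, best))
    pick = cand[np.argmax(tpr[cand])]
    return auc, float(thr[pick]), float(tpr[pick]), float(1.0 - fpr[pick])


def roc_youden(
    scores: np.ndarray,
    labels: np.ndarray,
    direction: str = "higher",
    n_boot: int = 2000,
    seed: int = 0,
) -> RocResult:
    """ROC analysis with the Youden-J optimal threshold.

    ``direction`` is "higher" when larger scores indicate the positive
    class (e.g. coupling strength in impairment) and "lower" when smaller
    scores do (e.g. tissue oxygenation). The AUC confidence interval is a
    stratified-bootstrap percentile interval (default 2000 resamples,
    seeded). The returned threshold is on the original score scale; for
    direction "lower" the rule is "score <= threshold -> positive".
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise InvalidArgumentError("labels must contain both classes (0 and 1)")
    if direction not in ("higher", "lower"):
        raise InvalidArgumentError("direction must be 'higher' or 'lower'")
    s = scores if direction == "higher" else -scores

    auc, thr, sens, spec = _auc_and_youden(s, labels)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = np.concatenate([rng.choice(pos, pos.size),
                              rng.choice(neg, neg.size)])
        boots[i], *_ = _auc_and_youden(s[idx], labels[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    threshold = thr if direction == "higher" else -thr
    return RocResult(auc, float(lo), float(hi), float(threshold), sens, spec)
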