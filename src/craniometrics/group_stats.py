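"""Assumption-gated group comparison of cephalometric z-scores.

One-way ANOVA is used only when every group passes Shapiro-Wilk normality
and Levene's homogeneity-of-variance test at the gate alpha; otherwise the
Kruskal-Wallis H test.  Post hoc testing (pairwise t tests after ANOVA,
Conover-Iman rank tests after Kruskal-Wallis) is Bonferroni-adjusted over
all group pairs.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateRankError, InsufficientDataError

DEFAULT_ALPHA = 0.05


@dataclass
class PosthocResult:
    pair: tuple[str, str]
    statistic: float
    p_raw: float
    p_adjusted: float


@dataclass
class GroupComparison:
    measurement_name: str
    group_sizes: dict[str, int]
    shapiro_p: dict[str, float]
    levene_p: float
    test_used: str                 # 'anova' or 'kruskal_wallis'
    omnibus_statistic: float
    omnibus_p: float
    posthoc: list[PosthocResult] = field(default_factory=list)
    alpha: float = DEFAULT_ALPHA

    def to_dict(self) -> dict:
        return {
            "measurement": self.measurement_name,
            "groups": self.group_sizes,
            "gate": {"shapiro_p": self.shapiro_p, "levene_p": self.levene_p},
            "test_used": self.test_used,
            "omnibus_statistic": self.omnibus_statistic,
            "omnibus_p": self.omnibus_p,
            "alpha": self.alpha,
            "posthoc": [
                {"pair": list(p.pair), "statistic": p.statistic,
                 "p_raw": p.p_raw, "p_adjusted": p.p_adjusted}
                for p in self.posthoc
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _as_groups(groups) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float) for g in groups]
    if len(out) < 2:
        raise InsufficientDataError("need at least 2 groups")
    for g in out:
        if len(g) < 3:
            raise InsufficientDataError("every group needs n >= 3")
    return out


def select_test(groups, alpha: float = DEFAULT_ALPHA):
    """Gate: ANOVA iff all Shapiro-Wilk p >= alpha and Levene p >= alpha,
    else Kruskal-Wallis.  Returns (test_name, shapiro_p list, levene_p)."""
    arrs = _as_groups(groups)
    shapiro_p = []
    for g in arrs:
        if np.ptp(g) < 1e-12:
            shapiro_p.append(0.0)  # constant sample: normality untestable, fail gate
            continue
        shapiro_p.append(float(stats.shapiro(g).pvalue))
    try:
        levene_p = float(stats.levene(*arrs).pvalue)
    except Exception:
        levene_p = 0.0
    if all(p >= alpha for p in shapiro_p) and levene_p >= alpha:
        return "anova", shapiro_p, levene_p
    return "kruskal_wallis", shapiro_p, levene_p


def conover_posthoc(groups, labels=None) -> list[PosthocResult]:
    """Conover-Iman pairwise rank comparisons after Kruskal-Wallis.

    t_ij = (Rbar_i - Rbar_j) / sqrt(S^2 * (N - 1 - H) / (N - k) * (1/n_i + 1/n_j))
    with midranks over the pooled sample, S^2 the variance of all ranks, H
    the (tie-corrected) Kruskal-Wallis statistic; two-sided p from Student t
    with N - k degrees of freedom.  p_adjusted applies Bonferroni over all
    pairs.
    """
    arrs = _as_groups(groups)
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(arrs))]
    pooled = np.concatenate(arrs)
    n_total = len(pooled)
    k = len(arrs)
    if np.ptp(pooled) < 1e-12:
        raise DegenerateRankError("all observations tied; ranks are degenerate")
    ranks = stats.rankdata(pooled)  # midranks
    sizes = [len(g) for g in arrs]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(k)]

    s2 = ranks.var(ddof=1)
    h_stat = float(stats.kruskal(*arrs).statistic)
    scale = s2 * (n_total - 1.0 - h_stat) / (n_total - k)
    scale = max(scale, 0.0)
    df = n_total - k

    n_pairs = k * (k - 1) // 2
    results = []
    for i, j in itertools.combinations(range(k), 2):
        denom = np.sqrt(scale * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if denom <= 0:
            t_val, p_raw = 0.0, 1.0
        else:
            t_val = (mean_ranks[i] - mean_ranks[j]) / denom
            p_raw = 2.0 * float(stats.t.sf(abs(t_val), df))
        results.append(PosthocResult(
            pair=(labels[i], labels[j]), statistic=float(t_val),
            p_raw=min(p_raw, 1.0), p_adjusted=min(1.0, p_raw * n_pairs)))
    return results


def pairwise_t_posthoc(groups, labels=None) -> list[PosthocResult]:
    """Pairwise two-sided t tests with Bonferroni adjustment (after ANOVA)."""
    arrs = _as_groups(groups)
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(arrs))]
    n_pairs = len(arrs) * (len(arrs) - 1) // 2
    results = []
    for i, j in itertools.combinations(range(len(arrs)), 2):
        res = stats.ttest_ind(arrs[i], arrs[j])
        results.append(PosthocResult(
            pair=(labels[i], labels[j]), statistic=float(res.statistic),
            p_raw=float(res.pvalue),
            p_adjusted=min(1.0, float(res.pvalue) * n_pairs)))
    return results


def compare_groups(groups_by_label: dict, measurement_name: str,
                   alpha: float = DEFAULT_ALPHA) -> GroupComparison:
    """Full gated comparison of one measurement across labeled groups.

    Post hoc tests run only when the omnibus test rejects at ``alpha``.
    """
    labels = list(groups_by_label)
    arrs = _as_groups([groups_by_label[lb] for lb in labels])
    test_used, shapiro_p, levene_p = select_test(arrs, alpha)
    if test_used == "anova":
        omnibus = stats.f_oneway(*arrs)
    else:
        try:
            omnibus = stats.kruskal(*arrs)
        except ValueError as exc:  # all values identical
            raise DegenerateRankError(str(exc)) from exc
    omnibus_stat = float(omnibus.statistic)
    omnibus_p = float(omnibus.pvalue)
    posthoc: list[PosthocResult] = []
    if omnibus_p < alpha:
        if test_used == "anova":
            posthoc = pairwise_t_posthoc(arrs, labels)
        else:
            posthoc = conover_posthoc(arrs, labels)
    return GroupComparison(
        measurement_name=measurement_name,
        group_sizes={lb: len(groups_by_label[lb]) for lb in labels},
        shapiro_p=dict(zip(labels, shapiro_p)),
        levene_p=levene_p,
        test_used=test_used,
        omnibus_statistic=omnibus_stat,
        omnibus_p=omnibus_p,
        posthoc=posthoc,
        alpha=alpha,
    )
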