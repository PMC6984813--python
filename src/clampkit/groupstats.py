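"""Normality-driven statistical test selection with FDR-corrected post hocs.

Normality is assessed per group with the Anderson-Darling test; normal
data route to the t-test family (one-way ANOVA + Tukey HSD for k groups)
and are summarized as mean ± s.e.m., non-normal data route to rank tests
(Wilcoxon signed-rank / Mann-Whitney U / Kruskal-Wallis with Mann-Whitney
post hocs, Benjamini-Hochberg corrected) and are summarized as median and
IQR.  All tests are two-tailed at alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05

DESIGNS = ("one_sample", "two_group", "k_group", "distribution")


@dataclass
class ComparisonSpec:
    groups: dict[str, np.ndarray]
    paired: bool = False
    design: str = "two_group"

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
        if self.paired:
            sizes = {v.size for v in self.groups.values()}
            if len(sizes) != 1:
                raise ValueError("paired design requires equal group lengths")


@dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    alpha_used: float
    significant: bool
    summary_style: str  # "mean±sem" or "median+IQR"
    group_summaries: dict[str, str] = field(default_factory=dict)
    posthoc: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def anderson_normal(x: np.ndarray, alpha: float = ALPHA) -> bool:
    """True if the Anderson-Darling test does not reject normality."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 observations for normality assessment")
    if np.std(x) == 0:
        return False  # degenerate sample; route to rank tests
    with warnings.catch_warnings():
        # scipy >= 1.17 warns about a future API change; the critical-value
        # interface used here is the current stable one
        warnings.simplefilter("ignore", FutureWarning)
        res = stats.anderson(x, dist="norm")
    crit = dict(zip(res.significance_level, res.critical_values))
    return bool(res.statistic < crit[100 * alpha])


def _summarize(x: np.ndarray, normal: bool) -> str:
    if normal:
        sem = np.std(x, ddof=1) / np.sqrt(x.size) if x.size > 1 else 0.0
        return f"{np.mean(x):.4g} ± {sem:.4g}"
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.4g} [{q1:.4g}/{q3:.4g}]"


def select_and_run(spec: ComparisonSpec, alpha: float = ALPHA) -> ComparisonResult:
    """Route a comparison to the paper's test-selection policy and run it."""
    groups = list(spec.groups.values())
    names = list(spec.groups.keys())

    if spec.design == "distribution":
        if len(groups) != 2:
            raise ValueError("distribution design takes two groups")
        stat, p = stats.ks_2samp(groups[0], groups[1])
        return _result("Kolmogorov-Smirnov", stat, p, alpha, spec, normal=False)

    normal = all(anderson_normal(g, alpha) for g in groups)

    if spec.design == "one_sample":
        (x,) = groups
        if normal:
            stat, p = stats.ttest_1samp(x, 0.0)
            return _result("one-sample t-test", stat, p, alpha, spec, normal)
        stat, p = stats.wilcoxon(x)
        return _result("Wilcoxon signed-rank", stat, p, alpha, spec, normal)

    if spec.design == "two_group":
        a, b = groups
        if normal:
            if spec.paired:
                stat, p = stats.ttest_rel(a, b)
                return _result("paired t-test", stat, p, alpha, spec, normal)
            stat, p = stats.ttest_ind(a, b)
            return _result("unpaired t-test", stat, p, alpha, spec, normal)
        if spec.paired:
            stat, p = stats.wilcoxon(a, b)
            return _result("Wilcoxon signed-rank", stat, p, alpha, spec, normal)
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        return _result("Mann-Whitney U", stat, p, alpha, spec, normal)

    # k_group
    if len(groups) < 3:
        raise ValueError("k_group design needs >= 3 groups")
    if normal:
        stat, p = stats.f_oneway(*groups)
        res = _result("one-way ANOVA", stat, p, alpha, spec, normal)
        if res.significant:
            flat = np.concatenate(groups)
            lab = np.concatenate([[n] * len(g) for n, g in zip(names, groups)])
            tk = pairwise_tukeyhsd(flat, lab, alpha=alpha)
            res.posthoc = pd.DataFrame(
                tk.summary().data[1:], columns=tk.summary().data[0]
            )
        return res
    stat, p = stats.kruskal(*groups)
    res = _result("Kruskal-Wallis", stat, p, alpha, spec, normal)
    if res.significant:
        rows = []
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                u, pp = stats.mannwhitneyu(
                    groups[i], groups[j], alternative="two-sided"
                )
                rows.append({"group1": names[i], "group2": names[j],
                             "statistic": u, "p": pp})
        ph = pd.DataFrame(rows)
        sig, alpha_fdr = fdr_adjust(ph["p"].to_numpy(), alpha)
        ph["significant"], ph["alpha_fdr"] = sig, alpha_fdr
        res.posthoc = ph
    return res


def _result(name, stat, p, alpha, spec, normal) -> ComparisonResult:
    return ComparisonResult(
        test_name=name,
        statistic=float(stat),
        p_value=float(p),
        alpha_used=alpha,
        significant=bool(p < alpha),
        summary_style="mean±sem" if normal else "median+IQR",
        group_summaries={
            k: _summarize(v, normal) for k, v in spec.groups.items()
        },
    )


def fdr_adjust(
    p_values: np.ndarray, alpha: float = ALPHA
) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up; returns (significance flags, alpha_FDR).

    alpha_FDR is the effective per-test threshold (k/m)·alpha where k is the
    largest rank with p_(k) ≤ (k/m)·alpha (0 when nothing is significant).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values outside [0, 1]")
    reject = multipletests(p, alpha=alpha, method="fdr_bh")[0]
    m = p.size
    order = np.sort(p)
    ranks = np.arange(1, m + 1)
    passing = np.nonzero(order <= ranks / m * alpha)[0]
    alpha_fdr = float((passing[-1] + 1) / m * alpha) if passing.size else 0.0
    return reject, alpha_fdr


def comparisons_to_csv(results: dict[str, ComparisonResult], path) -> pd.DataFrame:
    """Tidy per-comparison table (group, n, summary, test, p, alpha)."""
    rows = []
    for name, res in results.items():
        for g, summary in res.group_summaries.items():
            rows.append(
                {
                    "comparison": name,
                    "group": g,
                    "summary": summary,
                    "summary_style": res.summary_style,
                    "test": res.test_name,
                    "statistic": res.statistic,
                    "p": res.p_value,
                    "alpha": res.alpha_used,
                    "significant": res.significant,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
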