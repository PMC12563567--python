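"""Normality-gated group comparison with multiple-comparison correction.

The protocol: test every group with the D'Agostino & Pearson omnibus
normality test.  If all groups pass (p >= alpha_normality), compare with a
two-tailed unpaired t-test (2 groups) or one-way ANOVA with Dunnett's
vs-control multiple comparisons (>2 groups).  If any group fails — or is too
small for the omnibus test — fall back to Mann-Whitney (2 groups) or
Kruskal-Wallis with Dunn's vs-control multiple comparisons (>2 groups).

P-values map to asterisk categories:
    < 0.0001 "****"; 0.0001–0.001 "***"; 0.001–0.01 "**"; 0.01–0.05 "*";
    >= 0.05 "ns",
with boundary values assigned to the less-significant bin.

Dunnett is delegated to ``scipy.stats.dunnett``.  Dunn's test is implemented
here (rank z-statistic with tie correction, Bonferroni-adjusted over the
vs-control comparisons) and identified in results as
``dunn-z-bonferroni(vespos)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

log = logging.getLogger("vespos")

#: minimum group size for the D'Agostino & Pearson omnibus test
MIN_N_NORMALITY = 8

STAR_BINS = (
    (1e-4, "****"),
    (1e-3, "***"),
    (1e-2, "**"),
    (5e-2, "*"),
)


def star_category(p: float) -> str:
    """Map a p-value to the asterisk notation, boundaries to the weaker bin."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    for bound, stars in STAR_BINS:
        if p < bound:
            return stars
    return "ns"


@dataclass
class ComparisonPlan:
    """Named per-group value lists with a designated control group."""

    metric: str
    control: str
    groups: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, float) for k, v in self.groups.items()}
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        if self.control not in self.groups:
            raise ValueError(f"control group {self.control!r} not among groups")
        for name, vals in self.groups.items():
            if vals.size < 3:
                raise ValueError(f"group {name!r} has < 3 values")

    @property
    def treatments(self) -> list[str]:
        return [g for g in self.groups if g != self.control]


@dataclass
class PairResult:
    treatment: str
    p_value: float
    stars: str


@dataclass
class ComparisonResult:
    metric: str
    test_name: str
    parametric: bool
    normality_p: dict[str, float]
    normality_ok: dict[str, bool]
    pairs: list[PairResult]
    omnibus_p: float | None = None
    notes: str = ""


def _normality(values: np.ndarray, alpha: float):
    """(p, passed, testable) from the D'Agostino & Pearson omnibus test."""
    if values.size < MIN_N_NORMALITY:
        return float("nan"), False, False
    with warnings.catch_warnings():
        # the omnibus kurtosis component warns below n=20; the protocol
        # applies it at n=10 regardless
        warnings.simplefilter("ignore")
        p = float(stats.normaltest(values).pvalue)
    return p, p >= alpha, True


def _dunn_vs_control(groups: dict[str, np.ndarray], control: str) -> dict[str, float]:
    """Dunn's rank z-test of each treatment vs control, Bonferroni-adjusted.

    Uses the pooled ranks of all groups with the standard tie correction
    sum(t^3 - t) / (12 (N - 1)); two-sided normal p-values multiplied by the
    number of vs-control comparisons (capped at 1).
    """
    names = list(groups)
    all_vals = np.concatenate([groups[g] for g in names])
    ranks = stats.rankdata(all_vals)
    n = {g: groups[g].size for g in names}
    mean_rank = {}
    i = 0
    for g in names:
        mean_rank[g] = ranks[i:i + n[g]].mean()
        i += n[g]
    big_n = all_vals.size
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_corr = float(((tie_counts ** 3 - tie_counts).sum()) / (12.0 * (big_n - 1)))
    var_base = big_n * (big_n + 1) / 12.0 - tie_corr
    k = len(names) - 1  # vs-control comparisons
    out = {}
    for g in names:
        if g == control:
            continue
        se = np.sqrt(var_base * (1.0 / n[g] + 1.0 / n[control]))
        z = (mean_rank[g] - mean_rank[control]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        out[g] = min(1.0, p * k)
    return out


def choose_and_run(plan: ComparisonPlan, alpha_normality: float = 0.05,
                   ) -> ComparisonResult:
    """Run the normality-gated comparison protocol on a plan.

    Returns per-pair (treatment vs control) p-values with star categories,
    the chosen test's name, and the per-group normality verdicts.  Groups too
    small for the omnibus test are flagged in ``notes`` and force the
    nonparametric branch.
    """
    normality_p, normality_ok, notes = {}, {}, []
    for name, vals in plan.groups.items():
        p, ok, testable = _normality(vals, alpha_normality)
        normality_p[name], normality_ok[name] = p, ok
        if not testable:
            notes.append(f"group {name!r} too small for normality test "
                         f"(n={vals.size} < {MIN_N_NORMALITY}); "
                         "nonparametric fallback")
    parametric = all(normality_ok.values())
    ctrl = plan.groups[plan.control]
    treatments = plan.treatments
    omnibus_p = None

    if parametric:
        if len(treatments) == 1:
            t = treatments[0]
            p = float(stats.ttest_ind(plan.groups[t], ctrl).pvalue)
            pairs = [PairResult(t, p, star_category(p))]
            test_name = "unpaired two-tailed t-test"
        else:
            samples = [plan.groups[t] for t in treatments]
            omnibus_p = float(stats.f_oneway(ctrl, *samples).pvalue)
            dres = stats.dunnett(*samples, control=ctrl)
            pairs = [PairResult(t, float(p), star_category(float(p)))
                     for t, p in zip(treatments, np.atleast_1d(dres.pvalue))]
            test_name = "one-way ANOVA + Dunnett (scipy.stats.dunnett)"
    else:
        if len(treatments) == 1:
            t = treatments[0]
            p = float(stats.mannwhitneyu(plan.groups[t], ctrl,
                                         alternative="two-sided").pvalue)
            pairs = [PairResult(t, p, star_category(p))]
            test_name = "Mann-Whitney U"
        else:
            omnibus_p = float(stats.kruskal(ctrl, *[plan.groups[t]
                                                    for t in treatments]).pvalue)
            dunn = _dunn_vs_control(plan.groups, plan.control)
            pairs = [PairResult(t, dunn[t], star_category(dunn[t]))
                     for t in treatments]
            test_name = "Kruskal-Wallis + Dunn [dunn-z-bonferroni(vespos)]"

    result = ComparisonResult(
        metric=plan.metric, test_name=test_name, parametric=parametric,
        normality_p=normality_p, normality_ok=normality_ok, pairs=pairs,
        omnibus_p=omnibus_p, notes="; ".join(notes),
    )
    log.info("compare[%s]: %s; pairs=%s", plan.metric, test_name,
             [(pr.treatment, round(pr.p_value, 6), pr.stars) for pr in pairs])
    return result


def result_table(result: ComparisonResult):
    """Flat per-pair table (treatment, p_value, stars, test)."""
    import pandas as pd

    return pd.DataFrame([
        {"metric": result.metric, "treatment": pr.treatment,
         "p_value": pr.p_value, "stars": pr.stars, "test": result.test_name,
         "parametric": result.parametric}
        for pr in result.pairs
    ])
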