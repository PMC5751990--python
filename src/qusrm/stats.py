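"""Normality-gated group comparisons and recurrence-free survival.

Two- and multi-group comparisons first run a Shapiro-Wilk test on every
group at alpha = 0.05: when all groups look normal a parametric test runs
(unpaired t-test / one-way ANOVA), otherwise the rank-based alternative
(Mann-Whitney U / Kruskal-Wallis).  Post-hoc pairwise p-values can be
Bonferroni corrected (multiplied by the number of comparisons, capped at
one).  Survival uses the Kaplan-Meier product-limit estimator with right
censoring, and the log-rank test for curve comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

__all__ = [
    "TestResult",
    "SurvivalRecord",
    "KMResult",
    "two_group_test",
    "multi_group_test",
    "km_estimate",
    "logrank_compare",
]

SHAPIRO_ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    corrected: bool = False
    normal_gate_passed: bool | None = None


@dataclass(frozen=True)
class SurvivalRecord:
    time: float   # months
    event: bool   # recurrence observed
    group: str = ""

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("survival time must be >= 0")


@dataclass
class KMResult:
    survival: pd.Series        # step-function values indexed by time
    fitter: KaplanMeierFitter

    def at(self, t: float) -> float:
        """Survivor-function value S(t)."""
        return float(self.fitter.predict(t))


def _gate_normal(groups: list[np.ndarray]) -> bool:
    return all(sps.shapiro(g).pvalue >= SHAPIRO_ALPHA for g in groups)


def two_group_test(x, y, welch: bool = False) -> TestResult:
    """Shapiro-Wilk-gated two-sample comparison.

    Both samples normal at alpha = 0.05 -> unpaired t-test (equal-variance
    by default, Welch behind the flag); otherwise Mann-Whitney U.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample needs n >= 3 for the normality gate")
    normal = _gate_normal([x, y])
    if normal:
        res = sps.ttest_ind(x, y, equal_var=not welch)
        name = "welch_t" if welch else "t"
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
        name = "mannwhitney"
    return TestResult(name, float(res.statistic), float(res.pvalue),
                      (len(x), len(y)), normal_gate_passed=normal)


def bonferroni(p_values) -> list[float]:
    """Multiply each p by the number of comparisons, capped at 1."""
    m = len(p_values)
    return [min(1.0, float(p) * m) for p in p_values]


def multi_group_test(groups, correct: bool = False) -> TestResult:
    """Gated comparison of three or more groups.

    All groups normal -> one-way ANOVA, else Kruskal-Wallis.  With
    ``correct`` set, Bonferroni-corrected post-hoc pairwise results are
    attached via the returned object's ``pairwise`` attribute.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 3:
        raise ValueError("use two_group_test for fewer than 3 groups")
    if any(len(g) < 3 for g in gs):
        raise ValueError("each group needs n >= 3 for the normality gate")
    normal = _gate_normal(gs)
    if normal:
        res = sps.f_oneway(*gs)
        name = "anova"
    else:
        res = sps.kruskal(*gs)
        name = "kruskal"
    result = TestResult(name, float(res.statistic), float(res.pvalue),
                        tuple(len(g) for g in gs), corrected=correct,
                        normal_gate_passed=normal)
    if correct:
        raw = []
        pairs = []
        for i in range(len(gs)):
            for j in range(i + 1, len(gs)):
                raw.append(two_group_test(gs[i], gs[j]).p_value)
                pairs.append((i, j))
        corrected_p = bonferroni(raw)
        object.__setattr__(result, "_pairwise",
                           dict(zip(pairs, corrected_p)))
    return result


def pairwise_p(result: TestResult) -> dict[tuple[int, int], float]:
    """Bonferroni-corrected post-hoc pairwise p-values, if computed."""
    return getattr(result, "_pairwise", {})


def km_estimate(records: list[SurvivalRecord]) -> KMResult:
    """Kaplan-Meier product-limit estimate for one group."""
    if not records:
        raise ValueError("need at least one survival record")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    surv = kmf.survival_function_["KM_estimate"]
    return KMResult(survival=surv, fitter=kmf)


def logrank_compare(groups: dict[str, list[SurvivalRecord]]) -> TestResult:
    """Joint log-rank comparison of two or more survival curves."""
    if len(groups) < 2:
        raise ValueError("log-rank needs at least two groups")
    if any(len(v) == 0 for v in groups.values()):
        raise ValueError("every group needs at least one subject")
    times, events, labels = [], [], []
    for name, recs in groups.items():
        times += [r.time for r in recs]
        events += [int(r.event) for r in recs]
        labels += [name] * len(recs)
    res = multivariate_logrank_test(np.asarray(times), np.asarray(labels),
                                    np.asarray(events))
    return TestResult("logrank", float(res.test_statistic),
                      float(res.p_value),
                      tuple(len(v) for v in groups.values()))
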