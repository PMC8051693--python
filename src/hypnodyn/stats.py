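"""Paired statistical machinery for within-subject treatment comparisons.

Thin, contract-checked wrappers over scipy.stats, statsmodels and
lifelines: paired t (one/two-tailed with a pre-registered direction),
Wilcoxon signed-rank (exact for small n), Benjamini-Hochberg FDR,
two-sample Kolmogorov-Smirnov, Spearman rank correlation, and
Kaplan-Meier + log-rank survival analysis of (possibly censored)
sleep-onset latencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairedSample",
    "SurvivalSample",
    "paired_t",
    "wilcoxon_signed_rank",
    "benjamini_hochberg",
    "ks_two_sample",
    "spearman",
    "km_logrank",
]


@dataclass
class PairedSample:
    """Subject-aligned (control, treatment) value pairs.

    Pairs where either side is missing (NaN) are excluded and counted in
    ``n_dropped``; at least two complete pairs are required for any test.
    """

    control: np.ndarray
    treatment: np.ndarray
    n_dropped: int = 0

    def __post_init__(self):
        c = np.asarray(self.control, dtype=float)
        t = np.asarray(self.treatment, dtype=float)
        if c.shape != t.shape:
            raise ValueError("control and treatment must be the same length")
        keep = np.isfinite(c) & np.isfinite(t)
        self.n_dropped = int((~keep).sum())
        self.control = c[keep]
        self.treatment = t[keep]
        if self.control.size < 2:
            raise ValueError("need >= 2 complete pairs")

    @property
    def differences(self) -> np.ndarray:
        return self.treatment - self.control


def _alternative(tails: str, direction: str) -> str:
    if tails == "two":
        return "two-sided"
    if tails != "one":
        raise ValueError("tails must be 'one' or 'two'")
    if direction not in ("greater", "less"):
        raise ValueError("one-tailed tests need direction 'greater' or 'less' "
                         "(treatment vs control), set by design, never by data")
    return direction


def paired_t(s: PairedSample, tails: str = "two",
             direction: str = "greater") -> Tuple[float, int, float]:
    """Paired t test on treatment - control differences.

    Returns ``(t, df, p)``. One-tailed p is in the pre-registered
    ``direction``. Zero difference variance is an error (t undefined).
    """
    d = s.differences
    if np.std(d, ddof=1) == 0:
        if d[0] == 0:  # identical arms: t = 0; p = 1 (two-) or 0.5 (one-tailed)
            return 0.0, d.size - 1, 1.0 if tails == "two" else 0.5
        raise ValueError("zero variance of differences; t test undefined")
    res = sst.ttest_rel(s.treatment, s.control,
                        alternative=_alternative(tails, direction))
    return float(res.statistic), int(d.size - 1), float(res.pvalue)


def wilcoxon_signed_rank(s: PairedSample, tails: str = "two",
                         direction: str = "greater") -> Tuple[float, float]:
    """Wilcoxon matched-pairs signed-rank test on the paired differences.

    Exact null distribution for n <= 25 (no ties), normal approximation
    beyond; zero differences are dropped (standard practice). Returns
    ``(W, p)`` with W the signed-rank sum statistic.
    """
    d = s.differences
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    method = "exact" if d.size <= 25 else "approx"
    res = sst.wilcoxon(d, alternative=_alternative(tails, direction),
                       method=method)
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(pvals: Sequence[float], q: float = 0.05):
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(reject, p_adjusted)``; adjusted p-values are monotone
    nondecreasing in the rank of the raw p-value.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (sup-distance of empirical CDFs)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sst.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def spearman(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman rank correlation with tie-corrected ranks; needs n >= 4."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need n >= 4 for a meaningful rank correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has undefined rank correlation")
    res = sst.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class SurvivalSample:
    """Per-subject time-to-event data for latency survival analysis.

    ``times`` in seconds; ``censored[i]`` True if the state never occurred
    (time then equals the recording duration); ``arm`` labels control vs
    treatment.
    """

    times: np.ndarray
    censored: np.ndarray
    arm: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        self.arm = np.asarray(self.arm)
        if not (len(self.times) == len(self.censored) == len(self.arm)):
            raise ValueError("times, censored, arm must align")
        if np.any(self.times < 0):
            raise ValueError("times must be >= 0")


def km_logrank(sample: SurvivalSample):
    """Kaplan-Meier curves per arm plus a two-arm log-rank test.

    Curves are reported as the probability of the state *not yet* having
    occurred at each time. Returns ``(curves, statistic, p)`` where
    ``curves`` maps arm -> DataFrame(time_s, prob_no_event).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    arms = list(dict.fromkeys(sample.arm.tolist()))
    curves = {}
    per_arm = {}
    for arm in arms:
        m = sample.arm == arm
        if not m.any():
            raise ValueError(f"arm {arm!r} has no subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(sample.times[m], event_observed=~sample.censored[m])
        sf = kmf.survival_function_
        curves[arm] = pd.DataFrame({
            "time_s": sf.index.values,
            "prob_no_event": sf.iloc[:, 0].values,
        })
        per_arm[arm] = m
    stat = p = np.nan
    if len(arms) == 2:
        a, b = arms
        res = logrank_test(
            sample.times[per_arm[a]], sample.times[per_arm[b]],
            event_observed_A=~sample.censored[per_arm[a]],
            event_observed_B=~sample.censored[per_arm[b]],
        )
        stat, p = float(res.test_statistic), float(res.p_value)
    return curves, stat, p
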