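"""Summary statistics and two-sample comparisons from summary data.

All values in this pipeline are quoted mean +- SEM with n, so comparisons
are computed directly from those triplets.  The default test is Welch's
unequal-variance t-test with Welch-Satterthwaite degrees of freedom — the
defensible choice for the very unequal group sizes and variances that
single-channel datasets produce — with the pooled-variance Student form
available via ``pooled=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class SampleSummary:
    mean: float
    sem: float
    n: int


@dataclass(frozen=True)
class TestResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    degenerate: bool = False  # both SEMs zero with unequal means


def summarize(values) -> SampleSummary:
    """Mean, SEM (sd with n-1 denominator over sqrt n) and n of a sample."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to summarize")
    return SampleSummary(mean=float(v.mean()),
                         sem=float(v.std(ddof=1) / math.sqrt(v.size)),
                         n=int(v.size))


def welch_t(a: SampleSummary, b: SampleSummary, pooled: bool = False) -> TestResult:
    """Two-sided t-test from summary statistics.

    t = (mean_a - mean_b) / sqrt(sem_a^2 + sem_b^2) with Welch-Satterthwaite
    degrees of freedom (or the pooled-variance Student form when
    ``pooled=True``).  Degenerate zero-variance inputs: equal means give
    t=0, p=1; unequal means give p=0 with the result flagged.
    """
    for s in (a, b):
        if s.n < 2:
            raise ValueError("both samples need n >= 2")
    if a.sem == 0.0 and b.sem == 0.0:
        if a.mean == b.mean:
            return TestResult(0.0, float(a.n + b.n - 2), 1.0)
        return TestResult(math.copysign(math.inf, a.mean - b.mean),
                          float(a.n + b.n - 2), 0.0, degenerate=True)
    sd_a = a.sem * math.sqrt(a.n)
    sd_b = b.sem * math.sqrt(b.n)
    if pooled:
        df = float(a.n + b.n - 2)
        sp2 = ((a.n - 1) * sd_a ** 2 + (b.n - 1) * sd_b ** 2) / df
        se = math.sqrt(sp2 * (1 / a.n + 1 / b.n))
    else:
        va, vb = a.sem ** 2, b.sem ** 2
        se = math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    t = (a.mean - b.mean) / se
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult(float(t), float(df), p)
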