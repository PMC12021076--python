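"""Statistical comparisons used on the pipeline's outputs.

Three procedures, matching common practice for this kind of quantification:
a pooled-variance two-tailed Student's t test for two independent groups, a
one-sample t test for data normalized to control (reference 1), and one-way
ANOVA followed by Tukey's HSD for three or more groups. Significance is
conventionally read at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import SampleSizeError

__all__ = ["TestResult", "two_sample_t", "one_sample_t", "anova_tukey"]


@dataclass
class TestResult:
    """Outcome of one statistical test, with the Tukey table for ANOVA."""

    test: str
    statistic: float
    df: float
    p_value: float
    group_labels: Sequence[str] = ()
    tukey: Optional[pd.DataFrame] = None
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _check_group(values, min_n: int, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < min_n:
        raise SampleSizeError(f"{name} needs at least {min_n} values")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def two_sample_t(group_a, group_b, labels=("A", "B")) -> TestResult:
    """Pooled-variance two-tailed Student's t test; df = nA + nB − 2."""
    a = _check_group(group_a, 2, "group_a")
    b = _check_group(group_b, 2, "group_b")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return TestResult(
        test="two_sample_t",
        statistic=float(t),
        df=float(a.size + b.size - 2),
        p_value=float(p),
        group_labels=tuple(labels),
    )


def one_sample_t(values, reference: float = 1.0) -> TestResult:
    """Two-tailed one-sample t test against a reference; df = n − 1.

    Intended for data normalized to the control condition (reference 1).
    Zero variance with mean off the reference yields an infinite statistic
    and a p-value reported at the machine floor, flagged in ``note``.
    """
    x = _check_group(values, 2, "values")
    if np.ptp(x) == 0:
        if x[0] == reference:
            return TestResult("one_sample_t", 0.0, float(x.size - 1), 1.0)
        return TestResult(
            "one_sample_t",
            float(np.sign(x[0] - reference)) * np.inf,
            float(x.size - 1),
            np.finfo(float).tiny,
            note="zero variance: statistic infinite, p at machine floor",
        )
    t, p = sps.ttest_1samp(x, popmean=reference)
    return TestResult(
        test="one_sample_t",
        statistic=float(t),
        df=float(x.size - 1),
        p_value=float(p),
    )


def anova_tukey(groups: Sequence, labels: Optional[Sequence[str]] = None) -> TestResult:
    """One-way ANOVA F test followed by Tukey's HSD pairwise comparisons.

    Adjusted pairwise p-values come from the studentized-range
    distribution. Requires at least three groups of at least two values;
    with fewer groups, use :func:`two_sample_t`.
    """
    if len(groups) < 3:
        raise SampleSizeError(
            "anova_tukey needs >= 3 groups; use two_sample_t for 2"
        )
    arrays = [
        _check_group(g, 2, f"group {i}") for i, g in enumerate(groups)
    ]
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    f, p = sps.f_oneway(*arrays)
    n_total = sum(a.size for a in arrays)
    df_between = len(arrays) - 1
    df_within = n_total - len(arrays)
    hsd = sps.tukey_hsd(*arrays)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            rows.append({
                "group_1": labels[i],
                "group_2": labels[j],
                "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                "p_adj": float(hsd.pvalue[i, j]),
            })
    return TestResult(
        test="anova_tukey",
        statistic=float(f),
        df=float(df_between),
        p_value=float(p),
        group_labels=tuple(labels),
        tukey=pd.DataFrame(rows),
        note=f"df_between={df_between}, df_within={df_within}",
    )
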