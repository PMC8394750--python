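"""Divergent-group assignment for extreme-phenotype contrasts.

Animals are split into LOW and HIGH subsets of a trait by explicit kg
thresholds (or by quantiles), and the separation of group means is
verified with a two-sample Student t-test before any genomic contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

TRAITS = ("birth_weight", "weaning_weight")

LOW, HIGH, EXCLUDED = "LOW", "HIGH", "EXCLUDED"


@dataclass
class GroupAssignment:
    """Per-sample LOW/HIGH/EXCLUDED labels for one trait, with the t-test."""

    trait: str
    labels: pd.Series  # index-aligned with the cohort's samples frame
    low_threshold: float
    high_threshold: float
    t_statistic: float
    t_p_value: float

    @property
    def low_indices(self) -> np.ndarray:
        return np.flatnonzero((self.labels == LOW).to_numpy())

    @property
    def high_indices(self) -> np.ndarray:
        return np.flatnonzero((self.labels == HIGH).to_numpy())

    @property
    def n_low(self) -> int:
        return len(self.low_indices)

    @property
    def n_high(self) -> int:
        return len(self.high_indices)


def two_sample_t_test(low_values, high_values, welch: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test on group means.

    Pooled-variance Student test by default (``welch=True`` drops the
    equal-variance assumption).  With zero pooled variance the test is
    degenerate: p = 0 if the means differ, 1 otherwise (warned).
    """
    low = np.asarray(low_values, dtype=float)
    high = np.asarray(high_values, dtype=float)
    if len(low) < 2 or len(high) < 2:
        raise ValueError("each group needs >=2 values for a t-test")
    if np.var(low, ddof=1) == 0 and np.var(high, ddof=1) == 0:
        log.warning("zero variance in both groups; degenerate t-test")
        same = low.mean() == high.mean()
        return (0.0, 1.0) if same else (np.inf * np.sign(high.mean() - low.mean()), 0.0)
    t, p = sps.ttest_ind(high, low, equal_var=not welch)
    return float(t), float(p)


def assign_extreme_groups(
    samples: pd.DataFrame,
    trait: str,
    low_threshold: float | None = None,
    high_threshold: float | None = None,
    low_quantile: float | None = None,
    high_quantile: float | None = None,
    welch: bool = False,
) -> GroupAssignment:
    """Label each sample LOW (value <= low threshold), HIGH (>= high) or EXCLUDED.

    Thresholds are given either directly in kg or as quantiles of the
    recorded trait values (``low_quantile``/``high_quantile``).  Samples
    with no recorded trait value are EXCLUDED.  Both groups must end up
    with at least 2 members.
    """
    if trait not in TRAITS:
        raise ValueError(f"unknown trait {trait!r}; expected one of {TRAITS}")
    values = samples[trait].to_numpy(dtype=float)
    if low_threshold is None or high_threshold is None:
        if low_quantile is None or high_quantile is None:
            raise ValueError("provide kg thresholds or quantiles for both sides")
        low_threshold = float(np.nanquantile(values, low_quantile))
        high_threshold = float(np.nanquantile(values, high_quantile))
    if not low_threshold < high_threshold:
        raise ValueError(
            f"low threshold {low_threshold} must be below high threshold {high_threshold}"
        )
    labels = np.full(len(samples), EXCLUDED, dtype=object)
    with np.errstate(invalid="ignore"):
        labels[values <= low_threshold] = LOW
        labels[values >= high_threshold] = HIGH
    labels = pd.Series(labels, index=samples.index, name="group")
    low_vals = values[(labels == LOW).to_numpy()]
    high_vals = values[(labels == HIGH).to_numpy()]
    if len(low_vals) < 2 or len(high_vals) < 2:
        raise ValueError(
            f"divergent groups too small (LOW={len(low_vals)}, HIGH={len(high_vals)})"
        )
    t, p = two_sample_t_test(low_vals, high_vals, welch=welch)
    return GroupAssignment(
        trait=trait,
        labels=labels,
        low_threshold=low_threshold,
        high_threshold=high_threshold,
        t_statistic=t,
        t_p_value=p,
    )
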