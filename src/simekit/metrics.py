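"""Evaluation statistics: test-retest ICC, percent error, paired summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidParameterError, UndefinedMetricError

__all__ = [
    "icc",
    "icc_table",
    "percent_error",
    "paired_summary",
    "PairedSummary",
]


def icc(test, retest) -> float:
    """Test-retest intraclass correlation ``(BMS - WMS) / (BMS + WMS)``.

    One-way ANOVA decomposition over subjects with two repeats each: BMS is
    the between-subject mean square (n-1 df) and WMS the within-subject mean
    square with one df per subject (n df total).  Ranges over [-1, +1];
    identical repeats give +1.
    """
    test = np.asarray(test, dtype=float)
    retest = np.asarray(retest, dtype=float)
    if test.shape != retest.shape or test.ndim != 1:
        raise InvalidParameterError("icc: test/retest must be 1-D arrays of equal length")
    n = test.size
    if n < 2:
        raise InvalidParameterError("icc: need >= 2 subjects with complete pairs")
    data = np.stack([test, retest], axis=1)
    subj_means = data.mean(axis=1)
    grand = data.mean()
    bms = 2.0 * np.sum((subj_means - grand) ** 2) / (n - 1)
    wms = np.sum((data - subj_means[:, None]) ** 2) / n
    if bms + wms == 0:
        raise UndefinedMetricError("icc: all values identical; ICC undefined")
    return float((bms - wms) / (bms + wms))


def icc_table(table: pd.DataFrame, region: str) -> float:
    """ICC for one region of a long-format test-retest table.

    Expects columns ``subject``, ``region``, ``v_t_test``, ``v_t_retest``.
    """
    required = {"subject", "region", "v_t_test", "v_t_retest"}
    missing = required - set(table.columns)
    if missing:
        raise InvalidParameterError(f"icc_table: missing columns {sorted(missing)}")
    sub = table[table["region"] == region]
    if sub.empty:
        raise InvalidParameterError(f"icc_table: no rows for region {region!r}")
    return icc(sub["v_t_test"].to_numpy(), sub["v_t_retest"].to_numpy())


def percent_error(estimate: float, reference: float) -> float:
    """Signed percent error ``100 * (estimate - reference) / reference``."""
    if reference == 0:
        raise UndefinedMetricError("percent_error: reference must be nonzero")
    return 100.0 * (estimate - reference) / reference


@dataclass(frozen=True)
class PairedSummary:
    mean_diff: float
    sd_diff: float
    t_stat: float
    p_value: float
    n: int
    degenerate: bool = False


def paired_summary(values_a, values_b) -> PairedSummary:
    """Paired-difference summary with paired t statistic.

    A zero-variance difference vector (identical vectors, or a constant
    offset) is reported with ``degenerate=True`` and NaN t/p rather than an
    exception, so callers can still read the mean difference.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidParameterError("paired_summary: inputs must be 1-D of equal length")
    if a.size < 2:
        raise InvalidParameterError("paired_summary: need >= 2 pairs")
    diff = a - b
    sd = float(np.std(diff, ddof=1))
    mean = float(np.mean(diff))
    if sd == 0:
        return PairedSummary(mean, 0.0, float("nan"), float("nan"), a.size, degenerate=True)
    res = stats.ttest_rel(a, b)
    return PairedSummary(mean, sd, float(res.statistic), float(res.pvalue), a.size)
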