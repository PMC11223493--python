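"""Difference and equivalence testing between inferred cOA populations.

Two complementary questions arise when comparing composition estimates:
are two populations *different* (classical two-sample t-test), and are
they *equivalent* within a margin delta (TOST, two one-sided t-tests)?
Failing to show a difference is not evidence of equivalence; TOST makes
equivalence an explicit alternative hypothesis: both H01 (mu_x - mu_y <=
-delta) and H02 (mu_x - mu_y >= +delta) must be rejected.

Welch (unequal-variance) statistics are used throughout. No
multiple-testing correction is applied across class-pair comparisons;
outputs note this.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

logger = logging.getLogger(__name__)


def _welch(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(mean difference, standard error, Welch-Satterthwaite df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        return float(x.mean() - y.mean()), 0.0, float(nx + ny - 2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return float(x.mean() - y.mean()), float(np.sqrt(se2)), float(df)


def ttest_difference(sample_x: np.ndarray, sample_y: np.ndarray) -> float:
    """Two-sided Welch two-sample t-test p-value.

    Degenerate zero-variance inputs: equal means give p = 1 by convention
    (logged); unequal means give p = 0.
    """
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    diff, se, df = _welch(x, y)
    if se == 0:
        if diff == 0:
            logger.warning("zero variance in both samples with equal means: p = 1 by convention")
            return 1.0
        return 0.0
    t = diff / se
    return float(2 * spstats.t.sf(abs(t), df))


@dataclass
class EquivalenceResult:
    """Outcome of a TOST equivalence test."""

    p_lower: float  # test of H01: mu_x - mu_y <= -delta
    p_upper: float  # test of H02: mu_x - mu_y >= +delta
    p: float  # overall = max of the two one-sided p-values
    delta: float  # equivalence margin, units of the compared means
    alpha: float
    equivalent: bool  # both one-sided tests rejected at alpha


#: Default equivalence margin for composition-fraction comparisons: the
#: workflow's conservative resolution limit of 15 percentage points.
DEFAULT_DELTA = 0.15


def tost_equivalence(
    sample_x: np.ndarray,
    sample_y: np.ndarray,
    delta: float,
    alpha: float = 0.05,
) -> EquivalenceResult:
    """Two one-sided Welch t-tests for equivalence within +-delta.

    Equivalence (means differing by less than delta) is declared iff both
    one-sided null hypotheses are rejected at *alpha*; this agrees with
    the (1 - 2 alpha) confidence interval for the mean difference lying
    inside (-delta, +delta).
    """
    if not delta > 0:
        raise ValueError("delta must be positive")
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    diff, se, df = _welch(x, y)
    if se == 0:
        inside = abs(diff) < delta
        p_lower = p_upper = 0.0 if inside else 1.0
        logger.warning("zero variance in both samples: degenerate TOST verdict")
    else:
        p_lower = float(spstats.t.sf((diff + delta) / se, df))
        p_upper = float(spstats.t.cdf((diff - delta) / se, df))
    p = max(p_lower, p_upper)
    return EquivalenceResult(
        p_lower=p_lower,
        p_upper=p_upper,
        p=p,
        delta=delta,
        alpha=alpha,
        equivalent=bool(p_lower < alpha and p_upper < alpha),
    )
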