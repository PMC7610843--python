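"""Two-sample comparison machinery: Welch's t test and relative-error metrics.

The Welch test is the field's default for comparing two small animal
samples with possibly unequal variances.  Alongside the test itself this
module defines the two percent-scale metrics used to summarize how badly
a one-site-per-group design estimates a group difference:

* ``relative_difference`` — estimated difference as a percent of the
  reference-group mean (how a paper would report "group B scored 19%
  higher").
* ``relative_estimation_error`` — percent deviation of the estimated
  difference from the true difference (a magnitude/Type-M-style error;
  values below -100% flip the sign of the effect, a Type-S error).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ComparisonResult:
    """One two-sample Welch comparison.

    ``diff`` is ``mean_b - mean_a``; ``rel_diff`` is the difference as a
    percent of ``mean_a`` (NaN when ``mean_a`` is 0); ``rel_error`` is
    NaN until a true difference is supplied (see
    :func:`relative_estimation_error`).  ``degenerate`` flags the
    zero-variance/unequal-means limit where p=0 by convention.
    """

    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    diff: float
    t_stat: float
    df: float
    p_value: float
    rel_diff: float
    rel_error: float = float("nan")
    degenerate: bool = False

    def with_rel_error(self, true_diff: float) -> "ComparisonResult":
        """Return a copy with ``rel_error`` filled in against ``true_diff``."""
        return replace(
            self, rel_error=relative_estimation_error(self.diff, true_diff)
        )


def welch_test(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> ComparisonResult:
    """Two-sided Welch two-sample t test of ``sample_b`` against ``sample_a``.

    t = (mean_b - mean_a) / sqrt(s_a^2/n_a + s_b^2/n_b), with
    Welch–Satterthwaite degrees of freedom and a two-sided p from the t
    distribution.  If both samples have zero variance: equal means give
    t=0, p=1; unequal means give the degenerate p=0 limit, flagged.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"each sample needs >= 2 values, got {a.size} and {b.size}"
        )
    t, df, p, degenerate = _welch_core(
        a.mean(), a.var(ddof=1), a.size, b.mean(), b.var(ddof=1), b.size
    )
    mean_a = float(a.mean())
    mean_b = float(b.mean())
    diff = mean_b - mean_a
    return ComparisonResult(
        mean_a=mean_a,
        mean_b=mean_b,
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        n_a=int(a.size),
        n_b=int(b.size),
        diff=diff,
        t_stat=float(t),
        df=float(df),
        p_value=float(p),
        rel_diff=100.0 * diff / mean_a if mean_a != 0 else float("nan"),
        degenerate=bool(degenerate),
    )


def welch_from_moments(
    mean_a: np.ndarray,
    var_a: np.ndarray,
    n_a: int,
    mean_b: np.ndarray,
    var_b: np.ndarray,
    n_b: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch test from sample moments: (t, df, p) arrays.

    ``var_a``/``var_b`` are ddof=1 sample variances.  This is the engine
    the Monte-Carlo module uses to score 1e5 replicates at once; it agrees
    elementwise with :func:`welch_test` on the same samples.
    """
    t, df, p, _ = _welch_core(mean_a, var_a, n_a, mean_b, var_b, n_b)
    return t, df, p


def _welch_core(mean_a, var_a, n_a, mean_b, var_b, n_b):
    va = np.asarray(var_a, dtype=float) / n_a
    vb = np.asarray(var_b, dtype=float) / n_b
    diff = np.asarray(mean_b, dtype=float) - np.asarray(mean_a, dtype=float)
    se2 = va + vb
    # Welch–Satterthwaite; guard the zero-variance limit
    with np.errstate(divide="ignore", invalid="ignore"):
        df = se2**2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
        t = diff / np.sqrt(se2)
    zero_se = se2 == 0
    df = np.where(zero_se, n_a + n_b - 2, df)
    t = np.where(zero_se, np.sign(diff) * np.where(diff == 0, 0.0, np.inf), t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(zero_se & (diff == 0), 1.0, p)
    degenerate = zero_se & (diff != 0)
    if np.ndim(t) == 0:
        return float(t), float(df), float(p), bool(degenerate)
    return t, df, p, degenerate


def relative_difference(mean_ref: float, mean_other: float) -> float:
    """Percent difference of ``mean_other`` from the reference-group mean.

    100 * (mean_other - mean_ref) / mean_ref.  The reference (first)
    group's mean is the denominator; it must be nonzero.
    """
    if mean_ref == 0:
        raise ValueError("relative difference undefined for zero reference mean")
    return 100.0 * (mean_other - mean_ref) / mean_ref


def relative_estimation_error(est_diff: float, true_diff: float) -> float:
    """Percent over/under-estimation of a true difference.

    100 * (est_diff - true_diff) / true_diff.  Negative values are
    underestimation; values below -100% mean the estimate has the wrong
    sign.  Undefined (raises) when the true difference is zero — there
    is no scale to measure the error against.
    """
    if true_diff == 0:
        raise ValueError(
            "relative estimation error undefined when true difference is 0"
        )
    return 100.0 * (est_diff - true_diff) / true_diff
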