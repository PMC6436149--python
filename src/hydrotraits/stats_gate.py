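"""Assumption-gated two-sample testing.

Each pairwise comparison first checks normality per group (one-sample
Kolmogorov-Smirnov against a normal with the sample's own moments — a
Lilliefors-style check, so the nominal KS p-values are approximate) and
variance homogeneity (Levene). If Levene rejects at alpha the unequal-
variance Welch test is used, otherwise the pooled-variance Student test.
The gate is part of the procedure, not a user choice. Normality failure is
logged as a warning; no non-parametric fallback is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from hydrotraits.errors import InsufficientDataError, InvalidInputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GateReport:
    """Outcome of one gated two-sample comparison."""

    normality_p_a: float
    normality_p_b: float
    variance_p: float
    chosen_test: str  # "pooled" | "unequal-variance"
    test_statistic: float
    test_p: float
    significant: bool
    alpha: float

    def __post_init__(self) -> None:
        for name in ("normality_p_a", "normality_p_b", "variance_p", "test_p"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidInputError(f"{name} must lie in [0, 1], got {v!r}")
        if self.chosen_test not in ("pooled", "unequal-variance"):
            raise InvalidInputError(f"unknown chosen_test {self.chosen_test!r}")


def _ks_normality_p(x: np.ndarray) -> float:
    """One-sample KS p-value against N(mean(x), sd(x)); 1.0 if sd is zero."""
    sd = x.std(ddof=1)
    if sd == 0:
        return 1.0
    return float(stats.kstest(x, "norm", args=(x.mean(), sd)).pvalue)


def gated_two_sample_test(
    a: Sequence[float], b: Sequence[float], alpha: float = 0.05
) -> GateReport:
    """Compare two groups with the normality/variance-gated t procedure.

    Degenerate case: both groups with zero variance and equal means give
    p = 1 by convention (no evidence of a difference).
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if len(xa) < 3 or len(xb) < 3:
        raise InsufficientDataError(
            f"each group needs n >= 3 (got {len(xa)} and {len(xb)})"
        )
    if not (0.0 < alpha < 1.0):
        raise InvalidInputError(f"alpha must lie in (0, 1), got {alpha!r}")

    norm_p_a = _ks_normality_p(xa)
    norm_p_b = _ks_normality_p(xb)
    for label, p in (("a", norm_p_a), ("b", norm_p_b)):
        if p < alpha:
            logger.warning(
                "gated_two_sample_test: group %s fails KS normality (p = %.4f); "
                "proceeding with the t procedure regardless",
                label,
                p,
            )

    if xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0:
        variance_p = 1.0
        if xa.mean() == xb.mean():
            return GateReport(
                normality_p_a=norm_p_a,
                normality_p_b=norm_p_b,
                variance_p=variance_p,
                chosen_test="pooled",
                test_statistic=0.0,
                test_p=1.0,
                significant=False,
                alpha=alpha,
            )
        # Zero within-group variance but different means: certain difference.
        return GateReport(
            normality_p_a=norm_p_a,
            normality_p_b=norm_p_b,
            variance_p=variance_p,
            chosen_test="pooled",
            test_statistic=math.inf,
            test_p=0.0,
            significant=True,
            alpha=alpha,
        )

    variance_p = float(stats.levene(xa, xb).pvalue)
    equal_var = variance_p >= alpha
    chosen = "pooled" if equal_var else "unequal-variance"
    t_res = stats.ttest_ind(xa, xb, equal_var=equal_var)
    test_p = float(t_res.pvalue)
    return GateReport(
        normality_p_a=norm_p_a,
        normality_p_b=norm_p_b,
        variance_p=variance_p,
        chosen_test=chosen,
        test_statistic=float(t_res.statistic),
        test_p=test_p,
        significant=bool(test_p < alpha),
        alpha=alpha,
    )
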