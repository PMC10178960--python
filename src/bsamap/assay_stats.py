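"""Small-table assay arithmetic.

Percent change of composition means between groups, two-sample Student's t
from summary statistics, relative qPCR expression by the 2^-ddCT method,
and log2 fold-change of expression abundances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats


@dataclass
class PercentChange:
    """A signed percent change with the direction label used in reports."""

    value: float  # positive = lowered relative to reference
    direction: str  # "lowered" or "increased"

    @property
    def magnitude(self) -> float:
        return abs(self.value)


def percent_change(reference_mean: float, other_mean: float) -> PercentChange:
    """Percent change of ``other_mean`` relative to ``reference_mean``.

    Computed as (reference - other) / reference * 100: a positive value
    means the other group is *lowered* by that percentage relative to the
    reference, a negative value that it is *increased* by the magnitude.
    """
    if reference_mean == 0:
        raise ValueError("reference mean must be non-zero")
    value = (reference_mean - other_mean) / reference_mean * 100.0
    return PercentChange(value=value, direction="lowered" if value >= 0 else "increased")


def t_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: str = "pooled",
) -> tuple[float, float, float]:
    """Two-sample t-test from summary statistics.

    Returns (t, df, two-sided p).  ``variant`` is "pooled" (classic
    Student's t, equal variances) or "welch".
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0 or (sd1 == 0 and sd2 == 0):
        raise ValueError("sds must be >= 0 and not both zero")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    t, p = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(t), float(df), float(p)


def relative_expression_ddct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression by the 2^-ddCT method.

    The target gene's CT is normalized against the endogenous-control
    gene's CT within each sample, and the sample of interest is expressed
    relative to the calibrator sample:
    2^-[(CT_target,sample - CT_ref,sample) - (CT_target,cal - CT_ref,cal)].
    """
    for ct in (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator):
        if not math.isfinite(ct):
            raise ValueError("CT values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_calibrator - ct_ref_calibrator)
    return 2.0 ** (-ddct)


def log2fc(abundance_a: float, abundance_b: float, pseudocount: float = 1.0) -> float:
    """log2((a + pseudocount) / (b + pseudocount)) for abundances >= 0."""
    if abundance_a < 0 or abundance_b < 0:
        raise ValueError("abundances must be >= 0")
    if abundance_a + pseudocount <= 0 or abundance_b + pseudocount <= 0:
        raise ValueError("pseudocount too small for zero abundances")
    return math.log2((abundance_a + pseudocount) / (abundance_b + pseudocount))
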