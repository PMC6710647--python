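"""Digital-PCR copy-number estimation under Poisson partition loading.

A digital-PCR panel partitions a DNA dilution into ``n`` chambers and reads
each chamber positive (≥1 template molecule) or negative. Under Poisson
loading the mean molecules per chamber is recovered from the occupancy:

    λ = −ln(1 − k/n),  k positive chambers out of n.

Copy number of a repeated target relative to a single-copy reference gene is
the concentration ratio λ_target / λ_reference; with a one-copy reference
that ratio *is* the target's copy count per haploid genome. Confidence
intervals: Clopper–Pearson on the positive fraction mapped through −ln(1−p)
for a single channel; delta method on ln(ratio), assuming the two channels
are independent panels, for the ratio. Replicate panels are summarised by
their median with Tukey box statistics (1.5×IQR whiskers, outliers flagged).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InputError, ReferenceFailureError, SaturationError


@dataclass(frozen=True)
class DpcrAssay:
    """Partition counts from one panel: target and reference channels."""

    chambers: int
    positives_target: int
    positives_ref: int
    replicate_id: str = "rep1"
    sample_label: str = "sample"

    def __post_init__(self) -> None:
        if self.chambers < 1:
            raise InputError("chambers must be >= 1")
        for k, name in ((self.positives_target, "target"), (self.positives_ref, "reference")):
            if not 0 <= k <= self.chambers:
                raise InputError(f"{name} positives {k} outside [0, {self.chambers}]")


@dataclass(frozen=True)
class LambdaEstimate:
    lam: float
    ci_low: float
    ci_high: float
    saturated: bool = False


@dataclass
class BoxStats:
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[float]


@dataclass
class CopyNumberEstimate:
    ratio: float
    ci_low: float
    ci_high: float
    per_replicate_ratios: list[float]
    median: float
    box_stats: BoxStats | None = None
    sample_label: str = "sample"


def _clopper_pearson(k: int, n: int, conf: float) -> tuple[float, float]:
    """Exact (beta-quantile) binomial CI for the positive fraction."""
    alpha = 1.0 - conf
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def estimate_lambda(k: int, n: int, conf: float = 0.95) -> LambdaEstimate:
    """Poisson occupancy estimate λ = −ln(1 − k/n) with a Clopper–Pearson CI
    mapped through the same transform.

    k = 0 gives λ = 0 with a one-sided upper bound. k = n means every
    chamber was positive: the concentration is unbounded above and the
    estimate is returned with ``saturated=True`` and NaN for λ and the
    upper bound (only the lower bound is meaningful).
    """
    if not 0 <= k <= n or n < 1:
        raise InputError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    p_low, p_high = _clopper_pearson(k, n, conf)
    if k == n:
        return LambdaEstimate(
            lam=math.nan, ci_low=-math.log1p(-p_low), ci_high=math.nan, saturated=True
        )
    lam = -math.log1p(-k / n)
    return LambdaEstimate(
        lam=lam, ci_low=-math.log1p(-p_low), ci_high=-math.log1p(-p_high) if p_high < 1 else math.inf
    )


def _lam_logvar(k: int, n: int) -> float:
    # delta method: var(ln λ̂) ≈ p / (n (1−p) λ²)
    p = k / n
    lam = -math.log1p(-p)
    return p / (n * (1.0 - p) * lam * lam)


def estimate_copy_ratio(assay: DpcrAssay, conf: float = 0.95) -> CopyNumberEstimate:
    """Copy number of the target per reference copy, from one panel.

    ratio = λ_target / λ_reference; CI by the delta method on ln(ratio),
    treating the two channels as independent. A zero-positive target gives
    ratio 0 with a one-sided upper bound; a zero-positive reference or a
    saturated channel is an error.
    """
    n, kt, kr = assay.chambers, assay.positives_target, assay.positives_ref
    if kr == 0:
        raise ReferenceFailureError(
            f"reference channel of {assay.sample_label}/{assay.replicate_id} "
            "detected no molecules"
        )
    if kt == n or kr == n:
        raise SaturationError(
            f"saturated channel in {assay.sample_label}/{assay.replicate_id}: "
            "all chambers positive"
        )
    lam_r = estimate_lambda(kr, n, conf)
    if kt == 0:
        lam_t = estimate_lambda(kt, n, conf)
        upper = lam_t.ci_high / lam_r.ci_low if lam_r.ci_low > 0 else math.inf
        return CopyNumberEstimate(
            ratio=0.0,
            ci_low=0.0,
            ci_high=upper,
            per_replicate_ratios=[0.0],
            median=0.0,
            sample_label=assay.sample_label,
        )
    lam_t = estimate_lambda(kt, n, conf)
    ratio = lam_t.lam / lam_r.lam
    z = stats.norm.ppf(0.5 + conf / 2)
    se_log = math.sqrt(_lam_logvar(kt, n) + _lam_logvar(kr, n))
    return CopyNumberEstimate(
        ratio=ratio,
        ci_low=ratio * math.exp(-z * se_log),
        ci_high=ratio * math.exp(z * se_log),
        per_replicate_ratios=[ratio],
        median=ratio,
        sample_label=assay.sample_label,
    )


def aggregate_replicates(estimates: Sequence[CopyNumberEstimate]) -> CopyNumberEstimate:
    """Summarise replicate panels of one sample.

    Median and quartiles use the linear-interpolation definition; whiskers
    extend to the extreme values within 1.5×IQR of the quartiles and points
    beyond are flagged as outliers. The aggregate CI is the median of the
    per-replicate CI bounds.
    """
    if not estimates:
        raise InputError("no replicate estimates to aggregate")
    ratios = [float(e.ratio) for e in estimates]
    q1, med, q3 = np.percentile(ratios, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inliers = [r for r in ratios if lo_fence <= r <= hi_fence]
    outliers = [r for r in ratios if not lo_fence <= r <= hi_fence]
    box = BoxStats(
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        whisker_low=float(min(inliers)) if inliers else float(q1),
        whisker_high=float(max(inliers)) if inliers else float(q3),
        outliers=outliers,
    )
    return CopyNumberEstimate(
        ratio=float(med),
        ci_low=float(np.median([e.ci_low for e in estimates])),
        ci_high=float(np.median([e.ci_high for e in estimates])),
        per_replicate_ratios=ratios,
        median=float(med),
        box_stats=box,
        sample_label=estimates[0].sample_label,
    )
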