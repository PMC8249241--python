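"""Summary-statistics inference and multiple-comparison adjustments.

Group results in the source figures are printed as mean ± s.e.m. with a
group size n.  From such a triple the two-sample t statistic is fully
determined: sd = sem * sqrt(n), and either the pooled (classical Student)
or the Welch variant follows in closed form.  This module also provides
the step-down Holm–Šídák and step-up Benjamini–Hochberg adjustments and
the comparative-Ct (2^−ΔΔCt) copy-number transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

from .errors import InputError

__all__ = [
    "GroupSummary",
    "TTestResult",
    "FoldChange",
    "t_from_summary",
    "holm_sidak_adjust",
    "benjamini_hochberg_adjust",
    "ddct_copy_number",
]


@dataclass(frozen=True)
class GroupSummary:
    """A group's (mean, s.e.m., n) triple in native units."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise InputError(f"sem must be nonnegative, got {self.sem}")
        if self.n < 2:
            raise InputError(f"n must be at least 2, got {self.n}")

    @property
    def sd(self) -> float:
        return self.sem * math.sqrt(self.n)

    @property
    def var(self) -> float:
        return self.sd**2


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_two_sided: float
    variant: Literal["pooled", "welch"]


@dataclass(frozen=True)
class FoldChange:
    """2^−ΔΔCt fold change; copy number anchored at two copies for ΔΔCt = 0."""

    delta_delta_ct: float
    fold: float
    copy_number: float


def t_from_summary(
    a: GroupSummary, b: GroupSummary, variant: Literal["pooled", "welch"] = "pooled"
) -> TTestResult:
    """Unpaired two-tailed two-sample t-test from summary statistics.

    The sign of ``t`` follows ``a.mean - b.mean``.  ``pooled`` is the
    classical Student test with df = n_a + n_b - 2; ``welch`` divides by
    sqrt(sem_a^2 + sem_b^2) with Welch–Satterthwaite df.
    """
    diff = a.mean - b.mean
    if variant == "pooled":
        df = a.n + b.n - 2
        pooled_var = ((a.n - 1) * a.var + (b.n - 1) * b.var) / df
        se = math.sqrt(pooled_var * (1.0 / a.n + 1.0 / b.n))
    elif variant == "welch":
        va, vb = a.sem**2, b.sem**2  # variances of the means
        se = math.sqrt(va + vb)
        if va == 0.0 and vb == 0.0:
            df = a.n + b.n - 2
        else:
            df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    else:  # pragma: no cover - guarded by Literal
        raise InputError(f"unknown variant {variant!r}")

    if se == 0.0:
        # Degenerate: both sems zero.  Equal means -> no evidence; unequal
        # means with zero variance -> infinitely strong evidence.
        if diff == 0.0:
            return TTestResult(t=0.0, df=df, p_two_sided=1.0, variant=variant)
        return TTestResult(t=math.copysign(math.inf, diff), df=df, p_two_sided=0.0, variant=variant)

    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=t, df=df, p_two_sided=float(p), variant=variant)


def _check_pvalues(p_values: Sequence[float]) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise InputError("p-values must lie in [0, 1]")
    return p


def holm_sidak_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Holm–Šídák adjustment, input order preserved.

    Sorted ascending, the i-th smallest p (1-based) is adjusted to
    1 - (1 - p_(i))^(m - i + 1), then a running maximum enforces
    monotonicity before mapping back to the original order.
    """
    p = _check_pvalues(p_values)
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p, kind="stable")
    adjusted_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adjusted_sorted = np.maximum.accumulate(adjusted_sorted)
    adjusted = np.empty_like(p)
    adjusted[order] = np.clip(adjusted_sorted, 0.0, 1.0)
    return adjusted


def benjamini_hochberg_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Step-up Benjamini–Hochberg FDR adjustment, input order preserved."""
    p = _check_pvalues(p_values)
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    # step-up: each adjusted value is the minimum over itself and all larger ranks
    adjusted_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.empty_like(p)
    adjusted[order] = np.clip(adjusted_sorted, 0.0, 1.0)
    return adjusted


def ddct_copy_number(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> FoldChange:
    """Comparative-Ct gene copy number with the calibrator fixed at two copies.

    ΔΔCt = (Ct_target − Ct_ref)_sample − (Ct_target − Ct_ref)_calibrator;
    fold = 2^−ΔΔCt; copy number = 2 × fold.
    """
    cts = (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator)
    if not all(math.isfinite(c) for c in cts):
        raise InputError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_calibrator - ct_ref_calibrator)
    fold = 2.0 ** (-ddct)
    return FoldChange(delta_delta_ct=ddct, fold=fold, copy_number=2.0 * fold)
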