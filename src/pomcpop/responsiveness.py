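"""Peptide-responsiveness classification and voltage-clamp charge transfer.

A neuron is called responsive to a bath-applied peptide when the change
in firing frequency (or membrane potential, for silent cells) between
the pre-application baseline and the end of the application exceeds
three standard deviations of the baseline — the 3σ criterion.  Both
periods are 120 s summarized as 12 bins of 10 s.  Because the criterion
compares a change of *means* of 12 bins against 3 baseline-bin SDs, it
is strongly conservative under the null (the SD of the mean is σ/√12).

For voltage-clamp recordings of peptide-induced currents, the charge
transferred during the application window is the baseline-subtracted
time integral of the clamp current, reported in nC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import InputError
from .traces import CurrentTrace

__all__ = [
    "RateSeries",
    "ResponseCall",
    "ChargeResult",
    "bin_series",
    "classify_response_3sigma",
    "charge_transfer",
]


@dataclass(frozen=True)
class RateSeries:
    """Binned pre/post series, in Hz (firing rate) or mV (membrane potential)."""

    pre_bins: np.ndarray
    post_bins: np.ndarray
    bin_width: float  # s
    modality: Literal["firing_rate", "membrane_potential"] = "firing_rate"

    def __post_init__(self) -> None:
        object.__setattr__(self, "pre_bins", np.asarray(self.pre_bins, dtype=float))
        object.__setattr__(self, "post_bins", np.asarray(self.post_bins, dtype=float))
        if self.bin_width <= 0:
            raise InputError("bin_width must be positive")
        if self.pre_bins.size < 2:
            raise InputError("need at least 2 pre bins")


@dataclass(frozen=True)
class ResponseCall:
    label: Literal["excited", "inhibited", "not_responsive"]
    delta: float  # post mean - pre mean, Hz or mV
    sigma: float  # SD of the pre bins
    criterion_multiple: float = 3.0
    degenerate: bool = False  # zero baseline variance with nonzero delta


@dataclass(frozen=True)
class ChargeResult:
    charge: float  # nC, magnitude
    sign: int  # sign of the net deflection (+1 outward, -1 inward, 0)
    baseline_current: float  # pA
    application_window: tuple[float, float]


def bin_series(
    values,
    window_pre: tuple[float, float],
    window_post: tuple[float, float],
    bin_width: float = 10.0,
    modality: Literal["firing_rate", "membrane_potential"] = "firing_rate",
    sampling_rate: float | None = None,
) -> RateSeries:
    """Bin a spike train or a continuous trace into pre/post windows.

    For ``firing_rate``, ``values`` is an array of spike times (s) and
    each bin holds spikes/bin_width in Hz.  For ``membrane_potential``,
    ``values`` is a uniformly sampled trace (mV) starting at t = 0 with
    ``sampling_rate`` in kHz, and each bin holds the mean potential.
    Windows must not overlap and must span an integer number of bins.
    """
    if bin_width <= 0:
        raise InputError("bin_width must be positive")
    lo = min(window_pre[1], window_post[1])
    hi = max(window_pre[0], window_post[0])
    if hi < lo:
        raise InputError("pre and post windows overlap")

    def one_window(window: tuple[float, float]) -> np.ndarray:
        start, stop = window
        span = stop - start
        n_bins = span / bin_width
        if abs(n_bins - round(n_bins)) > 1e-9 or round(n_bins) < 1:
            raise InputError(f"window {window} is not an integer multiple of bin_width")
        n = int(round(n_bins))
        if n < 2:
            raise InputError(f"window {window} shorter than 2 bins")
        edges = start + np.arange(n + 1) * bin_width
        if modality == "firing_rate":
            t = np.asarray(values, dtype=float)
            # half-open [start, stop): np.histogram would close the last bin
            counts, _ = np.histogram(t[(t >= start) & (t < stop)], bins=edges)
            return counts / bin_width
        if sampling_rate is None:
            raise InputError("membrane_potential binning requires sampling_rate (kHz)")
        trace = np.asarray(values, dtype=float)
        dt = 1.0 / (sampling_rate * 1000.0)
        out = np.empty(n)
        for i in range(n):
            a = int(round(edges[i] / dt))
            b = int(round(edges[i + 1] / dt))
            if a < 0 or b > trace.size:
                raise InputError(f"window {window} outside the trace span")
            out[i] = trace[a:b].mean()
        return out

    return RateSeries(
        pre_bins=one_window(window_pre),
        post_bins=one_window(window_post),
        bin_width=bin_width,
        modality=modality,
    )


def classify_response_3sigma(series: RateSeries, criterion_multiple: float = 3.0) -> ResponseCall:
    """Classify a pre/post series by the 3σ criterion.

    delta = mean(post) - mean(pre); sigma = sample SD (n-1) of the pre
    bins only.  Excited if delta > kσ, inhibited if delta < -kσ, else
    not responsive.  A zero-variance baseline with a nonzero delta is
    labeled by the sign of delta and flagged degenerate.
    """
    delta = float(np.mean(series.post_bins) - np.mean(series.pre_bins))
    sigma = float(np.std(series.pre_bins, ddof=1))
    degenerate = False
    if sigma == 0.0:
        if delta == 0.0:
            label = "not_responsive"
        else:
            label = "excited" if delta > 0 else "inhibited"
            degenerate = True
    elif delta > criterion_multiple * sigma:
        label = "excited"
    elif delta < -criterion_multiple * sigma:
        label = "inhibited"
    else:
        label = "not_responsive"
    return ResponseCall(
        label=label,
        delta=delta,
        sigma=sigma,
        criterion_multiple=criterion_multiple,
        degenerate=degenerate,
    )


def charge_transfer(
    current: CurrentTrace,
    baseline_window: tuple[float, float],
    application_window: tuple[float, float],
) -> ChargeResult:
    """Baseline-subtracted charge during a peptide application, in nC.

    The baseline current is the mean over ``baseline_window``; the
    charge is the trapezoidal integral of (I - baseline) over
    ``application_window``.  pA·s = 1e-3 nC.  The magnitude is reported
    with the deflection sign kept separately.
    """
    if baseline_window[1] > application_window[0]:
        raise InputError("baseline window must precede (not overlap) the application window")
    baseline = float(np.mean(current.samples[current.window_slice(baseline_window)]))
    sl = current.window_slice(application_window)
    # include the right-edge sample so the integral is additive over a
    # partition of the application window
    hi = min(sl.stop + 1, current.samples.size)
    deflection = current.samples[sl.start : hi] - baseline
    integral_pa_s = float(np.trapezoid(deflection, dx=current.dt))
    charge_nc = integral_pa_s * 1e-3
    sign = 0 if charge_nc == 0 else (1 if charge_nc > 0 else -1)
    return ChargeResult(
        charge=abs(charge_nc),
        sign=sign,
        baseline_current=baseline,
        application_window=application_window,
    )
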