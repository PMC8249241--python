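"""Intrinsic electrophysiological feature extraction from current-clamp traces.

Implements the measurements used to contrast the two labeled POMC
subpopulations: spike detection, passive membrane properties (input
resistance R, membrane time constant tau, whole-cell capacitance
C = tau/R), sag amplitude during hyperpolarization, post-inhibitory
rebound profiles, ascending/descending ramp spike ratios, linear
excitability fits, mono-exponential spike-frequency-adaptation (SFA)
fits, and action-potential waveform metrics (threshold at the
10 mV/ms dV/dt criterion, depolarization and repolarization rates,
mean phase plots).

Window conventions the source analysis leaves open are explicit keyword
parameters here: the sag minimum is searched in the first 25% of the
pulse and the steady level averaged over the last 10%; the membrane time
constant is fitted on the 10-90% relaxation of the smallest pulse; spike
detection is an upward crossing of -20 mV with a 2-ms refractory period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .errors import AnalysisError, InputError
from .traces import SpikeTrain, StimulusProtocol, VoltageTrace

__all__ = [
    "PassiveProperties",
    "SFAFit",
    "APWaveformMetrics",
    "ReboundProfile",
    "detect_spikes",
    "passive_properties",
    "sag_amplitude",
    "rebound_profile",
    "ramp_spike_ratio",
    "excitability_fit",
    "sfa_analysis",
    "ap_waveform_metrics",
    "instantaneous_frequencies",
]

DEFAULT_SPIKE_THRESHOLD = -20.0  # mV
DEFAULT_REFRACTORY_MS = 2.0


@dataclass(frozen=True)
class PassiveProperties:
    input_resistance: float  # GΩ
    time_constant: float  # ms
    capacitance: float  # pF

    def __post_init__(self) -> None:
        if min(self.input_resistance, self.time_constant, self.capacitance) <= 0:
            raise AnalysisError("passive properties must all be positive")
        expected = self.time_constant / self.input_resistance
        if not math.isclose(self.capacitance, expected, rel_tol=1e-6):
            raise AnalysisError("capacitance must equal time_constant / input_resistance")


@dataclass(frozen=True)
class SFAFit:
    """Mono-exponential decay fit Y = (Y0 - plateau) exp(-K T) + plateau."""

    y0: float  # Hz, fixed to the maximum initial instantaneous frequency
    plateau: float  # Hz
    k: float  # 1/s
    sfa_ratio: float  # y0 / plateau


@dataclass(frozen=True)
class APWaveformMetrics:
    threshold: float  # mV, E_M where dE_M/dt first reaches 10 mV/ms
    depolarization_rate: float  # mV/ms, max dE_M/dt
    repolarization_rate: float  # mV/ms, |min dE_M/dt|
    phase_plot: np.ndarray  # (n, 2) mean (E_M, dE_M/dt) trajectory
    n_spikes_used: int


@dataclass(frozen=True)
class ReboundProfile:
    prepulse_potentials: np.ndarray  # mV
    max_instantaneous_frequency: np.ndarray  # Hz
    flagged: np.ndarray  # True where < 2 spikes in the test window

    def __post_init__(self) -> None:
        if not (
            len(self.prepulse_potentials)
            == len(self.max_instantaneous_frequency)
            == len(self.flagged)
        ):
            raise InputError("rebound profile arrays must have equal length")


def detect_spikes(
    trace: VoltageTrace,
    threshold: float = DEFAULT_SPIKE_THRESHOLD,
    refractory: float = DEFAULT_REFRACTORY_MS,
) -> SpikeTrain:
    """Detect spikes as upward threshold crossings with a refractory period.

    The spike time is the time of the first sample at or above the
    threshold; crossings closer than ``refractory`` ms to the previous
    accepted spike are discarded.
    """
    v = trace.samples
    if v.size == 0:
        raise InputError("empty trace")
    above = v >= threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        crossings = np.insert(crossings, 0, 0)
    refractory_s = refractory / 1000.0
    times = []
    last = -math.inf
    for idx in crossings:
        t = trace.t0 + idx * trace.dt
        if t - last >= refractory_s:
            times.append(t)
            last = t
    return SpikeTrain(spike_times=np.array(times), detection_threshold=threshold)


def _monoexp_tau_fit(t_ms: np.ndarray, v: np.ndarray) -> float:
    """Least-squares mono-exponential time constant (ms) of a relaxation."""
    v0, v_inf = v[0], v[-1]
    amplitude = v0 - v_inf
    if abs(amplitude) < 1e-12:
        raise AnalysisError("no relaxation to fit a time constant to")
    # 10-90% segment of the relaxation
    frac = np.clip((v - v_inf) / amplitude, None, None)
    mask = (frac <= 0.9) & (frac >= 0.1)
    if mask.sum() < 4:
        mask = np.ones_like(frac, dtype=bool)
    t_fit, v_fit = t_ms[mask], v[mask]

    def model(t, tau, amp, offset):
        return amp * np.exp(-t / tau) + offset

    tau0 = max((t_fit[-1] - t_fit[0]) / 3.0, 1e-3)
    popt, _ = optimize.curve_fit(
        model, t_fit - t_fit[0], v_fit, p0=(tau0, v_fit[0] - v_fit[-1], v_fit[-1]), maxfev=10000
    )
    tau = float(abs(popt[0]))
    if tau <= 0:
        raise AnalysisError("time-constant fit collapsed")
    return tau


def passive_properties(
    voltage: VoltageTrace,
    protocol: StimulusProtocol,
    spike_threshold: float = DEFAULT_SPIKE_THRESHOLD,
    steady_fraction: float = 0.2,
) -> PassiveProperties:
    """Input resistance, membrane time constant and capacitance.

    R is the least-squares slope of steady-state voltage deflection
    against injected current over the protocol's hyperpolarizing pulses;
    tau is a mono-exponential fit to the relaxation of the
    smallest-amplitude pulse; C = tau/R.  Any spike during the pulses
    marks the response as non-passive.
    """
    if protocol.kind != "hyperpol_series":
        raise InputError("passive_properties expects a hyperpol_series protocol")
    baseline = float(np.mean(voltage.samples[voltage.window_slice((0.0, protocol.pre_s))]))
    delta_v, delta_i = [], []
    smallest: tuple[float, slice] | None = None
    for amp, (pulse,) in protocol.iter_sweeps():
        sl = voltage.window_slice(pulse.window)
        seg = voltage.samples[sl]
        if np.any(seg >= spike_threshold):
            raise AnalysisError(f"pulse at {amp} pA elicited spikes; response is not passive")
        steady_n = max(int(seg.size * steady_fraction), 1)
        delta_v.append(float(np.mean(seg[-steady_n:])) - baseline)
        delta_i.append(amp)
        if smallest is None or abs(amp) < abs(smallest[0]):
            smallest = (amp, sl)
    if len(delta_i) < 2:
        raise InputError("need at least two pulse amplitudes for an I-V slope")
    slope = float(np.polyfit(delta_i, delta_v, 1)[0])  # mV/pA == GΩ
    resistance = abs(slope)
    if resistance <= 0:
        raise AnalysisError("non-positive input resistance")

    assert smallest is not None
    sl = smallest[1]
    seg = voltage.samples[sl]
    t_ms = np.arange(seg.size) / voltage.sampling_rate
    settle = max(int(seg.size * 0.6), 8)
    tau = _monoexp_tau_fit(t_ms[:settle], seg[:settle])
    return PassiveProperties(
        input_resistance=resistance, time_constant=tau, capacitance=tau / resistance
    )


def sag_amplitude(
    voltage: VoltageTrace,
    pulse_window: tuple[float, float],
    early_fraction: float = 0.25,
    steady_fraction: float = 0.10,
) -> float:
    """Sag during a hyperpolarizing pulse, in mV.

    Defined as (minimum voltage within the early part of the pulse)
    minus (mean voltage over the terminal steady window); a depolarizing
    relaxation therefore yields a negative sag, matching the reported
    sign convention.
    """
    sl = voltage.window_slice(pulse_window)
    seg = voltage.samples[sl]
    early_n = max(int(seg.size * early_fraction), 1)
    steady_n = max(int(seg.size * steady_fraction), 1)
    v_min = float(np.min(seg[:early_n]))
    v_steady = float(np.mean(seg[-steady_n:]))
    return v_min - v_steady


def instantaneous_frequencies(spike_times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(midpoint times, 1/ISI frequencies) for consecutive spike pairs."""
    t = np.asarray(spike_times, dtype=float)
    if t.size < 2:
        return np.empty(0), np.empty(0)
    isi = np.diff(t)
    return (t[:-1] + t[1:]) / 2.0, 1.0 / isi


def rebound_profile(
    voltage: VoltageTrace,
    protocol: StimulusProtocol,
    spikes: SpikeTrain,
    prepulse_tail_s: float = 0.2,
) -> ReboundProfile:
    """Maximum instantaneous rebound frequency vs pre-pulse potential.

    For each sweep, the pre-pulse potential is the mean voltage over the
    last ``prepulse_tail_s`` seconds of the hyperpolarizing pre-pulse
    and the rebound frequency is the maximum 1/ISI among spikes inside
    the test window.  Sweeps with fewer than two test-window spikes are
    recorded as 0 Hz and flagged.
    """
    if protocol.kind != "rebound":
        raise InputError("rebound_profile expects a rebound protocol")
    potentials, fmax, flagged = [], [], []
    for _amp, (prepulse, test) in protocol.iter_sweeps():
        tail = (max(prepulse.start, prepulse.stop - prepulse_tail_s), prepulse.stop)
        potentials.append(float(np.mean(voltage.samples[voltage.window_slice(tail)])))
        in_test = spikes.in_window(test.window)
        if in_test.size < 2:
            fmax.append(0.0)
            flagged.append(True)
        else:
            fmax.append(float(np.max(1.0 / np.diff(in_test))))
            flagged.append(False)
    return ReboundProfile(
        prepulse_potentials=np.array(potentials),
        max_instantaneous_frequency=np.array(fmax),
        flagged=np.array(flagged),
    )


def ramp_spike_ratio(spikes_ascending: SpikeTrain, spikes_descending: SpikeTrain) -> float:
    """Ascending-over-descending spike-count ratio for one ramp sweep.

    Zero descending spikes with ascending spikes present yields
    ``math.inf``; a sweep with no spikes in either phase is undefined.
    """
    n_up, n_down = len(spikes_ascending), len(spikes_descending)
    if n_up == 0 and n_down == 0:
        raise AnalysisError("no spikes in either ramp phase; sweep excluded")
    if n_down == 0:
        return math.inf
    return n_up / n_down


def excitability_fit(
    ap_counts: Sequence[int], amplitudes: Sequence[float]
) -> tuple[float, float, np.ndarray]:
    """OLS fit of spike count against current amplitude.

    Only amplitudes that elicited at least one action potential enter
    the fit.  Returns (slope in AP/pA, intercept in AP, boolean mask of
    the included points).
    """
    counts = np.asarray(ap_counts, dtype=float)
    amps = np.asarray(amplitudes, dtype=float)
    if counts.shape != amps.shape:
        raise InputError("ap_counts and amplitudes must have equal length")
    included = counts >= 1
    if included.sum() < 2:
        raise AnalysisError("fewer than two amplitudes elicited spikes; fit undefined")
    slope, intercept = np.polyfit(amps[included], counts[included], 1)
    return float(slope), float(intercept), included


def sfa_analysis(
    spikes: SpikeTrain,
    stimulus_window: tuple[float, float],
    expected_initial_band: tuple[float, float] = (30.0, 40.0),
    min_isis: int = 5,
) -> SFAFit:
    """Mono-exponential spike-frequency-adaptation fit.

    Instantaneous frequencies (1/ISI at the ISI midpoint, time measured
    from the first frequency sample) are fitted to
    ``Y = (Y0 - plateau) * exp(-K * T) + plateau`` with Y0 fixed to the
    maximum initial instantaneous frequency.  The SFA ratio is
    Y0/plateau.  Fewer than ``min_isis`` ISIs refuse the fit; a constant
    train yields plateau = Y0, ratio 1 and an unidentifiable K reported
    as 0.
    """
    in_win = spikes.in_window(stimulus_window)
    if in_win.size < min_isis + 1:
        raise AnalysisError(f"need at least {min_isis} ISIs inside the stimulus window")
    mid_t, freqs = instantaneous_frequencies(in_win)
    t_rel = mid_t - mid_t[0]  # time from the first measured frequency
    y0 = float(np.max(freqs[: max(3, freqs.size // 10)]))  # maximum initial frequency
    lo, hi = expected_initial_band
    if not lo <= y0 <= hi:
        import warnings

        warnings.warn(
            f"initial instantaneous frequency {y0:.1f} Hz outside the {lo}-{hi} Hz band",
            stacklevel=2,
        )
    if float(np.ptp(freqs)) < 1e-9:
        plateau = float(np.mean(freqs))
        return SFAFit(y0=plateau, plateau=plateau, k=0.0, sfa_ratio=1.0)

    def model(t, plateau, k):
        return (y0 - plateau) * np.exp(-k * t) + plateau

    p0 = (max(float(freqs[-3:].mean()), 1e-3), 1.0)
    bounds = ([1e-9, 0.0], [y0, np.inf])
    popt, _ = optimize.curve_fit(
        model, t_rel, freqs, p0=np.clip(p0, bounds[0], bounds[1]), bounds=bounds, maxfev=20000
    )
    plateau, k = float(popt[0]), float(popt[1])
    return SFAFit(y0=y0, plateau=plateau, k=k, sfa_ratio=y0 / plateau)


def _spike_eligibility(spike_times: np.ndarray, max_rate_hz: float) -> np.ndarray:
    """Spikes whose instantaneous frequency (vs the previous spike) is slow.

    The first spike of a train has no preceding interval and counts as
    eligible.
    """
    if spike_times.size == 0:
        return np.zeros(0, dtype=bool)
    eligible = np.ones(spike_times.size, dtype=bool)
    if spike_times.size > 1:
        rates = 1.0 / np.diff(spike_times)
        eligible[1:] = rates <= max_rate_hz
    return eligible


def ap_waveform_metrics(
    voltage: VoltageTrace,
    spikes: SpikeTrain,
    threshold_dvdt: float = 10.0,  # mV/ms
    max_rate_hz: float = 5.0,
    window_ms: float = 5.0,
    smooth: bool = False,
) -> APWaveformMetrics:
    """Action-potential waveform metrics averaged over eligible spikes.

    dE_M/dt is computed by centered finite differences (optionally
    lightly smoothed).  Per spike, the threshold is E_M at the first
    sample of the rising phase where dE_M/dt reaches ``threshold_dvdt``;
    depolarization/repolarization rates are the max/|min| of dE_M/dt in
    a +/- ``window_ms`` window around the peak.  Only spikes with
    instantaneous frequency <= ``max_rate_hz`` are used.
    """
    v = voltage.samples
    if smooth:
        kernel = np.ones(5) / 5.0
        v = np.convolve(v, kernel, mode="same")
    dt_ms = 1.0 / voltage.sampling_rate
    dvdt = np.gradient(v, dt_ms)

    eligible = _spike_eligibility(spikes.spike_times, max_rate_hz)
    times = spikes.spike_times[eligible]
    if times.size == 0:
        raise AnalysisError("no eligible spikes for waveform analysis")

    half = int(round(window_ms / dt_ms))
    thresholds, depol, repol, windows = [], [], [], []
    for t in times:
        center = int(round((t - voltage.t0) / voltage.dt))
        lo, hi = center - half, center + half + 1
        if lo < 0 or hi > v.size:
            continue
        seg_v, seg_d = v[lo:hi], dvdt[lo:hi]
        peak = int(np.argmax(seg_v))
        rising = seg_d[: peak + 1]
        above = np.flatnonzero(rising >= threshold_dvdt)
        if above.size == 0:
            continue
        thresholds.append(float(seg_v[above[0]]))
        depol.append(float(np.max(seg_d)))
        repol.append(float(abs(np.min(seg_d))))
        windows.append(np.column_stack([seg_v, seg_d]))
    if not thresholds:
        raise AnalysisError("no spike window produced a threshold crossing")
    phase = np.mean(np.stack(windows), axis=0)
    return APWaveformMetrics(
        threshold=float(np.mean(thresholds)),
        depolarization_rate=float(np.mean(depol)),
        repolarization_rate=float(np.mean(repol)),
        phase_plot=phase,
        n_spikes_used=len(thresholds),
    )
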