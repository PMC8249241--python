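"""Seeded generators for every raw input the pipeline consumes.

Four generators emulate the statistical structure of the study data so
each downstream stage can be exercised without recordings:

* an adaptive leaky-integrate-and-fire neuron with two presets, a
  tonically firing cell and a phasically adapting one, reproducing the
  qualitative contrast between the two labeled POMC subpopulations
  (spike-frequency adaptation, sag, post-inhibitory rebound);
* per-animal 3D Gaussian-mixture point clouds rejection-sampled into a
  bounding box, emulating atlas-registered neuron coordinates;
* gene-by-sample negative-binomial count matrices with paired
  input/pulldown samples and per-gene enrichment factors, emulating
  ribosome-affinity (TRAP) sequencing;
* binned firing-rate (or membrane-potential) series around a peptide
  application, with an optional step effect.

Every generator takes a single integer seed and is bit-reproducible;
per-animal/per-sample sub-streams are spawned deterministically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .traces import CurrentTrace, StimulusProtocol, VoltageTrace

__all__ = [
    "EphysSimConfig",
    "SpatialSimConfig",
    "MixtureComponent",
    "TrapSimConfig",
    "RateSeriesConfig",
    "simulate_membrane_trace",
    "generate_point_clouds",
    "generate_trap_counts",
    "generate_rate_series",
    "SPIKE_PEAK_MV",
]

# Stylized action-potential peak painted into simulated voltage traces so
# threshold-crossing spike detection sees one clean upstroke per spike.
SPIKE_PEAK_MV = 30.0


# ---------------------------------------------------------------------------
# Electrophysiology surrogate
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EphysSimConfig:
    """Adaptive integrate-and-fire parameters.

    The model has two state variables, membrane potential V (mV) and an
    adaptation current w (pA):

        C dV/dt = g_L (E_rest - V) + I(t) - w  [+ noise]
        tau_w dw/dt = a (V - E_rest) - w

    with a reset ``V -> reset_potential`` and a jump ``w -> w +
    adaptation_increment`` on each threshold crossing.  The subthreshold
    coupling ``a`` produces both the sag during hyperpolarization and
    the post-inhibitory rebound (w goes negative while hyperpolarized);
    the spike-triggered increment produces spike-frequency adaptation.
    """

    preset: Literal["tonic", "phasic_adaptive"] = "tonic"
    membrane_capacitance: float = 20.0  # pF
    leak_conductance: float = 1.0  # nS
    resting_potential: float = -70.0  # mV
    spike_threshold: float = -58.0  # mV
    reset_potential: float = -65.0  # mV
    adaptation_increment: float = 0.3  # pA, spike-triggered jump of w
    adaptation_time_constant: float = 120.0  # ms
    subthreshold_adaptation: float = 0.1  # nS, coupling a
    noise_sd: float = 0.0  # mV / sqrt(ms), membrane-noise scale
    sampling_rate: float = 25.0  # kHz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.adaptation_increment < 0:
            raise ConfigurationError("adaptation_increment must be nonnegative")
        if self.membrane_capacitance <= 0 or self.leak_conductance <= 0:
            raise ConfigurationError("capacitance and leak conductance must be positive")
        if self.adaptation_time_constant <= 0:
            raise ConfigurationError("adaptation_time_constant must be positive")
        if self.reset_potential >= self.spike_threshold:
            raise ConfigurationError("reset_potential must lie below spike_threshold")

    @classmethod
    def tonic(cls, **overrides) -> "EphysSimConfig":
        """Tonically firing preset: weak adaptation, near-constant ISIs."""
        return cls(preset="tonic", adaptation_increment=0.3,
                   adaptation_time_constant=120.0, subthreshold_adaptation=0.1,
                   **overrides)

    @classmethod
    def phasic_adaptive(cls, **overrides) -> "EphysSimConfig":
        """Phasically adapting preset: strong spike-triggered and
        subthreshold adaptation plus a higher input resistance, hence a
        high SFA ratio, voltage-dependent ramp adaptation and a
        pronounced post-inhibitory rebound."""
        return cls(preset="phasic_adaptive", leak_conductance=0.6,
                   adaptation_increment=3.0, adaptation_time_constant=400.0,
                   subthreshold_adaptation=0.4, **overrides)


def simulate_membrane_trace(
    config: EphysSimConfig, protocol: StimulusProtocol
) -> tuple[VoltageTrace, CurrentTrace]:
    """Integrate the adaptive LIF under a current-clamp protocol.

    Returns the voltage trace (with stylized spike peaks painted at
    threshold crossings) and the aligned injected-current trace.  A bias
    current holds the cell at ``protocol.holding_potential`` between
    stimuli, mirroring the recordings' holding at -70 mV.
    """
    current = protocol.current_waveform(config.sampling_rate)
    injected = current.samples
    dt_ms = 1.0 / config.sampling_rate  # integration step, ms
    n = injected.size
    rng = np.random.default_rng(config.seed)

    c = config.membrane_capacitance
    g_l = config.leak_conductance
    e_rest = config.resting_potential
    a = config.subthreshold_adaptation
    tau_w = config.adaptation_time_constant
    b = config.adaptation_increment

    # Steady-state bias holding the cell at the protocol's holding potential.
    v_hold = protocol.holding_potential
    bias = (g_l + a) * (v_hold - e_rest)

    v = np.empty(n)
    w_hold = a * (v_hold - e_rest)
    v_now, w_now = v_hold, w_hold
    noise = (
        rng.standard_normal(n) * config.noise_sd * math.sqrt(dt_ms)
        if config.noise_sd > 0
        else None
    )
    for i in range(n):
        i_total = injected[i] + bias
        dv = dt_ms * (g_l * (e_rest - v_now) + i_total - w_now) / c
        dw = dt_ms * (a * (v_now - e_rest) - w_now) / tau_w
        v_now += dv
        if noise is not None:
            v_now += noise[i]
        w_now += dw
        if v_now >= config.spike_threshold:
            v[i] = SPIKE_PEAK_MV
            v_now = config.reset_potential
            w_now += b
        else:
            v[i] = v_now
    voltage = VoltageTrace(samples=v, sampling_rate=config.sampling_rate)
    return voltage, current


# ---------------------------------------------------------------------------
# 3D point clouds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MixtureComponent:
    weight: float
    mean: tuple[float, float, float]  # µm
    covariance: Sequence[Sequence[float]]  # 3x3, µm^2


@dataclass(frozen=True)
class SpatialSimConfig:
    """Gaussian-mixture point clouds inside a bounded atlas region."""

    bounding_box: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]
    components: Mapping[str, Sequence[MixtureComponent]]  # group -> mixture
    neurons_per_animal: int = 400
    animals_per_group: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.components:
            raise ConfigurationError("at least one group with components is required")
        for group, comps in self.components.items():
            if not comps:
                raise ConfigurationError(f"group {group!r} has an empty component list")
            total = sum(c.weight for c in comps)
            if not math.isclose(total, 1.0, rel_tol=1e-9, abs_tol=1e-9):
                raise ConfigurationError(f"group {group!r} weights sum to {total}, expected 1")
            for comp in comps:
                cov = np.asarray(comp.covariance, dtype=float)
                if cov.shape != (3, 3):
                    raise ConfigurationError("covariance must be 3x3")
                if np.any(np.linalg.eigvalsh((cov + cov.T) / 2) < 0):
                    raise ConfigurationError("covariance must be positive semi-definite")
                for axis in range(3):
                    lo, hi = self.bounding_box[axis]
                    if not lo <= comp.mean[axis] <= hi:
                        raise ConfigurationError("component mean outside bounding box")
        if self.neurons_per_animal < 1 or self.animals_per_group < 1:
            raise ConfigurationError("neurons_per_animal and animals_per_group must be >= 1")


def _sample_mixture_in_box(
    rng: np.random.Generator,
    comps: Sequence[MixtureComponent],
    box: Sequence[tuple[float, float]],
    n: int,
) -> np.ndarray:
    """Rejection-sample n mixture draws into the box (edge bias accepted)."""
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])
    weights = np.array([c.weight for c in comps])
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        need = n - filled
        idx = rng.choice(len(comps), size=need, p=weights)
        draws = np.empty((need, 3))
        for k, comp in enumerate(comps):
            mask = idx == k
            if mask.any():
                draws[mask] = rng.multivariate_normal(
                    comp.mean, np.asarray(comp.covariance, dtype=float), size=int(mask.sum())
                )
        ok = np.all((draws >= lo) & (draws <= hi), axis=1)
        kept = draws[ok]
        out[filled : filled + kept.shape[0]] = kept
        filled += kept.shape[0]
    return out


def generate_point_clouds(config: SpatialSimConfig):
    """One :class:`~pomcpop.spatial.PointCloud` per simulated animal."""
    from .spatial import PointCloud  # local import to avoid a cycle

    root = np.random.default_rng(config.seed)
    clouds: list[PointCloud] = []
    for group in config.components:
        comps = config.components[group]
        for animal in range(config.animals_per_group):
            sub = np.random.default_rng(root.integers(0, 2**31))
            pts = _sample_mixture_in_box(sub, comps, config.bounding_box, config.neurons_per_animal)
            clouds.append(PointCloud(animal_id=f"{group}_{animal + 1}", group=group, coordinates=pts))
    return clouds


# ---------------------------------------------------------------------------
# TRAP count matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrapSimConfig:
    """Paired input/IP negative-binomial counts with per-gene enrichment.

    ``enrichment_log2fc`` maps each group to a per-gene log2 IP/input
    enrichment vector (genes absent from the map are unenriched).  The
    input mean is ``baseline_mean`` for every gene; the IP mean is the
    input mean times 2**log2fc.  ``dispersion`` is the negative-binomial
    shape parameter (variance = mu + mu^2/dispersion); ``math.inf``
    selects the documented noiseless limit where counts equal their
    means exactly.
    """

    n_genes: int = 2000
    samples_per_group: int = 4
    baseline_mean: float = 100.0
    dispersion: float = 50.0  # shape 50 ~ overdispersion 0.02, bulk-library regime
    enrichment_log2fc: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    marker_assignment: Mapping[str, Sequence[str]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        if self.n_genes < 1 or self.samples_per_group < 1:
            raise ConfigurationError("n_genes and samples_per_group must be >= 1")
        markers = {g for genes in self.marker_assignment.values() for g in genes}
        if len(markers) > self.n_genes:
            raise ConfigurationError("more marker genes than genes in the universe")

    def gene_names(self) -> list[str]:
        return [f"gene_{i:05d}" for i in range(self.n_genes)]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if math.isinf(dispersion):
        return mean.copy()
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p).astype(float)


def generate_trap_counts(config: TrapSimConfig):
    """Counts, sample metadata and marker sets for the TRAP stage.

    Returns ``(CountMatrix, SampleMeta, MarkerSet)`` as defined in
    :mod:`pomcpop.trap`.  Library-size factors are fixed to one; any
    normalization is the downstream stage's job.
    """
    from .trap import CountMatrix, MarkerSet, SampleMeta  # avoid cycle

    genes = config.gene_names()
    universe = set(genes)
    for cluster, markers in config.marker_assignment.items():
        missing = [g for g in markers if g not in universe]
        if missing:
            raise ConfigurationError(
                f"marker genes absent from gene universe in cluster {cluster!r}: {missing[:5]}"
            )
    gene_index = {g: i for i, g in enumerate(genes)}
    groups = list(config.enrichment_log2fc) or ["Lepr", "Glp1r"]

    root = np.random.default_rng(config.seed)
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for group in groups:
        lfc = np.zeros(config.n_genes)
        for g, value in config.enrichment_log2fc.get(group, {}).items():
            if g not in gene_index:
                raise ConfigurationError(f"enrichment gene {g!r} absent from gene universe")
            lfc[gene_index[g]] = value
        input_mean = np.full(config.n_genes, config.baseline_mean)
        ip_mean = input_mean * 2.0**lfc
        for rep in range(1, config.samples_per_group + 1):
            sub = np.random.default_rng(root.integers(0, 2**31))
            rep_id = f"{group}_rep{rep}"
            for fraction, mean in (("input", input_mean), ("IP", ip_mean)):
                sample_id = f"{rep_id}_{fraction}"
                columns[sample_id] = _nb_draw(sub, mean, config.dispersion)
                meta_rows.append(
                    {"sample_id": sample_id, "replicate_id": rep_id, "fraction": fraction, "group": group}
                )

    counts = CountMatrix(pd.DataFrame(columns, index=pd.Index(genes, name="gene")))
    meta = SampleMeta(pd.DataFrame(meta_rows))
    markers = MarkerSet({c: list(g) for c, g in config.marker_assignment.items()})
    return counts, meta, markers


# ---------------------------------------------------------------------------
# Binned rate series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateSeriesConfig:
    """Pre/post binned series around a peptide application.

    Defaults mirror the recording analysis: a 120-s window on each side
    of the application, divided into 12 bins of 10 s.
    """

    baseline_rate: float = 5.0  # Hz (or mV if modality is membrane_potential)
    bin_width: float = 10.0  # s
    n_bins_pre: int = 12
    n_bins_post: int = 12
    effect_delta: float = 0.0  # Hz added to every post bin before noise
    noise_model: Literal["poisson", "gaussian", "none"] = "none"
    noise_sd: float = 0.5  # Hz, gaussian model only
    modality: Literal["firing_rate", "membrane_potential"] = "firing_rate"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ConfigurationError("bin_width must be positive")
        if self.n_bins_pre < 2:
            raise ConfigurationError("need at least 2 pre bins")
        if self.modality == "firing_rate" and self.baseline_rate < 0:
            raise ConfigurationError("baseline_rate must be nonnegative for firing rates")


def generate_rate_series(config: RateSeriesConfig):
    """Simulate a :class:`~pomcpop.responsiveness.RateSeries`.

    ``poisson`` draws per-bin spike counts with mean rate*bin_width and
    rescales to Hz; ``gaussian`` adds N(0, noise_sd) per bin; ``none``
    returns the noiseless means.
    """
    from .responsiveness import RateSeries  # avoid cycle

    rng = np.random.default_rng(config.seed)
    pre_mean = np.full(config.n_bins_pre, config.baseline_rate)
    post_mean = np.full(config.n_bins_post, config.baseline_rate + config.effect_delta)
    if config.noise_model == "poisson":
        pre = rng.poisson(pre_mean * config.bin_width) / config.bin_width
        post = rng.poisson(np.clip(post_mean, 0, None) * config.bin_width) / config.bin_width
    elif config.noise_model == "gaussian":
        pre = pre_mean + rng.normal(0.0, config.noise_sd, size=pre_mean.size)
        post = post_mean + rng.normal(0.0, config.noise_sd, size=post_mean.size)
    else:
        pre, post = pre_mean, post_mean
    return RateSeries(
        pre_bins=pre, post_bins=post, bin_width=config.bin_width, modality=config.modality
    )
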