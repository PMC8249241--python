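"""End-to-end benchmark computations on the synthetic study conditions.

Each function rebuilds its inputs from the package's own generators (or
from published summary statistics), runs the corresponding pipeline
stage and measures the result.  `scripts/acceptance.py` and the
acceptance test suite both call these, so the reported quantities are
always recomputed from scratch.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping

import numpy as np

from . import ephys, responsiveness, spatial, synthetic, trap
from .stats import GroupSummary, t_from_summary
from .traces import SpikeTrain, StimulusProtocol

__all__ = [
    "legend_t_values",
    "voxel_null_calibration",
    "null_responsive_fraction",
    "sfa_fit_recovery",
    "trap_standin_benchmark",
    "preset_phenotype_contrast",
]

# Published (mean, s.e.m., n) group summaries and the statistic variant
# with which each two-sample t was reported.
LEGEND_SUMMARIES = {
    "t_fos_activation_lepr": ((94.03, 1.66, 3), (6.87, 2.64, 3), "pooled"),
    "t_fos_activation_glp1r": ((87.05, 6.05, 3), (8.23, 1.13, 3), "pooled"),
    "t_pomc_enrichment_lepr": ((4740.55, 618.41, 4), (39.44, 19.39, 4), "welch"),
    "t_pomc_enrichment_glp1r": ((1005.42, 40.19, 3), (14.14, 0.49, 3), "welch"),
    "t_ap_depolarization_rate": ((380.6, 14.5, 33), (320.5, 15.6, 30), "pooled"),
    "t_npy_charge_transfer": ((6.54, 0.80, 14), (3.53, 0.48, 14), "pooled"),
}


def legend_t_values() -> Mapping[str, dict]:
    """|t| recomputed from each published summary pair."""
    out = {}
    for name, (a, b, variant) in LEGEND_SUMMARIES.items():
        result = t_from_summary(GroupSummary(*a), GroupSummary(*b), variant=variant)
        out[name] = {"value": abs(result.t), "n": a[2] + b[2]}
    return out


def _null_spatial_config(seed: int, animals_per_group: int = 5) -> synthetic.SpatialSimConfig:
    mixture = [
        synthetic.MixtureComponent(
            weight=0.6, mean=(400.0, 300.0, 500.0),
            covariance=np.diag([150.0**2, 100.0**2, 250.0**2]),
        ),
        synthetic.MixtureComponent(
            weight=0.4, mean=(400.0, 300.0, 1100.0),
            covariance=np.diag([150.0**2, 100.0**2, 250.0**2]),
        ),
    ]
    return synthetic.SpatialSimConfig(
        bounding_box=((0.0, 800.0), (0.0, 600.0), (0.0, 1600.0)),
        components={"Glp1r": mixture, "Lepr": mixture},
        neurons_per_animal=300,
        animals_per_group=animals_per_group,
        seed=seed,
    )


def voxel_null_calibration(
    seed: int, replicates: int = 200, cube_edge: float = 200.0
) -> dict:
    """Type-I error of the per-cube t-test under identical group mixtures.

    Returns the pooled fraction of informative cubes with p < 0.05
    across `replicates` seeded simulations (5 animals per group each).
    """
    root = np.random.default_rng(seed)
    n_sig = 0
    n_tested = 0
    for _ in range(replicates):
        cfg = _null_spatial_config(int(root.integers(0, 2**31)))
        clouds = synthetic.generate_point_clouds(cfg)
        grid = spatial.voxelize(clouds, cube_edge=cube_edge)
        corrected, _ = spatial.apply_density_factor(grid)
        result = spatial.voxel_ttest(corrected)
        p = result.p[result.tested]
        n_sig += int(np.sum(p < 0.05))
        n_tested += p.size
    return {"value": n_sig / n_tested, "n": n_tested}


def null_responsive_fraction(seed: int, replicates: int = 10_000) -> dict:
    """Fraction of null rate series the 3σ criterion calls responsive."""
    root = np.random.default_rng(seed)
    n_called = 0
    for _ in range(replicates):
        series = synthetic.generate_rate_series(
            synthetic.RateSeriesConfig(
                baseline_rate=10.0, effect_delta=0.0, noise_model="gaussian",
                noise_sd=1.0, seed=int(root.integers(0, 2**31)),
            )
        )
        call = responsiveness.classify_response_3sigma(series)
        if call.label != "not_responsive":
            n_called += 1
    return {"value": 100.0 * n_called / replicates, "n": replicates}


def _train_from_curve(y0, plateau, k, duration, noise_sd=0.0, rng=None):
    """Spike train whose midpoint 1/ISI follows the mono-exponential SFA
    curve, optionally with gaussian frequency noise per ISI."""
    times = [0.0]
    first_mid = None
    while times[-1] < duration:
        t_prev = times[-1]
        isi = 1.0 / y0
        for _ in range(60):
            mid = t_prev + isi / 2.0
            ref = first_mid if first_mid is not None else mid
            f = (y0 - plateau) * math.exp(-k * (mid - ref)) + plateau
            isi = 1.0 / f
        if noise_sd > 0.0:
            f_noisy = max(f + rng.normal(0.0, noise_sd), 0.5)
            isi = 1.0 / f_noisy
        if first_mid is None:
            first_mid = t_prev + isi / 2.0
        times.append(t_prev + isi)
    return np.array(times[:-1])


def sfa_fit_recovery(
    seed: int, replicates: int = 100,
    y0: float = 36.0, plateau: float = 9.0, k: float = 1.2, noise_sd: float = 1.0,
) -> dict:
    """Recovery of the adaptation plateau from noisy frequency data.

    Returns the worst relative plateau error and the mean fitted SFA
    ratio across seeded replicates of a 10-s train generated from the
    decay curve with sd-1 Hz frequency noise.
    """
    root = np.random.default_rng(seed)
    plateau_errors, ratios = [], []
    for _ in range(replicates):
        rng = np.random.default_rng(int(root.integers(0, 2**31)))
        times = _train_from_curve(y0, plateau, k, duration=10.0, noise_sd=noise_sd, rng=rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = ephys.sfa_analysis(SpikeTrain(times, -20.0), (0.0, 10.0))
        plateau_errors.append(abs(fit.plateau - plateau) / plateau)
        ratios.append(fit.sfa_ratio)
    return {
        "plateau_max_rel_error": {"value": float(np.max(plateau_errors)), "n": replicates},
        "sfa_ratio_mean": {"value": float(np.mean(ratios)), "n": replicates},
    }


def trap_standin_benchmark(seed: int, n_null: int = 2000, n_true: int = 50) -> dict:
    """Recall/FDR of the enrichment stand-in and null p-value uniformity.

    Seeded synthetic TRAP data: `n_true` genes at |log2fc| = 3 among
    `n_null` nulls, 4 replicates per group, adjusted p <= 0.05 calls.
    """
    from scipy import stats as sps

    enriched = {f"gene_{i:05d}": 3.0 for i in range(n_true)}
    cfg = synthetic.TrapSimConfig(
        n_genes=n_null + n_true, samples_per_group=4,
        enrichment_log2fc={"Glp1r": enriched, "Lepr": {}}, seed=seed,
    )
    counts, meta, _ = synthetic.generate_trap_counts(cfg)
    table = trap.differential_enrichment(
        trap.ip_input_normalize(counts, meta), significance_on="padj"
    )
    result = table.result
    truth = set(enriched)
    called = set(result.index[result["padj"] <= 0.05])
    recall = len(called & truth) / len(truth)
    fdr = len(called - truth) / max(len(called), 1)
    null_p = result.drop(index=list(truth))["p"].to_numpy()
    ks_p = float(sps.kstest(null_p, "uniform").pvalue)
    return {
        "trap_recall": {"value": recall, "n": n_true},
        "trap_fdr": {"value": fdr, "n": len(called)},
        "trap_null_ks_p": {"value": ks_p, "n": n_null},
    }


def preset_phenotype_contrast(seed: int) -> dict:
    """SFA ratio, ramp spike ratio and rebound f_max for both presets."""
    out: dict[str, dict] = {}
    sfa_prot = StimulusProtocol(kind="step", amplitudes=[30.0], pulse_s=10.0)
    ramp_prot = StimulusProtocol(kind="ramp_updown", amplitudes=[15.0])
    reb_prot = StimulusProtocol(
        kind="rebound", amplitudes=[-50.0, -30.0, -10.0], test_amplitude=15.0
    )
    window = [s for s in sfa_prot.segments() if s.phase == "pulse"][0].window
    for name in ("tonic", "phasic_adaptive"):
        cfg = getattr(synthetic.EphysSimConfig, name)(seed=seed)
        v, _ = synthetic.simulate_membrane_trace(cfg, sfa_prot)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sfa = ephys.sfa_analysis(ephys.detect_spikes(v), window).sfa_ratio

        v, _ = synthetic.simulate_membrane_trace(cfg, ramp_prot)
        spikes = ephys.detect_spikes(v)
        _, (up, down) = next(iter(ramp_prot.iter_sweeps()))
        ramp_ratio = ephys.ramp_spike_ratio(
            SpikeTrain(spikes.in_window(up.window), -20.0),
            SpikeTrain(spikes.in_window(down.window), -20.0),
        )

        v, _ = synthetic.simulate_membrane_trace(cfg, reb_prot)
        profile = ephys.rebound_profile(v, reb_prot, ephys.detect_spikes(v))
        out[name] = {
            "sfa_ratio": float(sfa),
            "ramp_spike_ratio": float(ramp_ratio),
            "rebound_fmax_hz": float(profile.max_instantaneous_frequency.max()),
        }
    return out
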