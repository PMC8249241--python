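"""TRAP (ribosome-affinity) enrichment and single-cell marker overlap.

Each ribosomal pulldown (IP) sample is normalized to its own
whole-tissue input sample as a per-gene, per-replicate ratio
(IP + pseudocount) / (input + pseudocount).  Differential enrichment
between the two labeled subpopulations is then assessed on the
per-replicate log2 ratios with a Welch t-test and Benjamini–Hochberg
adjustment — a deliberately simple, clearly labeled stand-in for a
negative-binomial differential-expression model, recorded as such in
the output metadata.

The overlap score asks, for each single-cell cluster's marker list, how
many markers are significantly enriched toward each subpopulation and
summarizes the balance as log_ratio = log2(n_glp1r / n_lepr); a cluster
is called enriched for a subpopulation's markers when |log_ratio| >= 2
(boundary inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AnalysisError, InputError
from .stats import benjamini_hochberg_adjust

__all__ = [
    "CountMatrix",
    "SampleMeta",
    "MarkerSet",
    "EnrichmentTable",
    "ClusterCall",
    "ip_input_normalize",
    "differential_enrichment",
    "cluster_overlap_call",
    "gene_zscore_matrix",
]

STAND_IN_METHOD = "welch_t_on_log2_ip_input_ratios + benjamini_hochberg"


@dataclass(frozen=True)
class CountMatrix:
    """Gene-by-sample counts (genes as rows)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise InputError("gene identifiers must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise InputError("counts must be nonnegative")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns


@dataclass(frozen=True)
class SampleMeta:
    """Sample sheet: sample_id, replicate_id, fraction (input|IP), group."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "replicate_id", "fraction", "group")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise InputError(f"sample metadata lacks columns: {missing}")
        bad = set(self.table["fraction"]) - {"input", "IP"}
        if bad:
            raise InputError(f"unknown fraction labels: {sorted(bad)}")

    def pairs(self) -> list[tuple[str, str, str, str]]:
        """(replicate_id, group, input_sample, ip_sample) per replicate."""
        out = []
        for rep_id, sub in self.table.groupby("replicate_id", sort=False):
            ips = sub.loc[sub["fraction"] == "IP", "sample_id"].tolist()
            inputs = sub.loc[sub["fraction"] == "input", "sample_id"].tolist()
            if len(ips) != 1 or len(inputs) != 1:
                raise InputError(
                    f"replicate {rep_id!r} must pair exactly one IP with one input sample"
                )
            groups = set(sub["group"])
            if len(groups) != 1:
                raise InputError(f"replicate {rep_id!r} spans multiple groups")
            out.append((str(rep_id), groups.pop(), inputs[0], ips[0]))
        return out


@dataclass(frozen=True)
class MarkerSet:
    """Cluster id -> marker gene list (genes may repeat across clusters)."""

    clusters: Mapping[str, Sequence[str]]

    def __post_init__(self) -> None:
        for cluster, genes in self.clusters.items():
            if not list(genes):
                raise InputError(f"cluster {cluster!r} has an empty marker list")


@dataclass(frozen=True)
class EnrichmentTable:
    """Per-gene IP/input ratios and, once completed, the group contrast.

    ``ratios`` has one log2(IP/input) column per replicate.  After
    :func:`differential_enrichment`, ``result`` holds per-group mean
    log2 ratios, the between-group log2 fold difference
    (group_a - group_b), p, adjusted p and the significance flag.
    """

    ratios: pd.DataFrame  # genes x replicates, log2 scale
    replicate_groups: Mapping[str, str]
    pseudocount: float
    result: pd.DataFrame | None = None
    method: str = STAND_IN_METHOD
    group_a: str = "Glp1r"
    group_b: str = "Lepr"

    @property
    def completed(self) -> bool:
        return self.result is not None


@dataclass(frozen=True)
class ClusterCall:
    cluster_id: str
    n_glp1r: int
    n_lepr: int
    log_ratio: float  # log2(n_glp1r / n_lepr); +/- inf when one side is 0
    call: Literal["Lepr_enriched", "Glp1r_enriched", "neither", "undefined"]
    flagged: bool = False


def ip_input_normalize(
    counts: CountMatrix, meta: SampleMeta, pseudocount: float = 0.5
) -> EnrichmentTable:
    """Per-gene, per-replicate log2 (IP + pc) / (input + pc) ratios."""
    if pseudocount < 0:
        raise InputError("pseudocount must be nonnegative")
    ratios = {}
    groups = {}
    for rep_id, group, input_id, ip_id in meta.pairs():
        for sample in (input_id, ip_id):
            if sample not in counts.samples:
                raise InputError(f"sample {sample!r} missing from the count matrix")
        ip = counts.counts[ip_id].to_numpy(dtype=float) + pseudocount
        inp = counts.counts[input_id].to_numpy(dtype=float) + pseudocount
        if np.any(inp <= 0) or np.any(ip <= 0):
            raise InputError(
                f"replicate {rep_id!r} has zero counts with a zero pseudocount; "
                "ratios are undefined"
            )
        ratios[rep_id] = np.log2(ip / inp)
        groups[rep_id] = group
    table = pd.DataFrame(ratios, index=counts.genes)
    return EnrichmentTable(ratios=table, replicate_groups=groups, pseudocount=pseudocount)


def differential_enrichment(
    table: EnrichmentTable,
    group_a: str = "Glp1r",
    group_b: str = "Lepr",
    alpha: float = 0.05,
    significance_on: Literal["p", "padj"] = "p",
) -> EnrichmentTable:
    """Between-group contrast of per-replicate log2 IP/input ratios.

    Welch t per gene, Benjamini–Hochberg across genes.  The
    ``significant`` flag uses nominal p <= alpha by default (the volcano
    convention); set ``significance_on='padj'`` to require the adjusted
    value instead.  Genes with zero variance in both groups and equal
    means get p = 1.
    """
    reps_a = [r for r, g in table.replicate_groups.items() if g == group_a]
    reps_b = [r for r, g in table.replicate_groups.items() if g == group_b]
    if len(reps_a) < 2 or len(reps_b) < 2:
        raise AnalysisError("need at least 2 replicates per group")
    a = table.ratios[reps_a].to_numpy()
    b = table.ratios[reps_b].to_numpy()

    res = sps.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0) & (a.mean(axis=1) == b.mean(axis=1))
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    padj = benjamini_hochberg_adjust(p)

    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    significant = (p if significance_on == "p" else padj) <= alpha
    result = pd.DataFrame(
        {
            f"mean_log2_ratio_{group_a}": mean_a,
            f"mean_log2_ratio_{group_b}": mean_b,
            "log2_fold_difference": mean_a - mean_b,
            "t": t,
            "p": p,
            "padj": padj,
            "significant": significant,
        },
        index=table.ratios.index,
    )
    return EnrichmentTable(
        ratios=table.ratios,
        replicate_groups=table.replicate_groups,
        pseudocount=table.pseudocount,
        result=result,
        method=table.method,
        group_a=group_a,
        group_b=group_b,
    )


def _log_ratio(n_glp1r: int, n_lepr: int, pseudocount: float = 0.0) -> float:
    if pseudocount > 0:
        return math.log2((n_glp1r + pseudocount) / (n_lepr + pseudocount))
    if n_glp1r == 0 and n_lepr == 0:
        return math.nan
    if n_lepr == 0:
        return math.inf
    if n_glp1r == 0:
        return -math.inf
    return math.log2(n_glp1r / n_lepr)


def cluster_overlap_call(
    table: EnrichmentTable,
    markers: MarkerSet,
    threshold: float = 2.0,
    pseudocount: float = 0.0,
) -> list[ClusterCall]:
    """Score each cluster's markers against the enrichment contrast.

    n_glp1r (n_lepr) counts the cluster's markers that are significant
    and enriched toward the Glp1r (Lepr) group by the sign of the log2
    fold difference.  The call is Glp1r_enriched when
    log2(n_glp1r/n_lepr) >= threshold, Lepr_enriched when <= -threshold
    (boundary inclusive).  Zero counts on one side give an infinity
    sentinel and a flag; a cluster with no marker present in the table
    is undefined.
    """
    if not table.completed:
        raise AnalysisError("run differential_enrichment before cluster_overlap_call")
    result = table.result
    assert result is not None
    sig = result["significant"]
    lfd = result["log2_fold_difference"]  # positive -> toward group_a (Glp1r)

    calls = []
    for cluster_id, genes in markers.clusters.items():
        present = [g for g in genes if g in result.index]
        if not present:
            calls.append(
                ClusterCall(
                    cluster_id=str(cluster_id), n_glp1r=0, n_lepr=0,
                    log_ratio=math.nan, call="undefined", flagged=True,
                )
            )
            continue
        sub_sig = sig.loc[present].to_numpy()
        sub_lfd = lfd.loc[present].to_numpy()
        n_glp1r = int(np.sum(sub_sig & (sub_lfd > 0)))
        n_lepr = int(np.sum(sub_sig & (sub_lfd < 0)))
        lr = _log_ratio(n_glp1r, n_lepr, pseudocount)
        flagged = not math.isfinite(lr)
        if math.isnan(lr):
            call = "neither"
        elif lr >= threshold:
            call = "Glp1r_enriched"
        elif lr <= -threshold:
            call = "Lepr_enriched"
        else:
            call = "neither"
        calls.append(
            ClusterCall(
                cluster_id=str(cluster_id), n_glp1r=n_glp1r, n_lepr=n_lepr,
                log_ratio=lr, call=call, flagged=flagged,
            )
        )
    return calls


def gene_zscore_matrix(expression: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Standardize each gene row to mean 0, sample SD 1 across samples.

    Constant rows become all zeros (their SD is undefined) and are left
    flagged via an attrs note on the returned frame.
    """
    df = pd.DataFrame(expression).astype(float)
    if df.shape[1] < 2:
        raise InputError("need at least 2 samples to z-score")
    values = df.to_numpy()
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, ddof=1, keepdims=True)
    constant = sds[:, 0] == 0
    sds[constant] = 1.0
    z = (values - means) / sds
    z[constant] = 0.0
    out = pd.DataFrame(z, index=df.index, columns=df.columns)
    out.attrs["constant_rows"] = df.index[constant].tolist()
    return out
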