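"""Delimited-text interchange layer and run manifests.

All pipeline artifacts are plain TSV with JSON sidecars: traces as
two-column (time_s, value) files with a protocol descriptor, point
clouds as (animal_id, group, x_um, y_um, z_um) tables, counts as
gene-by-sample TSV with a sample sheet, marker sets as (cluster_id,
gene) pairs.  Readers validate the schema and fail with the offending
column or cell; writers are atomic (write to a temp file, then rename)
and every stage output is accompanied by a JSON manifest recording the
package version, seed, parameters and input digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import SchemaError
from .spatial import PointCloud
from .traces import CurrentTrace, StimulusProtocol, VoltageTrace
from .trap import CountMatrix, MarkerSet, SampleMeta

__all__ = [
    "read_table",
    "write_table",
    "write_manifest",
    "write_trace",
    "read_trace",
    "write_point_clouds",
    "read_point_clouds",
    "write_counts",
    "read_counts",
    "read_markers",
    "write_markers",
]

POINT_CLOUD_COLUMNS = {"animal_id": str, "group": str, "x_um": float, "y_um": float, "z_um": float}
SAMPLE_META_COLUMNS = {"sample_id": str, "replicate_id": str, "fraction": str, "group": str}
MARKER_COLUMNS = {"cluster_id": str, "gene": str}


def _atomic_write(path: Path, writer) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def read_table(path: str | Path, schema: Mapping[str, type]) -> pd.DataFrame:
    """Read a TSV and validate it against a column->type schema."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such table: {path}")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    for col, typ in schema.items():
        if typ is float:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(bad.idxmax()) + 2  # header is line 1
                raise SchemaError(f"{path}:{row}: non-numeric value in column {col!r}")
            df[col] = coerced
        else:
            df[col] = df[col].astype(str)
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    _atomic_write(Path(path), lambda tmp: df.to_csv(tmp, sep="\t", index=index))


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def write_manifest(
    out_path: str | Path,
    stage: str,
    parameters: Mapping[str, Any],
    seed: int | None = None,
    inputs: Sequence[str | Path] = (),
) -> Path:
    """Write ``<out_path>.manifest.json`` describing how the artifact was made."""

    def jsonable(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: jsonable(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, Mapping):
            return {str(k): jsonable(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [jsonable(v) for v in obj]
        return obj

    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "parameters": jsonable(dict(parameters)),
        "inputs": {str(p): _digest(Path(p)) for p in inputs},
    }
    path = Path(str(out_path) + ".manifest.json")
    _atomic_write(path, lambda tmp: Path(tmp).write_text(json.dumps(manifest, indent=2)))
    return path


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------


def write_trace(
    trace: VoltageTrace | CurrentTrace,
    path: str | Path,
    protocol: StimulusProtocol | None = None,
) -> None:
    """Two-column (time_s, value) TSV plus a JSON protocol sidecar."""
    label = "voltage_mv" if isinstance(trace, VoltageTrace) else "current_pa"
    df = pd.DataFrame({"time_s": trace.times, label: trace.samples})
    write_table(df, path)
    sidecar = {"sampling_rate_khz": trace.sampling_rate, "t0_s": trace.t0, "kind": label}
    if protocol is not None:
        sidecar["protocol"] = dataclasses.asdict(protocol)
        sidecar["protocol"]["amplitudes"] = list(protocol.amplitudes)
    _atomic_write(
        Path(str(path) + ".json"),
        lambda tmp: Path(tmp).write_text(json.dumps(sidecar, indent=2)),
    )


def read_trace(path: str | Path) -> tuple[VoltageTrace | CurrentTrace, StimulusProtocol | None]:
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    label = sidecar["kind"]
    df = read_table(path, {"time_s": float, label: float})
    cls = VoltageTrace if label == "voltage_mv" else CurrentTrace
    trace = cls(
        samples=df[label].to_numpy(),
        sampling_rate=sidecar["sampling_rate_khz"],
        t0=sidecar["t0_s"],
    )
    protocol = None
    if "protocol" in sidecar:
        protocol = StimulusProtocol(**sidecar["protocol"])
    return trace, protocol


# ---------------------------------------------------------------------------
# point clouds
# ---------------------------------------------------------------------------


def write_point_clouds(clouds: Sequence[PointCloud], path: str | Path) -> None:
    rows = []
    for cloud in clouds:
        for x, y, z in cloud.coordinates:
            rows.append(
                {"animal_id": cloud.animal_id, "group": cloud.group, "x_um": x, "y_um": y, "z_um": z}
            )
    write_table(pd.DataFrame(rows, columns=list(POINT_CLOUD_COLUMNS)), path)


def read_point_clouds(path: str | Path) -> list[PointCloud]:
    df = read_table(path, POINT_CLOUD_COLUMNS)
    clouds = []
    for (animal, group), sub in df.groupby(["animal_id", "group"], sort=False):
        clouds.append(
            PointCloud(
                animal_id=str(animal),
                group=str(group),
                coordinates=sub[["x_um", "y_um", "z_um"]].to_numpy(),
            )
        )
    return clouds


# ---------------------------------------------------------------------------
# counts / metadata / markers
# ---------------------------------------------------------------------------


def write_counts(counts: CountMatrix, meta: SampleMeta, counts_path, meta_path) -> None:
    write_table(counts.counts.rename_axis("gene").reset_index(), counts_path)
    write_table(meta.table, meta_path)


def read_counts(counts_path, meta_path) -> tuple[CountMatrix, SampleMeta]:
    raw = pd.read_csv(counts_path, sep="\t")
    if "gene" not in raw.columns:
        raise SchemaError(f"{counts_path}: missing column(s) ['gene']")
    numeric = raw.set_index("gene")
    for col in numeric.columns:
        coerced = pd.to_numeric(numeric[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.isna().to_numpy().argmax()) + 2
            raise SchemaError(f"{counts_path}:{row}: non-numeric count in sample {col!r}")
        numeric[col] = coerced
    meta = SampleMeta(read_table(meta_path, SAMPLE_META_COLUMNS))
    return CountMatrix(numeric), meta


def write_markers(markers: MarkerSet, path: str | Path) -> None:
    rows = [
        {"cluster_id": cluster, "gene": gene}
        for cluster, genes in markers.clusters.items()
        for gene in genes
    ]
    write_table(pd.DataFrame(rows, columns=list(MARKER_COLUMNS)), path)


def read_markers(path: str | Path) -> MarkerSet:
    df = read_table(path, MARKER_COLUMNS)
    clusters: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        clusters.setdefault(row["cluster_id"], []).append(row["gene"])
    return MarkerSet(clusters)
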