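"""On-disk formats: structure specs, angle histograms, ensembles, estimates.

All formats are plain text.  Structure specifications are JSON; angle
histograms are three-column CSV (``bin_start_deg,bin_end_deg,weight``
with contiguous bins); sampled ensembles are CSV with a JSON sidecar
carrying the configuration, seed and discard statistics needed to
reproduce or validate the run; estimates are JSON with an optional
per-point CSV for heat-map style plotting.
"""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .biophysics import AngleHistogram, BiophysicalConstants, ModelConfig
from .concentration import ConcentrationEstimate
from .errors import InputError
from .sampler import EnsembleResult
from .structures import DomainSpec, StructureSpec

__all__ = [
    "read_structure_spec",
    "write_structure_spec",
    "structure_spec_to_dict",
    "structure_spec_from_dict",
    "read_angle_histogram",
    "write_angle_histogram",
    "write_ensemble",
    "read_ensemble",
    "sidecar_path",
    "write_estimate",
    "write_per_point_csv",
]


def _package_version() -> str:
    try:
        return version("tethersample")
    except PackageNotFoundError:  # running from a source tree
        return "unknown"


# --- structure specs ------------------------------------------------------


def structure_spec_to_dict(spec: StructureSpec, notes: str | None = None) -> dict:
    data = {
        "name": spec.name,
        "tether": list(spec.tether),
        "domains": [
            {
                "name": d.name,
                "kind": d.kind,
                "n_nt": d.n_nt,
                "reactive": d.reactive,
                "nick_after": d.nick_after,
            }
            for d in spec.domains
        ],
    }
    if notes:
        data["notes"] = notes
    return data


def structure_spec_from_dict(data: dict) -> StructureSpec:
    if not isinstance(data, dict):
        raise InputError(f"structure spec must be a JSON object, got {type(data).__name__}")
    for key in ("name", "tether", "domains"):
        if key not in data:
            raise InputError(f"structure spec missing required field {key!r}")
    if not isinstance(data["domains"], list) or not data["domains"]:
        raise InputError("structure spec field 'domains' must be a non-empty list")
    domains = []
    for i, d in enumerate(data["domains"]):
        if not isinstance(d, dict):
            raise InputError(f"domains[{i}] must be an object")
        for key in ("name", "kind", "n_nt"):
            if key not in d:
                raise InputError(f"domains[{i}] missing required field {key!r}")
        domains.append(
            DomainSpec(
                name=str(d["name"]),
                kind=str(d["kind"]),
                n_nt=d["n_nt"],
                reactive=bool(d.get("reactive", False)),
                nick_after=bool(d.get("nick_after", False)),
            )
        )
    try:
        tether = tuple(float(c) for c in data["tether"])
    except (TypeError, ValueError) as exc:
        raise InputError(f"structure spec field 'tether' must be [x, y, z]: {exc}") from exc
    return StructureSpec(name=str(data["name"]), tether=tether, domains=tuple(domains))


def read_structure_spec(path: str | Path) -> StructureSpec:
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise InputError(f"{path}: not valid JSON ({exc})") from exc
    try:
        return structure_spec_from_dict(data)
    except InputError as exc:
        raise InputError(f"{path}: {exc}") from exc


def write_structure_spec(spec: StructureSpec, path: str | Path, notes: str | None = None) -> None:
    Path(path).write_text(json.dumps(structure_spec_to_dict(spec, notes=notes), indent=2) + "\n")


# --- angle histograms -----------------------------------------------------

_HIST_COLUMNS = ["bin_start_deg", "bin_end_deg", "weight"]


def read_angle_histogram(path: str | Path) -> AngleHistogram:
    """Read a nick-angle histogram CSV (bin_start_deg, bin_end_deg, weight)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise InputError(f"{path}: cannot parse histogram CSV ({exc})") from exc
    if list(df.columns) != _HIST_COLUMNS:
        raise InputError(
            f"{path}: expected header {','.join(_HIST_COLUMNS)}, got {','.join(df.columns)}"
        )
    starts = df["bin_start_deg"].to_numpy(dtype=float)
    ends = df["bin_end_deg"].to_numpy(dtype=float)
    if not np.allclose(starts[1:], ends[:-1]):
        raise InputError(f"{path}: histogram bins must be contiguous")
    edges = tuple(starts) + (float(ends[-1]),)
    try:
        return AngleHistogram(bin_edges=edges, weights=tuple(df["weight"]))
    except InputError as exc:
        raise InputError(f"{path}: {exc}") from exc


def write_angle_histogram(hist: AngleHistogram, path: str | Path) -> None:
    edges = hist.bin_edges
    df = pd.DataFrame(
        {
            "bin_start_deg": edges[:-1],
            "bin_end_deg": edges[1:],
            "weight": hist.weights,
        }
    )
    df.to_csv(path, index=False)


# --- ensembles ------------------------------------------------------------


def sidecar_path(csv_path: str | Path) -> Path:
    return Path(csv_path).with_suffix(".json")


def _model_config_meta(config: ModelConfig) -> dict:
    return {
        "model": config.name,
        "ss_length_model": config.ss_length_model.value,
        "nick_angle_model": config.nick_angle_model.value,
        "z_floor": config.z_floor,
        "constants": {
            "len_per_nt_ds": config.constants.len_per_nt_ds,
            "len_per_nt_ss": config.constants.len_per_nt_ss,
            "persistence_ss": config.constants.persistence_ss,
        },
        "nick_histogram": config.nick_histogram.to_dict() if config.nick_histogram else None,
    }


def write_ensemble(
    result: EnsembleResult,
    csv_path: str | Path,
    seed: int | None = None,
    extra_meta: dict | None = None,
) -> None:
    """Write an ensemble CSV (one row per accepted sample) plus JSON sidecar.

    Columns: sample_id, then x/y/z per named joint (tether first, then
    the distal end of each domain, when coordinates were kept), then
    rx/ry/rz for the reactive point.
    """
    csv_path = Path(csv_path)
    data: dict[str, np.ndarray] = {"sample_id": np.arange(result.n)}
    if result.joint_coords is not None:
        names = ["tether"] + [d.name for d in result.spec.domains]
        for j, name in enumerate(names):
            for axis, label in enumerate("xyz"):
                data[f"{name}_{label}"] = result.joint_coords[:, j, axis]
    for axis, label in enumerate("xyz"):
        data[f"r{label}"] = result.reactive_points[:, axis]
    pd.DataFrame(data).to_csv(csv_path, index=False)

    meta = {
        "format": "tethersample-ensemble",
        "package_version": _package_version(),
        "structure": structure_spec_to_dict(result.spec),
        "n": result.n,
        "seed": seed,
        "discard": {
            "n_requested": result.report.n_requested,
            "n_rejected": result.report.n_rejected,
            "discard_ratio": result.report.discard_ratio,
        },
        **_model_config_meta(result.config),
    }
    if extra_meta:
        meta.update(extra_meta)
    sidecar_path(csv_path).write_text(json.dumps(meta, indent=2) + "\n")


def read_ensemble(csv_path: str | Path) -> tuple[np.ndarray, dict]:
    """Load reactive points and sidecar metadata for an ensemble CSV."""
    csv_path = Path(csv_path)
    side = sidecar_path(csv_path)
    if not side.exists():
        raise InputError(f"{csv_path}: missing sidecar {side.name}")
    try:
        meta = json.loads(side.read_text())
    except json.JSONDecodeError as exc:
        raise InputError(f"{side}: not valid JSON ({exc})") from exc
    try:
        df = pd.read_csv(csv_path)
    except Exception as exc:
        raise InputError(f"{csv_path}: cannot parse ensemble CSV ({exc})") from exc
    for col in ("rx", "ry", "rz"):
        if col not in df.columns:
            raise InputError(f"{csv_path}: missing reactive-point column {col!r}")
    points = df[["rx", "ry", "rz"]].to_numpy(dtype=float)
    if points.shape[0] == 0:
        raise InputError(f"{csv_path}: ensemble is empty")
    return points, meta


def check_compatible_ensembles(meta_a: dict, meta_b: dict) -> None:
    """Refuse to mix ensembles sampled under incompatible conventions."""
    for key in ("z_floor", "model", "constants"):
        if meta_a.get(key) != meta_b.get(key):
            raise InputError(
                f"ensembles disagree on {key!r}: {meta_a.get(key)!r} vs {meta_b.get(key)!r}"
            )


# --- estimates ------------------------------------------------------------


def estimate_to_dict(estimate: ConcentrationEstimate, extra: dict | None = None) -> dict:
    data = {
        "format": "tethersample-estimate",
        "package_version": _package_version(),
        "threshold_nm": estimate.config.threshold,
        "k_bi_per_M_per_s": estimate.config.k_bi,
        "reactive_volume_nm3": estimate.reactive_volume,
        "n_target": estimate.n_target,
        "n_query": estimate.n_query,
        "mean_C_nM": estimate.mean_C_nM,
        "k_uni_per_s": estimate.k_uni_per_s,
    }
    if extra:
        data.update(extra)
    return data


def write_estimate(
    estimate: ConcentrationEstimate, path: str | Path, extra: dict | None = None
) -> None:
    Path(path).write_text(json.dumps(estimate_to_dict(estimate, extra), indent=2) + "\n")


def write_per_point_csv(
    estimate: ConcentrationEstimate, query_points: np.ndarray, path: str | Path
) -> None:
    """Per-query-point table (x, y, z, P, C_nM) for downstream plotting."""
    pts = np.asarray(query_points, dtype=float)
    if pts.shape[0] != estimate.per_point_P.shape[0]:
        raise InputError(
            f"query point count {pts.shape[0]} does not match estimate size "
            f"{estimate.per_point_P.shape[0]}"
        )
    pd.DataFrame(
        {
            "x": pts[:, 0],
            "y": pts[:, 1],
            "z": pts[:, 2],
            "P": estimate.per_point_P,
            "C_nM": estimate.per_point_C_nM,
        }
    ).to_csv(path, index=False)
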