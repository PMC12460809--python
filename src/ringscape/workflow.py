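"""Stage orchestration: run each analysis from a config and write tables.

Each stage function takes explicit inputs, writes deterministic TSV/JSON
artifacts into an output directory and returns the paths it wrote. A
machine-readable run log (parameters, package version, seed, input hashes)
accompanies every run so outputs can be traced back to their inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .assay import (
    disassembly_rate,
    find_chromatogram_peaks,
    integrate_window,
    rate_ratio,
    read_chromatogram,
    read_trace,
    smooth_chromatogram,
)
from .geometry import (
    DEFAULT_PAIRS,
    compare_protomer_groups,
    distance_distributions,
    fit_plane,
    subdomain_angle,
    subdomain_centers_of_mass,
)
from .landscape import analyze_landscape, project
from .model_io import load_ensemble, protomer_table
from .partition import read_latent_table, split_tails, write_subsets
from .synthetic import EnsembleSpec, generate_ensemble, write_ensemble

__all__ = [
    "run_extract",
    "run_landscape",
    "run_geometry",
    "run_distances",
    "run_sec",
    "run_kinetics",
    "run_split",
    "run_simulate",
    "run_reproduce",
]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_run_log(out_dir: Path, stage: str, params: dict, inputs: list) -> Path:
    log = {
        "stage": stage,
        "version": _version,
        "parameters": params,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).is_file()},
    }
    path = out_dir / f"{stage}_run.json"
    path.write_text(json.dumps(log, indent=2, default=str) + "\n")
    return path


def _prepare(out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return out_dir


def run_extract(manifest, out_dir) -> dict[str, Path]:
    """Protomer table from an ensemble manifest."""
    out_dir = _prepare(out_dir)
    protomers, _, _ = load_ensemble(manifest)
    table = protomer_table(protomers)
    path = out_dir / "protomers.tsv"
    table.to_csv(path, sep="\t", index=False)
    log = _write_run_log(out_dir, "extract", {"manifest": str(manifest)}, [manifest])
    return {"protomers": path, "log": log}


def run_landscape(
    manifest,
    out_dir,
    variance_target: float = 0.99,
    k_override: int | None = None,
    min_cluster_size: int = 3,
    modes: tuple[int, int] = (1, 5),
    mode: str = "split_subdomains",
) -> dict[str, Path]:
    """Latent coordinates, explained variance and cluster labels."""
    out_dir = _prepare(out_dir)
    protomers, _, domains = load_ensemble(manifest)
    _, result = analyze_landscape(
        protomers, domains, variance_target=variance_target,
        k_override=k_override, min_cluster_size=min_cluster_size, mode=mode,
    )
    latent = pd.DataFrame(
        result.C_trans, columns=[f"pc{i + 1}" for i in range(result.k)]
    )
    latent.insert(0, "model_id", [m for m, _ in result.row_index])
    latent.insert(1, "position", [p for _, p in result.row_index])
    latent["cluster"] = result.cluster_labels
    paths = {}
    paths["latent"] = out_dir / "latent_coordinates.tsv"
    latent.to_csv(paths["latent"], sep="\t", index=False)
    ev = pd.DataFrame(
        {
            "component": np.arange(1, len(result.explained_variance_ratio_full) + 1),
            "explained_variance_ratio": result.explained_variance_ratio_full,
        }
    )
    ev["cumulative"] = ev["explained_variance_ratio"].cumsum()
    paths["explained_variance"] = out_dir / "explained_variance.tsv"
    ev.to_csv(paths["explained_variance"], sep="\t", index=False)
    proj = project(result.C_trans, modes) if max(modes) <= result.k else None
    if proj is not None:
        pdf = pd.DataFrame(proj, columns=[f"mode{modes[0]}", f"mode{modes[1]}"])
        pdf.insert(0, "model_id", [m for m, _ in result.row_index])
        pdf.insert(1, "position", [p for _, p in result.row_index])
        paths["projection"] = out_dir / "projection.tsv"
        pdf.to_csv(paths["projection"], sep="\t", index=False)
    paths["log"] = _write_run_log(
        out_dir, "landscape",
        {
            "manifest": str(manifest), "variance_target": variance_target,
            "k_override": k_override, "k": result.k,
            "min_cluster_size": min_cluster_size, "modes": list(modes), "mode": mode,
        },
        [manifest],
    )
    return paths


def run_geometry(manifest, out_dir) -> dict[str, Path]:
    """Per-protomer subdomain angles and per-model ring-plane fits."""
    out_dir = _prepare(out_dir)
    protomers, _, domains = load_ensemble(manifest)
    rows = [
        {
            "model_id": p.model_id,
            "position": p.position_label,
            "nucleotide_state": p.nucleotide_state,
            "subdomain_angle_deg": subdomain_angle(p, domains),
        }
        for p in protomers
    ]
    paths = {}
    paths["angles"] = out_dir / "subdomain_angles.tsv"
    pd.DataFrame(rows).to_csv(paths["angles"], sep="\t", index=False)

    plane_rows = []
    for model_id in sorted({p.model_id for p in protomers}):
        group = [p for p in protomers if p.model_id == model_id]
        if len(group) < 3:
            continue
        for which in ("large", "small", "both"):
            fit = fit_plane(subdomain_centers_of_mass(group, domains, which))
            plane_rows.append(
                {
                    "model_id": model_id,
                    "points": which,
                    "rms_residual_A": fit.rms_residual,
                    "n_points": fit.points_used,
                }
            )
    paths["planes"] = out_dir / "ring_planes.tsv"
    pd.DataFrame(
        plane_rows, columns=["model_id", "points", "rms_residual_A", "n_points"]
    ).to_csv(paths["planes"], sep="\t", index=False)
    paths["log"] = _write_run_log(out_dir, "geometry", {"manifest": str(manifest)}, [manifest])
    return paths


def run_distances(manifest, out_dir, pairs=DEFAULT_PAIRS) -> dict[str, Path]:
    """Active-site distance table, group summaries and Welch tests."""
    out_dir = _prepare(out_dir)
    protomers, models, domains = load_ensemble(manifest)
    table = distance_distributions(protomers, models, domains, pairs=pairs)
    paths = {}
    paths["distances"] = out_dir / "distances.tsv"
    table.rows.to_csv(paths["distances"], sep="\t", index=False)
    paths["summaries"] = out_dir / "distance_summaries.tsv"
    table.summaries().to_csv(paths["summaries"], sep="\t", index=False)
    tests = []
    for spec in pairs:
        if (table.rows["pair_label"] == spec.label).any():
            tests.append(compare_protomer_groups(table, spec.label))
    paths["tests"] = out_dir / "welch_tests.tsv"
    pd.concat(tests, ignore_index=True).to_csv(paths["tests"], sep="\t", index=False)
    paths["log"] = _write_run_log(out_dir, "distances", {"manifest": str(manifest)}, [manifest])
    return paths


def run_sec(
    trace_path,
    out_dir,
    window: int = 1000,
    polyorder: int = 2,
    min_height: float = 10.0,
    min_distance_ml: float = 1.0,
    min_prominence: float = 0.5,
    integration_windows: list[tuple[float, float]] | None = None,
) -> dict[str, Path]:
    """Chromatogram smoothing, peak table and windowed IAUCs.

    IAUCs are reported for both the raw and the filtered trace.
    """
    out_dir = _prepare(out_dir)
    raw = read_chromatogram(trace_path)
    filtered = smooth_chromatogram(raw, window=window, polyorder=polyorder)
    peaks = find_chromatogram_peaks(
        filtered, min_height=min_height, min_distance_ml=min_distance_ml,
        min_prominence=min_prominence,
    )
    paths = {}
    paths["peaks"] = out_dir / "peaks.tsv"
    peaks.to_frame().to_csv(paths["peaks"], sep="\t", index=False)
    rows = []
    for lo, hi in integration_windows or []:
        rows.append(
            {
                "lo_mL": lo,
                "hi_mL": hi,
                "iauc_raw": integrate_window(raw, lo, hi),
                "iauc_filtered": integrate_window(filtered, lo, hi),
            }
        )
    paths["iauc"] = out_dir / "iauc.tsv"
    pd.DataFrame(rows, columns=["lo_mL", "hi_mL", "iauc_raw", "iauc_filtered"]).to_csv(
        paths["iauc"], sep="\t", index=False
    )
    paths["log"] = _write_run_log(
        out_dir, "sec",
        {
            "trace": str(trace_path), "window": window, "polyorder": polyorder,
            "min_height": min_height, "min_distance_ml": min_distance_ml,
            "min_prominence": min_prominence,
            "integration_windows": integration_windows,
        },
        [trace_path],
    )
    return paths


def run_kinetics(
    trace_paths: list,
    out_dir,
    fit_window: tuple[float, float] = (95.0, 350.0),
    ratio_pairs: list[tuple[str, str]] | None = None,
) -> dict[str, Path]:
    """Disassembly-rate slopes per trace and optional slope ratios."""
    out_dir = _prepare(out_dir)
    slopes = {}
    rows = []
    for p in trace_paths:
        trace = read_trace(p, fit_window=fit_window)
        slope, se = disassembly_rate(trace)
        slopes[trace.label] = (slope, se)
        rows.append({"trace": trace.label, "slope": slope, "stderr": se})
    paths = {}
    paths["rates"] = out_dir / "rates.tsv"
    pd.DataFrame(rows).to_csv(paths["rates"], sep="\t", index=False)
    ratio_rows = []
    for a, b in ratio_pairs or []:
        r, e = rate_ratio(slopes[a], slopes[b])
        ratio_rows.append({"numerator": a, "denominator": b, "ratio": r, "stderr": e})
    paths["ratios"] = out_dir / "rate_ratios.tsv"
    pd.DataFrame(
        ratio_rows, columns=["numerator", "denominator", "ratio", "stderr"]
    ).to_csv(paths["ratios"], sep="\t", index=False)
    paths["log"] = _write_run_log(
        out_dir, "kinetics",
        {"fit_window": list(fit_window), "traces": [str(p) for p in trace_paths]},
        list(trace_paths),
    )
    return paths


def run_split(
    latent_path, out_dir, cutoff_sigma: float = 1.5, absolute: bool = False
) -> dict[str, Path]:
    """Tail/middle particle split on a latent-coordinate table."""
    out_dir = _prepare(out_dir)
    table = read_latent_table(latent_path)
    result = split_tails(table, k=cutoff_sigma, absolute=absolute)
    paths = dict(write_subsets(result, latent_path, out_dir))
    paths["log"] = _write_run_log(
        out_dir, "split",
        {"latent": str(latent_path), "cutoff_sigma": cutoff_sigma, "absolute": absolute},
        [latent_path],
    )
    return paths


def run_simulate(out_dir, spec: EnsembleSpec | None = None, seed: int = 0) -> dict[str, Path]:
    """Write a synthetic ensemble (models + manifest + truth table)."""
    out_dir = _prepare(out_dir)
    if spec is None:
        spec = EnsembleSpec(seed=seed)
    result = generate_ensemble(spec)
    manifest = write_ensemble(result, out_dir)
    with open(out_dir / "spec.yaml", "w") as fh:
        yaml.safe_dump(asdict(spec), fh, sort_keys=False)
    log = _write_run_log(out_dir, "simulate", asdict(spec), [])
    return {"manifest": manifest, "truth": out_dir / "truth.tsv", "log": log}


def run_reproduce(
    manifest,
    out_dir,
    k_override: int | None = None,
    sec_trace=None,
) -> dict[str, Path]:
    """The full published parameterization in one call.

    Landscape at 99% variance (``k_override`` selects a fixed latent
    dimensionality instead), HDBSCAN minimum cluster size 3, projection on
    modes 1 and 5, subdomain angles, ring planes, active-site distances with
    Welch tests; optionally the SEC pipeline (Savitzky-Golay 1000/2, peak
    thresholds 10 mAU / 1 mL / 0.5, windows 12.8-14.8 and 14.8-16.8 mL) on
    ``sec_trace``.
    """
    out_dir = _prepare(out_dir)
    paths = {}
    paths.update({f"landscape_{k}": v for k, v in run_landscape(
        manifest, out_dir, variance_target=0.99, k_override=k_override,
        min_cluster_size=3, modes=(1, 5),
    ).items()})
    paths.update({f"geometry_{k}": v for k, v in run_geometry(manifest, out_dir).items()})
    paths.update({f"distances_{k}": v for k, v in run_distances(manifest, out_dir).items()})
    if sec_trace is not None:
        paths.update({f"sec_{k}": v for k, v in run_sec(
            sec_trace, out_dir, window=1000, polyorder=2, min_height=10.0,
            min_distance_ml=1.0, min_prominence=0.5,
            integration_windows=[(12.8, 14.8), (14.8, 16.8)],
        ).items()})
    return paths
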