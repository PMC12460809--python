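"""Particle-set splitting on 3D-variability latent coordinates.

Continuous conformational heterogeneity in a single-particle dataset can be
expressed as per-particle latent coordinates along variability modes. To
reconstruct the extremes of a mode, a normal distribution is fitted to the
latent coordinate (maximum likelihood: sample mean, population standard
deviation) and the particle set is sliced at ``mu +- k*sigma`` (default
k = 1.5); the two tails feed separate reconstructions while the middle is
set aside. Latent values are treated as signed by default (both tails are
meaningful); an absolute-value mode is available.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SplitResult",
    "read_latent_table",
    "fit_normal",
    "split_tails",
    "write_subsets",
]


def read_latent_table(path) -> pd.DataFrame:
    """Read a per-particle latent-coordinate table (CSV/TSV).

    Expects columns ``particle_id`` and ``coordinate`` (case-insensitive);
    otherwise the first column is taken as the id and the second as the
    coordinate.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    pid = cols.get("particle_id", df.columns[0])
    coord = cols.get("coordinate", df.columns[1])
    out = df.rename(columns={pid: "particle_id", coord: "coordinate"})
    if not np.all(np.isfinite(out["coordinate"].to_numpy(float))):
        raise ValueError(f"{path}: non-finite latent coordinates")
    return out


def fit_normal(values) -> tuple[float, float]:
    """Maximum-likelihood normal fit: (sample mean, population sd)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to fit a normal distribution")
    mu = float(values.mean())
    sigma = float(values.std(ddof=0))
    if sigma == 0.0:
        raise ValueError("all values identical; sigma = 0 is not a valid fit")
    return mu, sigma


@dataclass
class SplitResult:
    mu: float
    sigma: float
    cutoff_k: float
    lower_tail_ids: list
    upper_tail_ids: list
    middle_ids: list

    @property
    def sizes(self) -> dict[str, int]:
        return {
            "lower": len(self.lower_tail_ids),
            "upper": len(self.upper_tail_ids),
            "middle": len(self.middle_ids),
        }


def split_tails(
    table: pd.DataFrame, k: float = 1.5, absolute: bool = False
) -> SplitResult:
    """Partition particles into lower tail / middle / upper tail at
    ``mu +- k*sigma``; boundary ties go to the tails.

    ``absolute`` fits and slices |coordinate| instead of the signed value
    (the lower tail is then the near-mean-magnitude extreme).
    """
    if k <= 0:
        raise ValueError("cutoff multiplier k must be positive")
    coords = table["coordinate"].to_numpy(float)
    if absolute:
        coords = np.abs(coords)
    ids = table["particle_id"].tolist()
    mu, sigma = fit_normal(coords)
    lower = coords <= mu - k * sigma
    upper = coords >= mu + k * sigma
    middle = ~(lower | upper)
    result = SplitResult(
        mu=mu,
        sigma=sigma,
        cutoff_k=float(k),
        lower_tail_ids=[i for i, m in zip(ids, lower) if m],
        upper_tail_ids=[i for i, m in zip(ids, upper) if m],
        middle_ids=[i for i, m in zip(ids, middle) if m],
    )
    for name in ("lower", "upper"):
        if result.sizes[name] == 0:
            warnings.warn(f"{name} tail is empty at k = {k}", stacklevel=2)
    return result


def write_subsets(result: SplitResult, source_table_path, out_dir) -> dict[str, Path]:
    """Write one table per subset, preserving source columns and row order,
    plus a summary JSON with the fit and subset sizes."""
    source_table_path = Path(source_table_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = read_latent_table(source_table_path)
    sep = "\t" if source_table_path.suffix.lower() in {".tsv", ".tab"} else ","
    suffix = source_table_path.suffix or ".csv"
    paths: dict[str, Path] = {}
    for name, subset in (
        ("lower", result.lower_tail_ids),
        ("middle", result.middle_ids),
        ("upper", result.upper_tail_ids),
    ):
        wanted = set(subset)
        sub = table[table["particle_id"].isin(wanted)]
        p = out_dir / f"{source_table_path.stem}_{name}{suffix}"
        sub.to_csv(p, sep=sep, index=False)
        paths[name] = p
    summary = {
        "mu": result.mu,
        "sigma": result.sigma,
        "cutoff_k": result.cutoff_k,
        "sizes": result.sizes,
    }
    spath = out_dir / f"{source_table_path.stem}_split_summary.json"
    spath.write_text(json.dumps(summary, indent=2) + "\n")
    paths["summary"] = spath
    return paths
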