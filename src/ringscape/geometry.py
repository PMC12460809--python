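"""Subdomain geometry and active-site distance statistics.

Helix axes come from the SVD of mean-centered Calpha coordinates (first
right-singular vector, oriented N->C). The inter-helix angle between the
Walker A helix (alpha3, large subdomain) and helix alpha8 (small subdomain)
serves as a proxy for the large-small subdomain hinge angle and is computed
with the numerically stable half-angle form

    theta = 2 * atan2(|u - v|, |u + v|),

which equals arccos(u . v) exactly for unit vectors but does not lose
precision for nearly (anti)parallel axes.

Active-site geometry is summarized as distances between named atom pairs
(e.g. Sensor 1 N374 side chain to the P262 Calpha reference, or to the
nucleotide beta-phosphate Pbeta), tabulated per protomer and compared
between ring position E and every other position with Welch's unequal-
variance t-test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model_io import DomainDefinition, ProtomerRecord, StructureModel, find_site_ligands

__all__ = [
    "HelixAxis",
    "PlaneFit",
    "PairSpec",
    "DistanceTable",
    "DEFAULT_PAIRS",
    "helix_axis",
    "interhelix_angle",
    "subdomain_angle",
    "fit_plane",
    "atom_distance",
    "subdomain_centers_of_mass",
    "distance_distributions",
    "compare_protomer_groups",
    "export_attributes",
]

_DEGENERACY_TOL = 1e-8


@dataclass(frozen=True)
class HelixAxis:
    direction: np.ndarray  # unit vector, N->C oriented
    centroid: np.ndarray
    n_residues: int


def helix_axis(calpha: np.ndarray) -> HelixAxis:
    """Primary axis of an alpha-helix from its ordered Calpha coordinates."""
    calpha = np.asarray(calpha, dtype=float)
    if calpha.ndim != 2 or calpha.shape[1] != 3:
        raise ValueError("calpha must be an (n, 3) array")
    n = calpha.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 residues to fit a helix axis, got {n}")
    centroid = calpha.mean(axis=0)
    _, _, vt = np.linalg.svd(calpha - centroid, full_matrices=False)
    direction = vt[0]
    if float(direction @ (calpha[-1] - calpha[0])) < 0:
        direction = -direction
    return HelixAxis(direction=direction, centroid=centroid, n_residues=n)


def interhelix_angle(u, v) -> float:
    """Angle in degrees, [0, 180], between two helix axes (or 3-vectors)."""
    uu = u.direction if isinstance(u, HelixAxis) else np.asarray(u, dtype=float)
    vv = v.direction if isinstance(v, HelixAxis) else np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(uu), np.linalg.norm(vv)
    if nu <= _DEGENERACY_TOL or nv <= _DEGENERACY_TOL:
        raise ValueError("zero-length axis vector")
    uu, vv = uu / nu, vv / nv
    return math.degrees(
        2.0 * math.atan2(np.linalg.norm(uu - vv), np.linalg.norm(uu + vv))
    )


def subdomain_angle(protomer: ProtomerRecord, domains: DomainDefinition) -> float:
    """Hinge-angle proxy: angle between helices alpha3 and alpha8 (degrees).

    Computed in the protomer's own frame; no superposition is applied first,
    so the value is invariant under rigid motions of the whole protomer.
    """
    axes = []
    for name in ("helix_a3", "helix_a8"):
        residues = list(domains.residues(name))
        missing = [r for r in residues if r not in protomer.calpha_coords]
        if missing:
            lo, hi = getattr(domains, name)
            raise ValueError(
                f"protomer {protomer.key}: helix range {name} ({lo}-{hi}) "
                f"missing residues {missing}"
            )
        axes.append(helix_axis(protomer.coords(residues)))
    return interhelix_angle(axes[0], axes[1])


@dataclass(frozen=True)
class PlaneFit:
    normal: np.ndarray  # unit vector
    offset: float  # plane is n . x = offset
    rms_residual: float
    points_used: int


def fit_plane(points: np.ndarray) -> PlaneFit:
    """Total-least-squares plane through >= 3 non-collinear points."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or points.shape[0] < 3:
        raise ValueError("need an (n >= 3, 3) array of points")
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] <= _DEGENERACY_TOL * max(s[0], 1.0):
        raise ValueError("points are collinear; the plane is underdetermined")
    normal = vt[2]
    i_max = np.argmax(np.abs(normal))
    if normal[i_max] < 0:  # deterministic sign
        normal = -normal
    residuals = centered @ normal
    return PlaneFit(
        normal=normal,
        offset=float(normal @ centroid),
        rms_residual=float(np.sqrt(np.mean(residuals**2))),
        points_used=points.shape[0],
    )


def atom_distance(
    model: StructureModel,
    a: tuple[str, int, str],
    b: tuple[str, int, str],
) -> float:
    """Euclidean distance (Angstrom) between two atoms given as
    ``(chain_id, residue_number, atom_name)`` selectors."""
    pa = model.atom(*a).position
    pb = model.atom(*b).position
    return float(np.linalg.norm(pa - pb))


def subdomain_centers_of_mass(
    protomers: Sequence[ProtomerRecord],
    domains: DomainDefinition,
    which: str = "both",
) -> np.ndarray:
    """Calpha centroids of protomer subdomains, for ring-planarity fits.

    ``which`` selects ``large``, ``small`` or ``both`` (both returns one
    point per subdomain per protomer, large first).
    """
    pts = []
    ranges = {"large": ["large_range"], "small": ["small_range"],
              "both": ["large_range", "small_range"]}[which]
    for p in protomers:
        for rng in ranges:
            residues = [r for r in domains.residues(rng) if r in p.calpha_coords]
            if not residues:
                raise ValueError(f"protomer {p.key} has no residues in {rng}")
            pts.append(p.coords(residues).mean(axis=0))
    return np.array(pts)


# ---------------------------------------------------------------------------
# Distance tables


@dataclass(frozen=True)
class PairSpec:
    """One named atom pair to measure on every protomer.

    ``reference`` is either ``("residue", label, atom_name)`` — a named
    residue of the protomer chain — or ``("nucleotide_pb",)`` for the
    beta-phosphate phosphorus of the bound ATP/ADP (absent for apo sites).
    ``target`` is always ``(label, atom_name)`` against the named-residue map.
    """

    label: str
    reference: tuple
    target: tuple[str, str]


#: Default active-site pairs: Sensor 1, arginine finger 2 and Walker B
#: against both the P262 Calpha reference and the nucleotide Pbeta.
DEFAULT_PAIRS = (
    PairSpec("N374-P262CA", ("residue", "P262", "CA"), ("N374", "CG")),
    PairSpec("R388CZ-P262CA", ("residue", "P262", "CA"), ("R388", "CZ")),
    PairSpec("D328CG-P262CA", ("residue", "P262", "CA"), ("D328", "CG")),
    PairSpec("N374-Pbeta", ("nucleotide_pb",), ("N374", "CG")),
    PairSpec("R388CZ-Pbeta", ("nucleotide_pb",), ("R388", "CZ")),
    PairSpec("D328CG-Pbeta", ("nucleotide_pb",), ("D328", "CG")),
)


@dataclass
class DistanceTable:
    """Per-protomer distances for named atom pairs plus group summaries."""

    rows: pd.DataFrame  # model_id, position, pair_label, distance, nucleotide_state

    def summaries(self) -> pd.DataFrame:
        """Mean/sd/n per (pair_label, is_E)."""
        df = self.rows.copy()
        df["is_E"] = df["position"] == "E"
        out = (
            df.groupby(["pair_label", "is_E"])["distance"]
            .agg(["mean", "std", "count"])
            .rename(columns={"count": "n", "std": "sd"})
            .reset_index()
        )
        return out


def _resolve_reference(
    model: StructureModel,
    protomer: ProtomerRecord,
    domains: DomainDefinition,
    ref: tuple,
    site_radius: float,
):
    chain = protomer.chain_id or protomer.position_label
    if ref[0] == "residue":
        _, label, atom_name = ref
        resnum = domains.named_residues[label]
        if not model.has_atom(chain, resnum, atom_name):
            return None
        return model.atom(chain, resnum, atom_name).position
    if ref[0] == "nucleotide_pb":
        ligands = find_site_ligands(model, chain, domains, site_radius)
        for name in ("ATP", "ADP"):
            if name in ligands:
                lchain, lresnum = ligands[name]
                if model.has_atom(lchain, lresnum, "PB"):
                    return model.atom(lchain, lresnum, "PB").position
        return None
    raise ValueError(f"unknown reference spec {ref!r}")


def distance_distributions(
    protomers: Sequence[ProtomerRecord],
    models: Mapping[str, StructureModel],
    domains: DomainDefinition,
    pairs: Sequence[PairSpec] = DEFAULT_PAIRS,
    site_radius: float = 6.0,
) -> DistanceTable:
    """Measure every resolvable pair on every protomer.

    Missing atoms (including the absent Pbeta of apo protomers) yield absent
    rows with a warning rather than errors, matching how incompletely
    modeled side chains are handled in deposited coordinate sets.
    """
    records = []
    for p in protomers:
        model = models[p.model_id]
        chain = p.chain_id or p.position_label
        for spec in pairs:
            ref_pos = _resolve_reference(model, p, domains, spec.reference, site_radius)
            label, atom_name = spec.target
            resnum = domains.named_residues[label]
            if ref_pos is None or not model.has_atom(chain, resnum, atom_name):
                if spec.reference[0] != "nucleotide_pb" or p.nucleotide_state != "apo":
                    warnings.warn(
                        f"pair {spec.label} unresolvable on {p.key}; row omitted",
                        stacklevel=2,
                    )
                continue
            d = float(np.linalg.norm(model.atom(chain, resnum, atom_name).position - ref_pos))
            records.append(
                {
                    "model_id": p.model_id,
                    "position": p.position_label,
                    "pair_label": spec.label,
                    "distance": d,
                    "nucleotide_state": p.nucleotide_state,
                }
            )
    return DistanceTable(rows=pd.DataFrame.from_records(
        records, columns=["model_id", "position", "pair_label", "distance", "nucleotide_state"]
    ))


def compare_protomer_groups(
    table: DistanceTable,
    pair_label: str,
    focus_position: str = "E",
) -> pd.DataFrame:
    """Welch's t-test of the focus position against every other position.

    Returns one row per comparison with the t statistic, Welch-Satterthwaite
    degrees of freedom, two-sided p-value, and significance flags at 0.05 and
    0.005. Positions with fewer than 2 measurements are skipped with a
    warning.
    """
    df = table.rows[table.rows["pair_label"] == pair_label]
    if df.empty:
        raise ValueError(f"no rows for pair {pair_label!r}")
    focus = df[df["position"] == focus_position]["distance"].to_numpy()
    out = []
    for pos in sorted(df["position"].unique()):
        if pos == focus_position:
            continue
        other = df[df["position"] == pos]["distance"].to_numpy()
        if len(focus) < 2 or len(other) < 2:
            warnings.warn(
                f"pair {pair_label}: group {focus_position} (n={len(focus)}) vs "
                f"{pos} (n={len(other)}) has n < 2; skipped",
                stacklevel=2,
            )
            continue
        res = stats.ttest_ind(focus, other, equal_var=False)
        p = float(res.pvalue)
        out.append(
            {
                "pair_label": pair_label,
                "group_a": focus_position,
                "group_b": pos,
                "n_a": len(focus),
                "n_b": len(other),
                "t": float(res.statistic),
                "df": float(res.df),
                "p": p,
                "significant_0.05": p < 0.05,
                "significant_0.005": p < 0.005,
            }
        )
    return pd.DataFrame.from_records(
        out,
        columns=["pair_label", "group_a", "group_b", "n_a", "n_b", "t", "df",
                 "p", "significant_0.05", "significant_0.005"],
    )


# ---------------------------------------------------------------------------
# Attribute export (molecular-viewer annotation files)


def export_attributes(
    values: Mapping,
    path,
    attribute_name: str,
    recipient: str = "residues",
) -> Path:
    """Write a plain-text attribute file consumable by molecular viewers.

    The format follows the widely supported ``defattr`` convention: keys may
    be ``(chain_id, residue_number)`` tuples (recipient ``residues``) or bare
    chain ids (recipient ``chains``). Rows are emitted in sorted key order so
    output is deterministic.
    """
    if recipient not in {"residues", "chains"}:
        raise ValueError("recipient must be 'residues' or 'chains'")
    path = Path(path)
    lines = [
        f"attribute: {attribute_name}",
        "match mode: 1-to-1",
        f"recipient: {recipient}",
    ]
    for key in sorted(values):
        value = values[key]
        if recipient == "residues":
            try:
                chain, resnum = key
            except (TypeError, ValueError):
                raise ValueError(
                    f"residue attribute keys must be (chain, residue_number); got {key!r}"
                ) from None
            lines.append(f"\t/{chain}:{int(resnum)}\t{value}")
        else:
            lines.append(f"\t/{key}\t{value}")
    path.write_text("\n".join(lines) + "\n")
    return path
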