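"""Conformational-landscape analysis of D1 protomer ensembles.

Pipeline: per-subdomain rigid-body superposition (removes the dominant,
trivial rigid-body motion of the two subdomains) -> flattened Calpha
coordinate matrix over the residues shared by every protomer -> per-column
standardization -> PCA to a fixed explained-variance target -> HDBSCAN
density clustering in the latent space.

The reference protomer is placed in a deterministic canonical frame
(principal axes of its large subdomain, axis signs fixed by the third moment
of the projections, right-handed) before anything is superposed onto it.
This makes the whole pipeline invariant under a global rigid motion of all
input models, so the choice of reference affects only which conformation the
frame is anchored to, not distances in the latent space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation
from sklearn.cluster import HDBSCAN
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .model_io import DomainDefinition, ProtomerRecord, shared_residue_set

__all__ = [
    "CoordinateMatrix",
    "LandscapeResult",
    "superpose",
    "superpose_subdomain",
    "canonical_frame",
    "build_coordinate_matrix",
    "standardize_and_pca",
    "cluster_landscape",
    "project",
    "analyze_landscape",
]

_DEGENERACY_TOL = 1e-8


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[Rotation, np.ndarray, float]:
    """Least-squares rigid-body fit (Kabsch) of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation.apply(mobile) + translation`` best matches ``target`` in the
    least-squares sense (no scaling). Requires >= 3 non-collinear points.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and target must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 atoms to superpose, got {n}")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    a = mobile - mc
    s = np.linalg.svd(a, compute_uv=False)
    if s[1] <= _DEGENERACY_TOL * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) atom set; superposition is underdetermined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # align_vectors warns for exact fits
        rot, _ = Rotation.align_vectors(target - tc, a)
    moved = rot.apply(a) + tc
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    translation = tc - rot.apply(mc)
    return rot, translation, rmsd


def superpose_subdomain(
    protomer: ProtomerRecord,
    reference: ProtomerRecord,
    residue_range: tuple[int, int],
) -> tuple[dict[int, np.ndarray], float]:
    """Superpose one subdomain of ``protomer`` onto ``reference``.

    The fit uses the Calpha atoms shared by both records within
    ``residue_range``; the returned coordinates cover *all* of the
    protomer's residues in the range, transformed into the reference frame.
    """
    lo, hi = residue_range
    in_range = [r for r in range(lo, hi + 1) if r in protomer.calpha_coords]
    shared = [r for r in in_range if r in reference.calpha_coords]
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} shared Calpha in {lo}-{hi} between "
            f"{protomer.key} and {reference.key}; need >= 3"
        )
    rot, trans, rmsd = superpose(protomer.coords(shared), reference.coords(shared))
    moved = rot.apply(protomer.coords(in_range)) + trans
    return {r: moved[i] for i, r in enumerate(in_range)}, rmsd


def canonical_frame(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic, rigid-motion-equivariant frame for a point cloud.

    Returns ``(R, t)`` with ``R @ (x - centroid)`` mapping the cloud into a
    pose where its principal axes coincide with the coordinate axes
    (variance-ordered). Axis signs are fixed by requiring a nonnegative third
    moment of the projections (falling back to the largest-magnitude
    projection if the distribution is symmetric); the third axis is rebuilt
    as a cross product so the frame is always right-handed.
    """
    points = np.asarray(points, dtype=float)
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] <= _DEGENERACY_TOL * max(s[0], 1.0):
        raise ValueError("degenerate point cloud; canonical frame is undefined")
    axes = []
    for i in range(2):
        axis = vt[i]
        proj = centered @ axis
        skew = np.sum(proj**3)
        if abs(skew) <= _DEGENERACY_TOL * max(np.sum(np.abs(proj) ** 3), 1.0):
            sign = np.sign(proj[np.argmax(np.abs(proj))])
        else:
            sign = np.sign(skew)
        axes.append(axis * (sign if sign != 0 else 1.0))
    axes.append(np.cross(axes[0], axes[1]))
    rmat = np.vstack(axes)
    return rmat, centroid


@dataclass
class CoordinateMatrix:
    """Superposed Calpha coordinates over the all-protomer shared residues."""

    C: np.ndarray  # (n_protomers, n_shared_residues, 3)
    row_index: list[tuple[str, str]]  # (model_id, position_label)
    residue_index: list[int]

    def __post_init__(self) -> None:
        if self.C.ndim != 3 or self.C.shape[2] != 3:
            raise ValueError("C must have shape (n, m, 3)")
        if self.C.shape[0] != len(self.row_index) or self.C.shape[1] != len(self.residue_index):
            raise ValueError("index lengths inconsistent with C")

    @property
    def C_flat(self) -> np.ndarray:
        """Row-major flattening: (n_protomers, 3 * n_shared_residues)."""
        return self.C.reshape(self.C.shape[0], -1)


def build_coordinate_matrix(
    protomers: list[ProtomerRecord],
    domains: DomainDefinition,
    mode: str = "split_subdomains",
    reference: ProtomerRecord | None = None,
) -> CoordinateMatrix:
    """Assemble the coordinate matrix ``C`` for the landscape analysis.

    In ``split_subdomains`` mode each protomer's large-subdomain residues are
    superposed onto the reference large subdomain and the small-subdomain
    residues onto the reference small subdomain, then concatenated in residue
    order. ``whole_domain`` superposes over all shared residues at once.
    """
    if len(protomers) < 2:
        raise ValueError("need at least 2 protomers")
    if mode not in {"split_subdomains", "whole_domain"}:
        raise ValueError(f"unknown mode {mode!r}")
    if reference is None:
        reference = protomers[0]

    if mode == "split_subdomains":
        blocks = [domains.large_range, domains.small_range]
    else:
        blocks = [(min(domains.large_range[0], domains.small_range[0]),
                   max(domains.large_range[1], domains.small_range[1]))]

    shared_by_block: list[list[int]] = []
    canonical_ref: dict[int, np.ndarray] = {}
    for lo, hi in blocks:
        shared = shared_residue_set(protomers, [(lo, hi)])
        shared = [r for r in shared if r in reference.calpha_coords]
        if len(shared) < 3:
            raise ValueError(f"fewer than 3 shared residues in {lo}-{hi}")
        shared_by_block.append(shared)
    # canonical frame anchored on the large-subdomain (first block) residues
    rmat, centroid = canonical_frame(reference.coords(shared_by_block[0]))
    for shared in shared_by_block:
        moved = (reference.coords(shared) - centroid) @ rmat.T
        for i, r in enumerate(shared):
            canonical_ref[r] = moved[i]
    ref_canon = ProtomerRecord(
        model_id=reference.model_id,
        position_label=reference.position_label,
        condition=reference.condition,
        nucleotide_state=reference.nucleotide_state,
        substrate_engaged=reference.substrate_engaged,
        calpha_coords=canonical_ref,
        chain_id=reference.chain_id,
    )

    residue_index = [r for shared in shared_by_block for r in shared]
    rows = np.empty((len(protomers), len(residue_index), 3))
    for i, p in enumerate(protomers):
        parts = []
        for (lo, hi), shared in zip(blocks, shared_by_block):
            moved, _ = superpose_subdomain(p, ref_canon, (lo, hi))
            parts.append(np.array([moved[r] for r in shared]))
        rows[i] = np.concatenate(parts, axis=0)
    return CoordinateMatrix(
        C=rows,
        row_index=[p.key for p in protomers],
        residue_index=residue_index,
    )


@dataclass
class LandscapeResult:
    """Standardized/PCA-transformed coordinates plus optional clustering."""

    C_trans: np.ndarray  # (n_protomers, k)
    explained_variance_ratio: np.ndarray  # length k, nonincreasing
    explained_variance_ratio_full: np.ndarray
    k: int
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    components: np.ndarray  # (k, n_features), sign-fixed
    row_index: list[tuple[str, str]] = field(default_factory=list)
    cluster_labels: np.ndarray | None = None
    min_cluster_size: int | None = None


def standardize_and_pca(
    C_flat: np.ndarray,
    variance_target: float = 0.99,
    k_override: int | None = None,
    row_index: list[tuple[str, str]] | None = None,
) -> LandscapeResult:
    """Column-standardize ``C_flat`` and project onto the leading PCs.

    ``k`` is the smallest component count whose cumulative explained variance
    reaches ``variance_target`` unless ``k_override`` is given. Component
    signs follow the convention that each component's largest-magnitude
    loading is positive, making latent coordinates reproducible across runs
    and library versions.
    """
    C_flat = np.asarray(C_flat, dtype=float)
    n = C_flat.shape[0]
    if n < 2:
        raise ValueError("PCA requires at least 2 protomers")
    if not (0.0 < variance_target <= 1.0):
        raise ValueError("variance_target must be in (0, 1]")
    scaler = StandardScaler()
    X = scaler.fit_transform(C_flat)
    pca = PCA()  # all min(n, p) components; truncate after choosing k
    scores = pca.fit_transform(X)
    ratios = pca.explained_variance_ratio_
    if k_override is not None:
        if not (1 <= k_override <= len(ratios)):
            raise ValueError(f"k_override {k_override} outside 1..{len(ratios)}")
        k = int(k_override)
    else:
        k = int(np.searchsorted(np.cumsum(ratios), variance_target - 1e-12) + 1)
        k = min(k, len(ratios))
    components = pca.components_[:k].copy()
    scores = scores[:, :k].copy()
    for j in range(k):
        i_max = np.argmax(np.abs(components[j]))
        if components[j, i_max] < 0:
            components[j] *= -1.0
            scores[:, j] *= -1.0
    return LandscapeResult(
        C_trans=scores,
        explained_variance_ratio=ratios[:k].copy(),
        explained_variance_ratio_full=ratios.copy(),
        k=k,
        scaler_mean=scaler.mean_.copy(),
        scaler_scale=scaler.scale_.copy(),
        components=components,
        row_index=list(row_index) if row_index is not None else [],
    )


def cluster_landscape(C_trans: np.ndarray, min_cluster_size: int = 3) -> np.ndarray:
    """HDBSCAN clustering in the latent space; noise is labeled -1.

    Cluster labels are renumbered 0..m-1 by descending cluster size (ties by
    first appearance) so the labeling is deterministic across library
    versions.
    """
    C_trans = np.asarray(C_trans, dtype=float)
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be >= 2")
    n = C_trans.shape[0]
    if n < min_cluster_size:
        warnings.warn(
            f"{n} points < min_cluster_size {min_cluster_size}; all labeled noise",
            stacklevel=2,
        )
        return np.full(n, -1, dtype=int)
    if np.allclose(C_trans, C_trans[0]):
        return np.zeros(n, dtype=int)  # HDBSCAN is undefined on identical points
    raw = HDBSCAN(min_cluster_size=min_cluster_size, copy=True).fit_predict(C_trans)
    return _relabel_by_size(raw)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    uniq = [l for l in np.unique(labels) if l != -1]
    sizes = {l: int(np.sum(labels == l)) for l in uniq}
    first = {l: int(np.argmax(labels == l)) for l in uniq}
    order = sorted(uniq, key=lambda l: (-sizes[l], first[l]))
    remap = {l: i for i, l in enumerate(order)}
    remap[-1] = -1
    return np.array([remap[l] for l in labels], dtype=int)


def project(C_trans: np.ndarray, modes: tuple[int, int] = (1, 5)) -> np.ndarray:
    """Select two latent modes (1-based) as an (n, 2) projection."""
    C_trans = np.asarray(C_trans)
    k = C_trans.shape[1]
    for m in modes:
        if not (1 <= m <= k):
            raise ValueError(f"mode {m} out of range 1..{k}")
    return C_trans[:, [modes[0] - 1, modes[1] - 1]]


def analyze_landscape(
    protomers: list[ProtomerRecord],
    domains: DomainDefinition,
    variance_target: float = 0.99,
    k_override: int | None = None,
    min_cluster_size: int = 3,
    mode: str = "split_subdomains",
    reference: ProtomerRecord | None = None,
) -> tuple[CoordinateMatrix, LandscapeResult]:
    """Full pipeline: coordinate matrix -> PCA -> HDBSCAN."""
    cm = build_coordinate_matrix(protomers, domains, mode=mode, reference=reference)
    result = standardize_and_pca(
        cm.C_flat, variance_target=variance_target, k_override=k_override,
        row_index=cm.row_index,
    )
    result.cluster_labels = cluster_landscape(result.C_trans, min_cluster_size)
    result.min_cluster_size = min_cluster_size
    return cm, result
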