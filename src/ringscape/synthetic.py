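"""Synthetic inputs with known ground truth for every pipeline stage.

The coordinate generator builds an idealized poly-Calpha scaffold of an
AAA+ D1 domain — helical segments covering the large (224-373) and small
(400-486) subdomains, the connecting linker, and the catalytic marker
residues with minimal side-chain atoms plus a nucleotide site. Conformers
are produced by (i) rotating the small subdomain rigidly about a hinge axis
through the inter-subdomain linker, (ii) translating the Walker A helix
(alpha3) along its own axis between discrete "up/intermediate/down" states,
and (iii) adding isotropic Gaussian noise to every atom. Each planted
cluster therefore has a known hinge angle, helix-shift state and nucleotide
state, which downstream estimators must recover.

The cluster with the largest hinge angle plays the role of the
pre-hydrolysis ring position E: it keeps ATP+Mg with the nucleotide seated
deep in the site, while the other clusters carry ADP displaced outward.
This reproduces, with known effect sizes, the phenomenology the landscape
and distance statistics are designed to detect.

Chromatograms are sums of Gaussian peaks on an optional linear baseline with
white noise; latent-coordinate tables are draws from a single normal;
dequenching traces are straight lines with optional noise. All generators
are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.transform import Rotation

from .assay import Chromatogram, KineticTrace
from .model_io import (
    Atom,
    DomainDefinition,
    POSITION_LABELS,
    ProtomerRecord,
    StructureModel,
    extract_protomers,
    write_model,
)

__all__ = [
    "EnsembleSpec",
    "EnsembleResult",
    "ChromatogramSpec",
    "make_scaffold_model",
    "make_scaffold_protomer",
    "make_hexamer_model",
    "generate_ensemble",
    "write_ensemble",
    "generate_chromatogram",
    "generate_latents",
    "generate_trace",
]

# Ideal alpha-helix parameters: 1.5 A rise and 100 deg twist per residue,
# 2.3 A Calpha radius.
_RISE = 1.5
_TWIST = math.radians(100.0)
_RADIUS = 2.3

# The scaffold chain is built from short helical segments (<= 16 residues)
# whose directions cycle through a closed set, so the fold stays compact
# (~35 A across) and catalytic residues sit at credible mutual distances.
# Two segments are pinned: the Walker A helix alpha3 (350-358) runs along
# +z and helix alpha8 (442-452) is tilted 30 deg from +z in the xz-plane,
# so the baseline alpha3-alpha8 angle is ~30 deg and a hinge rotation about
# +y adds to it directly.
_BASELINE_ANGLE = 30.0
_PINNED_SEGMENTS = {
    (350, 358): (0.0, 0.0, 1.0),
    (442, 452): (math.sin(math.radians(_BASELINE_ANGLE)), 0.0,
                 math.cos(math.radians(_BASELINE_ANGLE))),
}
_DIRECTION_CYCLE = (
    (1.0, 0.25, 0.1),
    (0.2, 1.0, -0.15),
    (-1.0, 0.2, 0.2),
    (-0.15, -1.0, 0.1),
    (1.0, -0.3, -0.2),
    (-1.0, -0.2, -0.15),
)


def _build_segments() -> tuple:
    """Chop 200-486 into short directed segments around the pinned helices."""
    pinned = sorted(_PINNED_SEGMENTS)
    bounds = [200]
    for lo, hi in pinned:
        bounds.extend([lo, hi + 1])
    bounds.append(487)
    segments = []
    k = 0
    for start, stop in zip(bounds[:-1], bounds[1:]):
        if (start, stop - 1) in _PINNED_SEGMENTS:
            segments.append(((start, stop - 1), _PINNED_SEGMENTS[(start, stop - 1)]))
            continue
        r = start
        while r < stop:
            end = min(r + 15, stop - 1)
            segments.append(((r, end), _DIRECTION_CYCLE[k % len(_DIRECTION_CYCLE)]))
            k += 1
            r = end + 1
    return tuple(segments)


_SEGMENTS = _build_segments()

# Minimal side-chain atoms for the catalytic marker residues, as offsets
# from the residue Calpha. Only the atoms the distance statistics use.
_SIDECHAIN_ATOMS = {
    "T267": (("CB", (1.2, 0.8, 0.3)), ("OG1", (2.0, 1.4, 0.6))),
    "D328": (("CB", (1.2, -0.8, 0.3)), ("CG", (2.2, -1.4, 0.6))),
    "E329": (("CB", (1.0, 1.0, -0.3)), ("CD", (2.4, 1.6, -0.6))),
    "N374": (("CB", (1.2, 0.9, 0.2)), ("CG", (2.3, 1.5, 0.4))),
    "R385": (("CB", (0.9, -1.1, 0.2)), ("CZ", (3.0, -2.6, 0.7))),
    "R388": (("CB", (1.1, -0.9, -0.2)), ("CZ", (3.2, -2.2, -0.6))),
    "Y294": (("CB", (1.2, 0.6, -0.4)),),
    "P262": (("CB", (1.1, -0.6, 0.5)),),
}

_RESIDUE_NAMES = {
    "P262": "PRO", "T267": "THR", "Y294": "TYR", "D328": "ASP", "E329": "GLU",
    "N374": "ASN", "R385": "ARG", "R388": "ARG", "I209": "ILE", "S207": "SER",
}


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = _unit(np.cross(axis, ref))
    e2 = np.cross(axis, e1)
    return e1, e2


def ideal_helix(
    n: int, start: np.ndarray, axis, radius: float = _RADIUS,
    rise: float = _RISE, twist: float = _TWIST, phase: float = 0.0,
) -> np.ndarray:
    """Calpha positions of an ideal helix beginning exactly at ``start``."""
    axis = _unit(axis)
    e1, e2 = _frame(axis)
    i = np.arange(n)[:, None]
    ang = twist * np.arange(n) + phase
    ring = radius * (np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2)
    pts = i * rise * axis + ring
    return pts - pts[0] + np.asarray(start, dtype=float)


def _scaffold_calpha() -> dict[int, np.ndarray]:
    coords: dict[int, np.ndarray] = {}
    cursor = np.zeros(3)
    for (lo, hi), axis in _SEGMENTS:
        n = hi - lo + 1
        pts = ideal_helix(n, cursor + _RISE * _unit(axis), axis)
        for k in range(n):
            coords[lo + k] = pts[k]
        cursor = pts[-1]
    return coords


def make_scaffold_model(
    domains: DomainDefinition | None = None,
    chain_id: str = "A",
    nucleotide: str = "ATP_Mg",
    active_site_offset: float = 0.0,
    model_id: str = "scaffold",
) -> StructureModel:
    """Idealized single-protomer model with marker side chains and ligands.

    ``nucleotide`` is any recognized state label; the corresponding ligand
    residues (ATP/ADP, PO4, MG) are placed near the Walker A region,
    displaced outward by ``active_site_offset`` Angstrom (0 = seated deep in
    the site, as in the pre-hydrolysis state).
    """
    domains = domains or DomainDefinition()
    calpha = _scaffold_calpha()
    atoms: list[Atom] = []
    named_by_resnum = {v: k for k, v in domains.named_residues.items()}
    for resnum in sorted(calpha):
        label = named_by_resnum.get(resnum)
        resname = _RESIDUE_NAMES.get(label, "ALA") if label else "ALA"
        atoms.append(Atom(chain_id, resnum, resname, "CA", calpha[resnum], False))
        if label and label in _SIDECHAIN_ATOMS:
            for name, off in _SIDECHAIN_ATOMS[label]:
                atoms.append(
                    Atom(chain_id, resnum, resname, name,
                         calpha[resnum] + np.asarray(off, float), False)
                )
    atoms.extend(_ligand_atoms(domains, calpha, chain_id, nucleotide, active_site_offset))
    return StructureModel(model_id=model_id, atoms=atoms)


def _ligand_atoms(
    domains: DomainDefinition,
    calpha: dict[int, np.ndarray],
    chain_id: str,
    nucleotide: str,
    active_site_offset: float,
) -> list[Atom]:
    if nucleotide == "apo":
        return []
    anchor = calpha[domains.named_residues["T267"]]
    toward = _unit(calpha[domains.named_residues["N374"]] - anchor)
    base = anchor + np.array([3.0, 1.0, 1.0]) - active_site_offset * toward
    atoms: list[Atom] = []
    if nucleotide.startswith("ATP"):
        resname = "ATP"
        names = (("PA", (0.0, 0.0, 0.0)), ("PB", (1.6, 0.6, 0.2)), ("PG", (3.2, 1.1, 0.5)))
    else:
        resname = "ADP"
        names = (("PA", (0.0, 0.0, 0.0)), ("PB", (1.6, 0.6, 0.2)))
    for name, off in names:
        atoms.append(Atom(chain_id, 601, resname, name, base + np.asarray(off), True))
    if "Pi" in nucleotide:
        atoms.append(Atom(chain_id, 602, "PO4", "P", base + np.array([2.0, -1.0, 0.8]), True))
    if nucleotide.endswith("Mg"):
        atoms.append(Atom(chain_id, 603, "MG", "MG", base + np.array([1.0, 2.0, 0.5]), True))
    return atoms


def make_scaffold_protomer(
    domains: DomainDefinition | None = None,
    position_label: str = "A",
    condition: str = "non_hydrolyzing",
) -> ProtomerRecord:
    """Scaffold as a :class:`ProtomerRecord` (extracted via model_io)."""
    domains = domains or DomainDefinition()
    model = make_scaffold_model(domains)
    return extract_protomers(
        model, {position_label: "A"}, domains, condition=condition
    )[0]


def _transform_model(
    model: StructureModel,
    domains: DomainDefinition,
    hinge_angle_deg: float,
    helix_shift: float,
    rng: np.random.Generator | None,
    noise_sigma: float,
    missing_residue_rate: float,
    model_id: str,
    chain_id: str,
    state_phase: float = 0.0,
    loop_amp: float = 0.0,
) -> StructureModel:
    """Apply a planted conformational change plus noise to a scaffold copy."""
    calpha = {a.residue_number: a.position for a in model.atoms if a.atom_name == "CA"}
    hinge_point = 0.5 * (calpha[domains.large_range[1]] + calpha[domains.small_range[0]])
    hinge_axis = np.array([0.0, 1.0, 0.0])
    a3_axis = np.array([0.0, 0.0, 1.0])  # alpha3 is built along +z
    a3_lo, a3_hi = domains.helix_a3
    small_lo = domains.small_range[0]

    hinge_rot = Rotation.from_rotvec(np.radians(hinge_angle_deg) * hinge_axis)
    a8_lo, a8_hi = domains.helix_a8
    sub_lo = domains.large_range[0]
    sub_hi = domains.small_range[1]

    def loop_deformation(resnum: int) -> np.ndarray:
        # Each conformational state comes with its own pattern of
        # distributed loop remodeling (latch loop, linkers, pore loops):
        # a smooth displacement field over the subdomain residues with a
        # state-specific phase and ~1.5 A amplitude — real states differ in
        # which loops move, not merely by magnitudes along one mode. Helix
        # windows are exempt so secondary structure stays rigid and
        # helix-axis geometry reports the planted hinge exactly; this field
        # is what survives rigid-body subdomain superposition and makes the
        # states separable in coordinate PCA.
        if loop_amp == 0.0 or resnum < sub_lo or resnum > sub_hi:
            return np.zeros(3)
        if a3_lo <= resnum <= a3_hi or a8_lo <= resnum <= a8_hi:
            return np.zeros(3)
        return loop_amp * np.array(
            [
                math.sin(2.0 * math.pi * resnum / 37.0 + state_phase),
                math.sin(2.0 * math.pi * resnum / 53.0 + state_phase + 1.0),
                math.sin(2.0 * math.pi * resnum / 71.0 + state_phase + 2.0),
            ]
        )

    atoms: list[Atom] = []
    dropped: set[int] = set()
    if missing_residue_rate > 0 and rng is not None:
        for resnum in sorted(calpha):
            if rng.random() < missing_residue_rate:
                dropped.add(resnum)
    for a in model.atoms:
        if not a.is_hetero and a.residue_number in dropped:
            continue
        pos = a.position.copy()
        if not a.is_hetero and a.residue_number >= small_lo:
            pos = hinge_rot.apply(pos - hinge_point) + hinge_point
        if not a.is_hetero:
            pos = pos + loop_deformation(a.residue_number)
        if not a.is_hetero and a3_lo <= a.residue_number <= a3_hi:
            pos = pos + helix_shift * a3_axis
        if noise_sigma > 0 and rng is not None:
            pos = pos + rng.normal(0.0, noise_sigma, size=3)
        atoms.append(Atom(chain_id, a.residue_number, a.residue_name, a.atom_name, pos, a.is_hetero))
    return StructureModel(model_id=model_id, atoms=atoms)


@dataclass
class EnsembleSpec:
    """Study conditions for a synthetic protomer ensemble.

    Defaults mirror the discrete conformational structure the landscape
    pipeline is meant to resolve: five clusters of six protomers separated
    by >= 5 deg hinge steps, Walker A helix shifts cycling through the three
    discrete up/intermediate/down states (0 / 1.5 / 3.0 A), and 0.3 A
    isotropic coordinate noise. The largest-hinge cluster is the
    pre-hydrolysis "E" state (ATP+Mg, nucleotide seated 2 A deeper than in
    the other clusters).
    """

    n_clusters: int = 5
    protomers_per_cluster: int = 6
    hinge_angles_deg: tuple = (0.0, 6.0, 12.0, 18.0, 24.0)
    helix_shift_states: tuple = (0.0, 1.5, 3.0)
    coordinate_noise_sigma: float = 0.3
    missing_residue_rate: float = 0.0
    seed: int = 0
    condition: str = "hydrolyzing"
    #: amplitude (A) of each state's distributed loop-remodeling field;
    #: the internal (non-rigid) signature distinguishing the states.
    loop_deformation_amp: float = 1.5
    #: ligand displacement out of the active site, per cluster; None ->
    #: 0 A for the largest-hinge (E-like) cluster, 2 A for the others.
    active_site_offsets: tuple | None = None
    #: nucleotide state per cluster; None -> ATP_Mg for the largest-hinge
    #: cluster, ADP for the others.
    nucleotide_by_cluster: tuple | None = None

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.n_clusters > len(POSITION_LABELS):
            raise ValueError(f"n_clusters must be 1..{len(POSITION_LABELS)}")
        if len(self.hinge_angles_deg) != self.n_clusters:
            raise ValueError("need one hinge angle per cluster")
        if len(set(self.hinge_angles_deg)) != self.n_clusters:
            raise ValueError("hinge angles must be distinct")
        if self.coordinate_noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if not (0.0 <= self.missing_residue_rate < 1.0):
            raise ValueError("missing_residue_rate must be in [0, 1)")

    def cluster_positions(self) -> list[str]:
        """Ring-position label per cluster; the largest hinge gets 'E'."""
        e_like = int(np.argmax(self.hinge_angles_deg))
        labels = [l for l in POSITION_LABELS[: max(self.n_clusters, 5)] if l != "E"]
        out = []
        j = 0
        for i in range(self.n_clusters):
            if i == e_like:
                out.append("E")
            else:
                out.append(labels[j])
                j += 1
        return out


@dataclass
class EnsembleResult:
    models: list[StructureModel]
    protomers: list[ProtomerRecord]
    truth: pd.DataFrame
    domains: DomainDefinition
    spec: EnsembleSpec = field(repr=False, default=None)


def generate_ensemble(
    spec: EnsembleSpec, domains: DomainDefinition | None = None
) -> EnsembleResult:
    """Generate ``protomers_per_cluster`` ring models, one chain per cluster.

    Model ``syn000`` .. carry one chain per planted cluster (position label
    assigned by :meth:`EnsembleSpec.cluster_positions`); the ground truth
    table records cluster index, hinge angle, helix-shift state and
    nucleotide state per protomer.
    """
    import warnings as _warnings

    domains = domains or DomainDefinition()
    rng = np.random.default_rng(spec.seed)
    positions = spec.cluster_positions()
    e_like = int(np.argmax(spec.hinge_angles_deg))
    offsets = spec.active_site_offsets or tuple(
        0.0 if i == e_like else 2.0 for i in range(spec.n_clusters)
    )
    nucleotides = spec.nucleotide_by_cluster or tuple(
        "ATP_Mg" if i == e_like else "ADP" for i in range(spec.n_clusters)
    )
    shifts = tuple(
        spec.helix_shift_states[i % len(spec.helix_shift_states)]
        for i in range(spec.n_clusters)
    )

    models: list[StructureModel] = []
    protomers: list[ProtomerRecord] = []
    truth_rows = []
    for m in range(spec.protomers_per_cluster):
        model_id = f"syn{m:03d}"
        atoms: list[Atom] = []
        mapping = {}
        for ci in range(spec.n_clusters):
            chain = positions[ci]
            scaffold = make_scaffold_model(
                domains, chain_id=chain, nucleotide=nucleotides[ci],
                active_site_offset=offsets[ci],
            )
            conformer = _transform_model(
                scaffold, domains,
                hinge_angle_deg=spec.hinge_angles_deg[ci],
                helix_shift=shifts[ci],
                rng=rng,
                noise_sigma=spec.coordinate_noise_sigma,
                missing_residue_rate=spec.missing_residue_rate,
                model_id=model_id, chain_id=chain,
                state_phase=2.399963 * ci,  # golden angle: distinct patterns
                loop_amp=spec.loop_deformation_amp,
            )
            # place the chain at its ring position (a rigid motion; the
            # landscape pipeline removes it, but it keeps the chains and
            # their ligands spatially separated as in a real hexamer)
            ring_rot = Rotation.from_euler("z", 60.0 * POSITION_LABELS.index(chain), degrees=True)
            for a in conformer.atoms:
                atoms.append(
                    Atom(a.chain_id, a.residue_number, a.residue_name, a.atom_name,
                         ring_rot.apply(a.position + np.array([45.0, 0.0, 0.0])),
                         a.is_hetero)
                )
            mapping[chain] = chain
            truth_rows.append(
                {
                    "model_id": model_id,
                    "position": chain,
                    "cluster": ci,
                    "hinge_angle_deg": spec.hinge_angles_deg[ci],
                    "helix_shift": shifts[ci],
                    "nucleotide_state": nucleotides[ci],
                }
            )
        model = StructureModel(model_id=model_id, atoms=atoms)
        models.append(model)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # hetero-near-site warnings are expected
            protomers.extend(
                extract_protomers(model, mapping, domains, condition=spec.condition)
            )
    truth = pd.DataFrame(truth_rows)
    min_cluster = spec.protomers_per_cluster
    if min_cluster < 3:
        import warnings

        warnings.warn(
            f"{min_cluster} protomers per cluster is below the default HDBSCAN "
            "minimum cluster size (3); cluster-recovery tests will be unreliable",
            stacklevel=2,
        )
    return EnsembleResult(models=models, protomers=protomers, truth=truth,
                          domains=domains, spec=spec)


def make_hexamer_model(
    domains: DomainDefinition | None = None,
    ring_radius: float = 45.0,
    model_id: str = "hexamer",
    hinge_angles_deg: tuple = (0.0,) * 6,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> StructureModel:
    """Six scaffold protomers arranged around a ring (chains A-F).

    Subdomain centers of mass lie close to a common plane, which makes this
    the fixture for ring-planarity fits.
    """
    domains = domains or DomainDefinition()
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    for k, chain in enumerate(POSITION_LABELS):
        scaffold = make_scaffold_model(domains, chain_id=chain)
        conf = _transform_model(
            scaffold, domains, hinge_angle_deg=hinge_angles_deg[k], helix_shift=0.0,
            rng=rng if noise_sigma > 0 else None, noise_sigma=noise_sigma,
            missing_residue_rate=0.0, model_id=model_id, chain_id=chain,
        )
        rot = Rotation.from_euler("z", 60.0 * k, degrees=True)
        for a in conf.atoms:
            pos = rot.apply(a.position + np.array([ring_radius, 0.0, 0.0]))
            atoms.append(Atom(chain, a.residue_number, a.residue_name, a.atom_name, pos, a.is_hetero))
    return StructureModel(model_id=model_id, atoms=atoms)


def write_ensemble(result: EnsembleResult, out_dir) -> Path:
    """Write PDB models, a manifest YAML and the truth table to ``out_dir``."""
    out_dir = Path(out_dir)
    (out_dir / "models").mkdir(parents=True, exist_ok=True)
    entries = []
    for model in result.models:
        rel = f"models/{model.model_id}.pdb"
        write_model(model, out_dir / rel)
        chains = sorted({p.chain_id for p in result.protomers if p.model_id == model.model_id})
        entries.append(
            {
                "path": rel,
                "id": model.model_id,
                "condition": result.spec.condition if result.spec else "hydrolyzing",
                "chains": {c: c for c in chains},
            }
        )
    manifest = {"models": entries}
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    result.truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return out_dir / "manifest.yaml"


# ---------------------------------------------------------------------------
# Chromatograms, latent tables, kinetic traces


@dataclass
class ChromatogramSpec:
    """Multi-peak Gaussian elution profile.

    Default peaks emulate a four-species SEC separation (apexes at 9.6,
    11.6, 13.6 and 15.8 mL) sampled at 0.002 mL/point over 0-25 mL with
    0.5 mAU white noise and a flat baseline. ``peaks`` entries are
    (center mL, height mAU, sigma mL); the true area of each peak is
    ``height * sigma * sqrt(2 pi)``.
    """

    peaks: tuple = ((9.6, 50.0, 0.15), (11.6, 20.0, 0.20),
                    (13.6, 30.0, 0.20), (15.8, 25.0, 0.25))
    baseline_slope: float = 0.0  # mAU/mL
    baseline_intercept: float = 0.0  # mAU
    noise_sigma: float = 0.5  # mAU
    sampling_step: float = 0.002  # mL/point
    volume_range: tuple = (0.0, 25.0)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.volume_range
        for center, height, width in self.peaks:
            if not (lo <= center <= hi):
                raise ValueError(f"peak center {center} outside range {self.volume_range}")
            if width <= 0:
                raise ValueError("peak widths must be positive")

    def true_areas(self) -> list[float]:
        return [h * w * math.sqrt(2.0 * math.pi) for _, h, w in self.peaks]


def generate_chromatogram(spec: ChromatogramSpec) -> tuple[Chromatogram, pd.DataFrame]:
    """Synthesize the trace and return it with the per-peak truth table."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.volume_range
    volume = np.arange(lo, hi + spec.sampling_step / 2, spec.sampling_step)
    signal = spec.baseline_intercept + spec.baseline_slope * volume
    for center, height, width in spec.peaks:
        signal = signal + height * np.exp(-0.5 * ((volume - center) / width) ** 2)
    if spec.noise_sigma > 0:
        signal = signal + rng.normal(0.0, spec.noise_sigma, size=volume.size)
    truth = pd.DataFrame(
        {
            "center_mL": [p[0] for p in spec.peaks],
            "height_mAU": [p[1] for p in spec.peaks],
            "sigma_mL": [p[2] for p in spec.peaks],
            "area_mAU_mL": spec.true_areas(),
        }
    )
    return Chromatogram(volume, signal, label="synthetic"), truth


def generate_latents(
    n: int, mu: float = 0.0, sigma: float = 1.0, seed: int = 0
) -> pd.DataFrame:
    """Per-particle latent coordinates drawn from N(mu, sigma^2)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "particle_id": np.arange(n),
            "coordinate": rng.normal(mu, sigma, size=n),
        }
    )


def generate_trace(
    slope: float,
    intercept: float = 0.0,
    noise: float = 0.0,
    window: tuple = (95.0, 350.0),
    seed: int = 0,
    t_max: float = 600.0,
    dt: float = 2.5,
) -> KineticTrace:
    """Linear-phase dequenching trace: signal = intercept + slope * t."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_max + dt / 2, dt)
    s = intercept + slope * t
    if noise > 0:
        s = s + rng.normal(0.0, noise, size=t.size)
    return KineticTrace(t, s, fit_window=tuple(window), label="synthetic")
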