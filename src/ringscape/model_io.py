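"""Reading coordinate models and extracting AAA+ D1 protomers.

Structures are parsed with :mod:`gemmi` (PDB and mmCIF). A protomer is one
subunit of the hexameric ATPase ring; its catalytic D1 domain is split into a
large and a small subdomain whose relative rigid-body motion dominates the
conformational variance of the ring. Residue numbering is taken verbatim from
the deposited model (author numbering, 1-based inclusive intervals).

Nucleotide state is assigned geometrically: any recognized ligand (ATP, ADP,
inorganic phosphate, Mg) with an atom within ``site_radius`` of the protomer's
P-loop (Walker A) Calpha atoms is counted toward the state. Manual overrides
per protomer are supported through the ensemble manifest because deposited
annotations are frequently only available as supplementary tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

import gemmi

__all__ = [
    "Atom",
    "StructureModel",
    "DomainDefinition",
    "ProtomerRecord",
    "NUCLEOTIDE_STATES",
    "load_model",
    "write_model",
    "extract_protomers",
    "assign_nucleotide_state",
    "find_site_ligands",
    "shared_residue_set",
    "load_ensemble",
    "protomer_table",
]

#: Recognized nucleotide-state labels, from empty site to fully occupied.
NUCLEOTIDE_STATES = (
    "apo",
    "ATP",
    "ATP_Mg",
    "ADP",
    "ADP_Pi",
    "ADP_Pi_Mg",
    "ADP_Mg",
)

_LIGAND_NAMES = {"ATP", "ADP", "PO4", "PI", "MG"}

CONDITIONS = ("hydrolyzing", "non_hydrolyzing")


@dataclass(frozen=True)
class Atom:
    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    position: np.ndarray  # (3,) Angstrom
    is_hetero: bool


@dataclass
class StructureModel:
    """Parsed atomic coordinates with chain/residue/atom identity."""

    model_id: str
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"model {self.model_id!r} contains no atoms")
        for a in self.atoms:
            if not np.all(np.isfinite(a.position)):
                raise ValueError(
                    f"non-finite coordinates for {a.chain_id}/{a.residue_number}/{a.atom_name}"
                )
        self._index: dict[tuple[str, int, str], Atom] = {}
        for a in self.atoms:
            key = (a.chain_id, a.residue_number, a.atom_name)
            if key in self._index:
                raise ValueError(f"duplicate atom {key} in model {self.model_id!r}")
            self._index[key] = a

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def atom(self, chain_id: str, residue_number: int, atom_name: str) -> Atom:
        try:
            return self._index[(chain_id, residue_number, atom_name)]
        except KeyError:
            raise KeyError(
                f"atom {chain_id}/{residue_number}/{atom_name} not present "
                f"in model {self.model_id!r}"
            ) from None

    def has_atom(self, chain_id: str, residue_number: int, atom_name: str) -> bool:
        return (chain_id, residue_number, atom_name) in self._index

    def chain_atoms(self, chain_id: str) -> list[Atom]:
        return [a for a in self.atoms if a.chain_id == chain_id]


def _interval(v) -> tuple[int, int]:
    lo, hi = int(v[0]), int(v[1])
    if hi < lo:
        raise ValueError(f"empty residue interval {v}")
    return lo, hi


@dataclass
class DomainDefinition:
    """Residue intervals defining the D1 subdomains and marker elements.

    Intervals are author-numbered, 1-based, inclusive. Defaults correspond to
    the NSF D1 domain: large subdomain 224-373 (with the Walker A helix
    alpha3 at 350-358), small subdomain 400-486 (with helix alpha8 at
    442-452 and the latch loop at 457-467). ``named_residues`` maps catalytic
    and reference residue labels to author residue numbers.
    """

    large_range: tuple[int, int] = (224, 373)
    small_range: tuple[int, int] = (400, 486)
    helix_a3: tuple[int, int] = (350, 358)
    helix_a8: tuple[int, int] = (442, 452)
    latch_loop: tuple[int, int] = (457, 467)
    named_residues: dict[str, int] = field(
        default_factory=lambda: {
            "P262": 262,
            "T267": 267,
            "Y294": 294,
            "D328": 328,
            "E329": 329,
            "N374": 374,
            "R385": 385,
            "R388": 388,
            "I209": 209,
            "S207": 207,
        }
    )
    #: Calpha residues used as the Walker A / P-loop reference for ligand
    #: proximity (spans P262..T267 plus one residue of margin).
    p_loop_range: tuple[int, int] = (261, 268)

    def __post_init__(self) -> None:
        self.large_range = _interval(self.large_range)
        self.small_range = _interval(self.small_range)
        self.helix_a3 = _interval(self.helix_a3)
        self.helix_a8 = _interval(self.helix_a8)
        self.latch_loop = _interval(self.latch_loop)
        self.p_loop_range = _interval(self.p_loop_range)
        if not (self.large_range[1] < self.small_range[0]
                or self.small_range[1] < self.large_range[0]):
            raise ValueError("large and small subdomain ranges overlap")
        if not (self.large_range[0] <= self.helix_a3[0]
                and self.helix_a3[1] <= self.large_range[1]):
            raise ValueError("helix_a3 must lie within large_range")
        if not (self.small_range[0] <= self.helix_a8[0]
                and self.helix_a8[1] <= self.small_range[1]):
            raise ValueError("helix_a8 must lie within small_range")

    def residues(self, which: str) -> range:
        lo, hi = getattr(self, which)
        return range(lo, hi + 1)

    def subdomain_residues(self) -> list[int]:
        return list(self.residues("large_range")) + list(self.residues("small_range"))


POSITION_LABELS = ("A", "B", "C", "D", "E", "F")


@dataclass
class ProtomerRecord:
    """One D1 protomer: ring position, condition, state, and Calpha trace."""

    model_id: str
    position_label: str
    condition: str
    nucleotide_state: str
    substrate_engaged: bool
    calpha_coords: dict[int, np.ndarray]
    chain_id: str = ""

    def __post_init__(self) -> None:
        if self.position_label not in POSITION_LABELS:
            raise ValueError(f"position label must be one of {POSITION_LABELS}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.nucleotide_state not in NUCLEOTIDE_STATES:
            raise ValueError(f"unknown nucleotide state {self.nucleotide_state!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.model_id, self.position_label)

    def coords(self, residues: Iterable[int]) -> np.ndarray:
        """Stack Calpha coordinates for ``residues`` (all must be present)."""
        try:
            return np.array([self.calpha_coords[r] for r in residues], dtype=float)
        except KeyError as exc:
            raise KeyError(
                f"residue {exc.args[0]} missing from protomer "
                f"{self.model_id}/{self.position_label}"
            ) from None


# ---------------------------------------------------------------------------
# Parsing


def load_model(path, fmt: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken by alphabetical altloc id); hydrogens are dropped;
    insertion-coded residues are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt not in {"auto", "pdb", "mmcif"}:
        raise ValueError(f"unknown format {fmt!r}")
    try:
        if fmt == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path} contains no coordinate model")
    model = st[0]

    # altloc resolution: best = (highest occupancy, lowest altloc id)
    best: dict[tuple[str, int, str], tuple[float, str, Atom]] = {}
    order: list[tuple[str, int, str]] = []
    for chain in model:
        for res in chain:
            seqid = res.seqid
            if seqid.icode not in (" ", "", "\x00"):
                raise ValueError(
                    f"{path}: insertion-coded residue {chain.name}/{seqid.num}{seqid.icode} "
                    "is not supported; renumber the model first"
                )
            is_het = res.het_flag == "H"
            for at in res:
                if at.is_hydrogen():
                    continue
                key = (chain.name, seqid.num, at.name)
                cand = (
                    float(at.occ),
                    at.altloc or "",
                    Atom(
                        chain_id=chain.name,
                        residue_number=seqid.num,
                        residue_name=res.name,
                        atom_name=at.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        is_hetero=is_het,
                    ),
                )
                if key not in best:
                    best[key] = cand
                    order.append(key)
                else:
                    occ, alt, _ = best[key]
                    if cand[0] > occ or (cand[0] == occ and cand[1] < alt):
                        best[key] = cand
    atoms = [best[k][2] for k in order]
    if not atoms:
        raise ValueError(f"{path} contains no non-hydrogen atoms")
    return StructureModel(model_id=path.stem, atoms=atoms)


def write_model(model: StructureModel, path) -> Path:
    """Write a :class:`StructureModel` to PDB (or mmCIF by .cif suffix)."""
    path = Path(path)
    # group atoms by chain and residue first: gemmi's add_* methods copy
    # their argument, so containers must be fully populated bottom-up
    grouped: dict[str, dict[tuple[int, str, bool], list[Atom]]] = {}
    for a in model.atoms:
        grouped.setdefault(a.chain_id, {}).setdefault(
            (a.residue_number, a.residue_name, a.is_hetero), []
        ).append(a)
    st = gemmi.Structure()
    st.name = model.model_id
    gm = gemmi.Model("1")
    for chain_id, residues in grouped.items():
        chain = gemmi.Chain(chain_id)
        for (resnum, resname, is_het), atoms in residues.items():
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resnum, " ")
            res.het_flag = "H" if is_het else "A"
            for a in atoms:
                at = gemmi.Atom()
                at.name = a.atom_name
                at.pos = gemmi.Position(*a.position)
                at.occ = 1.0
                at.element = gemmi.Element(_guess_element(a.atom_name))
                res.add_atom(at)
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    if path.suffix.lower() in {".cif", ".mmcif"}:
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))
    return path


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    if stripped.upper().startswith("MG"):
        return "Mg"
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "C"


# ---------------------------------------------------------------------------
# Protomer extraction and nucleotide states


def extract_protomers(
    model: StructureModel,
    mapping: Mapping[str, str],
    domains: DomainDefinition,
    condition: str,
    engagement_flags: Mapping[str, bool] | None = None,
    nucleotide_overrides: Mapping[str, str] | None = None,
    site_radius: float = 6.0,
) -> list[ProtomerRecord]:
    """Extract one :class:`ProtomerRecord` per mapped ring position.

    ``mapping`` assigns ring positions (A-F) to chain ids. Calpha coordinates
    are restricted to the large/small subdomain ranges; residues absent from
    the model are simply absent from the record (never zero-filled).
    """
    if not mapping:
        raise ValueError("mapping must cover at least one ring position")
    engagement_flags = engagement_flags or {}
    nucleotide_overrides = nucleotide_overrides or {}
    available = set(model.chain_ids)
    records = []
    for position in sorted(mapping):
        chain_id = mapping[position]
        if chain_id not in available:
            raise ValueError(
                f"chain {chain_id!r} (position {position}) absent from model "
                f"{model.model_id!r}; available chains: {sorted(available)}"
            )
        calpha: dict[int, np.ndarray] = {}
        for resnum in domains.subdomain_residues():
            if model.has_atom(chain_id, resnum, "CA"):
                calpha[resnum] = model.atom(chain_id, resnum, "CA").position
        if position in nucleotide_overrides:
            state = nucleotide_overrides[position]
        else:
            state = assign_nucleotide_state(model, chain_id, domains, site_radius)
        records.append(
            ProtomerRecord(
                model_id=model.model_id,
                position_label=position,
                condition=condition,
                nucleotide_state=state,
                substrate_engaged=bool(engagement_flags.get(position, True)),
                calpha_coords=calpha,
                chain_id=chain_id,
            )
        )
    return records


def find_site_ligands(
    model: StructureModel,
    chain_id: str,
    domains: DomainDefinition,
    site_radius: float = 6.0,
) -> dict[str, tuple[str, int]]:
    """Locate recognized ligand residues near one protomer's P-loop.

    Returns ``{residue_name: (chain_id, residue_number)}`` for every ligand
    residue (ATP/ADP/PO4/PI/MG) with at least one atom within ``site_radius``
    of any P-loop Calpha of the given chain.
    """
    if site_radius <= 0:
        raise ValueError("site_radius must be positive")
    ref = np.array(
        [
            model.atom(chain_id, r, "CA").position
            for r in domains.residues("p_loop_range")
            if model.has_atom(chain_id, r, "CA")
        ]
    )
    if ref.size == 0:
        raise ValueError(
            f"no P-loop Calpha atoms in chain {chain_id!r} of model {model.model_id!r}"
        )
    found: dict[str, tuple[str, int]] = {}
    for a in model.atoms:
        if not a.is_hetero or a.residue_name.upper() not in _LIGAND_NAMES:
            continue
        d = np.linalg.norm(ref - a.position, axis=1).min()
        if d <= site_radius:
            found.setdefault(a.residue_name.upper(), (a.chain_id, a.residue_number))
    return found


def assign_nucleotide_state(
    model: StructureModel,
    chain_id: str,
    domains: DomainDefinition,
    site_radius: float = 6.0,
) -> str:
    """Geometric nucleotide-state call for one protomer (see module docs)."""
    ligands = find_site_ligands(model, chain_id, domains, site_radius)
    has_atp = "ATP" in ligands
    has_adp = "ADP" in ligands
    has_pi = "PO4" in ligands or "PI" in ligands
    has_mg = "MG" in ligands
    if has_atp and has_adp:
        raise ValueError(
            f"ambiguous nucleotide state for chain {chain_id!r} of "
            f"{model.model_id!r}: both ATP and ADP within {site_radius} A"
        )
    if has_atp:
        if has_pi:
            warnings.warn(
                f"free phosphate near an ATP site ({model.model_id}/{chain_id}); "
                "ignored in the state label",
                stacklevel=2,
            )
        return "ATP_Mg" if has_mg else "ATP"
    if has_adp:
        if has_pi and has_mg:
            return "ADP_Pi_Mg"
        if has_pi:
            return "ADP_Pi"
        if has_mg:
            return "ADP_Mg"
        return "ADP"
    return "apo"


def shared_residue_set(
    protomers: Sequence[ProtomerRecord],
    ranges: Sequence[tuple[int, int]],
) -> list[int]:
    """Sorted residues present in *every* protomer, restricted to ``ranges``."""
    if not protomers:
        raise ValueError("need at least one protomer")
    allowed: set[int] = set()
    for lo, hi in ranges:
        allowed.update(range(lo, hi + 1))
    shared = set(protomers[0].calpha_coords) & allowed
    for p in protomers[1:]:
        shared &= set(p.calpha_coords)
    if not shared:
        raise ValueError("no residue is present in all protomers within the given ranges")
    return sorted(shared)


# ---------------------------------------------------------------------------
# Ensemble manifests


def load_ensemble(
    manifest_path,
    domains: DomainDefinition | None = None,
    site_radius: float = 6.0,
) -> tuple[list[ProtomerRecord], dict[str, StructureModel], DomainDefinition]:
    """Load every protomer described by an ensemble manifest (YAML).

    The manifest lists model files with their experimental condition, a
    position->chain mapping, optional engagement flags and nucleotide-state
    overrides; an optional ``domains`` section overrides interval defaults.
    Paths are resolved relative to the manifest file.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        doc = yaml.safe_load(fh)
    if not doc or "models" not in doc or not doc["models"]:
        raise ValueError(f"manifest {manifest_path} lists no models")
    if domains is None:
        overrides = doc.get("domains") or {}
        domains = DomainDefinition(**overrides)
    protomers: list[ProtomerRecord] = []
    models: dict[str, StructureModel] = {}
    for entry in doc["models"]:
        mpath = Path(entry["path"])
        if not mpath.is_absolute():
            mpath = manifest_path.parent / mpath
        model = load_model(mpath, fmt=entry.get("format", "auto"))
        if "id" in entry:
            model.model_id = str(entry["id"])
        models[model.model_id] = model
        protomers.extend(
            extract_protomers(
                model,
                mapping=entry["chains"],
                domains=domains,
                condition=entry.get("condition", "non_hydrolyzing"),
                engagement_flags=entry.get("engaged"),
                nucleotide_overrides=entry.get("nucleotide_overrides"),
                site_radius=site_radius,
            )
        )
    return protomers, models, domains


def protomer_table(protomers: Sequence[ProtomerRecord]) -> pd.DataFrame:
    """Summary table: one row per protomer."""
    return pd.DataFrame(
        {
            "model_id": [p.model_id for p in protomers],
            "position": [p.position_label for p in protomers],
            "condition": [p.condition for p in protomers],
            "nucleotide_state": [p.nucleotide_state for p in protomers],
            "engaged": [p.substrate_engaged for p in protomers],
            "n_residues": [len(p.calpha_coords) for p in protomers],
        }
    )
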