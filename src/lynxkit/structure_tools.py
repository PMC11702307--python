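"""Desk-scale structural analysis of receptor–ligand complexes.

Small, transparent analogs of the structural operations used to place and
score a three-finger ligand against a receptor subunit interface: PDB
round-tripping, Kabsch least-squares superposition and chain-aligned Cα
RMSD, steric "bad contact" counting, the outward clash-minimizing
placement search along the inter-surface vector, simple nonbonded
(Lennard-Jones 12-6 + Coulomb) interaction energies, and distance-based
hydrogen-bond and salt-bridge detection.  These operate on toy or
user-supplied coordinate sets; they are not a molecular-mechanics engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial.distance import cdist

__all__ = [
    "Atom",
    "Structure",
    "PlacementResult",
    "InteractionReport",
    "NonbondedParams",
    "COULOMB_CONSTANT",
    "DEFAULT_CLASH_CUTOFF",
    "read_pdb",
    "write_pdb",
    "kabsch_superpose",
    "chain_aligned_rmsd",
    "count_bad_contacts",
    "outward_placement_search",
    "interaction_energy",
    "detect_hbonds",
    "detect_salt_bridges",
]

#: Coulomb constant, kcal·Å/(mol·e²), with a uniform dielectric of 1.
COULOMB_CONSTANT = 332.06

#: Inter-heavy-atom distance (Å) below which a pair is a "bad contact".
DEFAULT_CLASH_CUTOFF = 3.0

HBOND_MAX_DA = 3.5  # donor-acceptor heavy-atom distance, Å
SALT_BRIDGE_MAX = 4.0  # charged-group N/O distance, Å


@dataclass(frozen=True)
class Atom:
    chain: str
    residue_number: int
    residue_name: str
    name: str
    element: str
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError("atom coordinates must be finite")

    @property
    def key(self) -> tuple:
        return (self.chain, self.residue_number, self.name)


@dataclass
class Structure:
    """A list of atoms with unique (chain, residue, atom-name) keys."""

    atoms: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [a.key for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, residue, atom name) keys")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            replace(a, x=float(c[0]), y=float(c[1]), z=float(c[2]))
            for a, c in zip(self.atoms, coords)
        ]
        return Structure(atoms, metadata=dict(self.metadata))

    def translated(self, vector) -> "Structure":
        return self.with_coords(self.coords + np.asarray(vector, dtype=float))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        return self.with_coords(self.coords @ np.asarray(rotation).T + translation)

    def select(self, chain=None, residue_numbers=None, names=None) -> list:
        """Indices of atoms matching the given chain / residues / atom names."""
        out = []
        residue_numbers = set(residue_numbers) if residue_numbers is not None else None
        names = set(names) if names is not None else None
        for i, a in enumerate(self.atoms):
            if chain is not None and a.chain != chain:
                continue
            if residue_numbers is not None and a.residue_number not in residue_numbers:
                continue
            if names is not None and a.name not in names:
                continue
            out.append(i)
        return out

    def heavy_indices(self) -> list:
        return [i for i, a in enumerate(self.atoms) if a.element.upper() != "H"]

    def ca_coords(self, chains) -> tuple:
        """(sorted (chain, resnum) keys, Cα coordinate array) for the chains."""
        chains = set(chains)
        entries = {
            (a.chain, a.residue_number): (a.x, a.y, a.z)
            for a in self.atoms
            if a.chain in chains and a.name == "CA"
        }
        keys = sorted(entries)
        return keys, np.array([entries[k] for k in keys], dtype=float)


def read_pdb(path) -> Structure:
    """Parse ATOM/HETATM records of a PDB file into a :class:`Structure`."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure("s", str(path)).get_models())
    atoms = []
    for chain in model:
        for residue in chain:
            for atom in residue:
                x, y, z = atom.coord
                element = atom.element or atom.get_name()[0]
                atoms.append(
                    Atom(
                        chain=chain.id,
                        residue_number=residue.id[1],
                        residue_name=residue.get_resname().strip(),
                        name=atom.get_name().strip(),
                        element=element.strip().upper(),
                        x=float(x),
                        y=float(y),
                        z=float(z),
                    )
                )
    if not atoms:
        raise ValueError(f"no ATOM/HETATM records parsed from {path}")
    return Structure(atoms)


def write_pdb(structure: Structure, path) -> None:
    """Write a Structure as fixed-column PDB (coordinates to 3 decimals)."""
    from Bio.PDB import PDBIO
    from Bio.PDB.StructureBuilder import StructureBuilder

    builder = StructureBuilder()
    builder.init_structure("s")
    builder.init_model(0)
    current_chain = None
    current_res = None
    for i, a in enumerate(structure.atoms):
        if a.chain != current_chain:
            builder.init_chain(a.chain)
            builder.init_seg("    ")
            current_chain = a.chain
            current_res = None
        res_key = (a.residue_number, a.residue_name)
        if res_key != current_res:
            builder.init_residue(a.residue_name, " ", a.residue_number, " ")
            current_res = res_key
        builder.init_atom(
            a.name,
            np.array([a.x, a.y, a.z], dtype=float),
            0.0,
            1.0,
            " ",
            a.name.center(4),
            i + 1,
            element=a.element.upper(),
        )
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


def kabsch_superpose(mobile, reference) -> tuple:
    """Least-squares rigid superposition of two matched point sets.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference`` — the
    Kabsch algorithm, with the reflection corrected so the rotation is
    proper (det = +1).  Raises on fewer than 3 points or (near-)collinear
    degeneracy, where the in-plane/axial orientation is unconstrained.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if mob.shape[0] < 3:
        raise ValueError("need at least 3 points")
    cm, cr = mob.mean(axis=0), ref.mean(axis=0)
    h = (mob - cm).T @ (ref - cr)
    u, s, vt = np.linalg.svd(h)
    scale = max(np.linalg.norm(mob - cm), np.linalg.norm(ref - cr), 1.0)
    if s[1] <= 1e-8 * scale:
        raise ValueError("degenerate (collinear) point set: rotation ill-defined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = cr - rotation @ cm
    fitted = mob @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return rotation, translation, rmsd


def chain_aligned_rmsd(
    snapshot: Structure,
    initial: Structure,
    align_chains,
    target_chain: str,
) -> float:
    """Cα RMSD of ``target_chain`` after superposing on ``align_chains``.

    The snapshot is superposed onto the initial structure using only the
    Cα atoms of ``align_chains`` (e.g. the receptor), then the RMSD is
    taken over the Cα atoms of ``target_chain`` (e.g. the ligand).  The
    result therefore captures both the target's internal conformational
    change and its displacement relative to the alignment chains.
    """
    keys_a, align_snap = snapshot.ca_coords(align_chains)
    keys_b, align_init = initial.ca_coords(align_chains)
    if keys_a != keys_b or len(keys_a) == 0:
        raise ValueError("alignment chains have mismatched Cα sets")
    tk_a, target_snap = snapshot.ca_coords([target_chain])
    tk_b, target_init = initial.ca_coords([target_chain])
    if tk_a != tk_b or len(tk_a) == 0:
        raise ValueError("target chain has mismatched Cα sets")
    rotation, translation, _ = kabsch_superpose(align_snap, align_init)
    moved = target_snap @ rotation.T + translation
    return float(np.sqrt(np.mean(np.sum((moved - target_init) ** 2, axis=1))))


def count_bad_contacts(
    a: Structure, b: Structure, cutoff: float = DEFAULT_CLASH_CUTOFF
) -> int:
    """Number of inter-structure heavy-atom pairs closer than ``cutoff`` Å.

    Strict inequality; hydrogens are excluded.
    """
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    ia, ib = a.heavy_indices(), b.heavy_indices()
    if not ia or not ib:
        return 0
    d = cdist(a.coords[ia], b.coords[ib])
    return int((d < cutoff).sum())


@dataclass(frozen=True)
class PlacementResult:
    """Outcome of the outward clash-minimizing translation search."""

    offsets: tuple  # Å
    clash_counts: tuple
    chosen_offset: float  # Å
    translation: tuple  # applied (x, y, z) vector, Å
    placed_ligand: Structure = field(repr=False, default=None)

    def __post_init__(self) -> None:
        best = min(self.clash_counts)
        chosen = self.clash_counts[self.offsets.index(self.chosen_offset)]
        if chosen != best:
            raise ValueError("chosen offset does not attain the minimal clash count")


def outward_placement_search(
    receptor: Structure,
    ligand: Structure,
    receptor_surface,
    ligand_surface,
    max_offset: float = 2.0,
    step: float = 1.0,
    cutoff: float = DEFAULT_CLASH_CUTOFF,
) -> PlacementResult:
    """Slide the ligand outward to minimize steric clashes with the receptor.

    The ligand is translated along the unit vector from the
    receptor-surface centroid to the ligand-surface centroid by offsets
    {0, step, 2·step, … ≤ max_offset}; the placement with the fewest bad
    contacts wins, ties resolving to the smallest offset (offset 0 keeps
    the unmoved pose).  ``receptor_surface`` / ``ligand_surface`` are atom
    index lists defining the binding surfaces.
    """
    receptor_surface = list(receptor_surface)
    ligand_surface = list(ligand_surface)
    if not receptor_surface or not ligand_surface:
        raise ValueError("surface selections must be non-empty")
    if step <= 0 or max_offset < 0:
        raise ValueError("step must be positive and max_offset non-negative")
    c_rec = receptor.coords[receptor_surface].mean(axis=0)
    c_lig = ligand.coords[ligand_surface].mean(axis=0)
    direction = c_lig - c_rec
    norm = float(np.linalg.norm(direction))
    if norm < 1e-9:
        raise ValueError("coincident surface centroids: outward direction undefined")
    direction = direction / norm

    n_steps = int(math.floor(max_offset / step + 1e-9))
    offsets = tuple(j * step for j in range(n_steps + 1))
    counts = tuple(
        count_bad_contacts(receptor, ligand.translated(direction * off), cutoff)
        for off in offsets
    )
    chosen = offsets[int(np.argmin(counts))]  # first minimum = smallest offset
    vec = direction * chosen
    return PlacementResult(
        offsets=offsets,
        clash_counts=counts,
        chosen_offset=chosen,
        translation=tuple(float(v) for v in vec),
        placed_ligand=ligand.translated(vec),
    )


@dataclass
class NonbondedParams:
    """Per-element LJ parameters plus optional per-atom partial charges.

    ``elements`` maps element symbol → {"sigma": Å, "epsilon": kcal/mol};
    ``charges`` maps an atom key (chain, residue_number, atom name) → e.
    Atoms without a charge entry are neutral.
    """

    elements: dict
    default: dict | None = None
    charges: dict = field(default_factory=dict)

    @classmethod
    def bundled(cls) -> "NonbondedParams":
        """Load the generic per-element parameter file shipped with the package."""
        with resources.files("lynxkit.data").joinpath("nonbonded_params.yml").open() as fh:
            raw = yaml.safe_load(fh)
        return cls(elements=raw["elements"], default=raw.get("default"))

    def lj(self, element: str) -> tuple:
        entry = self.elements.get(element.upper(), self.default)
        if entry is None:
            raise KeyError(f"no LJ parameters for element {element!r}")
        return float(entry["sigma"]), float(entry["epsilon"])

    def charge(self, atom: Atom) -> float:
        return float(self.charges.get(atom.key, 0.0))


@dataclass(frozen=True)
class InteractionReport:
    """Nonbonded interaction energies plus polar-contact listings."""

    vdw_energy: float  # kcal/mol
    electrostatic_energy: float  # kcal/mol
    hydrogen_bonds: tuple = ()
    salt_bridges: tuple = ()

    @property
    def total_energy(self) -> float:
        return self.vdw_energy + self.electrostatic_energy


def interaction_energy(
    a: Structure,
    b: Structure,
    params: NonbondedParams | None = None,
    cutoff: float = 12.0,
) -> InteractionReport:
    """Pairwise LJ 12-6 + Coulomb energy between two structures, kcal/mol.

    All inter-structure atom pairs within ``cutoff`` Å contribute
    ``4ε[(σ/r)¹² − (σ/r)⁶]`` with Lorentz–Berthelot combination
    (σ arithmetic-, ε geometric-mean) plus ``332.06·q₁q₂/r`` with a
    uniform dielectric of 1.  A plain cutoff — no switching function.
    """
    params = params or NonbondedParams.bundled()
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    sig_a, eps_a = zip(*(params.lj(at.element) for at in a.atoms))
    sig_b, eps_b = zip(*(params.lj(at.element) for at in b.atoms))
    q_a = np.array([params.charge(at) for at in a.atoms])
    q_b = np.array([params.charge(at) for at in b.atoms])
    d = cdist(a.coords, b.coords)
    mask = d <= cutoff
    if not mask.any():
        return InteractionReport(0.0, 0.0)
    sigma = 0.5 * (np.add.outer(np.array(sig_a), np.array(sig_b)))
    epsilon = np.sqrt(np.multiply.outer(np.array(eps_a), np.array(eps_b)))
    with np.errstate(divide="ignore"):
        sr6 = np.where(mask, (sigma / np.where(mask, d, 1.0)) ** 6, 0.0)
    vdw = float((4.0 * epsilon * (sr6**2 - sr6))[mask].sum())
    qq = np.multiply.outer(q_a, q_b)
    elec = float((COULOMB_CONSTANT * qq / np.where(mask, d, 1.0))[mask].sum())
    return InteractionReport(vdw_energy=vdw, electrostatic_energy=elec)


# Residue-template polar-atom tables (heavy atoms only; hydrogens are
# implied).  Backbone N donates and backbone O accepts in every residue.
_SIDECHAIN_DONORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "ASN": {"ND2"}, "GLN": {"NE2"},
    "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}, "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"},
}
_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "SER": {"OG"}, "THR": {"OG1"},
    "TYR": {"OH"}, "ASN": {"OD1"}, "GLN": {"OE1"}, "HIS": {"ND1", "NE2"},
}
_ANION_ATOMS = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}
_CATION_ATOMS = {"LYS": {"NZ"}, "ARG": {"NH1", "NH2", "NE"}, "HIS": {"ND1", "NE2"}}


def _is_donor(atom: Atom) -> bool:
    if atom.element.upper() not in ("N", "O"):
        return False
    if atom.name == "N":
        return True
    return atom.name in _SIDECHAIN_DONORS.get(atom.residue_name, set())


def _is_acceptor(atom: Atom) -> bool:
    if atom.element.upper() not in ("N", "O"):
        return False
    if atom.name in ("O", "OXT"):
        return True
    return atom.name in _SIDECHAIN_ACCEPTORS.get(atom.residue_name, set())


def _polar_pairs(a: Structure, b: Structure, pred_a, pred_b, max_dist: float) -> list:
    ia = [i for i, at in enumerate(a.atoms) if pred_a(at)]
    ib = [i for i, at in enumerate(b.atoms) if pred_b(at)]
    out = []
    if not ia or not ib:
        return out
    d = cdist(a.coords[ia], b.coords[ib])
    for r, c in zip(*np.nonzero(d <= max_dist)):
        out.append((a.atoms[ia[r]], b.atoms[ib[c]], float(d[r, c])))
    return out


def detect_hbonds(a: Structure, b: Structure, max_da: float = HBOND_MAX_DA) -> list:
    """Inter-structure hydrogen bonds by donor–acceptor heavy-atom distance.

    A donor is an N/O that carries an implied hydrogen in its residue
    template; an acceptor is an N/O lone-pair carrier.  Pairs at or below
    ``max_da`` Å (default 3.5) are reported in both donor directions as
    ``(donor_atom, acceptor_atom, distance)``.  Distance-only criterion:
    with hydrogens absent from heavy-atom models, no angle term is applied.
    """
    pairs = _polar_pairs(a, b, _is_donor, _is_acceptor, max_da)
    pairs += [
        (donor, acceptor, dist)
        for acceptor, donor, dist in _polar_pairs(a, b, _is_acceptor, _is_donor, max_da)
    ]
    # de-duplicate pairs that qualify in both directions
    seen = set()
    unique = []
    for donor, acceptor, dist in pairs:
        key = (donor.key, acceptor.key)
        if key not in seen:
            seen.add(key)
            unique.append((donor, acceptor, dist))
    return unique


def detect_salt_bridges(a: Structure, b: Structure, max_no: float = SALT_BRIDGE_MAX) -> list:
    """Inter-structure salt bridges: carboxylate O to basic N within cutoff.

    Asp/Glu side-chain oxygens paired against Lys NZ, Arg NE/NH1/NH2 or
    His ring nitrogens at or below ``max_no`` Å (default 4.0); returned as
    ``(anionic_atom, cationic_atom, distance)`` regardless of which input
    structure carries the charge.
    """

    def is_anion(at: Atom) -> bool:
        return at.name in _ANION_ATOMS.get(at.residue_name, set())

    def is_cation(at: Atom) -> bool:
        return at.name in _CATION_ATOMS.get(at.residue_name, set())

    pairs = _polar_pairs(a, b, is_anion, is_cation, max_no)
    pairs += [
        (anion, cation, dist)
        for cation, anion, dist in _polar_pairs(a, b, is_cation, is_anion, max_no)
    ]
    return pairs
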