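"""Domain types and I/O for protein–ligand complex structures.

The unit of analysis throughout the package is one *binding site*: one
receptor protein together with one bound small-molecule ligand instance.
This module defines the in-memory types (atoms, residues, ligand instances,
complexes, the van der Waals radius table) and readers/writers for the two
text formats the pipeline touches: PDB (via gemmi) and Tripos MOL2 (own
minimal block parser, because the declared SYBYL atom-type strings must be
preserved verbatim).

Conventions applied at parse time, everywhere:

* hydrogens (H/D) are discarded — the contact statistics operate on heavy
  atoms only;
* waters (HOH, DOD, H2O, WAT) are discarded — only direct protein–ligand
  contacts are modelled;
* of alternate-location conformers only the highest-occupancy one is kept
  (ties broken toward the lexicographically first altloc);
* only the first MODEL of a multi-model file is read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

WATER_NAMES = frozenset({"HOH", "DOD", "H2O", "WAT"})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
STANDARD_RESIDUES = frozenset(THREE_TO_ONE)

#: Bondi (1964) van der Waals radii, Å.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
    "Se": 1.90, "Si": 2.10, "B": 1.92, "As": 1.85, "Te": 2.06,
    "Zn": 1.39, "Cu": 1.40, "Ni": 1.63, "Mg": 1.73, "K": 2.75,
    "Na": 2.27, "Li": 1.82, "Ga": 1.87, "Cd": 1.58, "Hg": 1.55,
}

#: Covalent radii (Cordero 2008), Å; used for distance-based bond inference.
COVALENT_RADII = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
    "Se": 1.20, "As": 1.19,
}
COVALENT_SLACK = 0.4  # Å added to the covalent-radius sum

ATOMIC_MASSES = {
    "H": 1.008, "B": 10.811, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Si": 28.086, "P": 30.974, "S": 32.06, "Cl": 35.45,
    "Br": 79.904, "I": 126.904, "Se": 78.971, "As": 74.922,
}

#: Nominal valences for implicit-hydrogen inference from MOL2 bonds.
_DEFAULT_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 5, "B": 3, "Si": 4}


class ParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


class LigandNotFoundError(KeyError):
    """Requested ligand component code absent from a structure."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom of a receptor or ligand."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: tuple[str, int, str]  # (chain id, residue number, insertion code)
    coordinates: np.ndarray           # shape (3,), Å
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False
    sybyl_type: str | None = None     # declared Tripos type, if read from MOL2

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        object.__setattr__(self, "coordinates", coords)

    @property
    def chain_id(self) -> str:
        return self.residue_id[0]


@dataclass
class Residue:
    name: str
    chain_id: str
    number: int
    insertion_code: str = ""
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class LigandInstance:
    """One bound copy of a small-molecule component."""

    component_code: str
    atoms: list[AtomRecord]
    bonds: list[tuple[int, int, str]] | None = None  # 0-based indices, MOL2 order code
    molecular_weight: float = 0.0
    chain_id: str = ""
    residue_number: int = 0
    covalent: bool = False  # flagged when covalently linked to the receptor

    def __post_init__(self):
        if len(self.atoms) < 1:
            raise ValueError("a ligand instance needs at least one atom")
        if self.bonds is not None:
            n = len(self.atoms)
            for i, j, _order in self.bonds:
                if not (0 <= i < n and 0 <= j < n):
                    raise ValueError(f"bond index ({i},{j}) out of range for {n} atoms")
        if self.molecular_weight <= 0:
            self.molecular_weight = molecular_weight(self.atoms, self.bonds)

    def coordinates(self) -> np.ndarray:
        return np.array([a.coordinates for a in self.atoms])


@dataclass
class ComplexStructure:
    """One structure entry: receptor residues plus bound ligand instances."""

    entry_id: str
    receptor: list[Residue]
    ligands: list[LigandInstance]
    resolution: float | None = None
    method: str | None = None
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.sequences:
            self.sequences = chain_sequences(self.receptor)

    def receptor_atoms(self) -> list[AtomRecord]:
        return [a for res in self.receptor for a in res.atoms]

    def ligand_codes(self) -> list[str]:
        seen: list[str] = []
        for lig in self.ligands:
            if lig.component_code not in seen:
                seen.append(lig.component_code)
        return seen

    def n_residues(self) -> int:
        """Amino-acid residues in the receptor, summed over chains."""
        return sum(1 for r in self.receptor if r.name in STANDARD_RESIDUES)


@dataclass
class VdwRadiusTable:
    """Element → van der Waals radius (Å), with a default for unknowns."""

    radii: dict[str, float] = field(default_factory=lambda: dict(BONDI_RADII))
    default_radius: float = 1.7

    def __post_init__(self):
        for el, r in self.radii.items():
            if not 0.5 < r < 3.0:
                raise ValueError(f"radius of {el} ({r} Å) outside (0.5, 3.0) Å")
        if not 0.5 < self.default_radius < 3.0:
            raise ValueError("default radius outside (0.5, 3.0) Å")

    def radius(self, element: str) -> float:
        return self.radii.get(_norm_element(element), self.default_radius)

    def knows(self, element: str) -> bool:
        return _norm_element(element) in self.radii

    def content_hash(self) -> str:
        import hashlib
        items = sorted(self.radii.items()) + [("*default*", self.default_radius)]
        text = ";".join(f"{k}={v:.4f}" for k, v in items)
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path) -> "VdwRadiusTable":
        """Two-column whitespace TSV: element, radius; line 'default <r>' sets the fallback."""
        radii, default = {}, 1.7
        with open(path) as fh:
            for line in fh:
                line = line.split("#")[0].strip()
                if not line:
                    continue
                el, val = line.split()[:2]
                if el.lower() == "default":
                    default = float(val)
                else:
                    radii[_norm_element(el)] = float(val)
        return cls(radii=radii, default_radius=default)


def _norm_element(element: str) -> str:
    return element.strip().capitalize()


def molecular_weight(atoms, bonds=None, implicit_hydrogens: bool | None = None) -> float:
    """Molecular weight in Da from heavy atoms, optionally adding implicit H.

    When ``bonds`` are available (MOL2 input) each atom's implicit hydrogen
    count is estimated as nominal valence minus the sum of its bond orders
    (aromatic bonds count 1.5).  Without bonds only heavy atoms are summed.
    ``implicit_hydrogens`` forces the mode either way.
    """
    total = sum(ATOMIC_MASSES.get(_norm_element(a.element), 0.0) for a in atoms)
    use_h = bonds is not None if implicit_hydrogens is None else implicit_hydrogens
    if not use_h or bonds is None:
        return total
    order_value = {"1": 1.0, "2": 2.0, "3": 3.0, "ar": 1.5, "am": 1.0, "du": 0.0, "un": 1.0}
    valence_sum = [0.0] * len(atoms)
    for i, j, order in bonds:
        v = order_value.get(str(order).lower(), 1.0)
        valence_sum[i] += v
        valence_sum[j] += v
    n_h = 0.0
    for a, vs in zip(atoms, valence_sum):
        nominal = _DEFAULT_VALENCE.get(_norm_element(a.element))
        if nominal is not None:
            n_h += max(0.0, nominal - vs)
    return total + n_h * ATOMIC_MASSES["H"]


def chain_sequences(receptor: list[Residue]) -> dict[str, str]:
    """One-letter amino-acid sequence per chain; unknown residues become X."""
    seqs: dict[str, list[str]] = {}
    for res in receptor:
        seqs.setdefault(res.chain_id, []).append(THREE_TO_ONE.get(res.name, "X"))
    return {c: "".join(letters) for c, letters in seqs.items()}


# ---------------------------------------------------------------------------
# PDB reading

def read_pdb(path, entry_id: str | None = None) -> ComplexStructure:
    """Read a PDB file into a ComplexStructure (first model only).

    ATOM records of standard amino acids form the receptor; every non-water
    HETATM residue becomes one LigandInstance (grouped per component code,
    chain and residue number).  Waters and hydrogens are dropped; alternate
    locations are resolved to the highest-occupancy conformer.
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"no models in PDB file {path}")
    model = st[0]

    receptor: list[Residue] = []
    residue_index: dict[tuple, Residue] = {}
    ligand_groups: dict[tuple, list[AtomRecord]] = {}

    for chain in model:
        for res in chain:
            rname = res.name.strip()
            if rname in WATER_NAMES:
                continue
            icode = res.seqid.icode.strip()
            key = (chain.name, res.seqid.num, icode, rname)
            is_het = res.het_flag == "H" and rname not in STANDARD_RESIDUES
            for atom in res:
                el = atom.element.name
                if el in ("H", "D"):
                    continue
                rec = AtomRecord(
                    serial=atom.serial,
                    name=atom.name.strip(),
                    element=_norm_element(el) if el else "X",
                    residue_name=rname,
                    residue_id=(chain.name, res.seqid.num, icode),
                    coordinates=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=float(atom.occ),
                    altloc=atom.altloc.strip("\x00").strip(),
                    is_hetero=is_het,
                )
                if is_het:
                    ligand_groups.setdefault(key, []).append(rec)
                else:
                    if key not in residue_index:
                        residue_index[key] = Residue(rname, chain.name, res.seqid.num, icode)
                        receptor.append(residue_index[key])
                    residue_index[key].atoms.append(rec)

    for residue in receptor:
        residue.atoms = _resolve_altlocs(residue.atoms)

    ligands = []
    for (chain_id, resnum, _icode, code), atoms in sorted(
        ligand_groups.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])
    ):
        atoms = _resolve_altlocs(atoms)
        ligands.append(LigandInstance(
            component_code=code, atoms=atoms, chain_id=chain_id, residue_number=resnum,
        ))

    _flag_covalent_ligands(receptor, ligands)

    info = dict(st.info)
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    method = info.get("_exptl.method") or None
    eid = entry_id or info.get("_entry.id") or ""
    return ComplexStructure(entry_id=eid, receptor=receptor, ligands=ligands,
                            resolution=resolution, method=method)


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom name: highest occupancy, ties → first altloc."""
    best: dict[str, AtomRecord] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        else:
            b = best[a.name]
            if a.occupancy > b.occupancy or (
                a.occupancy == b.occupancy and (a.altloc or "~") < (b.altloc or "~")
            ):
                best[a.name] = a
    return [replace(best[n], altloc="") for n in order]


def _flag_covalent_ligands(receptor: list[Residue], ligands: list[LigandInstance]) -> None:
    rec_atoms = [a for res in receptor for a in res.atoms]
    if not rec_atoms or not ligands:
        return
    from scipy.spatial import cKDTree
    rec_xyz = np.array([a.coordinates for a in rec_atoms])
    tree = cKDTree(rec_xyz)
    max_cut = 2 * max(COVALENT_RADII.values()) + COVALENT_SLACK
    for lig in ligands:
        for atom in lig.atoms:
            r_a = COVALENT_RADII.get(atom.element, 0.77)
            for idx in tree.query_ball_point(atom.coordinates, max_cut):
                r_b = COVALENT_RADII.get(rec_atoms[idx].element, 0.77)
                d = float(np.linalg.norm(atom.coordinates - rec_xyz[idx]))
                if d <= r_a + r_b + COVALENT_SLACK:
                    lig.covalent = True
                    break
            if lig.covalent:
                break


def select_binding_site(structure: ComplexStructure, ligand_code: str,
                        instance_index: int = 0) -> tuple[list[Residue], LigandInstance]:
    """Pick one ligand instance by component code; returns (receptor, ligand)."""
    matches = [lg for lg in structure.ligands if lg.component_code == ligand_code]
    if not matches:
        available = structure.ligand_codes()
        raise LigandNotFoundError(
            f"ligand {ligand_code!r} not found in {structure.entry_id or 'structure'}; "
            f"available codes: {available or 'none'}"
        )
    if not 0 <= instance_index < len(matches):
        raise LigandNotFoundError(
            f"instance index {instance_index} out of range: {len(matches)} "
            f"copies of {ligand_code!r}"
        )
    return structure.receptor, matches[instance_index]


# ---------------------------------------------------------------------------
# PDB writing (fixture output; fixed-width v3.3 columns)

def write_pdb(structure: ComplexStructure, path) -> None:
    with open(path, "w") as fh:
        fh.write(format_pdb(structure))


def format_pdb(structure: ComplexStructure) -> str:
    lines = []
    if structure.entry_id:
        lines.append(f"HEADER    {'COMPLEX':<40}{'':12}{structure.entry_id.upper()[:4]:<4}")
    if structure.method:
        lines.append(f"EXPDTA    {structure.method}")
    if structure.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {structure.resolution:7.2f} ANGSTROMS.")
    serial = 1
    for res in structure.receptor:
        for atom in res.atoms:
            lines.append(_pdb_atom_line("ATOM", serial, atom, res.name, res.chain_id,
                                        res.number, res.insertion_code))
            serial += 1
    for lig in structure.ligands:
        for atom in lig.atoms:
            lines.append(_pdb_atom_line("HETATM", serial, atom, lig.component_code,
                                        lig.chain_id or "L", lig.residue_number or 1,
                                        ""))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def _pdb_atom_line(record, serial, atom, resname, chain, resnum, icode) -> str:
    name = atom.name
    if len(name) < 4 and len(atom.element) == 1:
        name = " " + name
    x, y, z = atom.coordinates
    return (
        f"{record:<6}{serial:>5} {name:<4}{'':1}{resname:<3} {chain:>1}"
        f"{resnum:>4}{icode or ' ':1}   {x:8.3f}{y:8.3f}{z:8.3f}"
        f"{atom.occupancy:6.2f}{0.0:6.2f}{'':10}{atom.element.upper():>2}"
    )


# ---------------------------------------------------------------------------
# MOL2 reading

def read_mol2(path) -> LigandInstance:
    """Read one molecule from a Tripos MOL2 file, preserving declared SYBYL types.

    Hydrogens are dropped and the bond list is re-indexed accordingly.
    """
    with open(path) as fh:
        text = fh.read()
    return parse_mol2(text, source=str(path))


def parse_mol2(text: str, source: str = "<string>") -> LigandInstance:
    blocks: dict[str, list[str]] = {}
    current: list[str] | None = None
    for line in text.splitlines():
        if line.startswith("@<TRIPOS>"):
            current = []
            blocks[line.strip()[9:].upper()] = current
        elif current is not None:
            if line.strip() and not line.lstrip().startswith("#"):
                current.append(line)
    if "ATOM" not in blocks:
        raise ParseError(f"{source}: no @<TRIPOS>ATOM block")

    name = "LIG"
    if blocks.get("MOLECULE"):
        name = blocks["MOLECULE"][0].strip()[:3].upper() or "LIG"

    atoms: list[AtomRecord] = []
    keep: dict[int, int] = {}  # original 1-based id -> new 0-based index
    for lineno, line in enumerate(blocks["ATOM"], 1):
        parts = line.split()
        if len(parts) < 6:
            raise ParseError(f"{source}: malformed ATOM line {lineno}: {line!r}")
        aid, aname = int(parts[0]), parts[1]
        xyz = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
        sybyl = parts[5]
        element = _norm_element(sybyl.split(".")[0])
        if element in ("H", "D"):
            continue
        keep[aid] = len(atoms)
        atoms.append(AtomRecord(
            serial=aid, name=aname, element=element, residue_name=name,
            residue_id=("", 1, ""), coordinates=xyz, is_hetero=True,
            sybyl_type=sybyl,
        ))
    if not atoms:
        raise ParseError(f"{source}: no heavy atoms in ATOM block")

    bonds: list[tuple[int, int, str]] = []
    for line in blocks.get("BOND", []):
        parts = line.split()
        if len(parts) < 4:
            continue
        i, j, order = int(parts[1]), int(parts[2]), parts[3]
        if i in keep and j in keep:
            bonds.append((keep[i], keep[j], order))
    has_bond_block = "BOND" in blocks
    return LigandInstance(
        component_code=name, atoms=atoms,
        bonds=bonds if has_bond_block else None,
    )
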