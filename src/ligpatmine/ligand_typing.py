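"""SYBYL-style atom typing of ligand heavy atoms.

Ligand atoms are classified into Tripos/SYBYL force-field types (C.3, C.ar,
N.am, O.co2, ...).  Two routes exist:

* :func:`assign_types_from_mol2` echoes the types declared in a MOL2 file,
  normalised against the registry — the preferred route when a MOL2 exists;
* :func:`perceive_types` infers types from coordinates alone (element,
  connectivity, bond geometry, ring planarity) — the fallback for plain PDB
  input, which carries no chemistry.

The registry is a fixed list of 27 heavy-atom types plus UNKNOWN; it is the
conventional SYBYL heavy-atom list and is configurable because different
force-field builds merge or split a few entries (notably halogens and
sulfur oxidation states).
"""

from __future__ import annotations

import itertools
import logging
import math

import networkx as nx
import numpy as np

from .structure_model import COVALENT_RADII, COVALENT_SLACK, LigandInstance

logger = logging.getLogger(__name__)

UNKNOWN = "UNKNOWN"

#: The 27-entry heavy-atom type registry (configurable).
TYPE_REGISTRY: tuple[str, ...] = (
    "C.3", "C.2", "C.1", "C.ar", "C.cat",
    "N.3", "N.2", "N.1", "N.ar", "N.am", "N.pl3", "N.4",
    "O.3", "O.2", "O.co2",
    "S.3", "S.2", "S.o", "S.o2",
    "P.3",
    "F", "Cl", "Br", "I",
    "B", "Si", "Se",
)

# geometry thresholds, tuned for ~2.5 Å-resolution coordinates
PLANARITY_MAX_DEV = 0.15       # Å, max out-of-plane deviation for aromatic rings
SP1_ANGLE_MIN = 165.0          # degrees
SP2_ANGLE_MIN = 112.5          # degrees; below → sp3-like
DOUBLE_BOND_CO = 1.30          # Å, terminal C–O shorter than this is a C=O
DOUBLE_BOND_CN = 1.35          # Å, terminal C–N shorter than this is sp2/sp1 N
TRIPLE_BOND_CN = 1.20          # Å


def normalize_type(code: str) -> str:
    """Map a declared type string onto the registry (case-insensitive)."""
    code = code.strip()
    by_lower = {t.lower(): t for t in TYPE_REGISTRY}
    hit = by_lower.get(code.lower())
    if hit is None:
        return UNKNOWN
    return hit


def assign_types_from_mol2(ligand: LigandInstance) -> list[str]:
    """Echo the SYBYL types declared in a MOL2-derived ligand.

    Unregistered strings map to UNKNOWN with a warning; atoms without a
    declared type (e.g. a PDB-derived ligand) also become UNKNOWN.
    """
    out = []
    for atom in ligand.atoms:
        if atom.sybyl_type is None:
            out.append(UNKNOWN)
            continue
        norm = normalize_type(atom.sybyl_type)
        if norm == UNKNOWN:
            logger.warning("unregistered SYBYL type %r on atom %s -> UNKNOWN",
                           atom.sybyl_type, atom.name)
        out.append(norm)
    return out


def perceive_types(ligand: LigandInstance) -> list[str]:
    """Rule-based type perception from heavy-atom coordinates.

    Bonds are taken from the ligand when present, otherwise inferred from
    interatomic distances (covalent-radius sum + 0.4 Å).  Hybridisation
    comes from neighbour counts and bond angles; aromatic types from planar
    5/6-rings of sp2-capable atoms; carboxylates and amides from their
    characteristic C(=O) environments.  Output is independent of the atom
    input order.
    """
    n = len(ligand.atoms)
    xyz = np.array([a.coordinates for a in ligand.atoms])
    elements = [a.element for a in ligand.atoms]

    if ligand.bonds:
        adj: list[set[int]] = [set() for _ in range(n)]
        for i, j, _order in ligand.bonds:
            adj[i].add(j)
            adj[j].add(i)
    else:
        adj = _bonds_by_distance(elements, xyz)

    dist = lambda i, j: float(np.linalg.norm(xyz[i] - xyz[j]))
    aromatic = _aromatic_atoms(elements, xyz, adj)

    types = []
    for i, el in enumerate(elements):
        neigh = sorted(adj[i])
        deg = len(neigh)
        mean_angle = _mean_bond_angle(xyz, i, neigh)

        if el == "C":
            if i in aromatic:
                t = "C.ar"
            elif deg >= 4:
                t = "C.3"
            elif deg >= 2 and mean_angle is not None and mean_angle >= SP1_ANGLE_MIN:
                t = "C.1"
            elif deg == 3 and _is_locally_planar(xyz, i, neigh):
                t = "C.2"
            elif deg == 3:
                t = "C.3"
            elif deg == 2 and mean_angle is not None and mean_angle >= SP2_ANGLE_MIN:
                t = "C.2"
            else:
                t = "C.3"  # methyl-like / isolated: default sp3
        elif el == "N":
            if i in aromatic:
                t = "N.ar"
            elif deg >= 4:
                t = "N.4"
            elif any(_is_carbonyl_carbon(elements, adj, xyz, j) for j in neigh):
                t = "N.am"
            elif deg == 1 and neigh and dist(i, neigh[0]) < TRIPLE_BOND_CN:
                t = "N.1"
            elif deg == 1 and neigh and dist(i, neigh[0]) < DOUBLE_BOND_CN:
                t = "N.2"
            elif deg == 3 and _is_locally_planar(xyz, i, neigh):
                t = "N.pl3"
            elif deg == 2 and mean_angle is not None and mean_angle >= SP1_ANGLE_MIN:
                t = "N.1"
            elif deg == 2 and mean_angle is not None and mean_angle >= SP2_ANGLE_MIN \
                    and any(elements[j] == "C" and _is_sp2_like(elements, adj, xyz, j)
                            for j in neigh):
                t = "N.2"
            else:
                t = "N.3"
        elif el == "O":
            if deg == 1 and _is_carboxylate_oxygen(elements, adj, xyz, i):
                t = "O.co2"
            elif deg == 1 and neigh and dist(i, neigh[0]) < DOUBLE_BOND_CO:
                t = "O.2"
            else:
                t = "O.3"
        elif el == "S":
            if deg >= 4:
                t = "S.o2"
            elif deg == 3:
                t = "S.o"
            elif deg == 1 and neigh and dist(i, neigh[0]) < 1.75:
                t = "S.2"
            else:
                t = "S.3"
        elif el == "P":
            t = "P.3"
        elif el in ("F", "Cl", "Br", "I", "B", "Si", "Se"):
            t = el
        else:
            t = UNKNOWN
        types.append(t)
    return types


def resolve_types(ligand: LigandInstance,
                  overrides: dict[tuple[str, str], str] | None = None) -> list[str]:
    """Best available type per atom: override table > MOL2 declaration > perception."""
    declared = assign_types_from_mol2(ligand)
    perceived = None
    types = []
    for idx, atom in enumerate(ligand.atoms):
        if overrides:
            key = (ligand.component_code, atom.name)
            if key in overrides:
                types.append(normalize_type(overrides[key]))
                continue
        if declared[idx] != UNKNOWN:
            types.append(declared[idx])
        else:
            if perceived is None:
                perceived = perceive_types(ligand)
            types.append(perceived[idx])
    return types


def load_type_overrides(path) -> dict[tuple[str, str], str]:
    """TSV of (component code, atom name, type) for irregular ligands."""
    table: dict[tuple[str, str], str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip()
            if not line:
                continue
            code, name, typ = line.split("\t")[:3]
            table[(code.strip(), name.strip())] = typ.strip()
    return table


# ---------------------------------------------------------------------------
# geometry helpers

def _bonds_by_distance(elements, xyz) -> list[set[int]]:
    n = len(elements)
    adj: list[set[int]] = [set() for _ in range(n)]
    for i, j in itertools.combinations(range(n), 2):
        cutoff = (COVALENT_RADII.get(elements[i], 0.77)
                  + COVALENT_RADII.get(elements[j], 0.77) + COVALENT_SLACK)
        if np.linalg.norm(xyz[i] - xyz[j]) <= cutoff:
            adj[i].add(j)
            adj[j].add(i)
    return adj


def _mean_bond_angle(xyz, i, neigh) -> float | None:
    if len(neigh) < 2:
        return None
    angles = []
    for a, b in itertools.combinations(neigh, 2):
        u = xyz[a] - xyz[i]
        v = xyz[b] - xyz[i]
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        angles.append(math.degrees(math.acos(np.clip(cosang, -1.0, 1.0))))
    return float(np.mean(angles))


def _is_locally_planar(xyz, i, neigh) -> bool:
    """Central atom within PLANARITY_MAX_DEV of its three neighbours' plane."""
    if len(neigh) != 3:
        return False
    p = xyz[list(neigh)]
    normal = np.cross(p[1] - p[0], p[2] - p[0])
    norm = np.linalg.norm(normal)
    if norm < 1e-9:
        return False
    dev = abs(np.dot(xyz[i] - p[0], normal / norm))
    return dev <= PLANARITY_MAX_DEV


def _ring_planarity_dev(points: np.ndarray) -> float:
    centered = points - points.mean(axis=0)
    # smallest singular direction = ring normal; deviations along it
    _u, _s, vt = np.linalg.svd(centered, full_matrices=False)
    return float(np.max(np.abs(centered @ vt[-1])))


def _aromatic_atoms(elements, xyz, adj) -> set[int]:
    """Atoms in planar 5/6-membered rings of sp2-capable C/N/O/S."""
    g = nx.Graph()
    g.add_nodes_from(range(len(elements)))
    for i, nb in enumerate(adj):
        for j in nb:
            g.add_edge(i, j)
    aromatic: set[int] = set()
    for ring in nx.cycle_basis(g):
        if len(ring) not in (5, 6):
            continue
        if not all(elements[i] in ("C", "N", "O", "S") for i in ring):
            continue
        # sp2-capable: at most 3 heavy neighbours each
        if not all(len(adj[i]) <= 3 for i in ring):
            continue
        if _ring_planarity_dev(xyz[ring]) <= PLANARITY_MAX_DEV:
            aromatic.update(i for i in ring if elements[i] in ("C", "N"))
    return aromatic


def _is_carbonyl_carbon(elements, adj, xyz, j) -> bool:
    """Carbon with a short (< DOUBLE_BOND_CO) bond to a terminal oxygen."""
    if elements[j] != "C":
        return False
    for k in adj[j]:
        if elements[k] == "O" and len(adj[k]) == 1 \
                and np.linalg.norm(xyz[j] - xyz[k]) < DOUBLE_BOND_CO:
            return True
    return False


def _is_carboxylate_oxygen(elements, adj, xyz, i) -> bool:
    """Terminal O whose carbon carries exactly two terminal oxygens."""
    (j,) = tuple(adj[i]) if len(adj[i]) == 1 else (None,)
    if j is None or elements[j] != "C":
        return False
    terminal_o = [k for k in adj[j] if elements[k] == "O" and len(adj[k]) == 1]
    return len(terminal_o) == 2


def _is_sp2_like(elements, adj, xyz, j) -> bool:
    neigh = sorted(adj[j])
    if len(neigh) == 3:
        return _is_locally_planar(xyz, j, neigh)
    ang = _mean_bond_angle(xyz, j, neigh)
    return ang is not None and ang >= SP2_ANGLE_MIN
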