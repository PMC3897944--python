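"""Synthetic inputs for every pipeline stage.

Everything here is generated, deterministic in its seed, and chemically
*sane* rather than crystallographically realistic: residues use idealized
internal coordinates, ligand atoms are placed exactly where a test needs
them, and there is no coordinate noise, disorder or B-factor structure.
What the fixtures do guarantee is that every generated PDB round-trips
through the real parser and that planted Gaussian mixtures are recoverable
ground truth for the mining pipeline.

Contents:

* :class:`MixtureSpec` / :func:`sample_points` — ground-truth Gaussian
  mixtures and seeded sampling, the oracle for mixture fitting;
* :func:`ideal_residue` / :func:`make_toy_complex` — template-conformant
  residues placed rigidly in space plus caller-positioned ligand atoms,
  emitted as valid PDB;
* :func:`cage_complex` — a ligand fully enclosed in a synthetic atom shell
  (rASA ≈ 0 oracle);
* :func:`reference_mol2` — a hand-built set of small molecules with
  idealized geometry and declared SYBYL types (synthetic stand-ins for
  curated MOL2 files), the oracle for geometric type perception;
* :func:`end_to_end_fixture` — complexes with ligand atoms planted from
  known mixtures in fragment-local frames, for mine-and-annotate recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .curation import golden_spiral_points
from .structure_model import (
    AtomRecord,
    ComplexStructure,
    LigandInstance,
    Residue,
    format_pdb,
)


@dataclass
class MixtureSpec:
    """Ground-truth Gaussian mixture: (weight, mean, covariance) triples."""

    components: list[tuple[float, np.ndarray, np.ndarray]]
    n_samples: int = 0
    seed: int = 0

    def __post_init__(self):
        comps = []
        total = 0.0
        for w, mean, cov in self.components:
            mean = np.asarray(mean, dtype=float).reshape(3)
            cov = np.asarray(cov, dtype=float).reshape(3, 3)
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise ValueError("mixture covariances must be SPD")
            comps.append((float(w), mean, cov))
            total += w
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture weights sum to {total}, expected 1")
        self.components = comps


def sample_points(spec: MixtureSpec, n: int | None = None,
                  seed: int | None = None,
                  truncate_mahalanobis: float | None = None) -> np.ndarray:
    """Draw points from the mixture; reproducible for a fixed seed.

    With ``truncate_mahalanobis`` set, draws are rejected until they fall
    within that Mahalanobis radius of their own component — such points are
    pattern instances *by construction*, which is what a recognition test
    needs (an untruncated 3D Gaussian puts ~10% of its mass beyond
    Mahalanobis 2.5).
    """
    n = spec.n_samples if n is None else n
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if n == 0:
        return np.empty((0, 3))
    weights = np.array([c[0] for c in spec.components])
    choice = rng.choice(len(spec.components), size=n, p=weights)
    out = np.empty((n, 3))
    for k, (_w, mean, cov) in enumerate(spec.components):
        idx = np.flatnonzero(choice == k)
        if not idx.size:
            continue
        if truncate_mahalanobis is None:
            out[idx] = rng.multivariate_normal(mean, cov, size=idx.size)
        else:
            chol = np.linalg.cholesky(cov)
            filled = 0
            while filled < idx.size:
                z = rng.standard_normal((idx.size - filled, 3))
                keep = z[np.linalg.norm(z, axis=1) <= truncate_mahalanobis]
                for row in keep:
                    out[idx[filled]] = mean + chol @ row
                    filled += 1
                    if filled == idx.size:
                        break
    return out


# ---------------------------------------------------------------------------
# idealized residue geometry

def _ideal_ala_coords() -> dict[str, np.ndarray]:
    """Idealized alanine heavy-atom coordinates (CA at the origin)."""
    ca = np.zeros(3)
    n = np.array([1.458, 0.0, 0.0])
    ang = math.radians(111.0)
    c = 1.525 * np.array([math.cos(ang), math.sin(ang), 0.0])
    # O: sp2 on C, angle CA-C-O = 120.5°, in the z=0 plane, away from N
    u = (ca - c) / np.linalg.norm(ca - c)
    rot = Rotation.from_euler("z", -120.5, degrees=True)
    o = c + 1.231 * rot.apply(u)
    # CB: tetrahedral on CA w.r.t. N and C, out of plane (positive z)
    un = n / np.linalg.norm(n)
    uc = c / np.linalg.norm(c)
    bisector = -(un + uc)
    bisector /= np.linalg.norm(bisector)
    target = math.cos(math.radians(109.47))
    # v = a·bisector + b·ẑ with |v|=1 and v·un = target
    a = target / float(bisector @ un)
    b = math.sqrt(max(0.0, 1.0 - a * a))
    cb = ca + 1.530 * (a * bisector + b * np.array([0.0, 0.0, 1.0]))
    return {"N": n, "CA": ca, "C": c, "O": o, "CB": cb}


_IDEAL_COORDS: dict[str, dict[str, np.ndarray]] = {
    "ALA": _ideal_ala_coords(),
    "GLY": {k: v for k, v in _ideal_ala_coords().items() if k != "CB"},
}


def ideal_residue(name: str = "ALA", chain_id: str = "A", number: int = 1,
                  rotation: np.ndarray | None = None,
                  translation: np.ndarray | None = None) -> Residue:
    """A template-conformant residue, optionally rigidly placed."""
    coords = _IDEAL_COORDS.get(name)
    if coords is None:
        raise ValueError(f"no ideal geometry for residue {name!r}")
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
    atoms = []
    for i, (aname, xyz) in enumerate(coords.items(), start=1):
        atoms.append(AtomRecord(
            serial=i, name=aname, element=aname[0], residue_name=name,
            residue_id=(chain_id, number, ""), coordinates=R @ xyz + t,
        ))
    return Residue(name=name, chain_id=chain_id, number=number, atoms=atoms)


def make_toy_complex(residues: list[Residue] | None = None,
                     ligand_positions: np.ndarray | list | None = None,
                     ligand_code: str = "LIG", ligand_element: str = "C",
                     ligand_sybyl_type: str | None = None,
                     entry_id: str = "TOY1", resolution: float | None = 2.0,
                     method: str | None = "X-RAY DIFFRACTION",
                     ) -> tuple[ComplexStructure, str]:
    """A minimal valid complex: residues plus HETATM atoms at given positions.

    Returns the in-memory structure and its PDB text (which round-trips
    through ``read_pdb``).
    """
    residues = residues if residues is not None else [ideal_residue("ALA")]
    ligands = []
    if ligand_positions is not None and len(ligand_positions):
        atoms = [
            AtomRecord(
                serial=i + 1, name=f"{ligand_element.upper()}{i + 1}",
                element=ligand_element, residue_name=ligand_code,
                residue_id=("L", 1, ""), coordinates=np.asarray(p, dtype=float),
                is_hetero=True, sybyl_type=ligand_sybyl_type,
            )
            for i, p in enumerate(ligand_positions)
        ]
        ligands = [LigandInstance(component_code=ligand_code, atoms=atoms,
                                  chain_id="L", residue_number=1)]
    structure = ComplexStructure(entry_id=entry_id, receptor=residues,
                                 ligands=ligands, resolution=resolution,
                                 method=method)
    return structure, format_pdb(structure)


def cage_complex(n_shell: int = 240, shell_radius: float = 4.0,
                 ligand_code: str = "LIG") -> ComplexStructure:
    """A single ligand carbon fully enclosed by a spherical shell of atoms.

    The shell is dense enough that no 1.4 Å probe reaches the centre, so the
    ligand's relative accessible surface area is ≈ 0.
    """
    shell_xyz = shell_radius * golden_spiral_points(n_shell)
    residues = []
    for i, p in enumerate(shell_xyz):
        atom = AtomRecord(serial=i + 1, name="C", element="C",
                          residue_name="UNK", residue_id=("A", i + 1, ""),
                          coordinates=p)
        residues.append(Residue(name="UNK", chain_id="A", number=i + 1,
                                atoms=[atom]))
    lig_atom = AtomRecord(serial=n_shell + 1, name="C1", element="C",
                          residue_name=ligand_code, residue_id=("L", 1, ""),
                          coordinates=np.zeros(3), is_hetero=True)
    ligand = LigandInstance(component_code=ligand_code, atoms=[lig_atom],
                            chain_id="L", residue_number=1)
    return ComplexStructure(entry_id="CAGE", receptor=residues,
                            ligands=[ligand], resolution=2.0,
                            method="X-RAY DIFFRACTION")


# ---------------------------------------------------------------------------
# reference small molecules (synthetic MOL2 text, idealized geometry)

def _mol2_text(name: str, atoms: list[tuple[str, str, tuple]],
               bonds: list[tuple[int, int, str]]) -> str:
    lines = ["@<TRIPOS>MOLECULE", name, f"{len(atoms)} {len(bonds)} 0 0 0",
             "SMALL", "NO_CHARGES", "", "@<TRIPOS>ATOM"]
    for i, (aname, typ, (x, y, z)) in enumerate(atoms, start=1):
        lines.append(f"{i:>4} {aname:<4} {x:>9.4f} {y:>9.4f} {z:>9.4f} {typ:<6} 1 {name:<4} 0.0000")
    lines.append("@<TRIPOS>BOND")
    for i, (a, b, order) in enumerate(bonds, start=1):
        lines.append(f"{i:>4} {a:>4} {b:>4} {order}")
    return "\n".join(lines) + "\n"


def _hexagon(radius: float = 1.39) -> list[tuple[float, float, float]]:
    return [(radius * math.cos(k * math.pi / 3),
             radius * math.sin(k * math.pi / 3), 0.0) for k in range(6)]


def _build_reference_molecules() -> dict[str, str]:
    mols: dict[str, str] = {}
    deg = math.radians

    mols["ethane"] = _mol2_text("ETH", [
        ("C1", "C.3", (0.0, 0.0, 0.0)), ("C2", "C.3", (1.54, 0.0, 0.0)),
    ], [(1, 2, "1")])

    o = (1.54 + 1.43 * math.cos(deg(70.53)), 1.43 * math.sin(deg(70.53)), 0.0)
    mols["ethanol"] = _mol2_text("EOH", [
        ("C1", "C.3", (0.0, 0.0, 0.0)), ("C2", "C.3", (1.54, 0.0, 0.0)),
        ("O1", "O.3", o),
    ], [(1, 2, "1"), (2, 3, "1")])

    hexa = _hexagon()
    ring_bonds = [(k + 1, (k + 1) % 6 + 1, "ar") for k in range(6)]
    mols["benzene"] = _mol2_text("BNZ", [
        (f"C{k + 1}", "C.ar", p) for k, p in enumerate(hexa)
    ], ring_bonds)

    mols["pyridine"] = _mol2_text("PYR", [
        ("N1", "N.ar", hexa[0])] + [
        (f"C{k + 1}", "C.ar", p) for k, p in enumerate(hexa[1:], start=1)
    ], ring_bonds)

    tip = ((1.39 + 1.50), 0.0, 0.0)
    mols["toluene"] = _mol2_text("TOL", [
        (f"C{k + 1}", "C.ar", p) for k, p in enumerate(hexa)
    ] + [("C7", "C.3", tip)], ring_bonds + [(1, 7, "1")])

    mols["phenol"] = _mol2_text("PHN", [
        (f"C{k + 1}", "C.ar", p) for k, p in enumerate(hexa)
    ] + [("O1", "O.3", (1.39 + 1.36, 0.0, 0.0))], ring_bonds + [(1, 7, "1")])

    co2 = [(1.52 + 1.25 * 0.5, 1.25 * math.sin(deg(60)), 0.0),
           (1.52 + 1.25 * 0.5, -1.25 * math.sin(deg(60)), 0.0)]
    mols["acetate"] = _mol2_text("ACT", [
        ("C1", "C.3", (0.0, 0.0, 0.0)), ("C2", "C.2", (1.52, 0.0, 0.0)),
        ("O1", "O.co2", co2[0]), ("O2", "O.co2", co2[1]),
    ], [(1, 2, "1"), (2, 3, "ar"), (2, 4, "ar")])

    mols["acetamide"] = _mol2_text("ACM", [
        ("C1", "C.3", (0.0, 0.0, 0.0)), ("C2", "C.2", (1.52, 0.0, 0.0)),
        ("O1", "O.2", (1.52 + 1.23 * 0.5, 1.23 * math.sin(deg(60)), 0.0)),
        ("N1", "N.am", (1.52 + 1.33 * 0.5, -1.33 * math.sin(deg(60)), 0.0)),
    ], [(1, 2, "1"), (2, 3, "2"), (2, 4, "am")])

    mols["methylamine"] = _mol2_text("MAM", [
        ("C1", "C.3", (0.0, 0.0, 0.0)), ("N1", "N.3", (1.47, 0.0, 0.0)),
    ], [(1, 2, "1")])

    mols["methanethiol"] = _mol2_text("MSH", [
        ("C1", "C.3", (0.0, 0.0, 0.0)), ("S1", "S.3", (1.82, 0.0, 0.0)),
    ], [(1, 2, "1")])

    c2 = (1.81 * math.cos(deg(99.0)), 1.81 * math.sin(deg(99.0)), 0.0)
    mols["dimethyl_sulfide"] = _mol2_text("DMS", [
        ("C1", "C.3", (1.81, 0.0, 0.0)), ("S1", "S.3", (0.0, 0.0, 0.0)),
        ("C2", "C.3", c2),
    ], [(1, 2, "1"), (2, 3, "1")])

    mols["acetonitrile"] = _mol2_text("ACN", [
        ("C1", "C.3", (0.0, 0.0, 0.0)), ("C2", "C.1", (1.47, 0.0, 0.0)),
        ("N1", "N.1", (1.47 + 1.16, 0.0, 0.0)),
    ], [(1, 2, "1"), (2, 3, "3")])

    return mols


REFERENCE_MOLECULES: dict[str, str] = _build_reference_molecules()


def reference_mol2(name: str) -> str:
    """MOL2 text of one hand-built reference molecule (synthetic)."""
    return REFERENCE_MOLECULES[name]


# ---------------------------------------------------------------------------
# end-to-end plant-and-recover fixtures

DEFAULT_PLANT_COMBINATION = ("ALA:N-CA-CB", "C.3")


@dataclass
class PlantedFixture:
    complexes: list[ComplexStructure]
    truth: dict[tuple[str, str], MixtureSpec]
    seed: int
    pdb_texts: list[str] = field(default_factory=list)


def default_plant_spec(n_components: int = 1) -> MixtureSpec:
    """Planted ground truth inside the contact shell of the ALA N anchor.

    Component means sit ~2.5–3.5 Å from the anchor (well below the C/N
    contact threshold of 4.25 Å under Bondi radii + 1.0 Å) with σ = 0.25 Å,
    and for two components ≥ 4σ apart.
    """
    iso = (0.25 ** 2) * np.eye(3)
    if n_components == 1:
        comps = [(1.0, np.array([2.0, 1.5, 1.0]), iso)]
    elif n_components == 2:
        comps = [(0.5, np.array([2.0, 1.5, 1.0]), iso),
                 (0.5, np.array([2.0, 1.5, -1.5]), iso)]
    else:
        raise ValueError("default plant spec supports 1 or 2 components")
    return MixtureSpec(components=comps)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    return Rotation.random(rng=rng).as_matrix()


def _planted_complex(index: int, local_points: np.ndarray,
                     rng: np.random.Generator) -> ComplexStructure:
    """One ALA placed rigidly at random, ligand atoms planted in its
    N-CA-CB local frame at the given local coordinates."""
    from .contact_geometry import local_frame, to_global
    from .fragmenter import build_covalent_graph, enumerate_fragments

    R = random_rotation(rng)
    t = rng.uniform(-20.0, 20.0, size=3)
    residue = ideal_residue("ALA", rotation=R, translation=t)
    graph = build_covalent_graph([residue])
    frag = next(f for f in enumerate_fragments(graph)
                if f.type_label == DEFAULT_PLANT_COMBINATION[0])
    frame = local_frame(frag)
    global_pts = np.array([to_global(frame, p) for p in local_points])
    structure, _text = make_toy_complex(
        residues=[residue], ligand_positions=global_pts,
        ligand_sybyl_type="C.3", entry_id=f"PL{index:02d}",
    )
    return structure


def end_to_end_fixture(seed: int = 0, n_complexes: int = 30,
                       atoms_per_complex: int = 8,
                       spec: MixtureSpec | None = None,
                       truncate_mahalanobis: float | None = None) -> PlantedFixture:
    """Complexes whose ligand atoms are drawn from a known mixture in the
    ALA N-CA-CB fragment frame; the ground truth is retained so that mining
    and annotating can be checked against it.

    Mining fixtures use untruncated draws; a held-out *recognition* fixture
    should pass ``truncate_mahalanobis`` (e.g. 2.0) so every planted atom is
    a pattern instance by construction.
    """
    spec = spec or default_plant_spec()
    rng = np.random.default_rng(seed)
    complexes = []
    texts = []
    for i in range(n_complexes):
        pts = sample_points(spec, n=atoms_per_complex,
                            seed=int(rng.integers(2 ** 31)),
                            truncate_mahalanobis=truncate_mahalanobis)
        st = _planted_complex(i, pts, rng)
        complexes.append(st)
        texts.append(format_pdb(st))
    return PlantedFixture(complexes=complexes,
                         truth={DEFAULT_PLANT_COMBINATION: spec},
                         seed=seed, pdb_texts=texts)


def outlier_complex(seed: int = 0, mahalanobis: float = 3.5,
                    spec: MixtureSpec | None = None,
                    component: int = 0) -> ComplexStructure:
    """One complex with a single ligand atom planted at an exact Mahalanobis
    distance from a truth component (along its largest principal axis)."""
    spec = spec or default_plant_spec()
    rng = np.random.default_rng(seed)
    _w, mean, cov = spec.components[component]
    eigval, eigvec = np.linalg.eigh(cov)
    direction = eigvec[:, -1] * math.sqrt(eigval[-1])
    point = mean + mahalanobis * direction
    return _planted_complex(99, np.array([point]), rng)
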