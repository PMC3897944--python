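"""Decomposition of receptor residues into directed three-atom fragments.

A fragment is an ordered triple of covalently linked protein heavy atoms;
direction matters, so a path and its reverse are two distinct fragments.
For an isolated alanine (N, CA, C, O, CB) this yields eight fragments:
N-CA-CB, C-CA-CB, C-CA-N, O-C-CA and their reverses.

Covalent bonds come from per-residue template tables for the 20 standard
amino acids, plus inter-residue peptide bonds C(i)–N(i+1) gated on the two
atoms being within 1.8 Å (so chain breaks produce no spurious fragments).
Unknown residues fall back to distance-based bond inference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .structure_model import (
    AtomRecord,
    COVALENT_RADII,
    COVALENT_SLACK,
    ComplexStructure,
    Residue,
)

PEPTIDE_BOND_MAX = 1.8  # Å, C(i)–N(i+1) distance gate

#: Heavy-atom intra-residue bonds of the 20 standard amino acids.
#: Backbone bonds (N-CA, CA-C, C-O, C-OXT) are implicit for all of them.
_BACKBONE_BONDS = [("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "OXT")]
_SIDECHAIN_BONDS: dict[str, list[tuple[str, str]]] = {
    "ALA": [("CA", "CB")],
    "ARG": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"),
            ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")],
    "ASN": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "ASP": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "CYS": [("CA", "CB"), ("CB", "SG")],
    "GLN": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "NE2")],
    "GLU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")],
    "GLY": [],
    "HIS": [("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("ND1", "CE1"),
            ("CE1", "NE2"), ("NE2", "CD2"), ("CD2", "CG")],
    "ILE": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "LEU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "LYS": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ")],
    "MET": [("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PHE": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CD1", "CE1"),
            ("CE1", "CZ"), ("CZ", "CE2"), ("CE2", "CD2"), ("CD2", "CG")],
    "PRO": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "SER": [("CA", "CB"), ("CB", "OG")],
    "THR": [("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")],
    "TRP": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CD1", "NE1"),
            ("NE1", "CE2"), ("CE2", "CD2"), ("CD2", "CG"), ("CE2", "CZ2"),
            ("CZ2", "CH2"), ("CH2", "CZ3"), ("CZ3", "CE3"), ("CE3", "CD2")],
    "TYR": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CD1", "CE1"),
            ("CE1", "CZ"), ("CZ", "CE2"), ("CE2", "CD2"), ("CD2", "CG"),
            ("CZ", "OH")],
    "VAL": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")],
}

RESIDUE_TEMPLATES: dict[str, list[tuple[str, str]]] = {
    name: _BACKBONE_BONDS + side for name, side in _SIDECHAIN_BONDS.items()
}


@dataclass
class CovalentGraph:
    """Undirected covalent-bond graph over the receptor's heavy atoms."""

    atoms: list[AtomRecord]
    residue_of: list[int]          # atom index -> residue index
    residues: list[Residue]
    adjacency: list[set[int]] = field(default_factory=list)

    def add_edge(self, i: int, j: int) -> None:
        if i == j:
            raise ValueError("covalent graph cannot have self-loops")
        self.adjacency[i].add(j)
        self.adjacency[j].add(i)

    def n_edges(self) -> int:
        return sum(len(s) for s in self.adjacency) // 2

    def edges(self) -> set[frozenset]:
        return {frozenset((i, j)) for i, s in enumerate(self.adjacency) for j in s}


@dataclass(frozen=True)
class Fragment:
    """Ordered triple of covalently linked heavy atoms; the first is the anchor."""

    atoms: tuple[AtomRecord, AtomRecord, AtomRecord]
    type_label: str
    atom_indices: tuple[int, int, int] = (0, 1, 2)

    @property
    def anchor(self) -> AtomRecord:
        return self.atoms[0]

    def positions(self) -> np.ndarray:
        return np.array([a.coordinates for a in self.atoms])


def build_covalent_graph(structure_or_residues, link_disulfides: bool = False) -> CovalentGraph:
    """Bond graph from residue templates + distance-gated peptide bonds.

    Residues with no template get bonds inferred from interatomic distances
    (covalent-radius sum + 0.4 Å).  Disulfide (SG–SG) links are off by
    default and enabled with ``link_disulfides``.
    """
    if isinstance(structure_or_residues, ComplexStructure):
        residues = structure_or_residues.receptor
    else:
        residues = list(structure_or_residues)

    atoms: list[AtomRecord] = []
    residue_of: list[int] = []
    index_of: list[dict[str, int]] = []
    for ri, res in enumerate(residues):
        names: dict[str, int] = {}
        for a in res.atoms:
            names[a.name] = len(atoms)
            atoms.append(a)
            residue_of.append(ri)
        index_of.append(names)

    graph = CovalentGraph(atoms=atoms, residue_of=residue_of, residues=residues,
                          adjacency=[set() for _ in atoms])

    for ri, res in enumerate(residues):
        template = RESIDUE_TEMPLATES.get(res.name)
        names = index_of[ri]
        if template is not None:
            for a, b in template:
                if a in names and b in names:
                    graph.add_edge(names[a], names[b])
        else:
            _infer_bonds_by_distance(graph, list(names.values()))

    # peptide bonds between consecutive residues of the same chain
    for ri in range(len(residues) - 1):
        r1, r2 = residues[ri], residues[ri + 1]
        if r1.chain_id != r2.chain_id:
            continue
        i, j = index_of[ri].get("C"), index_of[ri + 1].get("N")
        if i is None or j is None:
            continue
        d = np.linalg.norm(atoms[i].coordinates - atoms[j].coordinates)
        if d <= PEPTIDE_BOND_MAX:
            graph.add_edge(i, j)

    if link_disulfides:
        sg = [i for i, a in enumerate(atoms) if a.name == "SG"]
        _infer_bonds_by_distance(graph, sg)

    return graph


def _infer_bonds_by_distance(graph: CovalentGraph, indices: list[int]) -> None:
    for i, j in itertools.combinations(indices, 2):
        a, b = graph.atoms[i], graph.atoms[j]
        cutoff = (COVALENT_RADII.get(a.element, 0.77)
                  + COVALENT_RADII.get(b.element, 0.77) + COVALENT_SLACK)
        if np.linalg.norm(a.coordinates - b.coordinates) <= cutoff:
            graph.add_edge(i, j)


def enumerate_fragments(graph: CovalentGraph) -> list[Fragment]:
    """All directed simple paths of exactly three atoms.

    For every middle atom b, each ordered pair of distinct neighbours (a, c)
    yields the fragment a–b–c, so the output is closed under reversal and
    its size is twice the number of undirected three-atom paths.
    """
    fragments: list[Fragment] = []
    for b, neigh in enumerate(graph.adjacency):
        for a in sorted(neigh):
            for c in sorted(neigh):
                if a == c:
                    continue
                triple = (graph.atoms[a], graph.atoms[b], graph.atoms[c])
                label = _label(graph, (a, b, c))
                fragments.append(Fragment(atoms=triple, type_label=label,
                                          atom_indices=(a, b, c)))
    return fragments


def _label(graph: CovalentGraph, idx: tuple[int, int, int]) -> str:
    anchor_res = graph.residue_of[idx[0]]
    parts = []
    for i in idx:
        name = graph.atoms[i].name
        delta = graph.residue_of[i] - anchor_res
        parts.append(name if delta == 0 else f"{name}{delta:+d}")
    return f"{graph.residues[anchor_res].name}:{'-'.join(parts)}"


def fragment_type_label(fragment: Fragment) -> str:
    """Canonical type label, e.g. ``ALA:N-CA-CB`` or ``HIS:O-C-N+1``.

    The residue context is the anchor atom's residue; atoms from other
    residues carry a relative-position suffix.
    """
    return fragment.type_label
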