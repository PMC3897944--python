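"""Dataset-inclusion filters for protein–ligand binding sites.

A binding site enters the mining dataset only if the structure was solved by
X-ray crystallography at resolution ≤ 2.5 Å, the receptor has ≥ 30 amino
acid residues, and the ligand has molecular weight between 80 and 800 Da,
more than 5 heavy atoms, and relative accessible surface area (rASA) below
0.6 — i.e. the ligand is substantially buried in a binding site rather than
sitting on the surface.

SASA is computed with a Shrake–Rupley numerical quadrature over a
deterministic golden-spiral point set, so results are exactly reproducible
for a fixed point count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .config import CurationThresholds
from .structure_model import (
    AtomRecord,
    ComplexStructure,
    LigandInstance,
    VdwRadiusTable,
)


@dataclass
class CurationVerdict:
    accepted: bool
    reasons: list[str] = field(default_factory=list)

    VALID_REASONS = frozenset({
        "method", "resolution", "receptor_size", "ligand_mw",
        "ligand_atoms", "ligand_rasa",
    })

    def __post_init__(self):
        bad = set(self.reasons) - self.VALID_REASONS
        if bad:
            raise ValueError(f"unknown curation reasons: {sorted(bad)}")
        if self.accepted != (not self.reasons):
            raise ValueError("accepted must be equivalent to an empty reason list")


def golden_spiral_points(n: int) -> np.ndarray:
    """n deterministic, nearly uniform points on the unit sphere."""
    if n < 2:
        raise ValueError("need at least 2 sphere points")
    i = np.arange(n)
    # evenly spaced in z, golden-angle spaced in azimuth
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def compute_sasa(atoms: list[AtomRecord], radii: VdwRadiusTable,
                 probe_radius: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²), Shrake–Rupley style.

    Each atom's accessible sphere (vdW radius + probe) is sampled at
    ``n_points`` golden-spiral points; a point is accessible when it lies
    outside every other atom's accessible sphere.  The per-atom area is the
    accessible fraction times 4π(r+probe)².
    """
    if not atoms:
        raise ValueError("cannot compute SASA of an empty atom set")
    if n_points < 2:
        raise ValueError("n_points must be ≥ 2")
    xyz = np.array([a.coordinates for a in atoms])
    rads = np.array([radii.radius(a.element) for a in atoms]) + probe_radius
    unit = golden_spiral_points(n_points)
    tree = cKDTree(xyz)
    max_reach = 2.0 * rads.max()
    areas = np.empty(len(atoms))
    for i in range(len(atoms)):
        pts = xyz[i] + rads[i] * unit
        neighbors = [j for j in tree.query_ball_point(xyz[i], max_reach) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            accessible &= d2 > rads[j] ** 2
            if not accessible.any():
                break
        areas[i] = accessible.mean() * 4.0 * np.pi * rads[i] ** 2
    return areas


def relative_ligand_asa(structure: ComplexStructure, ligand: LigandInstance,
                        radii: VdwRadiusTable | None = None,
                        probe_radius: float = 1.4, n_points: int = 960) -> float:
    """Ligand SASA in the full complex divided by its SASA in isolation.

    The complex context is the receptor plus every ligand instance of the
    structure; the ratio is clamped to [0, 1].
    """
    if radii is None:
        radii = VdwRadiusTable()
    lig_atoms = ligand.atoms
    isolated = compute_sasa(lig_atoms, radii, probe_radius, n_points).sum()
    if isolated <= 0.0:
        raise ValueError("degenerate ligand: zero accessible area in isolation")
    context = structure.receptor_atoms()
    for other in structure.ligands:
        if other is not ligand:
            context = context + other.atoms
    if not context:
        return 1.0
    all_atoms = lig_atoms + context
    in_complex = compute_sasa(all_atoms, radii, probe_radius, n_points)[:len(lig_atoms)].sum()
    return float(np.clip(in_complex / isolated, 0.0, 1.0))


def passes_curation(structure: ComplexStructure, ligand: LigandInstance,
                    thresholds: CurationThresholds | None = None,
                    radii: VdwRadiusTable | None = None,
                    probe_radius: float = 1.4, n_points: int = 960,
                    rasa: float | None = None) -> CurationVerdict:
    """Apply every inclusion criterion; all failures are reported, none raise.

    Boundary semantics: resolution 2.5 Å passes (≤), 30 residues passes (≥),
    MW 80 and 800 Da pass (inclusive), 6 atoms passes but 5 fails (strict >),
    rASA 0.6 fails (strict <).  Missing method/resolution metadata fails the
    corresponding criterion.  ``rasa`` short-circuits the SASA computation
    when the caller has it already.
    """
    t = thresholds or CurationThresholds()
    reasons = []
    if structure.method is None or "X-RAY" not in structure.method.upper().replace("–", "-"):
        reasons.append("method")
    if structure.resolution is None or structure.resolution > t.max_resolution:
        reasons.append("resolution")
    if structure.n_residues() < t.min_residues:
        reasons.append("receptor_size")
    if not (t.min_ligand_mw <= ligand.molecular_weight <= t.max_ligand_mw):
        reasons.append("ligand_mw")
    if len(ligand.atoms) <= t.min_ligand_atoms:
        reasons.append("ligand_atoms")
    if rasa is None:
        rasa = relative_ligand_asa(structure, ligand, radii, probe_radius, n_points)
    if rasa >= t.max_ligand_rasa:
        reasons.append("ligand_rasa")
    return CurationVerdict(accepted=not reasons, reasons=reasons)
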