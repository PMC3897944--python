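"""Fragment–ligand contact detection and fragment-local coordinates.

A ligand atom contacts a fragment when its distance to the fragment's
*anchor* (first) atom is strictly below the sum of the two van der Waals
radii plus a 1.0 Å offset.  Each contact's position is then re-expressed in
the fragment's local coordinate frame, so that contacts pooled over many
structures form a rigid-motion-invariant 3D point cloud per
(fragment type, ligand atom type) combination.

Frame convention (recorded in every pattern library):
origin at the anchor atom; x along anchor→second atom; the third atom in
the xy-plane with positive y; z = x × y (right-handed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .config import FRAME_CONVENTION
from .fragmenter import Fragment
from .structure_model import AtomRecord, LigandInstance, VdwRadiusTable

logger = logging.getLogger(__name__)

COLLINEARITY_MIN_AREA = 1e-6  # Å², minimum triangle area for a valid frame


class DegenerateFrameError(ValueError):
    """Fragment atoms are (nearly) collinear; no frame can be built."""


@dataclass(frozen=True)
class LocalFrame:
    """Rigid transform from global to fragment-local coordinates."""

    origin: np.ndarray    # (3,)
    rotation: np.ndarray  # (3,3), rows are the local axes in global coords

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))


@dataclass(frozen=True)
class Contact:
    """One (fragment, ligand atom) pair within the contact criterion."""

    fragment: Fragment
    ligand_atom: AtomRecord
    ligand_atom_type: str
    global_distance: float
    local_position: np.ndarray
    source: tuple = ()  # (entry id, chain, residue number, ligand code)

    @property
    def combination(self) -> tuple[str, str]:
        return (self.fragment.type_label, self.ligand_atom_type)


def local_frame(fragment: Fragment) -> LocalFrame:
    """Right-handed orthonormal frame from the fragment's three atoms.

    Raises DegenerateFrameError when the atoms are collinear (triangle area
    ≤ 1e-6 Å²).
    """
    p1, p2, p3 = (np.asarray(a.coordinates, dtype=float) for a in fragment.atoms)
    v12 = p2 - p1
    v13 = p3 - p1
    cross = np.cross(v12, v13)
    area = 0.5 * np.linalg.norm(cross)
    if area <= COLLINEARITY_MIN_AREA:
        raise DegenerateFrameError(
            f"collinear fragment {fragment.type_label} (triangle area {area:.2e} Å²)"
        )
    x = v12 / np.linalg.norm(v12)
    z = cross / np.linalg.norm(cross)
    y = np.cross(z, x)  # unit, orthogonal; p3 has positive y by construction
    return LocalFrame(origin=p1, rotation=np.vstack([x, y, z]))


def to_local(frame: LocalFrame, point: np.ndarray) -> np.ndarray:
    """Map a global point into the frame: R · (p − origin). Isometric."""
    return frame.rotation @ (np.asarray(point, dtype=float) - frame.origin)


def to_global(frame: LocalFrame, point: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_local`."""
    return frame.rotation.T @ np.asarray(point, dtype=float) + frame.origin


def detect_contacts(fragments: list[Fragment], ligand: LigandInstance,
                    radii: VdwRadiusTable | None = None, offset: float = 1.0,
                    ligand_types: list[str] | None = None,
                    source: tuple = ()) -> list[Contact]:
    """All (fragment, ligand atom) pairs below the vdW-sum + offset criterion.

    The distance is measured from the fragment's anchor atom and the
    comparison is strict (<).  A KD-tree prunes the pair scan but the
    contract is the plain pairwise distance check.  Fragments with collinear
    atoms are skipped and counted in a log message, never silently dropped.
    """
    if radii is None:
        radii = VdwRadiusTable()
    if not fragments or not ligand.atoms:
        return []
    if ligand_types is None:
        from .ligand_typing import resolve_types
        ligand_types = resolve_types(ligand)

    lig_xyz = ligand.coordinates()
    lig_radii = np.array([radii.radius(a.element) for a in ligand.atoms])
    tree = cKDTree(lig_xyz)
    max_threshold = float(lig_radii.max()) + max(radii.radii.values()) + offset

    contacts: list[Contact] = []
    n_degenerate = 0
    for frag in fragments:
        anchor = frag.anchor
        r_anchor = radii.radius(anchor.element)
        candidates = tree.query_ball_point(anchor.coordinates, max_threshold)
        if not candidates:
            continue
        frame = None
        for idx in sorted(candidates):
            threshold = r_anchor + lig_radii[idx] + offset
            d = float(np.linalg.norm(anchor.coordinates - lig_xyz[idx]))
            if d < threshold:
                if frame is None:
                    try:
                        frame = local_frame(frag)
                    except DegenerateFrameError:
                        n_degenerate += 1
                        break
                contacts.append(Contact(
                    fragment=frag,
                    ligand_atom=ligand.atoms[idx],
                    ligand_atom_type=ligand_types[idx],
                    global_distance=d,
                    local_position=to_local(frame, lig_xyz[idx]),
                    source=source,
                ))
    if n_degenerate:
        logger.info("skipped %d degenerate (collinear) fragments", n_degenerate)
    return contacts


FRAME_CONVENTION_TAG = FRAME_CONVENTION
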