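"""Mining orchestration, per-complex annotation tables and dataset statistics.

This module ties the pipeline together:

* :func:`mine_patterns` — run fragments → contacts → local coordinates over a
  set of binding sites, fit one Gaussian mixture per (fragment type, ligand
  atom type) combination, and return a pattern library whose components carry
  occurrence counts (``Freq.``) and protein-family spread (``Family``);
* :func:`annotate_complex` — the Complex-Analyzer-style interaction table
  for one binding site against a mined library;
* :func:`recognition_stats` — the fraction of ligand atoms recognized by at
  least one pattern, and the fraction of complexes where more than half the
  ligand atoms are recognized;
* :func:`pattern_summary` — the per-pattern table with supporting ligands
  and source complexes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ENGINE_VERSION, EngineConfig
from .contact_geometry import Contact, detect_contacts
from .family_clustering import FamilyAssignment, build_families
from .fragmenter import build_covalent_graph, enumerate_fragments
from .ligand_typing import resolve_types
from .pattern_model import (
    MixtureModel,
    PatternAssignment,
    PatternLibrary,
    assign_patterns,
    fit_mixture,
)
from .structure_model import (
    ComplexStructure,
    LigandInstance,
    VdwRadiusTable,
    select_binding_site,
)


@dataclass
class AnnotationRecord:
    """One row of the interaction table."""

    interaction_id: int
    residue: tuple[str, int, str]        # (chain, number, residue name)
    fragment_label: str
    ligand_atom_index: int
    ligand_atom_name: str
    ligand_atom_type: str
    distance: float                      # Å, anchor → ligand atom
    assignments: list[PatternAssignment] = field(default_factory=list)
    frequency: int | None = None         # nearest pattern's support count
    family_count: int | None = None      # nearest pattern's family count
    density: float | None = None         # mixture density at the contact, Å⁻³

    @property
    def recognized(self) -> bool:
        return bool(self.assignments)


@dataclass
class RecognitionStats:
    atom_recognized_fraction: float
    complexes_majority_recognized_fraction: float
    detail: pd.DataFrame                 # per complex: atoms, recognized, majority

    def __post_init__(self):
        for f in (self.atom_recognized_fraction,
                  self.complexes_majority_recognized_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("recognition fractions must lie in [0, 1]")


@dataclass
class MiningResult:
    library: PatternLibrary
    contacts: list[Contact]
    assignments: list[tuple[Contact, PatternAssignment]]
    families: FamilyAssignment
    site_of_contact: dict[int, str] = field(default_factory=dict)  # id(contact) -> site id
    skipped_combinations: list[tuple[str, str, int]] = field(default_factory=list)


def site_contacts(structure: ComplexStructure, ligand: LigandInstance,
                  radii: VdwRadiusTable, offset: float,
                  ligand_types: list[str] | None = None) -> list[Contact]:
    """Fragments → contacts for one binding site."""
    graph = build_covalent_graph(structure)
    fragments = enumerate_fragments(graph)
    if ligand_types is None:
        ligand_types = resolve_types(ligand)
    source = (structure.entry_id, ligand.chain_id, ligand.residue_number,
              ligand.component_code)
    return detect_contacts(fragments, ligand, radii, offset,
                           ligand_types=ligand_types, source=source)


def _site_id(structure: ComplexStructure, ligand: LigandInstance) -> str:
    return (f"{structure.entry_id or 'entry'}:{ligand.component_code}:"
            f"{ligand.chain_id}{ligand.residue_number}")


def mine_patterns(binding_sites: list[tuple[ComplexStructure, LigandInstance]],
                  config: EngineConfig | None = None,
                  radii: VdwRadiusTable | None = None) -> MiningResult:
    """Mine a pattern library from a set of binding sites.

    Contacts are pooled per (fragment type, ligand atom type) combination and
    a mixture is fitted to each pool with at least ``config.min_points``
    contacts (smaller pools are recorded as skipped).  Afterwards every mined
    contact is assigned back at the annotation threshold to fill each
    pattern's support count and protein-family spread.  Deterministic for a
    fixed config seed.
    """
    config = config or EngineConfig()
    radii = radii or VdwRadiusTable()

    all_contacts: list[Contact] = []
    site_of: dict[int, str] = {}
    site_sequences: dict[str, str] = {}
    for structure, ligand in binding_sites:
        sid = _site_id(structure, ligand)
        contacts = site_contacts(structure, ligand, radii, config.offset)
        for c in contacts:
            site_of[id(c)] = sid
        all_contacts.extend(contacts)
        chains = sorted({c.fragment.anchor.chain_id for c in contacts})
        seq = "".join(structure.sequences.get(ch, "") for ch in chains)
        if seq:
            site_sequences[sid] = seq

    families = build_families(site_sequences, config.identity_min,
                              config.coverage_min) if site_sequences else \
        FamilyAssignment(families={}, parameters=(config.identity_min,
                                                  config.coverage_min))

    pools: dict[tuple[str, str], list[Contact]] = {}
    for c in all_contacts:
        pools.setdefault(c.combination, []).append(c)

    library = PatternLibrary(
        offset=config.offset,
        mahalanobis_threshold=config.mahalanobis_threshold,
        radius_table=dict(radii.radii),
        default_radius=radii.default_radius,
    )
    skipped: list[tuple[str, str, int]] = []
    for idx, key in enumerate(sorted(pools)):
        pts = np.array([c.local_position for c in pools[key]])
        model = fit_mixture(
            pts, combination=key, k_max=config.k_max,
            n_restarts=config.restarts, seed=(config.seed + idx) % (2 ** 31),
            min_points=config.min_points,
            covariance_floor=config.covariance_floor,
        )
        if model is None:
            skipped.append((key[0], key[1], len(pools[key])))
        else:
            library.models[key] = model
    library.assign_ids()

    # support and family counts from re-assignment at the mining threshold
    assignments: list[tuple[Contact, PatternAssignment]] = []
    fam_sets: dict[int, set[str]] = {}
    comp_by_id = {comp.pattern_id: comp for _m, comp in library.components()}
    for key, contacts in sorted(pools.items()):
        model = library.models.get(key)
        if model is None:
            continue
        for c in contacts:
            for asg in assign_patterns(c.local_position, model,
                                       config.mahalanobis_threshold):
                assignments.append((c, asg))
                comp_by_id[asg.pattern_id].support_count += 1
                sid = site_of[id(c)]
                fam = families.families.get(sid)
                if fam is not None:
                    fam_sets.setdefault(asg.pattern_id, set()).add(fam)
    for pid, fams in fam_sets.items():
        comp_by_id[pid].family_count = len(fams)

    return MiningResult(library=library, contacts=all_contacts,
                        assignments=assignments, families=families,
                        site_of_contact=site_of, skipped_combinations=skipped)


# ---------------------------------------------------------------------------
# annotation

def annotate_complex(structure: ComplexStructure, ligand_code: str,
                     library: PatternLibrary, threshold: float | None = None,
                     instance_index: int = 0,
                     radii: VdwRadiusTable | None = None,
                     ligand: LigandInstance | None = None,
                     ligand_types: list[str] | None = None) -> list[AnnotationRecord]:
    """Interaction table for one binding site against a pattern library.

    Every contact produces one record; contacts whose combination has no
    mixture in the library get a record with no assignments.  Records are
    sorted by (ligand atom, distance).
    """
    if threshold is None:
        threshold = library.mahalanobis_threshold
    if radii is None:
        if library.radius_table:
            radii = VdwRadiusTable(radii=dict(library.radius_table),
                                   default_radius=library.default_radius)
        else:
            radii = VdwRadiusTable()
    if ligand is None:
        _receptor, ligand = select_binding_site(structure, ligand_code, instance_index)

    contacts = site_contacts(structure, ligand, radii, library.offset,
                             ligand_types=ligand_types)
    atom_index = {id(a): i for i, a in enumerate(ligand.atoms)}

    comp_by_id = {comp.pattern_id: comp for _m, comp in library.components()}
    records: list[AnnotationRecord] = []
    for c in contacts:
        model = library.lookup(*c.combination)
        assignments: list[PatternAssignment] = []
        density = None
        if model is not None:
            assignments = assign_patterns(c.local_position, model, threshold)
            from .pattern_model import mixture_density
            density = mixture_density(c.local_position, model)
        freq = fam = None
        if assignments:
            nearest = comp_by_id[assignments[0].pattern_id]
            freq, fam = nearest.support_count, nearest.family_count
        anchor = c.fragment.anchor
        records.append(AnnotationRecord(
            interaction_id=0,
            residue=(anchor.residue_id[0], anchor.residue_id[1], anchor.residue_name),
            fragment_label=c.fragment.type_label,
            ligand_atom_index=atom_index[id(c.ligand_atom)],
            ligand_atom_name=c.ligand_atom.name,
            ligand_atom_type=c.ligand_atom_type,
            distance=c.global_distance,
            assignments=assignments,
            frequency=freq, family_count=fam, density=density,
        ))
    records.sort(key=lambda r: (r.ligand_atom_index, r.distance, r.fragment_label))
    for i, rec in enumerate(records, start=1):
        rec.interaction_id = i
    return records


def recognition_stats(per_complex: list[tuple[int, list[AnnotationRecord]]]
                      ) -> RecognitionStats:
    """Dataset recognition statistics.

    ``per_complex`` holds (ligand atom count, annotation records) per
    binding site.  An atom is recognized iff at least one of its contacts
    carries at least one pattern assignment; a complex counts toward the
    majority statistic iff strictly more than half of its ligand atoms are
    recognized.
    """
    total_atoms = recognized_atoms = majority = 0
    rows = []
    for i, (n_atoms, records) in enumerate(per_complex):
        rec_atoms = {r.ligand_atom_index for r in records if r.recognized}
        n_rec = len(rec_atoms)
        total_atoms += n_atoms
        recognized_atoms += n_rec
        is_majority = n_rec * 2 > n_atoms
        majority += is_majority
        rows.append({"complex": i, "ligand_atoms": n_atoms,
                     "recognized_atoms": n_rec, "majority": bool(is_majority)})
    n_complexes = len(per_complex)
    return RecognitionStats(
        atom_recognized_fraction=recognized_atoms / total_atoms if total_atoms else 0.0,
        complexes_majority_recognized_fraction=majority / n_complexes if n_complexes else 0.0,
        detail=pd.DataFrame(rows, columns=["complex", "ligand_atoms",
                                           "recognized_atoms", "majority"]),
    )


def pattern_summary(result: MiningResult) -> pd.DataFrame:
    """Per-pattern table: support, family spread, ligands and source complexes."""
    rows = []
    supporters: dict[int, list[Contact]] = {}
    for contact, asg in result.assignments:
        supporters.setdefault(asg.pattern_id, []).append(contact)
    for model, comp in result.library.components():
        contacts = supporters.get(comp.pattern_id, [])
        ligands = sorted({c.source[3] for c in contacts if c.source})
        complexes = sorted({c.source[0] for c in contacts if c.source})
        rows.append({
            "pattern_id": comp.pattern_id,
            "fragment_type": model.combination[0],
            "ligand_type": model.combination[1],
            "support": comp.support_count,
            "families": comp.family_count,
            "ligands": ",".join(ligands),
            "complexes": ",".join(complexes),
        })
    rows.sort(key=lambda r: r["pattern_id"])
    return pd.DataFrame(rows, columns=["pattern_id", "fragment_type", "ligand_type",
                                       "support", "families", "ligands", "complexes"])


# ---------------------------------------------------------------------------
# TSV output

def _tsv_header(library: PatternLibrary | None, extra: dict | None = None) -> str:
    radii = VdwRadiusTable(radii=dict(library.radius_table)) \
        if library and library.radius_table else VdwRadiusTable()
    fields = {"engine_version": ENGINE_VERSION}
    if library is not None:
        fields.update({
            "offset_A": library.offset,
            "mahalanobis_threshold": library.mahalanobis_threshold,
            "radius_table_hash": radii.content_hash(),
            "frame_convention": library.frame_convention,
        })
    fields.update(extra or {})
    return "".join(f"# {k}={v}\n" for k, v in fields.items())


def annotation_table(records: list[AnnotationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "interaction_id": r.interaction_id,
            "chain": r.residue[0],
            "residue_number": r.residue[1],
            "residue_name": r.residue[2],
            "fragment": r.fragment_label,
            "ligand_atom": r.ligand_atom_name,
            "ligand_type": r.ligand_atom_type,
            "distance_A": round(r.distance, 3),
            "pattern_ids": ",".join(str(a.pattern_id) for a in r.assignments),
            "mahalanobis": round(r.assignments[0].mahalanobis, 4) if r.assignments else "",
            "freq": r.frequency if r.frequency is not None else "",
            "family": r.family_count if r.family_count is not None else "",
            "prob": f"{r.density:.6g}" if r.density is not None else "",
        })
    return pd.DataFrame(rows, columns=["interaction_id", "chain", "residue_number",
                                       "residue_name", "fragment", "ligand_atom",
                                       "ligand_type", "distance_A", "pattern_ids",
                                       "mahalanobis", "freq", "family", "prob"])


def write_annotation_tsv(records: list[AnnotationRecord], path,
                         library: PatternLibrary | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_tsv_header(library))
        annotation_table(records).to_csv(fh, sep="\t", index=False)


def write_summary_tsv(result: MiningResult, path) -> None:
    with open(path, "w") as fh:
        fh.write(_tsv_header(result.library))
        pattern_summary(result).to_csv(fh, sep="\t", index=False)
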