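# Methods

## The model

The unit of analysis is a *binding site*: one receptor protein and one
bound small-molecule ligand instance. The method assumes that preferred
protein–ligand contact geometries are local properties of short protein
fragments, so the receptor is decomposed into **directed three-atom
fragments** — ordered triples of covalently linked heavy atoms; a path and
its reverse are distinct fragments with distinct type labels. A fragment's
type label combines the anchor residue's name with the atom-name path
(`ALA:N-CA-CB`); atoms borrowed from a neighbouring residue carry a
relative-position suffix (`HIS:O-C-N+1` for the backbone carbonyl fragment
that reaches into the next residue's amide nitrogen).

A ligand atom and a fragment form a **contact** when the distance between
the atom and the fragment's first (anchor) atom is *strictly less than*
r_vdW(anchor) + r_vdW(atom) + 1.0 Å. Van der Waals radii default to the
Bondi (1964) table with a configurable 1.7 Å fallback for unlisted
elements. Only the anchor's distance is constrained; waters are excluded
wholesale (contacts that are water-mediated in reality appear as direct
contacts whenever the distance criterion holds), and hydrogens are
discarded everywhere, since X-ray structures at the curation resolution
rarely resolve them.

Each contact's position is re-expressed in the fragment's **local frame**:
origin at the anchor, x-axis along atom1→atom2, atom3 in the xy-plane with
positive y, z = x × y. Any consistent right-handed convention produces
equivalent statistics; this one is fixed, and its tag is serialized into
every pattern library so libraries are self-describing. Fragments whose
atoms are collinear (triangle area ≤ 1e-6 Å²) cannot define a frame; their
contacts are skipped and counted in a log message.

Contacts are pooled per (fragment type, SYBYL ligand-atom type)
combination, and a **Gaussian mixture** p(x) = Σₖ wₖ N(x; μₖ, Σₖ) with full
covariances is fitted to each pool. Every fitted component is one
*interaction pattern*. Annotation assigns a contact to every pattern whose
Mahalanobis distance √((x−μₖ)ᵀΣₖ⁻¹(x−μₖ)) is ≤ 2.5 (several patterns can
hold simultaneously; reports list them nearest-first). A ligand atom is
*recognized* when at least one of its contacts carries at least one
assignment; a complex counts toward the majority statistic when strictly
more than half of its ligand atoms are recognized.

Each pattern carries a support count ("Freq.": contacts assigned to it at
the mining threshold) and a protein-family spread ("Family": distinct
families among its supporters). Families are single-linkage clusters of
binding-site receptor sequences, linking any pair with ≥ 25% identity and
≥ 50% coverage. The sequence of a binding site is the concatenation of the
receptor chains that contribute at least one contact.

## Fitting and numerical choices

* **EM + BIC.** For each pool with ≥ `min_points` (default 20) contacts, EM
  runs for K = 1..`k_max` (default 10) with `restarts` (default 5) seeded
  k-means++-style initialisations each; the model with minimal BIC wins,
  where the parameter count is (K−1) + 3K + 6K. Restart runs that starve a
  component below one expected point are discarded (BIC comparisons among
  degenerate fits are meaningless); if every multi-component run starves,
  the K = 1 fit, which cannot starve, is used.
* **Covariance floor.** 1e-4 Å² is added to covariance diagonals every
  M-step so components cannot collapse onto replicated coordinates. Because
  the floor is re-applied after the exact M-step, the EM log-likelihood is
  guaranteed non-decreasing only up to a slack of the floor's order; the
  per-iteration assertion uses that slack and is strict when the floor is
  zero (covered by a dedicated test).
* **Stability.** Mahalanobis distances and Gaussian densities go through
  Cholesky factorisations, never explicit inverses. Library round-trips
  preserve parameters to 1e-12; loading validates weight sums (±1e-9),
  covariance positive-definiteness (eigenvalues > 1e-6 Å²) and pattern-id
  uniqueness.
* **Determinism.** Every stochastic step (EM restarts, fixture sampling) is
  driven by an explicit seed; per-combination fit seeds are derived from
  the base seed plus the combination's rank in sorted order, so mining is
  reproducible and independent of pool iteration order.
* **SASA.** Shrake–Rupley with a deterministic golden-spiral quadrature
  (default 960 points, probe 1.4 Å). An isolated sphere is exact by
  construction; occluded geometries converge as the point count grows.
  Relative accessible surface area = ligand SASA in the full complex /
  ligand SASA in isolation, clamped to [0, 1].
* **Sequence alignment.** Global Needleman–Wunsch (Biopython
  `PairwiseAligner`) with BLOSUM62, gap open −11 / extend −1. Identity is
  counted over aligned (non-gap) columns; coverage is aligned residues of
  the shorter sequence over its length.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `offset` | 1.0 Å | added to the vdW-radius sum in the contact criterion |
| `mahalanobis_threshold` | 2.5 | pattern assignment cut-off (≤) |
| `k_max` / `restarts` / `min_points` | 10 / 5 / 20 | mixture-fit search space |
| `covariance_floor` | 1e-4 Å² | collapse guard on covariance diagonals |
| `probe_radius` / `sasa_points` | 1.4 Å / 960 | SASA quadrature |
| `identity_min` / `coverage_min` | 0.25 / 0.50 | family linkage criterion |
| curation | ≤2.5 Å, ≥30 res, 80–800 Da, >5 atoms, <0.6 rASA | dataset inclusion |

The contact offset, Mahalanobis threshold, family thresholds and curation
cut-offs are the published constants of the method and are boundary-tested
exactly as printed (resolution 2.5 passes; 5 atoms fails, 6 passes; rASA
0.6 fails). The remaining knobs are implementation choices: mixture-search
defaults were chosen as conventional EM/BIC settings for 3D clouds of a few
hundred to a few thousand points, and the SASA quadrature is sized so the
isolated-sphere closed form is met well within 2%.

## Design decisions where the method is open

* **Model selection by BIC.** The pattern-count selection machinery of the
  original statistical survey is not reproducible from its description;
  EM + BIC is this package's own, documented choice, with the config left
  open for alternatives (e.g. variational pruning).
* **"Pattern" = one Gaussian component.** Assignment distance is measured
  to a single component, not to the mixture; each component is a separate
  pattern with its own id, support and family counts.
* **Fragment labels keep residue context.** `ALA:O-C-CA` and `GLY:O-C-CA`
  are distinct types; backbone-only labels could be merged by a relabeling
  pass if coarser statistics are wanted.
* **Cross-residue fragments are generated** (peptide-bond spanning, gated
  on C–N ≤ 1.8 Å so chain breaks produce nothing). Disulfide-spanning
  fragments are off by default.
* **MW for curation** sums heavy-atom masses plus implicit hydrogens
  inferred from bond orders when bonds are known (MOL2), else heavy atoms
  only. The heavy-atom count criterion always counts heavy atoms.
* **The 27-type SYBYL registry** is the conventional heavy-atom list
  (4 carbons + C.cat, 7 nitrogens, 3 oxygens, 4 sulfurs, P.3, 4 halogens,
  B/Si/Se); which 27 types the original classification used is not
  recoverable, so the registry is config-editable. Declared MOL2 types win
  over geometric perception; an override TSV wins over both.
* **Covalently bound ligands** are kept (flagged), and multiple copies of
  the same component are separate binding sites.

## What the synthetic data does and does not show

The fixture generator emulates the *geometry* of the mining problem:
template-conformant residues placed at random rigid poses, ligand atoms
drawn from known Gaussian mixtures in fragment-local frames (means
2.5–3.5 Å from the anchor, σ = 0.25 Å, components ≥ 4σ apart), declared
C.3 typing, and valid PDB output that round-trips the real parser. Held-out
recognition fixtures draw from the truth mixture *truncated* at Mahalanobis
2.0, so every planted atom is a pattern instance by construction and the
recognition rate measures parameter-estimation error only; an untruncated
3D Gaussian places ~10% of its mass beyond Mahalanobis 2.5, which would cap
the expected recognition of even a perfect model at ~90%.

The fixtures do **not** emulate coordinate noise, disorder/occupancy,
crystal contacts, chemically diverse ligands, redundant protein families,
or the heavy-tailed, anisotropic clouds of real contact statistics. Passing
the plant-and-recover suite therefore shows the pipeline is correct and
self-consistent, not that real-data recognition rates would match any
particular value; dataset-scale statistics depend on the PDB snapshot and
curation of a full mining run.

Problem sizes used by the test suite and the acceptance script — 30 mining
complexes × 8 planted atoms, 20 mixture replicates at n = 1000, 100
random contact fixtures, 1000 rigid motions — were chosen as the smallest
sets at which the measured quantities are stable across seeds.

## Known limitations

* PDB input only (first MODEL); no mmCIF, assemblies or symmetry mates.
* Geometric atom typing is rule-based and can mistype exotic chemistry
  (fused heteroaromatics, charged groups); supply a MOL2 or an override
  table for irregular ligands.
* No angle- or energy-based interaction classification — the method is
  deliberately purely statistical.
* Family clustering does all-pairs global alignment: fine for hundreds of
  binding sites, not for tens of thousands (swap in a clustering heuristic
  before dataset-scale runs).
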