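# ligpatmine

Statistical mining and annotation of 3D **interaction patterns** in
protein–small-ligand complexes.

Interpretation of ligand binding modes is usually guided by *a priori*
categories — hydrogen bonds, π-stacking, hydrophobic contacts. `ligpatmine`
takes the complementary, purely statistical route: it decomposes receptor
proteins into **directed three-atom fragments** (e.g. alanine yields
N-CA-CB, C-CA-CB, C-CA-N, O-C-CA and their reverses), collects every ligand
atom lying within the contact criterion of a fragment's first ("anchor")
atom — distance strictly below the sum of van der Waals radii plus a 1.0 Å
offset — and expresses each contact in the fragment's local coordinate
frame. Pooled over many structures, the contacts of one
(fragment type, ligand atom type) combination form a 3D point cloud; a
Gaussian mixture model

&nbsp;&nbsp;&nbsp;&nbsp; p(x) = Σₖ wₖ · N(x; μₖ, Σₖ)

is fitted to each cloud by EM with BIC model selection. Every fitted
component is one interaction pattern. A new complex is annotated by
assigning each of its contacts to all patterns within a Mahalanobis
distance √((x−μ)ᵀΣ⁻¹(x−μ)) ≤ 2.5, and reporting for each assignment the
pattern's occurrence count ("Freq."), its spread over protein families
("Family" — single-linkage clusters at ≥25% sequence identity with ≥50%
coverage), and the mixture density at the contact ("Prob.").

Ligand atoms are typed into SYBYL/Tripos classes (C.3, C.ar, N.am,
O.co2, ...) either from a MOL2 file or by geometric perception; binding
sites enter the mining dataset only if they pass the published curation
filters (X-ray, resolution ≤ 2.5 Å, receptor ≥ 30 residues, ligand
80–800 Da with > 5 heavy atoms and relative accessible surface area < 0.6).

Audience: structural bioinformaticians and medicinal chemists who want an
objective, statistics-first view of which atomic contacts in a complex are
over-represented across known structures.

## Worked example

Generate synthetic complexes with ligand atoms planted from a known
Gaussian pattern, mine a library, and annotate one of them:

```bash
ligpatmine fixtures --kind end2end --seed 7 --n-complexes 6 --out fxdir
ligpatmine mine --pdb-dir fxdir --out lib.json --k-max 2 --restarts 2 --seed 7 --skip-curation
ligpatmine annotate --pdb fxdir/pl00.pdb --ligand LIG --library lib.json --out table.tsv
```

which prints

```
wrote 6 planted complexes + truth.json -> fxdir
mined 8 patterns over 8 combinations from 6 binding sites -> lib.json
64 contacts, 64 with assigned patterns -> table.tsv
```

Eight patterns appear because the single planted cloud is seen once from
each of the eight alanine fragment frames. The interaction table starts:

```
interaction_id  chain  residue_number  residue_name  fragment     ligand_atom  ligand_type  distance_A  pattern_ids  mahalanobis  freq  family  prob
1               A      1               ALA           ALA:CB-CA-C  C1           C.3          0.86        4            1.0212       44    1       2.5611
```

Reading the row: ligand atom C1 contacts the CB-anchored fragment CB-CA-C
of Ala1 at 0.86 Å (planted synthetic positions may sit deep inside the vdW
shell; real-structure distances cluster near the radius sum). The contact
falls within pattern 4 at Mahalanobis 1.02; that pattern collected 44
contacts from 1 protein family during mining, and the mixture density at
this position is 2.56 Å⁻³.

The same pipeline is available as a library:

```python
import ligpatmine as lp
st = lp.read_pdb("complex.pdb")
library = lp.load_library("lib.json")
records = lp.annotate_complex(st, "MTX", library)
```

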