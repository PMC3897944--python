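"""Interaction tables, recognition statistics and pattern summaries."""

import numpy as np
import pytest

import ligpatmine as lp
from ligpatmine import fixtures as fx
from ligpatmine.annotation_report import write_annotation_tsv


def coincidence_library(local_mean=(2.0, 1.5, 1.0)):
    """Library with one pattern for (ALA:N-CA-CB, C.3) at a known position."""
    lib = lp.PatternLibrary()
    comp = lp.GaussianComponent(pattern_id=1, weight=1.0,
                                mean=np.asarray(local_mean, float),
                                covariance=0.0625 * np.eye(3),
                                support_count=42, family_count=7)
    lib.models[("ALA:N-CA-CB", "C.3")] = lp.MixtureModel(
        ("ALA:N-CA-CB", "C.3"), [comp], n_points=100)
    return lib


def complex_with_atom_at_local(local_point):
    """Toy complex whose single ligand atom sits at the given local position
    in the ALA N-CA-CB frame."""
    residue = fx.ideal_residue("ALA")
    graph = lp.build_covalent_graph([residue])
    frag = next(f for f in lp.enumerate_fragments(graph)
                if f.type_label == "ALA:N-CA-CB")
    frame = lp.local_frame(frag)
    pos = lp.to_global(frame, np.asarray(local_point, float))
    st, _ = fx.make_toy_complex(residues=[residue], ligand_positions=[pos],
                                ligand_sybyl_type="C.3")
    return st


class TestAnnotateComplex:
    def test_atom_at_component_mean_gets_distance_zero(self):
        lib = coincidence_library()
        st = complex_with_atom_at_local([2.0, 1.5, 1.0])
        records = lp.annotate_complex(st, "LIG", lib, ligand=st.ligands[0])
        hits = [r for r in records if r.fragment_label == "ALA:N-CA-CB"]
        assert len(hits) == 1
        assert hits[0].assignments[0].pattern_id == 1
        assert hits[0].assignments[0].mahalanobis == pytest.approx(0.0, abs=1e-9)
        assert hits[0].frequency == 42
        assert hits[0].family_count == 7
        assert hits[0].density == pytest.approx(
            (2 * np.pi) ** -1.5 / 0.0625 ** 1.5, rel=1e-9)

    def test_empty_library_records_without_assignments(self):
        st = complex_with_atom_at_local([2.0, 1.5, 1.0])
        records = lp.annotate_complex(st, "LIG", lp.PatternLibrary(),
                                      ligand=st.ligands[0])
        assert records
        assert all(not r.recognized for r in records)
        assert all(r.frequency is None and r.density is None for r in records)

    def test_records_sorted_and_numbered(self, planted, mined):
        st = planted.complexes[0]
        records = lp.annotate_complex(st, "LIG", mined.library,
                                      ligand=st.ligands[0])
        assert [r.interaction_id for r in records] == \
            list(range(1, len(records) + 1))
        keys = [(r.ligand_atom_index, r.distance) for r in records]
        assert keys == sorted(keys)

    def test_tightening_threshold_never_adds_assignments(self, planted, mined):
        st = planted.complexes[1]
        loose = lp.annotate_complex(st, "LIG", mined.library, threshold=2.5,
                                    ligand=st.ligands[0])
        tight = lp.annotate_complex(st, "LIG", mined.library, threshold=2.0,
                                    ligand=st.ligands[0])
        n_loose = sum(len(r.assignments) for r in loose)
        n_tight = sum(len(r.assignments) for r in tight)
        assert n_tight <= n_loose
        rec_loose = {r.ligand_atom_index for r in loose if r.recognized}
        rec_tight = {r.ligand_atom_index for r in tight if r.recognized}
        assert rec_tight <= rec_loose


class TestRecognitionStats:
    def rec(self, atom_idx, recognized):
        return lp.AnnotationRecord(
            interaction_id=1, residue=("A", 1, "ALA"),
            fragment_label="ALA:N-CA-CB", ligand_atom_index=atom_idx,
            ligand_atom_name=f"C{atom_idx}", ligand_atom_type="C.3",
            distance=3.0,
            assignments=[lp.PatternAssignment(1, 1.0, 0.1)] if recognized else [])

    def test_half_recognized_is_not_majority(self):
        records = [self.rec(0, True), self.rec(1, True),
                   self.rec(2, False), self.rec(3, False)]
        stats = lp.recognition_stats([(4, records)])
        assert stats.atom_recognized_fraction == 0.5
        assert stats.complexes_majority_recognized_fraction == 0.0

    def test_all_recognized(self):
        records = [self.rec(i, True) for i in range(3)]
        stats = lp.recognition_stats([(3, records)])
        assert stats.atom_recognized_fraction == 1.0
        assert stats.complexes_majority_recognized_fraction == 1.0

    def test_no_annotations(self):
        stats = lp.recognition_stats([])
        assert stats.atom_recognized_fraction == 0.0
        assert stats.complexes_majority_recognized_fraction == 0.0

    def test_atom_with_several_contacts_counted_once(self):
        records = [self.rec(0, True), self.rec(0, True), self.rec(1, False)]
        stats = lp.recognition_stats([(2, records)])
        assert stats.atom_recognized_fraction == 0.5


class TestPatternSummary:
    def test_support_conservation(self, mined):
        table = lp.pattern_summary(mined)
        assert table["support"].sum() == len(mined.assignments)

    def test_support_counts_match_components(self, mined):
        table = lp.pattern_summary(mined).set_index("pattern_id")
        for _model, comp in mined.library.components():
            assert table.loc[comp.pattern_id, "support"] == comp.support_count

    def test_ligand_lists_deduplicated(self, mined):
        table = lp.pattern_summary(mined)
        for entry in table["ligands"]:
            codes = entry.split(",") if entry else []
            assert len(codes) == len(set(codes))

    def test_family_counts_within_bounds(self, mined):
        n_fam = mined.families.n_families()
        for _model, comp in mined.library.components():
            assert 0 <= comp.family_count <= max(n_fam, 1)


class TestMining:
    def test_planted_combination_recovered(self, planted, mined):
        model = mined.library.lookup(*fx.DEFAULT_PLANT_COMBINATION)
        assert model is not None
        assert model.k == 1
        (_w, true_mean, _cov) = planted.truth[fx.DEFAULT_PLANT_COMBINATION].components[0]
        err = np.linalg.norm(model.components[0].mean - true_mean)
        assert err < 0.2

    def test_pattern_ids_unique_and_sequential(self, mined):
        ids = [c.pattern_id for _m, c in mined.library.components()]
        assert sorted(ids) == list(range(1, len(ids) + 1))

    def test_mining_deterministic(self, planted):
        cfg = lp.EngineConfig(k_max=2, restarts=2, seed=21)
        sites = [(st, st.ligands[0]) for st in planted.complexes[:5]]
        a = lp.mine_patterns(sites, cfg)
        b = lp.mine_patterns(sites, cfg)
        assert set(a.library.models) == set(b.library.models)
        for key in a.library.models:
            for ca, cb in zip(a.library.models[key].components,
                              b.library.models[key].components):
                np.testing.assert_array_equal(ca.mean, cb.mean)
                assert ca.support_count == cb.support_count


class TestTsvOutput:
    def test_byte_identical_reruns(self, planted, mined, tmp_path):
        st = planted.complexes[2]
        records = lp.annotate_complex(st, "LIG", mined.library,
                                      ligand=st.ligands[0])
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_annotation_tsv(records, p1, mined.library)
        write_annotation_tsv(records, p2, mined.library)
        assert p1.read_bytes() == p2.read_bytes()

    def test_header_carries_conditions(self, mined, tmp_path):
        path = tmp_path / "t.tsv"
        write_annotation_tsv([], path, mined.library)
        head = path.read_text()
        assert "mahalanobis_threshold=2.5" in head
        assert "offset_A=1.0" in head
        assert "radius_table_hash=" in head
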