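"""Contact criterion, local frames and rigid-motion invariance."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import ligpatmine as lp
from ligpatmine import fixtures as fx
from conftest import random_fragment


def fragment_at(points, label="ALA:N-CA-CB", names=("N", "CA", "CB")):
    atoms = tuple(
        lp.AtomRecord(i + 1, n, n[0], "ALA", ("A", 1, ""), np.asarray(p, float))
        for i, (n, p) in enumerate(zip(names, points))
    )
    return lp.Fragment(atoms=atoms, type_label=label)


def ligand_at(positions, element="N"):
    atoms = [lp.AtomRecord(i + 1, f"{element}{i + 1}", element, "LIG",
                           ("L", 1, ""), np.asarray(p, float), is_hetero=True)
             for i, p in enumerate(positions)]
    return lp.LigandInstance("LIG", atoms)


class TestContactCriterion:
    """Bondi radii: C 1.70 + N 1.55 + offset 1.0 -> threshold 4.25 Å, strict."""

    def frag_C_anchor(self):
        # anchor is a carbon; other atoms far from the ligand
        return fragment_at([[0, 0, 0], [1.5, 0, 0], [1.5, 1.5, 0]],
                           label="ALA:C-CA-CB", names=("C", "CA", "CB"))

    @pytest.mark.parametrize("distance,expected", [
        (4.0, 1), (4.2499, 1), (4.25, 0), (4.30, 0), (0.0, 1),
    ])
    def test_threshold_strict_less_than(self, radii, distance, expected):
        frag = self.frag_C_anchor()
        lig = ligand_at([[-distance, 0.0, 0.0]])  # away from CA/CB
        contacts = lp.detect_contacts([frag], lig, radii, offset=1.0,
                                      ligand_types=["N.ar"])
        assert len(contacts) == expected
        if contacts:
            assert contacts[0].global_distance == pytest.approx(distance)

    def test_empty_inputs(self, radii):
        assert lp.detect_contacts([], ligand_at([[0, 0, 0]]), radii) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_all_pairs_oracle(self, radii, seed):
        rng = np.random.default_rng(seed)
        frags = [random_fragment(rng) for _ in range(8)]
        lig = ligand_at(rng.uniform(-10, 10, size=(12, 3)), element="C")
        got = {(id(c.fragment), c.ligand_atom.name)
               for c in lp.detect_contacts(frags, lig, radii, 1.0,
                                           ligand_types=["C.3"] * 12)}
        expected = set()
        for f in frags:
            for a in lig.atoms:
                d = np.linalg.norm(f.anchor.coordinates - a.coordinates)
                if d < radii.radius(f.anchor.element) + radii.radius(a.element) + 1.0:
                    expected.add((id(f), a.name))
        assert got == expected


class TestLocalFrame:
    def test_axis_aligned_construction(self):
        frame = lp.local_frame(fragment_at([[0, 0, 0], [1, 0, 0], [1, 1, 0]]))
        np.testing.assert_allclose(frame.origin, [0, 0, 0])
        np.testing.assert_allclose(frame.rotation, np.eye(3), atol=1e-12)

    def test_rotation_is_right_handed_orthonormal(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            frame = lp.local_frame(random_fragment(rng))
            np.testing.assert_allclose(frame.rotation @ frame.rotation.T,
                                       np.eye(3), atol=1e-12)
            assert np.linalg.det(frame.rotation) == pytest.approx(1.0)

    def test_third_atom_in_positive_y_half_plane(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            frag = random_fragment(rng)
            frame = lp.local_frame(frag)
            local3 = lp.to_local(frame, frag.atoms[2].coordinates)
            assert local3[1] > 0
            assert abs(local3[2]) < 1e-12

    def test_collinear_raises(self):
        with pytest.raises(lp.DegenerateFrameError):
            lp.local_frame(fragment_at([[0, 0, 0], [1, 0, 0], [2, 0, 0]]))


class TestToLocal:
    def test_origin_maps_to_zero(self):
        rng = np.random.default_rng(5)
        frame = lp.local_frame(random_fragment(rng))
        np.testing.assert_allclose(lp.to_local(frame, frame.origin),
                                   np.zeros(3), atol=1e-12)

    def test_identity_frame_is_identity(self):
        frame = lp.local_frame(fragment_at([[0, 0, 0], [1, 0, 0], [1, 1, 0]]))
        np.testing.assert_allclose(lp.to_local(frame, [1, 2, 3]), [1, 2, 3])

    def test_isometry(self):
        rng = np.random.default_rng(6)
        frame = lp.local_frame(random_fragment(rng))
        for _ in range(50):
            p, q = rng.uniform(-20, 20, size=(2, 3))
            assert np.linalg.norm(lp.to_local(frame, p) - lp.to_local(frame, q)) \
                == pytest.approx(np.linalg.norm(p - q))

    def test_round_trip_with_to_global(self):
        rng = np.random.default_rng(7)
        frame = lp.local_frame(random_fragment(rng))
        p = rng.uniform(-20, 20, 3)
        np.testing.assert_allclose(lp.to_global(frame, lp.to_local(frame, p)),
                                   p, atol=1e-9)


class TestInvariance:
    def test_local_positions_invariant_under_rigid_motion(self, radii):
        st, _ = fx.make_toy_complex(
            ligand_positions=[[2.5, 1.0, 1.0], [3.0, -0.5, 0.8]])
        lig = st.ligands[0]
        frags = lp.enumerate_fragments(lp.build_covalent_graph(st))
        base = lp.detect_contacts(frags, lig, radii, 1.0,
                                  ligand_types=["C.3"] * 2)
        base_locals = sorted(map(tuple, (c.local_position for c in base)))
        rng = np.random.default_rng(8)
        for _ in range(50):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.uniform(-50, 50, 3)
            moved_res = [
                lp.Residue(r.name, r.chain_id, r.number, r.insertion_code, [
                    lp.AtomRecord(a.serial, a.name, a.element, a.residue_name,
                                  a.residue_id, R @ a.coordinates + t)
                    for a in r.atoms])
                for r in st.receptor
            ]
            moved_lig = lp.LigandInstance("LIG", [
                lp.AtomRecord(a.serial, a.name, a.element, a.residue_name,
                              a.residue_id, R @ a.coordinates + t,
                              is_hetero=True)
                for a in lig.atoms])
            mf = lp.enumerate_fragments(lp.build_covalent_graph(moved_res))
            moved = lp.detect_contacts(mf, moved_lig, radii, 1.0,
                                       ligand_types=["C.3"] * 2)
            got = sorted(map(tuple, (c.local_position for c in moved)))
            np.testing.assert_allclose(got, base_locals, atol=1e-9)

    def test_anchor_distance_equals_local_norm(self, radii):
        rng = np.random.default_rng(9)
        frags = [random_fragment(rng) for _ in range(5)]
        lig = ligand_at(rng.uniform(-6, 6, size=(10, 3)), element="C")
        for c in lp.detect_contacts(frags, lig, radii, 1.0,
                                    ligand_types=["C.3"] * 10):
            assert np.linalg.norm(c.local_position) == \
                pytest.approx(c.global_distance, abs=1e-9)


class TestIsometryProperty:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    coord = st.lists(st.floats(-50, 50, allow_nan=False, allow_infinity=False),
                     min_size=3, max_size=3)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(p=coord, q=coord)
    def test_to_local_preserves_distances(self, p, q):
        frame = lp.local_frame(fragment_at([[0.3, -1.2, 0.7],
                                            [1.6, 0.1, -0.4],
                                            [0.9, 1.8, 1.1]]))
        d_global = np.linalg.norm(np.subtract(p, q))
        d_local = np.linalg.norm(lp.to_local(frame, p) - lp.to_local(frame, q))
        assert d_local == pytest.approx(d_global, abs=1e-9, rel=1e-12)
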