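"""Geometric measurements: distances, angles, coordination shells,
hydrogen bonds, and their rigid-motion invariance."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import ircmech as m
from ircmech.errors import IrcmechError

# Mg-O distances of the base-assisted product state: the O2G contact at
# 3.18 A has left the first shell, the other five are conserved.
PRODUCT_MG_O = [3.18, 1.97, 2.03, 2.17, 2.17, 1.98]


def _frame(coords):
    return m.Frame(frame_index=0, coords=np.asarray(coords, float))


class TestDistanceAngle:
    def test_axis_distance(self):
        f = _frame([[0, 0, 0], [0, 0, 2.10]])
        assert m.distance(f, 1, 2) == pytest.approx(2.10)
        assert m.distance(f, 2, 1) == pytest.approx(2.10)

    def test_self_distance_is_zero(self):
        f = _frame([[1, 2, 3], [0, 0, 0]])
        assert m.distance(f, 1, 1) == 0.0

    def test_out_of_range_index(self):
        f = _frame([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(IndexError):
            m.distance(f, 1, 3)

    def test_collinear_angle(self):
        f = _frame([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        assert m.angle(f, 1, 2, 3) == pytest.approx(180.0)

    def test_right_angle_and_symmetry(self, triangle_frame):
        assert m.angle(triangle_frame, 2, 1, 3) == pytest.approx(90.0)
        assert m.angle(triangle_frame, 3, 1, 2) == pytest.approx(
            m.angle(triangle_frame, 2, 1, 3))

    def test_coincident_apex_is_undefined(self):
        f = _frame([[0, 0, 0], [0, 0, 0], [1, 0, 0]])
        with pytest.raises(IrcmechError, match="coincident"):
            m.angle(f, 1, 2, 3)

    def test_loose_ts_key_distances(self):
        # reactive triad laid out with the substrate-assisted TS values:
        # leaving O 3.04 A and entering O 2.10 A from the phosphorus
        f = _frame([[0, 0, 0], [0, 0, 3.04], [0, 0, 3.04 + 2.10]])
        assert m.distance(f, 1, 2) == pytest.approx(3.04)
        assert m.distance(f, 2, 3) == pytest.approx(2.10)
        assert m.angle(f, 1, 2, 3) == pytest.approx(180.0)  # in-line attack


class TestCoordination:
    def test_product_state_loses_one_ligand(self):
        assert m.coordination_number(PRODUCT_MG_O, cutoff=2.6) == 5

    def test_all_close_gives_six(self):
        assert m.coordination_number([2.0] * 6, cutoff=2.6) == 6

    def test_tiny_cutoff_gives_zero(self):
        assert m.coordination_number(PRODUCT_MG_O, cutoff=0.1) == 0

    @given(st.floats(0.5, 5.0), st.floats(0.0, 2.0))
    def test_monotone_in_cutoff(self, cutoff, bump):
        n1 = m.coordination_number(PRODUCT_MG_O, cutoff)
        n2 = m.coordination_number(PRODUCT_MG_O, cutoff + bump)
        assert n2 >= n1

    def test_profile_reports_distances_beyond_cutoff(self):
        # metal at origin, two ligands: one inside, one outside the shell
        coords = [[0, 0, 0], [2.0, 0, 0], [0, 3.18, 0]]
        atoms = [m.AtomRecord(1, "Mg"), m.AtomRecord(2, "O"),
                 m.AtomRecord(3, "O")]
        frames = [m.Frame(k, np.asarray(coords, float)) for k in range(2)]
        path = m.ReactionPath(atoms=atoms, frames=frames)
        spec = m.CoordinationSpec(metal=1, ligands=(2, 3))
        prof = m.coordination_profile(path, spec)
        assert list(prof["coordination_number"]) == [1, 1]
        assert prof.loc[0, "d_3"] == pytest.approx(3.18)


class TestHbonds:
    def test_ideal_linear_contact(self):
        f = _frame([[0, 0, 0], [1.0, 0, 0], [2.8, 0, 0]])
        contacts, warns = m.hbond_detect(f, donors=[(1, 2)], acceptors=[3])
        assert warns == []
        (d, h, a, d_da, ang), = contacts
        assert (d, h, a) == (1, 2, 3)
        assert d_da == pytest.approx(2.8)
        assert ang == pytest.approx(180.0)

    def test_long_contact_excluded(self):
        f = _frame([[0, 0, 0], [1.0, 0, 0], [4.0, 0, 0]])
        contacts, _ = m.hbond_detect(f, donors=[(1, 2)], acceptors=[3])
        assert contacts == []

    def test_bent_contact_threshold_semantics(self):
        # place A so the D-H...A angle is exactly 100 degrees at d_DA < 3.5
        ang = np.radians(100)
        h = np.array([1.0, 0, 0])
        a = h + 2.0 * np.array([-np.cos(ang), np.sin(ang), 0.0])
        f = _frame([[0, 0, 0], h, a])
        strict, _ = m.hbond_detect(f, donors=[(1, 2)], acceptors=[3])
        assert strict == []
        loose, _ = m.hbond_detect(f, donors=[(1, 2)], acceptors=[3],
                                  criteria=m.HBondCriteria(angle_min=90))
        assert len(loose) == 1
        assert loose[0][4] == pytest.approx(100.0, abs=1e-6)

    def test_unbonded_donor_pair_skipped_with_warning(self):
        f = _frame([[0, 0, 0], [2.0, 0, 0], [2.8, 0, 0]])
        contacts, warns = m.hbond_detect(f, donors=[(1, 2)], acceptors=[3])
        assert contacts == []
        assert len(warns) == 1 and "skipped" in warns[0]


class TestRigidMotionInvariance:
    @given(st.integers(0, 2**31 - 1))
    def test_distance_angle_hbond_invariant(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(0, 3, (4, 3))
        coords[1] = coords[0] + [1.0, 0, 0]       # bonded D-H
        f1 = _frame(coords)
        rot = Rotation.random(rng=np.random.default_rng(seed + 1))
        moved = rot.apply(coords) + rng.normal(0, 10, 3)
        f2 = _frame(moved)
        assert m.distance(f2, 1, 3) == pytest.approx(m.distance(f1, 1, 3))
        assert m.angle(f2, 1, 2, 3) == pytest.approx(
            m.angle(f1, 1, 2, 3), abs=1e-8)
        c1, _ = m.hbond_detect(f1, donors=[(1, 2)], acceptors=[3, 4])
        c2, _ = m.hbond_detect(f2, donors=[(1, 2)], acceptors=[3, 4])
        assert [(c[0], c[1], c[2]) for c in c1] == \
            [(c[0], c[1], c[2]) for c in c2]

    def test_hbond_invariant_under_consistent_reindexing(self):
        coords = np.array([[0, 0, 0], [1.0, 0, 0], [2.8, 0, 0],
                           [9.0, 9, 9]])
        f = _frame(coords)
        perm = [3, 0, 1, 2]  # new position of old atoms
        f_perm = _frame(coords[perm])
        inv = {old + 1: new + 1 for new, old in enumerate(perm)}
        c1, _ = m.hbond_detect(f, donors=[(1, 2)], acceptors=[3])
        c2, _ = m.hbond_detect(f_perm, donors=[(inv[1], inv[2])],
                               acceptors=[inv[3]])
        assert len(c1) == len(c2) == 1
        assert c2[0][3] == pytest.approx(c1[0][3])


class TestKeyDistanceTable:
    def test_matches_direct_calls_on_synthetic_path(self, base_bundle):
        path, _, _, truth = base_bundle
        specs = [m.DistanceSpec("O3B-PG", 2, 1),
                 m.DistanceSpec("PG-OG", 1, 3)]
        at = {s["kind"] + str(k): s["frame"]
              for k, s in enumerate(truth.stationary)}
        table = m.key_distance_table(path, specs, at)
        for name, f in at.items():
            assert table.loc["O3B-PG", name] == pytest.approx(
                round(m.distance(path.frames[f], 2, 1), 2))

    def test_single_spec_single_frame(self, base_bundle):
        path = base_bundle[0]
        table = m.key_distance_table(
            path, [m.DistanceSpec("x", 1, 2)], {"Reac": 0})
        assert table.shape == (1, 1)

    def test_empty_specs_yield_empty_table(self, base_bundle):
        path = base_bundle[0]
        table = m.key_distance_table(path, [], {"Reac": 0})
        assert table.empty
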