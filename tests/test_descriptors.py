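"""Descriptor geometry: moments, reference points, invariances."""

import numpy as np
import pytest

from usrml.descriptors import (
    AugmentedPointCloud,
    DescriptorScheme,
    augment_points,
    batch_descriptors,
    compute_descriptor,
    electroshape_reference_points,
    moment_triple,
    usr_reference_points,
)
from usrml.records import ConformerRecord
from usrml.synthetic_fixtures import mirror, random_point_cloud, rigid_transform

from conftest import naive_descriptor


def _conf(coords, charges=None, logp=None):
    return ConformerRecord("m", 0, np.asarray(coords, float), charges, logp)


class TestMomentTriple:
    @pytest.mark.parametrize(
        "distances, expected",
        [
            ([1.0, 1.0], (1.0, 0.0, 0.0)),
            ([0.0, 2.0], (1.0, 1.0, 0.0)),
            ([0.0, 0.0, 3.0], (1.0, np.sqrt(2.0), 2.0 ** (1.0 / 3.0))),
            ([5.0], (5.0, 0.0, 0.0)),
        ],
    )
    def test_known_values(self, distances, expected):
        assert moment_triple(distances) == pytest.approx(expected, abs=1e-12)

    def test_signed_cube_root_preserves_asymmetry_direction(self):
        left_skewed = moment_triple([0.0, 3.0, 3.0])
        right_skewed = moment_triple([0.0, 0.0, 3.0])
        assert left_skewed[2] < 0 < right_skewed[2]
        assert left_skewed[2] == pytest.approx(-right_skewed[2])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            moment_triple([])


class TestReferencePoints:
    def test_two_point_cloud(self):
        cloud = AugmentedPointCloud(np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        refs = usr_reference_points(cloud).points
        np.testing.assert_allclose(refs[0], [1, 0, 0])  # ctd
        np.testing.assert_allclose(refs[1], [0, 0, 0])  # cst: tie -> index 0
        np.testing.assert_allclose(refs[2], [0, 0, 0])  # fct: tie -> index 0
        np.testing.assert_allclose(refs[3], [2, 0, 0])  # ftf

    def test_right_triangle_cloud(self):
        cloud = AugmentedPointCloud(np.array([[0.0, 0, 0], [4.0, 0, 0], [0.0, 3, 0]]))
        refs = usr_reference_points(cloud).points
        np.testing.assert_allclose(refs[0], [4 / 3, 1, 0])
        np.testing.assert_allclose(refs[1], [0, 0, 0])  # cst
        np.testing.assert_allclose(refs[2], [4, 0, 0])  # fct
        np.testing.assert_allclose(refs[3], [0, 3, 0])  # ftf

    def test_single_atom_degenerates_to_itself(self):
        p = np.array([[1.5, -2.0, 0.7]])
        refs = usr_reference_points(AugmentedPointCloud(p)).points
        np.testing.assert_allclose(refs, np.repeat(p, 4, axis=0))

    def test_es_single_atom_degenerates_to_itself(self):
        p = np.array([[1.5, -2.0, 0.7, 3.0]])
        refs = electroshape_reference_points(AugmentedPointCloud(p)).points
        np.testing.assert_allclose(refs, np.repeat(p, 5, axis=0))

    def test_es_c2_c3_are_cloud_members(self, rng):
        pts = rng.normal(size=(10, 4))
        refs = electroshape_reference_points(AugmentedPointCloud(pts)).points
        for ref in refs[1:3]:
            assert any(np.allclose(ref, p) for p in pts)
        assert not any(np.allclose(refs[0], p) for p in pts)


class TestAugmentation:
    def test_usr_cloud_is_raw_coordinates(self, rng):
        conf = random_point_cloud(6, 11)
        cloud = augment_points(conf, DescriptorScheme(method="usr"))
        np.testing.assert_array_equal(cloud.points, conf.coords)

    def test_charge_dimension_is_scaled(self):
        conf = _conf([[0, 0, 0]], charges=np.array([0.2]))
        cloud = augment_points(conf, DescriptorScheme(method="es4d", charge_scale=25.0))
        assert cloud.points[0, 3] == pytest.approx(5.0)

    def test_zero_augmentation_reduces_to_spatial_distances(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0], [0.0, 4, 0]])
        conf = _conf(coords, charges=np.zeros(3), logp=np.zeros(3))
        d5 = compute_descriptor(conf, DescriptorScheme(method="es5d"))
        # c1..c3 coincide with the 3D constructions when dims 4,5 vanish
        cloud = augment_points(conf, DescriptorScheme(method="es5d"))
        refs = electroshape_reference_points(cloud).points
        assert np.allclose(refs[:3, 3:], 0.0)
        assert np.all(np.isfinite(d5.values))

    def test_missing_charges_fatal_for_es(self):
        conf = _conf([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError, match="charges"):
            augment_points(conf, DescriptorScheme(method="es4d"))

    def test_hydrogen_filtering(self):
        conf = ConformerRecord(
            "m", 0,
            coords=np.array([[0.0, 0, 0], [10.0, 0, 0], [1.0, 1, 1]]),
            is_hydrogen=np.array([False, True, False]),
        )
        with_h = compute_descriptor(conf, DescriptorScheme(include_hydrogens=True))
        without_h = compute_descriptor(conf, DescriptorScheme(include_hydrogens=False))
        assert not np.allclose(with_h.values, without_h.values)


class TestComputeDescriptor:
    def test_single_atom_all_zero(self):
        d = compute_descriptor(_conf([[3.0, 1.0, -2.0]]), DescriptorScheme())
        np.testing.assert_allclose(d.values, np.zeros(12))

    def test_two_atom_hand_computation(self):
        d = compute_descriptor(_conf([[0, 0, 0], [2.0, 0, 0]]), DescriptorScheme())
        np.testing.assert_allclose(d.values, [1, 0, 0, 1, 1, 0, 1, 1, 0, 1, 1, 0], atol=1e-12)

    @pytest.mark.parametrize("method", ["usr", "es4d", "es5d"])
    def test_matches_naive_oracle(self, method, rng):
        for _ in range(30):
            n = int(rng.integers(3, 31))
            conf = random_point_cloud(n, int(rng.integers(0, 2**31)))
            got = compute_descriptor(conf, DescriptorScheme(method=method)).values
            want = naive_descriptor(
                conf.coords, conf.charges, conf.logp_contribs, method=method
            )
            np.testing.assert_allclose(got, want, atol=1e-10)

    @pytest.mark.parametrize("method", ["usr", "es4d", "es5d"])
    def test_rigid_invariance(self, method, rng):
        conf = random_point_cloud(12, 77)
        base = compute_descriptor(conf, DescriptorScheme(method=method)).values
        for seed in range(5):
            moved = rigid_transform(conf, seed)
            got = compute_descriptor(moved, DescriptorScheme(method=method)).values
            np.testing.assert_allclose(got, base, atol=1e-9)

    def test_usr_mirror_degeneracy(self):
        conf = random_point_cloud(9, 5)
        a = compute_descriptor(conf, DescriptorScheme()).values
        b = compute_descriptor(mirror(conf), DescriptorScheme()).values
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_permutation_invariance(self, rng):
        conf = random_point_cloud(15, 9)
        perm = rng.permutation(conf.n_atoms)
        shuffled = ConformerRecord(
            "m", 0, conf.coords[perm], conf.charges[perm], conf.logp_contribs[perm]
        )
        for method in ("usr", "es5d"):
            a = compute_descriptor(conf, DescriptorScheme(method=method)).values
            b = compute_descriptor(shuffled, DescriptorScheme(method=method)).values
            np.testing.assert_allclose(a, b, atol=1e-10)

    def test_usr_scale_covariance(self):
        conf = random_point_cloud(10, 21)
        s = 2.75
        scaled = ConformerRecord("m", 0, s * conf.coords)
        a = compute_descriptor(ConformerRecord("m", 0, conf.coords), DescriptorScheme()).values
        b = compute_descriptor(scaled, DescriptorScheme()).values
        np.testing.assert_allclose(b, s * a, rtol=1e-9)


class TestBatch:
    def test_order_preserved(self):
        confs = [random_point_cloud(5, s) for s in range(3)]
        descs = batch_descriptors(confs, DescriptorScheme())
        assert [d.mol_id for d in descs] == [c.mol_id for c in confs]

    def test_failures_skipped_with_survivors(self):
        good = random_point_cloud(5, 1)
        bad = ConformerRecord("no-charges", 0, np.zeros((2, 3)))
        descs = batch_descriptors([good, bad, good], DescriptorScheme(method="es5d"))
        assert len(descs) == 2

    def test_all_failing_fatal(self):
        bad = ConformerRecord("no-charges", 0, np.zeros((2, 3)))
        with pytest.raises(ValueError):
            batch_descriptors([bad], DescriptorScheme(method="es4d"))

    def test_empty_input_empty_output(self):
        assert batch_descriptors([], DescriptorScheme()) == []
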