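import io

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sriselect import (
    CalphaCloud,
    CloudSpec,
    ResidueId,
    SRIVector,
    compute_sri,
    detect_surface_residues,
    generate_blob_cloud,
    octant_index,
    read_sri_csv,
    write_sri_csv,
)
from sriselect.errors import InsufficientPointsError, ParameterError
from sriselect.ics import build_frame, transform_to_ics
from sriselect.sri import _octant_indices

from conftest import random_rotation


def make_cloud(points) -> CalphaCloud:
    pts = np.asarray(points, dtype=float)
    return CalphaCloud(
        residues=[ResidueId("A", i + 1, "", "GLY") for i in range(len(pts))],
        positions=pts,
    )


class TestOctantIndex:
    @pytest.mark.parametrize(
        "point,expected",
        [
            ((1, 1, 1), 1),
            ((-1, 1, 1), 2),
            ((1, -1, 1), 3),
            ((-1, -1, 1), 4),
            ((1, 1, -1), 5),
            ((-1, 1, -1), 6),
            ((1, -1, -1), 7),
            ((-1, -1, -1), 8),
            ((0, 0, 0), 1),  # boundaries count as non-negative
            ((0, -2, 0), 3),
        ],
    )
    def test_convention(self, point, expected):
        assert octant_index(point) == expected

    @given(
        st.tuples(
            st.floats(-100, 100, allow_nan=False),
            st.floats(-100, 100, allow_nan=False),
            st.floats(-100, 100, allow_nan=False),
        )
    )
    def test_formula_and_vectorized_agree(self, point):
        x, y, z = point
        expected = 1 + (x < 0) + 2 * (y < 0) + 4 * (z < 0)
        assert octant_index(point) == expected
        assert _octant_indices(np.array([point]))[0] == expected


class TestSurfaceDetection:
    def _sphere_cloud(self, n=20, radius=10.0):
        # Fibonacci lattice: well-separated directions, one per angular bin
        i = np.arange(n)
        phi = np.arccos(1 - 2 * (i + 0.5) / n)
        theta = np.pi * (1 + 5**0.5) * i
        d = np.stack(
            [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], 1
        )
        return make_cloud(np.vstack([d * radius, [[0.0, 0.0, 0.0]]]))

    @pytest.mark.parametrize("method", ["angular_shell", "convex_hull"])
    def test_sphere_points_surface_centre_never(self, method):
        cloud = self._sphere_cloud()
        surface = detect_surface_residues(cloud, method=method)
        numbers = {r.residue_number for r in surface}
        assert 21 not in numbers  # the central point
        assert numbers == set(range(1, 21))

    def test_cube_corners_are_the_hull(self):
        corners = [
            (sx, sy, sz)
            for sx in (-1, 1)
            for sy in (-1, 1)
            for sz in (-1, 1)
        ]
        cloud = make_cloud(corners + [(0, 0, 0)])
        surface = detect_surface_residues(cloud, method="convex_hull")
        assert {r.residue_number for r in surface} == set(range(1, 9))

    def test_angular_shell_matches_exhaustive_bin_scan(self, rng):
        pts = rng.normal(size=(200, 3)) * 8
        cloud = make_cloud(pts)
        n_theta, n_phi = 18, 9
        surface = detect_surface_residues(cloud, n_theta=n_theta, n_phi=n_phi)
        # oracle: per-bin argmax by explicit iteration over all points
        bins: dict[tuple, tuple] = {}
        for i, p in enumerate(pts):
            r = np.linalg.norm(p)
            if r <= 1e-12:
                continue
            theta = np.arctan2(p[1], p[0])
            phi = np.arccos(np.clip(p[2] / r, -1, 1))
            tb = min(int((theta + np.pi) / (2 * np.pi) * n_theta), n_theta - 1)
            pb = min(int(phi / np.pi * n_phi), n_phi - 1)
            if (tb, pb) not in bins or r > bins[(tb, pb)][0]:
                bins[(tb, pb)] = (r, i)
        expected = {cloud.residues[i] for _, i in bins.values()}
        assert surface == expected

    def test_too_few_points_raises(self):
        with pytest.raises(InsufficientPointsError):
            detect_surface_residues(make_cloud([(1, 0, 0), (0, 1, 0), (0, 0, 1)]))

    def test_unknown_method_raises(self):
        with pytest.raises(ParameterError):
            detect_surface_residues(self._sphere_cloud(), method="voronoi")


class TestComputeSri:
    def test_matches_two_pass_sd_oracle(self, blob_cloud):
        cloud, _ = blob_cloud
        result = compute_sri(cloud)
        frame = build_frame(cloud)
        ics = transform_to_ics(cloud, frame)
        frame_atoms = {frame.zmax_residue, frame.xref_residue}
        det = CalphaCloud(
            residues=[r for r in ics.residues if r not in frame_atoms],
            positions=ics.positions[[r not in frame_atoms for r in ics.residues]],
        )
        surface = detect_surface_residues(det)
        per_octant: dict[int, list[float]] = {k: [] for k in range(1, 9)}
        for rid, p in zip(ics.residues, ics.positions):
            if rid in surface:
                per_octant[octant_index(p)].append(float(np.linalg.norm(p)))
        for k in range(1, 9):
            xs = per_octant[k]
            if len(xs) <= 1:
                expected = 0.0
            else:
                mean = sum(xs) / len(xs)
                expected = (sum((x - mean) ** 2 for x in xs) / len(xs)) ** 0.5
            assert result.values[k - 1] == pytest.approx(expected, abs=1e-9)
            assert result.octant_counts[k - 1] == len(xs)

    def test_zero_dispersion_cloud_has_near_zero_sri(self):
        spec = CloudSpec(
            points_per_octant=200,
            radial_mean=20.0,
            radial_sd_per_octant=np.zeros(8),
            seed=3,
        )
        sri = compute_sri(generate_blob_cloud(spec))
        # residual dispersion only from centroid estimation noise
        assert sri.values.max() < 0.01 * 20.0

    def test_rigid_motion_invariance(self, blob_cloud):
        cloud, _ = blob_cloud
        base = compute_sri(cloud)
        for seed in range(5):
            R = random_rotation(seed)
            t = np.random.default_rng(seed).uniform(-40, 40, 3)
            moved = cloud.with_positions(cloud.positions @ R.T + t)
            assert np.abs(compute_sri(moved).values - base.values).max() < 1e-6

    def test_scale_equivariance(self, blob_cloud):
        cloud, _ = blob_cloud
        base = compute_sri(cloud)
        for s in (0.5, 2.0, 7.3):
            scaled = compute_sri(cloud.with_positions(cloud.positions * s))
            assert np.allclose(scaled.values, s * base.values, atol=1e-9)

    def test_parameter_recovery_from_generating_dispersions(self):
        v = np.array([1.0, 1.4, 0.8, 1.2, 1.0, 1.3, 0.9, 1.1])
        spec = CloudSpec(
            points_per_octant=200, radial_mean=20.0, radial_sd_per_octant=v, seed=7
        )
        sri = compute_sri(generate_blob_cloud(spec), n_theta=72, n_phi=36)
        assert (sri.octant_counts >= 50).all()
        assert np.abs(sri.values - v).mean() < 0.15 * v.mean()

    def test_singleton_octant_rule_in_vector_type(self):
        with pytest.raises(ParameterError):
            SRIVector(values=np.full(8, -1.0))


def test_sri_csv_round_trip(blob_cloud):
    cloud, _ = blob_cloud
    vec = compute_sri(cloud, role="calculated_reference")
    buf = io.StringIO()
    write_sri_csv([vec], buf)
    buf.seek(0)
    back = read_sri_csv(buf)
    assert len(back) == 1
    assert back[0].role == "calculated_reference"
    assert np.allclose(back[0].values, vec.values, atol=1e-5)
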