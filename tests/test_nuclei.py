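"""3D nucleus detection, section/region assignment and neighbour
statistics, checked against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.spatial import ConvexHull

from spheropk import nuclei as nuc
from spheropk.render import RenderParams, render
from spheropk.simulate import SpheroidState


def state_from_positions(pos, radius=3.5):
    pos = np.asarray(pos, dtype=float)
    n = pos.shape[0]
    return SpheroidState(
        positions=pos,
        base_radii=np.full(n, radius),
        radii=np.full(n, radius),
        ages=np.zeros(n),
        ids=np.arange(n),
        next_id=n,
    )


def nuclei_table(pos, in_section=None):
    pos = np.asarray(pos, dtype=float)
    df = pd.DataFrame(
        {
            "nucleus_id": np.arange(len(pos)),
            "x_um": pos[:, 0],
            "y_um": pos[:, 1],
            "z_um": pos[:, 2],
        }
    )
    if in_section is not None:
        df["in_section"] = in_section
    return df


def match_precision_recall(detected, truth, radius=3.5):
    """Bipartite matching between detections and ground truth."""
    if len(detected) == 0 or len(truth) == 0:
        return 0.0, 0.0
    d = np.linalg.norm(detected[:, None, :] - truth[None, :, :], axis=2)
    cost = np.where(d <= radius, d, 1e6)
    ri, ci = linear_sum_assignment(cost)
    tp = int((d[ri, ci] <= radius).sum())
    return tp / len(detected), tp / len(truth)


class TestSubtractBackground:
    def test_constant_image_maps_to_zero(self):
        stack = np.full((3, 64, 64), 117.0)
        out = nuc.subtract_background(stack, 50.0)
        assert np.allclose(out, 0.0, atol=1e-6)

    def test_offset_invariance(self):
        rng = np.random.default_rng(3)
        stack = rng.uniform(0, 50, (2, 64, 64))
        a = nuc.subtract_background(stack, 50.0)
        b = nuc.subtract_background(stack + 300.0, 50.0)
        assert np.allclose(a, b, atol=1e-6)

    def test_small_blob_survives_the_ball(self):
        yy, xx = np.mgrid[0:96, 0:96]
        blob = 500.0 * np.exp(-(((yy - 48) ** 2 + (xx - 48) ** 2) / (2 * 3.5**2)))
        stack = (blob + 80.0)[None]
        out = nuc.subtract_background(stack, 50.0)
        assert out.max() > 0.9 * 500.0

    def test_tiny_radius_rejected(self):
        with pytest.raises(ValueError):
            nuc.subtract_background(np.zeros((1, 8, 8)), 1.0)


class TestSpheroidRegion:
    def test_otsu_threshold_separates_bimodal_stack(self):
        rng = np.random.default_rng(0)
        stack = rng.normal(100.0, 10.0, (20, 40, 40))
        stack[5:15, 10:30, 10:30] = rng.normal(1000.0, 10.0, (10, 20, 20))
        from skimage.filters import threshold_otsu

        thr = threshold_otsu(stack)
        # strictly between the two modes (background ~N(100,10), object ~N(1000,10))
        assert 100.0 + 3 * 10.0 < thr < 1000.0 - 3 * 10.0
        mask, geom = nuc.spheroid_region(stack)
        assert mask[10, 20, 20] and not mask[0, 0, 0]

    def test_rendered_sphere_centroid_recovered(self, small_state, small_stack):
        corrected = nuc.subtract_background(small_stack.astype(float))
        _, geom = nuc.spheroid_region(corrected)
        # true centre: field centre (64, 64) in x/y
        assert abs(geom.axis_x - 64.0) < 3.0
        assert abs(geom.axis_y - 64.0) < 3.0

    def test_flat_stack_raises_no_object(self):
        with pytest.raises(nuc.NoObjectError):
            nuc.spheroid_region(np.full((4, 16, 16), 7.0))


class TestDetectNuclei:
    def test_empty_stack_gives_no_detections(self):
        det = nuc.detect_nuclei(np.zeros((10, 32, 32)))
        assert len(det) == 0

    def test_separated_nuclei_recovered_exactly(self):
        """50 nuclei spaced > 20 µm, noise off: every one found within
        2 µm of its true position."""
        rng = np.random.default_rng(12)
        grid = [
            (x, y, z)
            for x in (-44, -22, 0, 22, 44)
            for y in (-44, -22, 0, 22, 44)
            for z in (-22, 22)
        ]
        pos = np.array(grid, dtype=float) + rng.uniform(-1, 1, (50, 3))
        st = state_from_positions(pos)
        params = RenderParams(field_px=128, n_z=61)
        stack = render(st, params, rng=None).astype(float)
        det = nuc.detect_nuclei(stack - 100.0)
        assert len(det) == 50
        truth = pos + np.array([64.0, 64.0, 61.0])
        d = np.linalg.norm(
            det[["x_um", "y_um", "z_um"]].to_numpy()[:, None, :] - truth[None, :, :],
            axis=2,
        )
        assert np.all(d.min(axis=1) <= 2.0)

    def test_dense_spheroid_precision_recall(self, small_state, small_stack):
        corrected = nuc.subtract_background(small_stack.astype(float))
        det = nuc.detect_nuclei(corrected)
        truth = small_state.positions + np.array([64.0, 64.0, 51.0])
        prec, rec = match_precision_recall(
            det[["x_um", "y_um", "z_um"]].to_numpy(), truth
        )
        assert prec >= 0.9 and rec >= 0.9

    def test_too_small_diameter_rejected(self):
        with pytest.raises(ValueError):
            nuc.detect_nuclei(np.zeros((4, 16, 16)), expected_diameter=3.0)


class TestSelectSection:
    def test_slab_boundaries_inclusive(self):
        geom = nuc.SectionGeometry(0, 0, z_mid=40.0, z_bottom=80.0)
        assert geom.z_section == 60.0
        df = nuclei_table([[0, 0, 60.0], [0, 0, 75.0], [0, 0, 75.1], [0, 0, 44.9]])
        out = nuc.select_section(df, geom)
        assert out["in_section"].tolist() == [True, True, False, False]

    def test_uniform_ball_slab_fraction_matches_analytic(self):
        """In-section fraction of a uniform ball equals the spherical
        slab volume fraction within Monte-Carlo error."""
        rng = np.random.default_rng(77)
        R, n = 100.0, 200_000
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = v * (R * rng.random(n) ** (1 / 3))[:, None]
        geom = nuc.SectionGeometry(0, 0, z_mid=0.0, z_bottom=50.0)  # z_s = 25
        out = nuc.select_section(nuclei_table(pts), geom)
        frac = out["in_section"].mean()

        # analytic slab volume between z1 and z2 inside a ball of radius R
        def cap_int(z):  # ∫ π(R²−z²) dz
            return np.pi * (R**2 * z - z**3 / 3)

        z1, z2 = 10.0, 40.0
        expected = (cap_int(z2) - cap_int(z1)) / (4 / 3 * np.pi * R**3)
        assert frac == pytest.approx(expected, abs=3 * np.sqrt(expected / n) + 1e-3)


class TestAssignRegions:
    def test_axis_nucleus_is_center_and_hull_vertices_are_shell(self):
        rng = np.random.default_rng(5)
        r = 80.0 * np.sqrt(rng.random(100))
        th = rng.uniform(0, 2 * np.pi, 100)
        pos = np.column_stack([r * np.cos(th), r * np.sin(th), np.zeros(100)])
        pos[0] = (0.0, 0.0, 0.0)
        geom = nuc.SectionGeometry(0.0, 0.0, z_mid=-10.0, z_bottom=10.0)
        out = nuc.assign_regions(
            nuc.select_section(nuclei_table(pos), geom), geom, band=35.0
        )
        assert out.loc[0, "region"] in ("center", "both")
        hull = ConvexHull(pos[:, :2])
        for v in hull.vertices:
            assert out.loc[v, "region"] in ("shell", "both")

    def test_labels_match_exhaustive_hull_distance_oracle(self):
        """200 random section nuclei: labels equal a brute-force oracle
        computing the distance to every hull edge segment."""
        rng = np.random.default_rng(21)
        pos = np.column_stack(
            [rng.uniform(-120, 120, 200), rng.uniform(-120, 120, 200), np.zeros(200)]
        )
        geom = nuc.SectionGeometry(0.0, 0.0, z_mid=-10.0, z_bottom=10.0)
        out = nuc.assign_regions(
            nuc.select_section(nuclei_table(pos), geom), geom, band=35.0
        )
        xy = pos[:, :2]
        hull = ConvexHull(xy)
        verts = xy[hull.vertices]

        def seg_dist(p, a, b):
            ab, ap = b - a, p - a
            t = np.clip(np.dot(ap, ab) / np.dot(ab, ab), 0.0, 1.0)
            return np.linalg.norm(p - (a + t * ab))

        for i, p in enumerate(xy):
            d_hull = min(
                seg_dist(p, verts[k], verts[(k + 1) % len(verts)])
                for k in range(len(verts))
            )
            d_axis = np.hypot(*p)
            want_center = d_axis <= 35.0
            want_shell = d_hull <= 35.0
            expected = (
                "both"
                if want_center and want_shell
                else "center"
                if want_center
                else "shell"
                if want_shell
                else "neither"
            )
            assert out.loc[i, "region"] == expected

    def test_degenerate_geometry_rejected(self):
        pos = np.array([[0, 0, 0], [1, 1, 0], [2, 2, 0]], dtype=float)
        geom = nuc.SectionGeometry(0, 0, z_mid=-10.0, z_bottom=10.0)
        with pytest.raises(ValueError):
            nuc.assign_regions(nuc.select_section(nuclei_table(pos), geom), geom)


class TestNeighborCounts:
    def test_single_nucleus_has_no_neighbors(self):
        out = nuc.neighbor_counts(nuclei_table([[0, 0, 0]]))
        assert out["n_neighbors"].tolist() == [0]

    def test_inclusive_20um_boundary(self):
        near = nuc.neighbor_counts(nuclei_table([[0, 0, 0], [19.9, 0, 0]]))
        far = nuc.neighbor_counts(nuclei_table([[0, 0, 0], [20.1, 0, 0]]))
        exact = nuc.neighbor_counts(nuclei_table([[0, 0, 0], [20.0, 0, 0]]))
        assert near["n_neighbors"].tolist() == [1, 1]
        assert far["n_neighbors"].tolist() == [0, 0]
        assert exact["n_neighbors"].tolist() == [1, 1]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 2000))
        pos = rng.uniform(0, 150, (n, 3))
        out = nuc.neighbor_counts(nuclei_table(pos), radius=20.0)
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
        expected = ((d <= 20.0).sum(axis=1) - 1).astype(int)
        assert np.array_equal(out["n_neighbors"].to_numpy(), expected)

    def test_section_candidate_restriction(self):
        df = nuclei_table(
            [[0, 0, 0], [10, 0, 0], [0, 0, 100]], in_section=[True, False, True]
        )
        all_cand = nuc.neighbor_counts(df, 20.0, candidates="all")
        sec_cand = nuc.neighbor_counts(df, 20.0, candidates="section")
        assert all_cand["n_neighbors"].tolist() == [1, 1, 0]
        assert sec_cand["n_neighbors"].tolist() == [0, 1, 0]


class TestRegionDensitySeries:
    def _frame(self, center_counts, shell_counts):
        n_c, n_s = len(center_counts), len(shell_counts)
        return pd.DataFrame(
            {
                "nucleus_id": np.arange(n_c + n_s),
                "x_um": np.zeros(n_c + n_s),
                "y_um": np.zeros(n_c + n_s),
                "z_um": np.zeros(n_c + n_s),
                "in_section": True,
                "region": ["center"] * n_c + ["shell"] * n_s,
                "n_neighbors": list(center_counts) + list(shell_counts),
            }
        )

    def test_constant_configuration_gives_constant_series(self):
        frames = [self._frame([4, 6], [2, 2]) for _ in range(4)]
        times = np.array([0.0, 1.4, 2.8, 4.2])
        out = nuc.region_density_series(frames, times)
        center = out[out.region == "center"]["mean_neighbors"]
        assert np.allclose(center, 5.0)
        shell = out[out.region == "shell"]["mean_neighbors"]
        assert np.allclose(shell, 2.0)

    def test_radial_density_gradient_keeps_center_above_shell(self):
        """A packing that tightens toward the core must report a larger
        mean neighbour count in the center than in the shell at every
        frame."""
        rng = np.random.default_rng(8)
        frames, times = [], []
        for k in range(3):
            # radial positions biased to the core -> denser center
            n = 400
            r = 100.0 * rng.random(n) ** 1.5
            th = rng.uniform(0, 2 * np.pi, n)
            pos = np.column_stack(
                [r * np.cos(th), r * np.sin(th), rng.uniform(-10, 10, n)]
            )
            geom = nuc.SectionGeometry(0.0, 0.0, z_mid=-15.0, z_bottom=15.0)
            df = nuc.select_section(nuclei_table(pos), geom)
            df = nuc.assign_regions(df, geom, band=35.0)
            df = nuc.neighbor_counts(df, 20.0)
            frames.append(df)
            times.append(1.4 * k)
        out = nuc.region_density_series(frames, np.array(times))
        piv = out.pivot(index="time_h", columns="region", values="mean_neighbors")
        assert (piv["center"] > piv["shell"]).all()

    def test_empty_region_yields_missing_not_zero(self):
        frames = [self._frame([4], []), self._frame([4], [])]
        out = nuc.region_density_series(frames, np.array([0.0, 1.4]))
        shell = out[out.region == "shell"]["mean_neighbors"]
        assert shell.isna().all()

    def test_all_empty_rejected(self):
        df = self._frame([], [])
        with pytest.raises(ValueError):
            nuc.region_density_series([df, df], np.array([0.0, 1.4]))
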