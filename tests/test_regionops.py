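"""Tests for region selection, solidity, disconnection, filling, boundary."""

import numpy as np
import pytest
from scipy import ndimage

from stomapore import (
    DisconnectFailedError,
    EmptySegmentationError,
    InvalidArgumentError,
    TooSmallRegionError,
    disconnect_region,
    extract_boundary,
    fill_holes,
    select_central_region,
    solidity,
)
from stomapore.evaluation import random_polyomino
from stomapore.synthgen import _ellipse_quadform


def disk_mask(shape, center, r):
    rr, cc = np.meshgrid(
        np.arange(shape[0], dtype=float), np.arange(shape[1], dtype=float), indexing="ij"
    )
    return np.hypot(rr - center[0], cc - center[1]) <= r


def plus_shape():
    m = np.zeros((50, 50), bool)
    m[10:40, 20:30] = True
    m[20:30, 10:40] = True
    return m


def dumbbell():
    m = np.zeros((60, 80), bool)
    m[20:40, 10:30] = True
    m[20:40, 40:60] = True
    m[29:31, 30:40] = True
    return m


def hull_pixel_count_oracle(mask):
    """Independent convex-area oracle: shapely hull of half-pixel-extended
    pixel points, counting the grid centres inside or on the hull polygon.

    Holes are filled first to match the solidity contract (a pore region
    is conceptually solid).
    """
    import shapely
    from shapely.geometry import MultiPoint

    mask = ndimage.binary_fill_holes(np.asarray(mask, bool))
    rr, cc = np.nonzero(mask)
    x, y = cc.astype(float), rr.astype(float)
    pts = np.concatenate(
        [
            np.column_stack([x - 0.5, y]),
            np.column_stack([x + 0.5, y]),
            np.column_stack([x, y - 0.5]),
            np.column_stack([x, y + 0.5]),
        ]
    )
    hull = MultiPoint(pts).convex_hull.buffer(1e-9)
    gr, gc = np.meshgrid(
        np.arange(mask.shape[0]), np.arange(mask.shape[1]), indexing="ij"
    )
    return int(shapely.contains_xy(hull, gc.ravel(), gr.ravel()).sum())


class TestSelectCentralRegion:
    def test_component_containing_center_wins(self):
        m = disk_mask((64, 64), (32, 32), 6) | disk_mask((64, 64), (10, 10), 9)
        sel = select_central_region(m, (32, 32))
        assert sel[32, 32] and not sel[10, 10]

    def test_nearest_centroid_when_center_uncovered(self):
        m = disk_mask((64, 64), (32, 37), 4) | disk_mask((64, 64), (5, 5), 4)
        sel = select_central_region(m, (32, 32))
        assert sel[32, 37]

    def test_empty_mask_raises(self):
        with pytest.raises(EmptySegmentationError):
            select_central_region(np.zeros((32, 32), bool), (16, 16))

    def test_agrees_with_brute_force_scan(self, rng):
        """Nearest-centroid rule checked against an exhaustive scan over all
        components on 200 random multi-blob masks."""
        for _ in range(200):
            m = np.zeros((48, 48), bool)
            for _ in range(int(rng.integers(2, 8))):
                m |= disk_mask(
                    (48, 48), rng.uniform(5, 43, size=2), rng.uniform(2, 5)
                )
            center = (23.5, 23.5)
            sel = select_central_region(m, center)
            labels, n = ndimage.label(m, structure=np.ones((3, 3), int))
            if labels[24, 24] > 0:
                expected = labels == labels[24, 24]
            else:
                best, best_key = None, None
                for lab in range(1, n + 1):
                    comp = labels == lab
                    rr, cc = np.nonzero(comp)
                    d = np.hypot(rr.mean() - center[0], cc.mean() - center[1])
                    key = (d, -comp.sum(), lab)
                    if best_key is None or key < best_key:
                        best, best_key = comp, key
                expected = best
            assert np.array_equal(sel, expected)


class TestSolidity:
    def test_rectangle_is_its_own_hull(self):
        m = np.zeros((40, 40), bool)
        m[10:30, 12:22] = True
        rep = solidity(m)
        assert rep.solidity == pytest.approx(1.0)
        assert rep.independent and not rep.touches_border

    def test_plus_shape_is_non_independent(self):
        rep = solidity(plus_shape())
        # continuous hull gives 500/700 = 5/7; pixel-count hulls sit ~0.02 above
        assert rep.solidity == pytest.approx(5.0 / 7.0, abs=0.025)
        assert not rep.independent

    def test_digital_ellipse_is_independent(self):
        m = _ellipse_quadform((128, 128), (63.5, 63.5), 40, 20, 0.0) <= 1
        rep = solidity(m)
        oracle = m.sum() / hull_pixel_count_oracle(m)
        assert rep.solidity == pytest.approx(oracle, abs=0.02)
        assert rep.solidity >= 0.97 and rep.independent

    def test_matches_independent_hull_oracle_on_polyominoes(self, rng):
        for _ in range(100):
            m = random_polyomino(rng, int(rng.integers(80, 400)))
            rep = solidity(m)
            oracle = ndimage.binary_fill_holes(m).sum() / hull_pixel_count_oracle(m)
            assert abs(rep.solidity - oracle) <= 0.02

    def test_solidity_decreases_with_concavity(self):
        convex = np.zeros((40, 40), bool)
        convex[10:30, 10:30] = True
        notched = convex.copy()
        notched[18:22, 22:30] = False  # bite from the edge
        assert solidity(notched).solidity < solidity(convex).solidity

    def test_multicomponent_rejected(self):
        m = disk_mask((64, 64), (20, 20), 5) | disk_mask((64, 64), (45, 45), 5)
        with pytest.raises(InvalidArgumentError):
            solidity(m)

    def test_empty_rejected(self):
        with pytest.raises(EmptySegmentationError):
            solidity(np.zeros((20, 20), bool))


class TestDisconnectRegion:
    def test_dumbbell_bridge_removed(self):
        db = dumbbell()
        out, rep, rounds = disconnect_region(db, (30, 20), se_radius=2)
        assert rounds >= 1 and rep.independent and rep.solidity >= 0.95
        assert out[30, 20] and not out[30, 50]  # block B gone
        assert not (out & ~db).any()  # never adds outside footprint

    def test_independent_region_is_noop(self):
        m = disk_mask((64, 64), (32, 32), 12)
        out, rep, rounds = disconnect_region(m, (32, 32))
        assert rounds == 0 and np.array_equal(out, m)

    def test_erosion_annihilation_raises(self):
        # small non-independent plus whose 3-px arms vanish under a radius-3 disk
        m = np.zeros((20, 20), bool)
        m[5:14, 8:11] = True
        m[8:11, 5:14] = True
        assert not solidity(m).independent
        with pytest.raises(DisconnectFailedError):
            disconnect_region(m, (9.5, 9.5), se_radius=3)

    def test_centroid_stays_near_center(self):
        db = dumbbell()
        center = (30.0, 20.0)
        rep0 = solidity(select_central_region(db, center))
        out, rep, _ = disconnect_region(db, center, se_radius=2)
        d_in = np.hypot(rep0.centroid[0] - center[0], rep0.centroid[1] - center[1])
        d_out = np.hypot(rep.centroid[0] - center[0], rep.centroid[1] - center[1])
        assert d_out <= d_in + 2.0  # within se_radius of the input's distance


class TestFillHoles:
    def test_annulus_becomes_disk(self):
        m = disk_mask((64, 64), (32, 32), 20) & ~disk_mask((64, 64), (32, 32), 10)
        filled = fill_holes(m)
        assert np.array_equal(filled, disk_mask((64, 64), (32, 32), 20))

    def test_solid_disk_unchanged(self):
        m = disk_mask((64, 64), (32, 32), 15)
        assert np.array_equal(fill_holes(m), m)

    def test_idempotent_on_random_blobs(self, rng):
        for _ in range(20):
            m = np.zeros((48, 48), bool)
            for _ in range(int(rng.integers(1, 5))):
                m |= disk_mask((48, 48), rng.uniform(8, 40, size=2), rng.uniform(3, 8))
            once = fill_holes(m)
            assert np.array_equal(fill_holes(once), once)


class TestExtractBoundary:
    def test_square_shoelace_area(self):
        m = np.zeros((30, 30), bool)
        m[10:20, 10:20] = True
        pts = extract_boundary(m)
        x, y = pts[:, 1], pts[:, 0]
        area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
        assert area == pytest.approx(100.0, abs=1.0)

    def test_points_adjacent_to_interface(self):
        m = disk_mask((64, 64), (32, 32), 14)
        pts = extract_boundary(m)
        dist_in = ndimage.distance_transform_edt(m)
        dist_out = ndimage.distance_transform_edt(~m)
        for r, c in pts:
            ri, ci = int(round(r)), int(round(c))
            assert min(dist_in[ri, ci], dist_out[ri, ci]) <= 1.0

    def test_tiny_region_rejected(self):
        m = np.zeros((20, 20), bool)
        m[10, 10] = True
        with pytest.raises(TooSmallRegionError):
            extract_boundary(m)

    def test_start_point_and_orientation(self):
        m = disk_mask((64, 64), (32, 32), 10)
        pts = extract_boundary(m)
        # first point is topmost-then-leftmost
        top = pts[np.lexsort((pts[:, 1], pts[:, 0]))[0]]
        assert np.allclose(pts[0], top)
        # display-CCW: negative shoelace in (x=col, y=row)
        x, y = pts[:, 1], pts[:, 0]
        assert np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y) < 0

    def test_shoelace_tracks_pixel_area_on_blobs(self, rng):
        for _ in range(10):
            m = np.zeros((64, 64), bool)
            for _ in range(int(rng.integers(1, 4))):
                m |= disk_mask((64, 64), rng.uniform(20, 44, size=2), rng.uniform(6, 12))
            m = fill_holes(select_central_region(m, (31.5, 31.5)))
            if m.sum() < 100:
                continue
            pts = extract_boundary(m)
            x, y = pts[:, 1], pts[:, 0]
            area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
            assert area == pytest.approx(m.sum(), rel=0.05)
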