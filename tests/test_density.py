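"""Density accumulation, morphology and shading against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from lnatlas import (
    DensityMap,
    LNcRecord,
    ReferenceGrid,
    accumulate,
    alpha_map,
    build_station_layer,
    close_mask,
    high_risk_mask,
    rasterize_disc,
    roberts_edge,
    to_gray,
)
from lnatlas.density import disc_footprint


def rec(station, x, y, z, evidence="PRLN", pid="p"):
    return LNcRecord(pid, station, evidence, (float(x), float(y), float(z)))


def brute_roberts(img):
    """Oracle: double loop over the Roberts 2x2 formula with edge replication."""
    img = np.asarray(img, int)
    h, w = img.shape
    out = np.zeros((h, w), bool)
    for r in range(h):
        for c in range(w):
            r1, c1 = min(r + 1, h - 1), min(c + 1, w - 1)
            g = abs(img[r, c] - img[r1, c1]) + abs(img[r1, c] - img[r, c1])
            out[r, c] = g > 0
    return out


def brute_minkowski_close(mask, radius):
    """Oracle: set-arithmetic dilation then erosion with a disc element."""
    offs = [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]
    pts = {(r, c) for r, c in zip(*np.nonzero(mask))}
    dil = {(r + dr, c + dc) for r, c in pts for dr, dc in offs}
    ero = {p for p in dil if all((p[0] + dr, p[1] + dc) in dil for dr, dc in offs)}
    out = np.zeros_like(np.asarray(mask, bool))
    for r, c in ero:
        if 0 <= r < out.shape[0] and 0 <= c < out.shape[1]:
            out[r, c] = True
    return out


class TestAccumulate:
    def test_no_records_is_empty(self, grid):
        res = accumulate([], grid)
        assert res.maps == {} and res.skipped == []

    def test_identical_records_double_counts(self, grid):
        r = rec("3", 50.5, 60.5, 12.0)
        res = accumulate([r, r], grid)
        d = res.maps["3"]
        arr = d.slice_array(2)
        assert d.max_count == 2
        assert set(np.unique(arr)) == {0, 2}
        assert arr.sum() == 2 * 21

    def test_matches_per_disc_loop_oracle(self, small_grid, rng):
        """50 random records accumulate to the naive per-disc double loop."""
        records = [
            rec("7", rng.uniform(5, 35), rng.uniform(5, 35), rng.uniform(0, 29.9))
            for _ in range(50)
        ]
        res = accumulate(records, small_grid)
        oracle = {}
        for r in records:
            m = rasterize_disc(r.position, 5.0, small_grid)
            arr = oracle.setdefault(m.slice_index, np.zeros(small_grid.shape, int))
            for pr, pc in m.pixels:
                arr[pr, pc] += 1
        d = res.maps["7"]
        assert set(d.slices) == set(oracle)
        for k in oracle:
            assert np.array_equal(d.slices[k], oracle[k])

    def test_mass_conservation(self, small_grid, rng):
        """Total counts equal the sum of per-disc pixel areas."""
        records = [
            rec("9", rng.uniform(5, 35), rng.uniform(5, 35), rng.uniform(0, 29.9))
            for _ in range(30)
        ]
        res = accumulate(records, small_grid)
        per_disc = sum(
            len(rasterize_disc(r.position, 5.0, small_grid).pixels) for r in records
        )
        assert res.maps["9"].total_mass == per_disc

    def test_out_of_grid_record_skipped_and_reported(self, small_grid):
        inside = rec("3", 20.5, 20.5, 10.0)
        outside = rec("3", 500.0, 20.0, 10.0, pid="far")
        res = accumulate([inside, outside], small_grid)
        assert res.n_skipped == 1
        assert res.skipped[0].patient_id == "far"
        assert res.maps["3"].total_mass == 21


class TestCloseMask:
    def test_empty_and_full_fixed_points(self):
        empty = np.zeros((12, 12), bool)
        full = np.ones((12, 12), bool)
        assert not close_mask(empty, 2).any()
        assert close_mask(full, 2).all()

    def test_bridges_gap_and_matches_minkowski_oracle(self, small_grid):
        """Two 5-px discs a pixel apart close into one blob, per the oracle."""
        m1 = rasterize_disc((12.5, 20.5, 1.0), 5.0, small_grid)
        m2 = rasterize_disc((18.5, 20.5, 1.0), 5.0, small_grid)
        mask = np.zeros(small_grid.shape, bool)
        for p in list(m1.pixels) + list(m2.pixels):
            mask[p] = True
        closed = close_mask(mask, 2)
        assert np.array_equal(closed, brute_minkowski_close(mask, 2))
        # the 1-px gap column between the discs gets bridged
        assert closed[20, 15] and not mask[20, 15]

    def test_matches_oracle_on_random_masks(self, rng):
        for _ in range(5):
            mask = rng.random((24, 24)) < 0.15
            for radius in (1, 2, 3):
                assert np.array_equal(
                    close_mask(mask, radius), brute_minkowski_close(mask, radius)
                )

    def test_extensive_and_idempotent(self, rng):
        mask = rng.random((30, 30)) < 0.2
        closed = close_mask(mask, 2)
        assert (closed | mask == closed).all()  # output contains input
        assert np.array_equal(close_mask(closed, 2), closed)

    def test_zero_radius_identity(self, rng):
        mask = rng.random((10, 10)) < 0.5
        assert np.array_equal(close_mask(mask, 0), mask)


class TestRobertsEdge:
    def test_uniform_masks_have_no_edge(self):
        assert not roberts_edge(np.zeros((8, 8), bool)).any()
        assert not roberts_edge(np.ones((8, 8), bool)).any()

    def test_isolated_pixel_neighborhood(self):
        """A lone pixel flags itself and the 2x2 backward diagonal window."""
        img = np.zeros((8, 8), bool)
        img[4, 4] = True
        assert np.array_equal(roberts_edge(img), brute_roberts(img))
        edges = roberts_edge(img)
        assert edges[4, 4] and edges[3, 3] and edges[3, 4] and edges[4, 3]

    def test_filled_rectangle_has_closed_frame(self):
        img = np.zeros((12, 12), bool)
        img[3:8, 2:9] = True
        edges = roberts_edge(img)
        assert np.array_equal(edges, brute_roberts(img))
        # interior strictly inside the frame is not flagged
        assert not edges[5:7, 4:7].any()

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(arrays(bool, (32, 32)))
    def test_matches_double_loop_oracle(self, img):
        assert np.array_equal(roberts_edge(img), brute_roberts(img))

    def test_every_edge_pixel_has_mixed_window(self, rng):
        img = rng.random((20, 20)) < 0.4
        ext = np.pad(img.astype(int), ((0, 1), (0, 1)), mode="edge")
        edges = roberts_edge(img)
        for r, c in zip(*np.nonzero(edges)):
            window = ext[r : r + 2, c : c + 2]
            assert window.min() != window.max()


class TestGrayAlphaHighRisk:
    def make_map(self, rng, station="3"):
        d = DensityMap(station=station, shape=(16, 16))
        d.slices[0] = rng.integers(0, 7, size=(16, 16))
        d.slices[3] = rng.integers(0, 7, size=(16, 16))
        return d

    def test_max_count_pixel_maps_to_one(self, rng):
        d = self.make_map(rng)
        gray = to_gray(d)
        peak = max(arr.max() for arr in gray.values())
        assert peak == pytest.approx(1.0)

    def test_zero_map_yields_zero_gray(self):
        d = DensityMap(station="3", shape=(8, 8))
        d.slices[0] = np.zeros((8, 8), int)
        gray = to_gray(d)
        assert not gray[0].any()

    def test_gray_roundtrip_recovers_counts(self, rng):
        d = self.make_map(rng)
        gray = to_gray(d)
        for k in d.slices:
            assert np.array_equal(
                np.rint(gray[k] * d.max_count).astype(int), d.slices[k]
            )

    def test_alpha_endpoints_and_monotonicity(self):
        ramp = np.linspace(0, 1, 11)
        a = alpha_map(ramp, alpha_max=0.8)
        assert a[0] == 0.0 and a[-1] == pytest.approx(0.8)
        assert (np.diff(a) > 0).all()

    def test_alpha_rejects_out_of_range_gray(self):
        with pytest.raises(ValueError):
            alpha_map(np.array([-0.1, 0.5]))
        with pytest.raises(ValueError):
            alpha_map(np.array([0.5, 1.2]))

    def test_order_preserved_count_to_alpha(self, rng):
        """Ranking by count equals ranking by gray equals ranking by alpha."""
        d = self.make_map(rng)
        gray = to_gray(d)
        for k in d.slices:
            counts = d.slices[k].ravel()
            a = alpha_map(gray[k]).ravel()
            assert np.array_equal(np.argsort(counts, kind="stable"),
                                  np.argsort(a, kind="stable"))

    def test_high_risk_fraction_one_keeps_only_peak(self, rng):
        d = self.make_map(rng)
        masks = high_risk_mask(d, fraction=1.0)
        for k in d.slices:
            assert np.array_equal(masks[k], d.slices[k] == d.max_count)

    def test_high_risk_matches_threshold_oracle(self, rng):
        d = self.make_map(rng)
        masks = high_risk_mask(d, fraction=0.5)
        thr = 0.5 * d.max_count
        for k in d.slices:
            oracle = np.zeros_like(d.slices[k], bool)
            for r in range(16):
                for c in range(16):
                    oracle[r, c] = d.slices[k][r, c] >= thr
            assert np.array_equal(masks[k], oracle)

    def test_high_risk_rejects_zero_map(self):
        d = DensityMap(station="3", shape=(4, 4))
        with pytest.raises(ValueError):
            high_risk_mask(d)


class TestStationLayer:
    def test_layer_invariants(self, small_grid, rng):
        records = [
            rec("11", rng.uniform(8, 32), rng.uniform(8, 32), rng.uniform(0, 29.9))
            for _ in range(25)
        ]
        d = accumulate(records, small_grid).maps["11"]
        layer = build_station_layer(d, se_radius_px=2, alpha_max=0.8)
        for k in d.slices:
            union, closed = layer.union_mask[k], layer.closed_mask[k]
            assert (union | closed == closed).all()  # union subset of closed
            assert np.array_equal(union, d.slices[k] > 0)
            # alpha vanishes exactly off the density support
            assert np.array_equal(layer.alpha[k] > 0, d.slices[k] > 0)

    def test_invert_alpha_reverses_order_on_support(self, small_grid):
        records = [rec("4", 20.5, 20.5, 1.0)] * 3 + [rec("4", 26.5, 20.5, 1.0)]
        d = accumulate(records, small_grid).maps["4"]
        normal = build_station_layer(d, invert_alpha=False)
        inverted = build_station_layer(d, invert_alpha=True)
        a_n, a_i = normal.alpha[0], inverted.alpha[0]
        dense, sparse = (20, 20), (20, 26)
        assert a_n[dense] > a_n[sparse]
        assert a_i[dense] < a_i[sparse]
        assert not a_i[d.slices[0] == 0].any()
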