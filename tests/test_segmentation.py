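import numpy as np
import pytest

from trabseg.segmentation import (
    ATParams,
    MethodSpec,
    adaptive_local_threshold_segment,
    global_threshold_segment,
    local_threshold_map,
    remove_small_components,
    segment,
    spherical_footprint,
)

from conftest import make_mask, make_volume, random_mask, random_volume


def brute_local_threshold(values, radius):
    """Naive per-voxel loop over the clipped spherical neighborhood."""
    nx, ny, nz = values.shape
    offsets = np.argwhere(spherical_footprint(radius)) - radius
    out = np.empty_like(values, dtype=np.float64)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                pts = offsets + (i, j, k)
                ok = np.all((pts >= 0) & (pts < (nx, ny, nz)), axis=1)
                neigh = values[tuple(pts[ok].T)]
                out[i, j, k] = min(neigh.mean(), (neigh.min() + neigh.max()) / 2.0)
    return out


def flood_fill_components(mask, connectivity=26):
    """Exhaustive BFS labeling; returns list of component voxel-index sets."""
    if connectivity == 6:
        neigh = [d for d in np.ndindex(3, 3, 3) if sum(abs(x - 1) for x in d) == 1]
    elif connectivity == 18:
        neigh = [
            d for d in np.ndindex(3, 3, 3) if 0 < sum(abs(x - 1) for x in d) <= 2
        ]
    else:
        neigh = [d for d in np.ndindex(3, 3, 3) if any(x != 1 for x in d)]
    neigh = [tuple(x - 1 for x in d) for d in neigh]
    todo = {tuple(p) for p in np.argwhere(mask > 0)}
    comps = []
    while todo:
        seed = todo.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            p = frontier.pop()
            for d in neigh:
                q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                if q in todo:
                    todo.discard(q)
                    comp.add(q)
                    frontier.append(q)
        comps.append(comp)
    return comps


class TestGlobalThreshold:
    def test_constant_above(self):
        vol = make_volume(np.full((4, 4, 4), 400.0))
        assert global_threshold_segment(vol, 320.0).count() == 64

    def test_boundary_is_inclusive(self):
        vol = make_volume(np.full((4, 4, 4), 400.0))
        assert global_threshold_segment(vol, 400.0).count() == 64

    def test_counting_oracle(self, rng):
        vol = random_volume(rng, (10, 10, 10))
        t = 415.0
        mask = global_threshold_segment(vol, t)
        assert mask.count() == int((vol.values >= t).sum())

    def test_monotone_in_threshold(self, rng):
        vol = random_volume(rng, (8, 8, 8))
        m1 = global_threshold_segment(vol, 300.0).values
        m2 = global_threshold_segment(vol, 360.0).values
        assert np.all(m2 <= m1)


class TestLocalThresholdMap:
    def test_constant_volume(self):
        vol = make_volume(np.full((7, 7, 7), 321.0))
        out = local_threshold_map(vol, 2)
        assert np.allclose(out.values, 321.0)

    def test_symmetric_neighborhood_values(self):
        # values {0, 100, 200}: mean = 100, midpoint = 100
        arr = np.full((3, 1, 1), 0.0)
        arr[1] = 100.0
        arr[2] = 200.0
        out = local_threshold_map(make_volume(arr), 1)
        assert out.values[1, 0, 0] == pytest.approx(100.0)

    @pytest.mark.parametrize("radius", [1, 2, 3])
    def test_matches_bruteforce(self, rng, radius):
        vol = random_volume(rng, (9, 9, 9))
        out = local_threshold_map(vol, radius)
        assert np.allclose(out.values, brute_local_threshold(vol.values, radius), atol=1e-9)

    def test_radius16_matches_bruteforce_spotcheck(self, rng):
        vol = random_volume(rng, (16, 16, 16))
        out = local_threshold_map(vol, 3)
        expected = brute_local_threshold(vol.values, 3)
        assert np.allclose(out.values, expected, atol=1e-9)


class TestRemoveSmallComponents:
    def test_keeps_only_large(self):
        arr = np.zeros((12, 12, 12), dtype=np.uint8)
        arr[1:3, 1:5, 1:2] = 1  # 2*4*1 = 8 voxels < 16
        arr[6:8, 6:11, 6:8] = 1  # 2*5*2 = 20 voxels >= 16
        out = remove_small_components(make_mask(arr), 16)
        assert out.count() == 20
        assert np.all(out.values[6:8, 6:11, 6:8] == 1)

    def test_min_size_zero_identity(self, rng):
        mask = random_mask(rng, (8, 8, 8), p=0.2)
        out = remove_small_components(mask, 0)
        assert np.array_equal(out.values, mask.values)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_floodfill_oracle(self, rng, connectivity):
        for _ in range(5):
            mask = random_mask(rng, (10, 10, 10), p=0.15)
            min_size = 4
            out = remove_small_components(mask, min_size, connectivity)
            comps = flood_fill_components(mask.values, connectivity)
            expected = np.zeros_like(mask.values)
            for comp in comps:
                if len(comp) >= min_size:
                    for p in comp:
                        expected[p] = 1
            assert np.array_equal(out.values, expected)

    def test_idempotent(self, rng):
        mask = random_mask(rng, (10, 10, 10), p=0.2)
        once = remove_small_components(mask, 5)
        twice = remove_small_components(once, 5)
        assert np.array_equal(once.values, twice.values)

    def test_antitone_in_min_size(self, rng):
        mask = random_mask(rng, (10, 10, 10), p=0.25)
        small = remove_small_components(mask, 3).values
        large = remove_small_components(mask, 10).values
        assert np.all(large <= small)

    def test_never_adds_voxels(self, rng):
        mask = random_mask(rng, (8, 8, 8), p=0.3)
        out = remove_small_components(mask, 6)
        assert np.all(out.values <= mask.values)


class TestAdaptiveThreshold:
    def _p(self, **kw):
        defaults = dict(
            kernel_radius=3, lower_threshold=350.0, min_structure_size=0, prefilter="none"
        )
        defaults.update(kw)
        return ATParams(**defaults)

    def test_constant_above_lower(self):
        vol = make_volume(np.full((6, 6, 6), 400.0))
        out = adaptive_local_threshold_segment(vol, self._p())
        assert out.count() == 216

    def test_constant_below_lower(self):
        vol = make_volume(np.full((6, 6, 6), 300.0))
        out = adaptive_local_threshold_segment(vol, self._p())
        assert out.count() == 0

    def test_composition_oracle(self, rng):
        vol = random_volume(rng, (12, 12, 12))
        p = self._p()
        out = adaptive_local_threshold_segment(vol, p)
        tmap = brute_local_threshold(vol.values, p.kernel_radius)
        expected = (vol.values >= np.maximum(tmap, p.lower_threshold)).astype(np.uint8)
        assert np.array_equal(out.values, expected)

    def test_subset_of_global_at_lower_threshold(self, rng):
        vol = random_volume(rng, (10, 10, 10))
        p = self._p(min_structure_size=4)
        at = adaptive_local_threshold_segment(vol, p).values
        glob = global_threshold_segment(vol, p.lower_threshold).values
        assert np.all(at <= glob)

    def test_monotone_in_lower_threshold(self, rng):
        vol = random_volume(rng, (10, 10, 10))
        lo = adaptive_local_threshold_segment(vol, self._p(lower_threshold=300)).values
        hi = adaptive_local_threshold_segment(vol, self._p(lower_threshold=380)).values
        assert np.all(hi <= lo)

    def test_whole_volume_radius_degenerates_to_global_rule(self, rng):
        """With the kernel covering everything, T is constant at
        min(global mean, global midpoint) wherever no border clipping occurs."""
        vol = random_volume(rng, (8, 8, 8))
        v = vol.values
        t_global = min(v.mean(), (v.min() + v.max()) / 2.0)
        out = adaptive_local_threshold_segment(
            vol, self._p(kernel_radius=14, lower_threshold=0.0)
        )
        # the center voxel's neighborhood is the full volume
        expected_center = 1 if v[4, 4, 4] >= t_global else 0
        assert out.values[4, 4, 4] == expected_center


class TestSegmentDispatch:
    def test_adaptive_constant_300_empty(self):
        vol = make_volume(np.full((8, 8, 8), 300.0))
        assert segment(vol, MethodSpec("adaptive")).count() == 0

    def test_standard_two_level_block(self):
        arr = np.full((32, 32, 32), 100.0)
        arr[8:24, 8:24, 8:24] = 700.0
        vol = make_volume(arr)
        mask = segment(vol, MethodSpec("standard"))
        # interior of the bright block survives smoothing + 320 threshold
        assert np.all(mask.values[10:22, 10:22, 10:22] == 1)
        assert np.all(mask.values[:6] == 0)

    def test_otsu_bimodal_foreground_fraction(self, rng):
        arr = np.full((24, 24, 24), 100.0)
        arr[:, :, :8] = 700.0  # exactly 1/3 bright
        arr += rng.normal(0, 20, arr.shape)
        mask = segment(make_volume(arr), MethodSpec("otsu"))
        frac = mask.count() / arr.size
        assert abs(frac - 1 / 3) < 0.02

    def test_laplace_hamming_method_thresholds_per_mille(self, rng):
        vol = random_volume(rng, (12, 12, 12))
        mask = segment(vol, MethodSpec("laplace_hamming"))
        assert set(np.unique(mask.values)) <= {0, 1}

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            MethodSpec("bogus")
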