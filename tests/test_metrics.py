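import numpy as np
import pytest
from scipy.spatial.distance import cdist

from thoraseg.errors import GridError, PairingError, UndefinedMetricError
from thoraseg.metrics import (
    assd,
    distance_range,
    dsc,
    evaluate_dataset,
    hausdorff,
    surface_points,
)

# ---------------------------------------------------------------------------
# independent brute-force oracles (explicit neighbour scan + all-pairs dist)


def brute_surface(mask):
    mask = np.asarray(mask).astype(bool)
    pts = []
    offsets = []
    for ax in range(mask.ndim):
        for d in (-1, 1):
            off = [0] * mask.ndim
            off[ax] = d
            offsets.append(tuple(off))
    for idx in np.argwhere(mask):
        for off in offsets:
            nb = tuple(idx + np.array(off))
            if any(c < 0 or c >= s for c, s in zip(nb, mask.shape)) or not mask[nb]:
                pts.append(tuple(idx))
                break
    return np.array(pts).reshape(-1, mask.ndim)


def brute_hd_assd(a, b, spacing):
    sa = brute_surface(a) * np.asarray(spacing)
    sb = brute_surface(b) * np.asarray(spacing)
    d = cdist(sa, sb)
    d_ab = d.min(axis=1)
    d_ba = d.min(axis=0)
    hd = max(d_ab.max(), d_ba.max())
    as_ = (d_ab.sum() + d_ba.sum()) / (len(sa) + len(sb))
    return hd, as_


# ---------------------------------------------------------------------------


class TestDSC:
    def test_perfect_match_is_one(self, rng):
        m = rng.random((20, 20)) > 0.6
        assert dsc(m, m.copy()) == 1.0

    def test_disjoint_is_zero(self):
        a = np.zeros((8, 8), dtype=bool)
        b = np.zeros((8, 8), dtype=bool)
        a[:2], b[6:] = True, True
        assert dsc(a, b) == 0.0

    def test_voxel_count_oracle(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0] = True  # |X| = 4
        b[:2] = True  # |Y| = 8, intersection 4
        assert dsc(a, b) == pytest.approx(2 * 4 / 12)

    def test_empty_conventions(self):
        e = np.zeros((5, 5), dtype=bool)
        f = e.copy()
        f[2, 2] = True
        assert dsc(e, e) == 1.0
        assert dsc(e, f) == 0.0

    def test_symmetry(self, rng):
        a = rng.random((12, 12)) > 0.5
        b = rng.random((12, 12)) > 0.5
        assert dsc(a, b) == dsc(b, a)

    def test_shape_mismatch(self):
        with pytest.raises(GridError):
            dsc(np.zeros((3, 3)), np.zeros((4, 4)))


class TestSurfacePoints:
    def test_single_voxel_is_its_own_border(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 3] = True
        np.testing.assert_array_equal(surface_points(m), [[2, 3]])

    def test_solid_3x3_square_has_8_border_points(self):
        m = np.zeros((7, 7), dtype=bool)
        m[2:5, 2:5] = True
        assert len(surface_points(m)) == 8

    def test_frame_filling_mask_border_is_frame_edge(self):
        m = np.ones((6, 9), dtype=bool)
        pts = {tuple(p) for p in surface_points(m)}
        expected = {
            (i, j)
            for i in range(6)
            for j in range(9)
            if i in (0, 5) or j in (0, 8)
        }
        assert pts == expected

    @pytest.mark.parametrize("shape", [(10, 12), (4, 8, 8)])
    def test_matches_explicit_neighbour_scan(self, shape, rng):
        m = rng.random(shape) > 0.5
        got = {tuple(p) for p in surface_points(m)}
        want = {tuple(p) for p in brute_surface(m)}
        assert got == want


class TestDistances:
    def test_identical_masks_give_zero(self, rng):
        m = rng.random((15, 15)) > 0.6
        m[7, 7] = True
        assert hausdorff(m, m.copy()) == 0.0
        assert assd(m, m.copy()) == 0.0

    def test_two_points_pythagoras(self):
        a = np.zeros((6, 6), dtype=bool)
        b = np.zeros((6, 6), dtype=bool)
        a[0, 0] = True
        b[3, 4] = True
        assert hausdorff(a, b, (1, 1)) == pytest.approx(5.0)
        assert assd(a, b, (1, 1)) == pytest.approx(5.0)  # (5+5)/2

    def test_anisotropic_spacing(self):
        a = np.zeros((5, 5), dtype=bool)
        b = np.zeros((5, 5), dtype=bool)
        a[0, 0] = True
        b[0, 2] = True
        assert hausdorff(a, b, (1.0, 0.7)) == pytest.approx(1.4)

    def test_assd_never_exceeds_hausdorff(self, rng):
        for _ in range(20):
            a = rng.random((12, 12)) > 0.5
            b = rng.random((12, 12)) > 0.5
            if not a.any() or not b.any():
                continue
            assert assd(a, b) <= hausdorff(a, b) + 1e-12

    def test_translation_invariance(self, rng):
        a = np.zeros((20, 20), dtype=bool)
        b = np.zeros((20, 20), dtype=bool)
        a[3:8, 4:9] = rng.random((5, 5)) > 0.3
        b[4:9, 5:10] = rng.random((5, 5)) > 0.3
        a[5, 6] = b[6, 7] = True
        sh = lambda m: np.roll(m, (7, 6), axis=(0, 1))
        assert hausdorff(sh(a), sh(b)) == pytest.approx(hausdorff(a, b))
        assert assd(sh(a), sh(b)) == pytest.approx(assd(a, b))
        assert dsc(sh(a), sh(b)) == pytest.approx(dsc(a, b))

    def test_brute_force_equivalence_random_masks(self, rng):
        for _ in range(60):
            h, w = rng.integers(3, 17, size=2)
            a = rng.random((h, w)) > rng.uniform(0.3, 0.8)
            b = rng.random((h, w)) > rng.uniform(0.3, 0.8)
            if not a.any() or not b.any():
                continue
            sp = tuple(rng.uniform(0.5, 3.0, size=2))
            hd_o, as_o = brute_hd_assd(a, b, sp)
            assert hausdorff(a, b, sp) == pytest.approx(hd_o, abs=1e-9)
            assert assd(a, b, sp) == pytest.approx(as_o, abs=1e-9)

    def test_empty_mask_is_undefined_not_zero(self):
        m = np.zeros((4, 4), dtype=bool)
        f = m.copy()
        f[1, 1] = True
        with pytest.raises(UndefinedMetricError):
            hausdorff(m, f)
        with pytest.raises(UndefinedMetricError):
            assd(f, m)


def test_distance_range_is_grid_diagonal():
    lo, hi = distance_range((128, 128))
    assert lo == 0.0
    assert hi == pytest.approx(np.sqrt(2) * 128)


class TestEvaluateDataset:
    def test_identical_predictions(self, rng):
        truths = [(rng.random((2, 10, 10)) > 0.5) for _ in range(3)]
        for t in truths:
            t[:, 5, 5] = True
        report = evaluate_dataset([t.copy() for t in truths], truths)
        assert report.summary["dsc_mean"] == 1.0
        assert report.summary["hd_mm_mean"] == 0.0
        assert report.summary["dsc_std"] == 0.0

    def test_two_case_mean_and_sample_std(self):
        # engineered DSCs of 0.8 and 1.0 -> mean 0.9, sample std 0.1414
        t = np.zeros((1, 6, 6), dtype=bool)
        t[0, 1:5, 1:5] = True  # 16 voxels
        p = t.copy()
        p[0, 1, 1:5] = False  # 12 voxels, intersection 12: dsc = 24/28
        t2 = t.copy()
        report = evaluate_dataset([p, t2], [t, t], mode="volume3d")
        dscs = [c["dsc"] for c in report.per_case]
        exp = [24 / 28, 1.0]
        assert dscs == pytest.approx(exp)
        assert report.summary["dsc_mean"] == pytest.approx(np.mean(exp))
        assert report.summary["dsc_std"] == pytest.approx(np.std(exp, ddof=1))

    def test_sample_std_formula_two_points(self):
        assert np.std([0.8, 1.0], ddof=1) == pytest.approx(0.1414, abs=5e-5)

    def test_undefined_distances_flagged_not_zeroed(self):
        t = np.zeros((1, 5, 5), dtype=bool)
        t[0, 2, 2] = True
        empty_pred = np.zeros_like(t)
        report = evaluate_dataset([empty_pred, t.copy()], [t, t], mode="volume3d")
        assert report.n_undefined_distances == 1
        assert report.summary["hd_mm_mean"] == 0.0  # from the one defined case

    def test_pairing_errors(self):
        with pytest.raises(PairingError):
            evaluate_dataset([np.zeros((2, 2))], [])
        with pytest.raises(PairingError):
            evaluate_dataset([], [])
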