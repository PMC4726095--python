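"""Cross-correlation PIV engine: ZNCC, P_c, sub-pixel fits, fields, ensembles."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from xpiv import (
    CorrelationMap,
    PivConfig,
    VelocityField,
    compute_field,
    correlate_batch,
    correlate_windows,
    ensemble_mean,
    subpixel_peak,
    to_physical,
)
from tests.conftest import fourier_shift


def zncc_oracle(a, b, my, mx):
    """Literal double-loop ZNCC: mean-subtracted product sums over the overlap,
    divided by the full-window energy N*sigma_a*sigma_b."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    h, w = a.shape
    da, db = a - a.mean(), b - b.mean()
    scale = h * w * a.std() * b.std()
    out = np.zeros((2 * my + 1, 2 * mx + 1))
    for i, dy in enumerate(range(-my, my + 1)):
        for j, dx in enumerate(range(-mx, mx + 1)):
            s = 0.0
            for y in range(max(0, -dy), min(h, h - dy)):
                for x in range(max(0, -dx), min(w, w - dx)):
                    s += da[y, x] * db[y + dy, x + dx]
            out[i, j] = s / scale
    return out


class TestCorrelation:
    def test_identical_windows_peak_at_origin_with_unit_pc(self, rng):
        w = rng.standard_normal((32, 64))
        cm = correlate_windows(w, w, (8, 8))
        assert cm.peak_lag == (0, 0)
        assert cm.p_c == pytest.approx(1.0, abs=1e-9)

    def test_periodic_integer_shift_recovered(self, rng):
        a = rng.standard_normal((64, 64))
        b = np.roll(a, (3, -7), axis=(0, 1))
        cm = correlate_windows(a, b, (10, 10))
        assert cm.peak_lag == (3, -7)

    def test_loss_of_pairs_shrinks_peak(self, rng):
        # translated white noise: peak value equals the overlap fraction
        a = rng.standard_normal((64, 64))
        b = np.roll(a, (0, 16), axis=(0, 1))
        cm = correlate_windows(a, b, (4, 20))
        assert cm.peak_lag == (0, 16)
        assert cm.p_c == pytest.approx((64 - 16) / 64, abs=0.05)

    def test_coefficients_bounded(self, rng):
        a = gaussian_filter(rng.standard_normal((48, 48)), 2.0)
        b = gaussian_filter(rng.standard_normal((48, 48)), 2.0)
        cm = correlate_windows(a, b, (12, 12))
        assert np.nanmax(np.abs(cm.coeffs)) <= 1.0 + 1e-12

    def test_matches_double_loop_oracle(self, rng):
        a = rng.standard_normal((16, 16))
        b = np.roll(a, (1, 2), axis=(0, 1)) + 0.3 * rng.standard_normal((16, 16))
        maps, lr, lc, ok = correlate_batch(a[None], b[None], (4, 4))
        oracle = zncc_oracle(a, b, 4, 4)
        assert ok[0]
        assert np.allclose(maps[0], oracle, atol=1e-10)

    def test_zero_variance_window_flagged_not_raised(self, rng):
        cm = correlate_windows(np.ones((16, 16)), rng.standard_normal((16, 16)))
        assert not cm.valid
        assert np.isnan(cm.p_c)

    def test_independent_noise_rarely_reaches_pc_03(self, rng):
        # empirical null over 10^4 seeded window pairs
        n_total, below = 10_000, 0
        for _ in range(10):
            a = rng.standard_normal((1000, 64, 64))
            b = rng.standard_normal((1000, 64, 64))
            maps, lr, lc, ok = correlate_batch(a, b, (8, 8))
            below += int(np.sum(np.nanmax(maps, axis=(1, 2)) < 0.3))
        assert below / n_total > 0.99


class TestSubpixel:
    def test_symmetric_peak_gives_zero_offset(self):
        lr = np.arange(-3, 4)
        yy, xx = np.meshgrid(lr, lr, indexing="ij")
        coeffs = np.exp(-(xx ** 2 + yy ** 2) / 4.0)
        cm = CorrelationMap(coeffs, lr, lr, (0, 0), 1.0, True)
        dx, dy = subpixel_peak(cm)
        assert dx == pytest.approx(0.0, abs=1e-12)
        assert dy == pytest.approx(0.0, abs=1e-12)

    def test_analytic_gaussian_peak_offset_recovered(self):
        lr = np.arange(-5, 6)
        yy, xx = np.meshgrid(lr, lr, indexing="ij")
        coeffs = np.exp(-((xx - 0.30) ** 2 + yy ** 2) / (2 * 1.5 ** 2))
        cm = CorrelationMap(coeffs, lr, lr, (0, 0), float(coeffs.max()), True)
        dx, dy = subpixel_peak(cm)
        assert dx == pytest.approx(0.30, abs=0.02)

    def test_fourier_shifted_speckle_5_25_px(self, rng):
        errs = []
        for _ in range(100):
            a = gaussian_filter(rng.standard_normal((64, 64)), 1.5, mode="wrap")
            b = fourier_shift(a, 0.0, 5.25)
            cm = correlate_windows(a, b, (8, 8))
            dx, dy = subpixel_peak(cm)
            errs.append(dx - 5.25)
        assert np.sqrt(np.mean(np.square(errs))) <= 0.1

    def test_border_peak_gets_no_refinement(self, rng):
        a = rng.standard_normal((32, 32))
        b = np.roll(a, (0, 6), axis=(0, 1))
        cm = correlate_windows(a, b, (2, 6))  # peak on the +x border
        dx, dy = subpixel_peak(cm)
        assert dx == pytest.approx(6.0)


class TestComputeField:
    def test_grid_shape_for_reference_geometry(self, rng):
        # 1024x1024 frame, 32 (transverse) x 64 (flow) windows, 50% overlap
        frame = rng.standard_normal((1024, 1024))
        field = compute_field(frame, frame, PivConfig(window_size=(32, 64)))
        assert field.shape == (63, 31)

    def test_uniform_shift_recovered_everywhere(self, rng):
        # reference geometry: 1024 px frames, 32 x 64 windows, 50% overlap
        a = gaussian_filter(rng.standard_normal((1024, 1024)), 1.5, mode="wrap")
        b = np.roll(a, 3, axis=1)
        cfg = PivConfig(window_size=(32, 64), pc_threshold=0.3,
                        max_displacement=(8, 8))
        field = compute_field(a, b, cfg)
        ok = field.valid
        assert ok.mean() > 0.99
        close = (np.abs(field.u[ok] - 3.0) <= 0.1) & (np.abs(field.v[ok]) <= 0.1)
        assert close.mean() >= 0.99

    def test_swapping_frames_negates_displacement(self, rng):
        a = gaussian_filter(rng.standard_normal((128, 128)), 1.5, mode="wrap")
        b = np.roll(a, 4, axis=1)
        cfg = PivConfig(window_size=(32, 32), pc_threshold=0.3)
        fab = compute_field(a, b, cfg)
        fba = compute_field(b, a, cfg)
        both = fab.valid & fba.valid
        assert np.allclose(fab.u[both], -fba.u[both], atol=0.05)

    def test_window_larger_than_frame_rejected(self):
        with pytest.raises(ValueError):
            compute_field(np.zeros((16, 16)), np.zeros((16, 16)),
                          PivConfig(window_size=(32, 32)))

    def test_median_test_removes_isolated_outlier(self, rng):
        a = gaussian_filter(rng.standard_normal((128, 128)), 1.5, mode="wrap")
        b = np.roll(a, 2, axis=1)
        # corrupt exactly one (non-overlapping) interrogation cell of frame b
        b = b.copy()
        b[48:64, 48:64] = rng.standard_normal((16, 16))
        cfg = PivConfig(window_size=(16, 16), overlap=0.0, pc_threshold=0.0,
                        max_displacement=(6, 6))
        field = compute_field(a, b, cfg)
        assert not field.valid[3, 3]  # the corrupted cell is rejected
        interior = field.valid[1:-1, 1:-1]
        u_in = field.u[1:-1, 1:-1][interior]
        # surviving vectors show only sub-pixel scatter, no gross outliers
        assert np.nanmax(np.abs(u_in - 2.0)) <= 0.5


class TestEnsemble:
    @staticmethod
    def make_field(u, v, valid=None):
        nr, nc = u.shape
        valid = np.ones_like(u, bool) if valid is None else valid
        return VelocityField(
            x_px=np.arange(nc, dtype=float), y_px=np.arange(nr, dtype=float),
            u=np.where(valid, u, np.nan), v=np.where(valid, v, np.nan),
            pc=np.full_like(u, 0.9), sr=np.full_like(u, 0.2),
            valid=valid, n_pairs=valid.astype(int),
        )

    def test_mean_of_identical_fields_is_that_field(self, rng):
        u = rng.standard_normal((6, 8))
        fields = [self.make_field(u, 0 * u) for _ in range(200)]
        mean = ensemble_mean(fields)
        assert np.allclose(mean.u, u)
        assert np.all(mean.n_pairs == 200)

    def test_ensemble_std_shrinks_like_sqrt_n(self, rng):
        base = np.full((20, 20), 3.0)
        spreads = {}
        for n in (50, 200):
            fields = [
                self.make_field(base + rng.standard_normal(base.shape), 0 * base)
                for _ in range(n)
            ]
            spreads[n] = np.std(ensemble_mean(fields).u - base)
        assert spreads[50] / spreads[200] == pytest.approx(2.0, rel=0.25)

    def test_sparsely_valid_points_dropped(self, rng):
        u = np.ones((4, 4))
        mostly_invalid = np.zeros((4, 4), bool)
        mostly_invalid[0, 0] = True
        fields = [self.make_field(u, u, valid=np.ones((4, 4), bool)) for _ in range(9)]
        fields += [self.make_field(u, u, valid=mostly_invalid) for _ in range(31)]
        mean = ensemble_mean(fields)  # 9/40 < 25% valid except at (0, 0)
        assert mean.valid[0, 0]
        assert not mean.valid[1, 1]

    def test_grid_mismatch_rejected(self, rng):
        f1 = self.make_field(np.ones((4, 4)), np.ones((4, 4)))
        f2 = self.make_field(np.ones((5, 4)), np.ones((5, 4)))
        with pytest.raises(ValueError):
            ensemble_mean([f1, f2])


class TestPhysicalUnits:
    @pytest.mark.parametrize(
        "px_per_frame,expected_mms",
        [(1.0, 1.8994), (0.0, 0.0), (10.0, 18.994)],
    )
    def test_pixel_to_mm_per_s(self, px_per_frame, expected_mms):
        u = np.full((3, 3), px_per_frame)
        f = TestEnsemble.make_field(u, 0 * u)
        phys = to_physical(f, pixel_pitch=1.8994, frame_rate=1000.0)
        assert np.allclose(phys.u_mms, expected_mms)
        assert phys.units == "mm/s"

    def test_missing_calibration_rejected(self):
        f = TestEnsemble.make_field(np.ones((3, 3)), np.ones((3, 3)))
        with pytest.raises(ValueError):
            to_physical(f)
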