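"""Two-frame cross-correlation PIV with relative peak height P_c.

Each pair of interrogation windows is compared by zero-normalized
cross-correlation (ZNCC): both windows are mean-subtracted, and at every
candidate lag the sum of products over the overlapping pixels is divided by
the full-window energy ``N * sigma_a * sigma_b``. By Cauchy-Schwarz every
coefficient lies in [-1, 1], identical windows give exactly 1 at zero lag,
and partial overlap at large lags shrinks the coefficient (loss of pairs) —
the mechanism that makes the relative peak height ``P_c`` fall off as the
true displacement grows past a fraction of the window extent. ``P_c`` is the
peak coefficient and serves as the reliability measure (vectors with ``P_c``
below threshold are rejected; ``P_c > 0.5`` is the standard acceptance
criterion for speckle velocimetry).
Sub-pixel displacement comes from a per-axis three-point Gaussian fit through
the peak, with a parabolic fallback when a neighbour is non-positive.

The batched implementation computes the ZNCC numerator with padded FFTs and
all per-lag means/variances with integral images, so a whole vector grid is
correlated in a handful of vectorized array operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import fft as spfft

__all__ = [
    "PivConfig",
    "CorrelationMap",
    "VelocityField",
    "correlate_windows",
    "subpixel_peak",
    "compute_field",
    "ensemble_mean",
    "to_physical",
]


@dataclass
class PivConfig:
    """Interrogation settings.

    ``window_size`` is (transverse, along-flow) = (rows, cols); the default
    32 x 64 px puts the long axis along the flow. ``max_displacement`` bounds
    the correlation search per axis (rows, cols); default just under half the
    window. Outlier rejection is the normalized median test on the 3x3 vector
    neighbourhood.
    """

    window_size: tuple[int, int] = (32, 64)
    overlap: float = 0.5
    pc_threshold: float = 0.5
    max_displacement: tuple[int, int] | None = None
    pixel_pitch: float | None = None     # um/px
    frame_rate: float | None = None      # frames/s
    median_test: bool = True
    median_threshold: float = 2.0
    median_eps: float = 0.1

    def __post_init__(self) -> None:
        h, w = self.window_size
        if h < 8 or w < 8:
            raise ValueError("window dimensions must be >= 8 px")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")
        if not 0.0 <= self.pc_threshold <= 1.0:
            raise ValueError("pc_threshold must be in [0, 1]")
        self.window_size = (int(h), int(w))

    def search_radius(self) -> tuple[int, int]:
        if self.max_displacement is not None:
            my, mx = self.max_displacement
            return int(my), int(mx)
        h, w = self.window_size
        return h // 2 - 1, w // 2 - 1

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CorrelationMap:
    """ZNCC coefficients over lags for one window pair.

    The coefficients carry the loss-of-pairs envelope (overlap/N), which is
    what makes P_c displacement-sensitive; sub-pixel localization divides the
    envelope back out (bias correction), which needs ``window_shape``.
    """

    coeffs: np.ndarray           # (2*my+1, 2*mx+1), rows = dy, cols = dx
    lag_rows: np.ndarray         # dy values along axis 0
    lag_cols: np.ndarray         # dx values along axis 1
    peak_lag: tuple[int, int]    # (dy, dx) of the peak
    p_c: float                   # coefficient at the peak
    valid: bool                  # False when a window had zero variance
    window_shape: tuple[int, int] | None = None

    @property
    def peak_index(self) -> tuple[int, int]:
        return (
            int(self.peak_lag[0] - self.lag_rows[0]),
            int(self.peak_lag[1] - self.lag_cols[0]),
        )


@dataclass
class VelocityField:
    """Regular grid of displacement/velocity vectors with quality measures.

    ``u`` is the along-flow (column) displacement component and ``v`` the
    transverse (row) component, both in px/frame; ``u_mms``/``v_mms`` are set
    once :func:`to_physical` has been applied. Invalid vectors hold NaN.
    """

    x_px: np.ndarray             # window-centre columns, (n_cols,)
    y_px: np.ndarray             # window-centre rows, (n_rows,)
    u: np.ndarray                # (n_rows, n_cols), px/frame
    v: np.ndarray
    pc: np.ndarray
    sr: np.ndarray
    valid: np.ndarray            # bool
    n_pairs: np.ndarray          # int, pairs averaged per vector
    pixel_pitch: float | None = None
    frame_rate: float | None = None
    u_mms: np.ndarray | None = None
    v_mms: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def units(self) -> str:
        return "mm/s" if self.u_mms is not None else "px/frame"

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    def to_dataframe(self) -> pd.DataFrame:
        yy, xx = np.meshgrid(self.y_px, self.x_px, indexing="ij")
        pitch = self.pixel_pitch or np.nan
        data = {
            "x_px": xx.ravel(),
            "y_px": yy.ravel(),
            "x_um": (xx * pitch).ravel(),
            "y_um": (yy * pitch).ravel(),
            "u_px": self.u.ravel(),
            "v_px": self.v.ravel(),
            "u_mms": (self.u_mms if self.u_mms is not None else np.full_like(self.u, np.nan)).ravel(),
            "v_mms": (self.v_mms if self.v_mms is not None else np.full_like(self.v, np.nan)).ravel(),
            "pc": self.pc.ravel(),
            "sr": self.sr.ravel(),
            "valid": self.valid.ravel(),
            "n_pairs": self.n_pairs.ravel(),
        }
        return pd.DataFrame(data)


# --------------------------------------------------------------------------
# batched ZNCC core
# --------------------------------------------------------------------------

def _rect_sums(cum: np.ndarray, r0, r1, c0, c1) -> np.ndarray:
    """Rectangle sums from a zero-padded 2D cumulative sum, batched over axis 0.

    r0/r1 index rows (broadcast over lag-rows axis), c0/c1 columns.
    """
    return (
        cum[:, r1[:, None], c1[None, :]]
        - cum[:, r0[:, None], c1[None, :]]
        - cum[:, r1[:, None], c0[None, :]]
        + cum[:, r0[:, None], c0[None, :]]
    )


def _cumsum2d(arr: np.ndarray) -> np.ndarray:
    n, h, w = arr.shape
    out = np.zeros((n, h + 1, w + 1))
    np.cumsum(np.cumsum(arr, axis=1), axis=2, out=out[:, 1:, 1:])
    return out


def correlate_batch(
    wins_a: np.ndarray, wins_b: np.ndarray, max_displacement: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """ZNCC maps for N window pairs.

    Parameters
    ----------
    wins_a, wins_b : ndarray, shape (n, h, w)
    max_displacement : (my, mx)
        Search radius; lags run over dy in [-my, my], dx in [-mx, mx].

    Returns
    -------
    maps : ndarray (n, 2*my+1, 2*mx+1)
        Per-lag ZNCC coefficients: the sum of mean-subtracted products over
        the overlap, divided by the full-window energy N sigma_a sigma_b
        (NaN for windows without variance).
    lag_rows, lag_cols : 1D int arrays of dy / dx values.
    window_ok : bool array (n,), False where a window has zero variance.
    """
    wins_a = np.asarray(wins_a, dtype=float)
    wins_b = np.asarray(wins_b, dtype=float)
    if wins_a.shape != wins_b.shape or wins_a.ndim != 3:
        raise ValueError("windows must be matching (n, h, w) arrays")
    n, h, w = wins_a.shape
    my, mx = int(max_displacement[0]), int(max_displacement[1])
    if my >= h or mx >= w:
        raise ValueError("max_displacement must be smaller than the window")

    mean_a = wins_a.mean(axis=(1, 2))
    mean_b = wins_b.mean(axis=(1, 2))
    std_a = wins_a.std(axis=(1, 2))
    std_b = wins_b.std(axis=(1, 2))
    window_ok = (std_a > 0) & (std_b > 0)

    lag_rows = np.arange(-my, my + 1)
    lag_cols = np.arange(-mx, mx + 1)

    # numerator sum_{y,x} a[y,x] * b[y+dy, x+dx] by zero-padded FFT correlation
    ph = spfft.next_fast_len(h + my + 1)
    pw = spfft.next_fast_len(w + mx + 1)
    fa = spfft.rfft2(wins_a, s=(ph, pw))
    fb = spfft.rfft2(wins_b, s=(ph, pw))
    corr = spfft.irfft2(np.conj(fa) * fb, s=(ph, pw))
    s_ab = corr[:, lag_rows % ph, :][:, :, lag_cols % pw]

    # per-lag overlap rectangles (a-frame coordinates)
    ay0 = np.maximum(0, -lag_rows)
    ay1 = np.minimum(h, h - lag_rows)
    ax0 = np.maximum(0, -lag_cols)
    ax1 = np.minimum(w, w - lag_cols)
    by0, by1 = ay0 + lag_rows, ay1 + lag_rows
    bx0, bx1 = ax0 + lag_cols, ax1 + lag_cols
    counts = ((ay1 - ay0)[:, None] * (ax1 - ax0)[None, :]).astype(float)

    s_a = _rect_sums(_cumsum2d(wins_a), ay0, ay1, ax0, ax1)
    s_b = _rect_sums(_cumsum2d(wins_b), by0, by1, bx0, bx1)

    ma = mean_a[:, None, None]
    mb = mean_b[:, None, None]
    num = s_ab - mb * s_a - ma * s_b + counts * ma * mb
    scale = (h * w) * (std_a * std_b)[:, None, None]
    tiny = 1e-12 * max(1.0, float(scale.max()))
    with np.errstate(invalid="ignore", divide="ignore"):
        maps = np.where(scale > tiny, num / np.maximum(scale, tiny), np.nan)
    np.clip(maps, -1.0, 1.0, out=maps)
    return maps, lag_rows, lag_cols, window_ok


def _tie_break_order(lag_rows: np.ndarray, lag_cols: np.ndarray) -> np.ndarray:
    """Flat indices ordered by (lag magnitude, row-major), for deterministic peaks."""
    dy, dx = np.meshgrid(lag_rows, lag_cols, indexing="ij")
    mag2 = (dy * dy + dx * dx).ravel()
    rowmajor = np.arange(mag2.size)
    return np.lexsort((rowmajor, mag2))


def _find_peaks(maps: np.ndarray, lag_rows, lag_cols) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Peak lag and value per map with deterministic tie-breaking.

    Ties in the maximum are resolved toward the smallest lag magnitude, then
    row-major order. NaN lags are ignored; an all-NaN map yields P_c = NaN.
    """
    n = maps.shape[0]
    flat = maps.reshape(n, -1)
    order = _tie_break_order(lag_rows, lag_cols)
    ordered = flat[:, order]
    filled = np.where(np.isnan(ordered), -np.inf, ordered)
    j = np.argmax(filled, axis=1)
    flat_idx = order[j]
    iy, ix = np.unravel_index(flat_idx, maps.shape[1:])
    p_c = flat[np.arange(n), flat_idx]
    return lag_rows[iy], lag_cols[ix], p_c


def correlate_windows(
    win_a: np.ndarray,
    win_b: np.ndarray,
    max_displacement: tuple[int, int] | None = None,
) -> CorrelationMap:
    """ZNCC map of one interrogation-window pair.

    A zero-variance window does not raise: the map is returned flagged
    invalid with ``P_c = NaN``.
    """
    win_a = np.asarray(win_a, dtype=float)
    win_b = np.asarray(win_b, dtype=float)
    if win_a.shape != win_b.shape:
        raise ValueError("windows must share a shape")
    if max_displacement is None:
        max_displacement = (win_a.shape[0] // 2 - 1, win_a.shape[1] // 2 - 1)
    maps, lag_rows, lag_cols, ok = correlate_batch(
        win_a[None], win_b[None], max_displacement
    )
    if ok[0]:
        dy, dx, p_c = _find_peaks(maps, lag_rows, lag_cols)
        peak = (int(dy[0]), int(dx[0]))
        p = float(p_c[0])
    else:
        peak, p = (0, 0), float("nan")
    return CorrelationMap(
        maps[0], lag_rows, lag_cols, peak, p, bool(ok[0]), win_a.shape
    )


def _overlap_envelope(
    window_shape: tuple[int, int], lag_rows: np.ndarray, lag_cols: np.ndarray
) -> np.ndarray:
    """Loss-of-pairs envelope overlap(lag)/N of a ZNCC map (triangular)."""
    h, w = window_shape
    fy = np.maximum(h - np.abs(lag_rows), 0) / h
    fx = np.maximum(w - np.abs(lag_cols), 0) / w
    return fy[:, None] * fx[None, :]


def subpixel_peak(cmap: CorrelationMap) -> tuple[float, float]:
    """Sub-pixel displacement (dx, dy) from a three-point fit at the peak.

    The triangular loss-of-pairs envelope is divided out first (bias
    correction — without it the envelope tilt drags the fitted peak toward
    zero lag), then per axis a Gaussian fit through the peak and its two
    neighbours is used when all three are positive, else a parabolic fit.
    Peaks on the map border get no refinement. Offsets are clamped to
    (-1, 1) px.
    """
    iy, ix = cmap.peak_index
    coeffs = cmap.coeffs
    if cmap.window_shape is not None:
        env = _overlap_envelope(cmap.window_shape, cmap.lag_rows, cmap.lag_cols)
        with np.errstate(invalid="ignore", divide="ignore"):
            coeffs = np.where(env > 0, coeffs / np.maximum(env, 1e-12), np.nan)
    dy = cmap.peak_lag[0] + _fit_1d(coeffs[:, ix], iy)
    dx = cmap.peak_lag[1] + _fit_1d(coeffs[iy, :], ix)
    return float(dx), float(dy)


def _fit_1d(profile: np.ndarray, i: int) -> float:
    if i <= 0 or i >= profile.size - 1:
        return 0.0
    cm, c0, cp = profile[i - 1], profile[i], profile[i + 1]
    if np.isnan(cm) or np.isnan(cp):
        return 0.0
    if cm > 0 and c0 > 0 and cp > 0:
        denom = np.log(cm) + np.log(cp) - 2.0 * np.log(c0)
        if denom >= 0:  # degenerate (flat or inverted) — no refinement
            return 0.0
        off = 0.5 * (np.log(cm) - np.log(cp)) / denom
    else:
        denom = cm - 2.0 * c0 + cp
        if denom >= 0:
            return 0.0
        off = 0.5 * (cm - cp) / denom
    return float(np.clip(off, -0.999, 0.999))


def _subpixel_batch(maps, lag_rows, lag_cols, iy, ix):
    """Vectorized 3-point refinement along each axis for all windows."""
    n = maps.shape[0]
    off_y = np.zeros(n)
    off_x = np.zeros(n)
    rows = np.arange(n)

    def axis_offsets(vals_m, vals_0, vals_p, interior):
        out = np.zeros(n)
        pos = interior & (vals_m > 0) & (vals_0 > 0) & (vals_p > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            denom_g = np.log(vals_m) + np.log(vals_p) - 2.0 * np.log(vals_0)
            gauss = 0.5 * (np.log(vals_m) - np.log(vals_p)) / denom_g
            denom_p = vals_m - 2.0 * vals_0 + vals_p
            para = 0.5 * (vals_m - vals_p) / denom_p
        use_g = pos & (denom_g < 0) & np.isfinite(gauss)
        out[use_g] = gauss[use_g]
        use_p = interior & ~pos & (denom_p < 0) & np.isfinite(para)
        out[use_p] = para[use_p]
        return np.clip(out, -0.999, 0.999)

    ny, nx = maps.shape[1], maps.shape[2]
    int_y = (iy > 0) & (iy < ny - 1)
    int_x = (ix > 0) & (ix < nx - 1)
    iy_c = np.clip(iy, 1, ny - 2)
    ix_c = np.clip(ix, 1, nx - 2)
    off_y = axis_offsets(
        maps[rows, iy_c - 1, ix], maps[rows, iy_c, ix], maps[rows, iy_c + 1, ix], int_y
    )
    off_x = axis_offsets(
        maps[rows, iy, ix_c - 1], maps[rows, iy, ix_c], maps[rows, iy, ix_c + 1], int_x
    )
    return off_x, off_y


# --------------------------------------------------------------------------
# field-level operations
# --------------------------------------------------------------------------

def compute_field(
    frame_a: np.ndarray, frame_b: np.ndarray, config: PivConfig | None = None
) -> VelocityField:
    """One instantaneous vector field from a frame pair.

    The frames are tiled into overlapping interrogation windows; each pair is
    correlated, refined to sub-pixel precision, thresholded on ``P_c`` and
    passed through the normalized median outlier test. Rejected vectors are
    flagged invalid and carry NaN displacements.
    """
    config = config or PivConfig()
    frame_a = np.asarray(frame_a, dtype=float)
    frame_b = np.asarray(frame_b, dtype=float)
    if frame_a.shape != frame_b.shape:
        raise ValueError("frames must share a shape")
    wh, ww = config.window_size
    fh, fw = frame_a.shape
    if wh > fh or ww > fw:
        raise ValueError(f"window {config.window_size} larger than frame {frame_a.shape}")
    sy = max(1, int(round(wh * (1.0 - config.overlap))))
    sx = max(1, int(round(ww * (1.0 - config.overlap))))

    wins_a, rows0, cols0 = _tile(frame_a, wh, ww, sy, sx)
    wins_b, _, _ = _tile(frame_b, wh, ww, sy, sx)
    nr, nc = rows0.size, cols0.size

    maps, lag_rows, lag_cols, ok = correlate_batch(
        wins_a, wins_b, config.search_radius()
    )
    dy, dx, p_c = _find_peaks(maps, lag_rows, lag_cols)
    iy = (dy - lag_rows[0]).astype(int)
    ix = (dx - lag_cols[0]).astype(int)
    env = _overlap_envelope((wh, ww), lag_rows, lag_cols)
    with np.errstate(invalid="ignore", divide="ignore"):
        unbiased = np.where(env > 0, maps / np.maximum(env, 1e-12), np.nan)
    off_x, off_y = _subpixel_batch(unbiased, lag_rows, lag_cols, iy, ix)

    u = (dx + off_x).reshape(nr, nc)
    v = (dy + off_y).reshape(nr, nc)
    pc = np.where(ok, p_c, np.nan).reshape(nr, nc)

    means = wins_a.mean(axis=(1, 2))
    stds = wins_a.std(axis=(1, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        contrast = np.where(means > 0, stds / means, np.nan)
    sr = (pc * contrast.reshape(nr, nc))

    valid = ok.reshape(nr, nc) & (pc >= config.pc_threshold)
    if config.median_test:
        valid &= ~_median_outliers(
            np.where(valid, u, np.nan),
            np.where(valid, v, np.nan),
            config.median_threshold,
            config.median_eps,
        )
    u = np.where(valid, u, np.nan)
    v = np.where(valid, v, np.nan)

    x = cols0 + (ww - 1) / 2.0
    y = rows0 + (wh - 1) / 2.0
    return VelocityField(
        x_px=x, y_px=y, u=u, v=v, pc=pc, sr=sr, valid=valid,
        n_pairs=valid.astype(int),
        pixel_pitch=config.pixel_pitch, frame_rate=config.frame_rate,
        meta={"piv_config": config.to_dict()},
    )


def _tile(frame: np.ndarray, wh: int, ww: int, sy: int, sx: int):
    fh, fw = frame.shape
    rows0 = np.arange(0, fh - wh + 1, sy)
    cols0 = np.arange(0, fw - ww + 1, sx)
    view = np.lib.stride_tricks.sliding_window_view(frame, (wh, ww))
    wins = view[rows0[:, None], cols0[None, :]].reshape(-1, wh, ww).copy()
    return wins, rows0, cols0


def _median_outliers(u, v, threshold: float, eps: float) -> np.ndarray:
    """Normalized median test (3x3 neighbourhood) on both components."""
    r_u = _normalized_median_residual(u, eps)
    r_v = _normalized_median_residual(v, eps)
    resid = np.fmax(r_u, r_v)
    return np.where(np.isnan(resid), False, resid > threshold)


def _normalized_median_residual(comp: np.ndarray, eps: float) -> np.ndarray:
    nr, nc = comp.shape
    padded = np.full((nr + 2, nc + 2), np.nan)
    padded[1:-1, 1:-1] = comp
    neigh = np.empty((8, nr, nc))
    k = 0
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            neigh[k] = padded[1 + dy : 1 + dy + nr, 1 + dx : 1 + dx + nc]
            k += 1
    n_valid = np.sum(~np.isnan(neigh), axis=0)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(neigh, axis=0)
        res_med = np.nanmedian(np.abs(neigh - med), axis=0)
        resid = np.abs(comp - med) / (res_med + eps)
    resid[n_valid < 3] = np.nan  # too few neighbours to judge
    return resid


def ensemble_mean(
    fields: list[VelocityField], min_valid_fraction: float = 0.25
) -> VelocityField:
    """Per-grid-point mean over instantaneous fields, counting valid vectors.

    A point is invalid in the ensemble when it is valid in fewer than
    ``min_valid_fraction`` of the fields.
    """
    if not fields:
        raise ValueError("need at least one field")
    ref = fields[0]
    for f in fields[1:]:
        if f.shape != ref.shape or not np.array_equal(f.x_px, ref.x_px):
            raise ValueError("all fields must share the same grid")
    u = np.stack([f.u for f in fields])
    v = np.stack([f.v for f in fields])
    pc = np.stack([f.pc for f in fields])
    sr = np.stack([f.sr for f in fields])
    count = np.stack([f.valid for f in fields]).sum(axis=0)
    valid = count >= max(1, int(np.ceil(min_valid_fraction * len(fields))))
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        u_m = np.where(valid, np.nanmean(u, axis=0), np.nan)
        v_m = np.where(valid, np.nanmean(v, axis=0), np.nan)
        pc_m = np.nanmean(pc, axis=0)
        sr_m = np.nanmean(sr, axis=0)
    return VelocityField(
        x_px=ref.x_px, y_px=ref.y_px, u=u_m, v=v_m, pc=pc_m, sr=sr_m,
        valid=valid, n_pairs=count,
        pixel_pitch=ref.pixel_pitch, frame_rate=ref.frame_rate,
        meta={"ensemble_size": len(fields), **ref.meta},
    )


def to_physical(
    field_px: VelocityField,
    pixel_pitch: float | None = None,
    frame_rate: float | None = None,
) -> VelocityField:
    """Attach physical velocities: v[mm/s] = d[px/frame] * pitch[um/px] * rate / 1000."""
    pitch = pixel_pitch if pixel_pitch is not None else field_px.pixel_pitch
    rate = frame_rate if frame_rate is not None else field_px.frame_rate
    if not pitch or not rate or pitch <= 0 or rate <= 0:
        raise ValueError("pixel_pitch and frame_rate must be positive")
    scale = pitch * rate / 1000.0
    out = VelocityField(
        x_px=field_px.x_px, y_px=field_px.y_px,
        u=field_px.u, v=field_px.v, pc=field_px.pc, sr=field_px.sr,
        valid=field_px.valid, n_pairs=field_px.n_pairs,
        pixel_pitch=pitch, frame_rate=rate,
        u_mms=field_px.u * scale, v_mms=field_px.v * scale,
        meta=dict(field_px.meta),
    )
    return out
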