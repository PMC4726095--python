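"""Synthetic X-ray microbubble flow scenes with known ground truth.

Emulates projection imaging of microbubble tracers advected through a straight
cylindrical vessel hidden behind static tissue-like structure: bubbles are
tracked in 3D cylinder coordinates, advected by the blunted power-law profile
``u(r) = V_max (1 - (r/R)^K)``, and rendered orthographically as bright-rim /
dark-core templates on top of a static background with multiplicative
illumination nonuniformity and additive sensor noise.

The renderer is phenomenological: bubbles are drawn as difference-of-Gaussians
rings that mimic the rim/core appearance of phase-contrast bubble speckle. No
wave-optics propagation is simulated, and all bubbles render equally sharp
(projection imaging has no focal plane).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .stack import ImageStack

__all__ = [
    "SceneConfig",
    "SyntheticScene",
    "GroundTruth",
    "make_scene",
    "advect",
    "render",
    "generate_sequence",
]


@dataclass
class SceneConfig:
    """Ground-truth description of a synthetic flow scene.

    Units: lengths in micrometres, velocities in mm/s, time in seconds,
    intensities in detector counts. ``bluntness_k`` >= 1 controls the profile
    shape (2 = parabolic Poiseuille flow; larger = blunter, more plug-like,
    typical of shear-thinning blood).
    """

    frame_shape: tuple[int, int] = (1024, 1024)
    pixel_pitch: float = 1.8994          # um/px (1945 um field of view / 1024 px)
    frame_rate: float = 1000.0           # frames/s
    vessel_radius: float = 500.0         # R, um
    vessel_center_row: float | None = None  # px; default = frame centre row
    vessel_axis: int = 1                 # image axis along flow (1 = horizontal)
    v_max: float = 10.0                  # centreline velocity, mm/s
    bluntness_k: float = 3.31            # K >= 1
    bubble_mean_diameter: float = 13.3   # um
    bubble_diameter_cv: float = 0.15     # lognormal coefficient of variation
    bubble_count: int = 8000             # bubbles in the cylinder volume
    rim_amplitude: float = 300.0         # bright-rim template amplitude, counts
    core_amplitude: float = 480.0        # dark-core template amplitude, counts
    background_level: float = 2000.0     # static transmission pedestal, counts
    background_amplitude: float = 130.0  # sd of static tissue structure, counts
    background_scale: float = 3.0        # correlation length of structure, px
    illumination_gradient: float = 0.10  # fractional peak-to-peak nonuniformity
    noise_sigma: float = 160.0           # additive Gaussian noise sd, counts
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vessel_radius <= 0:
            raise ValueError("vessel_radius must be positive")
        if self.bluntness_k < 1:
            raise ValueError("bluntness K must be >= 1")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.bubble_mean_diameter <= 0:
            raise ValueError("bubble_mean_diameter must be positive")
        if self.bubble_count < 0:
            raise ValueError("bubble_count must be >= 0")
        if len(self.frame_shape) != 2 or min(self.frame_shape) <= 0:
            raise ValueError("frame_shape must be two positive dimensions")
        if self.vessel_axis not in (0, 1):
            raise ValueError("vessel_axis must be 0 or 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        self.frame_shape = tuple(int(d) for d in self.frame_shape)

    # internal working frame: flow along columns; axis 0 swap happens in render
    @property
    def _work_shape(self) -> tuple[int, int]:
        h, w = self.frame_shape
        return (h, w) if self.vessel_axis == 1 else (w, h)

    @property
    def center_row(self) -> float:
        if self.vessel_center_row is not None:
            return float(self.vessel_center_row)
        return self._work_shape[0] / 2.0

    @property
    def fov_length_um(self) -> float:
        """Extent of the field of view along the flow axis, um."""
        return self._work_shape[1] * self.pixel_pitch

    @property
    def axial_pad_um(self) -> float:
        """Margin beyond the field of view so bubbles enter/exit smoothly."""
        per_frame = self.v_max * 1000.0 / self.frame_rate  # um per frame
        return 3.0 * self.bubble_mean_diameter + per_frame

    @property
    def max_count(self) -> int:
        return 2 ** self.bit_depth - 1

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticScene:
    """Bubble ensemble in cylinder coordinates plus frozen static fields.

    ``s`` is the axial coordinate along flow, ``r`` the radial distance from
    the vessel axis, ``theta`` the azimuth about the flow axis (the transverse
    in-image offset is ``r cos(theta)``, the line-of-sight depth ``r
    sin(theta)``); all lengths in micrometres. The background and illumination
    fields and the random stream are frozen at creation.
    """

    s: np.ndarray
    r: np.ndarray
    theta: np.ndarray
    diameters: np.ndarray
    background: np.ndarray
    illumination: np.ndarray
    rng: np.random.Generator

    @property
    def n_bubbles(self) -> int:
        return self.s.size


@dataclass
class GroundTruth:
    """Analytic truth for a generated sequence.

    ``amassed_mm_s`` is the line-of-sight (chord) averaged velocity profile
    ``V_max * alpha(|x|/R, K)`` sampled at transverse offsets ``x_um`` from the
    vessel axis — the quantity a projection PIV measurement converges to.
    """

    config: SceneConfig
    x_um: np.ndarray
    amassed_mm_s: np.ndarray
    positions: np.ndarray | None = None  # (n_frames, 3, n_bubbles): s, r, theta


def make_scene(config: SceneConfig) -> SyntheticScene:
    """Sample the bubble ensemble and freeze the static fields.

    Bubbles are uniform over the cylinder volume: uniform in the axial
    coordinate and azimuth, and uniform in r^2 so the number per unit
    cross-sectional area is constant.
    """
    rng = np.random.default_rng(config.seed)
    n = config.bubble_count
    pad = config.axial_pad_um
    s = rng.uniform(-pad, config.fov_length_um + pad, size=n)
    r = config.vessel_radius * np.sqrt(rng.uniform(0.0, 1.0, size=n))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    diameters = _sample_diameters(rng, n, config)

    h, w = config._work_shape
    if config.background_amplitude > 0:
        raw = rng.standard_normal((h, w))
        smooth = gaussian_filter(raw, config.background_scale, mode="reflect")
        smooth /= smooth.std()
        background = config.background_level + config.background_amplitude * smooth
    else:
        background = np.full((h, w), float(config.background_level))

    rows = np.linspace(-0.5, 0.5, h)[:, None]
    cols = np.linspace(-0.5, 0.5, w)[None, :]
    g = config.illumination_gradient
    illumination = 1.0 + g * cols + 0.25 * g * rows
    return SyntheticScene(s, r, theta, diameters, background, illumination, rng)


def _sample_diameters(rng: np.random.Generator, n: int, config: SceneConfig) -> np.ndarray:
    mean, cv = config.bubble_mean_diameter, config.bubble_diameter_cv
    if cv <= 0:
        return np.full(n, float(mean))
    sigma2 = np.log1p(cv ** 2)
    mu = np.log(mean) - 0.5 * sigma2
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def velocity_law(r: np.ndarray, config: SceneConfig) -> np.ndarray:
    """Axial bubble speed u(r) = V_max (1 - (r/R)^K), in um/s."""
    frac = np.clip(np.asarray(r, dtype=float) / config.vessel_radius, 0.0, 1.0)
    return config.v_max * 1000.0 * (1.0 - frac ** config.bluntness_k)


def _sample_inflow_radius(rng: np.random.Generator, n: int, config: SceneConfig) -> np.ndarray:
    """Radii of bubbles arriving at the inflow plane: density p(r) ∝ r·u(r).

    Faster streamlines deliver proportionally more bubbles per unit time, so
    flux-weighted arrivals are exactly what keeps the in-view distribution
    uniform per unit cross-sectional area (stationary) while still refreshing
    each recycled bubble's radius. Rejection sampling from the uniform-in-area
    proposal with acceptance probability u(r)/V_max.
    """
    out = np.empty(n)
    filled = 0
    frac_pow = config.bluntness_k
    while filled < n:
        cand = np.sqrt(rng.uniform(size=n - filled))  # r/R, uniform in area
        accept = rng.uniform(size=cand.size) < (1.0 - cand ** frac_pow)
        hits = cand[accept]
        out[filled : filled + hits.size] = hits
        filled += hits.size
    return config.vessel_radius * out


def advect(scene: SyntheticScene, dt: float, config: SceneConfig) -> SyntheticScene:
    """Advance every bubble axially by u(r) * dt; recycle those leaving the view.

    Bubbles crossing the outflow edge re-enter at the inflow edge with a fresh
    transverse position: the radius is redrawn from the flux-weighted inflow
    density p(r) ∝ r·u(r) and the azimuth uniformly, both from the scene's
    seeded stream. This boundary condition keeps the uniform-per-area bubble
    distribution — and hence the steady amassed profile — exactly stationary.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    s = scene.s + velocity_law(scene.r, config) * dt
    r = scene.r
    theta = scene.theta
    pad = config.axial_pad_um
    hi = config.fov_length_um + pad
    wrap = s >= hi
    if np.any(wrap):
        n_wrap = int(wrap.sum())
        s = s.copy()
        r = r.copy()
        theta = theta.copy()
        s[wrap] -= config.fov_length_um + 2.0 * pad
        r[wrap] = _sample_inflow_radius(scene.rng, n_wrap, config)
        theta[wrap] = scene.rng.uniform(0.0, 2.0 * np.pi, size=n_wrap)
    return SyntheticScene(
        s, r, theta, scene.diameters, scene.background, scene.illumination, scene.rng
    )


def render(scene: SyntheticScene, config: SceneConfig) -> np.ndarray:
    """Project the scene to one 2D frame (float64, clipped to the bit depth).

    Each bubble is a radially symmetric difference-of-Gaussians template
    (bright rim sigma = 0.35 d, dark core sigma = 0.20 d, in pixels) placed at
    its sub-pixel projected position; overlapping templates sum. The static
    background is added, the multiplicative illumination applied, and Gaussian
    noise of sd ``noise_sigma`` drawn from the scene's stream.
    """
    h, w = config._work_shape
    canvas = scene.background.copy()
    pitch = config.pixel_pitch

    rows_c = config.center_row + (scene.r * np.cos(scene.theta)) / pitch
    cols_c = scene.s / pitch
    d_px = scene.diameters / pitch
    sig_r = 0.35 * d_px
    sig_c = 0.20 * d_px

    # vectorized scatter-add of all templates, chunked to bound memory
    a_rim, a_core = config.rim_amplitude, config.core_amplitude
    if scene.n_bubbles:
        hmax = int(np.ceil(2.5 * sig_r.max()))
        offs = np.arange(-hmax, hmax + 1)
        for lo in range(0, scene.n_bubbles, 2048):
            sl = slice(lo, min(lo + 2048, scene.n_bubbles))
            gy = np.floor(rows_c[sl])[:, None].astype(int) + offs[None, :]
            gx = np.floor(cols_c[sl])[:, None].astype(int) + offs[None, :]
            dy = (gy - rows_c[sl, None]).astype(np.float32)
            dx = (gx - cols_c[sl, None]).astype(np.float32)
            rho2 = dy[:, :, None] ** 2 + dx[:, None, :] ** 2
            s_r = sig_r[sl, None, None].astype(np.float32)
            s_c = sig_c[sl, None, None].astype(np.float32)
            patch = a_rim * np.exp(-rho2 / (2.0 * s_r * s_r))
            patch -= a_core * np.exp(-rho2 / (2.0 * s_c * s_c))
            inside = ((gy >= 0) & (gy < h))[:, :, None] & ((gx >= 0) & (gx < w))[:, None, :]
            patch[~inside] = 0.0
            idx = (np.clip(gy, 0, h - 1)[:, :, None] * w
                   + np.clip(gx, 0, w - 1)[:, None, :])
            canvas += np.bincount(
                idx.ravel(), weights=patch.ravel().astype(float), minlength=h * w
            ).reshape(h, w)

    frame = canvas * scene.illumination
    if config.noise_sigma > 0:
        frame = frame + scene.rng.normal(0.0, config.noise_sigma, size=frame.shape)
    frame = np.clip(frame, 0.0, float(config.max_count))
    if config.vessel_axis == 0:
        frame = frame.T
    return frame


def generate_sequence(
    config: SceneConfig, n_frames: int, record_positions: bool = True
) -> tuple[ImageStack, GroundTruth]:
    """Render an image sequence by alternating advection and rendering.

    Returns the quantized (uint16) stack and the analytic ground truth,
    including the amassed (line-of-sight averaged) velocity profile sampled
    across the vessel. Fully deterministic: the same (config, n_frames) yields
    a byte-identical stack.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2 (PIV needs image pairs)")
    scene = make_scene(config)
    dt = 1.0 / config.frame_rate
    frames = np.empty((n_frames, *config.frame_shape), dtype=np.uint16)
    positions = (
        np.empty((n_frames, 3, scene.n_bubbles)) if record_positions else None
    )
    for i in range(n_frames):
        if i > 0:
            scene = advect(scene, dt, config)
        if positions is not None:
            positions[i, 0] = scene.s
            positions[i, 1] = scene.r
            positions[i, 2] = scene.theta
        frames[i] = np.round(render(scene, config)).astype(np.uint16)

    from .profile import alpha  # deferred: profile does not import scene

    x = np.linspace(-config.vessel_radius, config.vessel_radius, 201)
    xi = np.minimum(np.abs(x) / config.vessel_radius, 1.0)
    amassed = config.v_max * alpha(xi, config.bluntness_k)
    stack = ImageStack(
        frames,
        config.pixel_pitch,
        dt,
        meta={"scene_config": config.to_dict(), "seed": config.seed},
    )
    return stack, GroundTruth(config, x, amassed, positions)


def scaled_scene(config: SceneConfig, **overrides) -> SceneConfig:
    """Convenience: derive a modified copy of a scene configuration."""
    return replace(config, **overrides)
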