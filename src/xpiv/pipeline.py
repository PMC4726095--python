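"""End-to-end orchestration: restore -> metrics -> PIV -> profile inversion.

:func:`run_pipeline` chains the full measurement on an image stack (real or
synthetic): image restoration, speckle quality metrics, two-frame
cross-correlation PIV over an ensemble of frame pairs, ensemble averaging,
conversion to physical units, buoyancy correction, and amassed-profile
inversion for (V_max, K, x0) and the flow rate Q.

:func:`measurability_sweep` repeats the measurement over a ladder of
inter-frame displacement settings and reports mean P_c, speckle contrast C,
SR = P_c * C and the measured flow rate per setting — the experiment that
locates the maximum measurable velocity (the largest setting whose mean P_c
still exceeds 0.5).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .piv import PivConfig, VelocityField, compute_field, ensemble_mean, to_physical
from .profile import (
    AmassedProfileFit,
    AmassedProfileModel,
    StokesParams,
    buoyancy_correct,
    stokes_terminal_velocity,
)
from .restore import RestorationConfig, restore
from .scene import GroundTruth, SceneConfig, generate_sequence
from .speckle import SpeckleReport, measure_speckle, sr_value
from .stack import ImageStack, _jsonable

__all__ = [
    "RunConfig",
    "SweepRow",
    "PipelineResult",
    "run_pipeline",
    "run_piv_ensemble",
    "measurability_sweep",
    "vessel_roi",
    "config_hash",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full configuration of one pipeline run.

    ``scene`` is used when no stack is supplied (simulate-then-analyze mode).
    ``profile_radius_um`` fixes R in the profile fit; when None it defaults to
    the scene's vessel radius (synthetic mode) or is fitted as a free
    parameter.
    """

    scene: SceneConfig = field(default_factory=SceneConfig)
    restoration: RestorationConfig = field(default_factory=RestorationConfig)
    piv: PivConfig = field(default_factory=PivConfig)
    stokes: StokesParams = field(default_factory=StokesParams)
    n_frames: int = 400
    ensemble_size: int = 200
    metrics_frames: int = 100
    apply_buoyancy: bool = True
    profile_radius_um: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        # one seed drives everything; the scene echoes it
        self.scene = replace(self.scene, seed=self.seed)

    def to_dict(self) -> dict:
        return {
            "scene": self.scene.to_dict(),
            "restoration": self.restoration.to_dict(),
            "piv": self.piv.to_dict(),
            "stokes": dataclasses.asdict(self.stokes),
            "n_frames": self.n_frames,
            "ensemble_size": self.ensemble_size,
            "metrics_frames": self.metrics_frames,
            "apply_buoyancy": self.apply_buoyancy,
            "profile_radius_um": self.profile_radius_um,
            "seed": self.seed,
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "scene" in kwargs:
            scene = dict(kwargs.pop("scene"))
            if "frame_shape" in scene:
                scene["frame_shape"] = tuple(scene["frame_shape"])
            kwargs["scene"] = SceneConfig(**scene)
        if "restoration" in kwargs:
            kwargs["restoration"] = RestorationConfig(**kwargs.pop("restoration"))
        if "piv" in kwargs:
            piv = dict(kwargs.pop("piv"))
            for key in ("window_size", "max_displacement"):
                if piv.get(key) is not None:
                    piv[key] = tuple(piv[key])
            kwargs["piv"] = PivConfig(**piv)
        if "stokes" in kwargs:
            st = dict(kwargs.pop("stokes"))
            if "gravity_direction" in st:
                st["gravity_direction"] = tuple(st["gravity_direction"])
            kwargs["stokes"] = StokesParams(**st)
        return cls(**kwargs)


@dataclass
class SweepRow:
    """One point of the measurability sweep."""

    displacement_px: float       # input centreline displacement per frame
    v_max_mms: float             # corresponding centreline velocity
    input_q_ml_min: float        # ground-truth flow rate of the setting
    mean_pc: float
    mean_contrast: float
    mean_sr: float
    measured_q_ml_min: float     # NaN when the profile fit fails
    valid_fraction: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    """Bundle of everything one pipeline run produced."""

    speckle_raw: SpeckleReport
    speckle_restored: SpeckleReport
    field_px: VelocityField
    field_mms: VelocityField
    profile_fit: AmassedProfileFit | None
    stokes_v_t_mms: float
    provenance: dict
    ground_truth: GroundTruth | None = None
    fit_error: str | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "speckle_raw": self.speckle_raw.to_dict(),
            "speckle_restored": self.speckle_restored.to_dict(),
            "profile_fit": None if self.profile_fit is None else self.profile_fit.to_dict(),
            "stokes_v_t_mms": self.stokes_v_t_mms,
            "mean_pc": float(np.nanmean(self.field_px.pc)),
            "mean_sr": float(np.nanmean(self.field_px.sr)),
            "valid_fraction": float(np.mean(self.field_px.valid)),
            "fit_error": self.fit_error,
            "provenance": _jsonable(self.provenance),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(_jsonable(config.to_dict()), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def vessel_roi(scene: SceneConfig, frac: float = 0.7) -> tuple[int, int, int, int]:
    """ROI (row0, col0, h, w) inside the vessel lumen for speckle metrics."""
    h, w = scene._work_shape
    r_px = scene.vessel_radius / scene.pixel_pitch
    half = max(8, int(frac * min(r_px, h / 2)))
    r0 = int(np.clip(scene.center_row - half, 0, h - 16))
    r1 = int(np.clip(scene.center_row + half, r0 + 16, h))
    c0, c1 = int(0.1 * w), int(0.9 * w)
    return r0, c0, r1 - r0, c1 - c0


def run_piv_ensemble(
    stack: ImageStack, piv_config: PivConfig, ensemble_size: int
) -> tuple[VelocityField, list[VelocityField]]:
    """Ensemble-mean field over non-overlapping consecutive frame pairs."""
    n_pairs = min(ensemble_size, len(stack) // 2)
    if n_pairs < 1:
        raise ValueError("stack too short for a single frame pair")
    fields = [
        compute_field(stack.frames[2 * i], stack.frames[2 * i + 1], piv_config)
        for i in range(n_pairs)
    ]
    return ensemble_mean(fields), fields


def run_pipeline(
    config: RunConfig,
    stack: ImageStack | None = None,
    compare_raw_piv: bool = False,
) -> PipelineResult:
    """Full measurement chain on a stack (generated from config when absent)."""
    ground_truth = None
    if stack is None:
        stack, ground_truth = generate_sequence(
            config.scene, config.n_frames, record_positions=False
        )

    roi = vessel_roi(config.scene)
    n_metric = min(config.metrics_frames, len(stack))
    speckle_raw = measure_speckle(stack, roi=roi, n_frames=n_metric)

    restored = restore(stack, config.restoration)
    speckle_restored = measure_speckle(restored, roi=roi, n_frames=n_metric)

    piv_cfg = replace(
        config.piv, pixel_pitch=stack.pixel_pitch, frame_rate=stack.frame_rate
    )
    field, _ = run_piv_ensemble(restored, piv_cfg, config.ensemble_size)
    field_mms = to_physical(field)

    v_t = stokes_terminal_velocity(config.stokes)
    if config.apply_buoyancy:
        field_mms = buoyancy_correct(field_mms, v_t, config.stokes.gravity_direction)

    radius = config.profile_radius_um
    if radius is None and ground_truth is not None:
        radius = config.scene.vessel_radius

    profile_fit = None
    fit_error = None
    try:
        model = AmassedProfileModel.from_field(field_mms, radius=radius)
        profile_fit = model.fit().fit
    except (ValueError, RuntimeError) as exc:
        fit_error = str(exc)
        logger.warning("profile fit failed: %s", exc)

    provenance = {
        "seed": config.seed,
        "config_hash": config_hash(config),
        "n_frames": len(stack),
        "ensemble_pairs": int(field.meta.get("ensemble_size", 0)),
    }
    if compare_raw_piv:
        raw_field, _ = run_piv_ensemble(stack, piv_cfg, min(20, config.ensemble_size))
        provenance["sr_raw"] = _mean_sr(raw_field, speckle_raw)
        provenance["sr_processed"] = _mean_sr(field, speckle_restored)

    return PipelineResult(
        speckle_raw=speckle_raw,
        speckle_restored=speckle_restored,
        field_px=field,
        field_mms=field_mms,
        profile_fit=profile_fit,
        stokes_v_t_mms=v_t,
        provenance=provenance,
        ground_truth=ground_truth,
        fit_error=fit_error,
    )


def _mean_sr(field: VelocityField, report: SpeckleReport) -> float:
    pc = float(np.nanmean(np.clip(field.pc, 0.0, 1.0)))
    return sr_value(pc, report.contrast)


def displacement_to_v_max(displacement_px: float, scene: SceneConfig) -> float:
    """Centreline displacement in px/frame -> V_max in mm/s for a scene."""
    return displacement_px * scene.pixel_pitch * scene.frame_rate / 1000.0


def measurability_sweep(
    base_config: RunConfig,
    displacements_px: list[float],
    in_vessel_only: bool = True,
) -> tuple[list[SweepRow], float]:
    """Run the pipeline across displacement settings; find the P_c >= 0.5 limit.

    Each setting fixes the ground-truth centreline displacement (px/frame);
    the sweep records mean P_c, mean speckle contrast, SR and the measured
    flow rate. Returns the rows plus the largest setting whose mean P_c is
    still >= 0.5 (NaN when none qualifies). Measured flow rates are reported
    as computed — underestimates are not clipped.
    """
    if len(displacements_px) < 3:
        raise ValueError("sweep needs at least 3 settings")
    rows: list[SweepRow] = []
    for disp in displacements_px:
        v_max = displacement_to_v_max(disp, base_config.scene)
        cfg = replace(base_config, scene=replace(base_config.scene, v_max=v_max))
        result = run_pipeline(cfg)
        field = result.field_px
        pc = field.pc
        if in_vessel_only:
            mask = _vessel_rows_mask(field, cfg.scene)
            pc = pc[mask]
            valid = field.valid[mask]
        else:
            valid = field.valid
        mean_pc = float(np.nanmean(pc))
        contrast = result.speckle_restored.contrast
        q_meas = (
            result.profile_fit.q_ml_min if result.profile_fit is not None else np.nan
        )
        from .profile import flow_rate

        rows.append(
            SweepRow(
                displacement_px=float(disp),
                v_max_mms=v_max,
                input_q_ml_min=flow_rate(
                    v_max, cfg.scene.bluntness_k, cfg.scene.vessel_radius
                ),
                mean_pc=mean_pc,
                mean_contrast=contrast,
                mean_sr=sr_value(float(np.clip(mean_pc, 0, 1)), contrast),
                measured_q_ml_min=float(q_meas),
                valid_fraction=float(np.mean(valid)),
            )
        )
    measurable = [r.displacement_px for r in rows if r.mean_pc >= 0.5]
    limit = max(measurable) if measurable else float("nan")
    return rows, limit


def _vessel_rows_mask(field: VelocityField, scene: SceneConfig) -> np.ndarray:
    r_px = scene.vessel_radius / scene.pixel_pitch
    rows_in = np.abs(field.y_px - scene.center_row) <= 0.8 * r_px
    return np.broadcast_to(rows_in[:, None], field.shape)
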