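"""End-to-end orchestration: preprocess -> template -> sweep -> report.

The pipeline mirrors a minimal presurgical workflow: discard the first
frames of the BOLD series (scanner equilibration), build a brain mask
from the mean image, smooth, grow the tumor template if none is given,
sweep the ICA model order with DICI scoring, and write the report,
best-component volumes, overlay and (optionally) the seed-correlation
comparison.  A JSON manifest records the configuration, stage wall
times and checksums of every output for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dici import DICIConfig, render_overlay, sweep_and_select, write_dici_report, binarize_component
from .errors import ConfigError, FormatError
from .ica import DecompositionConfig
from .imaging import BinaryMask, Series4D, Volume3D, compute_brain_mask, smooth_gaussian, write_volume
from .seed import SeedSpec, seed_correlation, threshold_correlation
from .template import GrowthParams, TumorTemplate, grow_voi

log = logging.getLogger("tumorica")

__all__ = ["PipelineConfig", "RunManifest", "preprocess", "run_pipeline", "motion_gate"]

MOTION_TRANSLATION_LIMIT_MM = 3.0
MOTION_ROTATION_LIMIT_DEG = 3.0


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs."""

    out_dir: Path
    bold: object = None            # path or Series4D
    anat: object = None            # path or Volume3D (template drawing / overlay)
    template: object = None        # path or BinaryMask/TumorTemplate
    growth: GrowthParams | None = None
    seed_spec: SeedSpec | None = None
    n_discard_frames: int = 4
    fwhm_mm: float = 6.0
    mask_frac: float = 0.2
    decomposition: DecompositionConfig = field(
        default_factory=lambda: DecompositionConfig(tncs=10))
    dici: DICIConfig = field(default_factory=DICIConfig)
    rng_seed: int = 0


@dataclass
class RunManifest:
    config: dict
    version: str
    stage_seconds: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def preprocess(series: Series4D, cfg: PipelineConfig) -> tuple[Series4D, BinaryMask]:
    """Frame discard, brain-mask derivation and spatial smoothing."""
    if cfg.n_discard_frames >= series.n_frames:
        raise ConfigError(
            f"cannot discard {cfg.n_discard_frames} of {series.n_frames} frames")
    if cfg.n_discard_frames > 0:
        series = Series4D(series.grid, series.data[..., cfg.n_discard_frames:],
                          tr_seconds=series.tr_seconds)
    mask = compute_brain_mask(series.mean_volume(), frac=cfg.mask_frac)
    if cfg.fwhm_mm > 0:
        series = smooth_gaussian(series, cfg.fwhm_mm)
    else:
        warnings.warn("fwhm_mm <= 0: smoothing skipped", stacklevel=2)
    return series, mask


def motion_gate(params) -> dict:
    """Screen externally supplied rigid-body motion estimates.

    ``params`` is an (n_frames, 6) table: three translations in mm, then
    three rotations in degrees.  The run fails the gate if any absolute
    translation exceeds 3 mm or any absolute rotation exceeds 3 degrees.
    """
    if isinstance(params, pd.DataFrame):
        params = params.to_numpy()
    params = np.asarray(params, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6 or params.shape[0] == 0:
        raise FormatError("motion parameters must be a nonempty n_frames x 6 table")
    max_trans = float(np.abs(params[:, :3]).max())
    max_rot = float(np.abs(params[:, 3:]).max())
    return {
        "max_translation_mm": max_trans,
        "max_rotation_deg": max_rot,
        "passed": max_trans <= MOTION_TRANSLATION_LIMIT_MM
        and max_rot <= MOTION_ROTATION_LIMIT_DEG,
    }


def _load_series(obj) -> Series4D:
    if isinstance(obj, Series4D):
        return obj
    from .imaging import read_volume

    vol = read_volume(obj)
    if not isinstance(vol, Series4D):
        raise ConfigError(f"{obj!r} is not a 4D series")
    return vol


def _load_volume(obj) -> Volume3D:
    if isinstance(obj, Volume3D):
        return obj
    from .imaging import read_volume

    vol = read_volume(obj)
    if not isinstance(vol, Volume3D):
        raise ConfigError(f"{obj!r} is not a 3D volume")
    return vol


def _load_template(obj) -> TumorTemplate:
    if isinstance(obj, TumorTemplate):
        return obj
    if isinstance(obj, BinaryMask):
        return TumorTemplate(mask=obj)
    from .imaging import read_volume

    vol = _load_volume(obj)
    return TumorTemplate(mask=BinaryMask(vol.grid, vol.data > 0.5))


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute the full workflow described by ``cfg``; reproducible per seed."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=_config_snapshot(cfg), version=__version__)
    stage = _StageTimer(manifest)

    try:
        with stage("preprocess"):
            series = _load_series(cfg.bold)
            series, mask = preprocess(series, cfg)
            write_volume(mask, out_dir / "brain_mask.nii.gz")
            manifest.outputs["brain_mask"] = str(out_dir / "brain_mask.nii.gz")

        with stage("template"):
            if cfg.template is not None:
                template = _load_template(cfg.template)
            elif cfg.growth is not None and cfg.anat is not None:
                template = grow_voi(_load_volume(cfg.anat), cfg.growth)
            else:
                raise ConfigError(
                    "no tumor template given and no (anat, growth) pair to grow one")
            write_volume(template.mask, out_dir / "tumor_template.nii.gz")
            manifest.outputs["tumor_template"] = str(out_dir / "tumor_template.nii.gz")

        with stage("sweep"):
            sel = sweep_and_select(series, mask, template, cfg.decomposition, cfg.dici)
            log.info("optimal TNCs %d, component %d, DICI %.3f",
                     sel.optimal_tncs, sel.best.component_index, sel.best.dici)

        with stage("report"):
            paths = write_dici_report(sel, out_dir)
            manifest.outputs["dici_report_tsv"] = paths["tsv"]
            manifest.outputs["dici_summary_json"] = paths["json"]
            best_map = sel.best_map()
            write_volume(best_map, out_dir / "tumor_component_zmap.nii.gz")
            manifest.outputs["tumor_component_zmap"] = str(out_dir / "tumor_component_zmap.nii.gz")
            best_bin = binarize_component(best_map, cfg.dici)
            write_volume(best_bin, out_dir / "tumor_component_bin.nii.gz")
            manifest.outputs["tumor_component_bin"] = str(out_dir / "tumor_component_bin.nii.gz")
            background = _load_volume(cfg.anat) if cfg.anat is not None \
                else series.mean_volume()
            overlay = render_overlay(best_map, background, cfg.dici,
                                     out_dir / "tumor_overlay.png")
            manifest.outputs["overlay_png"] = overlay
            manifest.summary = {
                "optimal_tncs": sel.optimal_tncs,
                "best_component_index": sel.best.component_index,
                "best_dici": sel.best.dici,
            }

        if cfg.seed_spec is not None:
            with stage("seed_baseline"):
                cmap = seed_correlation(series, mask, cfg.seed_spec)
                rvol = Volume3D(series.grid, np.nan_to_num(cmap.r, nan=0.0))
                write_volume(rvol, out_dir / "seed_correlation_r.nii.gz")
                manifest.outputs["seed_correlation_r"] = str(out_dir / "seed_correlation_r.nii.gz")
                for thr in cfg.seed_spec.r_thresholds:
                    m = threshold_correlation(cmap, thr)
                    p = out_dir / f"seed_mask_r{thr:g}.nii.gz"
                    write_volume(m, p)
                    manifest.outputs[f"seed_mask_r{thr:g}"] = str(p)
    except Exception as exc:
        _write_manifest(manifest, out_dir, failed_stage=stage.current, error=str(exc))
        raise

    _write_manifest(manifest, out_dir)
    return manifest


def _config_snapshot(cfg: PipelineConfig) -> dict:
    snap = {}
    for k, v in vars(cfg).items():
        if hasattr(v, "__dataclass_fields__"):
            snap[k] = asdict(v)
        elif isinstance(v, (Path, str, int, float, bool, tuple, list)) or v is None:
            snap[k] = str(v) if isinstance(v, Path) else v
        else:
            snap[k] = f"<in-memory {type(v).__name__}>"
    return snap


class _StageTimer:
    def __init__(self, manifest: RunManifest):
        self.manifest = manifest
        self.current: str | None = None

    def __call__(self, name: str):
        self.current = name
        timer = self

        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                log.info("stage %s ...", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timer.manifest.stage_seconds[name] = round(
                    time.perf_counter() - self_inner.t0, 3)
                return False

        return _Ctx()


def _write_manifest(manifest: RunManifest, out_dir: Path,
                    failed_stage: str | None = None, error: str | None = None):
    for key, path in manifest.outputs.items():
        p = Path(path)
        if p.exists():
            manifest.checksums[key] = _sha256(p)
    payload = asdict(manifest)
    if failed_stage is not None:
        payload["failed_stage"] = failed_stage
        payload["error"] = error
    (out_dir / "manifest.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
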