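"""Discriminability-Index-based Component Identification (DICI).

Each z-standardised spatial component is binarised (positive tail above a
z threshold, small clusters removed) and compared with a binary tumor
template inside the brain mask as a signal-detection problem:

    HR  = |bin ∩ template| / |template|          (hit rate / sensitivity)
    FAR = |bin \\ template| / |brain \\ template|  (false-alarm rate)
    DICI = z(HR) - z(FAR),  z = Phi^{-1} the standard-normal quantile

A high DICI means the component covers the template well (HR high) while
staying out of the rest of the brain (FAR low); the d-prime form weights
the two rates on the normal-quantile scale, so it is robust to extreme
map values in a way plain spatial correlation is not.

Model-order selection: the decomposition is repeated across a grid of
total-number-of-components (TNCs) settings; for each setting the
component with the largest DICI is a candidate, and the candidate with
the globally largest DICI fixes both the optimal TNCs and the final
tumor-related component.  The four largest DICIs per TNCs and their
pairwise differences (ΔDICI) are reported as separability diagnostics.

Degenerate rates: an exactly 0 or 1 rate would map to an infinite
quantile, so rates are clamped to ``[1/(2N), 1 - 1/(2N)]`` with ``N`` the
respective denominator (the standard 1/(2N) correction for extreme
proportions); a component whose binarised map is entirely empty is marked
invalid and excluded from ranking instead of being scored at -inf.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm

from .errors import ConfigError, DegenerateTemplateError, NoTumorComponentError
from .ica import ComponentSet, DecompositionConfig, decompose
from .imaging import BinaryMask, Series4D, Volume3D
from .template import TumorTemplate

__all__ = [
    "DICIConfig",
    "ComponentScore",
    "SelectionResult",
    "binarize_component",
    "score_component",
    "score_component_set",
    "select_from_components",
    "sweep_and_select",
    "write_dici_report",
    "render_overlay",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class DICIConfig:
    """Binarisation, sweep and reporting settings for DICI identification."""

    z_threshold: float = 1.0
    min_cluster_voxels: int = 20     # clusters must be strictly larger to survive
    connectivity: int = 26
    tncs_grid: tuple[int, ...] = tuple(range(10, 101, 10))
    viz_threshold: float = 1.5

    def __post_init__(self):
        if self.z_threshold <= 0:
            raise ConfigError("z_threshold must be positive")
        if self.min_cluster_voxels < 0:
            raise ConfigError("min_cluster_voxels must be nonnegative")
        if self.connectivity not in _STRUCTURES:
            raise ConfigError("connectivity must be one of 6, 18, 26")
        grid = tuple(int(t) for t in self.tncs_grid)
        if any(b <= a for a, b in zip(grid, grid[1:])) or not grid:
            raise ConfigError("tncs_grid must be a nonempty strictly increasing sequence")
        object.__setattr__(self, "tncs_grid", grid)


@dataclass(frozen=True)
class ComponentScore:
    """DICI score of one component at one TNCs setting."""

    tncs: int
    component_index: int
    hr: float
    far: float
    z_hr: float
    z_far: float
    dici: float
    n_supra_voxels: int
    valid: bool
    reproducibility: float = float("nan")


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the TNCs sweep: the winning component plus the full report."""

    optimal_tncs: int
    best: ComponentScore
    top4_per_tncs: dict[int, list[ComponentScore]]
    delta_dici: dict[str, float]
    report_table: pd.DataFrame = field(repr=False)
    component_sets: dict[int, ComponentSet] | None = field(default=None, repr=False)

    @property
    def best_component_set(self) -> ComponentSet | None:
        if self.component_sets is None:
            return None
        return self.component_sets[self.optimal_tncs]

    def best_map(self) -> Volume3D:
        cs = self.best_component_set
        if cs is None:
            raise ValueError("component sets were not retained in this result")
        return cs.map_volume(self.best.component_index)


def binarize_component(map_vol: Volume3D | np.ndarray, cfg: DICIConfig,
                       grid=None) -> BinaryMask:
    """Positive-tail binarisation with cluster-extent filtering.

    Keeps voxels with ``z > z_threshold`` and removes connected clusters
    (``cfg.connectivity``) whose size is not strictly greater than
    ``cfg.min_cluster_voxels``.  An empty result is a legal output.
    """
    if isinstance(map_vol, Volume3D):
        data, grid = map_vol.data, map_vol.grid
    else:
        data = np.asarray(map_vol)
        if grid is None:
            raise ValueError("grid is required when passing a bare array")
    supra = data > cfg.z_threshold
    if supra.any() and cfg.min_cluster_voxels > 0:
        labels, n = ndimage.label(supra, structure=_STRUCTURES[cfg.connectivity])
        sizes = np.bincount(labels.ravel())
        keep = sizes > cfg.min_cluster_voxels
        keep[0] = False
        supra = keep[labels]
    return BinaryMask(grid, supra)


def _clamped_rate(count: int, denom: int) -> float:
    """Proportion with the 1/(2N) correction applied only at exactly 0 or 1."""
    rate = count / denom
    if rate == 0.0:
        return 1.0 / (2.0 * denom)
    if rate == 1.0:
        return 1.0 - 1.0 / (2.0 * denom)
    return rate


def score_component(bin_mask: BinaryMask, template: TumorTemplate | BinaryMask,
                    brain: BinaryMask, tncs: int = 0,
                    component_index: int = 0) -> ComponentScore:
    """Confusion counts and DICI of a binarised map against the template.

    All counting is restricted to the brain mask; the template must be a
    proper nonempty subset of it.
    """
    tmpl = template.mask if isinstance(template, TumorTemplate) else template
    if not (bin_mask.grid.same_geometry(tmpl.grid) and bin_mask.grid.same_geometry(brain.grid)):
        raise ConfigError("binarised map, template and brain mask must share one grid")
    t = tmpl.data & brain.data
    b = bin_mask.data & brain.data
    n_template = int(t.sum())
    n_outside = int(brain.data.sum()) - n_template
    if n_template == 0 or n_outside == 0:
        raise DegenerateTemplateError(
            "template must be a nonempty proper subset of the brain mask")
    hit = int((b & t).sum())
    false_alarm = int((b & ~t).sum())
    n_supra = int(b.sum())
    valid = n_supra > 0
    hr = _clamped_rate(hit, n_template)
    far = _clamped_rate(false_alarm, n_outside)
    z_hr = float(norm.ppf(hr))
    z_far = float(norm.ppf(far))
    return ComponentScore(tncs=tncs, component_index=component_index,
                          hr=hr, far=far, z_hr=z_hr, z_far=z_far,
                          dici=z_hr - z_far, n_supra_voxels=n_supra, valid=valid)


def score_component_set(cs: ComponentSet, template, brain: BinaryMask,
                        cfg: DICIConfig, tncs: int | None = None) -> list[ComponentScore]:
    """Score every component of a decomposition, sorted by descending DICI.

    Invalid (empty-after-binarisation) components sort last and keep
    ``valid=False``; ties in DICI break toward the lower component index.
    ``tncs`` labels the scores (defaults to the set's own model order).
    """
    tncs = cs.tncs if tncs is None else int(tncs)
    scores = []
    for i in range(cs.tncs):
        bm = binarize_component(cs.map_volume(i), cfg)
        s = score_component(bm, template, brain, tncs=tncs, component_index=i)
        s = ComponentScore(**{**s.__dict__, "reproducibility": float(cs.reproducibility[i])})
        scores.append(s)
    return sorted(scores, key=lambda s: (not s.valid, -s.dici if s.valid else 0.0,
                                         s.component_index))


def _pairwise_deltas(scores: list[ComponentScore]) -> dict[str, float]:
    labels = ["1st", "2nd", "3rd", "4th"]
    out: dict[str, float] = {}
    for i in range(len(scores)):
        for j in range(i + 1, len(scores)):
            out[f"{labels[i]}-{labels[j]}"] = scores[i].dici - scores[j].dici
    return out


def select_from_components(component_sets: dict[int, ComponentSet], template,
                           brain: BinaryMask, cfg: DICIConfig,
                           keep_component_sets: bool = True) -> SelectionResult:
    """Rank components at every TNCs and pick the global DICI maximiser.

    The rank-1 component of each TNCs is its candidate; the global best
    (ties: lower TNCs, then lower component index) defines the optimal
    TNCs and the final tumor-related component.
    """
    top4: dict[int, list[ComponentScore]] = {}
    rows = []
    candidates: list[ComponentScore] = []
    for tncs in sorted(component_sets):
        scores = score_component_set(component_sets[tncs], template, brain, cfg,
                                     tncs=tncs)
        valid = [s for s in scores if s.valid]
        top = valid[:4]
        top4[tncs] = top
        if valid:
            candidates.append(valid[0])
        for rank, s in enumerate(top, start=1):
            rows.append({"tncs": tncs, "rank": rank, "component_index": s.component_index,
                         "hr": s.hr, "far": s.far, "z_hr": s.z_hr, "z_far": s.z_far,
                         "dici": s.dici, "n_supra_voxels": s.n_supra_voxels,
                         "valid": s.valid})
    if not candidates:
        raise NoTumorComponentError(
            "no component survived binarisation at any TNCs setting; "
            "no tumor-related component could be identified")
    best = max(candidates, key=lambda s: (s.dici, -s.tncs, -s.component_index))
    report = pd.DataFrame(rows, columns=["tncs", "rank", "component_index", "hr", "far",
                                         "z_hr", "z_far", "dici", "n_supra_voxels", "valid"])
    return SelectionResult(
        optimal_tncs=best.tncs, best=best, top4_per_tncs=top4,
        delta_dici=_pairwise_deltas(top4[best.tncs]), report_table=report,
        component_sets=dict(component_sets) if keep_component_sets else None)


def decompose_grid(series: Series4D, mask: BinaryMask, dcfg: DecompositionConfig,
                   tncs_grid) -> dict[int, ComponentSet]:
    """Run the decomposition at every feasible TNCs of the grid.

    Infeasible entries (tncs >= n_frames or >= mask size) are skipped with
    a warning rather than aborting the sweep.
    """
    out: dict[int, ComponentSet] = {}
    for i, tncs in enumerate(tncs_grid):
        if not 2 <= tncs < min(series.n_frames, mask.n_voxels):
            warnings.warn(f"skipping infeasible tncs={tncs} "
                          f"(n_frames={series.n_frames}, mask={mask.n_voxels})",
                          stacklevel=2)
            continue
        cfg = DecompositionConfig(tncs=tncs, n_runs=dcfg.n_runs,
                                  base_rng_seed=dcfg.base_rng_seed + 10_000 * i,
                                  max_iter=dcfg.max_iter,
                                  convergence_tol=dcfg.convergence_tol)
        out[tncs] = decompose(series, mask, cfg)
    if not out:
        raise ConfigError("no feasible TNCs in the requested grid")
    return out


def sweep_and_select(series: Series4D, mask: BinaryMask, template,
                     dcfg: DecompositionConfig, icfg: DICIConfig) -> SelectionResult:
    """Full model-order sweep: decompose at every TNCs, score, select."""
    sets = decompose_grid(series, mask, dcfg, icfg.tncs_grid)
    return select_from_components(sets, template, mask, icfg)


def write_dici_report(sel: SelectionResult, out_dir) -> dict:
    """Write the per-TNCs report TSV and a JSON summary; returns the paths."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / "dici_report.tsv"
    sel.report_table.to_csv(tsv, sep="\t", index=False, float_format="%.6f")
    summary = {
        "optimal_tncs": sel.optimal_tncs,
        "best_component_index": sel.best.component_index,
        "best_dici": sel.best.dici,
        "best_hr": sel.best.hr,
        "best_far": sel.best.far,
        "delta_dici": sel.delta_dici,
    }
    js = out_dir / "dici_summary.json"
    js.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return {"tsv": str(tsv), "json": str(js)}


def render_overlay(best_map: Volume3D, anat: Volume3D, icfg: DICIConfig,
                   out_path, title: str = "tumor-related component") -> str:
    """Orthogonal-slice montage of the component over the anatomical image.

    The component is shown thresholded at ``icfg.viz_threshold`` (no
    cluster filtering, matching the visualisation convention) next to the
    unthresholded map.  An empty suprathreshold set still produces a
    montage, with a warning.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not best_map.grid.same_geometry(anat.grid):
        raise ConfigError("component map and anatomical image must share one grid")
    supra = best_map.data > icfg.viz_threshold
    if not supra.any():
        warnings.warn("no voxel exceeds the visualisation threshold", stacklevel=2)
        center = tuple(s // 2 for s in best_map.grid.shape)
    else:
        center = tuple(int(round(c)) for c in np.argwhere(supra).mean(axis=0))

    fig, axes = plt.subplots(2, 3, figsize=(9, 6))
    thr_map = np.where(supra, best_map.data, np.nan)
    for row, overlay in enumerate((thr_map, best_map.data)):
        for ax_i, axis in enumerate(range(3)):
            ax = axes[row][ax_i]
            sl = [slice(None)] * 3
            sl[axis] = center[axis]
            ax.imshow(anat.data[tuple(sl)].T, cmap="gray", origin="lower")
            ov = overlay[tuple(sl)].T
            ax.imshow(np.ma.masked_invalid(ov), cmap="hot", origin="lower", alpha=0.6)
            ax.set_axis_off()
    axes[0][1].set_title(f"{title} (z > {icfg.viz_threshold:g})")
    axes[1][1].set_title(f"{title} (unthresholded)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return str(out_path)
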