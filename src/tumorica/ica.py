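"""Spatial ICA of a masked 4D series with repeated runs merged by reproducibility.

The decomposition at a fixed model order (``tncs``, the total number of
components) is: voxelwise demeaning, a one-stage PCA reduction of the
voxel x time matrix to ``tncs`` dimensions, then Infomax ICA (natural-
gradient ascent of the information-maximisation objective with a logistic
nonlinearity) on the whitened spatial data, so the recovered sources are
spatially independent maps with associated mixing time courses.

Because Infomax starts from a random unmixing matrix, the decomposition
is repeated ``n_runs`` times with different seeds and the runs are merged
in the style of RAICAR (Ranking and Averaging Independent Component
Analysis by Reproducibility): components are matched across runs by
greedy maximum absolute spatial correlation, sign-aligned, averaged, and
the merged components are ranked by their mean pairwise absolute
correlation across runs ("reproducibility").  Merged maps are
z-standardised (mean 0, SD 1) over the in-mask voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .imaging import BinaryMask, Series4D, Volume3D

__all__ = [
    "DecompositionConfig",
    "ReducedData",
    "ICARun",
    "ComponentSet",
    "reduce_pca",
    "run_ica_once",
    "merge_runs_raicar",
    "decompose",
]


@dataclass(frozen=True)
class DecompositionConfig:
    """Model order and run-repetition settings for one decomposition."""

    tncs: int
    n_runs: int = 25
    base_rng_seed: int = 0
    max_iter: int = 300
    convergence_tol: float = 1e-6

    def __post_init__(self):
        if self.tncs < 2:
            raise ConfigError("tncs must be >= 2")
        if self.n_runs < 1:
            raise ConfigError("n_runs must be >= 1")
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")

    def with_tncs(self, tncs: int) -> "DecompositionConfig":
        return DecompositionConfig(tncs=tncs, n_runs=self.n_runs,
                                   base_rng_seed=self.base_rng_seed,
                                   max_iter=self.max_iter,
                                   convergence_tol=self.convergence_tol)


@dataclass(frozen=True)
class ReducedData:
    """PCA-reduced, spatially whitened data ready for ICA.

    ``whitened`` has shape (tncs, n_mask_voxels) with identity spatial
    covariance; ``time_basis`` (n_frames, tncs) and ``singular_values``
    reconstruct mixing time courses for any unmixing matrix.
    """

    whitened: np.ndarray = field(repr=False)
    time_basis: np.ndarray = field(repr=False)
    singular_values: np.ndarray = field(repr=False)
    retained_variance: float = 0.0
    mask: BinaryMask = None  # type: ignore[assignment]

    @property
    def tncs(self) -> int:
        return int(self.whitened.shape[0])


@dataclass(frozen=True)
class ICARun:
    """Raw output of a single Infomax run (maps not yet standardised)."""

    maps: np.ndarray = field(repr=False)          # (tncs, n_mask_voxels)
    time_courses: np.ndarray = field(repr=False)  # (n_frames, tncs)
    converged: bool = True
    rng_seed: int = 0


@dataclass(frozen=True)
class ComponentSet:
    """Merged, ranked, z-standardised components of one decomposition."""

    tncs: int
    maps: np.ndarray = field(repr=False)           # (tncs, n_mask_voxels), z-scored
    time_courses: np.ndarray = field(repr=False)   # (n_frames, tncs)
    reproducibility: np.ndarray = field(repr=False)
    mask: BinaryMask = None  # type: ignore[assignment]
    n_converged_runs: int = 0
    n_runs: int = 0

    def map_volume(self, i: int) -> Volume3D:
        """Component i as a full 3D volume (zero outside the mask)."""
        vol = np.zeros(self.mask.grid.shape)
        vol[self.mask.data] = self.maps[i]
        return Volume3D(self.mask.grid, vol)


def reduce_pca(series: Series4D, mask: BinaryMask, tncs: int) -> ReducedData:
    """One-stage PCA reduction of the masked voxel x time matrix.

    Removes each voxel's temporal mean, then keeps the top ``tncs``
    principal temporal components (economy SVD).  Returns the spatially
    whitened coordinates and the fraction of temporal variance retained.
    """
    if mask.n_voxels == 0:
        raise ConfigError("mask is empty")
    T = series.n_frames
    if not 2 <= tncs < T:
        raise ConfigError(f"tncs must satisfy 2 <= tncs < n_frames ({T}), got {tncs}")
    if tncs >= mask.n_voxels:
        raise ConfigError("tncs must be smaller than the number of mask voxels")
    X = series.data[mask.data]            # (V, T)
    X = X - X.mean(axis=1, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    total = float((S ** 2).sum())
    retained = float((S[:tncs] ** 2).sum()) / total if total > 0 else 1.0
    V = X.shape[0]
    whitened = np.sqrt(V) * U[:, :tncs].T                 # (k, V), unit spatial cov
    return ReducedData(whitened=whitened, time_basis=Vt[:tncs].T,
                       singular_values=S[:tncs].copy(),
                       retained_variance=retained, mask=mask)


def _infomax(Z: np.ndarray, rng: np.random.Generator, max_iter: int,
             tol: float) -> tuple[np.ndarray, bool]:
    """Natural-gradient Infomax with a logistic nonlinearity on whitened data.

    Full-batch updates with a step-size that anneals when the weight change
    oscillates; restarts with a smaller step on numerical blow-up.
    Returns the unmixing matrix W and a convergence flag.
    """
    k, n = Z.shape
    eye = np.eye(k)
    l_rate = 0.08 / max(np.log(k), 1.0)
    # random orthonormal initial unmixing matrix
    W = np.linalg.qr(rng.standard_normal((k, k)))[0]
    prev_change = np.inf
    converged = False
    for _ in range(max_iter):
        U = W @ Z
        Y = 1.0 / (1.0 + np.exp(-np.clip(U, -60.0, 60.0)))
        grad = (eye + (1.0 - 2.0 * Y) @ U.T / n) @ W
        W_new = W + l_rate * grad
        if not np.all(np.isfinite(W_new)) or np.abs(W_new).max() > 1e8:
            l_rate *= 0.5
            W = np.linalg.qr(rng.standard_normal((k, k)))[0]
            prev_change = np.inf
            continue
        change = float(np.linalg.norm(W_new - W) / max(np.linalg.norm(W), 1e-12))
        W = W_new
        if change < tol:
            converged = True
            break
        # bold-driver step size: grow while descending steadily, cut on overshoot
        if change > prev_change * 1.2:
            l_rate *= 0.7
        else:
            l_rate = min(l_rate * 1.05, 1.0)
        prev_change = change
    return W, converged


def run_ica_once(reduced: ReducedData, rng_seed: int,
                 cfg: DecompositionConfig) -> ICARun:
    """One Infomax decomposition of the reduced data; deterministic per seed.

    A run that does not reach the convergence tolerance within
    ``cfg.max_iter`` iterations is retained but flagged.
    """
    rng = np.random.default_rng(rng_seed)
    Z = reduced.whitened
    W, converged = _infomax(Z, rng, cfg.max_iter, cfg.convergence_tol)
    maps = W @ Z
    # variance-normalise each map so correlations/averaging are well scaled
    sd = maps.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    scale = sd.ravel()
    maps = maps / sd
    V = Z.shape[1]
    A = reduced.time_basis @ np.diag(reduced.singular_values) @ np.linalg.inv(W) / np.sqrt(V)
    A = A * scale  # keep A @ maps an invariant reconstruction
    return ICARun(maps=maps, time_courses=A, converged=converged, rng_seed=rng_seed)


def _abs_corr_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """|Pearson r| between rows of A and rows of B."""
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    A = A / np.maximum(np.linalg.norm(A, axis=1, keepdims=True), 1e-12)
    B = B / np.maximum(np.linalg.norm(B, axis=1, keepdims=True), 1e-12)
    return A @ B.T


def merge_runs_raicar(runs: list[ICARun], mask: BinaryMask) -> ComponentSet:
    """Match components across runs, average them and rank by reproducibility.

    Run 0 provides the cluster exemplars.  For every other run the
    components are assigned to exemplars greedily by descending absolute
    spatial correlation (ties broken toward lower component indices), so
    each run contributes exactly one member per cluster.  Members are
    sign-aligned to their exemplar before averaging.
    """
    if not runs:
        raise ConfigError("no runs to merge")
    k = runs[0].maps.shape[0]
    if any(r.maps.shape[0] != k for r in runs):
        raise ConfigError("all runs must share the same tncs")
    n_runs = len(runs)

    # membership[c][r] = (component index in run r, sign relative to exemplar)
    membership = [[(c, 1.0)] for c in range(k)]
    exemplars = runs[0].maps
    for r in range(1, n_runs):
        C = _abs_corr_matrix(exemplars, runs[r].maps)
        absC = np.abs(C).copy()
        for _ in range(k):
            flat = int(np.argmax(absC))        # row-major: lower indices win ties
            i, j = divmod(flat, k)
            membership[i].append((j, float(np.sign(C[i, j]) or 1.0)))
            absC[i, :] = -np.inf
            absC[:, j] = -np.inf

    maps = np.empty((k, exemplars.shape[1]))
    tcs = np.empty((runs[0].time_courses.shape[0], k))
    repro = np.empty(k)
    for c in range(k):
        stack = np.stack([s * runs[r].maps[j] for r, (j, s) in enumerate(membership[c])])
        tstack = np.stack([s * runs[r].time_courses[:, j] for r, (j, s) in enumerate(membership[c])])
        maps[c] = stack.mean(axis=0)
        tcs[:, c] = tstack.mean(axis=0)
        if n_runs == 1:
            repro[c] = 1.0
        else:
            C = np.abs(_abs_corr_matrix(stack, stack))
            iu = np.triu_indices(n_runs, k=1)
            repro[c] = float(C[iu].mean())

    order = np.argsort(-repro, kind="stable")
    maps, tcs, repro = maps[order], tcs[:, order], repro[order]

    # deterministic sign convention: positive spatial skewness
    centered = maps - maps.mean(axis=1, keepdims=True)
    skew = (centered ** 3).mean(axis=1)
    flip = np.where(skew < 0, -1.0, 1.0)
    maps = maps * flip[:, None]
    tcs = tcs * flip[None, :]

    # z-standardise over mask voxels
    mu = maps.mean(axis=1, keepdims=True)
    sd = maps.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    maps = (maps - mu) / sd

    return ComponentSet(tncs=k, maps=maps, time_courses=tcs, reproducibility=repro,
                        mask=mask, n_converged_runs=sum(r.converged for r in runs),
                        n_runs=n_runs)


def decompose(series: Series4D, mask: BinaryMask, cfg: DecompositionConfig) -> ComponentSet:
    """PCA reduction -> ``cfg.n_runs`` Infomax runs -> RAICAR-style merge."""
    reduced = reduce_pca(series, mask, cfg.tncs)
    runs = [run_ica_once(reduced, cfg.base_rng_seed + i, cfg) for i in range(cfg.n_runs)]
    return merge_runs_raicar(runs, mask)
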