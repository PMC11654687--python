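"""Impact-mode decomposition of a variant x element t-statistic matrix.

The variant-wise t-maps are stacked into a variant x element matrix and
decomposed into K spatially independent components ("impact modes"), each a
brain map together with per-variant weights.  Deliberately, no per-element
variance normalization or mean removal is applied to the t-matrix before
whitening: the mean and scale of t-maps carry real signal.  The rank-K
principal subspace is obtained by uncentered SVD, rotated to independence by
fixed-point ICA (logcosh contrast, symmetric decorrelation), and the mixing
matrix is recovered so that ``mixing @ sources`` reproduces the rank-K
projection of the input.
"""
from __future__ import annotations

import logging
import warnings
from typing import Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .types import (
    ConfigError,
    DataError,
    ElementMaps,
    ImpactModeSet,
    SyntheticTruth,
    TStatMatrix,
    VoxelGeometry,
)

logger = logging.getLogger(__name__)


def normalize_jacobians(maps: ElementMaps) -> ElementMaps:
    """Divide each subject's voxel values by that subject's in-mask mean.

    Emulates normalization of Jacobian-determinant volumes to total brain
    volume, removing global-size effects before decomposition.
    """
    if not isinstance(maps.geometry, VoxelGeometry):
        raise DataError("Jacobian normalization applies to voxel geometry only")
    means = maps.values.mean(axis=1)
    if np.any(means <= 0):
        raise DataError("nonpositive subject mean; cannot normalize")
    return ElementMaps(
        maps.values / means[:, None], maps.geometry, maps.subject_ids, maps.element_ids
    )


def _zscore_rows(a: np.ndarray) -> np.ndarray:
    mu = a.mean(axis=1, keepdims=True)
    sd = a.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise DataError("cannot z-score a constant spatial map")
    return (a - mu) / sd


def _orient(sources: np.ndarray, mixing: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Sign convention: positive spatial skewness per component
    (tie: largest-|z| element positive)."""
    z = _zscore_rows(sources)
    for k in range(sources.shape[0]):
        skew = stats.skew(z[k])
        if skew < 0:
            flip = True
        elif skew > 0:
            flip = False
        else:
            flip = z[k, np.argmax(np.abs(z[k]))] < 0
        if flip:
            sources[k] *= -1.0
            mixing[:, k] *= -1.0
    return sources, mixing


def decompose(
    tmat: TStatMatrix,
    k: int = 10,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    max_restarts: int = 5,
) -> ImpactModeSet:
    """Extract K impact modes from a variant x element t-matrix.

    Pipeline: uncentered rank-K SVD whitening -> fixed-point ICA (logcosh,
    symmetric decorrelation) on the whitened spatial coordinates -> sources
    scaled back, mixing by least squares, maps z-scored over elements,
    components ordered by variance explained.
    """
    x = np.asarray(tmat.t, dtype=float) if isinstance(tmat, TStatMatrix) else np.asarray(tmat, float)
    if not np.all(np.isfinite(x)):
        raise DataError("t-matrix must be finite (drop flagged variants first)")
    n_var, n_elem = x.shape
    if k < 1 or k > min(n_var, n_elem):
        raise ConfigError("K must satisfy 1 <= K <= min(n_variants, n_elements)")
    total_ss = float((x**2).sum())
    if total_ss == 0.0:
        raise DataError("t-matrix has zero norm")
    # no mean removal, no variance normalization: plain SVD of the raw matrix
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * max(n_var, n_elem) * np.finfo(float).eps).sum())
    if k > rank:
        raise ConfigError(f"K={k} exceeds the numerical rank {rank} of the t-matrix")
    z = vt[:k] * np.sqrt(n_elem)  # whitened spatial coordinates, unit variance

    n_iter = None
    used_restart = 0
    for restart in range(max_restarts):
        rng_seed = int(seed) + restart
        ica = FastICA(
            whiten=False,
            fun="logcosh",
            algorithm="parallel",
            tol=tol,
            max_iter=max_iter,
            random_state=rng_seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            sources_T = ica.fit_transform(z.T)  # (n_elem, k)
        n_iter = int(ica.n_iter_)
        if n_iter < max_iter:
            used_restart = restart
            break
    else:
        raise RuntimeError(
            f"ICA failed to converge in {max_iter} iterations after "
            f"{max_restarts} restarts (last n_iter={n_iter}, tol={tol})"
        )
    sources = sources_T.T  # (k, n_elem), spans the same subspace as vt[:k]
    mixing, *_ = np.linalg.lstsq(sources.T, x.T, rcond=None)
    mixing = mixing.T  # (n_var, k)
    sources, mixing = _orient(sources, mixing)
    # order components by variance explained (descending)
    contrib = np.array(
        [float(np.outer(mixing[:, j], sources[j]).ravel() @ np.outer(mixing[:, j], sources[j]).ravel()) for j in range(k)]
    )
    order = np.argsort(contrib)[::-1]
    sources, mixing, contrib = sources[order], mixing[:, order], contrib[order]
    recon = mixing @ sources
    total_ve = 1.0 - float(((x - recon) ** 2).sum()) / total_ss
    per_mode = contrib / total_ss
    weight_z = mode_weights_matrix(mixing)
    return ImpactModeSet(
        spatial_maps=_zscore_rows(sources),
        sources=sources,
        mixing=mixing,
        weight_z=weight_z,
        variance_explained_total=total_ve,
        variance_explained_modes=per_mode,
        k=k,
        convergence={
            "iterations": n_iter,
            "tolerance": tol,
            "seed": int(seed),
            "restarts_used": used_restart,
        },
    )


def mode_weights_matrix(mixing: np.ndarray) -> np.ndarray:
    """Standardize each mixing column over variants (population sd)."""
    mixing = np.asarray(mixing, dtype=float)
    if not np.all(np.isfinite(mixing)):
        raise DataError("mixing matrix must be finite")
    mu = mixing.mean(axis=0)
    sd = mixing.std(axis=0)
    if np.any(sd == 0):
        raise DataError("degenerate mode: constant mixing column")
    return (mixing - mu) / sd


def mode_weights(mixing: np.ndarray, variant_ids=None) -> pd.DataFrame:
    """Long-format table of per-variant mode weight z-scores."""
    z = mode_weights_matrix(mixing)
    n_var, k = z.shape
    if variant_ids is None:
        variant_ids = [f"var{i:05d}" for i in range(n_var)]
    rows = []
    for j in range(k):
        for i in range(n_var):
            rows.append((variant_ids[i], j + 1, z[i, j]))
    return pd.DataFrame(rows, columns=["id", "mode", "weight_z"])


def variance_explained(tmat, modeset: ImpactModeSet):
    """Fraction of t-matrix sum of squares captured by the modes.

    Baseline is the zero matrix (no mean removal, consistent with the
    decomposition); per-mode fractions are the rank-1 term contributions.
    """
    x = np.asarray(tmat.t, dtype=float) if isinstance(tmat, TStatMatrix) else np.asarray(tmat, float)
    total_ss = float((x**2).sum())
    if total_ss == 0.0:
        raise DataError("t-matrix has zero norm")
    if modeset.k == 0 or modeset.mixing.size == 0:
        return 0.0, np.zeros(0)
    recon = modeset.mixing @ modeset.sources
    total = 1.0 - float(((x - recon) ** 2).sum()) / total_ss
    per_mode = np.array(
        [
            float((np.outer(modeset.mixing[:, j], modeset.sources[j]) ** 2).sum())
            for j in range(modeset.k)
        ]
    ) / total_ss
    return total, per_mode


def match_modes(recovered: ImpactModeSet, truth: SyntheticTruth) -> pd.DataFrame:
    """Greedy maximum-|correlation| matching of recovered to planted modes.

    Reports per-pair spatial |r|, loading |r| and sign alignment (whether
    the spatial and loading correlations carry the same sign).
    """
    rec_maps = np.atleast_2d(recovered.spatial_maps)
    true_maps = np.atleast_2d(truth.spatial_modes)
    if rec_maps.shape[0] < 1:
        raise DataError("need at least one recovered mode")
    k_rec, k_true = rec_maps.shape[0], true_maps.shape[0]
    corr = np.zeros((k_rec, k_true))
    for i in range(k_rec):
        for j in range(k_true):
            c = np.corrcoef(rec_maps[i], true_maps[j])[0, 1]
            corr[i, j] = 0.0 if np.isnan(c) else c
    load_corr = np.zeros((k_rec, k_true))
    if (
        recovered.mixing.size
        and truth.variant_loadings.size
        and recovered.mixing.shape[0] == truth.variant_loadings.shape[0]
    ):
        for i in range(min(k_rec, recovered.mixing.shape[1])):
            for j in range(k_true):
                a = recovered.mixing[:, i]
                b = truth.variant_loadings[:, j]
                if a.std() == 0 or b.std() == 0:
                    continue
                load_corr[i, j] = np.corrcoef(a, b)[0, 1]
    rows = []
    free_rec = set(range(k_rec))
    free_true = set(range(k_true))
    work = np.abs(corr).copy()
    for _ in range(min(k_rec, k_true)):
        masked = np.full_like(work, -1.0)
        for i in free_rec:
            for j in free_true:
                masked[i, j] = work[i, j]
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        rows.append(
            {
                "recovered_mode": int(i),
                "true_mode": int(j),
                "spatial_abs_r": float(np.abs(corr[i, j])),
                "loading_abs_r": float(np.abs(load_corr[i, j])),
                "sign_aligned": bool(np.sign(corr[i, j]) == np.sign(load_corr[i, j]))
                if load_corr[i, j] != 0
                else True,
            }
        )
        free_rec.discard(int(i))
        free_true.discard(int(j))
    return pd.DataFrame(rows)
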