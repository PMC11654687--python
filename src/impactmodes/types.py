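"""Core in-memory containers shared across the pipeline.

All heavy data live in plain numpy arrays / pandas frames; the dataclasses
here add identity (variant / subject / element ids), geometry, and the light
validation that catches dimension and bound errors early.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class ConfigError(ValueError):
    """Invalid configuration (counts, ranges, rank budgets)."""


class DataError(ValueError):
    """Invalid or inconsistent data (dimension mismatch, bad values)."""


VARIANT_COLUMNS = ("id", "chrom", "pos", "ref", "alt", "maf", "info")
SUMSTAT_COLUMNS = ("id", "effect_allele", "other_allele", "beta", "se", "p")


@dataclass
class GenotypeMatrix:
    """Subject x variant allele dosages with per-variant metadata.

    Dosages are expected counts of the alternate allele in [0, 2]; NaN marks
    a missing call.  Variant metadata carries id, chrom, pos (1-based),
    ref/alt alleles, minor-allele frequency and imputation info score.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.dosages.ndim != 2:
            raise DataError("dosages must be 2-D (subjects x variants)")
        n_sub, n_var = self.dosages.shape
        if len(self.subject_ids) != n_sub:
            raise DataError("subject_ids length does not match dosage rows")
        if len(self.variants) != n_var:
            raise DataError("variant table length does not match dosage columns")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise DataError(f"variant table missing columns: {missing}")
        if self.variants["id"].duplicated().any():
            raise DataError("variant ids must be unique")
        if (self.variants["pos"] < 0).any():
            raise DataError("variant positions must be nonnegative")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < -1e-9 or np.nanmax(
                self.dosages, initial=0.0
            ) > 2.0 + 1e-9:
                raise DataError("dosages must lie in [0, 2]")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = pd.Index(self.variants["id"])
        idx = lookup.get_indexer(ids)
        if (idx < 0).any():
            bad = [v for v, i in zip(ids, idx) if i < 0]
            raise DataError(f"variants not present: {bad[:5]}")
        return idx

    def subset_variants(self, mask_or_ids) -> "GenotypeMatrix":
        if isinstance(mask_or_ids, (list, tuple, pd.Index)) or (
            isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype.kind in "UOS"
        ):
            idx = self.variant_index(list(mask_or_ids))
        else:
            idx = np.asarray(mask_or_ids)
            if idx.dtype == bool:
                idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.dosages[:, idx],
            self.variants.iloc[idx].reset_index(drop=True),
            self.subject_ids,
        )

    def subset_subjects(self, ids: Sequence[str]) -> "GenotypeMatrix":
        lookup = pd.Index(self.subject_ids)
        idx = lookup.get_indexer(list(ids))
        if (idx < 0).any():
            raise DataError("some requested subjects are absent")
        return GenotypeMatrix(
            self.dosages[idx], self.variants.copy(), self.subject_ids[idx]
        )


@dataclass
class SummaryStats:
    """Discovery-GWAS per-variant marginal effects (beta, se, p)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTAT_COLUMNS if c not in self.table.columns]
        if missing:
            raise DataError(f"summary statistics missing columns: {missing}")
        p = self.table["p"].to_numpy(dtype=float)
        if np.any(p <= 0) or np.any(p > 1):
            raise DataError("p-values must lie in (0, 1]")
        same = self.table["effect_allele"] == self.table["other_allele"]
        if same.any():
            raise DataError("effect and other allele must differ per variant")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class VoxelGeometry:
    """Masked 3-D voxel grid; elements are the in-mask voxels in C order."""

    shape: tuple
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.shape:
            raise DataError("mask shape does not match grid shape")

    @property
    def n_elements(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_indices(self) -> np.ndarray:
        return np.argwhere(self.mask)

    def element_ids(self) -> np.ndarray:
        return np.array([f"v{i}_{j}_{k}" for i, j, k in self.voxel_indices])


@dataclass
class FixelGeometry:
    """Flat list of fixels: voxel index plus unit direction vector."""

    voxel_index: np.ndarray
    directions: np.ndarray

    def __post_init__(self) -> None:
        self.voxel_index = np.asarray(self.voxel_index, dtype=int)
        self.directions = np.asarray(self.directions, dtype=float)
        if self.directions.shape != (len(self.voxel_index), 3):
            raise DataError("directions must be (n_fixels, 3)")
        norms = np.linalg.norm(self.directions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise DataError("fixel directions must be unit vectors")

    @property
    def n_elements(self) -> int:
        return len(self.voxel_index)

    def element_ids(self) -> np.ndarray:
        return np.array([f"f{i}" for i in range(self.n_elements)])


@dataclass
class ElementMaps:
    """Subject x element brain measures (voxel Jacobians or fixel AFD)."""

    values: np.ndarray
    geometry: object
    subject_ids: np.ndarray
    element_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.values.ndim != 2:
            raise DataError("map values must be 2-D (subjects x elements)")
        if not np.all(np.isfinite(self.values)):
            raise DataError("map values must be finite")
        if self.values.shape[0] != len(self.subject_ids):
            raise DataError("subject_ids length does not match value rows")
        if self.geometry.n_elements != self.values.shape[1]:
            raise DataError("geometry element count does not match value columns")
        if self.element_ids is None:
            self.element_ids = self.geometry.element_ids()
        self.element_ids = np.asarray(self.element_ids)
        if len(self.element_ids) != self.values.shape[1]:
            raise DataError("element_ids length does not match value columns")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_elements(self) -> int:
        return self.values.shape[1]

    def subset_subjects(self, ids: Sequence[str]) -> "ElementMaps":
        lookup = pd.Index(self.subject_ids)
        idx = lookup.get_indexer(list(ids))
        if (idx < 0).any():
            raise DataError("some requested subjects are absent from maps")
        return ElementMaps(
            self.values[idx], self.geometry, self.subject_ids[idx], self.element_ids
        )


@dataclass
class TStatMatrix:
    """Predictor x element t-statistics from mass-univariate GLM fits."""

    t: np.ndarray
    df: int
    predictor_ids: np.ndarray
    model: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.atleast_2d(np.asarray(self.t, dtype=float))
        self.predictor_ids = np.asarray(self.predictor_ids)
        if len(self.predictor_ids) != self.t.shape[0]:
            raise DataError("predictor_ids length does not match t rows")
        if self.df <= 0:
            raise DataError("residual degrees of freedom must be positive")


@dataclass
class FweResult:
    """Max-statistic permutation result: per-element FWE-corrected p-values."""

    p: np.ndarray
    t_obs: np.ndarray
    null_max: np.ndarray
    n_perm: int
    seed: Optional[int]
    tail: str = "two"

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.t_obs = np.asarray(self.t_obs, dtype=float)
        self.null_max = np.asarray(self.null_max, dtype=float)
        lo = 1.0 / (self.n_perm + 1)
        if np.any(self.p < lo - 1e-12) or np.any(self.p > 1 + 1e-12):
            raise DataError("FWE p-values must lie in [1/(n_perm+1), 1]")


@dataclass
class ImpactModeSet:
    """ICA decomposition of a variant x element t-matrix.

    ``sources`` holds the raw independent spatial sources (K x elements) such
    that ``mixing @ sources`` reproduces the rank-K projection of the input;
    ``spatial_maps`` are the same sources z-scored over elements for
    reporting, and ``weight_z`` are the mixing columns standardized over
    variants.
    """

    spatial_maps: np.ndarray
    sources: np.ndarray
    mixing: np.ndarray
    weight_z: np.ndarray
    variance_explained_total: float
    variance_explained_modes: np.ndarray
    k: int
    convergence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spatial_maps = np.atleast_2d(np.asarray(self.spatial_maps, dtype=float))
        self.sources = np.atleast_2d(np.asarray(self.sources, dtype=float))
        self.mixing = np.asarray(self.mixing, dtype=float)
        self.weight_z = np.asarray(self.weight_z, dtype=float)
        if self.k and not (0.0 - 1e-9 <= self.variance_explained_total <= 1.0 + 1e-9):
            raise DataError("variance explained must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Planted low-rank structure behind simulated brain maps.

    ``effect_maps`` (variants x elements) is exactly
    ``variant_loadings @ spatial_modes`` so that downstream decompositions
    have a known answer; ``causal_pgs_weights`` are per-variant effects on a
    scalar liability used to simulate the discovery GWAS.
    """

    spatial_modes: np.ndarray
    variant_loadings: np.ndarray
    effect_maps: np.ndarray
    causal_pgs_weights: np.ndarray

    def __post_init__(self) -> None:
        self.spatial_modes = np.atleast_2d(np.asarray(self.spatial_modes, dtype=float))
        self.variant_loadings = np.atleast_2d(
            np.asarray(self.variant_loadings, dtype=float)
        )
        self.effect_maps = np.asarray(self.effect_maps, dtype=float)
        self.causal_pgs_weights = np.asarray(self.causal_pgs_weights, dtype=float)
        expect = self.variant_loadings @ self.spatial_modes
        if self.effect_maps.shape != expect.shape or not np.array_equal(
            self.effect_maps, expect
        ):
            raise DataError("effect_maps must equal variant_loadings @ spatial_modes")
        if np.any(np.all(self.spatial_modes == 0.0, axis=1)):
            raise DataError("every spatial mode needs at least one nonzero element")

    @property
    def k(self) -> int:
        return self.spatial_modes.shape[0]

    def support_union(self) -> np.ndarray:
        """Boolean mask of elements touched by any planted mode."""
        return np.any(self.spatial_modes != 0.0, axis=0)


@dataclass
class PGSVector:
    """Per-subject polygenic score with provenance."""

    scores: np.ndarray
    subject_ids: np.ndarray
    weight_set: str = ""
    n_variants_used: int = 0
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(self.scores)):
            raise DataError("polygenic scores must be finite")
        if len(self.scores) != len(self.subject_ids):
            raise DataError("score length does not match subject ids")
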