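"""Synthetic cohort generator with planted low-rank brain/genotype structure.

Emulates, at desk scale, the ingredients of an imaging-genetics study:
dosage genotypes with a minor-allele-frequency spectrum and block LD, a
discovery-GWAS summary-statistic table, nuisance covariates, kinship pairs,
and per-subject brain maps whose variant effects have a planted
modes x loadings structure plus Gaussian noise.  Every generator is a pure
function of (config, seed); the global seed is split hierarchically so each
generator draws from its own stream.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    ConfigError,
    DataError,
    ElementMaps,
    FixelGeometry,
    GenotypeMatrix,
    SummaryStats,
    SyntheticTruth,
    VoxelGeometry,
)

logger = logging.getLogger(__name__)

# stream offsets for hierarchical seed splitting
_STREAMS = {
    "genotypes": 1,
    "covariates": 2,
    "truth": 3,
    "maps": 4,
    "discovery": 5,
    "kinship": 6,
}

DEFAULT_COVARIATE_EFFECTS = {"age": 5e-4, "sex": 0.02}


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic cohort.

    Defaults describe a desk-scale cohort: a few hundred subjects, a few
    hundred variants in short LD blocks, three planted spatial modes on a
    small masked voxel grid, and map noise small relative to planted
    per-variant effects (high SNR).
    """

    n_subjects: int = 400
    n_variants: int = 240
    maf_range: tuple = (0.1, 0.5)
    ld_block_size: int = 4
    ld_decay: float = 0.8
    n_modes: int = 3
    grid_shape: tuple = (10, 10, 10)
    mode_sparsity: float = 0.08
    loading_sparsity: float = 0.05
    noise_sd: float = 0.05
    covariate_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    loading_sd: float = 0.05
    pgs_weight_sd: float = 0.15
    n_discovery: int = 4000
    n_related_pairs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_variants", "ld_block_size", "n_modes"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.ld_decay < 1.0 or self.ld_decay == 1.0):
            raise ConfigError("ld_decay must lie in [0, 1]")
        for name in ("mode_sparsity", "loading_sparsity"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ConfigError(f"{name} must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        self.maf_range = tuple(float(v) for v in self.maf_range)
        self.grid_shape = tuple(int(v) for v in self.grid_shape)


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], int(seed)])


def subject_ids(n: int) -> np.ndarray:
    return np.array([f"S{i:05d}" for i in range(n)])


def ellipsoid_mask(shape) -> np.ndarray:
    """Brain-like ellipsoidal mask inscribed in the grid."""
    shape = tuple(int(s) for s in shape)
    axes = [np.arange(s) - (s - 1) / 2.0 for s in shape]
    grids = np.meshgrid(*axes, indexing="ij")
    r = sum((g / max(s / 2.0, 0.5)) ** 2 for g, s in zip(grids, shape))
    return r <= 1.0


def _simulate_dosages(
    n_subjects: int,
    mafs: np.ndarray,
    block_id: np.ndarray,
    ld_decay: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Hard-call dosages (0/1/2): block-leading variants are binomial draws,
    later block members copy the previous variant's alleles with per-allele
    flip probability (1 - ld_decay)/2."""
    n_variants = len(mafs)
    flip_p = (1.0 - ld_decay) / 2.0
    if len(np.unique(block_id)) == n_variants:  # unlinked: one binomial draw
        return rng.binomial(2, mafs, size=(n_subjects, n_variants)).astype(float)
    alleles = np.empty((n_subjects, n_variants, 2), dtype=np.int8)
    for v in range(n_variants):
        if v == 0 or block_id[v] != block_id[v - 1]:
            alleles[:, v, :] = rng.random((n_subjects, 2)) < mafs[v]
        else:
            flips = rng.random((n_subjects, 2)) < flip_p
            alleles[:, v, :] = alleles[:, v - 1, :] ^ flips
    return alleles.sum(axis=2).astype(float)


def _variant_table(cfg: SimConfig, mafs: np.ndarray, block_id: np.ndarray) -> pd.DataFrame:
    n = cfg.n_variants
    n_blocks = block_id.max() + 1
    chrom = np.empty(n, dtype=int)
    pos = np.empty(n, dtype=int)
    chrom_pos = {}
    for b in range(n_blocks):
        members = np.flatnonzero(block_id == b)
        c = 1 + (b % 22)
        start = chrom_pos.get(c, 0) + 1_000_000  # >window so blocks are unlinked
        for j, v in enumerate(members):
            chrom[v] = c
            pos[v] = start + j * 1_000  # 1 kb spacing within a block
        chrom_pos[c] = pos[members[-1]]
    return pd.DataFrame(
        {
            "id": [f"var{i:05d}" for i in range(n)],
            "chrom": chrom,
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "maf": mafs,
            "info": 1.0,
            "block": block_id,
        }
    )


def gen_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Dosage genotypes in LD blocks; block boundaries carry no LD."""
    if cfg.n_variants < 1:
        raise ConfigError("n_variants must be positive")
    rng = _rng(cfg.seed, "genotypes")
    block_id = np.arange(cfg.n_variants) // cfg.ld_block_size
    block_maf = rng.uniform(*cfg.maf_range, size=block_id.max() + 1)
    mafs = block_maf[block_id]
    dosages = _simulate_dosages(cfg.n_subjects, mafs, block_id, cfg.ld_decay, rng)
    return GenotypeMatrix(dosages, _variant_table(cfg, mafs, block_id), subject_ids(cfg.n_subjects))


def gen_covariates(cfg: SimConfig) -> pd.DataFrame:
    """Nuisance covariate table: age terms, sex, ancestry-PC stand-ins,
    imaging-site dummies, a preprocessing batch flag, and head size
    (head size is excluded from the base design; it enters only under the
    head-size adjustment flag)."""
    if cfg.n_subjects < 2:
        raise ConfigError("need at least 2 subjects for covariates")
    rng = _rng(cfg.seed, "covariates")
    n = cfg.n_subjects
    age = rng.uniform(45.0, 82.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    site = rng.integers(0, 4, size=n)
    cov = {
        "subject_id": subject_ids(n),
        "age": age,
        "sex": sex,
        "age2": age**2,
        "age_x_sex": age * sex,
        "age2_x_sex": age**2 * sex,
    }
    for i in range(10):
        cov[f"pc{i + 1}"] = rng.standard_normal(n)
    for s in (1, 2, 3):
        cov[f"site_{s + 1}"] = (site == s).astype(float)
    cov["batch"] = (rng.random(n) < 0.2).astype(float)
    cov["head_size"] = rng.normal(1500.0, 100.0, size=n)
    return pd.DataFrame(cov)


def _farthest_point_centers(coords: np.ndarray, k: int, rng) -> np.ndarray:
    """Greedy farthest-point sampling: k well-separated center indices."""
    n = coords.shape[0]
    centers = [int(rng.integers(n))]
    d = np.linalg.norm(coords - coords[centers[0]], axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(d))
        centers.append(nxt)
        d = np.minimum(d, np.linalg.norm(coords - coords[nxt], axis=1))
    return np.array(centers)


def make_modes(
    n_elements: int,
    k: int,
    sparsity: float,
    rng: np.random.Generator,
    coords: Optional[np.ndarray] = None,
) -> np.ndarray:
    """K smoothed sparse spatial sources with disjoint supports.

    Each mode is a Gaussian-falloff blob around a well-separated center,
    restricted to that center's Voronoi cell so supports never overlap.
    """
    if k > n_elements:
        raise ConfigError("more modes than elements")
    if coords is None:
        coords = np.arange(n_elements, dtype=float)[:, None]
    coords = np.asarray(coords, dtype=float)
    centers = _farthest_point_centers(coords, k, rng)
    dist = np.linalg.norm(coords[:, None, :] - coords[centers][None, :, :], axis=2)
    owner = np.argmin(dist, axis=1)
    m = max(1, int(round(sparsity * n_elements)))
    modes = np.zeros((k, n_elements))
    for j in range(k):
        cell = np.flatnonzero(owner == j)
        order = cell[np.argsort(dist[cell, j])]
        support = order[: max(1, min(m, len(order)))]
        d = dist[support, j]
        sigma = max(np.median(d), 1e-6)
        modes[j, support] = np.exp(-(d**2) / (2.0 * sigma**2))
    return modes


def gen_truth(cfg: SimConfig, n_elements: Optional[int] = None) -> SyntheticTruth:
    """Plant K spatial modes, sparse variant loadings, their product as
    per-variant effect maps, and sparse causal liability weights (on the
    same loader variants, so the polygenic score tracks the map effects)."""
    rng = _rng(cfg.seed, "truth")
    if n_elements is None:
        mask = ellipsoid_mask(cfg.grid_shape)
        n_elements = int(mask.sum())
        coords = np.argwhere(mask).astype(float)
    else:
        coords = None
    k = cfg.n_modes
    if k > min(cfg.n_variants, n_elements):
        raise ConfigError("n_modes exceeds the rank budget min(n_variants, n_elements)")
    modes = make_modes(n_elements, k, cfg.mode_sparsity, rng, coords)
    n_load = max(1, int(round(cfg.loading_sparsity * cfg.n_variants)))
    loadings = np.zeros((cfg.n_variants, k))
    perm = rng.permutation(cfg.n_variants)
    for j in range(k):
        if (j + 1) * n_load <= cfg.n_variants:
            who = perm[j * n_load : (j + 1) * n_load]
        else:  # rank budget too tight for disjoint loaders; sample freely
            who = rng.choice(cfg.n_variants, size=n_load, replace=False)
        loadings[who, j] = rng.normal(0.0, cfg.loading_sd, size=len(who))
        if np.all(loadings[:, j] == 0.0):
            loadings[who[0], j] = cfg.loading_sd
    # liability weights sign-aligned with each variant's net map loading, so
    # the disposing allele both raises liability and drives its map effect
    causal = loadings.sum(axis=1)
    nz = causal != 0.0
    causal[nz] *= cfg.pgs_weight_sd / max(causal[nz].std(), 1e-12)
    return SyntheticTruth(modes, loadings, loadings @ modes, causal)


def _fixel_geometry(cfg: SimConfig, n_elements: int, rng) -> FixelGeometry:
    vox = rng.integers(0, int(np.prod(cfg.grid_shape)), size=n_elements)
    d = rng.standard_normal((n_elements, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return FixelGeometry(vox, d)


def gen_maps(
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    truth: SyntheticTruth,
    cfg: SimConfig,
    geometry: str = "voxel",
) -> ElementMaps:
    """Per-subject brain maps: baseline 1.0 + centered-dosage effects +
    global covariate effects + Gaussian noise."""
    rng = _rng(cfg.seed, "maps")
    n_elements = truth.effect_maps.shape[1]
    if genotypes.n_variants != truth.effect_maps.shape[0]:
        raise DataError("genotypes and truth disagree on variant count")
    if genotypes.n_subjects != len(covariates):
        raise DataError("genotypes and covariates disagree on subject count")
    g_centered = genotypes.dosages - np.nanmean(genotypes.dosages, axis=0)
    values = 1.0 + g_centered @ truth.effect_maps
    for name, slope in cfg.covariate_effects.items():
        if name not in covariates.columns:
            raise DataError(f"covariate_effects refers to missing column {name!r}")
        values = values + slope * covariates[name].to_numpy()[:, None]
    if cfg.noise_sd > 0:
        values = values + rng.normal(0.0, cfg.noise_sd, size=values.shape)
    if geometry == "voxel":
        mask = ellipsoid_mask(cfg.grid_shape)
        if int(mask.sum()) != n_elements:
            raise DataError("truth element count does not match the voxel mask")
        geom = VoxelGeometry(cfg.grid_shape, mask)
    elif geometry == "fixel":
        geom = _fixel_geometry(cfg, n_elements, rng)
    else:
        raise ConfigError(f"unknown geometry {geometry!r}")
    return ElementMaps(values, geom, genotypes.subject_ids.copy())


def marginal_gwas(dosages: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Per-variant simple linear regression of y on dosage (beta, se, p)."""
    n = len(y)
    xc = dosages - dosages.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc**2).sum(axis=0)
    sxy = xc.T @ yc
    syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
        rss = np.maximum(syy - beta * sxy, 0.0)
        sigma2 = rss / max(n - 2, 1)
        se = np.sqrt(np.where(sxx > 0, sigma2 / np.where(sxx > 0, sxx, 1.0), np.inf))
        t = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=max(n - 2, 1))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame({"beta": beta, "se": se, "p": p})


def gen_sumstats(
    genotypes: GenotypeMatrix,
    truth: SyntheticTruth,
    n_discovery: int,
    seed: int,
    ld_decay: Optional[float] = None,
) -> SummaryStats:
    """Discovery-GWAS summary statistics from an independent simulated
    cohort: same variants (MAF and LD-block structure taken from the
    genotype metadata), liability = centered dosage . causal weights + N(0,1),
    then per-variant marginal regression."""
    if n_discovery < 10:
        raise ConfigError("n_discovery must be >= 10")
    rng = _rng(seed, "discovery")
    var = genotypes.variants
    block_id = (
        var["block"].to_numpy()
        if "block" in var.columns
        else np.arange(len(var))
    )
    if ld_decay is None:
        if np.any(np.bincount(block_id) > 1):
            raise ConfigError(
                "ld_decay must be given when variants form multi-variant LD blocks"
            )
        ld_decay = 0.0
    dosages = _simulate_dosages(
        n_discovery, var["maf"].to_numpy(), block_id, ld_decay, rng
    )
    liability = (dosages - dosages.mean(axis=0)) @ truth.causal_pgs_weights
    liability = liability + rng.standard_normal(n_discovery)
    res = marginal_gwas(dosages, liability)
    table = pd.DataFrame(
        {
            "id": var["id"].to_numpy(),
            "effect_allele": var["alt"].to_numpy(),
            "other_allele": var["ref"].to_numpy(),
            "beta": res["beta"].to_numpy(),
            "se": res["se"].to_numpy(),
            "p": res["p"].to_numpy(),
        }
    )
    return SummaryStats(table)


def gen_kinship(n_subjects: int, n_related_pairs: int, seed: int) -> pd.DataFrame:
    """Kinship pair table: n_related_pairs pairs at 3rd-degree-or-closer
    coefficients {0.25, 0.125, 0.0625} plus an equal number of sub-threshold
    pairs; unordered pairs are unique."""
    max_pairs = n_subjects * (n_subjects - 1) // 2
    if 2 * n_related_pairs > max_pairs:
        raise ConfigError("requested more related pairs than exist")
    rng = _rng(seed, "kinship")
    ids = subject_ids(n_subjects)
    want = 2 * n_related_pairs
    pairs: list = []
    seen = set()
    while len(pairs) < want:
        i, j = rng.choice(n_subjects, size=2, replace=False)
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        pairs.append(key)
    rows = []
    for idx, (i, j) in enumerate(pairs):
        if idx < n_related_pairs:
            kin = float(rng.choice([0.25, 0.125, 0.0625]))
        else:
            kin = float(rng.uniform(0.001, 0.04))
        rows.append((ids[i], ids[j], kin))
    return pd.DataFrame(rows, columns=["id1", "id2", "kinship"])


def simulate_cohort(cfg: SimConfig, geometry: str = "voxel"):
    """Convenience: generate every input of one synthetic study.

    Returns (genotypes, covariates, truth, maps, sumstats, kinship).
    """
    genotypes = gen_genotypes(cfg)
    covariates = gen_covariates(cfg)
    truth = gen_truth(cfg)
    maps = gen_maps(genotypes, covariates, truth, cfg, geometry=geometry)
    sumstats = gen_sumstats(
        genotypes, truth, cfg.n_discovery, cfg.seed, ld_decay=cfg.ld_decay
    )
    kinship = gen_kinship(cfg.n_subjects, cfg.n_related_pairs, cfg.seed)
    return genotypes, covariates, truth, maps, sumstats, kinship


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    return replace(cfg, seed=int(seed))
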