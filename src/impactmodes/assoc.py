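"""Mass-univariate GLM of brain elements on a predictor, with
max-statistic permutation inference for brain-wide FWE correction.

Fitting uses the Frisch-Waugh route: predictor and element values are both
residualized on the nuisance design, then the per-element simple regression
t equals the full-design OLS t (with df = n - p - 1).  Permutation
inference follows the Freedman-Lane scheme: rows of the design-residualized
maps are permuted, re-residualized on the design, and the maximum |t| over
elements is recorded per permutation; the per-element FWE p includes the
observed statistic in the null (the +1 rule), which guarantees validity.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    ConfigError,
    DataError,
    ElementMaps,
    FweResult,
    GenotypeMatrix,
    TStatMatrix,
)

logger = logging.getLogger(__name__)

#: covariate-table columns that never enter the design implicitly
_SPECIAL_COLUMNS = ("subject_id", "head_size", "global_afd")


@dataclass
class DesignSpec:
    """Nuisance design matrix (with intercept) plus transform flags."""

    matrix: np.ndarray
    columns: list
    log_transform: bool = False

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


def build_design(
    covariates: pd.DataFrame,
    head_size_adjust: bool = False,
    global_afd_adjust: bool = False,
    log_transform: bool = False,
    extra_covariates: Optional[Sequence[str]] = None,
) -> DesignSpec:
    """Assemble intercept + covariate columns per model options.

    All covariate columns except subject_id, head_size and global_afd form
    the base model; head size and global mean AFD enter only under their
    adjustment flags (secondary models), and ``log_transform`` records that
    element values are log-transformed before fitting.
    """
    base = [c for c in covariates.columns if c not in _SPECIAL_COLUMNS]
    wanted = list(base)
    if head_size_adjust:
        wanted.append("head_size")
    if global_afd_adjust:
        wanted.append("global_afd")
    for c in extra_covariates or ():
        if c not in wanted:
            wanted.append(c)
    missing = [c for c in wanted if c not in covariates.columns]
    if missing:
        raise DataError(f"covariate table missing columns: {missing}")
    sub = covariates[wanted]
    bad = sub.isna().any(axis=1)
    if bad.any():
        who = (
            covariates.loc[bad, "subject_id"].tolist()
            if "subject_id" in covariates.columns
            else bad[bad].index.tolist()
        )
        raise DataError(f"missing covariate values for subjects: {who[:10]}")
    matrix = np.column_stack(
        [np.ones(len(covariates))] + [sub[c].to_numpy(dtype=float) for c in wanted]
    )
    return DesignSpec(matrix, ["intercept"] + wanted, log_transform)


def transform_values(values: np.ndarray, design: DesignSpec) -> np.ndarray:
    if not design.log_transform:
        return values
    if np.any(values <= 0):
        raise DataError("log transform requires strictly positive map values")
    return np.log(values)


def _design_basis(design) -> np.ndarray:
    """Orthonormal basis Q of the design column space."""
    x = design.matrix if isinstance(design, DesignSpec) else np.asarray(design, float)
    if x.ndim != 2:
        raise DataError("design must be a 2-D matrix")
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(np.abs(np.diag(r)).max(), 1.0)
    return q[:, keep]


def _residualize(a: np.ndarray, q: np.ndarray) -> np.ndarray:
    return a - q @ (q.T @ a)


@dataclass
class GlmResult:
    """One mass-univariate fit: per-element t, beta, partial r2."""

    t: np.ndarray
    beta: np.ndarray
    partial_r2: np.ndarray
    df: int
    n_degenerate: int = 0


def fit_glm(maps, x: np.ndarray, design) -> GlmResult:
    """Per-element OLS of value on [x | design] via residualization.

    Degenerate elements (zero variance after residualization) get t = 0
    with a logged count.  A predictor collinear with the design is an error.
    """
    values = maps.values if isinstance(maps, ElementMaps) else np.asarray(maps, float)
    if values.ndim == 1:
        values = values[:, None]
    if isinstance(design, DesignSpec):
        values = transform_values(values, design)
    x = np.asarray(x, dtype=float)
    n = values.shape[0]
    if len(x) != n:
        raise DataError("predictor length does not match subject count")
    q = _design_basis(design)
    df = n - q.shape[1] - 1
    if df <= 0:
        raise DataError("not enough subjects for this design")
    xr = _residualize(x, q)
    sxx = float(xr @ xr)
    if sxx <= 1e-12 * max(float(x @ x), 1.0):
        raise DataError("predictor collinear with covariates")
    yr = _residualize(values, q)
    sxy = xr @ yr
    beta = sxy / sxx
    syy = (yr**2).sum(axis=0)
    rss = np.maximum(syy - beta * sxy, 0.0)
    degenerate = syy <= 1e-24 * (values**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / (df * sxx))
        t = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.inf * np.sign(beta)))
    t = np.where(degenerate, 0.0, t)
    if degenerate.any():
        logger.info("fit_glm: %d degenerate (zero-variance) elements", int(degenerate.sum()))
    with np.errstate(invalid="ignore"):
        partial_r2 = np.where(np.isinf(t), 1.0, t**2 / (t**2 + df))
    return GlmResult(t, beta, partial_r2, df, int(degenerate.sum()))


def disposing_dosage(
    g: GenotypeMatrix, variant_id: str, effect_allele: Optional[str] = None
) -> np.ndarray:
    """Dosage of the disposing (effect) allele, flipped when it is ref."""
    j = g.variant_index([variant_id])[0]
    d = g.dosages[:, j]
    if effect_allele is None or effect_allele == g.variants["alt"].iloc[j]:
        return d
    if effect_allele == g.variants["ref"].iloc[j]:
        return 2.0 - d
    raise DataError(
        f"effect allele {effect_allele!r} matches neither allele of {variant_id}"
    )


def variant_tmaps(
    g: GenotypeMatrix,
    variant_ids: Sequence[str],
    maps: ElementMaps,
    design,
    effect_alleles: Optional[dict] = None,
) -> TStatMatrix:
    """One fit_glm row per variant; predictor is disposing-allele dosage.

    Monomorphic variants yield a NaN row with a logged count.
    """
    rows = []
    df = None
    n_mono = 0
    for vid in variant_ids:
        ea = (effect_alleles or {}).get(vid)
        d = disposing_dosage(g, vid, ea)
        if np.nanstd(d) == 0.0:
            rows.append(np.full(maps.n_elements, np.nan))
            n_mono += 1
            continue
        res = fit_glm(maps, d, design)
        rows.append(res.t)
        df = res.df
    if df is None:
        raise DataError("all requested variants are monomorphic")
    if n_mono:
        logger.warning("variant_tmaps: %d monomorphic variants flagged NaN", n_mono)
    model = {
        "covariates": design.columns if isinstance(design, DesignSpec) else None,
        "log_transform": bool(getattr(design, "log_transform", False)),
    }
    return TStatMatrix(np.vstack(rows), df, np.asarray(list(variant_ids)), model)


def _tail_score(t: np.ndarray, tail: str) -> np.ndarray:
    if tail == "two":
        return np.abs(t)
    if tail == "right":
        return t
    if tail == "left":
        return -t
    raise ConfigError(f"unknown tail {tail!r}")


def permutation_fwe(
    maps,
    x: np.ndarray,
    design,
    n_perm: int = 5000,
    seed: Optional[int] = None,
    tail: str = "two",
    chunk: int = 256,
) -> FweResult:
    """Freedman-Lane max-statistic permutation FWE over elements.

    Maps are residualized on the design; for each permutation the rows of
    the residualized maps are permuted, re-residualized, and fitted against
    the residualized predictor; the maximum tail score over elements forms
    the null.  FWE p(element) = (1 + #{null maxima >= observed}) / (n_perm + 1).
    No cluster enhancement is applied.
    """
    if n_perm < 100:
        raise ConfigError("n_perm must be >= 100")
    values = maps.values if isinstance(maps, ElementMaps) else np.asarray(maps, float)
    if isinstance(design, DesignSpec):
        values = transform_values(values, design)
    n, n_elem = values.shape
    if math.lgamma(n + 1) < math.log(max(n_perm, 2)):
        logger.warning("only %d! distinct permutations exist for %d subjects", n, n)
    q = _design_basis(design)
    df = n - q.shape[1] - 1
    x = np.asarray(x, dtype=float)
    xr = _residualize(x, q)
    sxx = float(xr @ xr)
    if sxx <= 1e-12 * max(float(x @ x), 1.0):
        raise DataError("predictor collinear with covariates")
    yr = _residualize(values, q)
    syy = (yr**2).sum(axis=0)
    degenerate = syy <= 1e-24 * (values**2).sum(axis=0)

    def _t_from(num: np.ndarray, ss_fit: np.ndarray) -> np.ndarray:
        beta = num / sxx
        rss = np.maximum(syy[None, :] - ss_fit - beta * num, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta / np.sqrt(rss / (df * sxx))
        t = np.where(
            np.isfinite(t), t, np.where(beta == 0.0, 0.0, np.inf * np.sign(beta))
        )
        t[:, degenerate] = 0.0
        return t

    # observed: yr already orthogonal to the design
    t_obs = _t_from((xr @ yr)[None, :], np.zeros((1, n_elem)))[0]
    score_obs = _tail_score(t_obs, tail)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = np.stack([rng.permutation(n) for _ in range(m)])
        # numerator: xr' P yr for each permutation; the re-residualization of
        # P yr on the design leaves it unchanged because Q' xr = 0
        num = xr[perms.reshape(-1)].reshape(m, n) @ yr
        # sum of squares captured by the design after permutation
        ss_fit = np.zeros((m, n_elem))
        for col in range(q.shape[1]):
            proj = q[:, col][perms.reshape(-1)].reshape(m, n) @ yr
            ss_fit += proj**2
        t_perm = _t_from(num, ss_fit)
        null_max[done : done + m] = _tail_score(t_perm, tail).max(axis=1)
        done += m
    exceed = (null_max[None, :] >= score_obs[:, None]).sum(axis=1)
    p = (1.0 + exceed) / (n_perm + 1.0)
    p[degenerate] = 1.0
    return FweResult(p, t_obs, null_max, n_perm, seed, tail)


def idp_extract(maps, n_components: Sequence[int] = (11, 18, 29)):
    """Principal-component imaging-derived phenotypes (subject scores).

    The subject x element matrix is centered per element and decomposed by
    SVD; for each requested dimension d the top-d subject scores are
    returned, concatenated with provenance labels ``d{dim}_pc{i}``.
    """
    values = maps.values if isinstance(maps, ElementMaps) else np.asarray(maps, float)
    n, n_elem = values.shape
    dims = [int(d) for d in n_components]
    if max(dims) > min(n, n_elem):
        raise ConfigError("requested IDP dimension exceeds min(n_subjects, n_elements)")
    if max(dims) >= n:
        raise ConfigError("need more subjects than the largest IDP dimension")
    centered = values - values.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    scores = u * s
    blocks, labels = [], []
    for d in dims:
        blocks.append(scores[:, :d])
        labels.extend([f"d{d}_pc{i + 1}" for i in range(d)])
    return np.column_stack(blocks), labels
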