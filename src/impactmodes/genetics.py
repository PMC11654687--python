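"""Variant QC, LD clumping, relatedness pruning, and polygenic scoring.

The quality-control defaults match common GWAS practice on imputed cohort
data: MAF >= 0.01, imputation info > 0.7, Hardy-Weinberg chi-square
p > 1e-7.  Clumping is greedy p-value-ordered index selection with an LD r^2
threshold inside a fixed genomic window; relatedness pruning recursively
removes the most-connected individual from the kinship graph.  Polygenic
scores are weight-by-dosage sums with effect-allele alignment, and the
clumping+thresholding family is optimized by its strongest covariate-adjusted
association with any imaging-derived phenotype.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .types import DataError, GenotypeMatrix, PGSVector, SummaryStats

logger = logging.getLogger(__name__)


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Hardy-Weinberg equilibrium p-value (Pearson 1-df chi-square).

    Expected genotype counts come from the estimated allele frequency; a
    fixed (monomorphic) allele makes the test degenerate and returns 1.0.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if np.any(counts < 0):
        raise DataError("genotype counts must be nonnegative")
    n = counts.sum()
    if n < 1:
        raise DataError("need at least one genotype")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    if p <= 0.0 or p >= 1.0:
        return 1.0
    expected = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def hwe_from_dosages(dosages: np.ndarray) -> np.ndarray:
    """Per-variant HWE p from hard-call rounding of a subject x variant
    dosage matrix (missing values ignored)."""
    out = np.empty(dosages.shape[1])
    hard = np.rint(dosages)
    for v in range(dosages.shape[1]):
        col = hard[:, v]
        col = col[np.isfinite(col)]
        out[v] = hwe_test(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
    return out


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    info_min: float = 0.7,
    hwe_p_min: float = 1e-7,
    with_report: bool = False,
):
    """Keep variants with MAF >= maf_min, info > info_min and HWE p > hwe_p_min.

    Counts removed per criterion are logged (a variant can fail several).
    """
    maf = g.variants["maf"].to_numpy(dtype=float)
    info = g.variants["info"].to_numpy(dtype=float)
    hwe_p = hwe_from_dosages(g.dosages)
    fail_maf = maf < maf_min
    fail_info = ~(info > info_min)
    fail_hwe = ~(hwe_p > hwe_p_min)
    keep = ~(fail_maf | fail_info | fail_hwe)
    report = {
        "n_in": g.n_variants,
        "n_out": int(keep.sum()),
        "removed_maf": int(fail_maf.sum()),
        "removed_info": int(fail_info.sum()),
        "removed_hwe": int(fail_hwe.sum()),
    }
    logger.info(
        "QC: %(n_in)d -> %(n_out)d variants "
        "(MAF %(removed_maf)d, info %(removed_info)d, HWE %(removed_hwe)d removed)",
        report,
    )
    if report["n_out"] == 0:
        logger.warning("QC removed every variant")
    out = g.subset_variants(keep)
    return (out, report) if with_report else out


def ld_r2(d_i: np.ndarray, d_j: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors."""
    d_i = np.asarray(d_i, dtype=float)
    d_j = np.asarray(d_j, dtype=float)
    if d_i.shape != d_j.shape or d_i.ndim != 1 or len(d_i) < 2:
        raise DataError("dosage vectors must be equal-length 1-D with n >= 2")
    xi = d_i - d_i.mean()
    xj = d_j - d_j.mean()
    vi = float(xi @ xi)
    vj = float(xj @ xj)
    if vi == 0.0 or vj == 0.0:
        raise DataError("r2 undefined for a zero-variance dosage vector")
    r = float(xi @ xj) / np.sqrt(vi * vj)
    return r * r


def _safe_r2(xc: np.ndarray, yc: np.ndarray) -> float:
    """r2 between centered vectors, 0 when either is constant."""
    vi = float(xc @ xc)
    vj = float(yc @ yc)
    if vi == 0.0 or vj == 0.0:
        return 0.0
    r = float(xc @ yc) / np.sqrt(vi * vj)
    return r * r


def clump(
    ss: SummaryStats,
    g: GenotypeMatrix,
    p_thresh: float = 0.01,
    r2_thresh: float = 0.1,
    window_kb: float = 500.0,
) -> List[str]:
    """Greedy LD clumping: p-ordered index selection, discarding correlated
    same-chromosome neighbours within +/- window_kb.

    Ties on p are broken by smaller genomic position, then variant id, so
    the output is independent of input row order.  LD is computed in the
    target genotypes themselves.
    """
    merged = ss.table.merge(g.variants[["id", "chrom", "pos"]], on="id", how="inner")
    cand = merged[merged["p"] < p_thresh].copy()
    if cand.empty:
        return []
    cand = cand.sort_values(["p", "chrom", "pos", "id"], kind="mergesort")
    idx = g.variant_index(cand["id"].tolist())
    dos = g.dosages[:, idx]
    dos_c = dos - np.nanmean(dos, axis=0)
    chrom = cand["chrom"].to_numpy()
    pos = cand["pos"].to_numpy(dtype=float)
    ids = cand["id"].to_numpy()
    window = float(window_kb) * 1000.0
    alive = np.ones(len(cand), dtype=bool)
    indices: List[str] = []
    for i in range(len(cand)):
        if not alive[i]:
            continue
        indices.append(str(ids[i]))
        alive[i] = False
        near = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window)
        for j in np.flatnonzero(near):
            if _safe_r2(dos_c[:, i], dos_c[:, j]) >= r2_thresh:
                alive[j] = False
    return indices


def prune_relatedness(
    pairs: pd.DataFrame,
    threshold: float = 0.044,
    subjects: Optional[Iterable[str]] = None,
) -> set:
    """Maximal unrelated set by recursive max-degree removal.

    Builds a graph over pairs with kinship >= threshold and repeatedly
    deletes the highest-degree vertex (ties: lexicographically largest id)
    until no edge remains.  Subjects never listed in a qualifying pair are
    always kept.
    """
    keep = set(map(str, subjects)) if subjects is not None else set()
    graph = nx.Graph()
    for id1, id2, kin in pairs[["id1", "id2", "kinship"]].itertuples(index=False):
        keep.add(str(id1))
        keep.add(str(id2))
        if kin >= threshold:
            graph.add_edge(str(id1), str(id2))
    while graph.number_of_edges() > 0:
        degrees = dict(graph.degree())
        max_deg = max(degrees.values())
        victim = max(n for n, d in degrees.items() if d == max_deg)
        graph.remove_node(victim)
        keep.discard(victim)
    return keep


def compute_pgs(
    g: GenotypeMatrix, weights: pd.DataFrame, weight_set: str = ""
) -> PGSVector:
    """Polygenic score: sum of effect-allele-aligned dosage x weight.

    ``weights`` needs columns id, effect_allele, weight.  Dosage counts the
    alt allele, so a weight whose effect allele is ref enters as (2 - d);
    variants absent from the genotypes, or whose effect allele matches
    neither ref nor alt, are skipped with a logged count.  Missing dosages
    are mean-imputed per variant.
    """
    for col in ("id", "effect_allele", "weight"):
        if col not in weights.columns:
            raise DataError(f"weight table missing column {col!r}")
    lookup = pd.Index(g.variants["id"])
    idx = lookup.get_indexer(weights["id"])
    ea = weights["effect_allele"].to_numpy()
    w = weights["weight"].to_numpy(dtype=float)
    present = idx >= 0
    safe = np.where(present, idx, 0)
    is_alt = present & (ea == g.variants["alt"].to_numpy()[safe])
    is_ref = present & (ea == g.variants["ref"].to_numpy()[safe])
    for vid in weights["id"].to_numpy()[present & ~(is_alt | is_ref)]:
        logger.warning("variant %s: effect allele matches neither ref nor alt", vid)
    use = is_alt | is_ref
    d = g.dosages[:, idx[use]]
    if np.any(~np.isfinite(d)):
        col_mean = np.nanmean(d, axis=0)
        d = np.where(np.isfinite(d), d, col_mean)
    aligned = np.where(is_ref[use], 2.0 - d, d)
    scores = aligned @ w[use]
    n_used = int(use.sum())
    n_skipped = int((~use).sum())
    if n_skipped:
        logger.info("PGS %s: skipped %d of %d weights", weight_set, n_skipped, len(weights))
    return PGSVector(scores, g.subject_ids.copy(), weight_set, n_used, n_skipped)


def pgs_grid(
    ss: SummaryStats,
    g: GenotypeMatrix,
    p_thresholds: Sequence[float],
    clump_first: bool = True,
    r2_thresh: float = 0.1,
    window_kb: float = 500.0,
) -> Dict[float, PGSVector]:
    """Clumping+thresholding PGS family: one score per p-value threshold,
    using the discovery beta as weight.

    When ``clump_first`` is set the variants are clumped once at p < 1 and
    each threshold then selects the surviving index variants with p below it.
    """
    thresholds = list(p_thresholds)
    if thresholds != sorted(thresholds):
        raise DataError("p_thresholds must be sorted ascending")
    table = ss.table
    if clump_first:
        kept = clump(ss, g, p_thresh=1.0 + 1e-12, r2_thresh=r2_thresh, window_kb=window_kb)
        table = table[table["id"].isin(kept)]
    family: Dict[float, PGSVector] = {}
    for thr in thresholds:
        sel = table[table["p"] < thr]
        weights = pd.DataFrame(
            {
                "id": sel["id"],
                "effect_allele": sel["effect_allele"],
                "weight": sel["beta"],
            }
        )
        if weights.empty:
            logger.warning("no variant passes p < %g; zero-score PGS", thr)
            family[thr] = PGSVector(
                np.zeros(g.n_subjects), g.subject_ids.copy(), f"p<{thr:g}", 0, 0
            )
        else:
            family[thr] = compute_pgs(g, weights, weight_set=f"p<{thr:g}")
    return family


@dataclass
class PgsOptimizationReport:
    """Candidate x IDP grid of covariate-adjusted t-statistics."""

    t_grid: pd.DataFrame
    best: object
    best_t: float


def optimize_pgs(
    family: Dict, idps: np.ndarray, design) -> Tuple[object, PgsOptimizationReport]:
    """Select the candidate PGS maximizing max |t| over IDPs.

    Every IDP is regressed on each candidate score with the supplied
    covariate design; candidates are compared by their single strongest
    association, mirroring hyperparameter selection against an IDP panel.
    """
    from .assoc import fit_glm  # deferred: genetics must not be a hard dep of assoc

    if not family:
        raise DataError("empty PGS family")
    idps = np.asarray(idps, dtype=float)
    rows = {}
    best_key, best_t = None, -np.inf
    for key, pgs in family.items():
        scores = pgs.scores if isinstance(pgs, PGSVector) else np.asarray(pgs)
        if np.allclose(scores, scores[0]):
            t = np.zeros(idps.shape[1])
        else:
            t = fit_glm(idps, scores, design).t
        rows[key] = t
        top = float(np.nanmax(np.abs(t)))
        if top > best_t:
            best_key, best_t = key, top
    grid = pd.DataFrame(rows).T
    grid.columns = [f"idp{i}" for i in range(idps.shape[1])]
    return best_key, PgsOptimizationReport(grid, best_key, best_t)
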