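"""Validation experiments: planted-truth recovery and statistical calibration.

Each function runs one self-contained experiment against an independent
oracle (brute-force OLS, closed-form chi-square, exhaustive greedy
re-execution, known planted structure) and returns the measured quantity.
The test suite asserts on these numbers; the acceptance script reports them.
"""
from __future__ import annotations

import tempfile
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import fit_glm, permutation_fwe
from .config import RunConfig
from .genetics import clump, hwe_test, optimize_pgs, pgs_grid
from .io import read_table, read_truth
from .modes import decompose, match_modes
from .pipeline import run_pipeline
from .synth import SimConfig, _simulate_dosages, gen_genotypes, make_modes
from .types import GenotypeMatrix, SummaryStats, SyntheticTruth


# -- GLM oracle --------------------------------------------------------------

def ols_t_reference(y: np.ndarray, x: np.ndarray, design: np.ndarray):
    """Independent full-design OLS t for the x coefficient (normal equations)."""
    full = np.column_stack([x, design])
    beta, *_ = np.linalg.lstsq(full, y, rcond=None)
    resid = y - full @ beta
    df = len(y) - full.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(full.T @ full)
    return beta[0] / np.sqrt(cov[0, 0])


def glm_oracle_deviation(
    n_fixtures: int = 100, n: int = 50, n_elem: int = 10, n_cov: int = 5, seed: int = 0
) -> float:
    """Max |t_residualized - t_full_OLS| over random fixtures."""
    rng = np.random.default_rng([101, seed])
    worst = 0.0
    for _ in range(n_fixtures):
        design = np.column_stack([np.ones(n), rng.normal(size=(n, n_cov))])
        x = rng.normal(size=n)
        y = rng.normal(size=(n, n_elem))
        res = fit_glm(y, x, design)
        for e in range(n_elem):
            worst = max(worst, abs(res.t[e] - ols_t_reference(y[:, e], x, design)))
    return worst


# -- permutation calibration -------------------------------------------------

def fwe_null_rejection_rate(
    n_replicates: int = 500,
    n: int = 100,
    n_elem: int = 200,
    n_cov: int = 5,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Family-wise rejection rate under the global null.

    Each replicate draws covariates with real nuisance effects on the maps
    and a predictor unrelated to them; a rejection is any element with
    FWE p <= alpha.
    """
    rng = np.random.default_rng([202, seed])
    rejections = 0
    for rep in range(n_replicates):
        covs = rng.normal(size=(n, n_cov))
        design = np.column_stack([np.ones(n), covs])
        x = rng.normal(size=n)
        gamma = rng.normal(size=(n_cov, n_elem)) * 0.5
        y = covs @ gamma + rng.normal(size=(n, n_elem))
        res = permutation_fwe(
            y, x, design, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        rejections += int(np.any(res.p <= alpha))
    return rejections / n_replicates


# -- impact-mode recovery ----------------------------------------------------

def planted_tmatrix(
    k: int, n_variants: int, n_elements: int, snr: float, rng: np.random.Generator
):
    """Sparse planted sources x loadings plus Gaussian noise at a given
    component-SD : noise-SD ratio in t-space."""
    sources = make_modes(n_elements, k, 0.05, rng)
    mixing = np.zeros((n_variants, k))
    per = n_variants // k
    for j in range(k):
        mixing[j * per : (j + 1) * per, j] = rng.normal(0.0, 1.0, per)
    signal = mixing @ sources
    noise_sd = signal.std() / snr
    x = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    truth = SyntheticTruth(sources, mixing, mixing @ sources, np.zeros(n_variants))
    return x, truth


def mode_recovery(
    n_seeds: int = 10,
    k: int = 5,
    n_variants: int = 500,
    n_elements: int = 2000,
    snr: float = 5.0,
    seed: int = 0,
):
    """Mean matched spatial |r| and loading |r| over replicate seeds."""
    spatial, loading = [], []
    for rep in range(n_seeds):
        rng = np.random.default_rng([303, seed, rep])
        x, truth = planted_tmatrix(k, n_variants, n_elements, snr, rng)
        modeset = decompose(x, k=k, seed=seed + rep)
        match = match_modes(modeset, truth)
        spatial.append(match["spatial_abs_r"].mean())
        loading.append(match["loading_abs_r"].mean())
    return float(np.mean(spatial)), float(np.mean(loading))


def variance_accounting(seed: int = 0):
    """Variance-explained error on a rank-3 + noise matrix with a known
    signal-SS split, and the full-rank total (should be exactly 1)."""
    rng = np.random.default_rng([404, seed])
    sources = make_modes(500, 3, 0.08, rng)
    mixing = rng.normal(size=(150, 3)) * (rng.random((150, 3)) < 0.3)
    signal = mixing @ sources
    noise = rng.normal(0.0, 0.1, size=signal.shape)
    x = signal + noise
    known_fraction = float((signal**2).sum() / (x**2).sum())
    from .modes import variance_explained

    modeset = decompose(x, k=3, seed=seed)
    total, _ = variance_explained(x, modeset)
    noiseless = decompose(signal, k=3, seed=seed)
    total_full, _ = variance_explained(signal, noiseless)
    return {
        "fraction_error": abs(total - known_fraction),
        "full_rank_total": total_full,
        "known_fraction": known_fraction,
        "recovered_fraction": total,
    }


# -- genetics oracles --------------------------------------------------------

def hwe_oracle_deviation(n_triples: int = 1000, seed: int = 0) -> float:
    """Max |hwe_test - closed-form chi-square| over random count triples."""
    rng = np.random.default_rng([505, seed])
    worst = 0.0
    for _ in range(n_triples):
        c = rng.integers(0, 1000, size=3)
        if c.sum() == 0:
            c[0] = 1
        n = c.sum()
        p = (2 * c[0] + c[1]) / (2 * n)
        if p <= 0 or p >= 1:
            ref = 1.0
        else:
            exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
            ref = float(stats.chi2.sf(((c - exp) ** 2 / exp).sum(), 1))
        worst = max(worst, abs(hwe_test(*map(int, c)) - ref))
    return worst


def _clump_reference(ss_table, g, p_thresh, r2_thresh, window_kb):
    """Plain re-execution of the greedy clumping definition."""
    meta = g.variants.set_index("id")
    cand = sorted(
        (row.p, int(meta.loc[row.id, "pos"]), row.id)
        for row in ss_table.itertuples(index=False)
        if row.p < p_thresh and row.id in meta.index
    )
    alive = {c[2] for c in cand}
    chosen = []
    for _, _, vid in cand:
        if vid not in alive:
            continue
        chosen.append(vid)
        alive.discard(vid)
        j = g.variant_index([vid])[0]
        for _, _, other in cand:
            if other not in alive or meta.loc[other, "chrom"] != meta.loc[vid, "chrom"]:
                continue
            if abs(meta.loc[other, "pos"] - meta.loc[vid, "pos"]) > window_kb * 1000:
                continue
            a, b = g.dosages[:, j], g.dosages[:, g.variant_index([other])[0]]
            if a.std() == 0 or b.std() == 0:
                continue
            if np.corrcoef(a, b)[0, 1] ** 2 >= r2_thresh:
                alive.discard(other)
    return chosen


def clump_oracle_agreement(n_fixtures: int = 20, seed: int = 0) -> float:
    """Fraction of random <=20-variant fixtures where clumping matches the
    exhaustively re-executed greedy rule."""
    rng = np.random.default_rng([606, seed])
    agree = 0
    for _ in range(n_fixtures):
        n_var = int(rng.integers(5, 21))
        blocks = rng.integers(0, max(2, n_var // 3), size=n_var)
        d = rng.binomial(2, 0.5, size=(300, n_var)).astype(float)
        for v in range(n_var):
            first = int(np.flatnonzero(blocks == blocks[v])[0])
            if first != v:
                flip = rng.random(300) < 0.1
                d[:, v] = np.where(flip, 2 - d[:, first], d[:, first])
        pos = 1 + np.arange(n_var) * int(rng.integers(1_000, 400_000))
        freq = d.mean(axis=0) / 2
        variants = pd.DataFrame(
            {
                "id": [f"v{i}" for i in range(n_var)],
                "chrom": 1,
                "pos": pos,
                "ref": "A",
                "alt": "G",
                "maf": np.minimum(freq, 1 - freq),
                "info": 1.0,
            }
        )
        g = GenotypeMatrix(d, variants, np.array([f"S{i}" for i in range(300)]))
        ss = SummaryStats(
            pd.DataFrame(
                {
                    "id": variants["id"],
                    "effect_allele": "G",
                    "other_allele": "A",
                    "beta": rng.normal(size=n_var),
                    "se": 1.0,
                    "p": rng.uniform(1e-6, 1.0, n_var),
                }
            )
        )
        ours = clump(ss, g, 0.5, 0.2, 500)
        ref = _clump_reference(ss.table, g, 0.5, 0.2, 500)
        agree += int(ours == ref)
    return agree / n_fixtures


# -- polygenic-score validation ----------------------------------------------

def _pgs_scenario(seed: int, n_variants=2000, n_causal=30, causal_beta=0.09,
                  n_discovery=10_000, n_target=1000):
    """One discovery + target simulation with a constructed best threshold.

    Causal liability effects sit near z ~ 5 in the discovery GWAS, so a
    p < 1e-8 threshold misses most causal variants, p < 1e-3 captures nearly
    all of them with few nulls (the planted best), and p < 1 dilutes the
    score with every null variant.
    """
    rng = np.random.default_rng([707, seed])
    mafs = rng.uniform(0.1, 0.5, n_variants)
    block_id = np.arange(n_variants)
    causal_idx = rng.choice(n_variants, size=n_causal, replace=False)
    weights = np.zeros(n_variants)
    weights[causal_idx] = causal_beta * rng.choice([-1.0, 1.0], size=n_causal)
    # discovery cohort
    d_disc = _simulate_dosages(n_discovery, mafs, block_id, 0.0, rng)
    liab_disc = (d_disc - d_disc.mean(0)) @ weights + rng.standard_normal(n_discovery)
    from .synth import marginal_gwas

    res = marginal_gwas(d_disc, liab_disc)
    ids = [f"var{i:05d}" for i in range(n_variants)]
    variants = pd.DataFrame(
        {
            "id": ids, "chrom": 1 + (np.arange(n_variants) % 22),
            "pos": 1 + (np.arange(n_variants) // 22) * 1_000_000,
            "ref": "A", "alt": "G", "maf": mafs, "info": 1.0,
        }
    )
    ss = SummaryStats(
        pd.DataFrame(
            {
                "id": ids, "effect_allele": "G", "other_allele": "A",
                "beta": res["beta"], "se": res["se"], "p": res["p"],
            }
        )
    )
    # independent target cohort with the same architecture
    d_tgt = _simulate_dosages(n_target, mafs, block_id, 0.0, rng)
    liab_tgt = (d_tgt - d_tgt.mean(0)) @ weights + rng.standard_normal(n_target)
    g_tgt = GenotypeMatrix(
        d_tgt, variants, np.array([f"S{i:05d}" for i in range(n_target)])
    )
    return ss, g_tgt, liab_tgt


PGS_THRESHOLDS = (1e-8, 1e-3, 1.0)
PGS_PLANTED_BEST = 1e-3


def pgs_validation(n_seeds: int = 50, seed: int = 0):
    """Liability correlation of the planted-best C+T score, its 3-sigma
    lower bound, and how often the grid search selects that threshold."""
    rs, hits = [], 0
    for rep in range(n_seeds):
        ss, g, liab = _pgs_scenario(seed * 1000 + rep)
        family = pgs_grid(ss, g, list(PGS_THRESHOLDS))
        idps = liab[:, None] + np.random.default_rng([808, seed, rep]).normal(
            0.0, 0.5, size=(len(liab), 1)
        )
        design = np.ones((len(liab), 1))
        best, _ = optimize_pgs(family, idps, design)
        hits += int(best == PGS_PLANTED_BEST)
        rs.append(np.corrcoef(family[PGS_PLANTED_BEST].scores, liab)[0, 1])
    rs = np.asarray(rs)
    r_mean = float(rs.mean())
    r_3sigma_lower = r_mean - 3.0 * float(rs.std(ddof=1)) / np.sqrt(len(rs))
    return {
        "liability_r_mean": r_mean,
        "liability_r_3sigma_lower": r_3sigma_lower,
        "selection_rate": hits / n_seeds,
        "n_seeds": n_seeds,
    }


# -- end-to-end --------------------------------------------------------------

def endtoend_containment(n_seeds: int = 20, seed: int = 0, work_dir=None):
    """Fraction of high-SNR pipeline runs whose FWE-significant elements lie
    entirely inside the planted mode supports (and detect at least one)."""
    base = Path(work_dir) if work_dir else Path(tempfile.mkdtemp(prefix="e2e_"))
    sim = SimConfig(
        n_subjects=300, n_variants=160, ld_block_size=4, n_modes=3,
        grid_shape=(10, 10, 10), mode_sparsity=0.08, loading_sparsity=0.08,
        n_discovery=4000, n_related_pairs=8,
    )
    contained = 0
    detected = 0
    for rep in range(n_seeds):
        cfg = RunConfig(
            out_dir=str(base / f"run{rep}"), sim=sim, n_perm=300,
            k_modes=3, optimize=False,
        ).with_seed(seed * 100 + rep)
        out = run_pipeline(cfg)
        truth = read_truth(out / "inputs" / "truth.npz")
        fwe = read_table(out / "permute" / "fwe_p.tsv")
        sig = fwe["fwe_p"].to_numpy() <= 0.05
        support = truth.support_union()
        detected += int(sig.any())
        contained += int(sig.any() and not np.any(sig & ~support))
    return {
        "containment_rate": contained / n_seeds,
        "detection_rate": detected / n_seeds,
        "n_seeds": n_seeds,
    }
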