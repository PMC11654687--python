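"""End-to-end pipeline driver and reporting surface.

Stage sequence: simulate (optional) -> QC -> prune -> clump -> PGS
(+ grid/optimization) -> GLM (PGS and per-variant t-maps) -> permutation
FWE -> impact modes -> report.  Every stage reads its inputs from, and
writes its outputs to, the run directory, so stages can be re-run
individually; a manifest records the package version, config hash, seeds
and per-stage counts.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import build_design, fit_glm, idp_extract, permutation_fwe, variant_tmaps
from .config import RunConfig
from .genetics import clump, compute_pgs, optimize_pgs, pgs_grid, prune_relatedness, qc_filter
from .io import (
    read_genotypes,
    read_maps,
    read_sumstats,
    read_table,
    read_tmatrix,
    write_genotypes,
    write_maps,
    write_stat_map,
    write_sumstats,
    write_table,
    write_tmatrix,
    write_truth,
)
from .modes import decompose, mode_weights, normalize_jacobians, variance_explained
from .synth import simulate_cohort
from .types import DataError, VoxelGeometry

logger = logging.getLogger(__name__)

CORE_STAGES = ("qc", "prune", "clump", "pgs", "glm", "permute", "modes", "report")


def _dir(cfg: RunConfig, name: str) -> Path:
    d = Path(cfg.out_dir) / name
    d.mkdir(parents=True, exist_ok=True)
    return d


def _kept_subjects(cfg: RunConfig) -> np.ndarray:
    return np.loadtxt(Path(cfg.out_dir) / "prune" / "kept_subjects.txt", dtype=str, ndmin=1)


def _load_analysis_inputs(cfg: RunConfig):
    """QC'd genotypes, covariates, maps, all restricted to kept subjects."""
    kept = _kept_subjects(cfg)
    g = read_genotypes(Path(cfg.out_dir) / "qc").subset_subjects(kept)
    cov = read_table(Path(cfg.out_dir) / "inputs" / "covariates.tsv")
    cov = cov.set_index("subject_id").loc[kept].reset_index()
    maps = read_maps(Path(cfg.out_dir) / "inputs", cfg.geometry).subset_subjects(kept)
    return kept, g, cov, maps


def _design_for(cfg: RunConfig, cov: pd.DataFrame, maps):
    cov = cov.copy()
    if cfg.global_afd_adjust:
        cov["global_afd"] = maps.values.mean(axis=1)
    return build_design(
        cov,
        head_size_adjust=cfg.head_size_adjust,
        global_afd_adjust=cfg.global_afd_adjust,
        log_transform=cfg.log_jacobian and cfg.geometry == "voxel",
    )


# -- stages ------------------------------------------------------------------

def stage_simulate(cfg: RunConfig) -> dict:
    sim = replace(cfg.sim, seed=cfg.seed)
    genotypes, covariates, truth, maps, sumstats, kinship = simulate_cohort(
        sim, geometry=cfg.geometry
    )
    inputs = _dir(cfg, "inputs")
    write_genotypes(genotypes, inputs)
    write_table(covariates, inputs / "covariates.tsv")
    write_table(kinship, inputs / "kinship.tsv")
    write_sumstats(sumstats, inputs / "sumstats.tsv")
    write_maps(maps, inputs)
    write_truth(truth, inputs / "truth.npz")
    return {
        "n_subjects": genotypes.n_subjects,
        "n_variants": genotypes.n_variants,
        "n_elements": maps.n_elements,
    }


def stage_qc(cfg: RunConfig) -> dict:
    g = read_genotypes(Path(cfg.out_dir) / "inputs")
    g2, report = qc_filter(
        g, cfg.maf_min, cfg.info_min, cfg.hwe_p_min, with_report=True
    )
    write_genotypes(g2, _dir(cfg, "qc"))
    (Path(cfg.out_dir) / "qc" / "attrition.json").write_text(json.dumps(report, indent=2))
    return report


def stage_prune(cfg: RunConfig) -> dict:
    kinship = read_table(Path(cfg.out_dir) / "inputs" / "kinship.tsv")
    g = read_genotypes(Path(cfg.out_dir) / "qc")
    kept = prune_relatedness(kinship, cfg.kinship_threshold, subjects=g.subject_ids)
    ordered = [s for s in g.subject_ids if s in kept]
    out = _dir(cfg, "prune")
    np.savetxt(out / "kept_subjects.txt", np.asarray(ordered), fmt="%s")
    return {"n_in": g.n_subjects, "n_kept": len(ordered)}


def stage_clump(cfg: RunConfig) -> dict:
    kept = _kept_subjects(cfg)
    g = read_genotypes(Path(cfg.out_dir) / "qc").subset_subjects(kept)
    ss = read_sumstats(Path(cfg.out_dir) / "inputs" / "sumstats.tsv")
    indices = clump(ss, g, cfg.clump_p, cfg.clump_r2, cfg.clump_window_kb)
    table = ss.table[ss.table["id"].isin(indices)].copy()
    table["selection_order"] = [indices.index(i) for i in table["id"]]
    table = table.sort_values("selection_order")
    write_table(table, _dir(cfg, "clump") / "indices.tsv")
    return {"n_candidates": int((ss.table["p"] < cfg.clump_p).sum()), "n_indices": len(indices)}


def stage_pgs(cfg: RunConfig) -> dict:
    kept, g, cov, maps = _load_analysis_inputs(cfg)
    ss = read_sumstats(Path(cfg.out_dir) / "inputs" / "sumstats.tsv")
    indices = read_table(Path(cfg.out_dir) / "clump" / "indices.tsv")["id"].tolist()
    sel = ss.table[ss.table["id"].isin(indices)]
    weights = pd.DataFrame(
        {"id": sel["id"], "effect_allele": sel["effect_allele"], "weight": sel["beta"]}
    )
    pgs = compute_pgs(g, weights, weight_set=f"clump_p<{cfg.clump_p:g}")
    out = _dir(cfg, "pgs")
    write_table(
        pd.DataFrame({"subject_id": pgs.subject_ids, "score": pgs.scores}),
        out / "pgs.tsv",
    )
    info = {"n_variants_used": pgs.n_variants_used, "n_skipped": pgs.n_skipped}
    if cfg.optimize:
        family = pgs_grid(
            ss, g, list(cfg.pgs_grid_thresholds),
            clump_first=True, r2_thresh=cfg.clump_r2, window_kb=cfg.clump_window_kb,
        )
        idps, labels = idp_extract(maps, cfg.idp_dims)
        design = _design_for(cfg, cov, maps)
        best, report = optimize_pgs(family, idps, design)
        grid = report.t_grid.copy()
        grid.columns = labels
        grid.insert(0, "p_threshold", [f"{t:g}" for t in family])
        grid.insert(1, "n_variants", [family[t].n_variants_used for t in family])
        write_table(grid, out / "grid.tsv")
        (out / "optimize.json").write_text(
            json.dumps({"best_threshold": float(best), "best_abs_t": report.best_t}, indent=2)
        )
        info.update({"best_threshold": float(best), "best_abs_t": report.best_t})
    return info


def stage_glm(cfg: RunConfig) -> dict:
    kept, g, cov, maps = _load_analysis_inputs(cfg)
    design = _design_for(cfg, cov, maps)
    pgs = read_table(Path(cfg.out_dir) / "pgs" / "pgs.tsv")
    pgs = pgs.set_index("subject_id").loc[kept, "score"].to_numpy()
    res = fit_glm(maps, pgs, design)
    out = _dir(cfg, "glm")
    write_stat_map(res.t, maps.geometry, out / "tmap_pgs", maps.element_ids)
    write_table(
        pd.DataFrame(
            {"element_id": maps.element_ids, "t": res.t, "beta": res.beta,
             "partial_r2": res.partial_r2}
        ),
        out / "tmap_pgs.tsv",
    )
    indices = read_table(Path(cfg.out_dir) / "clump" / "indices.tsv")
    ea = dict(zip(indices["id"], indices["effect_allele"]))
    tmat = variant_tmaps(g, indices["id"].tolist(), maps, design, effect_alleles=ea)
    write_tmatrix(tmat, out / "tmat_variants.tsv", maps.element_ids)
    return {"df": res.df, "n_variants": tmat.t.shape[0],
            "max_abs_t_pgs": float(np.nanmax(np.abs(res.t)))}


def stage_permute(cfg: RunConfig) -> dict:
    kept, g, cov, maps = _load_analysis_inputs(cfg)
    design = _design_for(cfg, cov, maps)
    pgs = read_table(Path(cfg.out_dir) / "pgs" / "pgs.tsv")
    pgs = pgs.set_index("subject_id").loc[kept, "score"].to_numpy()
    fwe = permutation_fwe(
        maps, pgs, design, n_perm=cfg.n_perm, seed=cfg.seed + 1000, tail=cfg.perm_tail
    )
    out = _dir(cfg, "permute")
    write_table(
        pd.DataFrame({"element_id": maps.element_ids, "t": fwe.t_obs, "fwe_p": fwe.p}),
        out / "fwe_p.tsv",
    )
    write_stat_map(fwe.p, maps.geometry, out / "fwe_p", maps.element_ids)
    write_table(pd.DataFrame({"null_max": fwe.null_max}), out / "null_max.tsv")
    manifest = {"n_perm": fwe.n_perm, "seed": fwe.seed, "tail": fwe.tail,
                "n_significant_05": int((fwe.p <= 0.05).sum())}
    (out / "permute.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def stage_modes(cfg: RunConfig) -> dict:
    kept, g, cov, maps = _load_analysis_inputs(cfg)
    if cfg.normalize_before_modes and isinstance(maps.geometry, VoxelGeometry):
        maps = normalize_jacobians(maps)
    design = _design_for(cfg, cov, maps)
    indices = read_table(Path(cfg.out_dir) / "clump" / "indices.tsv")
    ea = dict(zip(indices["id"], indices["effect_allele"]))
    tmat = variant_tmaps(g, indices["id"].tolist(), maps, design, effect_alleles=ea)
    finite = np.all(np.isfinite(tmat.t), axis=1)
    if not finite.all():
        logger.warning("dropping %d monomorphic variant rows before ICA", int((~finite).sum()))
    from .types import TStatMatrix

    tmat = TStatMatrix(
        tmat.t[finite], tmat.df, tmat.predictor_ids[finite], tmat.model
    )
    modeset = decompose(tmat, k=cfg.k_modes, seed=cfg.seed + 2000)
    out = _dir(cfg, "modes")
    write_tmatrix(tmat, out / "tmat.tsv", maps.element_ids)
    maps_df = pd.DataFrame(
        modeset.spatial_maps.T, columns=[f"mode{j + 1}" for j in range(modeset.k)]
    )
    maps_df.insert(0, "element_id", maps.element_ids)
    write_table(maps_df, out / "spatial_maps.tsv")
    for j in range(modeset.k):
        write_stat_map(
            modeset.spatial_maps[j], maps.geometry, out / f"mode{j + 1}", maps.element_ids
        )
    write_table(mode_weights(modeset.mixing, tmat.predictor_ids), out / "weights.tsv")
    total, per_mode = variance_explained(tmat, modeset)
    summary = {
        "k": modeset.k,
        "variance_explained_total": total,
        "variance_explained_modes": per_mode.tolist(),
        "convergence": modeset.convergence,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return {"k": modeset.k, "variance_explained_total": total}


def stage_report(cfg: RunConfig) -> dict:
    text = report(cfg.out_dir)
    (Path(cfg.out_dir) / "report.txt").write_text(text)
    return {"n_lines": text.count("\n")}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "prune": stage_prune,
    "clump": stage_clump,
    "pgs": stage_pgs,
    "glm": stage_glm,
    "permute": stage_permute,
    "modes": stage_modes,
    "report": stage_report,
}


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages and write manifest.json; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    stages = (("simulate",) if cfg.simulate else ()) + CORE_STAGES
    manifest = {
        "package_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": [],
    }
    for name in stages:
        t0 = time.perf_counter()
        try:
            info = _STAGE_FUNCS[name](cfg)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        entry = {"name": name, "elapsed_s": round(time.perf_counter() - t0, 3)}
        entry.update(info or {})
        manifest["stages"].append(entry)
        logger.info("stage %s done in %.2fs", name, entry["elapsed_s"])
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def report(run_dir) -> str:
    """Human-readable summary of a (possibly partial) run."""
    run = Path(run_dir)
    lines = ["impact-mode pipeline report", "=" * 27]
    warn = []

    def _maybe(path):
        p = run / path
        return p if p.exists() else None

    if (p := _maybe("qc/attrition.json")) is not None:
        qc = json.loads(p.read_text())
        lines.append(
            f"QC: {qc['n_in']} -> {qc['n_out']} variants "
            f"(removed: MAF {qc['removed_maf']}, info {qc['removed_info']}, "
            f"HWE {qc['removed_hwe']})"
        )
    else:
        warn.append("qc outputs missing")
    if (p := _maybe("prune/kept_subjects.txt")) is not None:
        kept = np.loadtxt(p, dtype=str, ndmin=1)
        lines.append(f"Relatedness pruning: {len(kept)} subjects kept")
    else:
        warn.append("prune outputs missing")
    if (p := _maybe("clump/indices.tsv")) is not None:
        idx = read_table(p)
        lines.append(f"Clumping: {len(idx)} index variants")
        top = idx.nsmallest(min(5, len(idx)), "p")
        for row in top.itertuples(index=False):
            lines.append(f"  {row.id}  p={row.p:.3g}  beta={row.beta:+.3f}")
    else:
        warn.append("clump outputs missing")
    if (p := _maybe("pgs/grid.tsv")) is not None:
        grid = read_table(p)
        lines.append("PGS grid (max |t| over IDPs per threshold):")
        for row in grid.itertuples(index=False):
            tvals = np.abs(np.asarray(row[2:], dtype=float))
            lines.append(
                f"  p<{row.p_threshold}: n={row.n_variants}, max|t|={np.nanmax(tvals):.2f}"
            )
    if (p := _maybe("pgs/optimize.json")) is not None:
        opt = json.loads(p.read_text())
        lines.append(
            f"Selected PGS threshold: p<{opt['best_threshold']:g} "
            f"(max |t| = {opt['best_abs_t']:.2f})"
        )
    if (p := _maybe("permute/fwe_p.tsv")) is not None:
        fwe = read_table(p)
        sig = fwe[fwe["fwe_p"] <= 0.05]
        lines.append(
            f"Permutation FWE: {len(sig)} of {len(fwe)} elements significant at 0.05"
        )
        for row in sig.nsmallest(min(5, len(sig)), "fwe_p").itertuples(index=False):
            lines.append(f"  {row.element_id}  t={row.t:+.2f}  FWE p={row.fwe_p:.4g}")
    else:
        warn.append("permutation outputs missing")
    if (p := _maybe("modes/summary.json")) is not None:
        summ = json.loads(p.read_text())
        lines.append(
            f"Impact modes: K={summ['k']}, total variance explained "
            f"{100 * summ['variance_explained_total']:.1f}%"
        )
        weights = read_table(run / "modes" / "weights.tsv")
        for j in range(summ["k"]):
            wj = weights[weights["mode"] == j + 1]
            top = wj.loc[wj["weight_z"].abs().nlargest(3).index]
            ve = 100 * summ["variance_explained_modes"][j]
            names = ", ".join(
                f"{r.id} (z={r.weight_z:+.1f})" for r in top.itertuples(index=False)
            )
            lines.append(f"  mode {j + 1} ({ve:.1f}% var): {names}")
    else:
        warn.append("modes outputs missing")
    for w in warn:
        lines.append(f"WARNING: {w}")
    return "\n".join(lines) + "\n"
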