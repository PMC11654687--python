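"""Readers and writers for the pipeline's on-disk formats.

Tabular data are TSV; voxel maps are 4-D NIfTI (subject as 4th axis) with a
mask NIfTI and a subjects.txt sidecar; fixel data are a fixel-geometry TSV
(element_id, voxel_index, dir_x, dir_y, dir_z) paired with an AFD value
table.  The planted-truth archive is an internal .npz format.
"""
from __future__ import annotations

from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np
import pandas as pd

from .types import (
    DataError,
    ElementMaps,
    FixelGeometry,
    GenotypeMatrix,
    SummaryStats,
    SyntheticTruth,
    TStatMatrix,
    VoxelGeometry,
)

PathLike = Union[str, Path]


# -- tabular -----------------------------------------------------------------

def write_genotypes(g: GenotypeMatrix, out_dir: PathLike) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(g.dosages, columns=g.variants["id"])
    df.insert(0, "subject_id", g.subject_ids)
    df.to_csv(out / "genotypes.tsv", sep="\t", index=False)
    g.variants.to_csv(out / "variants.tsv", sep="\t", index=False)


def read_genotypes(in_dir: PathLike) -> GenotypeMatrix:
    src = Path(in_dir)
    df = pd.read_csv(src / "genotypes.tsv", sep="\t")
    variants = pd.read_csv(src / "variants.tsv", sep="\t")
    subject = df["subject_id"].to_numpy()
    dosages = df[variants["id"]].to_numpy(dtype=float)
    return GenotypeMatrix(dosages, variants, subject)


def write_sumstats(ss: SummaryStats, path: PathLike) -> None:
    ss.table.to_csv(path, sep="\t", index=False)


def read_sumstats(path: PathLike) -> SummaryStats:
    return SummaryStats(pd.read_csv(path, sep="\t"))


def write_table(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tmatrix(tmat: TStatMatrix, path: PathLike, element_ids=None) -> None:
    cols = element_ids if element_ids is not None else range(tmat.t.shape[1])
    df = pd.DataFrame(tmat.t, columns=list(cols))
    df.insert(0, "predictor", tmat.predictor_ids)
    df.to_csv(path, sep="\t", index=False)
    import json

    meta = {"df": int(tmat.df), "model": tmat.model}
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def read_tmatrix(path: PathLike) -> TStatMatrix:
    import json

    df = pd.read_csv(path, sep="\t")
    meta = json.loads(Path(str(path) + ".json").read_text())
    return TStatMatrix(
        df.drop(columns=["predictor"]).to_numpy(dtype=float),
        meta["df"],
        df["predictor"].to_numpy(),
        meta.get("model", {}),
    )


# -- maps --------------------------------------------------------------------

def write_maps(maps: ElementMaps, out_dir: PathLike, stem: str = "maps") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geom = maps.geometry
    np.savetxt(out / f"{stem}_subjects.txt", maps.subject_ids, fmt="%s")
    if isinstance(geom, VoxelGeometry):
        vol = np.zeros(geom.shape + (maps.n_subjects,))
        vol[geom.mask, :] = maps.values.T
        nib.save(nib.Nifti1Image(vol, geom.affine), out / f"{stem}.nii")
        nib.save(
            nib.Nifti1Image(geom.mask.astype(np.uint8), geom.affine),
            out / f"{stem}_mask.nii",
        )
    elif isinstance(geom, FixelGeometry):
        fixels = pd.DataFrame(
            {
                "element_id": maps.element_ids,
                "voxel_index": geom.voxel_index,
                "dir_x": geom.directions[:, 0],
                "dir_y": geom.directions[:, 1],
                "dir_z": geom.directions[:, 2],
            }
        )
        fixels.to_csv(out / f"{stem}_fixels.tsv", sep="\t", index=False)
        afd = pd.DataFrame(maps.values, columns=maps.element_ids)
        afd.insert(0, "subject_id", maps.subject_ids)
        afd.to_csv(out / f"{stem}_afd.tsv", sep="\t", index=False)
    else:
        raise DataError(f"unknown geometry type {type(geom).__name__}")


def read_maps(in_dir: PathLike, geometry: str, stem: str = "maps") -> ElementMaps:
    src = Path(in_dir)
    subjects = np.loadtxt(src / f"{stem}_subjects.txt", dtype=str, ndmin=1)
    if geometry == "voxel":
        img = nib.load(src / f"{stem}.nii")
        mask_img = nib.load(src / f"{stem}_mask.nii")
        mask = np.asarray(mask_img.dataobj).astype(bool)
        vol = np.asarray(img.dataobj, dtype=float)
        if vol.ndim != 4:
            raise DataError("voxel maps must be a 4-D NIfTI")
        if vol.shape[3] != len(subjects):
            raise DataError(
                f"subject count mismatch: {vol.shape[3]} volumes vs "
                f"{len(subjects)} listed subjects"
            )
        geom = VoxelGeometry(mask.shape, mask, np.asarray(img.affine))
        values = vol[mask, :].T
        return ElementMaps(values, geom, subjects)
    if geometry == "fixel":
        fixels = pd.read_csv(src / f"{stem}_fixels.tsv", sep="\t")
        dirs = fixels[["dir_x", "dir_y", "dir_z"]].to_numpy(dtype=float)
        norms = np.linalg.norm(dirs, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise DataError("fixel table contains non-unit direction vectors")
        geom = FixelGeometry(fixels["voxel_index"].to_numpy(), dirs)
        afd = pd.read_csv(src / f"{stem}_afd.tsv", sep="\t")
        if len(afd) != len(subjects):
            raise DataError(
                f"subject count mismatch: {len(afd)} AFD rows vs "
                f"{len(subjects)} listed subjects"
            )
        element_ids = fixels["element_id"].astype(str).to_numpy()
        values = afd[element_ids].to_numpy(dtype=float)
        return ElementMaps(values, geom, subjects, element_ids)
    raise DataError(f"unknown geometry {geometry!r}")


def write_stat_map(
    values: np.ndarray, geometry, path_stem: PathLike, element_ids=None
) -> None:
    """Write a per-element statistic map: NIfTI for voxels, TSV for fixels."""
    values = np.asarray(values, dtype=float)
    if isinstance(geometry, VoxelGeometry):
        vol = np.zeros(geometry.shape)
        vol[geometry.mask] = values
        nib.save(nib.Nifti1Image(vol, geometry.affine), str(path_stem) + ".nii")
    else:
        ids = element_ids if element_ids is not None else geometry.element_ids()
        pd.DataFrame({"element_id": ids, "value": values}).to_csv(
            str(path_stem) + ".tsv", sep="\t", index=False
        )


# -- truth archive -----------------------------------------------------------

def write_truth(truth: SyntheticTruth, path: PathLike) -> None:
    np.savez(
        path,
        spatial_modes=truth.spatial_modes,
        variant_loadings=truth.variant_loadings,
        effect_maps=truth.effect_maps,
        causal_pgs_weights=truth.causal_pgs_weights,
    )


def read_truth(path: PathLike) -> SyntheticTruth:
    with np.load(path) as z:
        return SyntheticTruth(
            z["spatial_modes"],
            z["variant_loadings"],
            z["effect_maps"],
            z["causal_pgs_weights"],
        )
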