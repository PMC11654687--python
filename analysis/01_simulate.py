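"""Simulate the synthetic cohort: genotypes in LD blocks, discovery-GWAS
summary statistics, covariates, kinship pairs, and voxel-wise brain maps
carrying a planted modes x loadings effect structure."""
import importlib.util
import sys
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "cfg00", Path(__file__).parent / "00_config.py"
)
cfg00 = importlib.util.module_from_spec(spec)
spec.loader.exec_module(cfg00)

from impactmodes.pipeline import stage_simulate

cfg = cfg00.get_config()
info = stage_simulate(cfg)
print(
    f"simulated {info['n_subjects']} subjects x {info['n_variants']} variants, "
    f"{info['n_elements']} in-mask voxels -> {cfg.out_dir}/inputs"
)
print(f"planted modes: {cfg.sim.n_modes}; map noise SD: {cfg.sim.noise_sd}")
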