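"""Genetic quality control: variant filters (MAF / info / Hardy-Weinberg),
relatedness pruning of the kinship graph, and LD clumping of the discovery
summary statistics down to independent index variants."""
import importlib.util
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "cfg00", Path(__file__).parent / "00_config.py"
)
cfg00 = importlib.util.module_from_spec(spec)
spec.loader.exec_module(cfg00)

from impactmodes.pipeline import stage_clump, stage_prune, stage_qc

cfg = cfg00.get_config()
qc = stage_qc(cfg)
print(
    f"QC: {qc['n_in']} -> {qc['n_out']} variants "
    f"(MAF {qc['removed_maf']}, info {qc['removed_info']}, HWE {qc['removed_hwe']})"
)
pr = stage_prune(cfg)
print(f"relatedness pruning at kinship >= {cfg.kinship_threshold}: "
      f"{pr['n_in']} -> {pr['n_kept']} subjects")
cl = stage_clump(cfg)
print(
    f"clumping (p<{cfg.clump_p}, r2<{cfg.clump_r2}, {cfg.clump_window_kb:g} kb): "
    f"{cl['n_candidates']} candidates -> {cl['n_indices']} index variants"
)
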