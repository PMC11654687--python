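"""Polygenic scoring: effect-allele-aligned weighted dosage sums over the
clumped index variants, plus a clumping+thresholding grid optimized against
PCA imaging-derived phenotypes."""
import importlib.util
import json
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "cfg00", Path(__file__).parent / "00_config.py"
)
cfg00 = importlib.util.module_from_spec(spec)
spec.loader.exec_module(cfg00)

from impactmodes.pipeline import stage_pgs

cfg = cfg00.get_config()
info = stage_pgs(cfg)
print(f"main PGS built from {info['n_variants_used']} clumped index variants")
if "best_threshold" in info:
    print(
        f"grid search over thresholds {cfg.pgs_grid_thresholds}: "
        f"selected p<{info['best_threshold']:g} "
        f"(max |t| over IDPs = {info['best_abs_t']:.2f})"
    )
grid = Path(cfg.out_dir) / "pgs" / "grid.tsv"
if grid.exists():
    print(f"candidate x IDP t grid written to {grid}")
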