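"""Mass-univariate brain associations: per-voxel GLM of the maps on the
polygenic score (and on each clumped variant's dosage), then max-statistic
permutation inference for brain-wide FWE-corrected p-values."""
import importlib.util
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "cfg00", Path(__file__).parent / "00_config.py"
)
cfg00 = importlib.util.module_from_spec(spec)
spec.loader.exec_module(cfg00)

from impactmodes.pipeline import stage_glm, stage_permute

cfg = cfg00.get_config()
glm = stage_glm(cfg)
print(
    f"GLM (df={glm['df']}): PGS max |t| = {glm['max_abs_t_pgs']:.2f}; "
    f"{glm['n_variants']} per-variant t-maps stacked"
)
perm = stage_permute(cfg)
print(
    f"permutation FWE ({perm['n_perm']} permutations, {perm['tail']}-tailed): "
    f"{perm['n_significant_05']} elements significant at FWE p <= 0.05"
)
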