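"""Shared configuration for the numbered analysis scripts.

Creates (or loads) the run configuration used by scripts 01-05: a synthetic
imaging-genetics cohort at desk scale with planted impact-mode structure,
analysed with the study-standard thresholds (MAF 0.01, info 0.7, HWE 1e-7,
kinship 0.044, clump p<0.01 / r2<0.1 / 500 kb, 5000 permutations, K modes).
"""
from pathlib import Path

from impactmodes.config import RunConfig
from impactmodes.synth import SimConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
RUN_DIR = RESULTS / "run"
CONFIG_PATH = RUN_DIR / "config.yaml"


def get_config() -> RunConfig:
    if CONFIG_PATH.exists():
        return RunConfig.from_yaml(CONFIG_PATH)
    cfg = RunConfig(
        out_dir=str(RUN_DIR),
        sim=SimConfig(n_subjects=400, n_variants=240, n_modes=3),
        k_modes=10,
        idp_dims=(11, 18, 29),
    ).with_seed(2024)
    RUN_DIR.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(CONFIG_PATH)
    return cfg


if __name__ == "__main__":
    cfg = get_config()
    print(f"run directory: {cfg.out_dir}")
    print(cfg.to_yaml())
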