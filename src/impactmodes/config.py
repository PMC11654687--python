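"""Run configuration: every stage toggle and threshold in one place.

Defaults follow standard imaging-genetics practice: MAF 0.01, info 0.7,
HWE p 1e-7, kinship 0.044, clumping at p < 0.01 / r^2 < 0.1 / 500 kb,
5000 permutations, and K = 10 impact modes.  The config serializes to a
plain-text YAML file with an exact round-trip.
"""
from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .synth import SimConfig
from .types import ConfigError


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    geometry: str = "voxel"
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    # variant QC
    maf_min: float = 0.01
    info_min: float = 0.7
    hwe_p_min: float = 1e-7
    # relatedness
    kinship_threshold: float = 0.044
    # clumping
    clump_p: float = 0.01
    clump_r2: float = 0.1
    clump_window_kb: float = 500.0
    # polygenic scoring
    pgs_grid_thresholds: tuple = (1e-5, 1e-3, 0.01, 0.1, 1.0)
    optimize: bool = True
    idp_dims: tuple = (11, 18, 29)
    # association / permutation
    n_perm: int = 5000
    perm_tail: str = "two"
    head_size_adjust: bool = False
    global_afd_adjust: bool = False
    log_jacobian: bool = False
    # impact modes
    normalize_before_modes: bool = True
    k_modes: int = 10

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        if not (0.0 <= self.maf_min <= 0.5):
            raise ConfigError("maf_min must lie in [0, 0.5]")
        if not (0.0 < self.clump_p <= 1.0):
            raise ConfigError("clump_p must lie in (0, 1]")
        if not (0.0 <= self.clump_r2 <= 1.0):
            raise ConfigError("clump_r2 must lie in [0, 1]")
        if self.kinship_threshold < 0:
            raise ConfigError("kinship_threshold must be nonnegative")
        if self.n_perm < 100:
            raise ConfigError("n_perm must be >= 100")
        if self.perm_tail not in ("two", "left", "right"):
            raise ConfigError("perm_tail must be one of two/left/right")
        if self.k_modes < 1:
            raise ConfigError("k_modes must be >= 1")
        if self.geometry not in ("voxel", "fixel"):
            raise ConfigError("geometry must be voxel or fixel")
        self.pgs_grid_thresholds = tuple(float(t) for t in self.pgs_grid_thresholds)
        self.idp_dims = tuple(int(d) for d in self.idp_dims)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["maf_range"] = list(self.sim.maf_range)
        d["sim"]["grid_shape"] = list(self.sim.grid_shape)
        d["pgs_grid_thresholds"] = list(self.pgs_grid_thresholds)
        d["idp_dims"] = list(self.idp_dims)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = dict(d.pop("sim", {}))
        for key in ("maf_range", "grid_shape"):
            if key in sim:
                sim[key] = tuple(sim[key])
        for key in ("pgs_grid_thresholds", "idp_dims"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(sim=SimConfig(**sim), **d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def with_seed(self, seed: int) -> "RunConfig":
        cfg = replace(self, seed=int(seed))
        cfg.sim = replace(self.sim, seed=int(seed))
        return cfg
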