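"""Pipeline configuration: every tunable in one schema-validated place.

Each parameter carries a provenance tag: ``protocol`` marks values fixed by
the WGBS analysis protocol this pipeline implements (site FDR 0.05, per-site
p < 1e-5, >50% significant loci, >=3 loci, >50 bp, 100 bp merge, 10 kb
windows, 2 kb promoters/flanks, DE padj 0.05); ``package`` marks
implementation-chosen defaults, so deviations from the protocol are
auditable.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml

from .synthetic_data import SimulationConfig

PARAM_PROVENANCE = {
    "alpha": "protocol",
    "p_threshold": "protocol",
    "sig_proportion": "protocol",
    "min_sites": "protocol",
    "min_length": "protocol",
    "merge_gap": "protocol",
    "promoter_length": "protocol",
    "bin_size": "protocol",
    "flank": "protocol",
    "de_alpha": "protocol",
    "max_site_gap": "package",
    "min_coverage": "package",
    "min_expr": "package",
    "dmr_method": "package",
    "smooth_span": "package",
    "body_bins": "package",
    "flank_bins": "package",
    "min_te_features": "package",
    "seed": "package",
}


@dataclass
class PipelineConfig:
    alpha: float = 0.05            # site-calling FDR threshold
    p_threshold: float = 1e-5      # per-site DMR p threshold (raw)
    sig_proportion: float = 0.5
    min_sites: int = 3
    min_length: int = 50
    merge_gap: int = 100
    max_site_gap: int = 500
    promoter_length: int = 2000
    bin_size: int = 10000
    flank: int = 2000
    min_coverage: int = 4
    de_alpha: float = 0.05
    min_expr: float = 0.1
    seed: int = 0
    body_bins: int = 60
    flank_bins: int = 20
    dmr_method: str = "smoothed"
    smooth_span: int = 600
    min_te_features: int = 5
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self):
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)

    def validate(self):
        for name in ("alpha", "p_threshold", "sig_proportion", "de_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in ("min_sites", "min_length", "merge_gap", "max_site_gap",
                     "promoter_length", "bin_size", "flank", "min_coverage",
                     "body_bins", "flank_bins", "smooth_span"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dmr_method not in ("smoothed", "fisher", "wald"):
            raise ValueError(f"unknown dmr_method {self.dmr_method!r}")
        self.simulation.validate()
        return self

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["provenance"] = dict(PARAM_PROVENANCE)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        data.pop("provenance", None)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim = data.get("simulation")
        if isinstance(sim, dict):
            sim_known = {f.name for f in fields(SimulationConfig)}
            sim_unknown = set(sim) - sim_known
            if sim_unknown:
                raise ValueError(
                    f"unknown simulation config keys: {sorted(sim_unknown)}"
                )
            for key in ("dmr_length_range", "gene_length_range", "groups"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
        return cls(**data).validate()

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        payload = yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)
        return hashlib.md5(payload.encode()).hexdigest()[:10]

    def with_seed(self, seed: int) -> "PipelineConfig":
        cfg = PipelineConfig.from_dict(
            {k: v for k, v in _plain(asdict(self)).items()}
        )
        cfg.seed = int(seed)
        cfg.simulation.seed = int(seed)
        return cfg


def _plain(obj):
    """Recursively convert tuples/numpy scalars so YAML stays canonical."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj
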