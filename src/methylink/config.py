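"""Pipeline configuration: every stage parameter with its standard default.

Configuration is a flat YAML key-value file; command-line flags override
file values.  The fully resolved configuration is logged at the start of
every CLI stage so each run records the thresholds it actually used.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    flank_bp: int = 2000
    window_bp: int = 200
    min_coverage: int = 4
    error_rate: float = 0.01
    call_alpha: float = 0.05
    # per-context DMR rules: min sites, min |diff|, max q
    dmr_thresholds: dict = field(
        default_factory=lambda: {
            "CG": [5, 0.25, 0.05],
            "CHG": [5, 0.25, 0.05],
            "CHH": [15, 0.15, 0.05],
            "allC": [20, 0.20, 0.05],
        }
    )
    fc_threshold: float = 1.0
    q_threshold: float = 0.05
    pseudocount: float = 1.0
    md_threshold: float = 25.0
    power: int = 8
    min_module_size: int = 50
    cut_height: float = 0.96
    n_bins_flank: int = 20
    n_bins_body: int = 20
    enrich_q: float = 0.05

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "PipelineConfig":
        values: dict = {}
        if path is not None:
            with open(path) as fh:
                loaded = yaml.safe_load(fh) or {}
            known = {f.name for f in fields(cls)}
            unknown = set(loaded) - known
            if unknown:
                raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
            values.update(loaded)
        values.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**values)
        logger.info("resolved config: %s", asdict(cfg))
        return cfg
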