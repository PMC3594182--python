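"""Pipeline configuration: thresholds, pKa table, logo options.

One flat key-value file (YAML) drives both the physicochemistry model
and the reporting options, and is echoed into every report so a run is
reproducible from its output alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .physchem import (
    DEFAULT_C_TERM_PKA,
    DEFAULT_N_TERM_PKA,
    DEFAULT_PHOSPHO_PKA,
    DEFAULT_SIDE_CHAIN_PKA,
    EnrichmentThresholds,
    IonizableModel,
)


@dataclass
class PipelineConfig:
    """All tunables of an end-to-end run."""

    pi_max: float = 4.5
    min_acidic: int = 3
    pfm_length: int = 14
    logo_small_sample_correction: bool = False
    mode: str = "auto"  # auto | nterm-only | sequence
    side_chain_pka: dict = field(
        default_factory=lambda: dict(DEFAULT_SIDE_CHAIN_PKA))
    n_term_pka: float = DEFAULT_N_TERM_PKA
    c_term_pka: float = DEFAULT_C_TERM_PKA
    phospho_pka: tuple = DEFAULT_PHOSPHO_PKA
    seed: Optional[int] = None

    def thresholds(self) -> EnrichmentThresholds:
        return EnrichmentThresholds(pi_max=self.pi_max,
                                    min_acidic=self.min_acidic)

    def ionizable_model(self) -> IonizableModel:
        return IonizableModel(
            side_chain_pka=dict(self.side_chain_pka),
            n_term_pka=self.n_term_pka,
            c_term_pka=self.c_term_pka,
            phospho_pka=tuple(self.phospho_pka),
        )

    def to_dict(self) -> dict:
        return {
            "pi_max": self.pi_max,
            "min_acidic": self.min_acidic,
            "pfm_length": self.pfm_length,
            "logo_small_sample_correction": self.logo_small_sample_correction,
            "mode": self.mode,
            "side_chain_pka": dict(self.side_chain_pka),
            "n_term_pka": self.n_term_pka,
            "c_term_pka": self.c_term_pka,
            "phospho_pka": list(self.phospho_pka),
            "seed": self.seed,
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise KeyError(f"unknown config key {key!r}")
            if key == "phospho_pka":
                value = tuple(value)
            setattr(cfg, key, value)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
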