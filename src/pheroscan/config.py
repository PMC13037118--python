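"""Pipeline configuration: every tunable threshold, with YAML round-trip.

Defaults reproduce the documented behaviour of each stage; unknown keys in a
config file are rejected rather than silently ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml


@dataclass
class TMConfig:
    """Transmembrane-segment detection (Kyte-Doolittle hydropathy)."""

    window: int = 19
    threshold: float = 1.6
    min_loop: int = 3


@dataclass
class SignalConfig:
    """Secretion-signal heuristic (hydrophobic core + basic n-region)."""

    window: int = 8
    threshold: float = 2.0
    first_n: int = 35
    n_region_len: int = 5
    c_region_scan: int = 10


@dataclass
class TurnConfig:
    """Beta-turn screen (Levitt propensity over 4-residue windows)."""

    threshold: float = 1.0


@dataclass
class NTermConfig:
    """N-terminal hydrophobicity gate for a-pheromone proteins."""

    k: int = 10
    threshold: float = 0.8


@dataclass
class CaaxConfig:
    """Residue classes for the CaaX/CpaX prenylation motif."""

    aliphatic: str = "AVLI"
    polar: str = "NSTQ"


@dataclass
class Kex2Config:
    allow_rr: bool = False


@dataclass
class Ste13Config:
    # de novo runs need >= min_dipeptides consecutive X-[AP] dipeptides;
    # runs anchored at a KEX2 cut or the signal end may be a single dipeptide
    min_dipeptides: int = 2


@dataclass
class AlphaConfig:
    """Mature alpha-peptide window and terminal-segment policy."""

    min_len: int = 9
    max_len: int = 15
    include_terminal_segment: bool = False


@dataclass
class APheromoneConfig:
    """a-pheromone ORF scan and mature-peptide window (lengths include the Cys)."""

    start_window_codons: int = 100
    mature_min: int = 7
    mature_max: int = 12


@dataclass
class AlignConfig:
    """Pairwise global alignment used for percent identity."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5


@dataclass
class SyntenyConfig:
    min_identity: float = 30.0


_SECTION_TYPES = {
    "tm": TMConfig,
    "signal": SignalConfig,
    "turn": TurnConfig,
    "nterm": NTermConfig,
    "caax": CaaxConfig,
    "kex2": Kex2Config,
    "ste13": Ste13Config,
    "alpha": AlphaConfig,
    "a_pheromone": APheromoneConfig,
    "align": AlignConfig,
    "synteny": SyntenyConfig,
}


@dataclass
class PipelineConfig:
    """All stage configurations plus the run seed."""

    tm: TMConfig = field(default_factory=TMConfig)
    signal: SignalConfig = field(default_factory=SignalConfig)
    turn: TurnConfig = field(default_factory=TurnConfig)
    nterm: NTermConfig = field(default_factory=NTermConfig)
    caax: CaaxConfig = field(default_factory=CaaxConfig)
    kex2: Kex2Config = field(default_factory=Kex2Config)
    ste13: Ste13Config = field(default_factory=Ste13Config)
    alpha: AlphaConfig = field(default_factory=AlphaConfig)
    a_pheromone: APheromoneConfig = field(default_factory=APheromoneConfig)
    align: AlignConfig = field(default_factory=AlignConfig)
    synteny: SyntenyConfig = field(default_factory=SyntenyConfig)
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        cfg = cls()
        for key, value in data.items():
            if key == "seed":
                cfg.seed = int(value)
                continue
            section_type = _SECTION_TYPES.get(key)
            if section_type is None:
                raise ValueError(f"unknown config section {key!r}")
            valid = {f.name for f in fields(section_type)}
            unknown = set(value) - valid
            if unknown:
                raise ValueError(
                    f"unknown key(s) in config section {key!r}: {sorted(unknown)}"
                )
            setattr(cfg, key, section_type(**value))
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


DEFAULT_CONFIG = PipelineConfig()
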