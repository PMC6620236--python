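"""Pipeline configuration: threshold regimes, context rules, assembly gaps.

Defaults are the published search settings: the strict ortholog (BBH) regime,
the relaxed shell-homolog regime, and the intermediate regime used for
evolutionary surveys, together with the 100 bp operon and 400 bp divergon
distance rules.  Everything is overridable from a YAML mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

from .model import BmcscanError


@dataclass(frozen=True)
class ThresholdSet:
    """Filter on alignment hits; unset criteria are not applied."""

    min_bits: Optional[float] = None
    max_evalue: Optional[float] = None
    min_identity_pct: Optional[float] = None
    min_positives_pct: Optional[float] = None
    min_coverage_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if all(
            v is None
            for v in (
                self.min_bits,
                self.max_evalue,
                self.min_identity_pct,
                self.min_positives_pct,
                self.min_coverage_pct,
            )
        ):
            raise BmcscanError("ThresholdSet: at least one criterion must be set")


#: the three published filter regimes (all comparisons inclusive)
REGIMES: dict[str, ThresholdSet] = {
    "bbh": ThresholdSet(
        min_bits=150.0,
        max_evalue=1e-50,
        min_identity_pct=30.0,
        min_positives_pct=50.0,
        min_coverage_pct=70.0,
    ),
    "shell": ThresholdSet(
        min_bits=20.0,
        max_evalue=1e-5,
        min_identity_pct=30.0,
        min_positives_pct=50.0,
        min_coverage_pct=40.0,
    ),
    "evolution": ThresholdSet(
        min_bits=100.0,
        max_evalue=1e-30,
        min_identity_pct=30.0,
    ),
}


@dataclass
class PipelineConfig:
    # aligner
    matrix: str = "BLOSUM62"
    gap_open: int = 11  # gap existence cost; a gap of length L costs open + L*extend
    gap_extend: int = 1
    ka_lambda: float = 0.267  # gapped Karlin–Altschul scale for BLOSUM62 11/1
    ka_k: float = 0.041
    # genomic context
    operon_gap_bp: int = 100
    divergon_start_gap_bp: int = 400
    # locus assembly
    locus_max_intervening_genes: int = 3
    locus_max_gap_bp: int = 5000
    # shell domain profiles
    profile_pseudocount: float = 0.1
    profile_threshold_margin_bits: float = 2.0
    # "associated with the BMC" scope for standalone calls: same locus or genome
    standalone_scope: str = "locus"
    # threshold regimes (name -> ThresholdSet)
    regimes: dict[str, ThresholdSet] = field(default_factory=lambda: dict(REGIMES))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["regimes"] = {k: asdict(v) for k, v in self.regimes.items()}
        return d

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        regimes = dict(REGIMES)
        for name, spec in (raw.pop("regimes", None) or {}).items():
            regimes[name] = ThresholdSet(**spec)
        known = {f for f in cls.__dataclass_fields__ if f != "regimes"}
        unknown = set(raw) - known
        if unknown:
            raise BmcscanError(f"unknown config keys: {sorted(unknown)}")
        return cls(regimes=regimes, **raw)


DEFAULT_CONFIG = PipelineConfig()
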