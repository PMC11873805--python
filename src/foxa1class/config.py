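"""One structured configuration for every threshold in the pipeline.

All published decision thresholds live here with their defaults: domain
boundaries (168/247/269), the R219C/S hotspot, amplification at >=6
copies, TMB-high at >=10 mut/Mb, the 100-day claim-gap death rule, the
90-day castration-state window, and the MTR window.  A YAML file can
override any subset; gene-set signatures are likewise configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import yaml

from .associations import DEFAULT_TMB_HIGH_THRESHOLD
from .classifier import DomainModel
from .mtr import DEFAULT_WINDOW
from .simulate import DEFAULT_SIGNATURES, GeneratorConfig
from .survival import DEFAULT_CASTRATION_WINDOW_DAYS, DEFAULT_GAP_DAYS


@dataclass
class AnalysisConfig:
    domain: DomainModel = field(default_factory=DomainModel)
    gap_days: float = DEFAULT_GAP_DAYS
    castration_window_days: float = DEFAULT_CASTRATION_WINDOW_DAYS
    tmb_high_threshold: float = DEFAULT_TMB_HIGH_THRESHOLD
    mtr_window: int = DEFAULT_WINDOW
    include_vus: bool = False
    chi2_continuity: bool = True
    signatures: dict = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_SIGNATURES.items()}
    )
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)


def load_config(path: Optional[str] = None, overrides: Optional[Mapping] = None) -> AnalysisConfig:
    """Build an AnalysisConfig from an optional YAML file plus overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data.update(overrides)
    cfg = AnalysisConfig()
    domain_kwargs = data.pop("domain", {})
    if domain_kwargs:
        if "class2_alt_residues" in domain_kwargs:
            domain_kwargs["class2_alt_residues"] = frozenset(
                domain_kwargs["class2_alt_residues"]
            )
        cfg.domain = dataclasses.replace(cfg.domain, **domain_kwargs)
    gen_kwargs = data.pop("generator", {})
    if gen_kwargs:
        cfg.generator = dataclasses.replace(cfg.generator, **gen_kwargs)
    cfg.generator.domain = cfg.domain
    for key, value in data.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown configuration key {key!r}")
        setattr(cfg, key, value)
    return cfg


def dump_config(cfg: AnalysisConfig) -> str:
    """Canonical YAML rendering (used for the run-manifest hash)."""

    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: clean(v) for k, v in sorted(dataclasses.asdict(obj).items())}
        if isinstance(obj, frozenset):
            return sorted(obj)
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in sorted(obj.items())}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        return obj

    return yaml.safe_dump(clean(cfg), sort_keys=True)
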