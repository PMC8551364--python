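"""Analysis and simulation configuration.

``AnalysisConfig`` carries the global statistical knobs (significance level,
reporter-score threshold, permutation count, FDR method, RNG seed and the
pseudocount used by log/JSD operations).  ``SimulationDesign`` lives in
:mod:`ragut.simulate`.  Both can be loaded from one YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    alpha: float = 0.05
    reporter_threshold: float = 1.65
    n_permutations: int = 9999
    fdr_method: str = "bh"
    rng_seed: int = 0
    pseudocount: float = 1e-6
    #: features present in fewer than this fraction of samples are dropped
    #: before differential testing; 0 disables the filter entirely.
    prevalence_min: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        if self.reporter_threshold <= 0:
            raise ValueError("reporter_threshold must be positive")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def _from_mapping(cls, mapping: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} key(s): {sorted(unknown)}")
    return cls(**mapping)


def load_config(path: str | Path):
    """Load a YAML config with optional ``analysis``, ``simulation`` and
    ``paths`` sections; returns (AnalysisConfig, dict, dict)."""
    from .simulate import SimulationDesign

    raw = yaml.safe_load(Path(path).read_text()) or {}
    analysis = _from_mapping(AnalysisConfig, raw.get("analysis", {}))
    design = _from_mapping(SimulationDesign, raw.get("simulation", {}))
    paths = raw.get("paths", {})
    return analysis, design, paths
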