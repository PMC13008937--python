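"""Analysis configuration shared by the pipeline stages and the CLI."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Knobs of the select → clump → harmonize → estimate chain.

    ``p_threshold`` is the instrument-selection threshold (1e-5, the
    conventional relaxed threshold for molecular exposures); clumping
    defaults r² = 0.001 within 10,000 kb; palindromic variants are dropped
    when either allele frequency falls in (0.40, 0.60) or is missing.
    """

    p_threshold: float = 1e-5
    r2_threshold: float = 0.001
    window_kb: float = 10_000.0
    palindrome_eaf_window: tuple[float, float] = (0.40, 0.60)
    ivw_model: str = "multiplicative_random"
    n_boot: int = 1000
    phi: float = 1.0
    seed: int = 0

    def replace(self, **kw) -> "AnalysisConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "AnalysisConfig":
        """Load from a YAML mapping; keyword overrides win over file values."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        merged = {k: v for k, v in data.items() if k in known}
        merged.update({k: v for k, v in overrides.items() if v is not None})
        if "palindrome_eaf_window" in merged:
            merged["palindrome_eaf_window"] = tuple(merged["palindrome_eaf_window"])
        return cls(**merged)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
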