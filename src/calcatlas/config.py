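"""Pipeline configuration with documented defaults.

Round-trips losslessly through JSON; every field maps to one tunable of the
pipeline stages (sigmoid enhancement, region growing, SPHARM order and MDL
search, FDR level for coefficient reduction, symmetry-analysis exclusion).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    sigmoid_gain: float = 0.4          # logistic gain g
    sigmoid_cutoff: float = 0.7        # logistic cut-off c
    region_tolerance: float = 0.2      # region-growing tau, post-sigmoid units
    sagittal_axis: int = 2             # array axis of the slice stack
    max_order: int = 11                # SPHARM L_max
    use_mdl: bool = True               # select L by MDL below L_max
    fdr_level: float = 0.05            # BH level for coefficient reduction
    quartile_method: str = "linear"    # quantile interpolation convention
    exclude_top: int = 3               # coefficients dropped in symmetry r^2
    seed: int = 0

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
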