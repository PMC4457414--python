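"""Run configuration: the thresholds that steer every pipeline stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All tunable thresholds of the analysis, with their conventional defaults.

    ``clustering_threshold`` (>0.80 identity) and ``activity_threshold``
    (~0.98) come from the introner literature; the remaining defaults are
    package choices documented in docs/methods.md and exposed here so a run
    is fully described by its config (echoed, hashed, into every output).
    """

    clustering_threshold: float = 0.80
    assignment_min_identity: float = 0.70
    min_overlap_frac: float = 0.6
    rsi_range: tuple[int, int] = (40, 60)
    long_intron_threshold: int = 70
    activity_threshold: float = 0.98
    sliding_window_nt: int = 15
    shift_window: int = 1
    refine: bool = True
    primer_len: int = 18
    max_variable: int = 4
    max_mismatch: int = 1
    max_amplicon: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        self.rsi_range = tuple(self.rsi_range)  # type: ignore[assignment]
        for name, lo, hi in [
            ("clustering_threshold", 0.0, 1.0),
            ("assignment_min_identity", 0.0, 1.0),
            ("min_overlap_frac", 0.0, 1.0),
            ("activity_threshold", 0.0, 1.0),
        ]:
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.sliding_window_nt < 1 or self.shift_window < 0:
            raise ValueError("window parameters must be positive")
        if self.rsi_range[0] > self.rsi_range[1]:
            raise ValueError("rsi_range must be (low, high)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rsi_range"] = list(self.rsi_range)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(str(path)).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(str(path)).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
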