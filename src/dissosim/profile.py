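"""The dissolution profile: cumulative % dissolved versus time in minutes.

The universal exchange object between the simulator, the profile metrics, the
fitting layer, and file I/O (two-column CSV ``time_min,pct_dissolved``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["DissolutionProfile"]


@dataclass
class DissolutionProfile:
    times_min: np.ndarray
    pct_dissolved: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.pct_dissolved = np.asarray(self.pct_dissolved, dtype=float)
        if self.times_min.shape != self.pct_dissolved.shape:
            raise ValueError("time and percent arrays must have equal length")
        if self.times_min.size and np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        # measured data may slightly exceed 100% (assay noise); allow 2 points
        if self.pct_dissolved.size and (
            np.any(self.pct_dissolved < 0) or np.any(self.pct_dissolved > 102.0)
        ):
            raise ValueError("percent dissolved must lie in [0, 102]")

    def __len__(self) -> int:
        return self.times_min.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_min": self.times_min, "pct_dissolved": self.pct_dissolved}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **metadata) -> "DissolutionProfile":
        df = pd.read_csv(path, comment="#")
        return cls(
            times_min=df["time_min"].to_numpy(),
            pct_dissolved=df["pct_dissolved"].to_numpy(),
            metadata=metadata,
        )
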