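"""Pipeline configuration with YAML/JSON round-tripping."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Everything a full reconstruction run needs, in one serializable object.

    Thresholds default to the conventional values for this analysis: a 1.6
    linear fold change for the DEG filter, |r| > 0.9 for prior edges (with
    the matching 0.1 dendrogram cut on the 1-|r| scale), and |r| > 0.5 for
    combinatorial TF pairs.
    """

    expression_path: str = ""
    tf_list_path: str = ""
    curated_edges_path: str | None = None
    output_dir: str = "ncanet_out"
    control_stage: str = "MP"

    fc_threshold: float = 1.6
    r_threshold: float = 0.9
    tf_corr_threshold: float = 0.5
    cut_height: float = 0.1

    tol: float = 1e-8
    max_iter: int = 1000
    n_restarts: int = 10
    n_boot: int = 0  # 0 disables the bootstrap stage

    motif_sizes: list[int] = field(default_factory=lambda: [3, 4, 5])
    n_random: int = 1000

    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 < self.fc_threshold:
            raise ValueError("fc_threshold must exceed 1")
        if not 0 < self.r_threshold < 1:
            raise ValueError("r_threshold must be in (0, 1)")
        if not 0 < self.tf_corr_threshold <= 1:
            raise ValueError("tf_corr_threshold must be in (0, 1]")
        if self.cut_height <= 0:
            raise ValueError("cut_height must be positive")
        bad = [k for k in self.motif_sizes if not 3 <= k <= 5]
        if bad:
            raise ValueError(f"motif sizes outside 3..5: {bad}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
                if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=True))
        path.write_text(text, encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)
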