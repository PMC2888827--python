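"""Run configuration shared by the CLI and report writers."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, with their defaults.

    The defaults are the canonical analysis constants: 1000-nt cluster
    cutoff, 5 flanking genes per side, 40-kb windows with >= 2 supporting
    orthologs, and 50-1000 randomization replicates.
    """

    cluster_cutoff_nt: int = 1000
    flank_k: int = 5
    window_nt: int = 40_000
    min_orthologs: int = 2
    n_max_replicates: int = 1000
    n_min_replicates: int = 50
    early_stop_p: float = 0.2
    statistic_kind: str = "pairs"
    pvalue_pseudocount: bool = False
    strand_specific: bool = True
    flank_orientation: str = "reading"
    seed: int | None = None
    exclude_species: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("cluster_cutoff_nt", "flank_k", "window_nt", "min_orthologs",
                     "n_max_replicates", "n_min_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def provenance_header(self) -> str:
        """Comment block embedded at the top of every report file."""
        lines = [f"# tdnakit config_hash={self.config_hash} seed={self.seed}"]
        lines.append("# " + json.dumps(self.to_dict(), sort_keys=True))
        return "\n".join(lines) + "\n"
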