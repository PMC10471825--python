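"""Run configuration: input paths, thresholds and seeds.

Thresholds default to the analysis conventions used throughout the package:
meta-QTLs are kept at average PVE >= 5% with support from >= 2 studies,
expression responsiveness is 1.5-fold at both timepoints and 2-fold at 24 h,
accessions with > 20% missing/heterozygous calls are dropped, and genetic
coordinates follow the fixed 1 cM = 250 kb conversion.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    catalog: str = "qtl_catalog.tsv"
    studies: str = "studies.tsv"
    markers: str = "markers.tsv"
    genes: str = "genes.tsv"
    gene2go: str = "gene2go.tsv"
    expression: str = "expression.tsv"
    subpop: str = "subpop.tsv"
    donors: str = "donors.tsv"
    snp_prefix: str = "snp_"

    min_avg_pve: float = 5.0
    min_studies: int = 2
    fc1: float = 1.5
    fc2: float = 2.0
    bad_fraction: float = 0.2
    bp_per_cm: float = 250_000.0
    small_threshold: int = 10
    seed: int = 0

    workspace: str = "."
    outdir: str = "results"

    def __post_init__(self) -> None:
        for name in ("min_avg_pve", "fc1", "fc2", "bad_fraction", "bp_per_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    def path(self, name: str) -> Path:
        return Path(self.workspace) / getattr(self, name)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the analysis configuration (inputs, thresholds,
        seed), echoed into output headers. The output directory is excluded
        so identical analyses hash identically wherever they are written."""
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
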