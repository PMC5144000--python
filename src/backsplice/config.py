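"""Run configuration with lossless JSON round-trip."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass


@dataclass
class RunConfig:
    # junction calling
    threshold: float = 10.0  # bits, donor+acceptor total
    min_circ_len: int = 100
    min_segment: int = 15
    min_read_coverage: float = 0.9
    microhomology_window: int = 10
    circ_max_span: int = 1_000_000
    fusion_max_span: int = 1_000_000
    # quantification
    min_overhang: int = 4
    seed_k: int = 32
    # pair merging
    min_overlap: int = 10
    max_mismatch_frac: float = 0.05
    # aligner
    aligner_k: int = 14
    # simulator
    n_genes: int = 50
    n_chroms: int = 2
    read_len: int = 100
    mode: str = "SE"
    n_reads_each: int = 20
    reads_per_junction: int = 10
    n_fusion_events: int = 10
    frac_two_circ: float = 0.05
    insert_mean: float = 200.0
    insert_sd: float = 50.0
    min_flank: int = 4
    seed: int = 0

    RANGES = {
        "threshold": (-100.0, 100.0),
        "min_circ_len": (1, 10**9),
        "min_segment": (1, 10**4),
        "min_read_coverage": (0.0, 1.0),
        "microhomology_window": (0, 100),
        "min_overhang": (1, 10**4),
        "max_mismatch_frac": (0.0, 1.0),
        "frac_two_circ": (0.0, 1.0),
    }

    def __post_init__(self):
        for name, (lo, hi) in self.RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.mode not in ("SE", "PE"):
            raise ValueError("mode must be SE or PE")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
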