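"""Pipeline configuration.

Every tunable threshold of the pipeline lives in :class:`RunConfig` with
the published analysis values as defaults, so a default-constructed config
reproduces the study's decision rules.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # --- lineage dependency scoring & filter cascade ---
    ld_cutoff: float = -1.2          # filter 1: LD score must be below this
    ld_p_cutoff: float = 0.05        # filter 1: significance cutoff
    ld_use_adjusted_p: bool = True   # filter 1 on BH-adjusted p (raw-p switch)
    bh_scope: str = "per-lineage"    # BH family: per-lineage | global
    ld_outgroup: str = "all"         # out-group pool: all annotated lines | eligible lineages only
    min_lineage_size: int = 10       # lineages with fewer lines are dropped
    strong_dep_ceres: float = -0.5   # filter 2: "strong dependency" CERES level
    strong_dep_fraction: float = 0.5 # filter 2: strict majority of lineage lines
    pan_essential_median: float = -0.2  # filter 3: pan-essential median cutoff

    # --- resistance classification & acquired-dependency scan ---
    resistance_cutoff: float = -0.45  # avg CERES above this -> resistant
    n_permutations: int = 1000
    q_threshold: float = 0.1

    # --- consensus peaks / differential accessibility ---
    consensus_width: int = 501       # summit +/- 250 bp
    peak_q_filter: float = 20.0      # -log10(q) significance filter
    peak_q_keep_significant: bool = True  # False = literal "< threshold" reading
    read_extension: int = 250        # modal fragment length, bp
    da_fc: float = 2.0               # fold-change threshold (|log2fc| >= 1)
    da_padj: float = 0.001

    # --- window enrichment ---
    # half-widths in bp; the axis of the accessibility-vs-expression coupling scan
    window_sizes: tuple[int, ...] = (
        5_000, 10_000, 25_000, 50_000, 100_000, 250_000, 500_000, 1_000_000,
    )

    # --- open-chromatin profile clustering ---
    pcc_threshold: float = 0.6
    top_variable_regions: int = 250_000
    min_cluster_size: int = 5
    presence_fraction: float = 0.8
    max_additional_clusters: int = 2
    summit_flank: int = 25

    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v}")
        ws = tuple(int(w) for w in self.window_sizes)
        if any(w <= 0 for w in ws) or any(b <= a for a, b in zip(ws, ws[1:])):
            raise ValueError("window_sizes must be strictly increasing positive integers")
        self.window_sizes = ws
        if self.bh_scope not in ("per-lineage", "global"):
            raise ValueError(f"bh_scope must be 'per-lineage' or 'global', got {self.bh_scope!r}")
        if self.ld_outgroup not in ("all", "eligible"):
            raise ValueError(f"ld_outgroup must be 'all' or 'eligible', got {self.ld_outgroup!r}")
        if self.consensus_width % 2 != 1:
            raise ValueError("consensus_width must be odd (symmetric around the summit)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load overrides from a YAML key: value file onto the defaults."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window_sizes"] = list(d["window_sizes"])
        return d
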