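"""Run configuration.

One :class:`RunConfig` object carries every tunable of the pipeline so a
run is a pure function of (inputs, config).  Defaults follow the copy-
characterization protocol for VIPER/TATE-like tyrosine-recombinase
retrotransposons: candidate loci are retrieved with 8 kb flanks, an ORF
counts as potentially encoding only above a role-specific protein size
(gag-like > 300 aa, YR > 250 aa, RT/RH > 600 aa), and same-species
redundancy is removed below 35% divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Mapping

import yaml

ROLES = ("gag_like", "yr", "rt_rh")


@dataclass
class RunConfig:
    # locus retrieval / reporting
    flank_bp: int = 8000

    # ORF discovery and role thresholds (strict ">" on translated length)
    min_aa: dict[str, int] = field(
        default_factory=lambda: {"gag_like": 300, "yr": 250, "rt_rh": 600}
    )
    orf_scan_min_aa: int = 100
    panel_score_floor: float = 60.0
    positional_gap_max_bp: int = 1000
    frameshift_gap_max_bp: int = 300
    frameshift_max_overlap_aa: int = 30

    # split-direct-repeat detection
    seed_len: int = 12
    min_repeat_len: int = 50
    max_mismatch_frac: float = 0.1
    terminal_window_bp: int = 1000
    gap_warn_bp: int = 1000
    tandem_min_len: int = 1000
    tandem_max_gap_bp: int = 100

    # copy-status classification
    contig_end_window_bp: int = 500
    n_run_min_len: int = 50

    # divergence / redundancy
    redundancy_threshold: float = 0.35
    redundancy_on_corrected: bool = False
    dedupe_identity: float = 0.95
    mask_window: int = 5
    mask_gap_frac: float = 0.5

    # subsampling ("most conserved" ranking by summed panel score)
    max_copies_per_dataset: int | None = None

    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "flank_bp",
            "orf_scan_min_aa",
            "seed_len",
            "min_repeat_len",
            "terminal_window_bp",
            "gap_warn_bp",
            "tandem_min_len",
            "contig_end_window_bp",
            "n_run_min_len",
            "mask_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("max_mismatch_frac", "redundancy_threshold", "mask_gap_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        missing = [r for r in ROLES if r not in self.min_aa]
        if missing:
            raise ValueError(f"min_aa missing roles: {missing}")
        if any(v <= 0 for v in self.min_aa.values()):
            raise ValueError("min_aa thresholds must be positive")

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
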