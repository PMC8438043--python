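"""Run configuration shared by all pipeline stages.

A single declarative object controls digestion limits, scoring
thresholds, FDR levels and simulator noise settings.  Every output file
header records the config hash and seed so that reruns are auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass
class RunConfig:
    # --- digestion / search space ---
    max_missed_cleavages: int = 1        # DIA search default
    min_peptide_length: int = 7
    max_peptide_length: int = 30
    max_variable_mods: int = 2
    precursor_charges: tuple[int, ...] = (2, 3)
    fragment_charge: int = 1
    max_fragments_per_series: int = 5
    min_fragment_index: int = 2

    # --- scoring ---
    smooth_width: int = 3                # moving-mean width (grid points)
    min_peak_points: int = 3
    max_candidates_per_precursor: int = 5
    max_peak_halfwidth: int = 8          # grid points
    corr_count_threshold: float = 0.75   # r cut-off for the n_corr_gt score

    # --- identification ---
    fdr_level: float = 0.01
    decoys_per_target: int = 1
    rt_window_sds: float = 3.0           # pass-2 window = ±k × residual SD
    rt_window_floor: int = 3             # grid steps

    # --- quantification ---
    top_k_fragments: int = 3
    min_shared_precursors: int = 1       # for pairwise MaxLFQ ratios

    # --- differential statistics / substrate calling ---
    presence_fraction: float = 0.5       # strict > 50 % presence filter
    q_threshold: float = 0.05
    fc_threshold: float = 1.0            # log2; "> twofold"
    down_threshold: float = 0.2          # "> 20 % down" => level < 0.8
    endpoint_only: bool = False          # degradation at any time vs endpoint

    # --- simulator ---
    cycle_time: float = 1.6              # s between consecutive DIA cycles
    gradient_length: float = 480.0       # s
    peak_sigma: float = 3.0              # s; FWHM/cycle_time ≈ 4.4 points
    noise_cv: float = 0.10               # multiplicative lognormal CV
    baseline_level: float = 30.0         # additive exponential baseline scale
    interference_rate: float = 0.15
    # co-fragmenting interferer: apex displacement (units of peak sigma)
    # and amplitude relative to the affected fragment — interference that
    # matters comes from comparable-or-larger co-eluting signals
    interference_shift_sigma: tuple[float, float] = (2.0, 6.0)
    interference_amplitude: tuple[float, float] = (1.0, 3.0)
    dirichlet_alpha: float = 2.0         # fragment relative-intensity spread
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def replace(self, **kw: Any) -> "RunConfig":
        return dataclasses.replace(self, **kw)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the full configuration."""
    payload = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | None) -> RunConfig:
    """Load a config from YAML/JSON; missing keys keep their defaults."""
    if path is None:
        return RunConfig()
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "precursor_charges" in data:
        data["precursor_charges"] = tuple(data["precursor_charges"])
    return RunConfig(**data)
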