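"""Run-level configuration shared by every pipeline stage.

Defaults follow the analysis settings used throughout: 0.4 Da fragment
tolerance, 0.1 Da precursor grouping window, Bernoulli match probability
theta = 0.05, pair p-value cutoff 5e-9, modifications bounded at +/-375 Da,
at most 100 distinct precursor masses per subnetwork, seed FDR a = 0.0003,
edge FDR r = 0.005 and a 1% aggregate propagation FDR budget.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

log = logging.getLogger("specnet")

# y above b: tryptic CID spectra are y-ion dominated, and the asymmetry is
# what lets the true prefix interpretation outscore its complementary mirror.
DEFAULT_CHANNEL_WEIGHTS: dict[str, float] = {
    "b": 0.8, "y": 1.2,
    "b-H2O": 0.25, "b-NH3": 0.25, "y-H2O": 0.25, "y-NH3": 0.25,
    "b2": 0.3, "y2": 0.3,
    "b+iso": 0.2, "y+iso": 0.2,
}


@dataclass
class Config:
    fragment_tolerance_da: float = 0.4
    precursor_tolerance_da: float = 0.1
    theta: float = 0.05
    pair_p_cutoff: float = 5e-9
    max_mod_mass_da: float = 375.0
    max_masses_per_component: int = 100
    seed_fdr: float = 0.0003
    edge_fdr: float = 0.005
    aggregate_fdr_threshold: float = 0.01
    peak_cap: int = 100
    score_grid: float = 0.1
    channel_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_WEIGHTS))
    #: Null rank-evidence rate per channel; evidence is log(rank_quantile / this).
    channel_null_rate: float = 0.05
    #: Penalty subtracted when a primary (b or y) channel has no supporting peak.
    major_miss_penalty: float = 3.1
    #: Localization penalty per theoretical ladder mass without a target peak.
    localization_miss_penalty: float = 0.5

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
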