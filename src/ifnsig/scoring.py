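"""Relative-MFI scoring and marker-level calls.

The central statistic is the *relative MFI*: the geometric mean fluorescence
of the antibody-stained tube divided by the geometric mean of its matched
fluorescence-minus-one (FMO) control.  A relative MFI below 1.5 is read as
no antigen expression over background; an induction fold (post-stimulation
relative MFI over baseline relative MFI) below 1.5 is read as no induction.

Induction folds are rounded half-up to one decimal before thresholding by
default, matching the precision at which cohort tables are reported; set
``fold_rounding_decimals=None`` for raw comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .gating import EventTable

MARKERS = ("HLA-ABC", "HLA-DR", "NGFR", "PD-L1", "PD-L2")


@dataclass
class ScoringConfig:
    expression_threshold: float = 1.5
    induction_threshold: float = 1.5
    fold_rounding_decimals: Optional[int] = 1
    fmo_positive_quantile: float = 0.99
    bimodal_bounds: tuple[float, float] = (0.10, 0.90)

    def __post_init__(self) -> None:
        if self.expression_threshold <= 1 or self.induction_threshold <= 1:
            raise ValueError("expression/induction thresholds must be > 1")
        if not 0.9 < self.fmo_positive_quantile < 1:
            raise ValueError("fmo_positive_quantile must be in (0.9, 1)")
        lo, hi = self.bimodal_bounds
        if not 0 < lo < hi < 1:
            raise ValueError("bimodal_bounds must be ordered within (0, 1)")


@dataclass
class MarkerMeasurement:
    """Scored stained/FMO pair for one marker in one condition."""

    marker: str
    condition: str
    stained_mfi: float
    fmo_mfi: float
    relative_mfi: float
    expressed: bool
    percent_positive: Optional[float] = None
    bimodal: Optional[bool] = None


def round_half_up(x: float, decimals: int) -> float:
    """Decimal rounding with ties away from zero (0.05 -> 0.1).

    A small epsilon absorbs binary-float representation error so that
    ratios of one-decimal table entries land on the intended side.
    """
    factor = 10.0 ** decimals
    return math.floor(x * factor + 0.5 + 1e-9) / factor


def relative_mfi(stained_mfi: float, fmo_mfi: float) -> float:
    """Ratio of stained to FMO geometric mean fluorescence."""
    if stained_mfi <= 0 or fmo_mfi <= 0:
        raise ValueError("relative_mfi requires positive MFIs")
    return stained_mfi / fmo_mfi


def call_expression(rel: float, cfg: Optional[ScoringConfig] = None) -> bool:
    """True when the marker is expressed over background.

    The threshold is exclusive on the low side: a relative MFI exactly at
    the threshold counts as expressed.
    """
    cfg = cfg or ScoringConfig()
    if rel <= 0:
        raise ValueError("relative MFI must be positive")
    return not rel < cfg.expression_threshold


def fold_induction(
    rel_post: float,
    rel_pre: float,
    cfg: Optional[ScoringConfig] = None,
) -> tuple[float, bool]:
    """Induction fold (post/pre relative MFI) and the induced call.

    Returns the fold after the configured rounding; induced means the
    (rounded) fold is at or above the induction threshold.
    """
    cfg = cfg or ScoringConfig()
    if rel_post <= 0 or rel_pre <= 0:
        raise ValueError("relative MFIs must be positive")
    fold = rel_post / rel_pre
    if cfg.fold_rounding_decimals is not None:
        fold = round_half_up(fold, cfg.fold_rounding_decimals)
    return fold, not fold < cfg.induction_threshold


def percent_positive(
    stained: EventTable,
    fmo: EventTable,
    channel: str = "MARKER",
    cfg: Optional[ScoringConfig] = None,
) -> float:
    """Fraction of stained events above the FMO positivity gate.

    The gate is the configured upper quantile (default 99th percentile) of
    the FMO channel distribution, so a stained tube identical to its control
    reads ~1 minus the quantile.
    """
    cfg = cfg or ScoringConfig()
    stained_values = stained.channel(channel)
    fmo_values = fmo.channel(channel)
    if stained_values.size == 0 or fmo_values.size == 0:
        raise ValueError("percent_positive requires non-empty tubes")
    gate = float(np.quantile(fmo_values, cfg.fmo_positive_quantile))
    return float(np.mean(stained_values > gate))


def call_bimodal(expressed: bool, pct_pos: float,
                 cfg: Optional[ScoringConfig] = None) -> bool:
    """True when an expressed marker is carried by only a subpopulation."""
    cfg = cfg or ScoringConfig()
    if not 0 <= pct_pos <= 1:
        raise ValueError("pct_pos must be in [0, 1]")
    lo, hi = cfg.bimodal_bounds
    return bool(expressed and lo <= pct_pos <= hi)


def score_tube_pair(
    stained: EventTable,
    fmo: EventTable,
    channel: str = "MARKER",
    cfg: Optional[ScoringConfig] = None,
) -> MarkerMeasurement:
    """Full marker measurement from a gated stained/FMO tube pair."""
    from .gating import geometric_mfi

    cfg = cfg or ScoringConfig()
    s_mfi = geometric_mfi(stained, channel)
    f_mfi = geometric_mfi(fmo, channel)
    rel = relative_mfi(s_mfi, f_mfi)
    expressed = call_expression(rel, cfg)
    pct = percent_positive(stained, fmo, channel, cfg)
    return MarkerMeasurement(
        marker=stained.marker,
        condition=stained.condition,
        stained_mfi=s_mfi,
        fmo_mfi=f_mfi,
        relative_mfi=rel,
        expressed=expressed,
        percent_positive=pct,
        bimodal=call_bimodal(expressed, pct, cfg),
    )
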