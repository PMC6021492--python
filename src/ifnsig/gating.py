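"""Event-level gating and geometric-MFI computation.

A tube of flow-cytometry events is reduced to live singlet cells in three
steps mirroring routine manual analysis: a scatter floor removes debris, the
forward-scatter area/height ratio removes doublets (aggregates accumulate
area roughly twice as fast as height), and a viability-dye ceiling removes
dead cells.  All downstream marker statistics are geometric means over the
surviving events, the standard summary for log-distributed fluorescence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical channel names for simulated / CSV tubes
SCATTER_AREA = "FSC_A"
SCATTER_HEIGHT = "FSC_H"
SIDE_SCATTER = "SSC_A"
VIABILITY = "VIABILITY"
MARKER_CHANNEL = "MARKER"
DNA_CHANNEL = "DNA"


class EmptyGateError(RuntimeError):
    """No events survived gating; downstream MFIs are undefined."""


@dataclass
class EventTable:
    """Per-event channel measurements for one acquisition tube.

    ``data`` holds one row per event with arbitrary-unit channel columns.
    Row order is the acquisition order.  Metadata identifies the tube within
    a cohort experiment.
    """

    data: pd.DataFrame
    line_id: str = "sim"
    marker: str = MARKER_CHANNEL
    condition: str = "vehicle"  # "vehicle" | "IFNg"
    tube_kind: str = "stained"  # "stained" | "FMO"

    def __post_init__(self) -> None:
        if len(self.data) < 1:
            raise ValueError("EventTable requires at least one event")
        for name in ("line_id", "marker", "condition", "tube_kind"):
            if not getattr(self, name):
                raise ValueError(f"EventTable metadata field {name!r} is empty")
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("EventTable channel values must all be finite")

    def __len__(self) -> int:
        return len(self.data)

    def channel(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise KeyError(f"channel {name!r} not present in tube "
                           f"(columns: {list(self.data.columns)})")
        return self.data[name].to_numpy(dtype=float)

    def with_data(self, data: pd.DataFrame) -> "EventTable":
        return replace(self, data=data.reset_index(drop=True))


@dataclass
class GatingConfig:
    """Thresholds for the debris / doublet / viability gates.

    Defaults match the scale of the synthetic event generator (scatter around
    1e5, live viability dye around 1e2, dead around 3e3); on real exports
    they are instrument-specific and must be supplied.
    """

    scatter_floor: float = 2e4
    doublet_ratio_window: tuple[float, float] = (0.7, 1.4)
    viability_cutoff: float = 1e3
    min_live_events: int = 10_000  # warn-only acquisition practice
    # optional acquisition-index trim against electronic noise, default off
    time_trim_fraction: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.doublet_ratio_window
        if not lo < hi:
            raise ValueError("doublet_ratio_window lower bound must be < upper")
        if self.scatter_floor < 0 or self.viability_cutoff < 0:
            raise ValueError("scatter_floor and viability_cutoff must be >= 0")
        if not 0 <= self.time_trim_fraction < 0.5:
            raise ValueError("time_trim_fraction must be in [0, 0.5)")


@dataclass
class GateReport:
    """Events entering and surviving each gate, in application order."""

    n_input: int
    n_after_trim: int
    n_after_debris: int
    n_after_doublet: int
    n_after_viability: int
    counts: dict = field(default_factory=dict)

    @property
    def n_live(self) -> int:
        return self.n_after_viability


def gate_events(
    raw: EventTable,
    cfg: Optional[GatingConfig] = None,
    return_report: bool = False,
):
    """Apply debris, doublet, and viability gates to a raw tube.

    Returns the gated :class:`EventTable` (metadata preserved), or a
    ``(events, report)`` pair when ``return_report`` is true.  Raises
    :class:`EmptyGateError` when no event survives.
    """
    cfg = cfg or GatingConfig()
    df = raw.data

    n_input = len(df)
    if cfg.time_trim_fraction > 0:
        k = int(round(n_input * cfg.time_trim_fraction))
        df = df.iloc[k: n_input - k if n_input - k > k else n_input]
    n_trim = len(df)

    fsc_a = df[SCATTER_AREA].to_numpy(dtype=float)
    ssc_a = df[SIDE_SCATTER].to_numpy(dtype=float)
    keep = (fsc_a >= cfg.scatter_floor) & (ssc_a >= cfg.scatter_floor)
    df = df.loc[keep]
    n_debris = len(df)

    fsc_a = df[SCATTER_AREA].to_numpy(dtype=float)
    fsc_h = df[SCATTER_HEIGHT].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(fsc_h > 0, fsc_a / fsc_h, np.inf)
    lo, hi = cfg.doublet_ratio_window
    df = df.loc[(ratio >= lo) & (ratio <= hi)]
    n_doublet = len(df)

    via = df[VIABILITY].to_numpy(dtype=float)
    df = df.loc[via <= cfg.viability_cutoff]
    n_live = len(df)

    if n_live == 0:
        raise EmptyGateError(
            f"empty gate: no live singlet events remain in tube "
            f"{raw.line_id}/{raw.marker}/{raw.condition}/{raw.tube_kind}"
        )
    if n_live < cfg.min_live_events:
        logger.warning(
            "tube %s/%s/%s/%s: only %d live events (< %d)",
            raw.line_id, raw.marker, raw.condition, raw.tube_kind,
            n_live, cfg.min_live_events,
        )

    report = GateReport(
        n_input=n_input,
        n_after_trim=n_trim,
        n_after_debris=n_debris,
        n_after_doublet=n_doublet,
        n_after_viability=n_live,
        counts={
            "trim": n_input - n_trim,
            "debris": n_trim - n_debris,
            "doublet": n_debris - n_doublet,
            "dead": n_doublet - n_live,
        },
    )
    gated = raw.with_data(df)
    if return_report:
        return gated, report
    return gated


def geometric_mfi(
    events: EventTable,
    channel: str,
    return_excluded: bool = False,
):
    """Geometric mean fluorescence intensity of one channel.

    Computed as ``exp(mean(log(x)))`` over events with ``x > 0``; nonpositive
    events are excluded (not floored) and their count is reported so that
    pathological tubes are detectable.
    """
    values = events.channel(channel)
    positive = values[values > 0]
    n_excluded = int(values.size - positive.size)
    if positive.size == 0:
        raise ValueError(
            f"geometric MFI undefined: no positive values in channel {channel!r}"
        )
    if n_excluded:
        logger.info("geometric_mfi: excluded %d nonpositive events on %s",
                    n_excluded, channel)
    gm = float(np.exp(np.mean(np.log(positive))))
    if return_excluded:
        return gm, n_excluded
    return gm
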