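"""Synthetic flow-cytometry data with known ground truth.

Three generators cover the data shapes the analysis consumes:

* :func:`generate_marker_tubes` — a stained/FMO tube pair for one surface
  marker.  Fluorescence is log-normal (strictly positive); the stained tube
  is a two-component log-normal mixture whose geometric mean over live
  singlets, divided by the FMO geometric mean, equals the configured target
  relative MFI in expectation.  Bimodal lines are emulated by a positive
  fraction below 1.  Dead cells carry a high viability-dye signal; doublets
  break the forward-scatter area/height relation of singlets.
* :func:`generate_dna_content` — a DNA-content histogram with configured
  sub-G1 / G1 / S / G2 phase fractions (G1 and G2 Gaussian peaks at 2N and
  4N, S uniform between them, sub-G1 uniform below the 2N peak).
* :func:`generate_cohort` — a whole cohort of cell lines across four driver
  genotypes with per-line true baseline relative MFIs and induction folds,
  optional engineered defects (global null responder, MHC-class-I loss), and
  the ground-truth table needed to validate every downstream call.

Seeds propagate hierarchically through :class:`numpy.random.SeedSequence`
so any single tube is reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .gating import (
    EventTable,
    DNA_CHANNEL,
    MARKER_CHANNEL,
    SCATTER_AREA,
    SCATTER_HEIGHT,
    SIDE_SCATTER,
    VIABILITY,
)

MARKERS = ("HLA-ABC", "HLA-DR", "NGFR", "PD-L1", "PD-L2")
GENOTYPE_GROUPS = ("BRAF", "NRAS", "WT", "GNAQ/GNA11")

# scatter / viability scales shared by all simulated tubes; the gating
# defaults are tuned to these
_FSC_MEAN, _FSC_SD = 1.0e5, 1.2e4
_SSC_MEAN, _SSC_SD = 6.0e4, 1.0e4
_LIVE_DYE_LOG10, _DEAD_DYE_LOG10 = 2.0, 3.6
_DYE_LOG10_SD = 0.15


def _check(cond: bool, message: str) -> None:
    if not cond:
        raise ValueError(message)


@dataclass
class MarkerSimConfig:
    """Parameters of one simulated stained/FMO marker tube pair.

    ``true_relative_mfi`` is the target ratio of stained to FMO geometric
    mean over live singlets; ``positive_fraction`` < 1 makes the stained
    distribution a bimodal mixture whose negative component coincides with
    the FMO background.
    """

    fmo_log_mean: float = 2.0      # log10 fluorescence location (a.u.)
    fmo_log_sd: float = 0.2        # log10 scale
    true_relative_mfi: float = 1.0
    positive_fraction: float = 1.0
    n_events: int = 10_000         # live-event acquisition floor in routine use
    dead_fraction: float = 0.0
    doublet_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_events >= 100, "n_events must be >= 100")
        _check(self.fmo_log_sd > 0, "fmo_log_sd must be > 0")
        _check(0.0 <= self.positive_fraction <= 1.0,
               "positive_fraction must be in [0, 1]")
        _check(self.true_relative_mfi >= 0.5,
               "true_relative_mfi must be >= 0.5")
        _check(0.0 <= self.dead_fraction <= 0.5,
               "dead_fraction must be in [0, 0.5]")
        _check(0.0 <= self.doublet_fraction <= 0.3,
               "doublet_fraction must be in [0, 0.3]")
        if self.positive_fraction == 0.0:
            _check(math.isclose(self.true_relative_mfi, 1.0),
                   "positive_fraction = 0 requires true_relative_mfi = 1")


@dataclass
class CellCycleSimConfig:
    """Parameters of one simulated DNA-content acquisition."""

    fractions: tuple[float, float, float, float] = (2.0, 60.0, 25.0, 13.0)
    g1_mean: float = 200.0  # DNA channel location of the 2N peak (a.u.)
    cv: float = 0.05        # coefficient of variation of the G1 peak
    n_events: int = 20_000
    seed: int = 0

    def validate(self) -> None:
        _check(len(self.fractions) == 4, "fractions must have 4 entries")
        _check(all(f >= 0 for f in self.fractions),
               "fractions must be non-negative")
        _check(abs(sum(self.fractions) - 100.0) <= 1e-9,
               "fractions must sum to 100")
        _check(0 < self.cv <= 0.15, "cv must be in (0, 0.15]")
        _check(self.n_events >= 1, "n_events must be >= 1")
        _check(self.g1_mean > 0, "g1_mean must be > 0")


def _default_baseline_params() -> dict:
    # log10 location/scale of baseline relative MFI per marker, loosely
    # emulating the spread observed across melanoma panels: MHC-I broadly
    # positive, HLA-DR/NGFR highly variable, PD-L1 at background, PD-L2 low
    return {
        "HLA-ABC": (math.log10(30.0), 0.35),
        "HLA-DR": (math.log10(4.0), 0.60),
        "NGFR": (math.log10(30.0), 0.80),
        "PD-L1": (math.log10(1.05), 0.05),
        "PD-L2": (math.log10(1.8), 0.25),
    }


def _default_fold_params() -> dict:
    # log10 location/scale of the IFNg induction fold per marker
    return {
        "HLA-ABC": (math.log10(3.0), 0.20),
        "HLA-DR": (math.log10(6.0), 0.45),
        "NGFR": (math.log10(1.8), 0.30),
        "PD-L1": (math.log10(2.8), 0.25),
        "PD-L2": (math.log10(2.5), 0.30),
    }


def _default_group_shifts() -> dict:
    # additive log10 shifts of baseline location per genotype group;
    # uveal (GNAQ/GNA11) lines sit lower for HLA-DR, NGFR and PD-L2
    return {
        "GNAQ/GNA11": {"HLA-DR": -0.45, "NGFR": -0.80, "PD-L2": -0.20},
    }


@dataclass
class CohortSimConfig:
    """Parameters of a simulated multi-line cohort.

    ``group_sizes`` fixes the number of cell lines per driver-genotype
    group; the default (11, 10, 10, 8) mirrors a BRAF / NRAS / wild-type /
    uveal panel of 39 lines.  Engineered defects are drawn per line, at most
    one per line: a *null responder* has all five induction folds ~ 1, an
    *MHC-I-loss* line keeps HLA-ABC at background in both conditions while
    the other markers induce normally.
    """

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"BRAF": 11, "NRAS": 10, "WT": 10,
                                 "GNAQ/GNA11": 8})
    baseline_log10: Mapping[str, tuple[float, float]] = field(
        default_factory=_default_baseline_params)
    fold_log10: Mapping[str, tuple[float, float]] = field(
        default_factory=_default_fold_params)
    group_baseline_shift: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_group_shifts)
    null_responder_fraction: float = 0.0
    mhc1_loss_fraction: float = 0.0
    n_events: int = 10_000
    fmo_log_mean: float = 2.0
    fmo_log_sd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        _check(all(v >= 0 for v in self.group_sizes.values()),
               "group sizes must be >= 0")
        _check(sum(self.group_sizes.values()) >= 1,
               "cohort must contain at least one line")
        _check(0 <= self.null_responder_fraction <= 1,
               "null_responder_fraction must be in [0, 1]")
        _check(0 <= self.mhc1_loss_fraction <= 1,
               "mhc1_loss_fraction must be in [0, 1]")
        _check(self.null_responder_fraction + self.mhc1_loss_fraction <= 1,
               "defect fractions must sum to <= 1")
        _check(self.n_events >= 100, "n_events must be >= 100")
        for marker in MARKERS:
            _check(marker in self.baseline_log10,
                   f"baseline_log10 missing marker {marker!r}")
            _check(marker in self.fold_log10,
                   f"fold_log10 missing marker {marker!r}")


def _scatter_and_viability(rng: np.random.Generator, n_singlet: int,
                           n_doublet: int, n_dead: int):
    """Scatter and viability channels for live singlets, doublets, dead."""
    n = n_singlet + n_doublet + n_dead
    fsc_h = rng.normal(_FSC_MEAN, _FSC_SD, size=n).clip(min=1.0)
    ratio = rng.normal(1.0, 0.05, size=n).clip(min=0.8, max=1.2)
    fsc_a = fsc_h * ratio
    # doublets accumulate ~2x area relative to the singlet area/height line
    fsc_a[n_singlet:n_singlet + n_doublet] *= rng.normal(
        2.0, 0.1, size=n_doublet).clip(min=1.6)
    ssc_a = rng.normal(_SSC_MEAN, _SSC_SD, size=n).clip(min=1.0)
    dye_log10 = rng.normal(_LIVE_DYE_LOG10, _DYE_LOG10_SD, size=n)
    dye_log10[n_singlet + n_doublet:] = rng.normal(
        _DEAD_DYE_LOG10, _DYE_LOG10_SD, size=n_dead)
    return fsc_a, fsc_h, ssc_a, 10.0 ** dye_log10


def _marker_values(rng: np.random.Generator, n: int, cfg: MarkerSimConfig,
                   stained: bool) -> np.ndarray:
    log_mean = cfg.fmo_log_mean
    values = rng.normal(log_mean, cfg.fmo_log_sd, size=n)
    if stained and cfg.positive_fraction > 0:
        # shift of the positive component so that the mixture's geometric
        # mean over all events equals true_relative_mfi times the background
        delta = math.log10(cfg.true_relative_mfi) / cfg.positive_fraction
        positive = rng.random(n) < cfg.positive_fraction
        values[positive] += delta
    return 10.0 ** values


def generate_marker_tubes(
    cfg: MarkerSimConfig,
    line_id: str = "sim",
    marker: str = "MARKER",
    condition: str = "vehicle",
) -> tuple[EventTable, EventTable]:
    """Simulate one stained tube and its matched FMO control."""
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    tubes = []
    for child, kind in zip(ss.spawn(2), ("stained", "FMO")):
        rng = np.random.default_rng(child)
        n = cfg.n_events
        n_dead = int(round(n * cfg.dead_fraction))
        n_doublet = int(round(n * cfg.doublet_fraction))
        n_singlet = n - n_dead - n_doublet
        fsc_a, fsc_h, ssc_a, dye = _scatter_and_viability(
            rng, n_singlet, n_doublet, n_dead)
        values = _marker_values(rng, n, cfg, stained=(kind == "stained"))
        df = pd.DataFrame({
            SCATTER_AREA: fsc_a,
            SCATTER_HEIGHT: fsc_h,
            SIDE_SCATTER: ssc_a,
            VIABILITY: dye,
            MARKER_CHANNEL: values,
        })
        # shuffle so acquisition order carries no population structure
        df = df.sample(frac=1.0, random_state=int(rng.integers(2**31 - 1)))
        tubes.append(EventTable(df.reset_index(drop=True), line_id=line_id,
                                marker=marker, condition=condition,
                                tube_kind=kind))
    return tubes[0], tubes[1]


def generate_dna_content(cfg: CellCycleSimConfig,
                         line_id: str = "sim",
                         condition: str = "vehicle") -> EventTable:
    """Simulate a single-channel DNA-content acquisition."""
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    probs = np.asarray(cfg.fractions, dtype=float) / 100.0
    n_sub, n_g1, n_s, n_g2 = rng.multinomial(cfg.n_events, probs)
    g1, cv = cfg.g1_mean, cfg.cv
    parts = [
        rng.uniform(0.2 * g1, 0.85 * g1, size=n_sub),
        rng.normal(g1, cv * g1, size=n_g1),
        rng.uniform(g1, 2.0 * g1, size=n_s),
        rng.normal(2.0 * g1, cv * 2.0 * g1, size=n_g2),
    ]
    dna = np.concatenate(parts).clip(min=1e-6)
    rng.shuffle(dna)
    df = pd.DataFrame({DNA_CHANNEL: dna})
    return EventTable(df, line_id=line_id, marker=DNA_CHANNEL,
                      condition=condition, tube_kind="stained")


@dataclass
class CohortSimResult:
    """Tube set plus ground truth for a simulated cohort.

    ``tubes`` maps ``(line_id, marker, condition, tube_kind)`` to an
    :class:`EventTable`; ``truth`` has one row per line with the true
    baseline relative MFIs, induction folds, engineered defect (if any) and
    the response class implied by the true folds.
    """

    tubes: dict
    truth: pd.DataFrame


def generate_cohort(cfg: CohortSimConfig) -> CohortSimResult:
    """Simulate stained/FMO tubes for every line x marker x condition."""
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    plan_rng = np.random.default_rng(root.spawn(1)[0])

    lines = []
    for group in GENOTYPE_GROUPS:
        for i in range(cfg.group_sizes.get(group, 0)):
            lines.append((f"{group.replace('/', '')}-{i + 1:02d}", group))

    # engineered defects, at most one per line
    defects = []
    for _ in lines:
        u = plan_rng.random()
        if u < cfg.null_responder_fraction:
            defects.append("null_responder")
        elif u < cfg.null_responder_fraction + cfg.mhc1_loss_fraction:
            defects.append("mhc1_loss")
        else:
            defects.append("")

    tubes: dict = {}
    rows = []
    tube_seeds = iter(root.spawn(len(lines) * len(MARKERS)))
    for (line_id, group), defect in zip(lines, defects):
        row = {"cell_line": line_id, "genotype": group, "defect": defect}
        n_induced = 0
        for marker in MARKERS:
            loc, scale = cfg.baseline_log10[marker]
            loc += cfg.group_baseline_shift.get(group, {}).get(marker, 0.0)
            floc, fscale = cfg.fold_log10[marker]
            rmfi_pre = 10.0 ** plan_rng.normal(loc, scale)
            fold = 10.0 ** plan_rng.normal(floc, fscale)
            if defect == "null_responder":
                fold = 10.0 ** plan_rng.normal(0.0, 0.02)
            if defect == "mhc1_loss" and marker == "HLA-ABC":
                rmfi_pre = 10.0 ** plan_rng.normal(0.0, 0.01)
                fold = 10.0 ** plan_rng.normal(0.0, 0.02)
            rmfi_pre = max(rmfi_pre, 0.5)
            fold = max(fold, 0.5 / rmfi_pre, 0.5)
            rmfi_post = rmfi_pre * fold
            n_induced += int(fold >= 1.5)
            row[f"{marker}_true_rmfi_pre"] = rmfi_pre
            row[f"{marker}_true_rmfi_post"] = rmfi_post
            row[f"{marker}_true_fold"] = fold

            marker_seed = next(tube_seeds)
            for child, (cond, rmfi) in zip(
                    marker_seed.spawn(2),
                    (("vehicle", rmfi_pre), ("IFNg", rmfi_post))):
                tube_cfg = MarkerSimConfig(
                    fmo_log_mean=cfg.fmo_log_mean,
                    fmo_log_sd=cfg.fmo_log_sd,
                    true_relative_mfi=rmfi,
                    positive_fraction=1.0,
                    n_events=cfg.n_events,
                    seed=int(child.generate_state(1)[0] % (2**31 - 1)),
                )
                stained, fmo = generate_marker_tubes(
                    tube_cfg, line_id=line_id, marker=marker, condition=cond)
                tubes[(line_id, marker, cond, "stained")] = stained
                tubes[(line_id, marker, cond, "FMO")] = fmo

        row["true_response_class"] = (
            "complete" if n_induced == 5 else
            "null" if n_induced == 0 else "partial")
        rows.append(row)

    truth = pd.DataFrame(rows)
    return CohortSimResult(tubes=tubes, truth=truth)
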