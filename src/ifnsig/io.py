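"""Cohort-table ingestion and packaged reference fixtures.

Two CSV layouts are understood, mirroring how published cohort summaries
are laid out: a surface-marker table (one line per row; driver mutation;
baseline and post-IFNg relative MFI per marker) and a cell-cycle table
(sub-G1/G1/S/G2 percentages in both conditions plus the reported effect
label).  Both ship as packaged fixtures transcribed from a 39-line melanoma
panel, so the published cohort doubles as an integration fixture.

Ingestion normalizes driver-mutation strings to four genotype groups
(V600x -> BRAF, Q61x -> NRAS, GNAQ/GNA11 Q209x -> uveal, otherwise WT) and
reconciles line-name variants that differ between tables (D35M1 -> D35).
"""

from __future__ import annotations

from importlib import resources
from typing import Optional, Union

import numpy as np
import pandas as pd

from .cellcycle import parse_effect_label
from .scoring import MARKERS

#: line-name variants mapped to one canonical id
LINE_NAME_ALIASES = {"D35M1": "D35"}

_PHASES = ("subg1", "g1", "s", "g2")


def normalize_genotype(driver: str) -> str:
    """Map a free-text driver-mutation string to its genotype group."""
    d = driver.upper()
    if "V600" in d:
        return "BRAF"
    if "Q61" in d:
        return "NRAS"
    if "GNAQ" in d or "GNA11" in d or "Q209" in d:
        return "GNAQ/GNA11"
    if "WT" in d or "WILD" in d:
        return "WT"
    raise ValueError(f"cannot assign genotype group for driver {driver!r}")


def normalize_line_id(line_id: str) -> str:
    line_id = str(line_id).strip()
    return LINE_NAME_ALIASES.get(line_id, line_id)


def _parse_number(value, row_no: int, column: str) -> float:
    """Parse a table cell; 'nd' (not determined) becomes NaN."""
    if isinstance(value, str):
        value = value.strip().replace(",", "")
        if value.lower() == "nd" or value == "":
            return np.nan
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValueError(
            f"row {row_no}: malformed value {value!r} in column {column!r}"
        ) from None


def _read_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, comment="#", keep_default_na=False)
    if df.empty:
        raise ValueError(f"{path}: table contains no rows")
    return df


def _normalize_ids(df: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame()
    out["cell_line"] = df["cell_line"].map(normalize_line_id)
    dupes = out["cell_line"][out["cell_line"].duplicated()]
    if not dupes.empty:
        raise ValueError(f"duplicate cell lines: {', '.join(sorted(set(dupes)))}")
    out["genotype"] = df["driver_mutation"].map(normalize_genotype)
    return out


def ingest_cohort_table(path) -> pd.DataFrame:
    """Read a surface-marker cohort CSV into the canonical typed layout.

    Returns a DataFrame with ``cell_line``, ``genotype`` and numeric
    ``<marker>_pre`` / ``<marker>_post`` relative-MFI columns.
    """
    df = _read_csv(path)
    required = {"cell_line", "driver_mutation"} | {
        f"{m}_{c}" for m in MARKERS for c in ("pre", "post")}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = _normalize_ids(df)
    for m in MARKERS:
        for c in ("pre", "post"):
            col = f"{m}_{c}"
            out[col] = [
                _parse_number(v, i + 2, col)
                for i, v in enumerate(df[col])
            ]
    return out


def ingest_cellcycle_table(path) -> pd.DataFrame:
    """Read a cell-cycle cohort CSV (phases x conditions, 'nd' allowed).

    The optional ``reported_effect`` column is parsed into frozensets of
    :class:`~ifnsig.cellcycle.CellCycleEffect` (None for 'nd' rows).
    """
    df = _read_csv(path)
    required = {"cell_line", "driver_mutation"} | {
        f"{p}_{c}" for p in _PHASES for c in ("pre", "post")}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = _normalize_ids(df)
    for p in _PHASES:
        for c in ("pre", "post"):
            col = f"{p}_{c}"
            out[col] = [
                _parse_number(v, i + 2, col)
                for i, v in enumerate(df[col])
            ]
    if "reported_effect" in df.columns:
        out["reported_effect"] = df["reported_effect"].map(parse_effect_label)
    return out


def _fixture_path(name: str):
    return resources.files("ifnsig.data").joinpath(name)


def load_reference_marker_table() -> pd.DataFrame:
    """Packaged 39-line surface-marker cohort fixture."""
    with resources.as_file(_fixture_path("table1_surface_markers.csv")) as p:
        return ingest_cohort_table(p)


def load_reference_cellcycle_table() -> pd.DataFrame:
    """Packaged 39-line cell-cycle cohort fixture (one 'nd' line)."""
    with resources.as_file(_fixture_path("table2_cell_cycle.csv")) as p:
        return ingest_cellcycle_table(p)


def write_events_csv(events, path) -> None:
    """Write a tube's event table as CSV with metadata header comments."""
    with open(path, "w") as fh:
        fh.write(f"# line_id={events.line_id} marker={events.marker} "
                 f"condition={events.condition} tube_kind={events.tube_kind}\n")
        events.data.to_csv(fh, index=False)


def read_events_csv(path, line_id: Optional[str] = None,
                    marker: Optional[str] = None,
                    condition: Optional[str] = None,
                    tube_kind: Optional[str] = None):
    """Read a tube CSV, recovering metadata from the header comment when
    not supplied explicitly."""
    from .gating import EventTable

    meta = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
    df = pd.read_csv(path, comment="#")
    return EventTable(
        df,
        line_id=line_id or meta.get("line_id", "unknown"),
        marker=marker or meta.get("marker", "MARKER"),
        condition=condition or meta.get("condition", "vehicle"),
        tube_kind=tube_kind or meta.get("tube_kind", "stained"),
    )
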