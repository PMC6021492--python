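"""End-to-end analysis over cohort tables: scoring, phenotyping,
cell-cycle effects, and cohort statistics in one run."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as ifnio
from .cellcycle import classify_ifn_effect, format_effect, CellCycleFractions
from .gating import GatingConfig
from .phenotype import (
    MARKERS,
    classify_response,
    flag_resistance_mechanisms,
    profiles_from_table,
    summarize_cohort,
)
from .scoring import ScoringConfig
from .stats import compare_groups, spearman_matrix

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and stage options for a full cohort analysis.

    When ``marker_table`` / ``cellcycle_table`` are None the packaged
    reference cohort fixtures are used.
    """

    marker_table: Optional[str] = None
    cellcycle_table: Optional[str] = None
    out_dir: str = "ifnsig_out"
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    gating: GatingConfig = field(default_factory=GatingConfig)
    subg1_abs_threshold: float = 10.0
    s_rel_threshold: float = 0.30
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scoring = raw.pop("scoring", None)
        gating = raw.pop("gating", None)
        cfg = cls(**raw)
        if scoring:
            if "bimodal_bounds" in scoring:
                scoring["bimodal_bounds"] = tuple(scoring["bimodal_bounds"])
            cfg.scoring = ScoringConfig(**scoring)
        if gating:
            if "doublet_ratio_window" in gating:
                gating["doublet_ratio_window"] = tuple(
                    gating["doublet_ratio_window"])
            cfg.gating = GatingConfig(**gating)
        return cfg

    def config_hash(self) -> str:
        """Hash of the analysis-relevant options (output location excluded)."""
        payload = self.to_dict()
        payload.pop("out_dir", None)
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, cfg_hash: str,
                 index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=index)


def run_full_analysis(cfg: Optional[PipelineConfig] = None) -> dict:
    """Run every stage over the configured (or packaged) cohort tables.

    Writes the per-line classification, cohort summary, cell-cycle effect
    calls, baseline correlation matrix, cutaneous-vs-uveal comparisons and
    a plain-text summary into ``cfg.out_dir``; returns the report bundle as
    a dict of in-memory objects.
    """
    cfg = cfg or PipelineConfig()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()

    try:
        markers = (ifnio.ingest_cohort_table(cfg.marker_table)
                   if cfg.marker_table
                   else ifnio.load_reference_marker_table())
    except Exception as exc:
        raise RuntimeError(f"stage ingest_cohort_table failed on "
                           f"{cfg.marker_table or 'packaged fixture'}: {exc}"
                           ) from exc

    profiles = profiles_from_table(markers, cfg.scoring)
    summary = summarize_cohort(profiles)

    classification = pd.DataFrame({
        "cell_line": [p.line_id for p in profiles],
        "genotype": [p.genotype for p in profiles],
        **{f"{m}_fold": [p.fold(m) for p in profiles] for m in MARKERS},
        **{f"{m}_induced": [p.induced(m) for p in profiles]
           for m in MARKERS},
        "response_class": [classify_response(p).value for p in profiles],
        "mechanism_flags": [
            "+".join(sorted(f.value for f in flag_resistance_mechanisms(p)))
            for p in profiles],
    })
    _write_table(classification, out / "classification.csv", cfg_hash)

    corr = spearman_matrix(markers, [f"{m}_pre" for m in MARKERS])
    _write_table(corr.rho, out / "correlation_baseline.csv", cfg_hash,
                 index=True)

    comparisons = compare_groups(markers, which="pre")
    comp_df = pd.DataFrame([{
        "marker": c.marker, "n_cutaneous": c.n_a, "n_uveal": c.n_b,
        "U": c.statistic, "p_value": c.p_value, "method": c.method,
    } for c in comparisons])
    _write_table(comp_df, out / "group_comparisons_baseline.csv", cfg_hash)

    cellcycle_counts = {}
    try:
        cc = (ifnio.ingest_cellcycle_table(cfg.cellcycle_table)
              if cfg.cellcycle_table
              else ifnio.load_reference_cellcycle_table())
    except Exception as exc:
        raise RuntimeError(f"stage ingest_cellcycle_table failed on "
                           f"{cfg.cellcycle_table or 'packaged fixture'}: "
                           f"{exc}") from exc
    cc_rows = []
    for _, row in cc.iterrows():
        if pd.isna(row["subg1_pre"]):
            cc_rows.append({"cell_line": row["cell_line"], "effect": "nd"})
            continue
        pre = CellCycleFractions(row["subg1_pre"], row["g1_pre"],
                                 row["s_pre"], row["g2_pre"],
                                 source="ingested")
        post = CellCycleFractions(row["subg1_post"], row["g1_post"],
                                  row["s_post"], row["g2_post"],
                                  source="ingested")
        effects = classify_ifn_effect(pre, post, cfg.subg1_abs_threshold,
                                      cfg.s_rel_threshold)
        cc_rows.append({"cell_line": row["cell_line"],
                        "effect": format_effect(effects)})
    cc_df = pd.DataFrame(cc_rows)
    _write_table(cc_df, out / "cellcycle_effects.csv", cfg_hash)
    tested = cc_df[cc_df["effect"] != "nd"]
    cellcycle_counts = {
        "n_tested": int(len(tested)),
        "subg1_up": int(tested["effect"].str.contains("subg1_up").sum()),
        "s_up": int(tested["effect"].str.contains("s_up").sum()),
        "s_down": int(tested["effect"].str.contains("s_down").sum()),
        "minimal_change": int((tested["effect"] == "").sum()),
    }

    summary_lines = [
        f"cohort size: {summary.n_lines}",
        f"complete responders: {summary.response_counts['complete']}",
        f"partial responders: {summary.response_counts['partial']}",
        f"null responders: {summary.response_counts['null']}",
        f"diminished (not complete): {summary.diminished}",
        "baseline-negative per marker: " + ", ".join(
            f"{m}={summary.baseline_negative[m]}" for m in MARKERS),
        "not induced per marker: " + ", ".join(
            f"{m}={summary.not_induced[m]}" for m in MARKERS),
        f"lacking both PD-1 ligands: {summary.both_pd_ligands_negative} "
        f"({summary.both_pd_ligands_negative_by_genotype})",
        f"mechanism flags: "
        f"{ {k: sorted(f.value for f in v) for k, v in summary.flagged.items()} }",
    ]
    if cellcycle_counts:
        summary_lines += [
            f"cell-cycle tested lines: {cellcycle_counts['n_tested']}",
            f"sub-G1 increase: {cellcycle_counts['subg1_up']}",
            f"S-phase increase: {cellcycle_counts['s_up']}",
            f"S-phase decrease: {cellcycle_counts['s_down']}",
            f"minimal cell-cycle change: {cellcycle_counts['minimal_change']}",
        ]
    (out / "summary.txt").write_text(
        f"# config_hash={cfg_hash}\n" + "\n".join(summary_lines) + "\n")

    return {
        "markers": markers,
        "profiles": profiles,
        "summary": summary,
        "classification": classification,
        "correlation": corr,
        "comparisons": comparisons,
        "cellcycle_effects": cc_df,
        "cellcycle_counts": cellcycle_counts,
        "config_hash": cfg_hash,
    }
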