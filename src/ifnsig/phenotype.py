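"""Per-line IFNg response classification and cohort summarization.

A cell line is a *complete responder* when all five surface markers are
induced by IFNg, a *null responder* when none is, and *partial* otherwise.
Two advisory resistance-mechanism flags follow recognized patterns:

* **MHC-I loss** — HLA-ABC at or near background at baseline and not
  induced while at least one other marker responds; a supplied surface B2M
  stain at background upgrades the flag to a confirmed B2M-loss pattern
  (surface MHC class I requires B2M).
* **Upstream defect** — a null response suggests a lesion above the
  transcriptional program (receptor or JAK/STAT); a supplied IFNGR1 stain
  absent from the surface but present intracellularly upgrades the flag to
  a receptor-loss pattern.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .scoring import MARKERS, ScoringConfig, call_expression, fold_induction

PD_LIGANDS = ("PD-L1", "PD-L2")

#: relative-MFI ceiling under which baseline HLA-ABC counts as "low" for the
#: MHC-I-loss flag; inclusive, so borderline lines at the expression
#: threshold still qualify when HLA-ABC fails to induce
MHC_LOW_CEILING = 1.5


class ResponseClass(str, enum.Enum):
    COMPLETE = "complete"
    PARTIAL = "partial"
    NULL = "null"


class MechanismFlag(str, enum.Enum):
    MHC1_LOSS_CANDIDATE = "mhc1_loss_candidate"
    B2M_LOSS_PATTERN = "b2m_loss_pattern"
    UPSTREAM_DEFECT_CANDIDATE = "upstream_defect_candidate"
    RECEPTOR_LOSS_PATTERN = "receptor_loss_pattern"


@dataclass
class CellLineProfile:
    """One line's genotype plus pre/post relative MFIs for all five markers.

    ``rel_mfi`` maps marker -> (baseline, post-IFNg) relative MFI.  The
    optional auxiliary stains are relative MFIs of surface/intracellular
    B2M and IFNGR1 used to refine mechanism flags.
    """

    line_id: str
    genotype: str  # BRAF | NRAS | WT | GNAQ/GNA11
    rel_mfi: Mapping[str, tuple[float, float]]
    b2m_surface: Optional[float] = None
    b2m_intracellular: Optional[float] = None
    ifngr1_surface: Optional[float] = None
    ifngr1_intracellular: Optional[float] = None
    scoring: ScoringConfig = field(default_factory=ScoringConfig)

    def __post_init__(self) -> None:
        missing = [m for m in MARKERS if m not in self.rel_mfi]
        if missing:
            raise ValueError(f"profile {self.line_id}: missing marker(s) "
                             f"{', '.join(missing)}")
        if self.genotype not in ("BRAF", "NRAS", "WT", "GNAQ/GNA11"):
            raise ValueError(f"profile {self.line_id}: unknown genotype "
                             f"{self.genotype!r}")

    def fold(self, marker: str) -> float:
        pre, post = self.rel_mfi[marker]
        return fold_induction(post, pre, self.scoring)[0]

    def induced(self, marker: str) -> bool:
        pre, post = self.rel_mfi[marker]
        return fold_induction(post, pre, self.scoring)[1]

    def expressed_at_baseline(self, marker: str) -> bool:
        return call_expression(self.rel_mfi[marker][0], self.scoring)


def classify_response(profile: CellLineProfile) -> ResponseClass:
    """Complete (all five induced), null (none), or partial."""
    n = sum(profile.induced(m) for m in MARKERS)
    if n == len(MARKERS):
        return ResponseClass.COMPLETE
    if n == 0:
        return ResponseClass.NULL
    return ResponseClass.PARTIAL


def flag_resistance_mechanisms(profile: CellLineProfile) -> set[MechanismFlag]:
    """Advisory flags for recognized immune-evasion patterns."""
    flags: set[MechanismFlag] = set()
    response = classify_response(profile)
    others_induced = any(profile.induced(m) for m in MARKERS
                         if m != "HLA-ABC")
    hla_low = profile.rel_mfi["HLA-ABC"][0] <= MHC_LOW_CEILING
    if hla_low and not profile.induced("HLA-ABC") and others_induced:
        flags.add(MechanismFlag.MHC1_LOSS_CANDIDATE)
        if (profile.b2m_surface is not None
                and not call_expression(profile.b2m_surface, profile.scoring)):
            flags.add(MechanismFlag.B2M_LOSS_PATTERN)
    if response is ResponseClass.NULL:
        flags.add(MechanismFlag.UPSTREAM_DEFECT_CANDIDATE)
        if (profile.ifngr1_surface is not None
                and profile.ifngr1_intracellular is not None
                and not call_expression(profile.ifngr1_surface,
                                        profile.scoring)
                and call_expression(profile.ifngr1_intracellular,
                                    profile.scoring)):
            flags.add(MechanismFlag.RECEPTOR_LOSS_PATTERN)
    return flags


@dataclass
class CohortSummary:
    """Cohort-level counts derived from per-line marker calls."""

    n_lines: int
    baseline_negative: dict  # marker -> count with relative MFI below threshold
    not_induced: dict        # marker -> count with fold below threshold
    both_pd_ligands_negative: int
    both_pd_ligands_negative_by_genotype: dict
    response_counts: dict    # "complete" / "partial" / "null" -> count
    diminished: int          # not complete = partial + null
    flagged: dict            # line_id -> set of MechanismFlag

    def __post_init__(self) -> None:
        assert sum(self.response_counts.values()) == self.n_lines
        assert (sum(self.both_pd_ligands_negative_by_genotype.values())
                == self.both_pd_ligands_negative)


def summarize_cohort(profiles: Sequence[CellLineProfile]) -> CohortSummary:
    """All headline counts for a scored cohort."""
    if not profiles:
        raise ValueError("summarize_cohort requires at least one profile")
    ids = [p.line_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate line ids: {', '.join(dupes)}")

    baseline_negative = {m: 0 for m in MARKERS}
    not_induced = {m: 0 for m in MARKERS}
    both_neg = 0
    both_neg_by_geno: dict[str, int] = {}
    response_counts = {c.value: 0 for c in ResponseClass}
    flagged: dict[str, set[MechanismFlag]] = {}

    for p in profiles:
        for m in MARKERS:
            if not p.expressed_at_baseline(m):
                baseline_negative[m] += 1
            if not p.induced(m):
                not_induced[m] += 1
        if all(not p.expressed_at_baseline(m) for m in PD_LIGANDS):
            both_neg += 1
            both_neg_by_geno[p.genotype] = both_neg_by_geno.get(
                p.genotype, 0) + 1
        response_counts[classify_response(p).value] += 1
        flags = flag_resistance_mechanisms(p)
        if flags:
            flagged[p.line_id] = flags

    return CohortSummary(
        n_lines=len(profiles),
        baseline_negative=baseline_negative,
        not_induced=not_induced,
        both_pd_ligands_negative=both_neg,
        both_pd_ligands_negative_by_genotype=both_neg_by_geno,
        response_counts=response_counts,
        diminished=(response_counts["partial"] + response_counts["null"]),
        flagged=flagged,
    )


def profiles_from_table(
    table: pd.DataFrame,
    scoring: Optional[ScoringConfig] = None,
) -> list[CellLineProfile]:
    """Build profiles from a cohort table in the canonical ingested layout.

    Expects columns ``cell_line``, ``genotype`` and ``<marker>_pre`` /
    ``<marker>_post`` relative-MFI columns for the five core markers.
    """
    scoring = scoring or ScoringConfig()
    profiles = []
    for _, row in table.iterrows():
        rel = {m: (float(row[f"{m}_pre"]), float(row[f"{m}_post"]))
               for m in MARKERS}
        profiles.append(CellLineProfile(
            line_id=str(row["cell_line"]),
            genotype=str(row["genotype"]),
            rel_mfi=rel,
            scoring=scoring,
        ))
    return profiles
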