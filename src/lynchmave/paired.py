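"""Joint germline-somatic ("two-hit") analyses on paired tumor-normal cases.

Lynch syndrome tumors typically arise by biallelic mismatch-repair loss: an
inherited first hit plus a somatic second hit (mutation, LOH, or epigenetic
silencing).  Given a cohort of paired cases — each a germline finding plus a
tumor test result — these analyses ask whether the function map's germline
tier predicts (i) a pathogenic somatic second hit in MSH2, (ii) tumor
microsatellite instability after removing MLH1-promoter-hypermethylated
cases, and (iii), among tumors with somatic MSH2 missense variants, whether
functionally neutral somatic variants coincide with an alternative somatic
mechanism (other-LS-gene mutations, MLH1 hypermethylation).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .stats import Contingency2x2, fisher_two_sided
from .variants import (
    LS_GENES,
    ClinicalClass,
    Consequence,
    FunctionTier,
    Gene,
    VariantRecord,
    assign_tier,
)

__all__ = [
    "MsiStatus",
    "SomaticVariant",
    "TumorTestResult",
    "PairedCase",
    "TableWithTest",
    "select_sole_msh2_missense_cases",
    "second_hit_analysis",
    "msi_analysis",
    "somatic_coincidence_analysis",
    "flag_sporadic_candidates",
    "read_paired_cohort",
    "write_paired_cohort",
]

logger = logging.getLogger(__name__)


class MsiStatus(str, enum.Enum):
    MSS = "MSS"
    MSI_LOW = "MSI_low"
    MSI_HIGH = "MSI_high"
    NOT_ASSAYED = "not_assayed"

    @property
    def unstable(self) -> bool:
        return self in (MsiStatus.MSI_LOW, MsiStatus.MSI_HIGH)


@dataclass(frozen=True)
class SomaticVariant:
    gene: Gene
    hgvs_c: str
    classification: ClinicalClass | None = None
    consequence: Consequence = Consequence.MISSENSE
    lof_score: float | None = None
    spliceai_deltamax: float | None = None

    @property
    def tier(self) -> FunctionTier:
        return assign_tier(self.lof_score, self.spliceai_deltamax)

    @property
    def is_plp(self) -> bool:
        return self.classification is not None and self.classification.is_path


@dataclass(frozen=True)
class TumorTestResult:
    somatic_variants: tuple[SomaticVariant, ...] = field(default_factory=tuple)
    loh_events: tuple[str, ...] = field(default_factory=tuple)
    msi_status: MsiStatus = MsiStatus.NOT_ASSAYED
    #: None = MLH1 methylation not assayed
    mlh1_promoter_hypermethylated: bool | None = None
    epcam_structural_variant: bool = False

    def __post_init__(self) -> None:
        for sv in self.somatic_variants:
            if sv.gene.value not in LS_GENES + ("EPCAM",):
                raise ValueError(f"somatic variant in unexpected gene {sv.gene}")


@dataclass(frozen=True)
class PairedCase:
    individual_id: str
    germline_variants: tuple[VariantRecord, ...]
    tumor: TumorTestResult


@dataclass(frozen=True)
class TableWithTest:
    """A 2x2 cross-tabulation with its two-sided Fisher p-value."""

    table: Contingency2x2
    p_value: float
    row_labels: tuple[str, str]
    col_labels: tuple[str, str]
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "table": self.table.to_dict(),
            "p_value": self.p_value,
            "rows": list(self.row_labels),
            "cols": list(self.col_labels),
            "n_excluded": self.n_excluded,
        }


def select_sole_msh2_missense_cases(cohort: Iterable[PairedCase]) -> list[PairedCase]:
    """Cases whose only germline LS-gene finding is one MSH2 missense variant.

    Idempotent and order-preserving; a case with any additional germline
    finding in an LS gene (including a second MSH2 variant) is excluded.
    """
    selected = []
    for case in cohort:
        ls_findings = [v for v in case.germline_variants if v.gene.value in LS_GENES]
        if (
            len(ls_findings) == 1
            and ls_findings[0].gene is Gene.MSH2
            and ls_findings[0].consequence is Consequence.MISSENSE
        ):
            selected.append(case)
    return selected


def _germline_tier(case: PairedCase) -> FunctionTier:
    ls = [v for v in case.germline_variants if v.gene.value in LS_GENES]
    return ls[0].tier


def _has_second_hit(case: PairedCase, include_loh: bool) -> bool:
    if any(sv.gene is Gene.MSH2 and sv.is_plp for sv in case.tumor.somatic_variants):
        return True
    if include_loh and "MSH2" in case.tumor.loh_events:
        return True
    return bool(case.tumor.epcam_structural_variant)


def second_hit_analysis(
    cases: Sequence[PairedCase], include_loh: bool = True
) -> TableWithTest:
    """Somatic MSH2 second hits by germline function tier.

    A second hit is any P/LP somatic MSH2 mutation, somatic MSH2 LOH (when
    ``include_loh``), or an EPCAM structural variant.  Rows are germline
    deleterious vs neutral; intermediate/unscored germline tiers are excluded.
    """
    groups = {"deleterious": [0, 0], "neutral": [0, 0]}  # [hit, no hit]
    excluded = 0
    for case in cases:
        tier = _germline_tier(case)
        if tier.is_deleterious:
            key = "deleterious"
        elif tier is FunctionTier.NEUTRAL:
            key = "neutral"
        else:
            excluded += 1
            continue
        groups[key][0 if _has_second_hit(case, include_loh) else 1] += 1
    table = Contingency2x2(
        groups["deleterious"][0], groups["deleterious"][1],
        groups["neutral"][0], groups["neutral"][1],
    )
    return TableWithTest(
        table=table,
        p_value=fisher_two_sided(table),
        row_labels=("germline_deleterious", "germline_neutral"),
        col_labels=("second_hit", "no_second_hit"),
        n_excluded=excluded,
    )


def msi_analysis(cases: Sequence[PairedCase]) -> TableWithTest:
    """Tumor MSI by germline function tier, excluding MLH1-methylated cases.

    MSI-high and MSI-low count together as unstable; cases without an MSI
    assay are excluded with a logged count.
    """
    groups = {"deleterious": [0, 0], "neutral": [0, 0]}  # [unstable, MSS]
    excluded = 0
    for case in cases:
        if case.tumor.mlh1_promoter_hypermethylated is True:
            excluded += 1
            continue
        if case.tumor.msi_status is MsiStatus.NOT_ASSAYED:
            excluded += 1
            continue
        tier = _germline_tier(case)
        if tier.is_deleterious:
            key = "deleterious"
        elif tier is FunctionTier.NEUTRAL:
            key = "neutral"
        else:
            excluded += 1
            continue
        groups[key][0 if case.tumor.msi_status.unstable else 1] += 1
    if sum(groups["deleterious"]) + sum(groups["neutral"]) == 0:
        raise ValueError("no evaluable cases after MLH1-methylation/MSI-assay exclusions")
    logger.info("msi_analysis excluded %d cases", excluded)
    table = Contingency2x2(
        groups["deleterious"][0], groups["deleterious"][1],
        groups["neutral"][0], groups["neutral"][1],
    )
    return TableWithTest(
        table=table,
        p_value=fisher_two_sided(table),
        row_labels=("germline_deleterious", "germline_neutral"),
        col_labels=("msi_unstable", "mss"),
        n_excluded=excluded,
    )


def _somatic_msh2_missense(case: PairedCase) -> list[SomaticVariant]:
    return [
        sv
        for sv in case.tumor.somatic_variants
        if sv.gene is Gene.MSH2 and sv.consequence is Consequence.MISSENSE
    ]


def somatic_coincidence_analysis(
    cohort: Sequence[PairedCase],
) -> dict[str, TableWithTest] | None:
    """Alternative somatic mechanisms by somatic MSH2 missense functional status.

    Among cases with at least one somatic MSH2 missense variant, the
    *disruptive* group has >= 1 such variant predicted functionally
    deleterious; the *neutral* group has exclusively neutral somatic MSH2
    missense variants and no other somatic P/LP MSH2 mutation.  Test A
    cross-tabulates somatic mutations in the other LS genes; test B, MLH1
    promoter hypermethylation among assayed tumors.  Returns None when the
    cohort has no somatic MSH2 missense variants.
    """
    neutral, disruptive = [], []
    for case in cohort:
        missense = _somatic_msh2_missense(case)
        if not missense:
            continue
        if any(sv.tier.is_deleterious for sv in missense):
            disruptive.append(case)
        elif all(sv.tier is FunctionTier.NEUTRAL for sv in missense) and not any(
            sv.gene is Gene.MSH2 and sv.is_plp and sv.consequence is not Consequence.MISSENSE
            for sv in case.tumor.somatic_variants
        ):
            neutral.append(case)
    if not neutral and not disruptive:
        return None

    def other_ls_hit(case: PairedCase) -> bool:
        return any(
            sv.gene.value in ("MSH6", "MLH1", "PMS2") for sv in case.tumor.somatic_variants
        )

    a_table = Contingency2x2(
        sum(1 for c in neutral if other_ls_hit(c)),
        sum(1 for c in neutral if not other_ls_hit(c)),
        sum(1 for c in disruptive if other_ls_hit(c)),
        sum(1 for c in disruptive if not other_ls_hit(c)),
    )
    test_a = TableWithTest(
        table=a_table,
        p_value=fisher_two_sided(a_table),
        row_labels=("somatic_neutral", "somatic_disruptive"),
        col_labels=("other_ls_somatic", "none"),
    )

    neut_assayed = [c for c in neutral if c.tumor.mlh1_promoter_hypermethylated is not None]
    disr_assayed = [c for c in disruptive if c.tumor.mlh1_promoter_hypermethylated is not None]
    if not neut_assayed and not disr_assayed:
        logger.warning("MLH1 methylation assayed in no case; coincidence test B absent")
        return {"other_ls_somatic": test_a, "mlh1_methylation": None}
    b_table = Contingency2x2(
        sum(1 for c in neut_assayed if c.tumor.mlh1_promoter_hypermethylated),
        sum(1 for c in neut_assayed if not c.tumor.mlh1_promoter_hypermethylated),
        sum(1 for c in disr_assayed if c.tumor.mlh1_promoter_hypermethylated),
        sum(1 for c in disr_assayed if not c.tumor.mlh1_promoter_hypermethylated),
    )
    test_b = TableWithTest(
        table=b_table,
        p_value=fisher_two_sided(b_table),
        row_labels=("somatic_neutral", "somatic_disruptive"),
        col_labels=("mlh1_hypermethylated", "not_hypermethylated"),
        n_excluded=(len(neutral) - len(neut_assayed)) + (len(disruptive) - len(disr_assayed)),
    )
    return {"other_ls_somatic": test_a, "mlh1_methylation": test_b}


def flag_sporadic_candidates(cohort: Sequence[PairedCase]) -> list[str]:
    """Lynch-like (sporadic) candidates: >= 2 somatic MSH2 hits, >= 1 of them
    functionally deleterious, and no deleterious germline variant."""
    flagged = []
    for case in cohort:
        msh2_somatic = [sv for sv in case.tumor.somatic_variants if sv.gene is Gene.MSH2]
        n_hits = len(msh2_somatic) + (1 if "MSH2" in case.tumor.loh_events else 0)
        if n_hits < 2:
            continue
        if not any(sv.tier.is_deleterious or sv.is_plp for sv in msh2_somatic):
            continue
        if any(v.tier.is_deleterious for v in case.germline_variants):
            continue
        flagged.append(case.individual_id)
    return flagged


# ---------------------------------------------------------------------------
# TSV I/O: a germline-findings table and a somatic/tumor table joined on
# individual_id.

_GERMLINE_COLS = ["individual_id", "gene", "hgvs_c", "hgvs_p", "consequence",
                  "classification", "lof_score", "spliceai_deltamax", "gnomad_af",
                  "evidence_codes"]
_SOMATIC_COLS = ["individual_id", "gene", "hgvs_c", "consequence", "classification",
                 "lof_score", "spliceai_deltamax", "loh_genes", "msi_status",
                 "mlh1_promoter_hypermethylated", "epcam_structural_variant"]


def _opt_float(v) -> float | None:
    return None if v in ("", None) or pd.isna(v) else float(v)


def read_paired_cohort(germline_path: str | Path, somatic_path: str | Path) -> list[PairedCase]:
    gdf = pd.read_csv(germline_path, sep="\t", dtype=str, keep_default_na=False)
    sdf = pd.read_csv(somatic_path, sep="\t", dtype=str, keep_default_na=False)
    cases = []
    somatic_by_id = dict(tuple(sdf.groupby("individual_id", sort=False)))
    for iid, grows in gdf.groupby("individual_id", sort=False):
        germline = tuple(
            VariantRecord(
                gene=Gene(r["gene"]),
                hgvs_c=r["hgvs_c"],
                hgvs_p=r.get("hgvs_p", ""),
                consequence=Consequence(r["consequence"] or "missense"),
                classification=ClinicalClass(r["classification"] or "VUS"),
                lof_score=_opt_float(r["lof_score"]),
                spliceai_deltamax=_opt_float(r["spliceai_deltamax"]),
                gnomad_af=_opt_float(r.get("gnomad_af", "")),
                evidence_codes=tuple(
                    tok for tok in (r.get("evidence_codes", "") or "").split(",") if tok
                ),
            )
            for _, r in grows.iterrows()
        )
        srows = somatic_by_id.get(iid)
        somatic: tuple[SomaticVariant, ...] = ()
        loh: tuple[str, ...] = ()
        msi = MsiStatus.NOT_ASSAYED
        meth: bool | None = None
        epcam = False
        if srows is not None:
            first = srows.iloc[0]
            loh = tuple(g for g in (first["loh_genes"] or "").split(",") if g)
            msi = MsiStatus(first["msi_status"] or "not_assayed")
            meth = (
                None if first["mlh1_promoter_hypermethylated"] == ""
                else first["mlh1_promoter_hypermethylated"] == "True"
            )
            epcam = first["epcam_structural_variant"] == "True"
            somatic = tuple(
                SomaticVariant(
                    gene=Gene(r["gene"]),
                    hgvs_c=r["hgvs_c"],
                    classification=(
                        None if r["classification"] == "" else ClinicalClass(r["classification"])
                    ),
                    consequence=Consequence(r["consequence"] or "missense"),
                    lof_score=_opt_float(r["lof_score"]),
                    spliceai_deltamax=_opt_float(r["spliceai_deltamax"]),
                )
                for _, r in srows.iterrows()
                if r["hgvs_c"] != ""
            )
        cases.append(
            PairedCase(
                individual_id=iid,
                germline_variants=germline,
                tumor=TumorTestResult(
                    somatic_variants=somatic,
                    loh_events=loh,
                    msi_status=msi,
                    mlh1_promoter_hypermethylated=meth,
                    epcam_structural_variant=epcam,
                ),
            )
        )
    return cases


def write_paired_cohort(
    cohort: Sequence[PairedCase], germline_path: str | Path, somatic_path: str | Path
) -> None:
    grows, srows = [], []
    for case in cohort:
        for v in case.germline_variants:
            grows.append(
                {
                    "individual_id": case.individual_id,
                    "gene": v.gene.value,
                    "hgvs_c": v.hgvs_c,
                    "hgvs_p": v.hgvs_p,
                    "consequence": v.consequence.value,
                    "classification": v.classification.value,
                    "lof_score": "" if v.lof_score is None else repr(v.lof_score),
                    "spliceai_deltamax": ""
                    if v.spliceai_deltamax is None
                    else repr(v.spliceai_deltamax),
                    "gnomad_af": "" if v.gnomad_af is None else repr(v.gnomad_af),
                    "evidence_codes": ",".join(v.evidence_codes),
                }
            )
        tumor = case.tumor
        shared = {
            "individual_id": case.individual_id,
            "loh_genes": ",".join(tumor.loh_events),
            "msi_status": tumor.msi_status.value,
            "mlh1_promoter_hypermethylated": ""
            if tumor.mlh1_promoter_hypermethylated is None
            else str(tumor.mlh1_promoter_hypermethylated),
            "epcam_structural_variant": str(tumor.epcam_structural_variant),
        }
        if tumor.somatic_variants:
            for sv in tumor.somatic_variants:
                srows.append(
                    {
                        **shared,
                        "gene": sv.gene.value,
                        "hgvs_c": sv.hgvs_c,
                        "consequence": sv.consequence.value,
                        "classification": ""
                        if sv.classification is None
                        else sv.classification.value,
                        "lof_score": "" if sv.lof_score is None else repr(sv.lof_score),
                        "spliceai_deltamax": ""
                        if sv.spliceai_deltamax is None
                        else repr(sv.spliceai_deltamax),
                    }
                )
        else:
            srows.append(
                {**shared, "gene": "MSH2", "hgvs_c": "", "consequence": "missense",
                 "classification": "", "lof_score": "", "spliceai_deltamax": ""}
            )
    pd.DataFrame(grows, columns=_GERMLINE_COLS).to_csv(germline_path, sep="\t", index=False)
    pd.DataFrame(srows, columns=_SOMATIC_COLS).to_csv(somatic_path, sep="\t", index=False)
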