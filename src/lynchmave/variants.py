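"""Domain types for MSH2 missense variants and functional tiering.

Every missense variant carries up to two function scores: a loss-of-function
(LoF) enrichment score from a deep mutational scan of MSH2 protein function
(higher = more functionally abnormal, unitless), and a SpliceAI ``deltaMax``
score in [0, 1] estimating the probability of splice disruption.  The two
scores are combined into a discrete function tier:

* ``deltaMax >= 0.5``            -> deleterious (splice mechanism)
* else ``LoF >= 0.4``            -> deleterious (protein mechanism)
* else either score in its
  intermediate band
  (``0 <= LoF < 0.4`` or
  ``0.2 <= deltaMax < 0.5``)     -> intermediate
* else                           -> neutral

Thresholds are inclusive on the deleterious side and exclusive on the
neutral side; a variant is called functionally neutral only when *both*
measures are in their neutral range.  Variants with no score at all are
``unscored`` and excluded from score-based analyses.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Gene",
    "Consequence",
    "ClinicalClass",
    "FunctionTier",
    "Mechanism",
    "TierThresholds",
    "DEFAULT_THRESHOLDS",
    "VariantRecord",
    "VariantTableError",
    "assign_tier",
    "count_by_mechanism",
    "read_variant_table",
    "write_variant_table",
]

LS_GENES = ("MSH2", "MLH1", "MSH6", "PMS2")


class Gene(str, enum.Enum):
    """Lynch syndrome mismatch repair genes plus EPCAM (structural events)."""

    MSH2 = "MSH2"
    MLH1 = "MLH1"
    MSH6 = "MSH6"
    PMS2 = "PMS2"
    EPCAM = "EPCAM"


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    TRUNCATING = "truncating"
    OTHER = "other"


class ClinicalClass(str, enum.Enum):
    """Five-tier clinical classification."""

    B = "B"
    LB = "LB"
    VUS = "VUS"
    LP = "LP"
    P = "P"

    @property
    def is_path(self) -> bool:
        return self in (ClinicalClass.P, ClinicalClass.LP)

    @property
    def is_benign(self) -> bool:
        return self in (ClinicalClass.B, ClinicalClass.LB)

    @property
    def rank(self) -> int:
        """Benign-to-pathogenic ordering: B=0, LB=1, VUS=2, LP=3, P=4."""
        return ("B", "LB", "VUS", "LP", "P").index(self.value)


class Mechanism(str, enum.Enum):
    PROTEIN = "protein"
    SPLICE = "splice"
    NONE = "none"


class FunctionTier(str, enum.Enum):
    DELETERIOUS_PROTEIN = "deleterious_protein"
    DELETERIOUS_SPLICE = "deleterious_splice"
    INTERMEDIATE = "intermediate"
    NEUTRAL = "neutral"
    UNSCORED = "unscored"

    @property
    def mechanism(self) -> Mechanism:
        if self is FunctionTier.DELETERIOUS_PROTEIN:
            return Mechanism.PROTEIN
        if self is FunctionTier.DELETERIOUS_SPLICE:
            return Mechanism.SPLICE
        return Mechanism.NONE

    @property
    def is_deleterious(self) -> bool:
        return self in (
            FunctionTier.DELETERIOUS_PROTEIN,
            FunctionTier.DELETERIOUS_SPLICE,
        )


@dataclass(frozen=True)
class TierThresholds:
    """Score cut-points for functional tiering.

    ``lof_deleterious``/``splice_deleterious`` are inclusive lower bounds of
    the deleterious bands; ``lof_neutral``/``splice_neutral`` are exclusive
    upper bounds of the neutral bands (scores in between are intermediate).
    """

    lof_deleterious: float = 0.4
    lof_neutral: float = 0.0
    splice_deleterious: float = 0.5
    splice_neutral: float = 0.2


DEFAULT_THRESHOLDS = TierThresholds()


def assign_tier(
    lof_score: float | None,
    deltamax: float | None,
    thresholds: TierThresholds = DEFAULT_THRESHOLDS,
) -> FunctionTier:
    """Map a (LoF score, SpliceAI deltaMax) pair to a function tier.

    Splice attribution takes precedence over protein attribution; the more
    severe band wins when the two scores disagree.  Total and deterministic
    over the valid input domain; a variant with neither score is unscored.
    """
    if deltamax is not None and not (0.0 <= deltamax <= 1.0):
        raise ValueError(f"spliceai_deltamax must be in [0, 1], got {deltamax}")
    if lof_score is None and deltamax is None:
        return FunctionTier.UNSCORED
    if deltamax is not None and deltamax >= thresholds.splice_deleterious:
        return FunctionTier.DELETERIOUS_SPLICE
    if lof_score is not None and lof_score >= thresholds.lof_deleterious:
        return FunctionTier.DELETERIOUS_PROTEIN
    lof_intermediate = (
        lof_score is not None and thresholds.lof_neutral <= lof_score < thresholds.lof_deleterious
    )
    splice_intermediate = (
        deltamax is not None and thresholds.splice_neutral <= deltamax < thresholds.splice_deleterious
    )
    if lof_intermediate or splice_intermediate:
        return FunctionTier.INTERMEDIATE
    return FunctionTier.NEUTRAL


@dataclass(frozen=True)
class VariantRecord:
    """One missense (or other) variant with identifiers, scores and class.

    ``evidence_codes`` holds the non-functional ACMG/AMP evidence code tokens
    already established for the variant (e.g. ``("PM2_P", "PP4")``); the
    classification engine parses and extends them.
    """

    gene: Gene
    hgvs_c: str
    hgvs_p: str = ""
    consequence: Consequence = Consequence.MISSENSE
    classification: ClinicalClass = ClinicalClass.VUS
    lof_score: float | None = None
    spliceai_deltamax: float | None = None
    gnomad_af: float | None = None
    evidence_codes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.hgvs_c:
            raise ValueError("hgvs_c must be non-empty")
        if self.spliceai_deltamax is not None and not (0.0 <= self.spliceai_deltamax <= 1.0):
            raise ValueError(
                f"{self.hgvs_c}: spliceai_deltamax {self.spliceai_deltamax} outside [0, 1]"
            )
        if self.gnomad_af is not None and not (0.0 <= self.gnomad_af <= 1.0):
            raise ValueError(f"{self.hgvs_c}: gnomad_af {self.gnomad_af} outside [0, 1]")

    @property
    def tier(self) -> FunctionTier:
        return assign_tier(self.lof_score, self.spliceai_deltamax)

    def with_codes(self, codes: Sequence[str]) -> "VariantRecord":
        return replace(self, evidence_codes=tuple(codes))


def count_by_mechanism(catalog: Iterable[VariantRecord]) -> pd.DataFrame:
    """Cross-tabulate function tier against mechanism attribution.

    Splice-disruptive variants are counted under the splice mechanism before
    any protein-score evaluation (the precedence is built into the tiering).
    Each variant is counted exactly once; the table total equals the catalog
    size.
    """
    tiers = [v.tier for v in catalog]
    idx = pd.Index([t.value for t in FunctionTier], name="tier")
    cols = pd.Index([m.value for m in Mechanism], name="mechanism")
    table = pd.DataFrame(0, index=idx, columns=cols, dtype=int)
    for t in tiers:
        table.loc[t.value, t.mechanism.value] += 1
    return table


class VariantTableError(ValueError):
    """Raised on malformed variant-catalog tables, naming the offending row."""


_COLUMNS = [
    "gene",
    "hgvs_c",
    "hgvs_p",
    "consequence",
    "classification",
    "lof_score",
    "spliceai_deltamax",
    "gnomad_af",
    "evidence_codes",
]


def _parse_float(value, row: int, column: str) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise VariantTableError(f"row {row}: malformed number {value!r} in column {column}")


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a tab-separated variant catalog (empty string = missing value)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS[:2] if c not in df.columns]
    if missing:
        raise VariantTableError(f"missing required columns: {missing}")
    records: list[VariantRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        hgvs_c = d.get("hgvs_c", "")
        if hgvs_c in seen:
            raise VariantTableError(f"row {i}: duplicate hgvs_c {hgvs_c!r}")
        seen.add(hgvs_c)
        try:
            gene = Gene(d.get("gene", ""))
        except ValueError:
            raise VariantTableError(f"row {i}: unknown gene symbol {d.get('gene')!r}")
        try:
            rec = VariantRecord(
                gene=gene,
                hgvs_c=hgvs_c,
                hgvs_p=d.get("hgvs_p", ""),
                consequence=Consequence(d.get("consequence") or "missense"),
                classification=ClinicalClass(d.get("classification") or "VUS"),
                lof_score=_parse_float(d.get("lof_score"), i, "lof_score"),
                spliceai_deltamax=_parse_float(d.get("spliceai_deltamax"), i, "spliceai_deltamax"),
                gnomad_af=_parse_float(d.get("gnomad_af"), i, "gnomad_af"),
                evidence_codes=tuple(
                    tok for tok in (d.get("evidence_codes") or "").split(",") if tok
                ),
            )
        except ValueError as exc:
            raise VariantTableError(f"row {i}: {exc}") from exc
        records.append(rec)
    return records


def variants_to_frame(catalog: Iterable[VariantRecord]) -> pd.DataFrame:
    rows = []
    for v in catalog:
        rows.append(
            {
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
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_variant_table(catalog: Iterable[VariantRecord], path: str | Path) -> None:
    """Write a catalog as TSV; ``write . read`` is the identity on records."""
    variants_to_frame(catalog).to_csv(path, sep="\t", index=False)
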