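"""Point-based ACMG/AMP evidence-code algebra and VUS reclassification.

Evidence codes (PS3, PM2, BS3, ...) carry a direction (pathogenic for P*,
benign for B*) and an applied strength, which defaults to the code's
intrinsic strength but may be overridden with a ``_P``/``_M``/``_S``/``_VS``
suffix (e.g. ``PM2_P`` is PM2 applied at supporting strength).  Strengths
map to integer points — supporting 1, moderate 2, strong 4, very strong 8,
negated for benign codes — and the point total places the variant in one of
the five clinical classes:

    points >= 10 -> P;  6..9 -> LP;  0..5 -> VUS;  -6..-1 -> LB;  <= -7 -> B

Functional evidence from the MSH2 function map enters as PS3 (abnormal
protein score) or BS3 (both measures normal).  PS3 is applied at strong
strength only for LoF scores at or above the lowest score in the validated
pathogenic set (1.7 by default); abnormal scores below that line are
PS3-moderate *eligible* but not auto-applied, a deliberately conservative
choice.  Splice-predicted deleterious variants never receive PS3 here: the
underlying assay is cDNA-based and blind to splicing.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .calibration import Direction, OddsPathResult, StrengthLevel
from .stats import binomial_two_sided
from .variants import ClinicalClass, FunctionTier, VariantRecord

__all__ = [
    "EvidenceCode",
    "CodeParseError",
    "PointScale",
    "DEFAULT_SCALE",
    "ClassificationResult",
    "ReclassificationSummary",
    "parse_code",
    "format_code",
    "points_for",
    "functional_evidence_code",
    "classify",
    "reclassify_catalog",
    "depletion_test",
    "CODE_REGISTRY",
]

logger = logging.getLogger(__name__)


class CodeParseError(ValueError):
    pass


#: base code -> intrinsic strength (BA1 treated as stand-alone/very strong)
CODE_REGISTRY: dict[str, StrengthLevel] = {
    "PVS1": StrengthLevel.VERY_STRONG,
    **{f"PS{i}": StrengthLevel.STRONG for i in range(1, 5)},
    **{f"PM{i}": StrengthLevel.MODERATE for i in range(1, 7)},
    **{f"PP{i}": StrengthLevel.SUPPORTING for i in range(1, 6)},
    "BA1": StrengthLevel.VERY_STRONG,
    **{f"BS{i}": StrengthLevel.STRONG for i in range(1, 5)},
    **{f"BP{i}": StrengthLevel.SUPPORTING for i in range(1, 8)},
}

_SUFFIX = {
    "P": StrengthLevel.SUPPORTING,
    "M": StrengthLevel.MODERATE,
    "S": StrengthLevel.STRONG,
    "VS": StrengthLevel.VERY_STRONG,
}
_SUFFIX_INV = {v: k for k, v in _SUFFIX.items()}
_CODE_RE = re.compile(r"^([A-Z]{2,3}\d)(?:_(P|M|S|VS))?$")


@dataclass(frozen=True)
class EvidenceCode:
    base: str
    applied_strength: StrengthLevel

    def __post_init__(self) -> None:
        if self.base not in CODE_REGISTRY:
            raise CodeParseError(f"unknown evidence code base {self.base!r}")
        if self.applied_strength is StrengthLevel.NONE:
            raise CodeParseError("evidence code cannot carry strength 'none'")

    @property
    def direction(self) -> Direction:
        return Direction.PATHOGENIC if self.base.startswith("P") else Direction.BENIGN


def parse_code(text: str) -> EvidenceCode:
    """Parse a code token such as ``"PS3"`` or ``"PM2_P"``."""
    m = _CODE_RE.match(text.strip())
    if not m or m.group(1) not in CODE_REGISTRY:
        raise CodeParseError(f"unrecognised evidence code token {text!r}")
    base, suffix = m.groups()
    strength = _SUFFIX[suffix] if suffix else CODE_REGISTRY[base]
    return EvidenceCode(base, strength)


def format_code(code: EvidenceCode) -> str:
    """Inverse of :func:`parse_code`: intrinsic strength prints bare."""
    if code.applied_strength is CODE_REGISTRY[code.base]:
        return code.base
    return f"{code.base}_{_SUFFIX_INV[code.applied_strength]}"


@dataclass(frozen=True)
class PointScale:
    """Configurable point values and class thresholds.

    Defaults follow the published point-based recasting of the ACMG/AMP
    guidelines; alternative scales can be swapped in wholesale.
    """

    points: dict = field(
        default_factory=lambda: {
            StrengthLevel.SUPPORTING: 1,
            StrengthLevel.MODERATE: 2,
            StrengthLevel.STRONG: 4,
            StrengthLevel.VERY_STRONG: 8,
        }
    )
    pathogenic_min: int = 10
    likely_pathogenic_min: int = 6
    likely_benign_max: int = -1
    benign_max: int = -7

    def category(self, points: int) -> ClinicalClass:
        if points >= self.pathogenic_min:
            return ClinicalClass.P
        if points >= self.likely_pathogenic_min:
            return ClinicalClass.LP
        if points <= self.benign_max:
            return ClinicalClass.B
        if points <= self.likely_benign_max:
            return ClinicalClass.LB
        return ClinicalClass.VUS


DEFAULT_SCALE = PointScale()


def points_for(code: EvidenceCode, scale: PointScale = DEFAULT_SCALE) -> int:
    value = scale.points[code.applied_strength]
    return value if code.direction is Direction.PATHOGENIC else -value


@dataclass(frozen=True)
class ClassificationResult:
    points: int
    category: ClinicalClass
    codes_applied: tuple[EvidenceCode, ...]


def classify(
    codes: Iterable[EvidenceCode], scale: PointScale = DEFAULT_SCALE
) -> ClassificationResult:
    """Sum evidence points and assign the five-tier class.

    Permutation-invariant; each base code may appear at most once.
    """
    codes = tuple(codes)
    bases = [c.base for c in codes]
    dupes = {b for b in bases if bases.count(b) > 1}
    if dupes:
        raise ValueError(f"duplicate evidence codes applied: {sorted(dupes)}")
    pts = sum(points_for(c, scale) for c in codes)
    return ClassificationResult(points=pts, category=scale.category(pts), codes_applied=codes)


def _require_strong_calibration(calibration: OddsPathResult) -> None:
    ok_abn = (
        calibration.strength_abnormal.direction is Direction.PATHOGENIC
        and calibration.strength_abnormal.level
        in (StrengthLevel.STRONG, StrengthLevel.VERY_STRONG)
    )
    ok_norm = (
        calibration.strength_normal.direction is Direction.BENIGN
        and calibration.strength_normal.level
        in (StrengthLevel.STRONG, StrengthLevel.VERY_STRONG)
    )
    if not (ok_abn and ok_norm):
        raise ValueError(
            "calibration does not support strong functional evidence in both "
            f"directions (abnormal: {calibration.strength_abnormal}, "
            f"normal: {calibration.strength_normal})"
        )


def functional_evidence_code(
    tier: FunctionTier,
    lof_score: float | None,
    calibration: OddsPathResult,
    ps3_strong_min: float = 1.7,
) -> EvidenceCode | None:
    """Derive the PS3/BS3 code a variant's function scores support.

    Requires a calibration establishing strong evidence in both directions.
    Protein-deleterious scores at or above ``ps3_strong_min`` earn PS3 at
    strong; below it (but still abnormal) PS3 at moderate; a functionally
    neutral variant (both measures normal) earns BS3 at strong.  Intermediate
    and splice-predicted tiers earn nothing from the assay.
    """
    _require_strong_calibration(calibration)
    if tier is FunctionTier.UNSCORED:
        logger.warning("unscored variant: no functional evidence applicable")
        return None
    if tier is FunctionTier.DELETERIOUS_PROTEIN:
        if lof_score is None:
            raise ValueError("protein-deleterious tier without a LoF score")
        if lof_score >= ps3_strong_min:
            return EvidenceCode("PS3", StrengthLevel.STRONG)
        return EvidenceCode("PS3", StrengthLevel.MODERATE)
    if tier is FunctionTier.NEUTRAL:
        return EvidenceCode("BS3", StrengthLevel.STRONG)
    return None  # intermediate or splice-predicted


@dataclass
class ReclassificationSummary:
    """Cohort-level tally of a reclassification pass plus per-variant audit."""

    n_catalog: int
    n_previously_classified: int
    n_vus: int
    newly_plp: int
    newly_blb: int
    remaining_vus: int
    remaining_intermediate: int
    remaining_abnormal_insufficient: int
    remaining_splice: int
    remaining_neutral_insufficient: int
    remaining_unscored: int
    ps3_strong_added: int
    ps3_moderate_eligible: int
    bs3_added: int
    audit: pd.DataFrame

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n_catalog",
                "n_previously_classified",
                "n_vus",
                "newly_plp",
                "newly_blb",
                "remaining_vus",
                "remaining_intermediate",
                "remaining_abnormal_insufficient",
                "remaining_splice",
                "remaining_neutral_insufficient",
                "remaining_unscored",
                "ps3_strong_added",
                "ps3_moderate_eligible",
                "bs3_added",
            )
        }
        return d

    def conserves(self) -> bool:
        return (
            self.newly_plp + self.newly_blb + self.remaining_vus + self.n_previously_classified
            == self.n_catalog
        )


def reclassify_catalog(
    catalog: Sequence[VariantRecord],
    calibration: OddsPathResult,
    scale: PointScale = DEFAULT_SCALE,
    ps3_strong_min: float = 1.7,
    apply_moderate: bool = False,
) -> ReclassificationSummary:
    """Add calibrated functional evidence to every VUS and re-classify.

    PS3 at strong strength is added only for LoF scores >= ``ps3_strong_min``;
    PS3-moderate-eligible variants are tallied but left unreclassified unless
    ``apply_moderate`` is set.  BS3 (strong) is added for functionally neutral
    variants.  Previously classified (non-VUS) variants pass through
    untouched.  Categories partition the catalog:
    newly P/LP + newly B/LB + remaining VUS + previously classified = total.
    """
    _require_strong_calibration(calibration)
    rows = []
    n_prev = newly_plp = newly_blb = 0
    rem = {"intermediate": 0, "abnormal": 0, "splice": 0, "neutral": 0, "unscored": 0}
    n_ps3_strong = n_ps3_mod = n_bs3 = 0

    for v in catalog:
        if v.classification is not ClinicalClass.VUS:
            n_prev += 1
            continue
        codes = [parse_code(tok) for tok in v.evidence_codes]
        tier = v.tier
        func = (
            functional_evidence_code(tier, v.lof_score, calibration, ps3_strong_min)
            if tier is not FunctionTier.UNSCORED
            else None
        )
        applied = func is not None and (
            func.applied_strength is not StrengthLevel.MODERATE or apply_moderate
        )
        if func is not None and func.base == "PS3":
            if func.applied_strength is StrengthLevel.STRONG:
                n_ps3_strong += 1
            else:
                n_ps3_mod += 1
        if applied and func is not None and func.base == "BS3":
            n_bs3 += 1
        final_codes = codes + [func] if (applied and func is not None) else codes
        result = classify(final_codes, scale)
        new_class = result.category
        if new_class.is_path:
            newly_plp += 1
        elif new_class.is_benign:
            newly_blb += 1
        else:
            if tier is FunctionTier.INTERMEDIATE:
                rem["intermediate"] += 1
            elif tier is FunctionTier.DELETERIOUS_PROTEIN:
                rem["abnormal"] += 1
            elif tier is FunctionTier.DELETERIOUS_SPLICE:
                rem["splice"] += 1
            elif tier is FunctionTier.UNSCORED:
                rem["unscored"] += 1
            else:
                rem["neutral"] += 1
        rows.append(
            {
                "hgvs_c": v.hgvs_c,
                "old_class": v.classification.value,
                "tier": tier.value,
                "codes_before": ",".join(v.evidence_codes),
                "functional_code": format_code(func) if func is not None else "",
                "functional_code_applied": applied and func is not None,
                "points": result.points,
                "new_class": new_class.value,
            }
        )

    audit = pd.DataFrame(
        rows,
        columns=[
            "hgvs_c",
            "old_class",
            "tier",
            "codes_before",
            "functional_code",
            "functional_code_applied",
            "points",
            "new_class",
        ],
    )
    remaining = sum(rem.values())
    return ReclassificationSummary(
        n_catalog=len(catalog),
        n_previously_classified=n_prev,
        n_vus=len(catalog) - n_prev,
        newly_plp=newly_plp,
        newly_blb=newly_blb,
        remaining_vus=remaining,
        remaining_intermediate=rem["intermediate"],
        remaining_abnormal_insufficient=rem["abnormal"],
        remaining_splice=rem["splice"],
        remaining_neutral_insufficient=rem["neutral"],
        remaining_unscored=rem["unscored"],
        ps3_strong_added=n_ps3_strong,
        ps3_moderate_eligible=n_ps3_mod,
        bs3_added=n_bs3,
        audit=audit,
    )


def depletion_test(
    n_abnormal_obs: int, n_obs: int, n_abnormal_ref: int, n_ref: int
) -> float:
    """Exact two-sided binomial test of the observed abnormal fraction against
    the reference fraction ``n_abnormal_ref / n_ref``."""
    if n_ref <= 0:
        raise ValueError("n_ref must be positive")
    p0 = n_abnormal_ref / n_ref
    if not (0 < p0 < 1):
        raise ValueError(f"reference proportion must be in (0, 1), got {p0}")
    return binomial_two_sided(n_abnormal_obs, n_obs, p0)
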