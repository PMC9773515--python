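"""OddsPath calibration of functional evidence strength.

A functional assay earns its ACMG/AMP evidence weight from a curated set of
control variants with established clinical classifications reached *without*
any prior functional evidence (population frequency, family history, tumor
characteristics only), which avoids circular validation of one assay by
another.

With prior proportion pathogenic ``P1 = n_path / (n_path + n_benign)`` over
the whole control set and posterior proportion ``P2_d`` among controls whose
function score falls in direction ``d`` (abnormal or normal), the odds of
pathogenicity delivered by the assay result is

    OddsPath_d = [P2_d * (1 - P1)] / [(1 - P2_d) * P1]

When a posterior cell is perfectly concordant (a discordant count of zero),
the proportion is recomputed as if one additional inconsistent variant were
present (denominator + 1, discordant cell = 1), a standard guard against
infinite odds from finite control sets.  OddsPath maps to evidence strength
through the cut-points 2.08 / 4.33 / 18.7 / 350 (supporting / moderate /
strong / very strong) on the pathogenic side and their reciprocals on the
benign side.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .variants import ClinicalClass, FunctionTier, VariantRecord

__all__ = [
    "ControlVariant",
    "OddsPathResult",
    "EvidenceStrength",
    "StrengthLevel",
    "Direction",
    "CalibrationError",
    "curate_controls",
    "compute_oddspath",
    "map_strength",
    "validation_recall",
    "RecallResult",
]

logger = logging.getLogger(__name__)


class CalibrationError(ValueError):
    pass


class Direction(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"
    INDETERMINATE = "indeterminate"


class StrengthLevel(str, enum.Enum):
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"
    NONE = "none"


@dataclass(frozen=True)
class EvidenceStrength:
    direction: Direction
    level: StrengthLevel

    def __post_init__(self) -> None:
        if self.direction is Direction.INDETERMINATE and self.level is not StrengthLevel.NONE:
            raise ValueError("indeterminate direction requires level 'none'")


#: OddsPath lower bounds for pathogenic evidence strength; benign strengths
#: use the reciprocal bounds.
STRENGTH_CUTPOINTS: tuple[tuple[float, StrengthLevel], ...] = (
    (350.0, StrengthLevel.VERY_STRONG),
    (18.7, StrengthLevel.STRONG),
    (4.33, StrengthLevel.MODERATE),
    (2.08, StrengthLevel.SUPPORTING),
)


@dataclass(frozen=True)
class ControlVariant:
    """A previously classified variant usable for assay calibration."""

    variant: VariantRecord
    classification_uses_functional_evidence: bool

    def __post_init__(self) -> None:
        if self.variant.classification is ClinicalClass.VUS:
            raise CalibrationError(
                f"{self.variant.hgvs_c}: control variants must be P/LP or B/LB, not VUS"
            )


@dataclass(frozen=True)
class OddsPathResult:
    """All counts and derived odds for both score directions.

    ``p1`` is the prior over the full control set (intermediate-scoring
    controls included); posteriors exclude intermediates.  ``oddspath_*`` is
    None for a direction with no scored controls.  Correction flags record
    whether the +1-inconsistent-variant adjustment was applied.
    """

    n_path: int
    n_benign: int
    n_path_abnormal: int
    n_benign_abnormal: int
    n_path_normal: int
    n_benign_normal: int
    n_intermediate: int
    p1: float
    p2_abnormal: float | None
    p2_normal: float | None
    oddspath_abnormal: float | None
    oddspath_normal: float | None
    correction_applied_abnormal: bool
    correction_applied_normal: bool

    @property
    def strength_abnormal(self) -> EvidenceStrength:
        if self.oddspath_abnormal is None:
            return EvidenceStrength(Direction.INDETERMINATE, StrengthLevel.NONE)
        return map_strength(self.oddspath_abnormal)

    @property
    def strength_normal(self) -> EvidenceStrength:
        if self.oddspath_normal is None:
            return EvidenceStrength(Direction.INDETERMINATE, StrengthLevel.NONE)
        return map_strength(self.oddspath_normal)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n_path",
                "n_benign",
                "n_path_abnormal",
                "n_benign_abnormal",
                "n_path_normal",
                "n_benign_normal",
                "n_intermediate",
                "p1",
                "p2_abnormal",
                "p2_normal",
                "oddspath_abnormal",
                "oddspath_normal",
                "correction_applied_abnormal",
                "correction_applied_normal",
            )
        }
        d["strength_abnormal"] = {
            "direction": self.strength_abnormal.direction.value,
            "level": self.strength_abnormal.level.value,
        }
        d["strength_normal"] = {
            "direction": self.strength_normal.direction.value,
            "level": self.strength_normal.level.value,
        }
        return d


def curate_controls(classified: Iterable[ControlVariant]) -> list[ControlVariant]:
    """Keep only controls whose classification stands without functional evidence."""
    classified = list(classified)
    usable = [c for c in classified if not c.classification_uses_functional_evidence]
    if not usable:
        raise CalibrationError("no usable controls: every candidate's classification "
                               "relies on prior functional evidence")
    n_path = sum(1 for c in usable if c.variant.classification.is_path)
    n_benign = len(usable) - n_path
    logger.info(
        "curated %d controls (%d P/LP, %d B/LB) from %d candidates",
        len(usable), n_path, n_benign, len(classified),
    )
    return usable


def _corrected_proportion(concordant: int, discordant: int) -> tuple[float, bool]:
    # +1 inconsistent-variant guard: only when the discordant cell is empty.
    n = concordant + discordant
    if discordant == 0:
        return concordant / (n + 1), True
    return concordant / n, False


def compute_oddspath(
    controls: Sequence[ControlVariant],
    tiers: Sequence[FunctionTier] | None = None,
) -> OddsPathResult:
    """Compute OddsPath for the abnormal and normal score directions.

    ``tiers`` may supply per-variant function tiers explicitly (parallel to
    ``controls``); by default they are derived from each control's scores.
    Invariant to the ordering of the control set.
    """
    if tiers is None:
        tiers = [c.variant.tier for c in controls]
    if len(tiers) != len(controls):
        raise CalibrationError("tiers must parallel controls")

    n_path = sum(1 for c in controls if c.variant.classification.is_path)
    n_benign = sum(1 for c in controls if c.variant.classification.is_benign)
    if n_path < 1 or n_benign < 1:
        raise CalibrationError("need at least one pathogenic and one benign control")

    counts = {  # (is_path, direction) -> count
        ("path", "abnormal"): 0, ("benign", "abnormal"): 0,
        ("path", "normal"): 0, ("benign", "normal"): 0,
    }
    n_intermediate = 0
    for c, tier in zip(controls, tiers):
        group = "path" if c.variant.classification.is_path else "benign"
        if tier.is_deleterious:
            counts[(group, "abnormal")] += 1
        elif tier is FunctionTier.NEUTRAL:
            counts[(group, "normal")] += 1
        else:
            n_intermediate += 1
            if tier is FunctionTier.UNSCORED:
                logger.warning("control %s has no function score", c.variant.hgvs_c)

    p1 = n_path / (n_path + n_benign)

    def direction(concordant_path: int, benign_cell: int, abnormal_side: bool):
        n_scored = concordant_path + benign_cell
        if n_scored == 0:
            logger.warning(
                "no scored controls in the %s direction; OddsPath absent",
                "abnormal" if abnormal_side else "normal",
            )
            return None, None, False
        if abnormal_side:
            # posterior proportion pathogenic among abnormal-scoring controls
            p2, corrected = _corrected_proportion(concordant_path, benign_cell)
        else:
            # proportion pathogenic among normal-scoring controls: here the
            # *pathogenic* cell is the discordant one
            n = concordant_path + benign_cell
            if concordant_path == 0:
                p2, corrected = 1 / (n + 1), True
            else:
                p2, corrected = concordant_path / n, False
        odds = (p2 * (1 - p1)) / ((1 - p2) * p1)
        return p2, odds, corrected

    p2_a, odds_a, corr_a = direction(
        counts[("path", "abnormal")], counts[("benign", "abnormal")], abnormal_side=True
    )
    p2_n, odds_n, corr_n = direction(
        counts[("path", "normal")], counts[("benign", "normal")], abnormal_side=False
    )

    return OddsPathResult(
        n_path=n_path,
        n_benign=n_benign,
        n_path_abnormal=counts[("path", "abnormal")],
        n_benign_abnormal=counts[("benign", "abnormal")],
        n_path_normal=counts[("path", "normal")],
        n_benign_normal=counts[("benign", "normal")],
        n_intermediate=n_intermediate,
        p1=p1,
        p2_abnormal=p2_a,
        p2_normal=p2_n,
        oddspath_abnormal=odds_a,
        oddspath_normal=odds_n,
        correction_applied_abnormal=corr_a,
        correction_applied_normal=corr_n,
    )


def map_strength(oddspath: float) -> EvidenceStrength:
    """Map an OddsPath value to ACMG evidence strength.

    A monotone step function; the benign side mirrors the pathogenic side at
    the reciprocal bounds, so ``map_strength(x)`` on the pathogenic side
    equals ``map_strength(1/x)`` on the benign side.
    """
    if not oddspath > 0:
        raise ValueError(f"oddspath must be positive, got {oddspath}")
    for bound, level in STRENGTH_CUTPOINTS:
        if oddspath >= bound:
            return EvidenceStrength(Direction.PATHOGENIC, level)
        if oddspath <= 1.0 / bound:
            return EvidenceStrength(Direction.BENIGN, level)
    return EvidenceStrength(Direction.INDETERMINATE, StrengthLevel.NONE)


@dataclass(frozen=True)
class RecallResult:
    recall: float
    n_total: int
    n_deleterious_protein: int
    n_deleterious_splice: int

    def to_dict(self) -> dict:
        return {
            "recall": self.recall,
            "n_total": self.n_total,
            "n_deleterious_protein": self.n_deleterious_protein,
            "n_deleterious_splice": self.n_deleterious_splice,
        }


def validation_recall(known_plp: Sequence[VariantRecord]) -> RecallResult:
    """Fraction of known P/LP variants scored functionally deleterious.

    Splice-predicted deleterious variants count as true positives alongside
    protein-deleterious ones, with the mechanism split reported.
    """
    if not known_plp:
        raise CalibrationError("validation set is empty")
    bad = [v.hgvs_c for v in known_plp if not v.classification.is_path]
    if bad:
        raise CalibrationError(f"validation set must be all P/LP; offending: {bad[:5]}")
    n_prot = sum(1 for v in known_plp if v.tier is FunctionTier.DELETERIOUS_PROTEIN)
    n_spl = sum(1 for v in known_plp if v.tier is FunctionTier.DELETERIOUS_SPLICE)
    return RecallResult(
        recall=(n_prot + n_spl) / len(known_plp),
        n_total=len(known_plp),
        n_deleterious_protein=n_prot,
        n_deleterious_splice=n_spl,
    )
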