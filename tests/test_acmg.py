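import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from lynchmave.acmg import (
    CODE_REGISTRY,
    CodeParseError,
    EvidenceCode,
    classify,
    depletion_test,
    format_code,
    functional_evidence_code,
    parse_code,
    points_for,
    reclassify_catalog,
)
from lynchmave.calibration import Direction, StrengthLevel
from lynchmave.datasets import load_abnormal_vus_reference
from lynchmave.simulate import (
    SimulationConfig,
    gen_catalog,
    make_reclassifiable_vus,
)
from lynchmave.variants import ClinicalClass, FunctionTier


class TestParseFormat:
    @pytest.mark.parametrize(
        "text, base, strength, direction",
        [
            ("PS3", "PS3", StrengthLevel.STRONG, Direction.PATHOGENIC),
            ("PM2_P", "PM2", StrengthLevel.SUPPORTING, Direction.PATHOGENIC),
            ("PS4_M", "PS4", StrengthLevel.MODERATE, Direction.PATHOGENIC),
            ("BS2_P", "BS2", StrengthLevel.SUPPORTING, Direction.BENIGN),
            ("BS3", "BS3", StrengthLevel.STRONG, Direction.BENIGN),
            ("PVS1", "PVS1", StrengthLevel.VERY_STRONG, Direction.PATHOGENIC),
        ],
    )
    def test_examples(self, text, base, strength, direction):
        code = parse_code(text)
        assert (code.base, code.applied_strength, code.direction) == (base, strength, direction)

    @pytest.mark.parametrize("bad", ["XX9", "PS3_Q", "PM", "ps3", "PS3_", "PP9"])
    def test_unknown_tokens_rejected(self, bad):
        with pytest.raises(CodeParseError):
            parse_code(bad)

    def test_round_trip_over_full_registry(self):
        strengths = [StrengthLevel.SUPPORTING, StrengthLevel.MODERATE,
                     StrengthLevel.STRONG, StrengthLevel.VERY_STRONG]
        for base, strength in itertools.product(CODE_REGISTRY, strengths):
            code = EvidenceCode(base, strength)
            assert parse_code(format_code(code)) == code


class TestPoints:
    @pytest.mark.parametrize(
        "code, expected",
        [
            (EvidenceCode("PS3", StrengthLevel.STRONG), 4),
            (EvidenceCode("BS3", StrengthLevel.STRONG), -4),
            (EvidenceCode("PM1", StrengthLevel.SUPPORTING), 1),
            (EvidenceCode("PVS1", StrengthLevel.VERY_STRONG), 8),
            (EvidenceCode("BP4", StrengthLevel.SUPPORTING), -1),
        ],
    )
    def test_point_scale(self, code, expected):
        assert points_for(code) == expected


class TestClassify:
    def test_strong_plus_supporting_reaches_lp(self):
        codes = [parse_code(t) for t in ("PS3", "PM2_P", "PS4_M", "PP3", "PM1_P")]
        result = classify(codes)
        assert result.points == 9
        assert result.category is ClinicalClass.LP

    def test_no_evidence_is_vus(self):
        result = classify([])
        assert (result.points, result.category) == (0, ClinicalClass.VUS)

    def test_single_bs3_is_likely_benign(self):
        result = classify([parse_code("BS3")])
        assert (result.points, result.category) == (-4, ClinicalClass.LB)

    @pytest.mark.parametrize(
        "points, expected",
        [(10, "P"), (9, "LP"), (6, "LP"), (5, "VUS"), (0, "VUS"),
         (-1, "LB"), (-6, "LB"), (-7, "B")],
    )
    def test_category_thresholds(self, points, expected):
        from lynchmave.acmg import DEFAULT_SCALE

        assert DEFAULT_SCALE.category(points).value == expected

    def test_duplicate_codes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            classify([parse_code("PS3"), parse_code("PS3_M")])

    _code_pool = sorted(CODE_REGISTRY)

    @given(
        bases=st.lists(st.sampled_from(_code_pool), unique=True, max_size=8),
        extra=st.sampled_from([b for b in _code_pool if b.startswith("P")]),
    )
    @settings(max_examples=200, derandomize=True)
    def test_adding_pathogenic_evidence_never_lowers_category(self, bases, extra):
        codes = [EvidenceCode(b, CODE_REGISTRY[b]) for b in bases if b != extra]
        before = classify(codes).category
        after = classify(codes + [EvidenceCode(extra, CODE_REGISTRY[extra])]).category
        assert after.rank >= before.rank

    @given(
        bases=st.lists(st.sampled_from(_code_pool), unique=True, max_size=8),
        extra=st.sampled_from([b for b in _code_pool if b.startswith("B")]),
    )
    @settings(max_examples=200, derandomize=True)
    def test_adding_benign_evidence_never_raises_category(self, bases, extra):
        codes = [EvidenceCode(b, CODE_REGISTRY[b]) for b in bases if b != extra]
        before = classify(codes).category
        after = classify(codes + [EvidenceCode(extra, CODE_REGISTRY[extra])]).category
        assert after.rank <= before.rank

    @given(bases=st.lists(st.sampled_from(_code_pool), unique=True, max_size=8))
    @settings(max_examples=100, derandomize=True)
    def test_permutation_invariance(self, bases):
        codes = [EvidenceCode(b, CODE_REGISTRY[b]) for b in bases]
        forward, backward = classify(codes), classify(list(reversed(codes)))
        assert forward.points == backward.points
        assert forward.category is backward.category


class TestFunctionalEvidence:
    @pytest.mark.parametrize(
        "tier, lof, expected",
        [
            (FunctionTier.DELETERIOUS_PROTEIN, 4.511, ("PS3", StrengthLevel.STRONG)),
            (FunctionTier.DELETERIOUS_PROTEIN, 1.7, ("PS3", StrengthLevel.STRONG)),
            (FunctionTier.DELETERIOUS_PROTEIN, 1.669, ("PS3", StrengthLevel.MODERATE)),
            (FunctionTier.NEUTRAL, -0.3, ("BS3", StrengthLevel.STRONG)),
        ],
    )
    def test_code_assignment(self, strong_calibration, tier, lof, expected):
        code = functional_evidence_code(tier, lof, strong_calibration)
        assert (code.base, code.applied_strength) == expected

    @pytest.mark.parametrize(
        "tier", [FunctionTier.INTERMEDIATE, FunctionTier.DELETERIOUS_SPLICE,
                 FunctionTier.UNSCORED],
    )
    def test_no_assay_evidence_for_other_tiers(self, strong_calibration, tier):
        assert functional_evidence_code(tier, 0.2, strong_calibration) is None

    def test_requires_strong_calibration(self, rng):
        from conftest import build_control_set
        from lynchmave.calibration import compute_oddspath

        weak = compute_oddspath(build_control_set(rng, n_path=3, n_benign=3,
                                                  n_path_intermediate=0))
        with pytest.raises(ValueError, match="calibration"):
            functional_evidence_code(FunctionTier.NEUTRAL, -0.5, weak)


class TestReclassifyCatalog:
    def test_reference_abnormal_vus_split_at_1_7(self, strong_calibration):
        """14 of the 24 published abnormal VUS clear the strong-PS3 line."""
        catalog = load_abnormal_vus_reference()
        assert len(catalog) == 24
        summary = reclassify_catalog(catalog, strong_calibration)
        assert summary.ps3_strong_added == 14
        assert summary.ps3_moderate_eligible == 10

    def test_bs3_moves_reclassifiable_fraction(self, rng, strong_calibration):
        catalog = make_reclassifiable_vus(635, 497, rng)
        summary = reclassify_catalog(catalog, strong_calibration)
        assert summary.newly_blb == 497
        assert math.isclose(summary.newly_blb / summary.n_vus, 0.782, abs_tol=1e-3)

    def test_no_vus_yields_empty_summary(self, rng, strong_calibration):
        from lynchmave.simulate import make_tier_catalog

        catalog = make_tier_catalog({FunctionTier.NEUTRAL: 5}, rng,
                                    classification=ClinicalClass.B)
        summary = reclassify_catalog(catalog, strong_calibration)
        assert summary.n_vus == 0 and summary.audit.empty
        assert summary.conserves()

    def test_partitions_generated_catalog(self, strong_calibration):
        catalog = gen_catalog(SimulationConfig(seed=9, n_variants=600))
        summary = reclassify_catalog(catalog, strong_calibration)
        assert summary.conserves()
        assert (
            summary.remaining_intermediate + summary.remaining_abnormal_insufficient
            + summary.remaining_splice + summary.remaining_neutral_insufficient
            + summary.remaining_unscored
            == summary.remaining_vus
        )

    def test_moderate_codes_applied_only_on_request(self, rng, strong_calibration):
        from lynchmave.simulate import make_tier_catalog

        catalog = [
            v.with_codes(("PM2_P", "PP4", "PP3", "PM1"))
            for v in make_tier_catalog({FunctionTier.DELETERIOUS_PROTEIN: 6}, rng)
        ]
        conservative = reclassify_catalog(catalog, strong_calibration)
        permissive = reclassify_catalog(catalog, strong_calibration, apply_moderate=True)
        assert permissive.newly_plp >= conservative.newly_plp


class TestDepletionTest:
    def test_tiny_case_matches_enumeration(self):
        # 1 abnormal of 4 observed vs reference rate 1/2
        p0 = 0.5
        pmf = [binom.pmf(k, 4, p0) for k in range(5)]
        expected = sum(p for p in pmf if p <= pmf[1] * (1 + 1e-7))
        assert math.isclose(depletion_test(1, 4, 1, 2), expected, rel_tol=1e-12)

    def test_modal_count_gives_p_one(self):
        assert depletion_test(5, 10, 5, 10) == 1.0

    def test_invalid_reference_rejected(self):
        with pytest.raises(ValueError):
            depletion_test(1, 10, 0, 10)
        with pytest.raises(ValueError):
            depletion_test(1, 10, 10, 10)
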