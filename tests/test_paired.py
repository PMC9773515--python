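import math

import numpy as np
import pytest

from lynchmave.paired import (
    MsiStatus,
    PairedCase,
    SomaticVariant,
    TumorTestResult,
    flag_sporadic_candidates,
    msi_analysis,
    read_paired_cohort,
    second_hit_analysis,
    select_sole_msh2_missense_cases,
    somatic_coincidence_analysis,
    write_paired_cohort,
)
from lynchmave.simulate import SimulationConfig, gen_catalog, gen_paired_cohort
from lynchmave.stats import fisher_two_sided
from lynchmave.variants import ClinicalClass, Consequence, Gene, VariantRecord


def _germline_missense(i, lof):
    return VariantRecord(gene=Gene.MSH2, hgvs_c=f"c.{i}A>G",
                         classification=ClinicalClass.VUS,
                         lof_score=lof, spliceai_deltamax=0.01)


def _case(i, lof, second_hit=False, msi=MsiStatus.NOT_ASSAYED, meth=None,
          extra_germline=(), somatic=(), loh=(), epcam=False):
    svs = tuple(somatic)
    if second_hit:
        svs = svs + (SomaticVariant(gene=Gene.MSH2, hgvs_c=f"c.s{i}dup",
                                    classification=ClinicalClass.P,
                                    consequence=Consequence.TRUNCATING),)
    return PairedCase(
        individual_id=f"PT{i}",
        germline_variants=(_germline_missense(i, lof),) + tuple(extra_germline),
        tumor=TumorTestResult(somatic_variants=svs, loh_events=tuple(loh),
                              msi_status=msi, mlh1_promoter_hypermethylated=meth,
                              epcam_structural_variant=epcam),
    )


def published_margin_cohort():
    """25 sole-MSH2-missense cases: 13 deleterious (12 with second hits),
    12 neutral (2 with second hits)."""
    cases = []
    for i in range(13):
        cases.append(_case(i, lof=2.5, second_hit=i < 12,
                           msi=MsiStatus.MSI_HIGH if i < 11 else MsiStatus.MSS,
                           meth=(False if i < 11 else True)))
    for i in range(13, 25):
        j = i - 13
        unstable = j < 2
        cases.append(_case(i, lof=-0.5, second_hit=j < 2,
                           msi=MsiStatus.MSI_HIGH if unstable else MsiStatus.MSS,
                           meth=(False if j < 6 else True)))
    return cases


class TestSelection:
    def test_sole_msh2_missense_subset(self):
        cohort = published_margin_cohort()
        # distractors: extra MLH1 germline P/LP; non-missense MSH2; other gene
        cohort.append(_case(100, 2.0, extra_germline=(
            VariantRecord(gene=Gene.MLH1, hgvs_c="c.x1del",
                          consequence=Consequence.TRUNCATING,
                          classification=ClinicalClass.P),)))
        cohort.append(PairedCase("PT101", (VariantRecord(
            gene=Gene.MSH2, hgvs_c="c.y1del", consequence=Consequence.TRUNCATING,
            classification=ClinicalClass.P),), TumorTestResult()))
        selected = select_sole_msh2_missense_cases(cohort)
        assert len(selected) == 25
        n_del = sum(1 for c in selected if c.germline_variants[0].tier.is_deleterious)
        assert n_del == 13

    def test_idempotent(self):
        cohort = published_margin_cohort()
        once = select_sole_msh2_missense_cases(cohort)
        assert select_sole_msh2_missense_cases(once) == once

    def test_empty_cohort(self):
        assert select_sole_msh2_missense_cases([]) == []


class TestSecondHit:
    def test_published_margins(self):
        result = second_hit_analysis(select_sole_msh2_missense_cases(published_margin_cohort()))
        assert (result.table.a, result.table.b, result.table.c, result.table.d) == (12, 1, 2, 10)
        assert round(result.p_value, 5) == 0.00021

    def test_uninformative_when_hits_universal(self):
        cases = [_case(i, 2.5, second_hit=True) for i in range(5)]
        cases += [_case(10 + i, -0.5, second_hit=True) for i in range(5)]
        assert second_hit_analysis(cases).p_value == 1.0

    def test_toy_table_matches_hand_enumeration(self):
        cases = [
            _case(0, 2.5, second_hit=True),
            _case(1, 2.5, second_hit=False),
            _case(2, -0.5, second_hit=True),
            _case(3, -0.5, second_hit=False),
        ]
        result = second_hit_analysis(cases)
        assert (result.table.a, result.table.b, result.table.c, result.table.d) == (1, 1, 1, 1)
        assert math.isclose(result.p_value, 1.0)

    def test_loh_and_epcam_count_as_hits(self):
        with_loh = _case(0, 2.5, loh=("MSH2",))
        with_epcam = _case(1, 2.5, epcam=True)
        neutral = _case(2, -0.5)
        result = second_hit_analysis([with_loh, with_epcam, neutral])
        assert result.table.a == 2
        no_loh = second_hit_analysis([with_loh, with_epcam, neutral], include_loh=False)
        assert no_loh.table.a == 1

    def test_group_sizes_partition_selection(self):
        cases = select_sole_msh2_missense_cases(published_margin_cohort())
        result = second_hit_analysis(cases)
        assert result.table.total + result.n_excluded == len(cases)


class TestMsi:
    def test_published_margins_after_methylation_exclusion(self):
        result = msi_analysis(select_sole_msh2_missense_cases(published_margin_cohort()))
        assert (result.table.a, result.table.b, result.table.c, result.table.d) == (11, 0, 2, 4)
        assert round(result.p_value, 4) == 0.0063

    def test_methylated_case_is_excluded(self):
        cases = [
            _case(0, 2.5, msi=MsiStatus.MSI_HIGH, meth=False),
            _case(1, 2.5, msi=MsiStatus.MSI_HIGH, meth=True),
            _case(2, -0.5, msi=MsiStatus.MSS, meth=False),
        ]
        result = msi_analysis(cases)
        assert result.table.total == 2 and result.n_excluded == 1

    def test_msi_low_counts_as_unstable(self):
        cases = [
            _case(0, 2.5, msi=MsiStatus.MSI_LOW, meth=False),
            _case(1, -0.5, msi=MsiStatus.MSS, meth=False),
        ]
        assert msi_analysis(cases).table.a == 1

    def test_all_excluded_is_an_error(self):
        cases = [_case(0, 2.5, msi=MsiStatus.MSI_HIGH, meth=True)]
        with pytest.raises(ValueError, match="no evaluable"):
            msi_analysis(cases)


def _somatic_missense(i, lof):
    return SomaticVariant(gene=Gene.MSH2, hgvs_c=f"c.m{i}T>C",
                          consequence=Consequence.MISSENSE,
                          lof_score=lof, spliceai_deltamax=0.01)


def _somatic_other_ls(i):
    return SomaticVariant(gene=Gene.MLH1, hgvs_c=f"c.o{i}del",
                          classification=ClinicalClass.P,
                          consequence=Consequence.TRUNCATING)


class TestSomaticCoincidence:
    def build_cohort(self):
        cases = []
        # 38 exclusively neutral somatic MSH2 missense; all with other-LS hits;
        # 28 assayed for MLH1 methylation, 9 methylated
        for i in range(38):
            somatic = [_somatic_missense(i, -0.5), _somatic_other_ls(i)]
            meth = (i < 9) if i < 28 else None
            cases.append(_case(i, -0.5, somatic=somatic, meth=meth))
        # 46 with >= 1 disruptive somatic missense; 30 with other-LS hits;
        # all 38 assayed ... here: 38 assayed, 1 methylated
        for i in range(46):
            somatic = [_somatic_missense(100 + i, 3.0)]
            if i < 30:
                somatic.append(_somatic_other_ls(100 + i))
            meth = (i < 1) if i < 38 else None
            cases.append(_case(100 + i, -0.5, somatic=somatic, meth=meth))
        return cases

    def test_published_margins(self):
        result = somatic_coincidence_analysis(self.build_cohort())
        a = result["other_ls_somatic"]
        assert (a.table.a, a.table.b, a.table.c, a.table.d) == (38, 0, 30, 16)
        assert math.isclose(a.p_value, 2.70e-5, rel_tol=5e-3)
        b = result["mlh1_methylation"]
        assert (b.table.a, b.table.b, b.table.c, b.table.d) == (9, 19, 1, 37)
        assert round(b.p_value, 4) == 0.0013

    def test_neutral_group_requires_no_other_plp_msh2(self):
        sv_plp = SomaticVariant(gene=Gene.MSH2, hgvs_c="c.z1del",
                                classification=ClinicalClass.P,
                                consequence=Consequence.TRUNCATING)
        disqualified = _case(0, -0.5, somatic=[_somatic_missense(0, -0.5), sv_plp])
        ok = _case(1, -0.5, somatic=[_somatic_missense(1, -0.5)])
        result = somatic_coincidence_analysis([disqualified, ok])
        assert result["other_ls_somatic"].table.a + result["other_ls_somatic"].table.b == 1

    def test_no_somatic_missense_returns_none(self):
        assert somatic_coincidence_analysis([_case(0, 2.5)]) is None


class TestSporadicCandidates:
    def test_biallelic_somatic_without_germline_hit(self):
        double = _case(0, -0.5, somatic=[_somatic_missense(0, 3.0),
                                         _somatic_missense(1, -0.3)])
        germline_hit = _case(1, 2.5, somatic=[_somatic_missense(2, 3.0),
                                              _somatic_missense(3, 2.0)])
        single = _case(2, -0.5, somatic=[_somatic_missense(4, 3.0)])
        assert flag_sporadic_candidates([double, germline_hit, single]) == ["PT0"]


class TestGeneratorRecovery:
    def test_second_hit_rates_recovered_at_scale(self):
        cfg = SimulationConfig(seed=31, n_variants=800, n_paired=5000,
                               frac_sole_msh2_missense=1.0)
        catalog = gen_catalog(cfg)
        cases = gen_paired_cohort(cfg, catalog)
        result = second_hit_analysis(select_sole_msh2_missense_cases(cases))
        t = result.table
        for observed_hits, n, rate in [
            (t.a, t.a + t.b, cfg.second_hit_rate_deleterious),
            (t.c, t.c + t.d, cfg.second_hit_rate_neutral),
        ]:
            se = np.sqrt(rate * (1 - rate) / n)
            assert abs(observed_hits / n - rate) <= 2 * se + 1e-9

    def test_msi_certain_given_two_hits(self):
        cfg = SimulationConfig(seed=5, n_variants=800, n_paired=400,
                               frac_sole_msh2_missense=1.0,
                               msi_given_two_hits=1.0, msi_assay_rate=1.0)
        cases = gen_paired_cohort(cfg, gen_catalog(cfg))
        for case in cases:
            germ_del = case.germline_variants[0].tier.is_deleterious
            hit = any(sv.gene is Gene.MSH2 and sv.is_plp
                      for sv in case.tumor.somatic_variants) \
                or "MSH2" in case.tumor.loh_events or case.tumor.epcam_structural_variant
            if germ_del and hit:
                assert case.tumor.msi_status.unstable


class TestPairedIO:
    def test_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=13, n_variants=400, n_paired=60,
                               frac_sole_msh2_missense=0.5)
        cases = gen_paired_cohort(cfg, gen_catalog(cfg))
        gp, sp = tmp_path / "germ.tsv", tmp_path / "som.tsv"
        write_paired_cohort(cases, gp, sp)
        back = read_paired_cohort(gp, sp)
        assert len(back) == len(cases)
        assert back == cases
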