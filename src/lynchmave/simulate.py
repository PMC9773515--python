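"""Synthetic variant catalogs, germline cohorts, and paired tumor-normal cohorts.

The generator emulates the statistical structure the downstream analyses
assume, so the whole pipeline is exercisable without any external data:

* LoF scores follow a two-component Normal mixture (a neutral component
  centred at 0 and a deleterious component centred in the abnormal range),
  with a small fraction of splice-disruptive variants given high deltaMax.
* Prior classifications are score-concordant (deleterious variants may be
  P/LP, neutral ones B/LB, the rest VUS), with a configurable injected
  discordant fraction.
* Cancer outcomes in the germline cohort are drawn from the same logistic
  model the association stage fits — sex-specific baseline prevalences plus
  per-feature log-odds-ratios — so the configured odds ratios are the truth
  that parameter-recovery tests target.
* Paired cases follow the two-hit model: somatic second hits arrive at a
  higher rate on a deleterious germline background, MSI tracks biallelic
  loss, and MLH1 promoter hypermethylation appears preferentially where no
  MSH2 two-hit explanation exists.

Every sub-generator owns an RNG stream split deterministically from the
master seed, so a fixed seed yields byte-identical outputs and adding one
generator does not perturb the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .calibration import ControlVariant
from .paired import (
    MsiStatus,
    PairedCase,
    SomaticVariant,
    TumorTestResult,
    write_paired_cohort,
)
from .stats import FEATURE_COLUMNS
from .variants import (
    ClinicalClass,
    Consequence,
    FunctionTier,
    Gene,
    VariantRecord,
    assign_tier,
    variants_to_frame,
)

__all__ = [
    "ControlSetSpec",
    "SimulationConfig",
    "SyntheticCohort",
    "gen_catalog",
    "gen_control_set",
    "gen_germline_cohort",
    "gen_paired_cohort",
    "simulate",
    "make_tier_catalog",
    "make_reclassifiable_vus",
    "make_validation_set",
    "write_control_table",
    "read_control_table",
]


class ControlSetSpec(BaseModel):
    n_pathogenic: int = 22
    n_benign: int = 26
    n_pathogenic_intermediate: int = 1


class SimulationConfig(BaseModel):
    """All generator parameters; defaults are the emulated cohort conditions."""

    seed: int = 0

    # --- variant catalog -------------------------------------------------
    n_variants: int = 2000
    #: fraction of variants drawn from the deleterious LoF component
    frac_deleterious: float = 0.068
    lof_neutral_mean: float = 0.0
    lof_neutral_sd: float = 0.2
    lof_deleterious_mean: float = 2.5
    lof_deleterious_sd: float = 1.0
    #: fraction of variants predicted splice-disruptive (deltaMax >= 0.5)
    frac_splice_disruptive: float = 0.012
    frac_splice_intermediate: float = 0.02
    #: P(classified P/LP | deleterious component), P(B/LB | neutral component)
    p_plp_given_deleterious: float = 0.35
    p_blb_given_neutral: float = 0.05
    #: fraction of classified variants given a score-discordant classification
    frac_discordant: float = 0.0
    #: non-functional evidence code sets carried by VUS, with probabilities;
    #: the mix controls how many functionally normal VUS a BS3 code can move
    #: to B/LB
    vus_code_sets: list = Field(
        default_factory=lambda: [
            [[], 0.25],
            [["PM2_P"], 0.30],
            [["PM2_P", "PP4"], 0.15],
            [["PM2_P", "PP3"], 0.082],
            [["PM2", "PP3", "PP4"], 0.118],
            [["PM2", "PM1", "PP3"], 0.10],
        ]
    )

    control_set_spec: ControlSetSpec = Field(default_factory=ControlSetSpec)

    # --- germline cohort -------------------------------------------------
    n_carriers: int = 20000
    sex_ratio_female: float = 0.84
    baseline_crc_female: float = 0.089
    baseline_crc_male: float = 0.383
    baseline_uec_female: float = 0.095
    baseline_other_female: float = 0.496
    baseline_other_male: float = 0.407
    #: carrier-category mixture (one category per carrier)
    carrier_category_probs: dict = Field(
        default_factory=lambda: {
            "msh2_missense_deleterious": 0.010,
            "msh2_missense_neutral": 0.120,
            "msh2_missense_intermediate": 0.005,
            "msh2_other_plp": 0.100,
            "mlh1_plp": 0.150,
            "msh6_plp": 0.250,
            "pms2_plp": 0.245,
            "none": 0.120,
        }
    )
    or_crc: dict = Field(
        default_factory=lambda: {
            "msh2_missense_deleterious": 2.53,
            "msh2_missense_neutral": 1.0,
            "msh2_other_plp": 8.10,
            "mlh1_plp": 14.4,
            "msh6_plp": 2.0,
            "pms2_plp": 1.5,
        }
    )
    or_uec: dict = Field(
        default_factory=lambda: {
            "msh2_missense_deleterious": 5.56,
            "msh2_missense_neutral": 1.0,
            "msh2_other_plp": 11.9,
            "mlh1_plp": 4.0,
            "msh6_plp": 13.2,
            "pms2_plp": 2.0,
        }
    )
    non_ls_plp_rate: float = 0.01
    dual_carrier_rate: float = 0.01

    # --- paired tumor-normal cohort --------------------------------------
    n_paired: int = 1604
    frac_sole_msh2_missense: float = 0.0156
    frac_paired_germline_deleterious: float = 0.52
    second_hit_rate_deleterious: float = 0.92
    second_hit_rate_neutral: float = 0.17
    msi_given_two_hits: float = 0.95
    msi_given_no_hit: float = 0.20
    msi_assay_rate: float = 0.95
    mlh1_methylation_rate: float = 0.15
    mlh1_methylation_assay_rate: float = 0.80
    epcam_sv_rate: float = 0.02
    somatic_msh2_missense_rate: float = 0.052
    frac_somatic_missense_disruptive: float = 0.55
    other_ls_somatic_rate_neutral: float = 0.97
    other_ls_somatic_rate_disruptive: float = 0.65
    meth_rate_somatic_neutral: float = 0.32
    meth_rate_somatic_disruptive: float = 0.026

    @field_validator(
        "frac_deleterious", "frac_splice_disruptive", "sex_ratio_female",
        "second_hit_rate_deleterious", "second_hit_rate_neutral",
        "msi_given_two_hits", "msi_given_no_hit", "mlh1_methylation_rate",
        "frac_sole_msh2_missense", "frac_discordant",
    )
    @classmethod
    def _check_proportion(cls, v: float) -> float:
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"proportion must be in [0, 1], got {v}")
        return v

    @field_validator("vus_code_sets")
    @classmethod
    def _normalize_code_sets(cls, v: list) -> list:
        out = [[list(codes), float(p)] for codes, p in v]
        if abs(sum(p for _, p in out) - 1.0) > 1e-9:
            raise ValueError("vus_code_sets probabilities must sum to 1")
        return out

    @field_validator("lof_neutral_sd", "lof_deleterious_sd")
    @classmethod
    def _check_sd(cls, v: float) -> float:
        if v <= 0:
            raise ValueError(f"standard deviation must be positive, got {v}")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)


def _streams(seed: int, n: int = 6) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


_AA3 = ["Ala", "Arg", "Asn", "Asp", "Gly", "Leu", "Lys", "Pro", "Ser", "Val"]


def _hgvs(i: int) -> tuple[str, str]:
    # unique placeholder identifiers; no attempt at real transcript coordinates
    return f"c.{i + 1}A>G", f"p.{_AA3[i % 10]}{i // 10 + 1}{_AA3[(i + 3) % 10]}"


@dataclass
class SyntheticCohort:
    catalog: list[VariantRecord]
    controls: list[ControlVariant]
    germline: pd.DataFrame
    paired: list[PairedCase]
    truth: dict


def gen_catalog(config: SimulationConfig, rng: np.random.Generator | None = None) -> list[VariantRecord]:
    """Draw a variant catalog from the configured score mixture."""
    if rng is None:
        rng = _streams(config.seed)[0]
    n = config.n_variants
    deleterious = rng.random(n) < config.frac_deleterious
    # the neutral component is truncated just below the deleterious cutoff so
    # only the deleterious component can produce abnormal protein scores
    lof = np.where(
        deleterious,
        rng.normal(config.lof_deleterious_mean, config.lof_deleterious_sd, n),
        np.minimum(rng.normal(config.lof_neutral_mean, config.lof_neutral_sd, n), 0.39),
    )
    u = rng.random(n)
    splice = u < config.frac_splice_disruptive
    splice_int = (~splice) & (u < config.frac_splice_disruptive + config.frac_splice_intermediate)
    deltamax = rng.uniform(0.0, 0.199, n)
    deltamax[splice] = rng.uniform(0.5, 1.0, int(splice.sum()))
    deltamax[splice_int] = rng.uniform(0.2, 0.499, int(splice_int.sum()))

    code_sets = [tuple(cs) for cs, _ in config.vus_code_sets]
    code_probs = np.array([p for _, p in config.vus_code_sets])
    code_probs = code_probs / code_probs.sum()
    code_idx = rng.choice(len(code_sets), size=n, p=code_probs)

    u_cls = rng.random(n)
    u_disc = rng.random(n)
    records = []
    for i in range(n):
        tier = assign_tier(float(lof[i]), float(deltamax[i]))
        if tier.is_deleterious and u_cls[i] < config.p_plp_given_deleterious:
            cls = ClinicalClass.P if u_cls[i] < config.p_plp_given_deleterious / 2 else ClinicalClass.LP
            if u_disc[i] < config.frac_discordant:
                cls = ClinicalClass.LB
        elif tier is FunctionTier.NEUTRAL and u_cls[i] < config.p_blb_given_neutral:
            cls = ClinicalClass.B if u_cls[i] < config.p_blb_given_neutral / 2 else ClinicalClass.LB
            if u_disc[i] < config.frac_discordant:
                cls = ClinicalClass.LP
        else:
            cls = ClinicalClass.VUS
        hgvs_c, hgvs_p = _hgvs(i)
        records.append(
            VariantRecord(
                gene=Gene.MSH2,
                hgvs_c=hgvs_c,
                hgvs_p=hgvs_p,
                consequence=Consequence.MISSENSE,
                classification=cls,
                lof_score=round(float(lof[i]), 4),
                spliceai_deltamax=round(float(deltamax[i]), 4),
                evidence_codes=code_sets[code_idx[i]] if cls is ClinicalClass.VUS else (),
            )
        )
    return records


def gen_control_set(
    config: SimulationConfig,
    catalog: Sequence[VariantRecord],
    rng: np.random.Generator | None = None,
) -> list[ControlVariant]:
    """Draw calibration controls from the catalog per ``control_set_spec``.

    ``n_pathogenic`` P/LP variants with abnormal protein scores are drawn, of
    which ``n_pathogenic_intermediate`` are forced into the intermediate score
    band, plus ``n_benign`` B/LB variants with neutral scores; all are flagged
    as classified without functional evidence.
    """
    if rng is None:
        rng = _streams(config.seed)[1]
    spec = config.control_set_spec
    plp = [
        v for v in catalog
        if v.classification.is_path
        and v.tier is FunctionTier.DELETERIOUS_PROTEIN
        and (v.spliceai_deltamax or 0.0) < 0.2
    ]
    blb = [
        v for v in catalog
        if v.classification.is_benign and v.tier is FunctionTier.NEUTRAL
    ]
    if len(plp) < spec.n_pathogenic or len(blb) < spec.n_benign:
        raise ValueError(
            f"catalog has insufficient concordant variants for the control set "
            f"({len(plp)} P/LP abnormal, {len(blb)} B/LB neutral)"
        )
    path_pick = [plp[i] for i in rng.choice(len(plp), spec.n_pathogenic, replace=False)]
    benign_pick = [blb[i] for i in rng.choice(len(blb), spec.n_benign, replace=False)]
    controls = []
    for j, v in enumerate(path_pick):
        if j < spec.n_pathogenic_intermediate:
            v = VariantRecord(
                gene=v.gene, hgvs_c=v.hgvs_c, hgvs_p=v.hgvs_p,
                consequence=v.consequence, classification=v.classification,
                lof_score=round(float(rng.uniform(0.01, 0.39)), 4),
                spliceai_deltamax=v.spliceai_deltamax,
            )
        controls.append(ControlVariant(v, classification_uses_functional_evidence=False))
    controls.extend(
        ControlVariant(v, classification_uses_functional_evidence=False) for v in benign_pick
    )
    return controls


_CATEGORY_TO_FEATURE = {
    "msh2_missense_deleterious": "msh2_missense_deleterious",
    "msh2_missense_neutral": "msh2_missense_neutral",
    "msh2_other_plp": "msh2_other_plp",
    "mlh1_plp": "mlh1_plp",
    "msh6_plp": "msh6_plp",
    "pms2_plp": "pms2_plp",
}


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


def gen_germline_cohort(
    config: SimulationConfig,
    catalog: Sequence[VariantRecord] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw a carrier table whose cancer outcomes follow the logistic model.

    Outcomes are generated from sex-specific baseline log-odds plus the sum
    of the carried features' log-odds-ratios; the log-odds shift between the
    sexes is additive, so a logistic refit with a sex indicator is correctly
    specified.  Risk for dual carriers (MSH2 missense VUS plus another LS
    gene's P/LP) is driven by the reassigned gene only, matching how the
    association stage categorises them.
    """
    if rng is None:
        rng = _streams(config.seed)[2]
    n = config.n_carriers
    cats = list(config.carrier_category_probs)
    probs = np.array([config.carrier_category_probs[c] for c in cats], dtype=float)
    probs /= probs.sum()
    category = rng.choice(cats, size=n, p=probs)
    female = rng.random(n) < config.sex_ratio_female

    features = pd.DataFrame(0, index=range(n), columns=FEATURE_COLUMNS, dtype=int)
    for cat, col in _CATEGORY_TO_FEATURE.items():
        features.loc[category == cat, col] = 1

    # dual carriers: an MSH2 missense VUS plus a P/LP in another LS gene
    missense = features["msh2_missense_deleterious"] + features["msh2_missense_neutral"] > 0
    dual = missense.to_numpy() & (rng.random(n) < config.dual_carrier_rate)
    dual_gene = rng.choice(["mlh1_plp", "msh6_plp", "pms2_plp"], size=n)
    for g in ("mlh1_plp", "msh6_plp", "pms2_plp"):
        features.loc[dual & (dual_gene == g), g] = 1
    non_ls = rng.random(n) < config.non_ls_plp_rate

    # effective (post-reassignment) features drive the generated risk
    eff = features.copy()
    eff.loc[dual, ["msh2_missense_deleterious", "msh2_missense_neutral"]] = 0

    log_or_crc = np.array([np.log(config.or_crc[f]) for f in FEATURE_COLUMNS])
    log_or_uec = np.array([np.log(config.or_uec[f]) for f in FEATURE_COLUMNS])
    eta_crc = (
        np.where(female, _logit(config.baseline_crc_female), _logit(config.baseline_crc_male))
        + eff.to_numpy() @ log_or_crc
    )
    crc = rng.random(n) < 1 / (1 + np.exp(-eta_crc))
    eta_uec = _logit(config.baseline_uec_female) + eff.to_numpy() @ log_or_uec
    uec = (rng.random(n) < 1 / (1 + np.exp(-eta_uec))) & female
    other = rng.random(n) < np.where(
        female, config.baseline_other_female, config.baseline_other_male
    )

    msh2_variant = np.full(n, "", dtype=object)
    if catalog is not None:
        by_kind = {
            "msh2_missense_deleterious": [
                v.hgvs_c for v in catalog if v.tier is FunctionTier.DELETERIOUS_PROTEIN
            ],
            "msh2_missense_neutral": [
                v.hgvs_c for v in catalog if v.tier is FunctionTier.NEUTRAL
            ],
            "msh2_missense_intermediate": [
                v.hgvs_c for v in catalog if v.tier is FunctionTier.INTERMEDIATE
            ],
        }
        for kind, pool in by_kind.items():
            idx = np.flatnonzero(category == kind)
            if len(idx) and pool:
                msh2_variant[idx] = rng.choice(pool, size=len(idx), replace=True)

    df = pd.DataFrame(
        {
            "individual_id": [f"IND{i:06d}" for i in range(n)],
            "sex": np.where(female, "F", "M"),
            "crc_dx": crc.astype(int),
            "uec_dx": uec.astype(int),
            "other_cancer_dx": other.astype(int),
            **{c: features[c] for c in FEATURE_COLUMNS},
            "non_ls_plp": non_ls.astype(int),
            "msh2_variant": msh2_variant,
            "category": category,
        }
    )
    return df


def _somatic_plp_truncating(i: int) -> SomaticVariant:
    return SomaticVariant(
        gene=Gene.MSH2,
        hgvs_c=f"c.s{i}dup",
        classification=ClinicalClass.P,
        consequence=Consequence.TRUNCATING,
    )


def gen_paired_cohort(
    config: SimulationConfig,
    catalog: Sequence[VariantRecord],
    rng: np.random.Generator | None = None,
) -> list[PairedCase]:
    """Draw paired tumor-normal cases under the two-hit model."""
    if rng is None:
        rng = _streams(config.seed)[3]
    del_pool = [
        v for v in catalog
        if v.tier is FunctionTier.DELETERIOUS_PROTEIN and v.consequence is Consequence.MISSENSE
    ]
    neu_pool = [
        v for v in catalog
        if v.tier is FunctionTier.NEUTRAL and v.consequence is Consequence.MISSENSE
    ]
    if not del_pool or not neu_pool:
        raise ValueError("catalog lacks deleterious or neutral missense variants")

    cases = []
    other_genes = [Gene.MLH1, Gene.MSH6, Gene.PMS2]
    for i in range(config.n_paired):
        sole = rng.random() < config.frac_sole_msh2_missense
        if sole:
            germ_del = rng.random() < config.frac_paired_germline_deleterious
            pool = del_pool if germ_del else neu_pool
            germline = (pool[int(rng.integers(len(pool)))],)
        else:
            germ_del = False
            g = other_genes[i % 3]
            germline = (
                VariantRecord(
                    gene=g,
                    hgvs_c=f"c.g{i}del",
                    consequence=Consequence.TRUNCATING,
                    classification=ClinicalClass.P,
                ),
            )

        somatic: list[SomaticVariant] = []
        loh: list[str] = []
        epcam = False
        hit_rate = (
            config.second_hit_rate_deleterious if germ_del else config.second_hit_rate_neutral
        )
        second_hit = sole and rng.random() < hit_rate
        if second_hit:
            kind = rng.random()
            if kind < 0.7:
                somatic.append(_somatic_plp_truncating(i))
            elif kind < 0.7 + 0.2:
                loh.append("MSH2")
            else:
                epcam = True

        # somatic MSH2 missense variants (coincidence analyses)
        som_missense_disruptive: bool | None = None
        if rng.random() < config.somatic_msh2_missense_rate:
            som_missense_disruptive = rng.random() < config.frac_somatic_missense_disruptive
            n_mis = 1 + int(rng.random() < 0.3)
            for k in range(n_mis):
                disruptive_draw = som_missense_disruptive and k == 0
                somatic.append(
                    SomaticVariant(
                        gene=Gene.MSH2,
                        hgvs_c=f"c.m{i}_{k}T>C",
                        classification=None,
                        consequence=Consequence.MISSENSE,
                        lof_score=round(
                            float(
                                rng.normal(config.lof_deleterious_mean, config.lof_deleterious_sd)
                                if disruptive_draw
                                else np.clip(
                                    rng.normal(config.lof_neutral_mean, config.lof_neutral_sd),
                                    None, -0.01,
                                )
                            ),
                            4,
                        ),
                        spliceai_deltamax=round(float(rng.uniform(0, 0.199)), 4),
                    )
                )

        if som_missense_disruptive is None:
            other_ls_rate = 0.30
        elif som_missense_disruptive:
            other_ls_rate = config.other_ls_somatic_rate_disruptive
        else:
            other_ls_rate = config.other_ls_somatic_rate_neutral
        if rng.random() < other_ls_rate:
            g = other_genes[int(rng.integers(3))]
            somatic.append(
                SomaticVariant(
                    gene=g,
                    hgvs_c=f"c.o{i}del",
                    classification=ClinicalClass.P,
                    consequence=Consequence.TRUNCATING,
                )
            )

        two_hit = germ_del and second_hit
        msi_rate = config.msi_given_two_hits if two_hit else config.msi_given_no_hit
        if rng.random() < config.msi_assay_rate:
            if rng.random() < msi_rate:
                msi = MsiStatus.MSI_HIGH if rng.random() < 0.85 else MsiStatus.MSI_LOW
            else:
                msi = MsiStatus.MSS
        else:
            msi = MsiStatus.NOT_ASSAYED

        if som_missense_disruptive is None:
            meth_rate = config.mlh1_methylation_rate if not two_hit else 0.01
        elif som_missense_disruptive:
            meth_rate = config.meth_rate_somatic_disruptive
        else:
            meth_rate = config.meth_rate_somatic_neutral
        meth: bool | None
        if rng.random() < config.mlh1_methylation_assay_rate:
            meth = bool(rng.random() < meth_rate)
        else:
            meth = None
        if not epcam:
            epcam = bool(rng.random() < config.epcam_sv_rate * 0.1)

        cases.append(
            PairedCase(
                individual_id=f"PT{i:05d}",
                germline_variants=germline,
                tumor=TumorTestResult(
                    somatic_variants=tuple(somatic),
                    loh_events=tuple(loh),
                    msi_status=msi,
                    mlh1_promoter_hypermethylated=meth,
                    epcam_structural_variant=epcam,
                ),
            )
        )
    return cases


def simulate(config: SimulationConfig, out_dir: str | Path | None = None) -> SyntheticCohort:
    """Run all sub-generators; optionally write the TSVs plus a truth JSON."""
    s_cat, s_ctl, s_germ, s_pair = _streams(config.seed)[:4]
    catalog = gen_catalog(config, s_cat)
    controls = gen_control_set(config, catalog, s_ctl)
    germline = gen_germline_cohort(config, catalog, s_germ)
    paired = gen_paired_cohort(config, catalog, s_pair)
    truth = {
        "config": config.model_dump(),
        "n_catalog": len(catalog),
        "tier_counts": {
            t.value: sum(1 for v in catalog if v.tier is t) for t in FunctionTier
        },
    }
    cohort = SyntheticCohort(catalog, controls, germline, paired, truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        variants_to_frame(catalog).to_csv(out / "catalog.tsv", sep="\t", index=False)
        write_control_table(controls, out / "controls.tsv")
        germline.to_csv(out / "germline.tsv", sep="\t", index=False)
        write_paired_cohort(paired, out / "paired_germline.tsv", out / "paired_somatic.tsv")
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
    return cohort


def write_control_table(controls: Sequence[ControlVariant], path: str | Path) -> None:
    df = variants_to_frame([c.variant for c in controls])
    df["uses_functional_evidence"] = [
        str(c.classification_uses_functional_evidence) for c in controls
    ]
    df.to_csv(path, sep="\t", index=False)


def read_control_table(path: str | Path) -> list[ControlVariant]:
    from .variants import read_variant_table

    records = read_variant_table(path)
    flags = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)[
        "uses_functional_evidence"
    ]
    return [
        ControlVariant(rec, classification_uses_functional_evidence=flag == "True")
        for rec, flag in zip(records, flags)
    ]


# ---------------------------------------------------------------------------
# Deterministic margin-based constructors for worked examples and tests.


def make_tier_catalog(
    counts: dict[FunctionTier, int],
    rng: np.random.Generator,
    classification: ClinicalClass = ClinicalClass.VUS,
    start: int = 0,
) -> list[VariantRecord]:
    """Build a catalog with exact per-tier counts, scores drawn within bands."""
    bands = {
        FunctionTier.DELETERIOUS_PROTEIN: (lambda: (float(rng.uniform(0.4, 5.0)), float(rng.uniform(0, 0.199)))),
        FunctionTier.DELETERIOUS_SPLICE: (lambda: (float(rng.normal(0, 0.2)), float(rng.uniform(0.5, 1.0)))),
        FunctionTier.INTERMEDIATE: (lambda: (float(rng.uniform(0.0, 0.39)), float(rng.uniform(0, 0.199)))),
        FunctionTier.NEUTRAL: (lambda: (float(rng.uniform(-1.0, -0.01)), float(rng.uniform(0, 0.199)))),
    }
    records = []
    i = start
    for tier, n in counts.items():
        for _ in range(n):
            lof, dmax = bands[tier]()
            hgvs_c, hgvs_p = _hgvs(i)
            records.append(
                VariantRecord(
                    gene=Gene.MSH2,
                    hgvs_c=hgvs_c,
                    hgvs_p=hgvs_p,
                    classification=classification,
                    lof_score=round(lof, 4),
                    spliceai_deltamax=round(dmax, 4),
                )
            )
            i += 1
    return records


def make_reclassifiable_vus(
    n_total: int,
    n_reclassifiable: int,
    rng: np.random.Generator,
) -> list[VariantRecord]:
    """Functionally neutral VUS of which exactly ``n_reclassifiable`` carry
    few enough prior evidence points (<= 3) for a strong BS3 code (-4) to
    move them to LB/B."""
    light = [(), ("PM2_P",), ("PM2_P", "PP4")]
    heavy = [("PM2", "PP3", "PP4"), ("PM2", "PM1", "PP3")]  # >= 4 points
    base = make_tier_catalog({FunctionTier.NEUTRAL: n_total}, rng)
    out = []
    for j, v in enumerate(base):
        codes = (
            light[j % len(light)] if j < n_reclassifiable else heavy[j % len(heavy)]
        )
        out.append(v.with_codes(codes))
    return out


def make_validation_set(
    n_protein: int,
    n_splice: int,
    n_intermediate: int,
    rng: np.random.Generator,
) -> list[VariantRecord]:
    """Known P/LP variants with the given mechanism split, for recall checks."""
    return make_tier_catalog(
        {
            FunctionTier.DELETERIOUS_PROTEIN: n_protein,
            FunctionTier.DELETERIOUS_SPLICE: n_splice,
            FunctionTier.INTERMEDIATE: n_intermediate,
        },
        rng,
        classification=ClinicalClass.LP,
    )
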