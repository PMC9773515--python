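# Methods

## Functional tiering

Each *MSH2* missense variant carries up to two function scores: a unitless
loss-of-function (LoF) enrichment score from a cDNA-based deep mutational
scan of MSH2 protein activity (higher = more abnormal), and a SpliceAI
deltaMax score in [0, 1] estimating splice-disruption probability.  Tiers
are assigned with splice precedence: deltaMax ≥ 0.5 → deleterious (splice);
else LoF ≥ 0.4 → deleterious (protein); else intermediate if LoF ∈ [0, 0.4)
or deltaMax ∈ [0.2, 0.5); else neutral.  Thresholds are inclusive on the
deleterious side and exclusive on the neutral side, so LoF exactly 0 is
intermediate.  When the two scores fall in different bands the more severe
band wins — a variant is called functionally neutral only if *both* measures
are normal.  A variant with LoF < 0 but deltaMax in [0.2, 0.5) is banded
intermediate; the alternative (tallying it neutral) is defensible, and the
choice matters only for variants in that narrow corner.  Variants with no
score are `unscored` and excluded from score-based analyses with a logged
count.  All cut-points (0 / 0.4 for LoF, 0.2 / 0.5 for deltaMax) are
configuration, not constants.

HGVS strings are opaque identifiers throughout: no genome coordinates,
transcript mapping, or liftover is implemented, and no VCF parsing — the
catalog interface is a TSV with empty string for missing values.

## OddsPath calibration

Control variants must be previously classified P/LP or B/LB *without* any
prior functional evidence (population frequency, family history, tumor
characteristics only), which avoids validating one functional assay with
another.  The prior `p1` is the pathogenic fraction over the whole curated
set — intermediate-scoring controls included, because the prior describes
the set before functional scoring.  Posteriors `p2` are computed per score
direction over controls scoring in that direction (intermediates excluded
from both).  When a posterior cell is perfectly concordant, the proportion
is recomputed as if one additional inconsistent variant were present
(denominator + 1, discordant cell = 1), flagged on the result.  Evidence
strength uses the cut-points 2.08 / 4.33 / 18.7 / 350 (supporting /
moderate / strong / very strong) and their reciprocals for benign evidence.

On the reference control specification (22 P/LP with one intermediate, 26
B/LB, otherwise concordant) this bookkeeping gives OddsPath ≈ 24.82 for
abnormal scores and 1/22 ≈ 0.0455 for normal scores, both mapping to
*strong*.  No single consistent (p1, p2) bookkeeping reproduces published
round-figure values such as 24.9/0.043 exactly; the result object therefore
exposes every count and correction flag so any convention can be audited,
and nothing is force-fitted.  Bootstrap uncertainty on OddsPath is out of
scope.

Validation recall counts splice-predicted deleterious variants as true
positives alongside protein-deleterious ones (recall 31/32 = 96.9% on a
27 + 4 + 1 split), even though PS3 assignment downstream is strictly
protein-score-driven.

## Point-based classification

Evidence codes follow the standard ACMG/AMP registry (PVS1, PS1–4, PM1–6,
PP1–5, BA1, BS1–4, BP1–7) with `_P/_M/_S/_VS` strength overrides.  Points
are supporting 1, moderate 2, strong 4, very strong 8, negated for benign
codes; category thresholds are P ≥ 10, LP 6–9, VUS 0–5, LB −6…−1, B ≤ −7.
Both the point values and the thresholds live in a `PointScale` object so
alternative published scales can be swapped in.  Each base code may be
applied at most once per variant; duplicates are a validation error.

Functional evidence enters as PS3/BS3 only.  PS3 is applied at strong
strength for protein-deleterious variants with LoF ≥ 1.7 — the lowest score
observed in the validated pathogenic set — and at moderate strength below
that line; moderate-eligible variants are tallied but not auto-reclassified
(a deliberately conservative default, switchable with `apply_moderate`).
Splice-predicted deleterious variants never receive PS3 from this pipeline,
because the underlying assay is cDNA-based and blind to splicing; their
splice predictions belong in computational evidence upstream.  Codes other
than PS3/BS3 are inputs: this package implements no per-criterion evidence
logic (no frequency lookups, no segregation counting).

The bundled reference table of 24 abnormal-scoring missense VUS carries
best-effort parses of their published evidence-code lists; a few printed
code strings in the source material are internally inconsistent, so the
engine is tested on point arithmetic, not on reproducing any outcome column
row by row.

## Exact statistics

Fisher's two-sided test enumerates the hypergeometric distribution over all
tables with the observed margins; the binomial test enumerates all outcome
counts.  Both sum point probabilities ≤ the observed one with relative
tolerance 1 + 1e−7 (the method of small p-values, matching the convention
of mainstream scientific stacks).  Point probabilities are evaluated in log
space via log-gamma, so totals of order 10⁴ do not overflow.  A table with
a zero margin returns p = 1.  The implementation is checked exhaustively
against an independent library oracle for every 2×2 table with total ≤ 30.
No multiple-testing correction is applied anywhere; raw p-values are
reported.

Odds ratios use the cross-product with Woolf (log-scale Wald) 95% intervals;
tables with an empty cell get a 0.5 continuity correction in every cell,
flagged.  The cancer-association model is a maximum-likelihood logistic
regression (statsmodels) of a cancer diagnosis on six binary carrier-status
features: *MSH2* missense with deleterious scores, *MSH2* missense with
neutral scores, *MSH2* other P/LP, and any P/LP in *MLH1*, *MSH6*, *PMS2*.
The UEC model is fit on females only.  Exclusions are applied first:
carriers of a P/LP variant in a non-Lynch-syndrome gene are dropped from
missense-feature analyses, and carriers of both an *MSH2* missense VUS and
another LS gene's P/LP variant are re-assigned to the latter gene.  Wald
intervals are reported (consistent with how such cohort results are usually
printed); confidence intervals are not profile-likelihood.  The CRC model
includes no sex covariate by default, mirroring the six-feature analysis;
`include_sex=True` adds a male indicator, and the parameter-recovery tests
use it because the marginal (sex-omitted) odds ratio is non-collapsible and
attenuated relative to the conditional odds ratio that generated the data.
Complete or quasi-separation is flagged on the affected terms (with a
ridge-stabilised point estimate) rather than failing silently.

## Paired tumor–normal analyses

A case enters the two-hit analyses when its only germline Lynch-gene
finding is exactly one *MSH2* missense variant.  A somatic second hit is
any P/LP somatic *MSH2* mutation, somatic *MSH2* LOH (configurable, default
included), or an *EPCAM* structural variant (which silences *MSH2*
epigenetically).  The MSI analysis first excludes *MLH1*-promoter-
hypermethylated cases (an independent somatic mechanism sufficient for MMR
deficiency), codes MSI-high and MSI-low together as unstable, and drops
unassayed cases with a logged count.  The somatic-coincidence analyses
compare tumors whose somatic *MSH2* missense variants are exclusively
functionally neutral (and that carry no other P/LP somatic *MSH2* mutation)
against tumors with at least one disruptive somatic missense variant, on
(A) somatic mutations in the other LS genes and (B) *MLH1* promoter
hypermethylation among assayed tumors.  Cases with ≥ 2 somatic *MSH2* hits
(≥ 1 deleterious) and no deleterious germline variant are flagged as
sporadic ("Lynch-like") candidates in the audit output.  Exact fractions
are reported throughout; printed roundings in source material are not
replicated.

## Synthetic cohort generator

The generator's defaults are the emulated study conditions: 2000 catalog
variants, 20,000 germline carriers, 1604 paired cases.  LoF scores follow a
two-component Normal mixture — neutral N(0, 0.2), truncated just below the
deleterious cutoff so only the deleterious component N(2.5, 1.0) produces
abnormal protein scores — with 1.2% of variants splice-disruptive and a
deleterious-component weight of 6.8%.  Classifications are score-concordant
(35% of deleterious variants P/LP, 5% of neutral variants B/LB, the rest
VUS) with an injectable discordant fraction (default 0).  VUS carry
non-functional evidence-code sets drawn from a configured mixture whose
weights put 78.2% of functionally normal VUS within reach of B/LB once a
strong BS3 code (−4 points) is added.

Germline cohort: sex is Bernoulli(0.84 female); every carrier gets one
category from a configured mixture; cancer outcomes are drawn from the same
logistic model the association stage fits, with sex-specific baselines
(CRC 8.9% female / 38.3% male, UEC 9.5% of females, additive on the logit
scale) and odds ratios CRC = {MLH1 14.4, MSH2-other-P/LP 8.10,
MSH2-deleterious-missense 2.53} and UEC = {MSH6 13.2, MSH2-other-P/LP 11.9,
MSH2-deleterious-missense 5.56}.  No published values exist for the
remaining cells ("lesser effects"); the defaults MSH6 2.0 / PMS2 1.5 (CRC)
and MLH1 4.0 / PMS2 2.0 (UEC) were chosen once as realistic and are plain
configuration.  Dual carriers are generated with risk driven by the
re-assigned gene only, so the fitted model is correctly specified after the
exclusion rules run.  Variant-to-carrier assignment is uniform; real
per-variant recurrence and family structure are unknowable from aggregate
descriptions, so carriers are independent (a noted limitation for
confidence-interval coverage assessments).

Paired cohort: a configurable fraction of cases (default 25/1604) carry a
sole *MSH2* missense germline variant, deleterious with probability 0.52;
somatic second hits arrive at rate 0.92 on a deleterious background and
0.17 on a neutral one; MSI tracks biallelic loss (0.95 given two hits, 0.20
otherwise); *MLH1* hypermethylation appears preferentially where no *MSH2*
two-hit explanation exists; somatic *MSH2* missense variants occur in 5.2%
of cases, 55% of those tumors harbouring a disruptive one, with other-LS-gene
somatic mutation rates of 0.97 (exclusively neutral) vs 0.65 (disruptive).

Each sub-generator owns an RNG stream split deterministically from the
master seed (`numpy.random.SeedSequence.spawn`), so outputs are
byte-identical under a fixed seed and adding a generator does not perturb
the others.  The generator does not attempt realistic HGVS nomenclature,
sequence context, or mutational signatures, and the score mixture is Normal
by construction — analyses that depend only on tier counts are insensitive
to the shape, but passing tests say nothing about how a real score
distribution's tails behave.  Default sizes trade fidelity for desk-scale
runtime; full-scale settings are reachable through configuration.

## Pipeline and reports

The CLI stages run in dependency order (tier → calibrate → reclassify;
tier → associate; tier → paired); a missing calibration aborts `reclassify`
with an error naming the `calibrate` stage.  Reports are JSON plus TSV;
every JSON report embeds a run manifest (command, config hash, input
digests, seed, tool version).  Wall-clock timestamps are written to the log
only, so identical runs produce byte-identical reports.  Reclassification
output is checked for conservation: newly P/LP + newly B/LB + remaining VUS
+ previously classified must equal the catalog size.

## Numerical choices and degenerate inputs

- Fisher/binomial tie tolerance 1 + 1e−7; degenerate margins → p = 1.
- deltaMax outside [0, 1] and malformed table rows are validation errors
  naming the offending row; duplicate `hgvs_c` within a catalog is rejected.
- An empty curated control set, a control classified VUS, a direction with
  no scored controls, and an all-excluded MSI analysis each raise or warn
  explicitly rather than returning silent defaults.
- Generator scores are rounded to 4 decimals for stable TSV round-trips;
  band edges are kept clear of the rounding step so a drawn score never
  crosses its tier threshold in serialisation.

## Known limitations

- The depletion test's exact two-sided p-value for the published example
  margins (34/682 observed vs 351/5130 reference) is ≈ 0.057 under the
  small-p-values convention (and ≈ 0.055–0.067 under common alternatives);
  published round figures for this comparison may derive from unstated
  conventions or slightly different counts.
- OddsPath values are point estimates; no uncertainty is attached.
- PS3/BS3 are the only evidence codes this package derives; everything else
  must be supplied.
- The generator's independence assumptions (carriers, variants) understate
  real-world clustering; coverage statements hold under the generator's
  model only.
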