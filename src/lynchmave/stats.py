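"""Exact 2x2 and binomial tests and the cancer-association logistic model.

The exact tests are self-contained: Fisher's test enumerates the
hypergeometric distribution over all tables with the observed margins, and
the binomial test enumerates all outcome counts, in both cases summing the
point probabilities no larger than the observed one (the "method of small
p-values", with relative tolerance 1 + 1e-7 to absorb floating-point ties).
Point probabilities are evaluated in log space via log-gamma so tables with
totals of order 1e4 do not overflow.  No multiple-testing correction is
applied anywhere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import binom

__all__ = [
    "Contingency2x2",
    "AssociationResult",
    "fisher_two_sided",
    "binomial_two_sided",
    "odds_ratio_2x2",
    "fit_cancer_association",
    "apply_exclusion_rules",
    "FEATURE_COLUMNS",
]

logger = logging.getLogger(__name__)

#: relative tolerance for "point probability <= observed" comparisons
_REL_TOL = 1.0 + 1e-7


@dataclass(frozen=True)
class Contingency2x2:
    """Counts [[a, b], [c, d]]: rows = groups, columns = outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")
        if self.total == 0:
            raise ValueError("contingency table must have at least one positive cell")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "c": self.c, "d": self.d}


def fisher_two_sided(t: Contingency2x2) -> float:
    """Two-sided Fisher's exact p-value by hypergeometric enumeration.

    Conditional on the observed margins, cell ``a`` follows a hypergeometric
    distribution; the p-value sums the point probabilities of all tables at
    most as probable as the observed one.  A table with a zero margin admits
    only one outcome and returns p = 1.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = t.total
    if min(r1, r2, c1, c2) == 0:
        return 1.0
    lo = max(0, r1 - c2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    # log hypergeometric pmf: C(c1, k) C(c2, r1 - k) / C(n, r1)
    logpmf = (
        gammaln(c1 + 1) - gammaln(support + 1) - gammaln(c1 - support + 1)
        + gammaln(c2 + 1) - gammaln(r1 - support + 1) - gammaln(c2 - r1 + support + 1)
        - (gammaln(n + 1) - gammaln(r1 + 1) - gammaln(n - r1 + 1))
    )
    pmf = np.exp(logpmf - logpmf.max())
    pmf /= pmf.sum()
    observed = pmf[a - lo]
    p = float(pmf[pmf <= observed * _REL_TOL].sum())
    return min(p, 1.0)


def binomial_two_sided(x: int, n: int, p0: float) -> float:
    """Exact two-sided binomial test of ``x`` successes in ``n`` trials vs ``p0``."""
    if not (0 < p0 < 1):
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    if not (0 <= x <= n):
        raise ValueError(f"x must be in [0, n], got x={x}, n={n}")
    k = np.arange(n + 1)
    logpmf = binom.logpmf(k, n, p0)
    pmf = np.exp(logpmf - logpmf.max())
    pmf /= pmf.sum()
    p = float(pmf[pmf <= pmf[x] * _REL_TOL].sum())
    return min(p, 1.0)


@dataclass(frozen=True)
class AssociationResult:
    """An odds ratio with 95% Wald confidence interval and p-value."""

    term: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    continuity_corrected: bool = False
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError(
                f"{self.term}: CI [{self.ci_low}, {self.ci_high}] does not "
                f"bracket OR {self.odds_ratio}"
            )

    def to_dict(self) -> dict:
        return {
            "term": self.term,
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "continuity_corrected": self.continuity_corrected,
            "flags": list(self.flags),
        }


def odds_ratio_2x2(t: Contingency2x2, term: str = "exposure") -> AssociationResult:
    """Sample odds ratio ad/bc with Woolf (log-scale Wald) 95% CI.

    Tables with an empty cell get a 0.5 continuity correction in every cell,
    flagged on the result.
    """
    cells = np.array([t.a, t.b, t.c, t.d], dtype=float)
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    a, b, c, d = cells
    log_or = np.log(a * d) - np.log(b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = log_or / se
    from scipy.stats import norm

    return AssociationResult(
        term=term,
        odds_ratio=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - 1.959963984540054 * se)),
        ci_high=float(np.exp(log_or + 1.959963984540054 * se)),
        p_value=float(2 * norm.sf(abs(z))),
        continuity_corrected=corrected,
    )


#: the six binary carrier-status features of the cancer-association model
FEATURE_COLUMNS = [
    "msh2_missense_deleterious",
    "msh2_missense_neutral",
    "msh2_other_plp",
    "mlh1_plp",
    "msh6_plp",
    "pms2_plp",
]

_OUTCOME_COLUMNS = {"CRC": "crc_dx", "UEC": "uec_dx"}


def apply_exclusion_rules(cohort: pd.DataFrame) -> pd.DataFrame:
    """Apply the carrier-categorisation exclusions before model fitting.

    * Individuals carrying a P/LP variant in a non-Lynch-syndrome gene are
      dropped from MSH2 VUS (missense-feature) analyses.
    * Individuals with both an MSH2 missense VUS and a P/LP variant in
      MLH1/MSH6/PMS2 are treated as carriers of the latter gene: their MSH2
      missense feature columns are zeroed.
    """
    df = cohort.copy()
    missense = df[["msh2_missense_deleterious", "msh2_missense_neutral"]].sum(axis=1) > 0
    other_ls = df[["mlh1_plp", "msh6_plp", "pms2_plp"]].sum(axis=1) > 0
    reassigned = missense & other_ls
    if reassigned.any():
        df.loc[reassigned, ["msh2_missense_deleterious", "msh2_missense_neutral"]] = 0
        logger.info("reassigned %d dual carriers to their P/LP gene", int(reassigned.sum()))
    if "non_ls_plp" in df.columns:
        drop = missense & df["non_ls_plp"].astype(bool)
        if drop.any():
            logger.info("excluded %d carriers with non-LS-gene P/LP variants", int(drop.sum()))
            df = df.loc[~drop]
    return df


def fit_cancer_association(
    cohort: pd.DataFrame,
    outcome: str = "CRC",
    features: list[str] | None = None,
    include_sex: bool = False,
    apply_exclusions: bool = True,
) -> list[AssociationResult]:
    """Fit the six-feature logistic cancer-association model.

    Response is the cancer diagnosis flag; features are per-individual binary
    carrier statuses.  The UEC model is fit on females only.  Empty feature
    columns are dropped with a warning; quasi-/complete separation is flagged
    on the affected terms rather than failing silently.
    """
    import statsmodels.api as sm

    if outcome not in _OUTCOME_COLUMNS:
        raise ValueError(f"outcome must be one of {sorted(_OUTCOME_COLUMNS)}, got {outcome!r}")
    features = list(FEATURE_COLUMNS if features is None else features)
    df = apply_exclusion_rules(cohort) if apply_exclusions else cohort.copy()
    if outcome == "UEC":
        df = df.loc[df["sex"] == "F"]

    y = df[_OUTCOME_COLUMNS[outcome]].astype(int)
    kept = []
    for f in features:
        if df[f].astype(int).sum() == 0:
            logger.warning("feature %s has no carriers; dropped from %s model", f, outcome)
        else:
            kept.append(f)
    X = df[kept].astype(float)
    if include_sex:
        X = X.assign(sex_male=(df["sex"] == "M").astype(float))
    X = sm.add_constant(X, has_constant="add")

    flags: tuple[str, ...] = ()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        try:
            fit = model.fit(disp=0, maxiter=200)
            if not fit.mle_retvals.get("converged", True):
                flags = ("non_converged",)
        except Exception as exc:  # perfect separation raises in statsmodels
            fit = model.fit_regularized(alpha=1e-6, disp=0, maxiter=500)
            flags = ("separation", str(type(exc).__name__))

    params = fit.params
    try:
        bse = fit.bse
        pvals = fit.pvalues
    except Exception:
        bse = pd.Series(np.nan, index=params.index)
        pvals = pd.Series(np.nan, index=params.index)

    results = []
    for f in kept:
        beta, se = float(params[f]), float(bse[f])
        term_flags = flags
        if np.isfinite(se) and se > 10:
            term_flags = term_flags + ("separation_suspect",)
        with np.errstate(over="ignore"):
            lo = np.exp(beta - 1.959963984540054 * se) if np.isfinite(se) else np.nan
            hi = np.exp(beta + 1.959963984540054 * se) if np.isfinite(se) else np.nan
        results.append(
            AssociationResult(
                term=f,
                odds_ratio=float(np.exp(beta)),
                ci_low=float(lo) if np.isfinite(lo) else float(np.exp(beta)),
                ci_high=float(hi) if np.isfinite(hi) else float(np.exp(beta)),
                p_value=float(pvals[f]) if np.isfinite(pvals[f]) else float("nan"),
                flags=term_flags,
            )
        )
    return results
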