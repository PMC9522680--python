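"""Sham-corrected crossover statistics and per-mg emission factors.

The measurement model for one analyte is a mixed-effects ANCOVA on the
product-session value with the paired sham-session value as a covariate:

    y_ijk = mu + sequence_i + period_j + product_k + beta * sham_ijk
            + subject(sequence)_i + eps_ijk

Least-squares (marginal) means per product are evaluated at the grand mean
of the sham covariate, balanced over sequences and periods; the test of
interest is whether each sham-corrected LS mean differs from zero.  The LS
mean for the reference product, divided by the session e-liquid consumption,
gives the emission factor in µg exhaled per mg consumed — the source-term
bridge into the indoor-air model.

Estimation uses REML via :class:`statsmodels` ``MixedLM`` with subject as
the random grouping factor (subjects are uniquely labelled, so nesting
within sequence is implicit).  When the mixed fit degenerates (zero
variance, perfect fit, non-convergence) the model falls back to ordinary
least squares with subject fixed blocks, which preserves the LS-mean
contract.  Intervals and p-values use a t reference with between-subject
degrees of freedom ``n_subjects - n_sequences``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

import statsmodels.formula.api as smf
from patsy import build_design_matrices

__all__ = [
    "AncovaResult",
    "EmissionFactorEstimate",
    "fit_sham_ancova",
    "emission_factor",
    "estimate_emission_factors",
    "round_reported_factor",
]

STATUS_COMPUTED = "COMPUTED"
STATUS_BELOW_MDL = "BELOW_MDL"

_FORMULA = "product_value_ug ~ C(sequence) + C(period) + C(product) + sham_value_ug"


@dataclass(frozen=True)
class AncovaResult:
    analyte: str
    product: str
    ls_mean: float  # µg per 10 puffs
    ci_low: float
    ci_high: float
    p_value: float
    n: int  # subjects

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.ls_mean <= self.ci_high):
            raise ValueError("confidence interval must bracket the LS mean")
        if self.n <= 0:
            raise ValueError("n must be positive")


@dataclass(frozen=True)
class EmissionFactorEstimate:
    analyte: str
    product: str
    factor: float  # µg exhaled per mg e-liquid consumed, reporting precision
    factor_full: float  # same, full precision
    reference_consumption: float  # mg, the divisor
    status: str = STATUS_COMPUTED


def _validate_sessions(data: pd.DataFrame, analyte: str) -> pd.DataFrame:
    sub = data.loc[data["analyte"] == analyte].copy()
    if sub.empty:
        raise ValueError(f"no sessions for analyte {analyte!r}")
    per_seq = sub.groupby("sequence")["subject_id"].nunique()
    if (per_seq < 2).any():
        raise ValueError("need at least 2 subjects per sequence to estimate")
    seen = sub.groupby("sequence")["product"].nunique()
    n_products = sub["product"].nunique()
    if (seen < n_products).any():
        raise ValueError("singular design: some sequence is missing a product")
    counts = sub.groupby(["subject_id", "product"]).size()
    if (counts != 1).any():
        raise ValueError("each subject must have exactly one record per product")
    return sub


def _fit_models(sub: pd.DataFrame):
    """Return (design_info, params, cov) from MixedLM, or the OLS fallback."""
    formula = _FORMULA
    if sub["sham_value_ug"].nunique() == 1:
        # all-censored sham arm: the covariate is constant (absorbed by the
        # intercept) and would make the design singular
        formula = formula.replace(" + sham_value_ug", "")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, sub, groups=sub["subject_id"])
            res = model.fit(reml=True)
            ok = (
                res.converged
                and np.isfinite(res.fe_params).all()
                and np.isfinite(res.scale)
                and res.scale > 1e-10 * max(1.0, float(sub["product_value_ug"].mean()) ** 2)
            )
            if ok:
                k = len(res.fe_params)
                cov = np.asarray(res.cov_params())[:k, :k]
                return model.data.design_info, np.asarray(res.fe_params), cov
        except (np.linalg.LinAlgError, ValueError):
            pass
        # degenerate or non-converged: subject fixed blocks
        res = smf.ols(formula + " + C(subject_id)", sub).fit()
        return (
            res.model.data.design_info,
            np.asarray(res.params),
            np.asarray(res.cov_params()),
        )


def _lsmean_rows(design_info, sub: pd.DataFrame, product: str) -> np.ndarray:
    """Balanced prediction rows for one product at the mean sham value."""
    sequences = sorted(sub["sequence"].unique())
    periods = sorted(sub["period"].unique())
    sham_bar = float(sub["sham_value_ug"].mean())
    grid = pd.DataFrame(
        [
            {
                "sequence": s,
                "period": p,
                "product": product,
                "sham_value_ug": sham_bar,
                # present only in the fallback design; averaging over all
                # subjects keeps the blocks balanced
                "subject_id": subj,
            }
            for s in sequences
            for p in periods
            for subj in sub["subject_id"].unique()
        ]
    )
    (mat,) = build_design_matrices([design_info], grid)
    return np.asarray(mat).mean(axis=0)


def fit_sham_ancova(
    sessions: pd.DataFrame, analyte: str, alpha: float = 0.05
) -> list[AncovaResult]:
    """Fit the sham-covariate mixed ANCOVA and return per-product LS means.

    ``sessions`` is the tidy frame produced by
    :func:`evpexposure.synthetic_study.generate_study` (censoring already
    applied).  Returns one :class:`AncovaResult` per product, ordered by
    product label.
    """
    sub = _validate_sessions(sessions, analyte)
    design_info, params, cov = _fit_models(sub)
    n_subjects = sub["subject_id"].nunique()
    ddf = max(n_subjects - sub["sequence"].nunique(), 1)
    tcrit = st.t.ppf(1 - alpha / 2.0, ddf)
    out: list[AncovaResult] = []
    for product in sorted(sub["product"].unique()):
        L = _lsmean_rows(design_info, sub, product)
        ls = float(L @ params)
        var = float(L @ cov @ L)
        se = math.sqrt(max(var, 0.0))
        if se == 0.0:
            p = 0.0 if ls != 0.0 else 1.0
            lo = hi = ls
        else:
            tstat = ls / se
            p = float(2.0 * st.t.sf(abs(tstat), ddf))
            lo, hi = ls - tcrit * se, ls + tcrit * se
        out.append(AncovaResult(analyte, product, ls, lo, hi, p, n_subjects))
    return out


def round_reported_factor(value: float, sig_figs: int | None = None) -> float:
    """Reporting precision for emission factors.

    The default convention is two decimal places for factors of at least
    0.1 µg/mg and two significant figures below that; pass ``sig_figs`` to
    override with a fixed number of significant figures.
    """
    if value == 0:
        return 0.0
    if sig_figs is not None:
        return float(round(value, sig_figs - 1 - int(math.floor(math.log10(abs(value))))))
    if abs(value) >= 0.1:
        return float(round(value, 2))
    return float(round(value, 1 - int(math.floor(math.log10(abs(value))))))


def emission_factor(
    ls_mean: float,
    consumption: float,
    sig_figs: int | None = None,
    analyte: str = "",
    product: str = "",
    status: str = STATUS_COMPUTED,
) -> EmissionFactorEstimate:
    """Convert an LS mean (µg per session) to µg per mg e-liquid consumed."""
    if consumption <= 0:
        raise ValueError("consumption must be positive")
    full = ls_mean / consumption
    return EmissionFactorEstimate(
        analyte=analyte,
        product=product,
        factor=round_reported_factor(full, sig_figs),
        factor_full=full,
        reference_consumption=consumption,
        status=status,
    )


def estimate_emission_factors(
    sessions: pd.DataFrame,
    product: str = "tp3",
    reference_consumption: dict[int, float] | None = None,
    mdl_upper_bound: bool = False,
) -> pd.DataFrame:
    """End-to-end per-analyte emission factors for one product.

    Analytes censored in every session (both sham and product arms) carry no
    information beyond the MDL; they are reported with factor 0 and
    ``BELOW_MDL`` status rather than a spurious positive factor from the
    substituted MDL values.  Set ``mdl_upper_bound`` to instead report the
    MDL-based upper bound for such analytes.

    ``reference_consumption`` maps collection type to the divisor in mg; by
    default it is the observed mean consumption for the product in that
    collection, rounded to the nearest mg.
    """
    rows = []
    for analyte in sessions["analyte"].unique():
        sub = sessions.loc[sessions["analyte"] == analyte]
        coll = int(sub["collection"].iloc[0])
        if reference_consumption and coll in reference_consumption:
            consumption = float(reference_consumption[coll])
        else:
            mask = sub["product"] == product
            consumption = float(round(sub.loc[mask, "consumed_mg"].mean()))
        fully_censored = bool(
            (sub["censored_product"] & sub["censored_sham"]).all()
        )
        if fully_censored and not mdl_upper_bound:
            est = EmissionFactorEstimate(
                analyte, product, 0.0, 0.0, consumption, STATUS_BELOW_MDL
            )
            ls_mean, ci_low, ci_high, p = 0.0, 0.0, 0.0, float("nan")
        else:
            if fully_censored:
                # upper bound: the substituted MDL value itself
                mdl_val = float(sub["product_value_ug"].iloc[0])
                est = emission_factor(
                    mdl_val, consumption, analyte=analyte, product=product,
                    status=STATUS_BELOW_MDL,
                )
                ls_mean, ci_low, ci_high, p = mdl_val, 0.0, mdl_val, float("nan")
            else:
                results = {r.product: r for r in fit_sham_ancova(sessions, analyte)}
                r = results[product]
                est = emission_factor(
                    r.ls_mean, consumption, analyte=analyte, product=product
                )
                ls_mean, ci_low, ci_high, p = r.ls_mean, r.ci_low, r.ci_high, r.p_value
        rows.append(
            {
                "analyte": analyte,
                "product": product,
                "ls_mean_ug": ls_mean,
                "ci_low_ug": ci_low,
                "ci_high_ug": ci_high,
                "p_value": p,
                "reference_consumption_mg": est.reference_consumption,
                "emission_factor_ug_per_mg": est.factor,
                "emission_factor_full": est.factor_full,
                "status": est.status,
            }
        )
    return pd.DataFrame(rows)
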