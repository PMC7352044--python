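"""Conditional incidence of one disease given another, plus covariate screening.

The co-incidence analysis reduces a patient-level cohort to four counts —
total patients N, exposed n_UF, outcome n_EC, and doubly affected n_both —
and reports the conditional incidences

    P(EC | UF)      = n_both / n_UF
    P(EC | not UF)  = (n_EC - n_both) / (N - n_UF)

as percentages, together with the relative change

    ratio_change = (P(EC | not UF) - P(EC | UF)) / P(EC | UF) * 100%

(positive when exposure is associated with a *decrease* in incidence; the
denominator is the incidence among the exposed). This is Bayes-consistent
direct conditioning: P(EC|UF) = P(UF|EC) P(EC) / P(UF) holds exactly on the
same four counts.

Covariate screening uses ordinary least squares on the binary outcome flag — a
linear probability model, deliberately, because that is the analysis the
clinical design calls for here; its limitations are documented in the methods
note.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    CollinearityError,
    DataError,
    InfiniteRatioError,
    UndefinedConditionalError,
)

__all__ = [
    "ContingencySummary",
    "CoincidenceResult",
    "MLRResult",
    "CoincidenceReport",
    "tabulate",
    "conditional_incidence",
    "mlr_fit",
    "coincidence_report",
    "write_report",
]


@dataclass(frozen=True)
class ContingencySummary:
    """The four counts driving the conditional-incidence formulas."""

    n_total: int
    n_uf: int
    n_ec: int
    n_both: int

    def __post_init__(self) -> None:
        c = (self.n_total, self.n_uf, self.n_ec, self.n_both)
        if any(v < 0 for v in c):
            raise DataError(f"counts must be non-negative, got {c}")
        if self.n_both > min(self.n_uf, self.n_ec):
            raise DataError("n_both cannot exceed n_uf or n_ec")
        if max(self.n_uf, self.n_ec) > self.n_total:
            raise DataError("n_uf and n_ec cannot exceed n_total")


@dataclass(frozen=True)
class CoincidenceResult:
    """Conditional incidences as percentages (full precision retained)."""

    p_ec_given_uf: float
    p_ec_given_not_uf: float
    ratio_change_pct: float  # positive = incidence lower among the exposed
    overall_incidence_pct: float

    def rounded(self, ndigits: int = 2) -> "CoincidenceResult":
        """Display form: percentages to 2 decimals (e.g. 1.43, 0.95, 50.53).

        The displayed relative change is recomputed from the *rounded*
        conditionals — the reporting convention of the clinical worked
        example, where (1.43 - 0.95) / 0.95 gives 50.53%. The full-precision
        ``ratio_change_pct`` field remains exactly consistent with the
        unrounded conditionals.
        """
        p_uf = round(self.p_ec_given_uf, ndigits)
        p_not = round(self.p_ec_given_not_uf, ndigits)
        ratio = (p_not - p_uf) / p_uf * 100.0 if p_uf > 0 else self.ratio_change_pct
        return CoincidenceResult(
            p_uf,
            p_not,
            round(ratio, ndigits),
            round(self.overall_incidence_pct, ndigits),
        )


@dataclass
class MLRResult:
    """OLS summary: one row per term (coef, 95% CI from the t distribution, p)."""

    table: pd.DataFrame  # index: term; columns: beta, ci_low, ci_high, p_value
    df_resid: int

    def __post_init__(self) -> None:
        t = self.table
        if not ((t["ci_low"] <= t["beta"] + 1e-12) & (t["beta"] <= t["ci_high"] + 1e-12)).all():
            raise DataError("confidence limits must bracket the estimate")


def tabulate(cohort: pd.DataFrame) -> ContingencySummary:
    """Count total, exposed, outcome, and doubly affected patients.

    Flags must be exactly 0 or 1; the first offending row is named.
    """
    if len(cohort) == 0:
        raise DataError("empty cohort")
    for col in ("uf", "ec"):
        if col not in cohort.columns:
            raise DataError(f"cohort lacks required column '{col}'")
        vals = cohort[col]
        bad = ~vals.isin([0, 1]) | vals.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(f"invalid {col} flag at row {row}: {vals.iloc[row]!r}")
    uf = cohort["uf"].to_numpy(dtype=np.int64)
    ec = cohort["ec"].to_numpy(dtype=np.int64)
    return ContingencySummary(
        n_total=len(cohort),
        n_uf=int(uf.sum()),
        n_ec=int(ec.sum()),
        n_both=int((uf & ec).sum()),
    )


def conditional_incidence(c: ContingencySummary) -> CoincidenceResult:
    """Conditional incidences and relative change from the four counts."""
    if c.n_uf == 0:
        raise UndefinedConditionalError("no exposed patients: P(EC|UF) undefined")
    if c.n_total == c.n_uf:
        raise UndefinedConditionalError("no unexposed patients: P(EC|not UF) undefined")
    p_uf = c.n_both / c.n_uf * 100.0
    p_not_uf = (c.n_ec - c.n_both) / (c.n_total - c.n_uf) * 100.0
    if c.n_both == 0:
        raise InfiniteRatioError()
    ratio = (p_not_uf - p_uf) / p_uf * 100.0
    return CoincidenceResult(
        p_ec_given_uf=p_uf,
        p_ec_given_not_uf=p_not_uf,
        ratio_change_pct=ratio,
        overall_incidence_pct=c.n_ec / c.n_total * 100.0,
    )


def _check_rank(X: pd.DataFrame) -> None:
    """Raise CollinearityError naming the dependent columns of a design with intercept."""
    design = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(design) == design.shape[1]:
        return
    # greedy rank growth: a column that fails to raise the rank is offending
    offending = []
    kept = np.ones((len(X), 1))
    rank = 1
    for name in X.columns:
        cand = np.column_stack([kept, X[name].to_numpy(dtype=float)])
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            kept, rank = cand, r
        else:
            offending.append(name)
    raise CollinearityError(offending)


def mlr_fit(response, covariates: pd.DataFrame) -> MLRResult:
    """OLS with intercept; per-term t-test p-values and 95% t-based CIs.

    ``covariates`` is a labelled design matrix (no intercept column); the
    intercept is added internally. Rank-deficient designs raise
    :class:`CollinearityError` naming the offending columns.
    """
    y = np.asarray(response, dtype=float)
    if len(covariates) != len(y):
        raise DataError("response and covariates have different lengths")
    if len(y) <= covariates.shape[1] + 1:
        raise DataError("need more observations than parameters")
    _check_rank(covariates)
    X = sm.add_constant(covariates.astype(float), prepend=True)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "beta": fit.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p_value": fit.pvalues,
        }
    )
    table.index = ["intercept"] + list(covariates.columns)
    return MLRResult(table=table, df_resid=int(fit.df_resid))


@dataclass
class CoincidenceReport:
    summary: ContingencySummary
    coincidence: CoincidenceResult
    mlr_ec: MLRResult  # EC flag on age + other_gyn
    mlr_uf: MLRResult  # UF flag on age + other_gyn


def coincidence_report(cohort: pd.DataFrame, covariates: list[str] | None = None) -> CoincidenceReport:
    """Bundle the conditional-incidence result with covariate screens.

    Two linear-probability screens are fitted: the outcome flag and the
    exposure flag, each on age and the other-gynecological-disease flag.
    """
    covariates = covariates or ["age", "other_gyn"]
    summary = tabulate(cohort)
    coin = conditional_incidence(summary)
    X = cohort[covariates]
    mlr_ec = mlr_fit(cohort["ec"], X)
    mlr_uf = mlr_fit(cohort["uf"], X)
    return CoincidenceReport(summary=summary, coincidence=coin, mlr_ec=mlr_ec, mlr_uf=mlr_uf)


def write_report(report: CoincidenceReport, out_dir: str | Path) -> None:
    """Serialize a report to TSVs under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    c, r = report.summary, report.coincidence.rounded()
    pd.DataFrame(
        [
            {
                "n_total": c.n_total,
                "n_uf": c.n_uf,
                "n_ec": c.n_ec,
                "n_both": c.n_both,
                "p_ec_given_uf_pct": r.p_ec_given_uf,
                "p_ec_given_not_uf_pct": r.p_ec_given_not_uf,
                "ratio_change_pct": r.ratio_change_pct,
                "overall_incidence_pct": r.overall_incidence_pct,
            }
        ]
    ).to_csv(out / "coincidence.tsv", sep="\t", index=False)
    for name, mlr in (("mlr_ec", report.mlr_ec), ("mlr_uf", report.mlr_uf)):
        mlr.table.rename_axis("term").to_csv(out / f"{name}.tsv", sep="\t")
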