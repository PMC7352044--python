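"""Significance screening of meta-results and study-level moderator regression.

A gene passes the screen iff all three criteria hold:

1. supported by at least ``min_studies`` independent studies (default 3);
2. pooled meta-analysis p below ``alpha`` (default 0.05);
3. pooled log2 fold change above ``lfc_upper`` (default 0.59 = log2 1.5, a
   >50% increase) or below ``lfc_lower`` (default -1 = log2 0.5, a >50%
   decrease).

The thresholds are asymmetric on the log2 scale by design: a 50% increase and
a 50% decrease are not mirror images in log units, and the asymmetry is kept.

Moderator regression fits per-study effect sizes on study-level covariates
(total sample size, region, study date) by plain OLS. With only a handful of
studies per gene these fits are near-saturated; they are reported with a
degenerate-design flag rather than suppressed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .coincidence import MLRResult, mlr_fit
from .errors import DataError, DegenerateDesignWarning, ParameterError

__all__ = [
    "SignificanceCriteria",
    "ModeratorFit",
    "apply_criteria",
    "validate_moderators",
    "moderator_regression",
]


@dataclass(frozen=True)
class SignificanceCriteria:
    """The three-part screen: study support, pooled p, and LFC magnitude."""

    min_studies: int = 3
    alpha: float = 0.05
    lfc_upper: float = 0.59
    lfc_lower: float = -1.0

    def __post_init__(self) -> None:
        if self.min_studies < 1:
            raise ParameterError("min_studies must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ParameterError("alpha must be in (0, 1)")
        if not (self.lfc_lower < 0.0 < self.lfc_upper):
            raise ParameterError("need lfc_lower < 0 < lfc_upper")


def apply_criteria(
    results: pd.DataFrame, criteria: SignificanceCriteria = SignificanceCriteria()
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition a meta-results table into (significant_up, significant_down, rejected).

    ``results`` needs columns ``gene, k, pooled_lfc, p_value``. Every input
    gene lands in exactly one of the three outputs; rejected rows carry a
    ``reason`` column naming the first failed criterion
    (study_count, p_value, lfc_magnitude).
    """
    required = {"gene", "k", "pooled_lfc", "p_value"}
    missing = required - set(results.columns)
    if missing:
        raise DataError(f"results table missing columns: {sorted(missing)}")

    reasons = []
    for row in results.itertuples(index=False):
        if row.k < criteria.min_studies:
            reasons.append("study_count")
        elif not (row.p_value < criteria.alpha):  # NaN p fails here
            reasons.append("p_value")
        elif not (row.pooled_lfc > criteria.lfc_upper or row.pooled_lfc < criteria.lfc_lower):
            reasons.append("lfc_magnitude")
        else:
            reasons.append("")
    reasons = pd.Series(reasons, index=results.index)

    passed = results[reasons == ""]
    up = passed[passed["pooled_lfc"] > criteria.lfc_upper].reset_index(drop=True)
    down = passed[passed["pooled_lfc"] < criteria.lfc_lower].reset_index(drop=True)
    rejected = results[reasons != ""].copy()
    rejected["reason"] = reasons[reasons != ""]
    return up, down, rejected.reset_index(drop=True)


def validate_moderators(moderators: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-study moderator table (study_id, sample_size, region, study_date)."""
    required = {"study_id", "sample_size", "region", "study_date"}
    missing = required - set(moderators.columns)
    if missing:
        raise DataError(f"moderator table missing columns: {sorted(missing)}")
    if moderators["study_id"].duplicated().any():
        raise DataError("moderator table must have one row per study")
    if (moderators["sample_size"] < 4).any():
        raise DataError("sample_size must be >= 4 for every study")
    return moderators


@dataclass
class ModeratorFit:
    """Result of a moderator regression; ``degenerate`` when the fit is saturated."""

    gene: str
    degenerate: bool
    reason: str = ""
    result: MLRResult | None = None


def moderator_regression(effects: pd.DataFrame, moderators: pd.DataFrame) -> ModeratorFit:
    """OLS of one gene's per-study LFCs on sample size, region and study date.

    ``effects`` holds one row per study for a single gene (columns ``gene,
    study_id, lfc``). Region is dummy-encoded with the alphabetically first
    level as reference, so replication is deterministic. When the number of
    studies is not strictly greater than the number of encoded covariates
    plus one, a degenerate flag is returned instead of estimates.
    """
    genes = effects["gene"].unique()
    if len(genes) != 1:
        raise DataError(f"moderator regression expects one gene, got {list(genes)}")
    gene = genes[0]
    validate_moderators(moderators)

    merged = effects.merge(moderators, on="study_id", how="left", validate="one_to_one")
    if merged["sample_size"].isna().any():
        lost = merged.loc[merged["sample_size"].isna(), "study_id"].tolist()
        raise DataError(f"{gene}: studies missing from moderator table: {lost}")

    region = pd.Categorical(merged["region"], categories=sorted(merged["region"].unique()))
    dummies = pd.get_dummies(region, prefix="region", drop_first=True, dtype=float)
    X = pd.concat(
        [
            merged[["sample_size"]].astype(float),
            dummies,
            merged[["study_date"]].astype(float),
        ],
        axis=1,
    )

    k = len(merged)
    if k <= X.shape[1] + 1:
        warnings.warn(
            f"{gene}: {k} studies for {X.shape[1]} covariates — saturated design",
            DegenerateDesignWarning,
            stacklevel=2,
        )
        return ModeratorFit(
            gene=gene,
            degenerate=True,
            reason=f"k={k} studies <= {X.shape[1]} covariates + 1",
        )
    result = mlr_fit(merged["lfc"], X)
    return ModeratorFit(gene=gene, degenerate=False, result=result)
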