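"""Per-study log-fold-change effect sizes and fixed/random-effects pooling.

The effect size for one gene in one study is the raw difference of mean log2
expression between cases and controls — the log2 fold change (LFC) — with the
Welch (unpooled) sampling variance

    v = s2_case / n_case + s2_control / n_control.

Raw log2 differences (not standardized mean differences) are the right scale
here: an LFC above log2(1.5) ~= 0.59 means the expression level rose by more
than 50%, and that interpretation only holds on the raw log2 scale.

Pooling follows the standard inverse-variance machinery:

* fixed effect — weights w_i = 1/v_i, pooled = sum(w y)/sum(w),
  se = sum(w)^(-1/2), Q = sum(w (y - pooled)^2);
* random effects (DerSimonian–Laird) — tau2 = max(0, (Q - (k-1)) / C) with
  C = sum(w) - sum(w^2)/sum(w), then re-pool with w*_i = 1/(v_i + tau2);
* model selection — chi-square Q-test on k-1 df; heterogeneity p below
  ``het_alpha`` (default 0.10, the conventional screen) selects the
  random-effects model.

95% CIs use the 1.96 normal multiplier and p-values the two-sided normal
test of pooled/se. Per-study weights are reported normalized to sum to one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateGroupError,
    MissingGeneError,
    ParameterError,
    VarianceFloorWarning,
)
from .synthetic import ExpressionStudy

__all__ = [
    "StudyEffect",
    "MetaResult",
    "VARIANCE_FLOOR",
    "compute_study_effect",
    "pool_fixed",
    "pool_random",
    "pool_auto",
    "run_mega",
    "collapse_duplicate_genes",
    "forest_plot",
]

VARIANCE_FLOOR = 1e-8  # survives degenerate zero-variance toy inputs
_Z95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass(frozen=True)
class StudyEffect:
    """One gene's log2 fold change and its sampling variance in one study."""

    gene: str
    study_id: str
    lfc: float
    variance: float
    n_case: int
    n_control: int
    floored: bool = False

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ParameterError(f"variance must be > 0, got {self.variance}")
        if self.n_case < 2 or self.n_control < 2:
            raise ParameterError("each group needs at least 2 samples")


@dataclass(frozen=True)
class MetaResult:
    """Pooled effect for one gene with heterogeneity statistics.

    ``model_used`` is 'fixed' or 'random'; ``weights`` maps study_id to the
    normalized pooling weight (sums to 1).
    """

    gene: str
    k: int
    pooled_lfc: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    Q: float
    tau2: float
    I2: float
    model_used: str
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.pooled_lfc <= self.ci_high):
            raise ParameterError("CI must bracket the pooled estimate")
        if self.tau2 < 0:
            raise ParameterError("tau2 must be >= 0")


def collapse_duplicate_genes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate gene rows (multiple probes) to the row with the
    highest mean expression."""
    if matrix.index.is_unique:
        return matrix
    means = matrix.mean(axis=1).to_numpy()
    order = np.argsort(-means, kind="stable")
    picked = matrix.iloc[order]
    return picked[~picked.index.duplicated(keep="first")]


def compute_study_effect(study: ExpressionStudy, gene: str) -> StudyEffect:
    """Welch-form LFC effect size for ``gene`` in ``study``.

    Raises :class:`MissingGeneError` when the gene is not measured (callers
    skip the study for that gene) and :class:`DegenerateGroupError` when a
    group has fewer than two samples. A zero sampling variance (constant
    values in both groups) is floored at ``VARIANCE_FLOOR`` and flagged.
    """
    matrix = collapse_duplicate_genes(study.matrix)
    if gene not in matrix.index:
        raise MissingGeneError(gene)
    case_cols = study.case_columns
    ctrl_cols = study.control_columns
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise DegenerateGroupError(
            f"study {study.study_id}: needs >=2 samples per group "
            f"(case={len(case_cols)}, control={len(ctrl_cols)})"
        )
    case = matrix.loc[gene, case_cols].to_numpy(dtype=float)
    ctrl = matrix.loc[gene, ctrl_cols].to_numpy(dtype=float)
    lfc = float(case.mean() - ctrl.mean())
    v = float(case.var(ddof=1) / len(case) + ctrl.var(ddof=1) / len(ctrl))
    floored = v < VARIANCE_FLOOR
    if floored:
        warnings.warn(
            f"variance floored for {gene} in {study.study_id}",
            VarianceFloorWarning,
            stacklevel=2,
        )
        v = VARIANCE_FLOOR
    return StudyEffect(
        gene=gene,
        study_id=study.study_id,
        lfc=lfc,
        variance=v,
        n_case=len(case),
        n_control=len(ctrl),
        floored=floored,
    )


def _common_gene(effects: list[StudyEffect]) -> str:
    if not effects:
        raise ParameterError("need at least one study effect")
    genes = {e.gene for e in effects}
    if len(genes) != 1:
        raise ParameterError(f"effects mix genes: {sorted(genes)}")
    return effects[0].gene


def _assemble(
    gene: str,
    effects: list[StudyEffect],
    w: np.ndarray,
    Q: float,
    tau2: float,
    model: str,
) -> MetaResult:
    y = np.array([e.lfc for e in effects])
    sw = w.sum()
    pooled = float((w * y).sum() / sw)
    se = float(sw**-0.5)
    z = pooled / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    k = len(effects)
    i2 = max(0.0, (Q - (k - 1)) / Q) * 100.0 if k >= 2 and Q > 0 else 0.0
    return MetaResult(
        gene=gene,
        k=k,
        pooled_lfc=pooled,
        se=se,
        ci_low=pooled - _Z95 * se,
        ci_high=pooled + _Z95 * se,
        p_value=p,
        Q=Q,
        tau2=tau2,
        I2=i2,
        model_used=model,
        weights={e.study_id: float(wi / sw) for e, wi in zip(effects, w)},
    )


def _fixed_weights_and_q(effects: list[StudyEffect]) -> tuple[np.ndarray, float]:
    y = np.array([e.lfc for e in effects])
    w = np.array([1.0 / e.variance for e in effects])
    pooled = (w * y).sum() / w.sum()
    Q = float((w * (y - pooled) ** 2).sum())
    return w, Q


def pool_fixed(effects: list[StudyEffect]) -> MetaResult:
    """Inverse-variance fixed-effect pooling."""
    gene = _common_gene(effects)
    w, Q = _fixed_weights_and_q(effects)
    return _assemble(gene, effects, w, Q, tau2=0.0, model="fixed")


def pool_random(effects: list[StudyEffect]) -> MetaResult:
    """DerSimonian–Laird random-effects pooling (requires k >= 2)."""
    gene = _common_gene(effects)
    k = len(effects)
    if k < 2:
        raise ParameterError("random-effects pooling needs at least 2 studies")
    w, Q = _fixed_weights_and_q(effects)
    C = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (Q - (k - 1)) / C)
    w_star = np.array([1.0 / (e.variance + tau2) for e in effects])
    return _assemble(gene, effects, w_star, Q, tau2=tau2, model="random")


def pool_auto(effects: list[StudyEffect], het_alpha: float = 0.10) -> MetaResult:
    """Pool under the model selected by the heterogeneity Q-test.

    Q is referred to chi-square with k-1 df; heterogeneity p < ``het_alpha``
    selects the random-effects model. A single study forces the fixed model
    (with a warning), since between-study variance is not estimable.
    """
    gene = _common_gene(effects)
    k = len(effects)
    if k == 1:
        warnings.warn(
            f"{gene}: single study, forcing fixed-effect model", UserWarning, stacklevel=2
        )
        return pool_fixed(effects)
    _, Q = _fixed_weights_and_q(effects)
    p_het = float(stats.chi2.sf(Q, k - 1))
    if p_het < het_alpha:
        return pool_random(effects)
    return pool_fixed(effects)


def run_mega(
    studies: list[ExpressionStudy],
    genes,
    het_alpha: float = 0.10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool every candidate gene over the studies that measure it.

    ``genes`` may be an iterable of symbols or a :class:`coimeta.overlap.GeneSet`.
    Returns ``(meta_table, effects_table)``. The number of contributing
    studies k varies per gene; genes measured nowhere are reported with k=0
    and null statistics. A Benjamini–Hochberg column ``p_bh`` is emitted as
    supplementary output; the replica screening criteria use the raw p.
    Results are independent of study order (effects are sorted by study_id).
    """
    if not studies:
        raise ParameterError("need at least one study")
    gene_list = sorted(genes.genes) if hasattr(genes, "genes") else list(genes)
    if not gene_list:
        raise ParameterError("need at least one gene")

    studies = sorted(studies, key=lambda s: s.study_id)
    meta_rows, effect_rows = [], []
    for gene in gene_list:
        effects = []
        for study in studies:
            try:
                effects.append(compute_study_effect(study, gene))
            except MissingGeneError:
                continue
        if not effects:
            meta_rows.append(
                {
                    "gene": gene,
                    "model_used": np.nan,
                    "k": 0,
                    "pooled_lfc": np.nan,
                    "se": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p_value": np.nan,
                    "Q": np.nan,
                    "tau2": np.nan,
                    "I2": np.nan,
                }
            )
            continue
        res = pool_auto(effects, het_alpha=het_alpha)
        meta_rows.append(
            {
                "gene": gene,
                "model_used": 1 if res.model_used == "random" else 0,
                "k": res.k,
                "pooled_lfc": res.pooled_lfc,
                "se": res.se,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p_value": res.p_value,
                "Q": res.Q,
                "tau2": res.tau2,
                "I2": res.I2,
            }
        )
        for e in effects:
            effect_rows.append(
                {
                    "gene": e.gene,
                    "study_id": e.study_id,
                    "lfc": e.lfc,
                    "variance": e.variance,
                    "n_case": e.n_case,
                    "n_control": e.n_control,
                    "weight": res.weights[e.study_id],
                }
            )

    meta = pd.DataFrame(meta_rows)
    measured = meta["k"] > 0
    meta["p_bh"] = np.nan
    if measured.any():
        meta.loc[measured, "p_bh"] = multipletests(
            meta.loc[measured, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    effects_df = pd.DataFrame(
        effect_rows,
        columns=["gene", "study_id", "lfc", "variance", "n_case", "n_control", "weight"],
    )
    return meta, effects_df


def forest_plot(effects: list[StudyEffect], result: MetaResult, path) -> None:
    """Forest plot: per-study effect +/- 95% CI with normalized weight bars,
    and the pooled estimate at the bottom."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    effects = sorted(effects, key=lambda e: e.study_id)
    k = len(effects)
    fig, (ax, axw) = plt.subplots(
        1, 2, figsize=(7, 0.6 * (k + 2)), sharey=True, width_ratios=[3, 1]
    )
    ys = np.arange(k, 0, -1)
    for y, e in zip(ys, effects):
        half = _Z95 * math.sqrt(e.variance)
        ax.plot([e.lfc - half, e.lfc + half], [y, y], color="tab:blue")
        ax.plot(e.lfc, y, "*", color="tab:red", markersize=9)
        axw.barh(y, result.weights[e.study_id], color="tab:green", height=0.5)
        axw.text(result.weights[e.study_id], y, f" {result.weights[e.study_id]:.2f}", va="center")
    ax.plot([result.ci_low, result.ci_high], [0, 0], color="black")
    ax.plot(result.pooled_lfc, 0, "D", color="black")
    ax.axvline(0.0, color="grey", linewidth=0.8, linestyle="--")
    ax.set_yticks(list(ys) + [0])
    ax.set_yticklabels([e.study_id for e in effects] + [f"pooled ({result.model_used})"])
    ax.set_xlabel("log2 fold change")
    axw.set_xlabel("normalized weight")
    axw.set_xlim(0, 1)
    fig.suptitle(result.gene)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
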