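"""Synthetic data generators with known ground truth.

Three generators stand in for the data sources of the study design:

* :func:`simulate_cohort` — a patient-level gynecological registry with binary
  uterine-fibroid (UF) and endometrial-carcinoma (EC) flags, where the EC rate
  is specified conditionally on UF status so the downstream conditional
  incidence analysis has an exact planted truth.
* :func:`simulate_expression_studies` — a collection of case/control expression
  studies on the log2 scale with per-gene planted log fold changes and an
  optional between-study random effect (the classic random-effects generating
  model).
* :func:`simulate_gene_sets` — two candidate gene lists over a shared
  background with an exact planted overlap.

All generators are deterministic under their integer seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, SmallCollectionWarning

__all__ = [
    "CohortSpec",
    "ExpressionStudySpec",
    "ExpressionStudy",
    "simulate_cohort",
    "simulate_expression_studies",
    "simulate_gene_sets",
    "cohort_from_counts",
    "registry_like_cohort_spec",
    "table1_like_study_specs",
]

# Registry-scale defaults: 4537 patients, age 43.98 +/- 9.64 with hard minimum 23,
# 1259 UF, 59 EC, 12 with both.
_REGISTRY_N = 4537
_REGISTRY_P_UF = 1259 / 4537
_REGISTRY_P_EC_UF = 12 / 1259
_REGISTRY_P_EC_NOT_UF = 47 / 3278


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ParameterError(f"{name} must be a probability in [0, 1], got {value!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic patient registry.

    The EC flag is drawn conditionally on the UF flag, so ``p_ec_given_uf`` and
    ``p_ec_given_not_uf`` are the exact planted conditional incidences. Ages
    are truncated normal: the registry reports a hard minimum age alongside a
    mean and SD, and truncation reproduces all three jointly. ``age_ec_slope``
    optionally tilts the EC probability on the log-odds scale per year of age
    (centred at ``age_mean``), for power studies of the age covariate.
    """

    n_patients: int = _REGISTRY_N
    p_uf: float = _REGISTRY_P_UF
    p_ec_given_uf: float = _REGISTRY_P_EC_UF
    p_ec_given_not_uf: float = _REGISTRY_P_EC_NOT_UF
    p_other: float = 0.5
    age_mean: float = 43.98
    age_sd: float = 9.64
    age_min: float = 23.0
    age_ec_slope: float = 0.0
    other_ec_log_or: float = 0.0  # optional dependence of EC on the other-disease flag
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ParameterError(f"n_patients must be positive, got {self.n_patients}")
        for name in ("p_uf", "p_ec_given_uf", "p_ec_given_not_uf", "p_other"):
            _check_prob(name, getattr(self, name))
        if self.age_sd <= 0:
            raise ParameterError(f"age_sd must be > 0, got {self.age_sd}")
        if self.age_min >= self.age_mean:
            raise ParameterError("age_min must be below age_mean")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic cohort table.

    Returns a DataFrame with columns ``patient_id, age, uf, ec, other_gyn``
    (flags coded 0/1). UF ~ Bernoulli(p_uf); EC ~ Bernoulli with probability
    chosen by UF status, optionally modulated by age and the other-disease
    flag on the log-odds scale.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    a = (spec.age_min - spec.age_mean) / spec.age_sd
    age = stats.truncnorm.rvs(
        a, np.inf, loc=spec.age_mean, scale=spec.age_sd, size=n, random_state=rng
    )

    uf = (rng.random(n) < spec.p_uf).astype(np.int64)
    other = (rng.random(n) < spec.p_other).astype(np.int64)

    p_base = np.where(uf == 1, spec.p_ec_given_uf, spec.p_ec_given_not_uf)
    if spec.age_ec_slope != 0.0 or spec.other_ec_log_or != 0.0:
        with np.errstate(divide="ignore"):
            logit = np.log(p_base) - np.log1p(-p_base)
        logit = logit + spec.age_ec_slope * (age - spec.age_mean)
        logit = logit + spec.other_ec_log_or * other
        p_ec = 1.0 / (1.0 + np.exp(-logit))
        # zero/one base probabilities stay exact
        p_ec = np.where((p_base == 0.0) | (p_base == 1.0), p_base, p_ec)
    else:
        p_ec = p_base
    ec = (rng.random(n) < p_ec).astype(np.int64)

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(1, n + 1)],
            "age": age,
            "uf": uf,
            "ec": ec,
            "other_gyn": other,
        }
    )


def registry_like_cohort_spec(seed: int = 0, n_patients: int = _REGISTRY_N) -> CohortSpec:
    """A CohortSpec whose planted rates match the registry's observed counts."""
    return CohortSpec(n_patients=n_patients, seed=seed)


def cohort_from_counts(
    n_total: int,
    n_uf: int,
    n_ec: int,
    n_both: int,
    age_mean: float = 43.98,
    age_sd: float = 9.64,
    age_min: float = 23.0,
    p_other: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Deterministically reconstruct a cohort with exact contingency counts.

    Any arrangement with the given four counts yields the same conditional
    incidences, so flags are laid out in blocks (both, exposure only, outcome
    only, neither) while ages and the other-disease flag are drawn randomly.
    """
    if n_both > min(n_uf, n_ec) or max(n_uf, n_ec) > n_total:
        raise ParameterError(f"infeasible counts ({n_total}, {n_uf}, {n_ec}, {n_both})")
    rng = np.random.default_rng(seed)
    uf = np.zeros(n_total, dtype=np.int64)
    ec = np.zeros(n_total, dtype=np.int64)
    uf[:n_uf] = 1
    ec[:n_both] = 1
    ec[n_uf : n_uf + (n_ec - n_both)] = 1
    a = (age_min - age_mean) / age_sd
    age = stats.truncnorm.rvs(
        a, np.inf, loc=age_mean, scale=age_sd, size=n_total, random_state=rng
    )
    other = (rng.random(n_total) < p_other).astype(np.int64)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(1, n_total + 1)],
            "age": age,
            "uf": uf,
            "ec": ec,
            "other_gyn": other,
        }
    )


@dataclass(frozen=True)
class ExpressionStudySpec:
    """Parameters of one synthetic case/control expression study.

    Expression is simulated directly on the log2 scale. Control samples are
    ``Normal(baseline_g, noise_sd)``; case samples add the planted log2 fold
    change and, when ``tau > 0``, a study-level deviation ``u_g ~ N(0, tau^2)``
    shared by all case samples of the study — the additive random effect the
    random-effects pooling model assumes.
    """

    study_id: str
    n_case: int
    n_control: int
    region: str = "RegionA"
    study_date: int = 2010
    genes: tuple[str, ...] = ()
    planted_lfc: dict[str, float] = field(default_factory=dict)
    tau: float = 0.0
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ParameterError("gene list must be non-empty")
        if self.n_case < 2 or self.n_control < 2:
            raise ParameterError("each group needs at least 2 samples")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be > 0")
        if self.tau < 0:
            raise ParameterError("tau must be >= 0")


@dataclass
class ExpressionStudy:
    """One loaded case/control expression study.

    ``matrix`` is genes x samples on the log2 scale; ``groups`` maps each
    sample column to 'case' or 'control'.
    """

    study_id: str
    matrix: pd.DataFrame
    groups: pd.Series
    region: str = "RegionA"
    study_date: int = 2010

    def __post_init__(self) -> None:
        if set(self.matrix.columns) != set(self.groups.index):
            raise ParameterError(
                f"study {self.study_id}: matrix columns do not match group annotation"
            )
        bad = set(self.groups.unique()) - {"case", "control"}
        if bad:
            raise ParameterError(f"study {self.study_id}: unknown group labels {sorted(bad)}")

    @property
    def n_case(self) -> int:
        return int((self.groups == "case").sum())

    @property
    def n_control(self) -> int:
        return int((self.groups == "control").sum())

    @property
    def case_columns(self) -> list[str]:
        return [c for c in self.matrix.columns if self.groups[c] == "case"]

    @property
    def control_columns(self) -> list[str]:
        return [c for c in self.matrix.columns if self.groups[c] == "control"]


def simulate_expression_studies(specs: list[ExpressionStudySpec]) -> list[ExpressionStudy]:
    """Simulate a collection of studies sharing a gene universe.

    A warning is raised for any study with total sample size below 8 — the
    collection-design filter used when assembling real array series — but small
    studies are still generated so toy analyses remain possible.
    """
    if not specs:
        raise ParameterError("need at least one study spec")
    universe = set(specs[0].genes)
    for s in specs[1:]:
        if not set(s.genes) <= universe and not universe <= set(s.genes):
            universe |= set(s.genes)

    studies = []
    for s in specs:
        if s.n_case + s.n_control < 8:
            warnings.warn(
                f"study {s.study_id}: total sample size {s.n_case + s.n_control} < 8",
                SmallCollectionWarning,
                stacklevel=2,
            )
        rng = np.random.default_rng(s.seed)
        genes = list(s.genes)
        g = len(genes)
        baseline = rng.normal(s.baseline_mean, s.baseline_sd, size=g)
        lfc = np.array([s.planted_lfc.get(gene, 0.0) for gene in genes])
        u = rng.normal(0.0, s.tau, size=g) if s.tau > 0 else np.zeros(g)

        ctrl = baseline[:, None] + rng.normal(0.0, s.noise_sd, size=(g, s.n_control))
        case = (baseline + lfc + u)[:, None] + rng.normal(0.0, s.noise_sd, size=(g, s.n_case))

        cols = [f"{s.study_id}_ctrl{i + 1}" for i in range(s.n_control)] + [
            f"{s.study_id}_case{i + 1}" for i in range(s.n_case)
        ]
        matrix = pd.DataFrame(np.hstack([ctrl, case]), index=genes, columns=cols)
        matrix.index.name = "gene"
        groups = pd.Series(
            ["control"] * s.n_control + ["case"] * s.n_case, index=cols, name="group"
        )
        studies.append(
            ExpressionStudy(
                study_id=s.study_id,
                matrix=matrix,
                groups=groups,
                region=s.region,
                study_date=s.study_date,
            )
        )
    return studies


# sample splits, regions and dates mirroring a six-study array collection
_SIX_STUDY_LAYOUT = [
    ("S1", 5, 5, "USA", 2003),
    ("S2", 5, 5, "USA", 2010),
    ("S3", 4, 4, "USA", 2012),
    ("S4", 6, 3, "Japan", 2013),
    ("S5", 6, 3, "Japan", 2013),
    ("S6", 9, 3, "Japan", 2017),
]


def table1_like_study_specs(
    genes: tuple[str, ...],
    planted_lfc: dict[str, float],
    tau: float = 0.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> list[ExpressionStudySpec]:
    """Six study specs with the sample splits, regions and dates of the
    real array collection the generator emulates (5/5, 5/5, 4/4, 3/6, 3/6, 3/9)."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(len(_SIX_STUDY_LAYOUT))]
    return [
        ExpressionStudySpec(
            study_id=sid,
            n_case=nca,
            n_control=nco,
            region=region,
            study_date=date,
            genes=genes,
            planted_lfc=planted_lfc,
            tau=tau,
            noise_sd=noise_sd,
            seed=sd,
        )
        for (sid, nca, nco, region, date), sd in zip(_SIX_STUDY_LAYOUT, seeds)
    ]


def simulate_gene_sets(
    n_background: int, n_setA: int, n_setB: int, n_overlap: int, seed: int = 0
):
    """Two gene sets over a shared background with an exact planted overlap.

    Returns ``(setA, setB, background)`` where the sets are
    :class:`coimeta.overlap.GeneSet` instances and ``background`` is the full
    symbol list. ``|A & B| == n_overlap`` exactly.
    """
    from .overlap import GeneSet  # local import to avoid a cycle

    if n_overlap > min(n_setA, n_setB):
        raise ParameterError("n_overlap cannot exceed either set size")
    if max(n_setA, n_setB) > n_background:
        raise ParameterError("set sizes cannot exceed the background")
    if n_setA + n_setB - n_overlap > n_background:
        raise ParameterError("union of the sets exceeds the background")

    rng = np.random.default_rng(seed)
    width = max(5, len(str(n_background)))
    background = [f"G{i:0{width}d}" for i in range(1, n_background + 1)]
    perm = rng.permutation(n_background)
    shared = [background[i] for i in perm[:n_overlap]]
    a_only = [background[i] for i in perm[n_overlap : n_setA]]
    b_only = [background[i] for i in perm[n_setA : n_setA + n_setB - n_overlap]]

    set_a = GeneSet(name="setA", genes=frozenset(shared + a_only), polarity="positive")
    set_b = GeneSet(name="setB", genes=frozenset(shared + b_only), polarity="negative")
    return set_a, set_b, background
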