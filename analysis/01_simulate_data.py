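#!/usr/bin/env python
"""Generate the synthetic study inputs for the whole analysis.

Produces, under scratch/analysis_data/ (regenerated on every run, not part of
the repository):

* a registry-like cohort of 4537 patients whose planted conditional EC rates
  match the observed registry counts, plus an exact-count reconstruction used
  for the clinical worked example;
* a six-study case/control expression collection (sample splits 5/5, 5/5,
  4/4, 3/6, 3/6, 3/9) over 130 candidate genes — 47 tagged positive and 83
  negative regulators — with five genes carrying planted log2 fold changes at
  the magnitudes the downstream screen is designed to detect;
* the two polarity-tagged candidate gene lists as TSVs.
"""

from pathlib import Path

import numpy as np

from coimeta.io import write_cohort, write_study_collection
from coimeta.synthetic import (
    cohort_from_counts,
    registry_like_cohort_spec,
    simulate_cohort,
    simulate_expression_studies,
    table1_like_study_specs,
)

SEED = 20240901
DATA = Path(__file__).resolve().parent.parent / "scratch" / "analysis_data"

# planted truths: three up-regulated and two down-regulated EC-negative
# regulators, at effect sizes straddling the screen's asymmetric thresholds
PLANTED = {"HTRA3": 1.00, "HOPX": 0.82, "PCNA": 0.79, "PPARG": -1.24, "EFEMP1": -2.14}


def candidate_genes():
    positive = [f"ECP{i:03d}" for i in range(1, 48)]  # 47 positive regulators
    negative = [f"ECN{i:03d}" for i in range(1, 79)] + list(PLANTED)  # 83 negative
    return positive, negative


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    exact = cohort_from_counts(4537, 1259, 59, 12, seed=SEED)
    write_cohort(exact, DATA / "cohort_exact_counts.tsv")

    sampled = simulate_cohort(registry_like_cohort_spec(seed=SEED + 1))
    write_cohort(sampled, DATA / "cohort_sampled.tsv")
    print(
        f"cohorts: exact-count reconstruction ({len(exact)} patients) and "
        f"sampled registry ({sampled['uf'].sum()} UF, {sampled['ec'].sum()} EC)"
    )

    positive, negative = candidate_genes()
    genes = tuple(positive + negative)
    specs = table1_like_study_specs(genes, PLANTED, tau=0.1, noise_sd=0.5, seed=SEED + 2)
    studies = simulate_expression_studies(specs)
    manifest = write_study_collection(studies, DATA / "studies", truth=PLANTED)
    print(f"expression collection: {len(studies)} studies x {len(genes)} genes -> {manifest}")

    for name, symbols, polarity in (
        ("ec_positive.tsv", positive, "positive"),
        ("ec_negative.tsv", negative, "negative"),
    ):
        with open(DATA / name, "w") as fh:
            fh.write("gene\tpolarity\tn_refs\n")
            for g in symbols:
                fh.write(f"{g}\t{polarity}\t{int(rng.integers(1, 12))}\n")
    print(f"gene lists: {len(positive)} positive, {len(negative)} negative regulators")


if __name__ == "__main__":
    main()
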