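#!/usr/bin/env python
"""Significance screening of the meta-results and moderator regressions.

Applies the three-part screen (>=3 supporting studies, pooled p<0.05, LFC
> 0.59 or < -1) to the mega-analysis table from 03, then regresses each
significant gene's per-study effect sizes on the study-level moderators
(total sample size, region, study date). Outputs under results/screen/.

With six studies and three encoded covariates the moderator fits are close to
saturated; degenerate fits are reported as such rather than suppressed.
"""

import warnings
from pathlib import Path

import pandas as pd

from coimeta.errors import DegenerateDesignWarning
from coimeta.io import read_study_manifest
from coimeta.screening import SignificanceCriteria, apply_criteria, moderator_regression

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "analysis_data"
OUT = ROOT / "results" / "screen"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    meta = pd.read_csv(ROOT / "results" / "mega" / "meta_results.tsv", sep="\t")
    effects = pd.read_csv(ROOT / "results" / "mega" / "study_effects.tsv", sep="\t")

    criteria = SignificanceCriteria()
    up, down, rejected = apply_criteria(meta, criteria)
    up.to_csv(OUT / "significant_up.tsv", sep="\t", index=False, float_format="%.6g")
    down.to_csv(OUT / "significant_down.tsv", sep="\t", index=False, float_format="%.6g")
    rejected.to_csv(OUT / "rejected.tsv", sep="\t", index=False, float_format="%.6g")
    print(f"screen: {sorted(up['gene'])} up, {sorted(down['gene'])} down, "
          f"{len(rejected)} rejected")
    print(rejected["reason"].value_counts().to_string())

    studies = read_study_manifest(DATA / "studies" / "manifest.tsv")
    moderators = pd.DataFrame(
        {
            "study_id": [s.study_id for s in studies],
            "sample_size": [s.n_case + s.n_control for s in studies],
            "region": [s.region for s in studies],
            "study_date": [s.study_date for s in studies],
        }
    )
    rows = []
    for gene in list(up["gene"]) + list(down["gene"]):
        eff = effects[effects["gene"] == gene][["gene", "study_id", "lfc"]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateDesignWarning)
            fit = moderator_regression(eff, moderators)
        if fit.degenerate:
            rows.append({"gene": gene, "degenerate": True, "note": fit.reason})
            continue
        row = {"gene": gene, "degenerate": False, "note": ""}
        for term in fit.result.table.index:
            if term != "intercept":
                row[f"p_{term}"] = fit.result.table.loc[term, "p_value"]
        rows.append(row)
    mods = pd.DataFrame(rows)
    mods.to_csv(OUT / "moderator_pvalues.tsv", sep="\t", index=False, float_format="%.4g")
    print(mods.to_string(index=False))


if __name__ == "__main__":
    main()
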