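#!/usr/bin/env python
"""Fisher-exact overlap of disease-linked candidate gene sets.

Simulates two regulator sets of the sizes used throughout the analysis (47
and 83 genes) over a 2000-gene background with a planted overlap, tests the
overlap against the hypergeometric null, and also tests the overlap between
the screen's significant genes and the negative-regulator list. Output:
results/overlap.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from coimeta.overlap import GeneSet, fisher_overlap, read_gene_sets
from coimeta.synthetic import simulate_gene_sets

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "analysis_data"
OUT = ROOT / "results"

SEED = 20240905
N_BACKGROUND = 2000  # plausible literature-mined regulator universe


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []

    # planted-overlap benchmark: 47- and 83-gene sets sharing 25 symbols
    set_a, set_b, background = simulate_gene_sets(N_BACKGROUND, 47, 83, 25, seed=SEED)
    r = fisher_overlap(set_a, set_b, len(background))
    rows.append({"comparison": "planted_47x83_overlap25", **r.__dict__})
    print(
        f"planted sets: |A|=47 |B|=83 overlap=25 of {N_BACKGROUND} -> "
        f"p={r.p_value:.3e}, OR={r.odds_ratio:.2f}"
    )

    # screen hits vs the negative-regulator candidate list
    up = pd.read_csv(OUT / "screen" / "significant_up.tsv", sep="\t")
    down = pd.read_csv(OUT / "screen" / "significant_down.tsv", sep="\t")
    hits = GeneSet("screen_hits", frozenset(up["gene"]) | frozenset(down["gene"]))
    negative = read_gene_sets(DATA / "ec_negative.tsv")
    r2 = fisher_overlap(hits, negative, N_BACKGROUND)
    rows.append({"comparison": "screen_hits_x_negative_regulators", **r2.__dict__})
    print(
        f"screen hits ({len(hits)}) vs negative regulators ({len(negative)}): "
        f"overlap={r2.n_overlap}, p={r2.p_value:.3e}"
    )

    pd.DataFrame(rows).to_csv(OUT / "overlap.tsv", sep="\t", index=False)
    with open(OUT / "overlap.json", "w") as fh:
        json.dump(rows, fh, indent=2, default=str)
        fh.write("\n")


if __name__ == "__main__":
    main()
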