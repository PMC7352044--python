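"""Gene-set overlap against a hypergeometric null (Fisher's exact test).

Given two candidate sets A and B drawn from a background universe of size N,
the 2x2 table is

    | in A & B | in A only |
    | in B only | in neither |

and the enrichment p-value is the one-sided upper-tail hypergeometric
probability P(X >= |A & B|). The background size is a required input — there
is no defensible default universe — and the test direction is enrichment by
default, with the two-sided alternative exposed as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError

__all__ = ["GeneSet", "OverlapResult", "fisher_overlap", "read_gene_sets"]

_POLARITIES = {"positive", "negative", "mixed"}


@dataclass(frozen=True)
class GeneSet:
    """A polarity-tagged candidate gene list; symbols are case-normalized."""

    name: str
    genes: frozenset[str]
    polarity: str = "mixed"
    ref_counts: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.polarity not in _POLARITIES:
            raise ParameterError(f"polarity must be one of {sorted(_POLARITIES)}")
        normalized = frozenset(g.upper() for g in self.genes)
        object.__setattr__(self, "genes", normalized)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class OverlapResult:
    n_background: int
    n_a: int
    n_b: int
    n_overlap: int
    p_value: float
    odds_ratio: float
    haldane_corrected: bool = False


def fisher_overlap(
    set_a: GeneSet, set_b: GeneSet, n_background: int, alternative: str = "greater"
) -> OverlapResult:
    """Fisher's exact test of the overlap of two gene sets.

    ``alternative='greater'`` (default) tests enrichment via the upper-tail
    hypergeometric sum. The sample odds ratio uses the Haldane–Anscombe +0.5
    correction only when a table cell is zero (flagged in the result).
    """
    union = set_a.genes | set_b.genes
    if n_background < len(union):
        raise ParameterError(
            f"background ({n_background}) smaller than the union of the sets ({len(union)})"
        )
    n_a, n_b = len(set_a), len(set_b)
    k = len(set_a.genes & set_b.genes)
    table = [[k, n_a - k], [n_b - k, n_background - n_a - n_b + k]]
    p = float(stats.fisher_exact(table, alternative=alternative)[1])

    cells = [c for row in table for c in row]
    corrected = any(c == 0 for c in cells)
    if corrected:
        a, b, c, d = (c + 0.5 for c in cells)
    else:
        a, b, c, d = cells
    odds = (a * d) / (b * c)
    return OverlapResult(
        n_background=n_background,
        n_a=n_a,
        n_b=n_b,
        n_overlap=k,
        p_value=p,
        odds_ratio=float(odds),
        haldane_corrected=corrected,
    )


def read_gene_sets(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a polarity-tagged gene list from TSV (columns: gene, polarity[, n_refs]).

    Duplicate symbols (case-insensitive) are collapsed with a warning;
    malformed rows raise a :class:`DataError` naming the line. The set's
    polarity is 'mixed' when both positive and negative rows occur.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "polarity"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")

    seen: dict[str, str] = {}
    polarities: set[str] = set()
    ref_counts: list[tuple[str, int]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after the header
        gene = (row.gene or "").strip() if isinstance(row.gene, str) else ""
        pol = (row.polarity or "").strip().lower() if isinstance(row.polarity, str) else ""
        if not gene:
            raise DataError(f"{path}: empty gene symbol at line {line}")
        if pol not in {"positive", "negative"}:
            raise DataError(f"{path}: invalid polarity {pol!r} at line {line}")
        symbol = gene.upper()
        if symbol in seen:
            warnings.warn(
                f"{path}: duplicate symbol {symbol} at line {line} collapsed",
                UserWarning,
                stacklevel=2,
            )
            continue
        seen[symbol] = pol
        polarities.add(pol)
        if "n_refs" in df.columns:
            raw = getattr(row, "n_refs")
            try:
                n_refs = int(raw)
            except (TypeError, ValueError):
                raise DataError(f"{path}: invalid n_refs {raw!r} at line {line}") from None
            if n_refs < 1:
                raise DataError(f"{path}: n_refs must be >= 1 at line {line}")
            ref_counts.append((symbol, n_refs))

    polarity = polarities.pop() if len(polarities) == 1 else "mixed"
    return GeneSet(
        name=name or path.stem,
        genes=frozenset(seen),
        polarity=polarity,
        ref_counts=tuple(ref_counts),
    )
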