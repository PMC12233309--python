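"""Cross-dataset overlap statistics and recurrence counting."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from scipy import stats

__all__ = ["OverlapReport", "overlap_stats", "count_recurrent_genes"]


def _round_half_up(value: float, digits: int = 1) -> float:
    return float(Decimal(repr(value)).quantize(
        Decimal("1." + "0" * digits), rounding=ROUND_HALF_UP
    ))


@dataclass
class OverlapReport:
    """Overlap of set A with set B inside a stated universe.

    ``percent`` is 100 * overlap / |A| (rounded half-up to one decimal in
    ``percent_rounded``); ``pvalue`` is the upper-tail hypergeometric
    probability P(X >= overlap) of drawing |A| items from the universe
    with |B| marked successes.
    """

    n_a: int
    n_b: int
    n_overlap: int
    n_universe: int
    percent: float
    percent_rounded: float
    pvalue: float


def overlap_stats(set_a, set_b, universe) -> OverlapReport:
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u:
        raise ValueError(f"set A not contained in universe: {sorted(a - u)[:5]}")
    if not b <= u:
        raise ValueError(f"set B not contained in universe: {sorted(b - u)[:5]}")
    k = len(a & b)
    percent = 100.0 * k / len(a) if a else 0.0
    # P(X >= k), X ~ Hypergeom(population |U|, successes |B|, draws |A|)
    pvalue = float(stats.hypergeom.sf(k - 1, len(u), len(b), len(a)))
    return OverlapReport(
        n_a=len(a),
        n_b=len(b),
        n_overlap=k,
        n_universe=len(u),
        percent=percent,
        percent_rounded=_round_half_up(percent, 1),
        pvalue=pvalue,
    )


def count_recurrent_genes(mutations: pd.DataFrame, min_count: int = 5) -> pd.DataFrame:
    """Genes with at least ``min_count`` mutation events.

    ``mutations`` needs a ``gene`` column, one row per mutation event.
    Returns a frame (gene, n_mutations) sorted by count descending then
    gene id.
    """
    if "gene" not in mutations.columns:
        raise ValueError("mutation table needs a 'gene' column")
    counts = mutations.groupby("gene").size().rename("n_mutations").reset_index()
    out = counts[counts["n_mutations"] >= min_count]
    return out.sort_values(
        ["n_mutations", "gene"], ascending=[False, True]
    ).reset_index(drop=True)
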