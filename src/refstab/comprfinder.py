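"""Composite ranking of stability algorithms.

Different stability algorithms report values on incommensurate scales
(geNorm M values, model variances, cycles), so they cannot be averaged
directly, and averaging their integer ranks (the RefFinder approach)
flattens the real spacing between genes.  The composite score implemented
here instead min-max standardizes each algorithm's column,

    delta_A = A_max - A_min
    A'_i    = (A_i - A_min) / delta_A,

so every column spans [0, 1] with its most stable gene at 0 and least
stable at 1, and then averages the standardized values over the n
algorithms into a final score

    FS_i = (A'_i + B'_i + ... ) / n,

ranked ascending (lower FS = more stable).  Because min-max scaling is
invariant under strictly increasing affine transforms of a column, the
composite ranking is robust to each algorithm's arbitrary scale.

A geometric-mean-of-ranks comparator (the RefFinder convention) is also
provided for side-by-side comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import StabilitySeries, series_to_frame
from .errors import GeneSetError, OrientationError, ShapeError

__all__ = ["ComprFinderResult", "comprfinder", "reffinder_score", "comparison_table"]


@dataclass
class ComprFinderResult:
    input_table: pd.DataFrame        # gene x algorithm raw stability values
    standardized: pd.DataFrame       # gene x algorithm values in [0, 1]
    column_range: pd.Series          # delta_A per algorithm
    final_score: pd.Series           # FS per gene
    ranking: pd.Series               # gene -> rank, 1 = most stable
    n_algorithms: int
    constant_columns: list[str]
    dropped_genes: list[str]


def _validated_table(
    series: list[StabilitySeries], strict_missing: bool
) -> tuple[pd.DataFrame, list[str]]:
    if len(series) < 2:
        raise ShapeError("need at least 2 stability series to aggregate")
    for s in series:
        if not s.lower_is_stable:
            raise OrientationError(
                f"series {s.algorithm!r} is oriented higher-is-stable; negate it first"
            )
    gene_sets = [set(s.gene_ids) for s in series]
    union = set.union(*gene_sets)
    common = set.intersection(*gene_sets)
    dropped = sorted(union - common)
    if dropped:
        if strict_missing:
            raise GeneSetError(f"gene sets differ across series: missing {dropped}")
        warnings.warn(
            f"dropping genes absent from some series: {dropped}", stacklevel=3
        )
    if len(common) < 2:
        raise ShapeError("need at least 2 genes shared by all series")
    table = series_to_frame(series).loc[sorted(common)]
    # preserve the first series' gene order for readability
    order = [g for g in series[0].gene_ids if g in common]
    return table.loc[order], dropped


def comprfinder(
    series: list[StabilitySeries], strict_missing: bool = False
) -> ComprFinderResult:
    """Min-max standardize each algorithm's values and average into FS."""
    table, dropped = _validated_table(series, strict_missing)
    rng = table.max() - table.min()
    constant = list(rng.index[rng == 0.0])
    std = table.copy()
    for col in table.columns:
        if rng[col] == 0.0:
            # a non-discriminating column should not separate genes
            std[col] = 0.0
        else:
            std[col] = (table[col] - table[col].min()) / rng[col]
    fs = std.mean(axis=1)
    order = sorted(fs.index, key=lambda g: (fs[g], g))
    ranking = pd.Series(
        np.arange(1, len(order) + 1), index=pd.Index(order, name="gene"), name="rank"
    )
    return ComprFinderResult(
        input_table=table,
        standardized=std,
        column_range=rng,
        final_score=fs.rename("FS"),
        ranking=ranking,
        n_algorithms=table.shape[1],
        constant_columns=constant,
        dropped_genes=dropped,
    )


def reffinder_score(
    series: list[StabilitySeries], strict_missing: bool = False
) -> pd.Series:
    """Geometric mean of each gene's per-algorithm ranks (ties -> average)."""
    table, _ = _validated_table(series, strict_missing)
    ranks = pd.DataFrame(
        {col: stats.rankdata(table[col].to_numpy()) for col in table.columns},
        index=table.index,
    )
    return pd.Series(
        np.exp(np.log(ranks.to_numpy()).mean(axis=1)),
        index=table.index,
        name="reffinder_score",
    )


def comparison_table(series: list[StabilitySeries]) -> pd.DataFrame:
    """Side-by-side composite-score vs geometric-mean-of-ranks comparison."""
    res = comprfinder(series)
    ref = reffinder_score(series)
    ref_order = sorted(ref.index, key=lambda g: (ref[g], g))
    ref_rank = pd.Series(
        np.arange(1, len(ref_order) + 1), index=pd.Index(ref_order, name="gene")
    )
    out = pd.DataFrame(
        {
            "FS": res.final_score,
            "comprfinder_rank": res.ranking.reindex(res.final_score.index),
            "reffinder_score": ref,
            "reffinder_rank": ref_rank.reindex(res.final_score.index),
        }
    )
    out.index.name = "gene"
    return out.sort_values("comprfinder_rank")
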