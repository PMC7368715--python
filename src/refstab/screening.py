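"""Transcriptome screening of housekeeping-gene candidates.

Candidates are genes that are (i) well expressed and (ii) uniform across
samples.  Four per-gene metrics over an FPKM matrix quantify this:

mean FPKM
    expression level; candidates should be comfortably detectable.
CV (%)
    100 * sample SD / mean of the FPKM vector; low CV = uniform expression.
MFC
    maximum fold change, max/min FPKM; undefined when the minimum is 0.
SPM / DPM
    the specificity and dispersion measures of the pattern-gene approach:
    SPM_i = x_i^2 / sum_j x_j^2 per sample, and DPM = sample SD of the SPM
    vector scaled by sqrt(n).  DPM is 0 for a constant non-zero gene and 1
    for a one-hot gene, so housekeeping-like genes sit near 0.

Candidates are the intersection of the four thresholded criterion sets
(the Venn-diagram step of the screening workflow).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix
from .errors import DomainError, EmptySetError

__all__ = [
    "GeneScreenSummary",
    "ScreenThresholds",
    "ScreenResult",
    "prefilter_genes",
    "gene_summary",
    "summary_frame",
    "screen_candidates",
    "rank_by_cv",
]


@dataclass(frozen=True)
class GeneScreenSummary:
    gene: str
    mean_fpkm: float
    cv_pct: float
    mfc: float | None  # None when min FPKM == 0 (undefined fold change)
    dpm: float
    spm: np.ndarray  # per-sample specificity measure, sums to 1


@dataclass(frozen=True)
class ScreenThresholds:
    """Screening cut-offs.

    FPKM and CV thresholds are inclusive (>= / <=); DPM and MFC are strict
    (<), matching the conventional phrasing "FPKM >= 10", "CV <= 20%",
    "DPM < 0.2", "MFC < 2.5".  Exactly one FPKM rule is active: the absolute
    cut-off (default) or the percentile rule.
    """

    min_mean_fpkm: float = 10.0
    max_cv_pct: float = 20.0
    max_dpm: float = 0.2
    max_mfc: float = 2.5
    fpkm_percentile_alternative: float | None = None  # e.g. 80.0 to use the 80th pct

    def __post_init__(self) -> None:
        for name in ("min_mean_fpkm", "max_cv_pct", "max_dpm", "max_mfc"):
            if getattr(self, name) <= 0:
                raise DomainError(f"threshold {name} must be positive")
        if self.fpkm_percentile_alternative is not None and not (
            0 < self.fpkm_percentile_alternative < 100
        ):
            raise DomainError("fpkm_percentile_alternative must lie in (0, 100)")


@dataclass
class ScreenResult:
    criterion_sets: dict[str, set[str]]  # keys: fpkm, cv, dpm, mfc
    intersection: set[str]
    counts: dict[str, int]  # the four criterion counts plus 'intersection'
    fpkm_cutoff_used: float


def prefilter_genes(
    m: ExpressionMatrix, zero_policy: str = "any-zero"
) -> tuple[ExpressionMatrix, int]:
    """Remove zero-expression genes before computing screening metrics.

    ``any-zero`` drops a gene if any sample has FPKM 0 (the default: a true
    housekeeping gene is never off); ``all-zero`` drops only genes that are
    0 everywhere.  Returns the filtered matrix and the removed-gene count.
    """
    arr = m.values.to_numpy()
    if zero_policy == "any-zero":
        keep = (arr > 0).all(axis=1)
    elif zero_policy == "all-zero":
        keep = (arr > 0).any(axis=1)
    else:
        raise ValueError(f"unknown zero_policy: {zero_policy!r}")
    removed = int((~keep).sum())
    if not keep.any():
        raise EmptySetError("prefilter removed every gene")
    return ExpressionMatrix(m.values.loc[keep].copy()), removed


def _summary_one(gene: str, x: np.ndarray) -> GeneScreenSummary:
    n = x.size
    mean = float(x.mean())
    if mean == 0.0:
        raise DomainError(f"all-zero gene reached gene_summary: {gene!r}")
    sd = float(x.std(ddof=1))
    cv_pct = 100.0 * sd / mean
    xmin = float(x.min())
    mfc = float(x.max() / xmin) if xmin > 0 else None
    spm = x.astype(float) ** 2
    spm /= spm.sum()
    dpm = float(spm.std(ddof=1) * np.sqrt(n))
    return GeneScreenSummary(gene, mean, cv_pct, mfc, dpm, spm)


def gene_summary(m: ExpressionMatrix) -> list[GeneScreenSummary]:
    """Per-gene screening metrics; genes must have been prefiltered of zeros."""
    arr = m.values.to_numpy()
    return [_summary_one(g, arr[i]) for i, g in enumerate(m.gene_ids)]


def summary_frame(summaries: list[GeneScreenSummary]) -> pd.DataFrame:
    """Tabular view (gene, mean_fpkm, cv_pct, mfc, dpm) for reports."""
    return pd.DataFrame(
        {
            "mean_fpkm": [s.mean_fpkm for s in summaries],
            "cv_pct": [s.cv_pct for s in summaries],
            "mfc": [np.nan if s.mfc is None else s.mfc for s in summaries],
            "dpm": [s.dpm for s in summaries],
        },
        index=pd.Index([s.gene for s in summaries], name="gene"),
    )


def screen_candidates(
    summaries: list[GeneScreenSummary], t: ScreenThresholds | None = None
) -> ScreenResult:
    """Threshold the four metrics and intersect the criterion sets."""
    t = t or ScreenThresholds()
    means = np.array([s.mean_fpkm for s in summaries])
    if t.fpkm_percentile_alternative is not None:
        fpkm_cut = float(np.percentile(means, t.fpkm_percentile_alternative))
    else:
        fpkm_cut = float(t.min_mean_fpkm)
    sets: dict[str, set[str]] = {
        "fpkm": {s.gene for s in summaries if s.mean_fpkm >= fpkm_cut},
        "cv": {s.gene for s in summaries if s.cv_pct <= t.max_cv_pct},
        "dpm": {s.gene for s in summaries if s.dpm < t.max_dpm},
        # genes with undefined MFC (a zero sample) never qualify
        "mfc": {s.gene for s in summaries if s.mfc is not None and s.mfc < t.max_mfc},
    }
    inter = sets["fpkm"] & sets["cv"] & sets["dpm"] & sets["mfc"]
    counts = {k: len(v) for k, v in sets.items()}
    counts["intersection"] = len(inter)
    return ScreenResult(sets, inter, counts, fpkm_cut)


def rank_by_cv(summaries: list[GeneScreenSummary]) -> pd.DataFrame:
    """Genes ordered by ascending CV; ties broken lexicographically by id."""
    order = sorted(summaries, key=lambda s: (s.cv_pct, s.gene))
    return pd.DataFrame(
        {
            "cv_pct": [s.cv_pct for s in order],
            "rank": np.arange(1, len(order) + 1),
        },
        index=pd.Index([s.gene for s in order], name="gene"),
    )
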