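"""Validation-stage utilities: normalization factors, relative expression,
stage comparisons, scheme correlation, and dilution-series efficiency.

A normalization scheme is a set of reference genes; its per-sample
normalization factor NF is the geometric mean of the member genes' Ct
values (a single-gene scheme's NF is simply that gene's Ct).  Target-gene
expression relative to a scheme is 2**(-(Ct_target - NF)).  Stage effects
are tested with a classical paired t-test on the relative expression of
the same subjects across two levels, and alternative schemes are compared
by Pearson correlation of the pooled relative-expression vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CtMatrix, StudyDesign
from .errors import DesignMismatchError, DomainError, GeneSetError, ShapeError

__all__ = [
    "NormalizationScheme",
    "RelativeExpressionTable",
    "normalization_factor",
    "relative_expression",
    "stage_comparison",
    "scheme_correlation",
    "efficiency_from_dilutions",
]


@dataclass
class NormalizationScheme:
    """A labelled set of reference genes used to build per-sample NFs."""

    label: str
    hkgs: tuple[str, ...]

    def __init__(self, label: str, hkgs: Iterable[str]):
        self.label = label
        self.hkgs = tuple(dict.fromkeys(hkgs))
        if not self.hkgs:
            raise GeneSetError("a normalization scheme needs at least one gene")


@dataclass
class RelativeExpressionTable:
    """Target gene x sample table of 2**-deltaCt values for one scheme."""

    scheme: str
    values: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def normalization_factor(
    ct: CtMatrix, hkgs: Iterable[str], nf_mode: str = "ct-geomean"
) -> pd.Series:
    """Per-sample normalization factor in Ct units.

    ``nf_mode='ct-geomean'`` (default) takes the geometric mean of the
    member genes' raw Ct values.  ``nf_mode='quantity-geomean'`` takes the
    geometric mean of the relative quantities 2**-Ct, which in Ct units is
    the arithmetic mean Ct; only the latter is exactly invariant under a
    global Ct offset, but the two differ by well under 0.1 cycle in the
    usual Ct range because the geometric and arithmetic means of values
    near 20-30 cycles almost coincide.
    """
    hkgs = list(dict.fromkeys(hkgs))
    unknown = [g for g in hkgs if g not in ct.gene_ids]
    if unknown:
        raise GeneSetError(f"unknown reference gene id(s): {unknown}")
    sub = ct.ct.loc[hkgs]
    if sub.isna().any().any():
        raise DomainError(f"missing Ct among reference genes {hkgs}")
    if nf_mode == "ct-geomean":
        nf = np.exp(np.log(sub.to_numpy()).mean(axis=0))
    elif nf_mode == "quantity-geomean":
        nf = sub.to_numpy().mean(axis=0)
    else:
        raise ValueError(f"unknown nf_mode: {nf_mode!r}")
    return pd.Series(nf, index=ct.ct.columns, name="NF")


def relative_expression(
    target_ct: CtMatrix,
    scheme: NormalizationScheme,
    reference_ct: CtMatrix | None = None,
    nf_mode: str = "ct-geomean",
) -> RelativeExpressionTable:
    """2**-(Ct_target - NF) per target gene and sample.

    ``reference_ct`` holds the scheme's reference genes; it defaults to
    ``target_ct`` when reference and target genes live in one table.
    """
    ref = reference_ct if reference_ct is not None else target_ct
    if list(ref.sample_ids) != list(target_ct.sample_ids):
        raise DesignMismatchError(
            "target and reference Ct tables cover different samples"
        )
    nf = normalization_factor(ref, scheme.hkgs, nf_mode=nf_mode)
    targets = [g for g in target_ct.gene_ids if g not in scheme.hkgs]
    if not targets:
        raise GeneSetError("no target genes outside the scheme")
    delta = target_ct.ct.loc[targets] - nf
    return RelativeExpressionTable(scheme.label, 2.0 ** (-delta))


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def stage_comparison(
    expr: RelativeExpressionTable,
    design: StudyDesign,
    factor: str,
    pairing: dict[str, str],
    levels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Paired t-tests of relative expression between every two factor levels.

    ``pairing`` maps each sample id to a subject key (the same animal
    measured at every level).  Returns one row per (target gene, level
    pair) with the t statistic, two-sided p, n pairs, the level means, and
    significance stars at 0.05 (*) and 0.01 (**).
    """
    level_of = design.level_of(factor)
    missing = [s for s in expr.sample_ids if s not in level_of]
    if missing:
        raise DesignMismatchError(f"samples without a {factor!r} level: {missing}")
    unpaired = [s for s in expr.sample_ids if s not in pairing]
    if unpaired:
        raise DesignMismatchError(f"samples without a pairing key: {unpaired}")
    use_levels = list(levels) if levels else sorted(set(level_of[s] for s in expr.sample_ids))

    # subject x level sample lookup
    by_level: dict[str, dict[str, str]] = {lv: {} for lv in use_levels}
    for s in expr.sample_ids:
        lv = level_of[s]
        if lv in by_level:
            by_level[lv][pairing[s]] = s

    rows = []
    for gene in expr.values.index:
        for i, a in enumerate(use_levels):
            for b in use_levels[i + 1:]:
                subjects = sorted(set(by_level[a]) & set(by_level[b]))
                if len(subjects) < 2:
                    raise DesignMismatchError(
                        f"fewer than 2 complete pairs for levels {a!r} vs {b!r}"
                    )
                xa = expr.values.loc[gene, [by_level[a][s] for s in subjects]].to_numpy()
                xb = expr.values.loc[gene, [by_level[b][s] for s in subjects]].to_numpy()
                if np.allclose(xa, xb):
                    t, p = 0.0, 1.0  # identical pairs carry no evidence
                else:
                    t, p = stats.ttest_rel(xa, xb)
                rows.append(
                    {
                        "target": gene,
                        "level_a": a,
                        "level_b": b,
                        "n_pairs": len(subjects),
                        "mean_a": float(xa.mean()),
                        "mean_b": float(xb.mean()),
                        "sem_a": float(xa.std(ddof=1) / np.sqrt(len(xa))),
                        "sem_b": float(xb.std(ddof=1) / np.sqrt(len(xb))),
                        "t": float(t),
                        "p": float(p),
                        "stars": _stars(float(p)),
                    }
                )
    return pd.DataFrame(rows)


def scheme_correlation(
    tables: list[RelativeExpressionTable], per_target: bool = False
) -> pd.DataFrame:
    """Pearson correlation between schemes' pooled relative expression.

    All tables must cover identical target x sample cells; each scheme's
    values are flattened to one vector (all targets x all samples pooled),
    and the symmetric correlation matrix is returned with two-sided
    p-values in a parallel ``p_...`` block when requested via attrs.
    """
    if len(tables) < 2:
        raise ShapeError("need at least 2 schemes to correlate")
    ref_shape = tables[0].values.shape
    ref_index = tables[0].values.index
    ref_cols = tables[0].values.columns
    for t in tables[1:]:
        if t.values.shape != ref_shape or not (
            t.values.index.equals(ref_index) and t.values.columns.equals(ref_cols)
        ):
            raise ShapeError("relative-expression tables cover different cells")
    labels = [t.scheme for t in tables]
    vecs = {t.scheme: t.values.to_numpy().ravel() for t in tables}
    r = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    p = pd.DataFrame(np.zeros((len(labels), len(labels))), index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            rv, pv = stats.pearsonr(vecs[a], vecs[b])
            r.loc[a, b] = r.loc[b, a] = float(rv)
            p.loc[a, b] = p.loc[b, a] = float(pv)
    r.attrs["p_values"] = p
    return r


def efficiency_from_dilutions(points: Sequence[tuple[float, float]]) -> dict[str, float]:
    """Amplification efficiency from a dilution-series standard curve.

    ``points`` are (log10 template input, Ct) pairs from a serial dilution.
    The least-squares slope of Ct on log10 input gives the per-cycle
    amplification: efficiency % = 100 * (10**(-1/slope) - 1), with 100%
    corresponding to perfect doubling (slope -3.3219).
    """
    if len(points) < 3:
        raise ShapeError("need at least 3 dilution points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise DomainError(
            f"non-negative standard-curve slope ({fit.slope:.3f}): not amplifying"
        )
    e_pct = 100.0 * (10.0 ** (-1.0 / fit.slope) - 1.0)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "efficiency_pct": float(e_pct),
        "r_squared": float(fit.rvalue ** 2),
    }
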