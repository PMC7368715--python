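"""The four Ct-based reference-gene stability algorithms.

All four operate on a gene x sample table of quantification cycles (Ct) and
return a per-gene stability value oriented lower-is-more-stable:

geNorm
    pairwise-variation approach: V_jk is the sample SD of log2(Q_j/Q_k)
    over samples, M_j the mean of V_jk over partners k.  The least stable
    gene (highest M) is excluded and M recomputed until two genes remain,
    which geNorm itself cannot separate; the ranking follows the exclusion
    order.  Pairwise variations V_n between normalization factors built
    from the top n and n+1 genes indicate how many reference genes are
    needed (V_n < 0.15 is the customary cut-off).
NormFinder
    model-based variance decomposition of log quantities into intragroup
    variance and intergroup deviation per gene, combined into one
    stability value per gene (averaged over groups).
BestKeeper
    descriptive statistics on raw Ct: the stability value is the mean
    absolute deviation of a gene's Ct about its central Ct (in cycles),
    plus each gene's Pearson correlation with the per-sample geometric
    mean of all genes (the BestKeeper index).
Comparative delta-Ct method
    for each gene pair, the SD over samples of their Ct difference; a
    gene's stability is the mean pair SD over all partners.

Ct values enter geNorm/NormFinder as relative quantities anchored at each
gene's minimum Ct, Q = E**(Ct_min - Ct), with amplification base E = 2
unless per-gene efficiencies are supplied.  The anchoring constant cancels
in every ratio, so results are invariant to per-gene Ct offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CtMatrix, StabilitySeries, StudyDesign
from .errors import DesignMismatchError, DomainError, ShapeError

__all__ = [
    "RelativeQuantityMatrix",
    "GenormResult",
    "BestKeeperStats",
    "ct_to_quantity",
    "genorm",
    "normfinder",
    "bestkeeper",
    "delta_ct",
    "run_all",
]

E_MIN, E_MAX = 1.6, 2.1  # plausible per-cycle amplification bases


@dataclass
class RelativeQuantityMatrix:
    """Gene x sample relative quantities Q in (0, 1], anchored per gene."""

    q: pd.DataFrame
    efficiencies: pd.Series  # per-gene base E actually used

    @property
    def gene_ids(self) -> list[str]:
        return list(self.q.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.q.columns)


@dataclass
class GenormResult:
    m_values: pd.Series          # full-panel M per gene
    exclusion_order: list[str]   # first excluded (least stable) ... last
    ranking: pd.Series           # gene -> rank 1..G (1 = most stable)
    pairwise_variation: pd.Series  # index 'V2/V3', 'V3/V4', ...
    stage_m: dict[int, pd.Series] = field(default_factory=dict)  # panel size -> M

    @property
    def series(self) -> StabilitySeries:
        return StabilitySeries("geNorm", self.m_values, lower_is_stable=True)


@dataclass
class BestKeeperStats:
    per_gene: pd.DataFrame  # geo_mean, arith_mean, min, max, std_value, cv_pct
    index: pd.Series        # per-sample geometric mean Ct
    correlation: pd.DataFrame  # per gene: r, p versus the index
    center: str

    @property
    def series(self) -> StabilitySeries:
        return StabilitySeries(
            "BestKeeper", self.per_gene["std_value"], lower_is_stable=True,
            flags={"center": self.center},
        )


def _resolve_efficiencies(
    genes: list[str], efficiencies: float | Mapping[str, float] | pd.Series | None
) -> pd.Series:
    if efficiencies is None:
        eff = pd.Series(2.0, index=genes)
    elif np.isscalar(efficiencies):
        eff = pd.Series(float(efficiencies), index=genes)
    else:
        eff = pd.Series(efficiencies, dtype=float)
        missing = [g for g in genes if g not in eff.index]
        if missing:
            raise DomainError(f"no amplification base for genes: {missing}")
        eff = eff.reindex(genes)
    bad = eff[(eff < E_MIN) | (eff > E_MAX)]
    if len(bad):
        raise DomainError(
            f"amplification base outside [{E_MIN}, {E_MAX}]: {bad.to_dict()}"
        )
    return eff


def ct_to_quantity(
    ct: CtMatrix,
    efficiencies: float | Mapping[str, float] | pd.Series | None = None,
) -> RelativeQuantityMatrix:
    """Anchored relative quantities Q = E**(Ct_min,gene - Ct)."""
    ct.require_complete()
    eff = _resolve_efficiencies(ct.gene_ids, efficiencies)
    arr = ct.ct.to_numpy(dtype=float)
    base = eff.to_numpy()[:, None]
    q = base ** (arr.min(axis=1, keepdims=True) - arr)
    return RelativeQuantityMatrix(
        pd.DataFrame(q, index=ct.ct.index, columns=ct.ct.columns), eff
    )


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------

def _genorm_m(logq: pd.DataFrame) -> pd.Series:
    """M_j = mean over partners k of SD_samples(log2 Q_j - log2 Q_k)."""
    genes = list(logq.index)
    arr = logq.to_numpy()
    G = len(genes)
    m = np.empty(G)
    for j in range(G):
        sds = [arr[j] - arr[k] for k in range(G) if k != j]
        m[j] = np.mean([np.std(d, ddof=1) for d in sds])
    return pd.Series(m, index=logq.index)


def genorm(q: RelativeQuantityMatrix) -> GenormResult:
    """Stepwise-exclusion geNorm on relative quantities."""
    if len(q.gene_ids) < 3:
        raise ShapeError("geNorm needs at least 3 genes")
    if len(q.sample_ids) < 2:
        raise ShapeError("geNorm needs at least 2 samples")
    logq = np.log2(q.q)
    full_m = _genorm_m(logq)

    stage_m: dict[int, pd.Series] = {len(full_m): full_m}
    remaining = list(logq.index)
    exclusion: list[str] = []
    current_m = full_m
    while len(remaining) > 2:
        # least stable = highest M; ties broken by gene id for determinism
        worst = max(remaining, key=lambda g: (current_m[g], g))
        exclusion.append(worst)
        remaining = [g for g in remaining if g != worst]
        if len(remaining) > 2:
            current_m = _genorm_m(logq.loc[remaining])
            stage_m[len(remaining)] = current_m

    # ranking: excluded genes take ranks G..3; the final untouched pair is
    # ordered by its M at the 3-gene stage (geNorm itself cannot split it)
    G = len(logq.index)
    ranking = {}
    for i, g in enumerate(exclusion):
        ranking[g] = G - i
    three_stage = stage_m[3] if 3 in stage_m else full_m
    last_two = sorted(remaining, key=lambda g: (three_stage[g], g))
    ranking[last_two[0]] = 1
    ranking[last_two[1]] = 2
    rank_series = pd.Series(ranking, name="rank").sort_values()
    ordered_genes = list(rank_series.index)

    # pairwise variation between NF_n and NF_{n+1}
    v = {}
    logq_by_rank = logq.loc[ordered_genes].to_numpy()
    for n in range(2, G):
        log_nf_n = logq_by_rank[:n].mean(axis=0)       # log2 geometric mean
        log_nf_n1 = logq_by_rank[: n + 1].mean(axis=0)
        v[f"V{n}/V{n + 1}"] = float(np.std(log_nf_n - log_nf_n1, ddof=1))
    return GenormResult(
        m_values=full_m,
        exclusion_order=exclusion,
        ranking=rank_series,
        pairwise_variation=pd.Series(v, dtype=float),
        stage_m=stage_m,
    )


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------

def _two_way_residual_variance(y: np.ndarray) -> np.ndarray:
    """Per-gene residual variance of a gene x sample block after removing
    gene means, sample means and the grand mean (n-1 denominator)."""
    r = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + y.mean()
    n = y.shape[1]
    return (r ** 2).sum(axis=1) / (n - 1)


def _bias_corrected_sigma2(s: np.ndarray, k: int) -> np.ndarray:
    """Unbiased per-gene error variances from two-way residual variances.

    Solving E[s_i] = (1-2/k) sigma_i^2 + (1/k^2) sum_l sigma_l^2 gives
    sigma_i^2 = k/(k-2) * (s_i - sum_l s_l / (k (k-1))).
    """
    return (k / (k - 2)) * (s - s.sum() / (k * (k - 1)))


def normfinder(
    q: RelativeQuantityMatrix,
    design: StudyDesign | None = None,
    factor: str | None = None,
) -> StabilitySeries:
    """Model-based stability of log2 quantities (lower = more stable).

    With a design and factor, the intragroup variance and the intergroup
    deviation of each gene are estimated per group; deviations are centred
    to sum to zero over genes, shrunk toward zero by the ratio
    gamma^2 / (gamma^2 + sigma^2/n_g), and each gene's stability is the
    average over groups of |shrunk deviation| + sqrt(sigma^2/n_g).
    Without a design the model-based variance of each gene's deviation
    from the per-sample mean profile is returned.
    """
    genes = q.gene_ids
    k = len(genes)
    if k < 3:
        raise ShapeError("NormFinder needs at least 3 genes")
    y = np.log2(q.q.to_numpy())
    truncated: list[str] = []

    if design is None or factor is None:
        s = _two_way_residual_variance(y)
        sigma2 = _bias_corrected_sigma2(s, k)
        neg = sigma2 < 0
        truncated = [g for g, b in zip(genes, neg) if b]
        sigma2 = np.maximum(sigma2, 0.0)
        return StabilitySeries(
            "NormFinder",
            pd.Series(sigma2, index=q.q.index),
            lower_is_stable=True,
            flags={"grouped": False, "variance_truncated": truncated},
        )

    level_of = design.level_of(factor)
    unassigned = [s_ for s_ in q.sample_ids if s_ not in level_of]
    if unassigned:
        raise DesignMismatchError(
            f"samples missing from design for factor {factor!r}: {unassigned}"
        )
    groups: dict[str, list[str]] = {}
    for s_ in q.sample_ids:
        groups.setdefault(level_of[s_], []).append(s_)
    for level, members in groups.items():
        if len(members) < 2:
            raise DesignMismatchError(
                f"factor {factor!r} level {level!r} has fewer than 2 samples"
            )
    levels = sorted(groups)
    col = {s_: i for i, s_ in enumerate(q.sample_ids)}
    grand_gene_mean = y.mean(axis=1)

    sigma2_g = np.zeros((k, len(levels)))
    d_hat = np.zeros((k, len(levels)))
    n_g = np.zeros(len(levels))
    for gi, level in enumerate(levels):
        idx = [col[s_] for s_ in groups[level]]
        block = y[:, idx]
        n_g[gi] = len(idx)
        s = _two_way_residual_variance(block)
        sig2 = _bias_corrected_sigma2(s, k)
        truncated += [g for g, b in zip(genes, sig2 < 0) if b]
        sigma2_g[:, gi] = np.maximum(sig2, 0.0)
        z = block.mean(axis=1) - grand_gene_mean
        d_hat[:, gi] = z - z.mean()  # deviations sum to zero over genes

    samp_var = sigma2_g / n_g[None, :]
    gamma2 = max(0.0, float(d_hat.var()) - float(samp_var.mean()))
    if gamma2 > 0:
        d_tilde = d_hat * gamma2 / (gamma2 + samp_var)
    else:
        d_tilde = np.zeros_like(d_hat)
    rho = np.abs(d_tilde) + np.sqrt(samp_var)
    stability = rho.mean(axis=1)
    return StabilitySeries(
        "NormFinder",
        pd.Series(stability, index=q.q.index),
        lower_is_stable=True,
        flags={
            "grouped": True,
            "factor": factor,
            "variance_truncated": sorted(set(truncated)),
            "gamma2": gamma2,
        },
    )


# ---------------------------------------------------------------------------
# BestKeeper
# ---------------------------------------------------------------------------

def bestkeeper(ct: CtMatrix, center: str = "arith") -> BestKeeperStats:
    """Descriptive Ct statistics, stability = MAD about the central Ct.

    ``center`` picks the centring of the mean absolute deviation:
    ``'arith'`` (default) or ``'geo'``.  The BestKeeper index is the
    per-sample geometric mean of all genes' Ct; each gene's Pearson r
    against the index (with a two-sided p-value) is also reported.
    """
    ct.require_complete()
    if len(ct.sample_ids) < 2:
        raise ShapeError("BestKeeper needs at least 2 samples")
    if center not in ("arith", "geo"):
        raise ValueError(f"unknown centering: {center!r}")
    arr = ct.ct.to_numpy(dtype=float)
    arith = arr.mean(axis=1)
    geo = np.exp(np.log(arr).mean(axis=1))
    central = arith if center == "arith" else geo
    std_value = np.abs(arr - central[:, None]).mean(axis=1)
    per_gene = pd.DataFrame(
        {
            "geo_mean": geo,
            "arith_mean": arith,
            "min": arr.min(axis=1),
            "max": arr.max(axis=1),
            "std_value": std_value,
            "cv_pct": 100.0 * std_value / arith,
        },
        index=ct.ct.index,
    )
    index = pd.Series(
        np.exp(np.log(arr).mean(axis=0)), index=ct.ct.columns, name="bestkeeper_index"
    )
    corr = {}
    for g in ct.gene_ids:
        x = ct.ct.loc[g].to_numpy()
        if np.ptp(x) == 0 or np.ptp(index.to_numpy()) == 0:
            corr[g] = (np.nan, np.nan)  # undefined for constant vectors
        else:
            r, p = stats.pearsonr(x, index.to_numpy())
            corr[g] = (float(r), float(p))
    correlation = pd.DataFrame(corr, index=["r", "p"]).T
    correlation.index.name = "gene"
    return BestKeeperStats(per_gene, index, correlation, center)


# ---------------------------------------------------------------------------
# comparative delta-Ct method
# ---------------------------------------------------------------------------

def delta_ct(ct: CtMatrix) -> StabilitySeries:
    """Mean pairwise delta-Ct SD per gene (cycles; lower = more stable)."""
    ct.require_complete()
    genes = ct.gene_ids
    if len(genes) < 2:
        raise ShapeError("the delta-Ct method needs at least 2 genes")
    if len(ct.sample_ids) < 2:
        raise ShapeError("the delta-Ct method needs at least 2 samples")
    arr = ct.ct.to_numpy(dtype=float)
    G = len(genes)
    pair_sd = np.zeros((G, G))
    for j in range(G):
        for k_ in range(j + 1, G):
            sd = float(np.std(arr[j] - arr[k_], ddof=1))
            pair_sd[j, k_] = pair_sd[k_, j] = sd
    stability = pair_sd.sum(axis=1) / (G - 1)
    return StabilitySeries(
        "deltaCt", pd.Series(stability, index=ct.ct.index), lower_is_stable=True
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_all(
    ct: CtMatrix,
    design: StudyDesign | None = None,
    factor: str | None = None,
    efficiencies: float | Mapping[str, float] | pd.Series | None = None,
    bestkeeper_center: str = "arith",
) -> list[StabilitySeries]:
    """Run all four algorithms on one Ct matrix.

    Samples with any missing Ct are dropped listwise first (never imputed).
    Returns four StabilitySeries over the identical gene set, in the order
    geNorm, NormFinder, BestKeeper, deltaCt.
    """
    if ct.missing_cells():
        ct = ct.drop_incomplete_samples()
    q = ct_to_quantity(ct, efficiencies)
    return [
        genorm(q).series,
        normfinder(q, design, factor),
        bestkeeper(ct, center=bestkeeper_center).series,
        delta_ct(ct),
    ]
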