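"""Seeded generators of qPCR Ct panels and FPKM matrices with planted truth.

The Ct generator emulates a multi-factor reference-gene study: each gene
has a baseline Ct, a per-gene biological noise SD (cycles, Gaussian in Ct
space — i.e. log-normal in expression space, the standard qPCR noise
model), optional additive per-level shifts (a "regulated" gene that
stability algorithms must demote), and technical replicates with small
jitter that are collapsed by arithmetic mean.  The default design mirrors
a typical livestock qPCR panel: 12 genes, 39 samples shared across four
overlapping experimental factors (4/3/4/5 levels, 3 biological samples
per level), 3 technical replicates.

The FPKM generator plants three classes of genes for the screening stage:
housekeeping-like (high log-normal mean, low spread), variable, and
all-zero.  Truth tables record every planted parameter so tests can check
recovery against the generator's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CtMatrix, ExpressionMatrix, StudyDesign, collapse_replicates
from .errors import SpecError

__all__ = [
    "GeneCtSpec",
    "FactorSpec",
    "CtSimSpec",
    "FpkmSimSpec",
    "CtSimResult",
    "simulate_ct",
    "simulate_fpkm",
    "default_ct_spec",
    "default_fpkm_spec",
]


@dataclass(frozen=True)
class GeneCtSpec:
    name: str
    baseline_ct: float
    noise_sd: float  # cycles
    # factor -> level -> additive Ct shift (multiplicative in expression)
    shifts: dict = field(default_factory=dict)


@dataclass(frozen=True)
class FactorSpec:
    name: str
    levels: tuple[str, ...]
    samples_per_level: int = 3


@dataclass
class CtSimSpec:
    genes: list[GeneCtSpec]
    factors: list[FactorSpec]
    n_samples: int | None = None  # pool size; blocks wrap to share samples
    replicates: int = 3
    replicate_sd: float = 0.05  # cycles of technical jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genes:
            raise SpecError("need at least one gene spec")
        for g in self.genes:
            if g.noise_sd < 0:
                raise SpecError(f"negative noise SD for gene {g.name!r}")
        if self.replicates < 1:
            raise SpecError("replicates must be >= 1")
        if self.replicate_sd < 0:
            raise SpecError("replicate_sd must be >= 0")
        slots = sum(len(f.levels) * f.samples_per_level for f in self.factors)
        if self.n_samples is not None and self.n_samples > slots:
            raise SpecError(
                f"n_samples={self.n_samples} exceeds the {slots} factor-level slots"
            )


@dataclass
class CtSimResult:
    ct: CtMatrix                # technical replicates already collapsed
    design: StudyDesign
    truth: pd.DataFrame         # per gene: baseline, noise_sd, shifted flag
    long: pd.DataFrame          # replicate-level gene/sample/replicate/ct
    group_sizes: dict           # (factor, level) -> n samples


def simulate_ct(spec: CtSimSpec) -> CtSimResult:
    """Draw a Ct panel; byte-identical for a fixed spec and seed."""
    rng = np.random.default_rng(spec.seed)
    slots = sum(len(f.levels) * f.samples_per_level for f in spec.factors)
    n = spec.n_samples if spec.n_samples is not None else slots
    samples = [f"s{i + 1:02d}" for i in range(n)]

    # assign factor-level blocks over the sample pool, wrapping so that
    # later factors reuse earlier samples (as real designs reuse animals)
    rows = []
    cohort: dict[str, str] = {}
    cursor = 0
    group_sizes: dict[tuple[str, str], int] = {}
    for fi, f in enumerate(spec.factors):
        for level in f.levels:
            members = [samples[(cursor + i) % n] for i in range(f.samples_per_level)]
            cursor += f.samples_per_level
            group_sizes[(f.name, level)] = len(members)
            for s in members:
                rows.append((s, f.name, level))
                cohort.setdefault(s, f"g{fi + 1}")
    design_rows = pd.DataFrame(rows, columns=["sample", "factor", "level"])
    design_rows = design_rows.drop_duplicates(subset=["sample", "factor"], keep="first")
    cohort_rows = pd.DataFrame(
        [(s, "cohort", cohort[s]) for s in samples], columns=["sample", "factor", "level"]
    )
    design = StudyDesign(pd.concat([design_rows, cohort_rows], ignore_index=True))
    level_by_factor = {
        f.name: design.level_of(f.name) for f in spec.factors
    }

    long_records = []
    for g in spec.genes:
        bio = rng.normal(0.0, g.noise_sd, size=n)
        for j, s in enumerate(samples):
            mean_ct = g.baseline_ct + bio[j]
            for fname, shifts in g.shifts.items():
                lv = level_by_factor.get(fname, {}).get(s)
                if lv is not None:
                    mean_ct += shifts.get(lv, 0.0)
            jitter = rng.normal(0.0, spec.replicate_sd, size=spec.replicates)
            for r in range(spec.replicates):
                long_records.append((g.name, s, r + 1, mean_ct + jitter[r]))
    long = pd.DataFrame(long_records, columns=["gene", "sample", "replicate", "ct"])
    ct = collapse_replicates(long)
    truth = pd.DataFrame(
        {
            "baseline_ct": [g.baseline_ct for g in spec.genes],
            "noise_sd": [g.noise_sd for g in spec.genes],
            "shifted": [bool(g.shifts) for g in spec.genes],
        },
        index=pd.Index([g.name for g in spec.genes], name="gene"),
    )
    return CtSimResult(ct, design, truth, long, group_sizes)


def default_ct_spec(seed: int = 0, noisy_gene_sd: float = 1.0) -> CtSimSpec:
    """The package's reference simulation: 12 genes x 39 shared samples.

    Eleven genes carry biological noise SDs from 0.10 to 0.30 cycles (the
    range seen for credible reference genes); the twelfth is a poor
    reference with a 1.0-cycle SD that every algorithm should rank last.
    """
    sds = [0.10, 0.12, 0.14, 0.16, 0.18, 0.20, 0.22, 0.24, 0.26, 0.28, 0.30]
    baselines = np.linspace(21.0, 29.0, 12)
    genes = [
        GeneCtSpec(f"HKG{i + 1:02d}", float(baselines[i]), sds[i]) for i in range(11)
    ]
    genes.append(GeneCtSpec("HKG12", float(baselines[11]), noisy_gene_sd))
    factors = [
        FactorSpec("stage", ("P0", "P60", "P240", "Adult")),
        FactorSpec("cycle", ("T1", "T2", "T3")),
        FactorSpec("breed", ("B1", "B2", "B3", "B4")),
        FactorSpec("site", ("forearm", "dorsal", "lateral", "thigh", "inner")),
    ]
    return CtSimSpec(genes=genes, factors=factors, n_samples=39, seed=seed)


@dataclass
class FpkmSimSpec:
    n_hkg: int = 3
    n_variable: int = 100
    n_zero: int = 5
    n_samples: int = 39
    hkg_log_mean: tuple[float, float] = (np.log(20.0), np.log(500.0))  # uniform range
    hkg_log_sd: float = 0.08     # ~8% CV: passes every screening threshold
    var_log_mean: tuple[float, float] = (np.log(0.5), np.log(500.0))
    var_log_sd: float = 0.6      # ~66% CV: fails the CV criterion
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_hkg, self.n_variable, self.n_zero) < 0:
            raise SpecError("class counts must be >= 0")
        if self.n_hkg + self.n_variable + self.n_zero == 0:
            raise SpecError("need at least one gene")
        if self.n_samples < 2:
            raise SpecError("need at least 2 samples")
        if self.hkg_log_sd < 0 or self.var_log_sd < 0:
            raise SpecError("log-SDs must be >= 0")


def simulate_fpkm(spec: FpkmSimSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw an FPKM matrix with planted housekeeping/variable/zero genes."""
    rng = np.random.default_rng(spec.seed)
    names, classes, rows = [], [], []
    for i in range(spec.n_hkg):
        mu = rng.uniform(*spec.hkg_log_mean)
        rows.append(np.exp(rng.normal(mu, spec.hkg_log_sd, size=spec.n_samples)))
        names.append(f"hkg{i + 1:03d}")
        classes.append("hkg")
    for i in range(spec.n_variable):
        mu = rng.uniform(*spec.var_log_mean)
        rows.append(np.exp(rng.normal(mu, spec.var_log_sd, size=spec.n_samples)))
        names.append(f"var{i + 1:03d}")
        classes.append("variable")
    for i in range(spec.n_zero):
        rows.append(np.zeros(spec.n_samples))
        names.append(f"zero{i + 1:03d}")
        classes.append("zero")
    values = pd.DataFrame(
        np.vstack(rows),
        index=pd.Index(names, name="gene"),
        columns=[f"s{j + 1:02d}" for j in range(spec.n_samples)],
    )
    truth = pd.DataFrame({"class": classes}, index=values.index)
    return ExpressionMatrix(values), truth


def default_fpkm_spec(seed: int = 0) -> FpkmSimSpec:
    return FpkmSimSpec(seed=seed)
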