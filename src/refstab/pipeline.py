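"""One-command orchestration: inputs -> screening / stability / composite /
validation tables, with a reproducible run log.

The bundle produced by :func:`run_pipeline` is a plain dict of pandas
objects keyed by table name; :func:`write_report` serializes it to TSV (one
file per table, stability values printed "value (rank)" style) or to a
single JSON document.  Re-running with an identical config and seed yields
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .comprfinder import comparison_table, comprfinder
from .core_io import (
    CtMatrix,
    StabilitySeries,
    StudyDesign,
    read_ct_table,
    read_design,
    read_expression_matrix,
    write_json,
)
from .errors import ConfigError
from .normalize_validate import (
    NormalizationScheme,
    relative_expression,
    scheme_correlation,
    stage_comparison,
)
from .screening import (
    ScreenThresholds,
    gene_summary,
    prefilter_genes,
    screen_candidates,
    summary_frame,
)
from .stability import bestkeeper, ct_to_quantity, delta_ct, genorm, normfinder


@dataclass
class PipelineConfig:
    """Everything a full run needs; unset stage inputs disable that stage."""

    # screening
    expression_path: str | None = None
    zero_policy: str = "any-zero"
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    # stability + aggregation
    ct_path: str | None = None
    ct_layout: str = "wide"
    design_path: str | None = None
    factors: list[str] = field(default_factory=list)  # per-group runs
    pooled_factor: str | None = None  # grouping for the pooled NormFinder run
    efficiency: float | None = None
    bestkeeper_center: str = "arith"
    # aggregation of an externally supplied gene x algorithm table
    aggregate_path: str | None = None
    # validation
    target_genes: list[str] = field(default_factory=list)
    schemes: dict[str, list[str]] = field(default_factory=dict)
    validate_factor: str | None = None
    pairing: dict[str, str] = field(default_factory=dict)
    # misc
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        thr = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if thr:
            cfg.thresholds = ScreenThresholds(**thr)
        return cfg


def _value_rank_table(series_by_run: dict[str, StabilitySeries]) -> pd.DataFrame:
    """Gene x run table of 'value (rank)' strings, plus sortable columns."""
    genes = list(next(iter(series_by_run.values())).gene_ids)
    out = pd.DataFrame(index=pd.Index(genes, name="gene"))
    for run, s in series_by_run.items():
        ranks = s.ranking()
        out[run] = [f"{s.values[g]:.3f} ({int(ranks[g])})" for g in genes]
    return out


def _stability_runs(
    ct: CtMatrix,
    design: StudyDesign | None,
    cfg: PipelineConfig,
) -> dict[str, dict[str, StabilitySeries]]:
    """algorithm -> run label -> series (runs: each factor, then pooled)."""
    runs: dict[str, tuple[CtMatrix, str | None]] = {}
    if design is not None:
        for f in cfg.factors:
            members = sorted(design.level_of(f))
            sub = ct.subset_samples([s for s in ct.sample_ids if s in members])
            runs[f] = (sub, f)
    pooled_factor = cfg.pooled_factor if design is not None else None
    runs["all_samples"] = (ct, pooled_factor)

    out: dict[str, dict[str, StabilitySeries]] = {
        "genorm": {}, "normfinder": {}, "bestkeeper": {}, "delta_ct": {}
    }
    v_seq = {}
    for label, (sub_ct, factor) in runs.items():
        if sub_ct.missing_cells():
            sub_ct = sub_ct.drop_incomplete_samples()
        q = ct_to_quantity(sub_ct, cfg.efficiency)
        g = genorm(q)
        out["genorm"][label] = g.series
        v_seq[label] = g.pairwise_variation
        out["normfinder"][label] = normfinder(q, design if factor else None, factor)
        out["bestkeeper"][label] = bestkeeper(sub_ct, cfg.bestkeeper_center).series
        out["delta_ct"][label] = delta_ct(sub_ct)
    out["_v_sequence"] = v_seq  # type: ignore[assignment]
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage whose inputs are configured; returns the table bundle."""
    bundle: dict = {}
    ran_any = False

    if config.expression_path:
        ran_any = True
        m = read_expression_matrix(config.expression_path)
        filtered, removed = prefilter_genes(m, config.zero_policy)
        summaries = gene_summary(filtered)
        res = screen_candidates(summaries, config.thresholds)
        bundle["screening_summary"] = summary_frame(summaries)
        bundle["screening_counts"] = dict(res.counts)
        bundle["screening_candidates"] = sorted(res.intersection)
        bundle["screening_removed_genes"] = removed

    design = read_design(config.design_path) if config.design_path else None

    series_for_aggregation: list[StabilitySeries] | None = None
    if config.ct_path:
        ran_any = True
        ct = read_ct_table(config.ct_path, layout=config.ct_layout)
        runs = _stability_runs(ct, design, config)
        v_seq = runs.pop("_v_sequence")
        for alg, by_run in runs.items():
            bundle[f"stability_{alg}"] = _value_rank_table(by_run)
        bundle["genorm_v_sequence"] = pd.DataFrame(
            {label: seq for label, seq in v_seq.items()}
        )
        series_for_aggregation = [runs[a]["all_samples"] for a in
                                  ("genorm", "normfinder", "bestkeeper", "delta_ct")]
        # composite per run label
        agg_rows = {}
        for label in runs["genorm"]:
            series = [runs[a][label] for a in
                      ("genorm", "normfinder", "bestkeeper", "delta_ct")]
            agg_rows[label] = comprfinder(series).final_score
        bundle["comprfinder_by_run"] = pd.DataFrame(agg_rows)

    if config.aggregate_path and series_for_aggregation is None:
        ran_any = True
        table = pd.read_csv(
            config.aggregate_path,
            sep="\t" if str(config.aggregate_path).endswith(".tsv") else ",",
            index_col=0,
        )
        series_for_aggregation = [
            StabilitySeries(col, table[col]) for col in table.columns
        ]

    if series_for_aggregation is not None:
        bundle["aggregation"] = comparison_table(series_for_aggregation)

    if config.ct_path and config.target_genes and config.schemes:
        ct = read_ct_table(config.ct_path, layout=config.ct_layout)
        target_ct = ct.subset_genes(
            [g for g in ct.gene_ids if g in set(config.target_genes)]
        )
        tables = []
        for label, hkgs in config.schemes.items():
            expr = relative_expression(
                target_ct, NormalizationScheme(label, hkgs), reference_ct=ct
            )
            tables.append(expr)
            bundle[f"expression_{label}"] = expr.values
        if len(tables) >= 2:
            corr = scheme_correlation(tables)
            bundle["scheme_correlation"] = corr
            bundle["scheme_correlation_p"] = corr.attrs["p_values"]
        if design is not None and config.validate_factor and config.pairing:
            comp = pd.concat(
                [
                    stage_comparison(t, design, config.validate_factor, config.pairing)
                    .assign(scheme=t.scheme)
                    for t in tables
                ],
                ignore_index=True,
            )
            bundle["stage_comparison"] = comp

    if not ran_any:
        raise ConfigError("no stage inputs configured: nothing to run")

    bundle["run_log"] = {
        "refstab_version": __version__,
        "seed": config.seed,
        "zero_policy": config.zero_policy,
        "bestkeeper_center": config.bestkeeper_center,
        "efficiency": config.efficiency if config.efficiency is not None else 2.0,
        "pooled_factor": config.pooled_factor,
        "thresholds": {
            "min_mean_fpkm": config.thresholds.min_mean_fpkm,
            "max_cv_pct": config.thresholds.max_cv_pct,
            "max_dpm": config.thresholds.max_dpm,
            "max_mfc": config.thresholds.max_mfc,
            "fpkm_percentile_alternative": config.thresholds.fpkm_percentile_alternative,
        },
    }
    return bundle


def _format_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.3f}")
    return out


def write_report(bundle: dict, out_dir: str | Path, fmt: str = "tsv") -> list[Path]:
    """Serialize a bundle deterministically; numeric cells to 3 decimals."""
    if not bundle:
        raise ConfigError("empty bundle: nothing to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    if fmt == "json":
        path = out_dir / "report.json"
        payload = {}
        for name, obj in bundle.items():
            if isinstance(obj, pd.DataFrame):
                payload[name] = {c: obj[c].to_dict() for c in obj.columns}
            elif isinstance(obj, pd.Series):
                payload[name] = obj.to_dict()
            else:
                payload[name] = obj
        write_json(payload, path)
        return [path]
    if fmt != "tsv":
        raise ValueError(f"unknown format: {fmt!r}")
    for name in sorted(bundle):
        obj = bundle[name]
        path = out_dir / f"{name}.tsv"
        if isinstance(obj, pd.DataFrame):
            _format_frame(obj).to_csv(path, sep="\t")
        elif isinstance(obj, pd.Series):
            _format_frame(obj.to_frame()).to_csv(path, sep="\t")
        else:
            path = out_dir / f"{name}.json"
            write_json(obj, path)
        paths.append(path)
    return paths
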