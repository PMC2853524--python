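"""The two headline workflows, as library functions the CLI wraps.

``run_chemostat_validation`` solves the biomass-maximizing LP for each row of
a chemostat condition table and writes a predicted-vs-observed report.
``run_switch_analysis`` executes the whole switch pipeline — dynamic FBA,
gene-reaction matching, correlation and classification, clustering, genome
track, zero-flux and essentiality screens — and writes all tabular outputs
plus run metadata (config hash, seed, versions).  On any stage failure the
partial outputs of this run are removed and the stage is named.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .clustering import cluster_profiles, genome_track, hierarchical_clusters
from .dynamic import build_schedule, run_dynamic_fba
from .errors import ConfigError, SwitchFBAError
from .expression import (
    ExpressionMatrix,
    classify,
    correlate,
    essential_expression_summary,
    match_genes,
    read_expression,
    zero_flux_genes,
)
from .fba import ExchangeMap, chemostat_panel, read_conditions_tsv
from .sbml_io import read_sbml


@dataclass
class RunConfig:
    """Everything a reproducible run needs; serializable and hashable."""

    model_path: str
    output_dir: str
    expression_path: Optional[str] = None
    schedule_path: Optional[str] = None
    controls_path: Optional[str] = None  # one negative-control gene id per line
    schedule_map: dict = field(default_factory=dict)  # column → reaction id
    antibiotic_map: dict = field(default_factory=dict)
    r_low: float = -0.5
    r_high: float = 0.5
    k_clusters: int = 12
    switch_time: float = 34.0
    objective_mode: str = "weighted"  # or "forced"
    weight_scale: float = 1.0
    zero_flux_tol: float = 1e-9
    low_expression_cutoff: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.r_low >= self.r_high:
            raise ConfigError("r_low must be below r_high")
        if self.k_clusters < 1:
            raise ConfigError("k_clusters must be >= 1")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(f"bad config file {path}: {exc}") from None


def _metadata(config: RunConfig, extra: dict) -> dict:
    return {
        "switchfba_version": __version__,
        "config_hash": config.digest(),
        "config": asdict(config),
        "seed": config.seed,
        **extra,
    }


def run_chemostat_validation(
    config: RunConfig, conditions_path: str | Path
) -> dict:
    """Chemostat validation: one biomass-maximizing solve per condition.

    Writes ``chemostat_predictions.tsv`` (conditions + predicted_mu) and
    ``chemostat_summary.json`` (observed-vs-predicted agreement statistics,
    the data behind a D-vs-μ scatter).  Returns the summary dict.
    """
    model = read_sbml(config.model_path)
    conditions = read_conditions_tsv(conditions_path)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    exchanges = _guess_exchanges(model)
    results = chemostat_panel(model, conditions, exchanges)
    rows = []
    for cond, mu in results:
        rows.append(
            {
                "glucose_uptake": cond.glucose_uptake,
                "o2_uptake": cond.o2_uptake,
                "co2_production": cond.co2_production,
                "actinorhodin_production": cond.actinorhodin_production,
                "observed_dilution_rate": cond.observed_dilution_rate,
                "predicted_mu": mu,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "glucose_uptake", "o2_uptake", "co2_production",
            "actinorhodin_production", "observed_dilution_rate", "predicted_mu",
        ],
    )
    df.to_csv(out_dir / "chemostat_predictions.tsv", sep="\t", index=False)
    observed = df["observed_dilution_rate"].to_numpy(dtype=float)
    predicted = df["predicted_mu"].to_numpy(dtype=float)
    ok = np.isfinite(observed) & np.isfinite(predicted)
    summary = {
        "n_conditions": len(df),
        "rmse": float(np.sqrt(np.mean((observed[ok] - predicted[ok]) ** 2)))
        if ok.any()
        else None,
        "max_abs_error": float(np.max(np.abs(observed[ok] - predicted[ok])))
        if ok.any()
        else None,
        "pearson_r": float(np.corrcoef(observed[ok], predicted[ok])[0, 1])
        if ok.sum() >= 2 and np.std(observed[ok]) > 0 and np.std(predicted[ok]) > 0
        else None,
    }
    meta = _metadata(config, {"summary": summary})
    (out_dir / "chemostat_summary.json").write_text(json.dumps(meta, indent=2))
    return summary


def _guess_exchanges(model) -> ExchangeMap:
    """Best-effort mapping of glucose/O2/CO2/actinorhodin exchanges by id."""
    def find(*needles):
        for r in model.reactions:
            if r.is_exchange and any(n in r.id.lower() for n in needles):
                return r.id
        return None

    return ExchangeMap(
        glucose=find("glc", "glucose"),
        o2=find("o2", "oxygen"),
        co2=find("co2"),
        actinorhodin=find("act"),
    )


def run_switch_analysis(config: RunConfig, gene_order: Optional[list[str]] = None) -> dict:
    """The full switch pipeline; returns a summary dict.

    Output files (all TSV/JSON, in ``config.output_dir``): flux_matrix.tsv,
    growth_curve.tsv, gene_correlations.tsv, correlation_summary.json,
    clusters.tsv, cluster_profiles.tsv, genome_track.tsv,
    zero_flux_genes.txt, essentiality.json, run_metadata.json.
    """
    if config.expression_path is None or config.schedule_path is None:
        raise ConfigError("switch analysis needs expression_path and schedule_path")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "load inputs"
    try:
        model = read_sbml(config.model_path)
        controls = None
        if config.controls_path:
            controls = {
                line.strip()
                for line in Path(config.controls_path).read_text().splitlines()
                if line.strip()
            }
        expr = read_expression(config.expression_path, control_rows=controls)
        measurements = pd.read_csv(config.schedule_path, sep="\t")
        schedule = build_schedule(
            measurements,
            uptake_columns=dict(config.schedule_map),
            antibiotic_columns=dict(config.antibiotic_map),
            switch_time=config.switch_time,
        )

        stage = "dynamic FBA"
        flux_ts = run_dynamic_fba(
            model,
            schedule,
            objective_mode=config.objective_mode,
            weight_scale=config.weight_scale,
        )

        def emit(name, writer):
            path = out_dir / name
            writer(path)
            written.append(path)

        emit("flux_matrix.tsv",
             lambda p: flux_ts.flux_matrix.to_csv(p, sep="\t", index_label="reaction"))
        emit("growth_curve.tsv",
             lambda p: flux_ts.growth_curve.to_csv(p, sep="\t", index_label="time_h"))

        stage = "gene-reaction matching"
        matching = match_genes(model, flux_ts)

        stage = "correlation"
        report = correlate(flux_ts, expr, matching, zero_tol=config.zero_flux_tol)
        counts = classify(report, config.r_low, config.r_high)
        emit("gene_correlations.tsv",
             lambda p: report.to_frame().to_csv(p, sep="\t", index=False))

        stage = "clustering"
        # cluster the observed profiles of classified genes (controls and
        # excluded genes stay out of the dendrogram)
        classified = [p.gene for p in report.profiles if p.cls is not None]
        cluster_genes = classified if classified else expr.genes
        sub_expr = ExpressionMatrix(values=expr.values.loc[cluster_genes].copy())
        assignment = hierarchical_clusters(
            sub_expr, k=min(config.k_clusters, len(cluster_genes))
        )
        emit("clusters.tsv", lambda p: assignment.to_frame().to_csv(p, sep="\t",
                                                                    index=False))
        profiles = cluster_profiles(expr, assignment)
        emit("cluster_profiles.tsv",
             lambda p: profiles.to_csv(p, sep="\t", index_label="cluster"))

        stage = "genome track"
        order = gene_order if gene_order is not None else sorted(assignment.genes)
        track = genome_track(assignment, report, order)
        emit("genome_track.tsv", lambda p: track.to_csv(p, sep="\t", index=False))

        stage = "zero-flux and essentiality screens"
        zero = zero_flux_genes(matching, flux_ts, tol=config.zero_flux_tol)
        emit("zero_flux_genes.txt",
             lambda p: p.write_text("\n".join(sorted(zero)) + "\n"))
        ess = essential_expression_summary(
            flux_ts, expr, matching,
            low_cutoff=config.low_expression_cutoff, tol=config.zero_flux_tol,
        )
        summary = {
            "class_counts": counts.counts,
            "class_fractions": counts.fractions,
            "n_classified": counts.n_classified,
            "n_excluded": counts.n_excluded,
            "n_zero_flux_genes": len(zero),
            "n_essential_genes": len(ess.essential),
            "medians": ess.medians,
            "low_expressed_essential": ess.low_expressed_essential,
            "n_infeasible_timepoints": sum(s != "optimal" for s in flux_ts.statuses),
            "resolution_method": flux_ts.resolution_method,
            "objective_mode": flux_ts.objective_mode,
        }
        emit("correlation_summary.json",
             lambda p: p.write_text(json.dumps(
                 {"thresholds": list(report.thresholds), **summary}, indent=2)))
        emit("essentiality.json",
             lambda p: p.write_text(json.dumps(
                 {
                     "essential_genes": sorted(ess.essential),
                     "medians": ess.medians,
                     "low_expression_cutoff": ess.low_expression_cutoff,
                     "low_expressed_essential": ess.low_expressed_essential,
                     "low_expressed_non_essential": ess.low_expressed_non_essential,
                 }, indent=2)))
        emit("run_metadata.json",
             lambda p: p.write_text(json.dumps(_metadata(config, {}), indent=2)))
        return summary
    except SwitchFBAError as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise type(exc)(f"stage '{stage}' failed: {exc}") from exc
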