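"""End-to-end orchestration: simulate/load -> filter -> fit -> reconstruct
-> count -> features -> regressions, with a row-count ledger and a
reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import cpgrates
from cpgrates.alignments import GenomicTrack, TripletAlignment, filter_introns, read_alignments
from cpgrates.features import build_features
from cpgrates.phylo import fit_branch_lengths, models_to_tsv, reconstruct_ancestor
from cpgrates.rates import (
    counting_estimator,
    noncpg_divergence,
    rates_table,
    scan_dinucleotide_events,
    strand_bias,
)
from cpgrates.simulate import ConfigError, SimulationConfig, StudyBundle, simulate_study
from cpgrates.stats import (
    COVARIATES,
    anova_by_chromosome,
    complete_cases,
    concatenate_by_gene,
    cpg_specific_rate,
    fit_glm,
    fit_kappa_ols,
    spearman_panel,
)

log = logging.getLogger("cpgrates")

_RESPONSES = {"cpg_ts": ("n_cpg_ts", "n_cpg_sites"), "cpg_tv": ("n_cpg_tv", "n_cpg_sites"),
              "cph_ts": ("n_cph_ts", "n_cph_sites")}


@dataclass
class RunConfig:
    """Normalized pipeline configuration (YAML-loadable)."""

    outdir: str = "results"
    seed: int = 0
    simulation: dict | None = None
    alignments_path: str | None = None
    alignments_format: str = "fasta-triplet"
    methylation_bed: str | None = None
    recombination_bed: str | None = None
    cgi_bed: str | None = None
    dhs_bed: str | None = None
    expression_tsv: str | None = None
    min_unambiguous: int = 1000
    min_meth_windows: int = 5
    fit_exchangeabilities: bool = True
    cgi_dialect: dict = field(
        default_factory=lambda: {"min_length": 200, "min_gc": 0.5, "min_oe": 0.6}
    )
    responses: tuple = ("cpg_ts", "cpg_tv", "cph_ts")
    datasets: tuple = ("all", "A", "B", "C")
    concatenate_genes: bool = False
    run_stats: bool = True
    write_models: bool = True
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.min_unambiguous < 0:
            raise ConfigError("min_unambiguous must be >= 0")
        if self.min_meth_windows < 0:
            raise ConfigError("min_meth_windows must be >= 0")
        for r in self.responses:
            if r not in _RESPONSES:
                raise ConfigError(f"unknown response: {r!r}")
        if self.simulation is None and self.alignments_path is None:
            raise ConfigError("either a simulation block or alignments_path is required")
        if self.simulation is None:
            for attr in ("alignments_path", "methylation_bed", "recombination_bed",
                         "expression_tsv"):
                p = getattr(self, attr)
                if p is not None and not Path(p).exists():
                    raise ConfigError(f"{attr}: no such file {p!r}")


def validate_config(path) -> RunConfig:
    """Load, fill defaults, reject unknown keys, and normalize."""
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(payload) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("responses", "datasets"):
        if key in payload:
            payload[key] = tuple(payload[key])
    cfg = RunConfig(**payload)
    if cfg.simulation is not None:
        SimulationConfig(**{**cfg.simulation, "seed": cfg.simulation.get("seed", cfg.seed)})
    cfg.validate()
    return cfg


def compute_rates(
    alignments: list[TripletAlignment], fit_exchangeabilities: bool = True
) -> tuple[pd.DataFrame, dict]:
    """Per-intron model fit, marginal reconstruction and event counting."""
    models = {}
    records = []
    extra = []
    for aln in alignments:
        model = fit_branch_lengths(aln, fit_exchangeabilities=fit_exchangeabilities)
        models[aln.intron_id] = model
        profile = reconstruct_ancestor(aln, model)
        mask = profile.mask
        counts = scan_dinucleotide_events(
            profile.map_codes, aln.codes()[0], mask=mask, intron_id=aln.intron_id
        )
        div, n_div = noncpg_divergence(aln, profile)
        counts.noncpg_divergence = div
        counts.n_noncpg_sites = n_div
        records.append(counts)
        extra.append(
            {
                "intron_id": aln.intron_id,
                "n_sites": int(mask.sum()),
                "counting_cpg_ts_rate": counting_estimator(aln),
                "t_human": model.branch_lengths["human"],
                "converged": model.converged,
            }
        )
    df = rates_table(records).merge(pd.DataFrame(extra), on="intron_id")
    return df, models


def _study_from_config(config: RunConfig) -> tuple[StudyBundle | None, dict]:
    """Either simulate a study or load the input files."""
    if config.simulation is not None:
        sim_cfg = SimulationConfig(
            **{**config.simulation, "seed": config.simulation.get("seed", config.seed)}
        )
        bundle = simulate_study(sim_cfg)
        inputs = {
            "alignments": bundle.alignments,
            "methylation": bundle.methylation_track,
            "recombination": bundle.recombination_track,
            "cgi": bundle.cgi_track,
            "dhs": bundle.dhs_track,
            "expression": bundle.expression,
        }
        return bundle, inputs
    alignments = list(read_alignments(config.alignments_path, format=config.alignments_format))
    inputs = {
        "alignments": alignments,
        "methylation": GenomicTrack.read_bed(
            config.methylation_bed, columns=("methylation", "cpg_count"), name="methylation"
        )
        if config.methylation_bed
        else None,
        "recombination": GenomicTrack.read_bed(
            config.recombination_bed, columns=("female", "male"), name="recombination"
        )
        if config.recombination_bed
        else None,
        "cgi": GenomicTrack.read_bed(config.cgi_bed, name="cgi") if config.cgi_bed else None,
        "dhs": GenomicTrack.read_bed(config.dhs_bed, name="dhs") if config.dhs_bed else None,
        "expression": pd.read_csv(config.expression_tsv, sep="\t")
        if config.expression_tsv
        else pd.DataFrame(columns=["gene_id", "index_1", "index_2", "index_3"]),
    }
    return None, inputs


@dataclass
class PipelineResult:
    config: RunConfig
    rates: pd.DataFrame
    features: pd.DataFrame
    joined: pd.DataFrame
    regressions: dict
    panels: pd.DataFrame | None
    strand: list
    anova: dict
    manifest: dict
    bundle: StudyBundle | None = None


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute all enabled stages in dependency order.

    Writes per-intron rates and features TSVs, regression tables shaped
    like the standard report (one per response x dataset), the Spearman
    panels, strand-bias intervals, and a manifest with the row-count
    ledger, seed and config hash.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    ledger: dict[str, dict] = {}

    bundle, inputs = _study_from_config(config)
    alignments = inputs["alignments"]
    ledger["input"] = {"alignments": len(alignments)}
    log.info("stage input: %d alignments", len(alignments))

    kept, report = filter_introns(alignments, min_unambiguous=config.min_unambiguous)
    ledger["filter"] = report
    log.info("stage filter: %s", report)

    rates_df, models = compute_rates(kept, fit_exchangeabilities=config.fit_exchangeabilities)
    ledger["rates"] = {"introns": len(rates_df),
                       "converged": int(rates_df["converged"].sum())}
    log.info("stage rates: %d introns", len(rates_df))

    cgi_track = inputs["cgi"]
    if cgi_track is None:
        # CGIs are sequence-defined; detect them under the configured dialect
        from cpgrates.features import detect_cgi_track

        cgi_track = detect_cgi_track(kept, **config.cgi_dialect)
        log.info("stage features: detected %d CGI intervals", len(cgi_track.intervals))
    feats = build_features(
        kept,
        inputs["methylation"],
        inputs["recombination"],
        cgi_track,
        inputs["dhs"],
        inputs["expression"],
        min_meth_windows=config.min_meth_windows,
    )
    ledger["features"] = {
        "introns": len(feats),
        "dataset_counts": feats["dataset"].value_counts().to_dict(),
    }

    joined = rates_df.merge(feats, on="intron_id", how="inner")
    n_before = len(joined)
    joined_kept = joined[joined["dataset"] != "discard"]
    analysis = complete_cases(joined_kept, ["noncpg_divergence", "methylation", "gc_content",
                                            "expression", "recomb_female", "recomb_male"])
    ledger["join"] = {
        "joined": n_before,
        "discarded_cgi_only": int(n_before - len(joined_kept)),
        "incomplete": int(len(joined_kept) - len(analysis)),
        "analysis": len(analysis),
    }
    log.info("stage join: %s", ledger["join"])

    rates_df.to_csv(out / "rates.tsv", sep="\t", index=False)
    feats.to_csv(out / "features.tsv", sep="\t", index=False)
    analysis.to_csv(out / "analysis_table.tsv", sep="\t", index=False)
    if config.write_models:
        models_to_tsv(models, out / "fitted_models.tsv")

    regressions: dict = {}
    panels = None
    strand_rows: list = []
    anova_tables: dict = {}
    if config.run_stats and len(analysis):
        tables = {"per_intron": analysis}
        if config.concatenate_genes:
            tables["per_gene"] = concatenate_by_gene(analysis)
        for scope, table in tables.items():
            for response in config.responses:
                ev_col, site_col = _RESPONSES[response]
                for ds in config.datasets:
                    sub = table if ds == "all" else table[table["dataset"] == ds]
                    sub = sub[sub[site_col] >= 1]
                    if len(sub) < len(COVARIATES) + 2:
                        continue
                    try:
                        res = fit_glm(
                            sub[ev_col].to_numpy(),
                            sub[site_col].to_numpy(),
                            sub[list(COVARIATES)],
                        )
                    except Exception as exc:  # noqa: BLE001 - record, keep going
                        log.warning("glm %s/%s/%s failed: %s", scope, response, ds, exc)
                        continue
                    regressions[(scope, response, ds)] = res
                    tab = res.to_table()
                    tab.to_csv(out / f"glm_{scope}_{response}_{ds}.tsv", sep="\t", index=False)
            # kappa OLS (introns with positive transversion rate only)
            for ds in config.datasets:
                sub = table if ds == "all" else table[table["dataset"] == ds]
                sub = sub[(sub["n_cpg_tv"] > 0) & (sub["n_cpg_sites"] > 0)]
                if len(sub) < len(COVARIATES) + 2:
                    continue
                kappa = (sub["n_cpg_ts"] / sub["n_cpg_sites"]) / (
                    sub["n_cpg_tv"] / sub["n_cpg_sites"]
                )
                try:
                    res = fit_kappa_ols(kappa.to_numpy(), sub[list(COVARIATES)])
                except Exception as exc:  # noqa: BLE001
                    log.warning("kappa OLS %s/%s failed: %s", scope, ds, exc)
                    continue
                regressions[(scope, "kappa", ds)] = res
                res.to_table().to_csv(out / f"ols_{scope}_kappa_{ds}.tsv", sep="\t", index=False)

        panels = spearman_panel(analysis)
        panels.to_csv(out / "spearman_panels.tsv", sep="\t", index=False)

        for ds in config.datasets:
            sub = analysis if ds == "all" else analysis[analysis["dataset"] == ds]
            try:
                strand_rows.append(strand_bias(sub, dataset_label=ds))
            except Exception as exc:  # noqa: BLE001
                log.info("strand bias skipped for %s: %s", ds, exc)
        if strand_rows:
            pd.DataFrame(strand_rows).to_csv(out / "strand_bias.tsv", sep="\t", index=False)

        if (analysis["chrom"] == "chrX").any() and analysis["chrom"].nunique() >= 2:
            sub = analysis[analysis["n_cpg_sites"] > 0]
            raw = anova_by_chromosome(
                (sub["n_cpg_ts"] / sub["n_cpg_sites"]).to_numpy(), sub["chrom"].to_numpy()
            )
            resid, _ = cpg_specific_rate(
                sub["n_cpg_ts"].to_numpy(), sub["n_cpg_sites"].to_numpy(),
                sub[list(COVARIATES)],
            )
            corrected = anova_by_chromosome(resid, sub["chrom"].to_numpy())
            anova_tables = {"raw": raw, "cpg_specific": corrected}
            raw.to_csv(out / "anova_raw.tsv", sep="\t", index=False)
            corrected.to_csv(out / "anova_cpg_specific.tsv", sep="\t", index=False)

    cfg_text = json.dumps(asdict(config), sort_keys=True, default=str)
    manifest = {
        "version": cpgrates.__version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(cfg_text.encode()).hexdigest()[:16],
        "ledger": ledger,
        "wall_time_s": round(time.time() - t_start, 2),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return PipelineResult(
        config=config,
        rates=rates_df,
        features=feats,
        joined=joined,
        regressions=regressions,
        panels=panels,
        strand=strand_rows,
        anova=anova_tables,
        manifest=manifest,
        bundle=bundle,
    )
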