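"""End-to-end orchestration: parse inputs, call events, window, test, report.

`analyze` is the in-memory composition of all stages; `run_analysis` wraps
it with file parsing, report writing and a manifest, and `run_simulation`
drives the bundled generator. Every random stage receives a seed derived
from the run seed, so a config + seed pair reproduces its reports byte for
byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .activity import activity_times, detect_nesting, write_activity_table
from .decay import bootstrap_ci, filter_triples, read_triples
from .indels import call_indels, write_events
from .io import (
    GenomeAnnotation,
    PolymorphicIndel,
    RecombMap,
    RepeatAlignment,
    parse_annotation,
    parse_polymorphisms,
    parse_recomb_map,
    parse_repeat_alignments,
)
from .simulate import SimConfig, emit_fixtures, scenario_config, simulate_genome
from .stats import (
    BootstrapSpec,
    bh_adjust,
    chromosome_randomization_test,
    kendall_tau_b,
    sfs_contingency_test,
    stratified_bootstrap_diff,
)
from .windows import (
    FilterConfig,
    filter_repeats,
    genome_features,
    size_class_summary,
    window_rates,
)

logger = logging.getLogger(__name__)

_VERSION = "0.1.0"

FEATURE_COLUMNS = [
    "deletion_rate",
    "insertion_rate",
    "deletion_bias",
    "net_loss",
    "n_del_events",
    "mean_line_length",
    "mean_intron_length",
    "mean_first_intron_length",
    "unique_intronic_bp",
    "unique_intergenic_bp",
    "intergenic_spacer_length",
    "gene_density",
]


@dataclass
class RunConfig:
    out_table: str | None = None
    align_file: str | None = None
    recomb_map: str | None = None
    annotation: str | None = None
    annotation_format: str = "BED12"
    polymorphisms: str | None = None
    triples: str | None = None
    window_size: int = 1_000_000
    unique_events: bool = False
    normalization: bool = True
    seed: int = 0
    output_dir: str | None = None
    z_chromosomes: tuple[str, ...] = ("chrZ", "Z")
    w_chromosomes: tuple[str, ...] = ("chrW", "W")
    min_windows: int = 20
    randomization_replicates: int = 10_000
    bootstrap_replicates: int = 10_000
    decay_bootstrap_replicates: int = 1000
    divergence_time: float | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)

    def validate(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window size must be positive")

    def content_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _element_table(
    alignments: list[RepeatAlignment], events, z_chroms, w_chroms
) -> pd.DataFrame:
    per_copy: dict[str, dict] = {}
    for a in alignments:
        rec = per_copy.setdefault(
            a.copy_id,
            {
                "copy_id": a.copy_id,
                "stratum": a.subfamily,
                "chromosome": a.chromosome,
                "length": 0,
                "deleted_bp": 0,
                "inserted_bp": 0,
            },
        )
        rec["length"] += a.copy_length
    for e in events:
        rec = per_copy.get(e.copy_id)
        if rec is None:
            continue
        rec["deleted_bp" if e.kind == "deletion" else "inserted_bp"] += e.length
    df = pd.DataFrame(per_copy.values())
    if df.empty:
        return df
    df["category"] = np.where(
        df["chromosome"].isin(z_chroms),
        "Z",
        np.where(df["chromosome"].isin(w_chroms), "W", "autosome"),
    )
    return df


def analyze(
    alignments: list[RepeatAlignment],
    recomb_map: RecombMap,
    annotation: GenomeAnnotation | None = None,
    polymorphisms: list[PolymorphicIndel] | None = None,
    triples=None,
    config: RunConfig | None = None,
) -> dict:
    """Run every in-scope statistic on parsed inputs; returns a report bundle."""
    config = config or RunConfig()
    config.validate()
    rng_seed = config.seed

    alignments = filter_repeats(alignments, annotation, config.filter)
    if not alignments:
        raise ValueError("no repeats survive filtering")
    events = [e for a in alignments for e in call_indels(a)]

    nesting = detect_nesting(alignments)
    activities, t_bar = activity_times(nesting)

    chrom_sizes = dict(annotation.chrom_sizes) if annotation else None
    windows = window_rates(
        alignments,
        events,
        window_size=config.window_size,
        chrom_sizes=chrom_sizes,
        recomb_map=recomb_map,
        activities=activities if config.normalization else None,
        t_bar=t_bar if config.normalization else None,
        unique_only=config.unique_events,
    )
    if annotation is not None:
        windows = genome_features(
            annotation, alignments, windows, window_size=config.window_size
        )

    autosomal = ~windows["chromosome"].isin(
        tuple(config.z_chromosomes) + tuple(config.w_chromosomes)
    )
    corr_rows = []
    for col in FEATURE_COLUMNS + (
        ["normalized_divergence"] if "normalized_divergence" in windows else []
    ):
        if col not in windows:
            continue
        sub = windows[autosomal]
        try:
            res = kendall_tau_b(sub["recomb_rate"], sub[col])
        except ValueError:
            continue
        corr_rows.append(
            {"feature": col, "tau": res.tau, "p": res.p_value, "n_windows": res.n}
        )
    correlations = pd.DataFrame(corr_rows)
    if not correlations.empty:
        correlations["p_bh"] = bh_adjust(correlations["p"].fillna(1.0))

    elements = _element_table(
        alignments, events, config.z_chromosomes, config.w_chromosomes
    )
    sex_reports = {}
    if not elements.empty and (elements["category"] == "Z").sum() > 0:
        for stat in ("mean-length-diff", "bias-diff"):
            spec = BootstrapSpec(
                categories=("Z", "autosome"),
                replicates=config.bootstrap_replicates,
                seed=rng_seed + 11,
                statistic=stat,
            )
            try:
                sex_reports[stat] = stratified_bootstrap_diff(spec, elements)
            except ValueError as exc:
                logger.warning("sex-chromosome bootstrap (%s) skipped: %s", stat, exc)

    randomization = {}
    for col in ("deletion_rate", "deletion_bias"):
        try:
            randomization[col] = chromosome_randomization_test(
                windows[autosomal],
                "recomb_rate",
                col,
                min_windows=config.min_windows,
                replicates=config.randomization_replicates,
                seed=rng_seed + 23,
            )
        except ValueError as exc:
            logger.warning("randomization test (%s) skipped: %s", col, exc)
    per_chrom_tables = {}
    for col, res in randomization.items():
        tbl = res.per_chromosome.copy()
        ps = []
        for chrom in tbl["chromosome"]:
            sub = windows[windows["chromosome"] == chrom]
            ps.append(kendall_tau_b(sub["recomb_rate"], sub[col]).p_value)
        tbl["p"] = ps
        tbl["p_bh"] = bh_adjust(tbl["p"])
        per_chrom_tables[col] = tbl

    sizes = size_class_summary(events)

    sfs = {}
    if polymorphisms:
        for context in ("intron", "intergenic", "LINE"):
            try:
                sfs[context] = sfs_contingency_test(polymorphisms, context)
            except ValueError as exc:
                logger.warning("SFS test (%s) skipped: %s", context, exc)

    decay = None
    if triples:
        filtered = filter_triples(triples)
        decay = bootstrap_ci(
            filtered,
            replicates=config.decay_bootstrap_replicates,
            seed=rng_seed + 37,
            divergence=config.divergence_time,
        )

    genome_bias = (
        float(np.nansum(windows["deleted_bp"]) / np.nansum(windows["inserted_bp"]))
        if np.nansum(windows["inserted_bp"]) > 0
        else float("nan")
    )
    return {
        "windows": windows,
        "events": events,
        "alignments": alignments,
        "activities": activities,
        "t_bar": t_bar,
        "nesting": nesting,
        "correlations": correlations,
        "sex_chromosome": sex_reports,
        "randomization": randomization,
        "per_chromosome": per_chrom_tables,
        "size_classes": sizes,
        "sfs": sfs,
        "decay": decay,
        "genome_deletion_bias": genome_bias,
        "genome_deletion_bias_window_mean": float(
            np.nanmean(windows["deletion_bias"])
        ),
    }


def _write_reports(bundle: dict, config: RunConfig) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle["windows"].to_csv(outdir / "windows.tsv", sep="\t", index=False)
    with open(outdir / "events.tsv", "w") as fh:
        write_events(bundle["events"], fh)
    with open(outdir / "activity.tsv", "w") as fh:
        write_activity_table(bundle["activities"], fh)
    bundle["correlations"].to_csv(outdir / "correlations.tsv", sep="\t", index=False)
    bundle["size_classes"].to_csv(outdir / "size_classes.tsv", sep="\t", index=False)
    for col, tbl in bundle["per_chromosome"].items():
        tbl.to_csv(outdir / f"per_chromosome_{col}.tsv", sep="\t", index=False)

    stats_json: dict = {
        "genome_deletion_bias": bundle["genome_deletion_bias"],
        "genome_deletion_bias_window_mean": bundle["genome_deletion_bias_window_mean"],
        "t_bar": bundle["t_bar"],
    }
    for stat, res in bundle["sex_chromosome"].items():
        stats_json[f"sex_chromosome.{stat}"] = {
            "observed": res.observed,
            "p_two_sided": res.p_two_sided,
            "p_one_sided": res.p_one_sided,
            "replicates": res.replicates,
        }
    for col, res in bundle["randomization"].items():
        stats_json[f"randomization.{col}"] = {
            "mean_tau": res.mean_tau,
            "p": res.p_value,
            "replicates": res.replicates,
            "n_chromosomes": len(res.per_chromosome),
        }
    for context, res in bundle["sfs"].items():
        stats_json[f"sfs.{context}"] = {
            "proportion_rare": res.proportion_rare,
            "chi_square": res.chi_square,
            "p": res.p_value,
        }
    if bundle["decay"] is not None:
        d = bundle["decay"]
        stats_json["decay"] = {
            "deletion_rate": d.deletion_rate,
            "insertion_rate": d.insertion_rate,
            "substitution_rate": d.substitution_rate,
            "loss_per_substitution": d.loss_per_substitution,
            "decay_rate": d.decay_rate,
            "ci": d.ci,
        }
    with open(outdir / "stats.json", "w") as fh:
        json.dump(stats_json, fh, indent=2, sort_keys=True, default=str)

    manifest = {
        "version": _VERSION,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "config": dataclasses.asdict(config),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def run_analysis(config: RunConfig) -> dict:
    """File-based entry point: parse inputs per config, analyze, write reports."""
    config.validate()
    missing = [
        name
        for name, path in (
            ("out_table", config.out_table),
            ("align_file", config.align_file),
            ("recomb_map", config.recomb_map),
        )
        if path is None
    ]
    if missing:
        raise FileNotFoundError(
            f"mandatory input(s) not configured: {', '.join(missing)}"
        )
    with open(config.out_table) as out_fh, open(config.align_file) as aln_fh:
        alignments = parse_repeat_alignments(out_fh, aln_fh)
    with open(config.recomb_map) as fh:
        recomb = parse_recomb_map(fh)
    annotation = None
    if config.annotation:
        with open(config.annotation) as fh:
            annotation = parse_annotation(fh, config.annotation_format)
    polymorphisms = None
    if config.polymorphisms:
        with open(config.polymorphisms) as fh:
            polymorphisms = parse_polymorphisms(fh)
    triples = None
    if config.triples:
        with open(config.triples) as fh:
            triples = read_triples(fh)

    bundle = analyze(
        alignments, recomb, annotation, polymorphisms, triples, config
    )
    if config.output_dir:
        _write_reports(bundle, config)
    return bundle


def run_simulation(
    config: SimConfig | str, output_dir: str, seed: int | None = None
) -> dict[str, str]:
    """Simulate a genome (a SimConfig or a named scenario) and emit fixtures."""
    if isinstance(config, str):
        config = scenario_config(config, seed=seed if seed is not None else 0)
    elif seed is not None:
        config = dataclasses.replace(config, seed=seed)
    sim = simulate_genome(config)
    return emit_fixtures(sim, output_dir)
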