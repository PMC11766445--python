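"""End-to-end orchestration: files in, TSV reports out.

Stage order: codon metrics -> modification profiles -> linkage -> A-site
pausing.  Every artifact is plain TSV/FASTA so reruns are diffable; a flat
key=value manifest records package version, seed, config hash and warning
counts.  Reruns with an identical config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .genetic_code import build_codon_table, read_cds_fasta
from .linkage import linkage_report
from .metrics import (
    METRIC_ISO,
    METRIC_TOTAL,
    count_matrix,
    ending_bias_summary,
    frequency_matrix,
    gene_set_tstat,
    genome_baseline,
    isoacceptor_frequency,
    select_gene_sets,
    total_frequency,
)
from .modifications import pearson_matrix, replicate_means, tissue_zscores
from .pausing import DEFAULT_OFFSETS, pause_scores, read_footprints, relative_pausing

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class PipelineConfig:
    cds_fasta: str = "cds.fasta"
    expression_tsv: str = "expression.tsv"
    modifications_tsv: str = "modifications.tsv"
    footprints: dict[str, str] = field(default_factory=dict)  # tissue -> path
    outdir: str = "pipeline_out"
    n_top: int = 200
    metrics: tuple[str, ...] = (METRIC_ISO, METRIC_TOTAL)
    reference_tissue: str = "brain"
    min_expected: float = 5.0
    log_transform_z: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_top < 2:
            raise PipelineError("configuration: n_top must be >= 2")
        for name in ("cds_fasta", "expression_tsv", "modifications_tsv"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise PipelineError(f"configuration: missing input file {path}")
        for tissue, path in self.footprints.items():
            if not Path(path).exists():
                raise PipelineError(
                    f"configuration: missing footprint file for {tissue}: {path}"
                )


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; returns the output directory."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    table = build_codon_table("DNA")
    n_warnings = 0

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # ---- stage: codon metrics ----------------------------------------
        stage = "codon_metrics"
        try:
            cds = read_cds_fasta(config.cds_fasta)
            expr = pd.read_csv(config.expression_tsv, sep="\t", index_col="gene_id")
            counts = count_matrix(cds, table)
            freqs = {
                METRIC_ISO: isoacceptor_frequency(counts, table),
                METRIC_TOTAL: total_frequency(counts, table),
            }
            tissues = [c.split("_")[0] for c in expr.columns]
            tissues = list(dict.fromkeys(tissues))
            baselines = {}
            tstats: dict[tuple[str, str, str], pd.DataFrame] = {}
            for metric in config.metrics:
                baseline = genome_baseline(freqs[metric], metric)
                baselines[metric] = baseline
                baseline.to_csv(out / f"baseline_{metric}.tsv", sep="\t")
                for tissue in tissues:
                    top, bottom = select_gene_sets(expr, tissue, config.n_top)
                    for direction, genes in (("top", top), ("bottom", bottom)):
                        ts = gene_set_tstat(
                            freqs[metric],
                            genes,
                            baseline,
                            table,
                            metric=metric,
                            tissue=tissue,
                            direction=direction,
                        )
                        tstats[(metric, tissue, direction)] = ts
                        ts.to_csv(
                            out / f"tstat_{metric}_{tissue}_{direction}.tsv", sep="\t"
                        )
            bias_rows = []
            for (metric, tissue, direction), ts in tstats.items():
                row = ending_bias_summary(ts)
                bias_rows.append(
                    {"metric": metric, "tissue": tissue, "direction": direction, **row}
                )
            pd.DataFrame(bias_rows).to_csv(
                out / "ending_bias.tsv", sep="\t", index=False
            )
        except Exception as exc:  # noqa: BLE001 - stage attribution
            raise PipelineError(f"stage {stage}: {exc}") from exc

        # ---- stage: modification profiles --------------------------------
        stage = "modification_profiles"
        try:
            mods_long = pd.read_csv(config.modifications_tsv, sep="\t")
            means = replicate_means(mods_long)
            zscores = tissue_zscores(means, log_transform=config.log_transform_z)
            means.to_csv(out / "modification_means.tsv", sep="\t")
            zscores.to_csv(out / "modification_zscores.tsv", sep="\t")
            pearson_matrix(zscores, "tissues").to_csv(
                out / "correlation_tissues.tsv", sep="\t"
            )
            pearson_matrix(means, "modifications").to_csv(
                out / "correlation_modifications.tsv", sep="\t"
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage {stage}: {exc}") from exc

        # ---- stage: linkage ------------------------------------------------
        stage = "linkage"
        try:
            reports = []
            for metric in config.metrics:
                for direction in ("top", "bottom"):
                    per_tissue = {
                        t: tstats[(metric, t, direction)]
                        for t in tissues
                        if (metric, t, direction) in tstats
                    }
                    report, full = linkage_report(
                        per_tissue,
                        zscores,
                        table,
                        metric=metric,
                        direction=direction,
                    )
                    reports.append(report)
                    full.to_csv(
                        out / f"linkage_matrix_{metric}_{direction}.tsv", sep="\t"
                    )
            pd.concat(reports, ignore_index=True).to_csv(
                out / "linkage_report.tsv", sep="\t", index=False
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage {stage}: {exc}") from exc

        # ---- stage: asite_pausing -----------------------------------------
        stage = "asite_pausing"
        pause_tables = {}
        try:
            for tissue, path in config.footprints.items():
                fp = read_footprints(path)
                pt = pause_scores(
                    fp,
                    cds,
                    table,
                    tissue=tissue,
                    min_expected=config.min_expected,
                )
                pause_tables[tissue] = pt
                pt.to_csv(out / f"pause_{tissue}.tsv", sep="\t")
            ref = config.reference_tissue
            if ref in pause_tables:
                lfc = {
                    t: relative_pausing(pause_tables[ref], pause_tables[t])
                    for t in pause_tables
                    if t != ref
                }
                if lfc:
                    pd.DataFrame(lfc).rename_axis("codon").to_csv(
                        out / f"pause_log2fc_{ref}_vs_all.tsv", sep="\t"
                    )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage {stage}: {exc}") from exc

        n_warnings = len(caught)

    manifest = {
        "package": "codonmod",
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_genes": len(cds),
        "n_tissues": len(tissues),
        "n_warnings": n_warnings,
        "n_pause_tissues": len(pause_tables),
    }
    (out / "manifest.txt").write_text(
        "".join(f"{k}={v}\n" for k, v in manifest.items())
    )
    return out
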