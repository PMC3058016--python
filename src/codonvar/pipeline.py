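"""End-to-end orchestration: sequences -> codon composition -> SOM ->
amplification factors -> variance partition -> enrichment.

The genome is clustered once; any number of fold-change datasets is then
evaluated against that shared clustering, producing one summary row per
dataset (within/total, between/total, F, p).  A synthetic block in the
config replaces file inputs with the generator, so the whole pipeline
can run on data with known ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import hypergeometric_enrichment, read_annotations
from .sequences import (
    CodonCountMatrix,
    CodonFrequencyMatrix,
    amino_acid_composition,
    codon_count_matrix,
    normalize_frequencies,
    read_cds_fasta,
)
from .som import SOMConfig, assign_clusters, init_som, train_som, u_matrix
from .synth import (
    FoldChangeTable,
    counts_to_fasta_records,
    noise_sigma_for_between_fraction,
    sample_world,
    simulate_dataset,
)
from .variance import (
    amplification_factors,
    partition_variance,
    per_cluster_summary,
    VariancePartitionResult,
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    mode: str = "codon"  # or "amino_acid"
    seed: int = 0
    fasta: str | None = None
    fold_changes: dict[str, str] = field(default_factory=dict)
    annotations: str | None = None
    annotation_format: str = "two_column_tsv"
    som: dict[str, Any] = field(default_factory=dict)
    enrichment: dict[str, Any] = field(default_factory=dict)
    synthetic: dict[str, Any] | None = None
    max_ambiguous_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.mode not in ("codon", "amino_acid"):
            raise ValueError(f"unknown mode {self.mode!r}")
        has_real = self.fasta is not None
        has_synth = self.synthetic is not None
        if has_real == has_synth:
            raise ValueError(
                "exactly one of a FASTA input or a synthetic block must be set"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        return cls(**raw)

    def som_config(self) -> SOMConfig:
        return SOMConfig(seed=self.seed, **self.som)


@dataclass
class ReportBundle:
    partitions: dict[str, VariancePartitionResult]
    cluster_sizes: list[int]
    summary: pd.DataFrame
    enrichment: pd.DataFrame | None
    provenance: dict[str, Any]
    output_dir: Path


def _significant(v: float, digits: int = 4) -> str:
    if not np.isfinite(v):
        return str(v)
    return f"{v:.{digits}g}"


def _load_fold_table(path: str | Path) -> FoldChangeTable:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: missing gene_id column")
    cols = {c.lower(): c for c in df.columns}
    p_col = cols.get("fold_protein")
    r_col = cols.get("fold_mrna")
    if p_col is None or r_col is None:
        raise ValueError(f"{path}: need fold_protein and fold_mrna columns")
    return FoldChangeTable(
        gene_ids=[str(g) for g in df["gene_id"]],
        f_P=df[p_col].to_numpy(dtype=float),
        f_R=df[r_col].to_numpy(dtype=float),
    )


def _synthetic_inputs(
    config: PipelineConfig,
) -> tuple[CodonCountMatrix, dict[str, FoldChangeTable]]:
    opts = dict(config.synthetic or {})
    target = opts.pop("target_between_fraction", None)
    opts.setdefault("seed", config.seed)
    truth = sample_world(**opts)
    if target is not None:
        truth = dataclasses.replace(
            truth, noise_sigma=noise_sigma_for_between_fraction(truth, target)
        )
    counts, table = simulate_dataset(truth)
    return counts, {"synthetic": table}


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> ReportBundle:
    """Execute all stages; writes stage outputs, a summary table and a
    machine-readable report under ``out_dir``.  On a stage failure the
    partial outputs remain with a MANIFEST marking incompleteness."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"status": "incomplete", "files": []}

    def emit(name: str) -> Path:
        manifest["files"].append(name)
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
        return out / name

    stage = "inputs"
    try:
        if config.synthetic is not None:
            counts, tables = _synthetic_inputs(config)
            seqs = counts_to_fasta_records(counts) if config.mode == "amino_acid" else None
            exclusion_counts = {"frame": 0, "ambiguity": 0}
        else:
            seqs = read_cds_fasta(config.fasta, config.max_ambiguous_fraction)
            exclusion_counts = {
                "frame": sum("multiple of 3" in e.reason for e in seqs.exclusions),
                "ambiguity": sum("ambiguous" in e.reason for e in seqs.exclusions),
            }
            counts = codon_count_matrix(seqs)
            tables = {
                name: _load_fold_table(path)
                for name, path in config.fold_changes.items()
            }

        stage = "composition"
        if config.mode == "amino_acid":
            freqs = amino_acid_composition(seqs)
        else:
            freqs = normalize_frequencies(counts)
        freqs.write_tsv(emit("composition.tsv"))

        stage = "som"
        som_cfg = config.som_config()
        model = train_som(init_som(som_cfg, freqs), freqs)
        clusters = assign_clusters(model, freqs)
        pd.DataFrame(
            {"gene_id": clusters.gene_ids, "cluster": clusters.labels}
        ).to_csv(emit("clusters.tsv"), sep="\t", index=False)
        pd.DataFrame(model.codebook, columns=list(model.feature_labels)).to_csv(
            emit("codebook.tsv"), sep="\t", index=False
        )
        pd.DataFrame(u_matrix(model)).to_csv(
            emit("u_matrix.tsv"), sep="\t", index=False, header=False
        )

        stage = "variance_partition"
        partitions: dict[str, VariancePartitionResult] = {}
        exclusions_per_table: dict[str, int] = {}
        for name, table in tables.items():
            amp = amplification_factors(table)
            exclusions_per_table[name] = len(amp.excluded)
            partitions[name] = partition_variance(amp, clusters)
            per_cluster_summary(amp, clusters).to_csv(
                emit(f"per_cluster.{name}.tsv"), sep="\t", index=False
            )
        summary = pd.DataFrame(
            {
                "dataset": list(partitions),
                "within_total": [
                    _significant(r.frac_within) for r in partitions.values()
                ],
                "between_total": [
                    _significant(r.frac_between) for r in partitions.values()
                ],
                "f_stat": [_significant(r.f_stat) for r in partitions.values()],
                "p_value": [_significant(r.p_value) for r in partitions.values()],
                "degenerate": [r.degenerate or "" for r in partitions.values()],
            }
        )
        summary.to_csv(emit("summary.tsv"), sep="\t", index=False)

        stage = "enrichment"
        enrich_df = None
        if config.annotations is not None:
            ann = read_annotations(config.annotations, config.annotation_format)
            enrich_df = hypergeometric_enrichment(
                clusters, ann, **config.enrichment
            )
            enrich_df.to_csv(emit("enrichment.tsv"), sep="\t", index=False)

        stage = "report"
        provenance = {
            "config": dataclasses.asdict(config),
            "seed": config.seed,
            "codonvar_version": __version__,
            "python_version": sys.version.split()[0],
            "exclusions": {
                "sequence": exclusion_counts,
                "fold_change": exclusions_per_table,
            },
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        }
        report = {
            "partitions": {k: v.to_dict() for k, v in partitions.items()},
            "cluster_sizes": [int(s) for s in clusters.cluster_sizes],
            "provenance": provenance,
        }
        (out / "report.json").write_text(json.dumps(report, indent=2))
        manifest["files"].append("report.json")
        manifest["status"] = "complete"
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise StageError(stage, exc) from exc

    return ReportBundle(
        partitions=partitions,
        cluster_sizes=[int(s) for s in clusters.cluster_sizes],
        summary=summary,
        enrichment=enrich_df,
        provenance=provenance,
        output_dir=out,
    )
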