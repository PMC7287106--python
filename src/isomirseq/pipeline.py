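"""End-to-end orchestration: simulate -> clean -> align -> call -> quantify ->
test -> report, with every stage artifact written as a plain table.

The funnel (raw reads -> length-filtered -> non-contaminant -> aligned ->
expressed -> strongly modulated) is logged per sample and echoed into
``qc.json`` so shrinkage at each stage is auditable. All randomness flows
from the single config seed; rerunning a config byte-reproduces every table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import align as align_mod
from . import diffexp as de
from . import quantify as qt
from .align import AlignParams, HairpinAlignment
from .isomir import IsomiRCatalog, assign_names, catalog_summary, classify
from .preprocess import CleanReadBatch, clean_reads, filter_contaminants
from .reference import ReferenceSet, load_reference, write_reference
from .simulate import SimulationConfig, emit_reads, simulate_counts, simulate_reference

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    output_dir: str = "isomirseq_out"
    seed: int = 0
    simulate: bool = True
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    reference_fasta: str | None = None
    mature_table: str | None = None
    decoy_fasta: str | None = None
    manifest: str | None = None
    fastq: dict = field(default_factory=dict)  # sample -> path (non-simulated runs)
    adapter: str | None = None
    min_len: int = 15
    max_len: int = 40
    align: dict = field(default_factory=dict)  # AlignParams overrides
    min_mean_percent: float = 0.001
    min_mean_cpm: float = 10.0
    lfc_threshold: float = 2.0
    fdr_threshold: float = 0.1
    concordance_lfc: float = 0.5
    prior_df: float = 10.0
    reference_group: str = "A"
    comparison_group: str = "B"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def process_sample(
    fastq: str | Path,
    sample_id: str,
    ref: ReferenceSet,
    decoy_fasta: str | Path | None,
    params: AlignParams,
    adapter: str | None = None,
    min_len: int = 15,
    max_len: int = 40,
) -> tuple[CleanReadBatch, list[HairpinAlignment], dict]:
    """Clean, decontaminate and align one sample; returns alignments + QC."""
    batch = clean_reads(fastq, sample_id, min_len=min_len, max_len=max_len, adapter=adapter)
    if decoy_fasta is not None:
        batch = filter_contaminants(batch, decoy_fasta)
    batch.check_conservation()
    alignments, unaligned = align_mod.align_to_hairpins(batch, ref, params)
    qc = {
        "sample": sample_id,
        "n_raw": batch.n_raw,
        "n_len_filtered": batch.n_len_filtered,
        "n_contaminant": batch.n_contaminant,
        "n_retained": batch.n_retained,
        "n_unaligned": unaligned,
        "n_aligned": batch.n_retained - unaligned,
    }
    log.info("%s: %s", sample_id, qc)
    return batch, alignments, qc


def call_and_count(
    alignments_per_sample: dict[str, list[HairpinAlignment]],
) -> tuple[IsomiRCatalog, dict[str, qt.CountMatrix]]:
    """Classify alignments, name isomiRs over the pooled cohort, build both
    count matrices."""
    calls_per_sample = {
        s: [classify(a) for a in alns] for s, alns in alignments_per_sample.items()
    }
    catalog = assign_names(c for calls in calls_per_sample.values() for c in calls)
    matrices = {
        "canonical": qt.build_matrix(calls_per_sample, catalog, level="canonical"),
        "isomir": qt.build_matrix(calls_per_sample, catalog, level="isomir"),
    }
    return catalog, matrices


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the output directory.

    With ``config.simulate`` a synthetic cohort (reference, decoys, FASTQ,
    ground truth) is generated first; otherwise reference/FASTQ/manifest
    paths must be supplied.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    if config.simulate:
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", config.seed)
        cfg = SimulationConfig(**sim_kwargs)
        ref = simulate_reference(cfg.n_mirnas, cfg.seed)
        write_reference(ref, out / "reference.fasta", out / "matures.tsv")
        counts, truth = simulate_counts(cfg, ref)
        counts.to_csv(out / "true_counts.tsv", sep="\t")
        fastqs = emit_reads(counts, truth, ref, cfg, out / "reads")
        decoy_fasta: Path | None = out / "reads" / "decoys.fasta"
        groups = truth.groups
        truth.log2fc.rename("true_log2fc").to_csv(out / "true_log2fc.tsv", sep="\t")
    else:
        if not (config.reference_fasta and config.mature_table and config.fastq and config.manifest):
            missing = [k for k in ("reference_fasta", "mature_table", "fastq", "manifest")
                       if not getattr(config, k)]
            raise ValueError(f"config missing required fields: {missing}")
        ref = load_reference(config.reference_fasta, config.mature_table)
        fastqs = {s: Path(p) for s, p in config.fastq.items()}
        decoy_fasta = Path(config.decoy_fasta) if config.decoy_fasta else None
        groups = qt.load_manifest(config.manifest)

    params = AlignParams(**config.align)
    alignments_per_sample: dict[str, list[HairpinAlignment]] = {}
    qc_all = []
    for sample, fq in fastqs.items():
        _, alns, qc = process_sample(
            fq, sample, ref, decoy_fasta, params,
            adapter=config.adapter, min_len=config.min_len, max_len=config.max_len,
        )
        alignments_per_sample[sample] = alns
        qc_all.append(qc)
    (out / "qc.json").write_text(json.dumps(qc_all, indent=2))

    catalog, matrices = call_and_count(alignments_per_sample)
    catalog.to_frame().to_csv(out / "catalog.tsv", sep="\t", index=False)

    results = {}
    for level, matrix in matrices.items():
        matrix.counts.to_csv(out / f"counts_{level}.tsv", sep="\t")
        expressed = qt.expression_filter(matrix, config.min_mean_percent)
        pd.Series(expressed, name="feature").to_csv(
            out / f"expressed_{level}.tsv", sep="\t", index=False
        )
        shares = qt.abundance_shares(matrix, groups)
        shares.to_csv(out / f"abundance_shares_{level}.tsv", sep="\t", index=False)
        sub = matrix.counts.loc[matrix.counts.index.intersection(expressed)]
        table = de.differential_expression(
            sub, groups, config.reference_group, config.comparison_group,
            min_mean_cpm=config.min_mean_cpm, prior_df=config.prior_df,
            fdr_threshold=config.fdr_threshold, lfc_threshold=config.lfc_threshold,
        )
        table.to_csv(out / f"diffexp_{level}.tsv", sep="\t")
        strong = de.select_strong(
            table, lfc_threshold=config.lfc_threshold, fdr_threshold=config.fdr_threshold
        )
        strong.to_csv(out / f"strong_{level}.tsv", sep="\t")
        results[level] = (table, strong)
        log.info("%s level: %d expressed, %d tested, %d strong (%d up / %d down)",
                 level, len(expressed), len(table), len(strong),
                 int((strong["direction"] == "up").sum()),
                 int((strong["direction"] == "down").sum()))

    summary = catalog_summary(catalog, matrices["isomir"].counts.astype(float))
    summary["by_class"].to_csv(out / "isomir_class_summary.tsv", sep="\t")

    checksums = {
        p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))
    }
    (out / "checksums.json").write_text(json.dumps(checksums, indent=2))
    return out


def render_reports(outdir: str | Path) -> list[Path]:
    """Figure analogues (abundance pie, fold-change bars) from on-disk tables.

    Every number plotted is read back from a TSV the pipeline wrote; nothing
    is recomputed here.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    written: list[Path] = []

    shares_path = outdir / "abundance_shares_canonical.tsv"
    if shares_path.exists():
        shares = pd.read_csv(shares_path, sep="\t")
        groups = shares["group"].unique()
        fig, axes = plt.subplots(1, len(groups), figsize=(5 * len(groups), 5), squeeze=False)
        for ax, g in zip(axes.ravel(), groups):
            sub = shares[shares["group"] == g]
            rest = 100 - sub["share_percent"].sum()
            vals = list(sub["share_percent"]) + ([rest] if rest > 1e-9 else [])
            labels = list(sub["feature"]) + (["other"] if rest > 1e-9 else [])
            ax.pie(vals, labels=labels, textprops={"fontsize": 6})
            ax.set_title(f"group {g}")
        path = outdir / "abundance_pie.png"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    for level in ("canonical", "isomir"):
        strong_path = outdir / f"strong_{level}.tsv"
        if not strong_path.exists():
            continue
        strong = pd.read_csv(strong_path, sep="\t", index_col=0)
        fig, ax = plt.subplots(figsize=(6, max(2, 0.25 * len(strong))))
        if len(strong):
            ax.barh(strong.index.astype(str), strong["log2fc"])
        ax.set_xlabel("log2 fold-change (comparison vs reference)")
        path = outdir / f"log2fc_{level}.png"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written
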