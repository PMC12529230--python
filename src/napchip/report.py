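"""End-to-end orchestration: characterize a peak table against a genome and
annotation, or write a full simulation bundle to disk."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atstats import at_report
from .genome import (
    GeneSet,
    GenomeAssembly,
    GenomicInterval,
    genic_partition,
    pooled_at,
    write_bed,
)
from .peaks import (
    PeakTable,
    SummitContextClassifier,
    annotate_genes,
    category_report,
    merge_subpeaks,
    width_fe_correlation,
)
from .simulate import (
    GenomeSpec,
    OccupancySpec,
    call_toy_peaks,
    occupancy_track,
    sample_coverage,
)

__all__ = ["RunConfig", "run_characterize", "run_simulate"]

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Analysis parameters shared by the CLI subcommands."""

    flank: int = 30
    min_intergenic_bp: int = 30
    fe_threshold: float = 2.0
    k: int = 20
    t_variant: str = "welch"
    background: str = "per_region"
    n_perm: int = 999
    merge_gap_bp: int = 200
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_characterize(
    genome: GenomeAssembly,
    genes: GeneSet,
    peaks: PeakTable,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Full characterization of one peak table: context calls, category
    statistics, AT comparisons, width-enrichment correlation, parent
    regions and gene annotations. Writes TSV/JSON outputs when ``outdir``
    is given and returns the report as a dict of DataFrames/objects."""
    config = config or RunConfig()
    peaks.validate_against(genome)
    partition = genic_partition(genes, genome)

    clf = SummitContextClassifier(
        flank=config.flank, min_intergenic_bp=config.min_intergenic_bp,
    ).fit(partition.intergenic, genome)
    contexts = clf.transform(peaks)

    categories = category_report(
        peaks, contexts, genome, k=config.k, fe_threshold=config.fe_threshold)
    comparisons = at_report(
        peaks, contexts, genome, partition.intergenic, partition.coding,
        k=config.k, fe_threshold=config.fe_threshold, variant=config.t_variant,
        background=config.background, flank=config.flank, seed=config.seed)

    try:
        correlation = width_fe_correlation(peaks)
        corr_dict = asdict(correlation)
    except ValueError as exc:
        correlation = None
        corr_dict = {"error": str(exc)}

    regions = merge_subpeaks(peaks, max_gap_bp=config.merge_gap_bp)
    region_rows = []
    for region in regions:
        covered = annotate_genes(region.interval, genes)
        region.covered_genes = covered
        region_rows.append({
            "region_id": region.region_id,
            "contig": region.interval.contig,
            "start": region.interval.start,
            "end": region.interval.end,
            "n_subpeaks": region.n_subpeaks,
            "members": ",".join(region.members),
            "source_peaks": ",".join(region.member_source_ids),
            "max_fold_enrichment": region.max_fold_enrichment,
            "covered_genes": ",".join(g.locus_tag for g in covered),
        })
    regions_df = pd.DataFrame(region_rows)

    gene_rows = []
    for row in peaks:
        span = GenomicInterval(row.contig, int(row.start), int(row.end))
        covered = annotate_genes(span, genes)
        gene_rows.append({
            "peak_id": row.peak_id,
            "covered_genes": ";".join(
                f"{g.locus_tag}:{g.product}" if g.product else g.locus_tag
                for g in covered),
        })
    annotations_df = pd.DataFrame(gene_rows)

    report = {
        "schema_version": SCHEMA_VERSION,
        "napchip_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "n_peaks": len(peaks),
        "genome_bp": genome.total_length,
        "intergenic_fraction": partition.intergenic.total_length / genome.total_length,
        "intergenic_at": pooled_at(genome, partition.intergenic)
        if len(partition.intergenic) else float("nan"),
        "coding_at": pooled_at(genome, partition.coding)
        if len(partition.coding) else float("nan"),
        "contexts": contexts,
        "categories": categories,
        "at_comparisons": comparisons,
        "correlation": corr_dict,
        "parent_regions": regions_df,
        "gene_annotations": annotations_df,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        contexts.to_csv(outdir / "contexts.tsv", sep="\t", index=False)
        categories.to_csv(outdir / "categories.tsv", sep="\t", index=False)
        comparisons.to_csv(outdir / "at_comparisons.tsv", sep="\t", index=False)
        regions_df.to_csv(outdir / "parent_regions.tsv", sep="\t", index=False)
        annotations_df.to_csv(outdir / "gene_annotations.tsv", sep="\t", index=False)
        scalar = {k: v for k, v in report.items()
                  if not isinstance(v, pd.DataFrame)}
        with open(outdir / "report.json", "w") as fh:
            json.dump(scalar, fh, indent=2, default=float)
    return report


def run_simulate(
    outdir: str | Path,
    genome_spec: GenomeSpec | None = None,
    occupancy_spec: OccupancySpec | None = None,
    depth: float = 50.0,
    n_replicates: int = 3,
    seed: int = 0,
    smoothing_bp: int = 300,
    fe_cutoff: float = 1.5,
    min_width_bp: int = 100,
    merge_gap_bp: int = 200,
) -> dict:
    """Write a complete simulation bundle (FASTA, GFF3, bedGraph coverage,
    peak tables, ground truth, manifest with checksums) and return the
    manifest dict."""
    genome_spec = genome_spec or GenomeSpec()
    occupancy_spec = occupancy_spec or OccupancySpec()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    master = np.random.SeedSequence(seed)
    genome_seed, coverage_seed = master.spawn(2)
    genome, genes = simulate_genome_with_seed(genome_spec, genome_seed)
    contig = genome_spec.contig_id
    expected = occupancy_track(genome, occupancy_spec)[contig]
    coverage = sample_coverage(expected, depth=depth, n_replicates=n_replicates,
                               seed=coverage_seed, contig=contig)
    peaks = call_toy_peaks(coverage, smoothing_bp=smoothing_bp,
                           fe_cutoff=fe_cutoff, min_width_bp=min_width_bp,
                           merge_gap_bp=merge_gap_bp)

    genome.to_fasta(outdir / "genome.fa")
    _write_gff3(genes, genome, outdir / "genes.gff3")
    for r in range(n_replicates):
        _write_bedgraph(contig, coverage.ip[r], outdir / f"ip_rep{r + 1}.bedgraph")
        _write_bedgraph(contig, coverage.input[r], outdir / f"input_rep{r + 1}.bedgraph")
    peaks.to_summary_tsv(outdir / "peaks.tsv")
    peaks.to_narrowpeak(outdir / "peaks.narrowPeak")

    partition = genic_partition(genes, genome)
    write_bed(partition.intergenic, outdir / "intergenic.bed")
    truth = {
        "seed": seed,
        "genome_spec": asdict(genome_spec),
        "occupancy_spec": asdict(occupancy_spec),
        "depth": depth,
        "n_replicates": n_replicates,
        "n_peaks": len(peaks),
        "intergenic_fraction": partition.intergenic.total_length / genome.total_length,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, default=float)

    manifest = {"files": {}}
    for path in sorted(outdir.iterdir()):
        if path.name == "manifest.json":
            continue
        manifest["files"][path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def simulate_genome_with_seed(spec: GenomeSpec, seed):
    from .simulate import simulate_genome

    rng = np.random.default_rng(seed)
    return simulate_genome(spec, rng)


def _write_gff3(genes: GeneSet, genome: GenomeAssembly, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig, length in genome.lengths.items():
            fh.write(f"##sequence-region {contig} 1 {length}\n")
        for gene in genes:
            iv = gene.interval
            attrs = f"ID={gene.locus_tag};locus_tag={gene.locus_tag}"
            if gene.product:
                attrs += f";product={gene.product}"
            fh.write(
                f"{iv.contig}\tnapchip\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand if iv.strand != '.' else '+'}\t.\t{attrs}\n")


def _write_bedgraph(contig: str, values: np.ndarray, path: Path) -> None:
    """Run-length-compressed bedGraph of a per-bp track."""
    values = np.asarray(values)
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(values)]])
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            fh.write(f"{contig}\t{s}\t{e}\t{values[s]}\n")
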