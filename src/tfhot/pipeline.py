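"""End-to-end orchestration: classify -> annotate -> matrices -> signal ->
enrichment, from a single config, with a machine-readable report.

Optional stages degrade gracefully: without a gene model the annotation
and gene-matrix stages are skipped with a warning, without tags there are
no height statistics, and so on. Every number in the report is a pure
function of the inputs, the config and the seed.
"""

from __future__ import annotations

import json
import logging
import os

import pandas as pd
from dataclasses import dataclass, field

import yaml

from . import __version__
from .annotation import feature_distribution
from .enrichment import (
    MotifPattern,
    factor_hotspot_occupancy,
    gene_set_enrichment,
    motif_group_enrichment,
    region_overlap_enrichment,
)
from .intervals import (
    read_bed,
    read_bedgraph,
    read_chrom_sizes,
    read_genes,
    read_peaks,
    read_tags,
    write_regions,
)
from .matrices import (
    build_gene_matrix,
    build_peak_matrix,
    cluster_columns,
    column_correlation,
    unify_loci,
)
from .occupancy import (
    OccupancyConfig,
    classify_regions,
    group_summary,
    merge_peaks,
    occupancy_spectrum,
)
from .annotation import map_to_gene
from .signal import (
    average_profile,
    classify_modality,
    compare_heights,
    height_table,
)

logger = logging.getLogger("tfhot")


@dataclass
class RunConfig:
    """Validated inputs and options of one pipeline run."""

    manifest: str
    out_dir: str
    genes: str | None = None
    genes_format: str = "bed12"
    chrom_sizes: str | None = None
    fasta: str | None = None
    tags: dict[str, str] = field(default_factory=dict)  # cell type -> BED
    signal: dict[str, str] = field(default_factory=dict)  # cell type -> bedGraph
    annotation_bed: str | None = None
    annotation_name: str = "annotation"
    gene_list: str | None = None
    motifs: dict[str, str] = field(default_factory=dict)  # name -> IUPAC
    hotspot_min: int = 6
    merge_gap: int = 0
    profile_window: int = 10_000
    profile_bin: int = 100
    height_window: int = 400
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        paths = [self.manifest, self.genes, self.chrom_sizes, self.fasta,
                 self.annotation_bed, self.gene_list]
        paths += list(self.tags.values()) + list(self.signal.values())
        for p in paths:
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(p)


def read_manifest(path: str) -> list[tuple[str, str, str]]:
    """Read a peak-file manifest TSV: path, factor, cell_type (header
    optional); relative paths are resolved against the manifest's
    directory."""
    base = os.path.dirname(os.path.abspath(path))
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if lineno == 1 and fields[:3] == ["path", "factor", "cell_type"]:
                continue
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: need path, factor, cell_type")
            p = fields[0]
            if not os.path.isabs(p):
                p = os.path.join(base, p)
            rows.append((p, fields[1], fields[2]))
    return rows


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage; write outputs and return the report."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    occ_config = OccupancyConfig(config.hotspot_min, config.merge_gap)
    report: dict = {
        "tool": "tfhot",
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: v for k, v in config.__dict__.items()
        },
        "cell_types": {},
    }

    entries = read_manifest(config.manifest)
    by_ct: dict[str, list] = {}
    for p, factor, ct in entries:
        fmt = "narrowPeak" if p.endswith(("narrowPeak", "npk")) else "bed"
        by_ct.setdefault(ct, []).append(
            read_peaks(p, fmt, factor=factor, cell_type=ct)
        )

    genes = read_genes(config.genes, config.genes_format) if config.genes else None

    regions_by_ct = {}
    for ct in sorted(by_ct):
        logger.info("classify: %s (%d peak sets)", ct, len(by_ct[ct]))
        regions = merge_peaks(by_ct[ct], occ_config)
        regions, counts = classify_regions(regions, occ_config)
        regions_by_ct[ct] = regions
        write_regions(regions, os.path.join(config.out_dir, f"{ct}.regions.bed"))
        spectrum = occupancy_spectrum(regions)
        spectrum.to_csv(
            os.path.join(config.out_dir, f"{ct}.spectrum.tsv"), sep="\t"
        )
        ct_report = {"groups": group_summary(counts)}
        report["cell_types"][ct] = ct_report

        hotspots = [r for r in regions if r.group == "hotspot"]
        if hotspots:
            pioneers = factor_hotspot_occupancy(by_ct[ct], hotspots)
            pioneers.to_csv(
                os.path.join(config.out_dir, f"{ct}.pioneers.tsv"),
                sep="\t", index=False,
            )
            ct_report["pioneers"] = pioneers[pioneers.pioneer].factor.tolist()

        if genes is not None:
            groups = _group_regions(regions)
            fractions, tests = feature_distribution(
                {g: [r.interval for r in rs] for g, rs in groups.items()}, genes
            )
            fractions.to_csv(
                os.path.join(config.out_dir, f"{ct}.features.tsv"), sep="\t"
            )
            ct_report["feature_fractions"] = {
                g: {f: _nan_to_none(v) for f, v in row.items()}
                for g, row in fractions.iterrows()
            }

        if ct in config.tags:
            tags = read_tags(config.tags[ct])
            heights = height_table(regions, tags, config.height_window)
            heights.to_csv(
                os.path.join(config.out_dir, f"{ct}.heights.tsv"),
                sep="\t", index=False,
            )
            groups = {
                g: sub.height.to_numpy()
                for g, sub in heights.groupby("group")
                if len(sub)
            }
            if len(groups) >= 2:
                mwu = compare_heights(groups)
                mwu.to_csv(
                    os.path.join(config.out_dir, f"{ct}.mwu.tsv"),
                    sep="\t", index=False,
                )
                ct_report["height_tests"] = mwu.to_dict(orient="records")

        if ct in config.signal:
            sig = read_bedgraph(config.signal[ct])
            sizes = read_chrom_sizes(config.chrom_sizes) if config.chrom_sizes else None
            modality = {}
            for g, rs in _group_regions(regions).items():
                if not rs:
                    continue
                pm = average_profile(
                    [(r.interval.chrom, r.summit) for r in rs],
                    sig,
                    config.profile_window,
                    config.profile_bin,
                    sizes,
                )
                call = classify_modality(pm.aggregate, config.profile_bin)
                modality[g] = call.call
            ct_report["modality"] = modality
        elif config.signal:
            logger.warning("no signal track for %s; modality skipped", ct)

        if config.annotation_bed:
            anno = read_bed(config.annotation_bed)
            results = region_overlap_enrichment(
                _group_regions(regions), anno, regions, config.annotation_name
            )
            ct_report["region_enrichment"] = [r.to_dict() for r in results]

        if config.fasta and config.motifs:
            from pyfaidx import Fasta

            from .enrichment import gc_group_comparison
            from .intervals import GenomicInterval, fetch_sequence

            fa = Fasta(config.fasta)
            half = config.height_window // 2
            group_seqs: dict[str, list[str]] = {}
            for g, rs in _group_regions(regions).items():
                seqs = []
                for r in rs:
                    c = r.summit
                    seqs.append(fetch_sequence(
                        fa, GenomicInterval(r.interval.chrom, max(0, c - half),
                                            c + half)))
                group_seqs[g] = seqs
            motif_tables = []
            for name, consensus in sorted(config.motifs.items()):
                frac, tests = motif_group_enrichment(
                    group_seqs, MotifPattern(name, consensus)
                )
                motif_tables.append((frac, tests))
            pd.concat([f for f, _ in motif_tables]).to_csv(
                os.path.join(config.out_dir, f"{ct}.motif_fractions.tsv"),
                sep="\t", index=False,
            )
            gc_means, _gc_tests = gc_group_comparison(group_seqs)
            ct_report["gc_means"] = {
                row["group"]: row["mean_gc"] for _, row in gc_means.iterrows()
            }
            ct_report["motif_fractions"] = {
                name: {
                    row["group"]: row["fraction"]
                    for _, row in frac.iterrows()
                }
                for (name, _), (frac, _) in zip(
                    sorted(config.motifs.items()), motif_tables
                )
            }

        if config.gene_list and genes is not None:
            with open(config.gene_list) as fh:
                query = [l.strip() for l in fh if l.strip()]
            group_genes = {}
            for g, rs in _group_regions(regions).items():
                ids = {
                    a.gene_id
                    for a in (map_to_gene(r.interval, genes) for r in rs)
                    if a.gene_id
                }
                group_genes[g] = sorted(ids)
            universe = [gm.gene_id for gm in genes]
            try:
                results = gene_set_enrichment(group_genes, query, universe)
                ct_report["gene_set_enrichment"] = [r.to_dict() for r in results]
            except ValueError as exc:
                logger.warning("gene-set enrichment skipped for %s: %s", ct, exc)

    # cross-cell-type matrices
    if regions_by_ct:
        loci, mapping = unify_loci(regions_by_ct)
        peak_matrix = build_peak_matrix(loci, mapping, regions_by_ct)
        _write_sparse(peak_matrix, os.path.join(config.out_dir, "peak_matrix.tsv"))
        report["peak_matrix_shape"] = list(peak_matrix.shape)
        if peak_matrix.shape[0] >= 2 and peak_matrix.shape[1] >= 2:
            corr = column_correlation(peak_matrix)
            corr.to_csv(os.path.join(config.out_dir, "correlation.tsv"), sep="\t")
            tree = cluster_columns(corr)
            newick = tree.to_newick()
            with open(os.path.join(config.out_dir, "tree.nwk"), "w") as fh:
                fh.write(newick + "\n")
            report["dendrogram"] = newick
        if genes is not None:
            gene_matrix = build_gene_matrix(regions_by_ct, genes)
            _write_sparse(gene_matrix, os.path.join(config.out_dir, "gene_matrix.tsv"))
            report["gene_matrix_shape"] = list(gene_matrix.shape)

    report_path = os.path.join(config.out_dir, "report.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    return report


def _group_regions(regions) -> dict[str, list]:
    out: dict[str, list] = {"singleton": [], "combinatorial": [], "hotspot": []}
    for r in regions:
        out[r.group].append(r)
    return {g: rs for g, rs in out.items() if rs}


def _nan_to_none(v):
    try:
        return None if v != v else float(v)
    except TypeError:  # pragma: no cover
        return v


def _write_sparse(df, path: str) -> None:
    """Write a binary matrix as row/column/value triplets."""
    with open(path, "w") as fh:
        fh.write("row\tcolumn\tvalue\n")
        arr = df.to_numpy()
        rows, cols = arr.nonzero()
        for i, j in zip(rows, cols):
            fh.write(f"{df.index[i]}\t{df.columns[j]}\t1\n")
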