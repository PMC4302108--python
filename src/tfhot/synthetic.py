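"""Synthetic multi-cell-type, multi-factor binding landscapes with ground
truth.

The generator plants loci on a toy chromosome in three occupancy tiers --
singletons (one bound factor), combinatorials (intermediate occupancy) and
hotspots (>= ``hotspot_min`` factors) -- and emits per-factor peak files,
tag pseudo-samples with occupancy-correlated heights, enhancer-mark signal
whose aggregate is mono- or bimodal by tier, genome sequence with planted
IUPAC motifs, annotation region sets with tier-specific overlap rates,
gene models placed so each locus has a known nearest-gene target, and
differential-expression gene lists biased toward chosen tiers. A truth
manifest records everything planted, so every pipeline stage can be
checked against construction.

Defaults emulate the structure of a published multi-factor compendium:
ten cell types assayed for 6-21 factors each (108 peak sets in total), an
occupancy spectrum with roughly half the regions bound by a single factor
and about 1% hotspots, hotspot tag counts well above singleton counts,
and a bimodal enhancer-mark profile at hotspots.
"""

from __future__ import annotations

import copy
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from .intervals import (
    BedGraph,
    GeneModel,
    GenomicInterval,
    PeakRecord,
    PeakSet,
    TagCollection,
    write_bed,
    write_bed12,
    write_fasta,
    write_narrowpeak,
    write_tags,
)
from .enrichment import IUPAC, MotifPattern

# sub-stream codes so all randomness flows from one config seed
_STREAM_LANDSCAPE = 0
_STREAM_TAGS = 1
_STREAM_SIGNAL = 2
_STREAM_SEQUENCE = 3
_STREAM_DE = 4

DEFAULT_CELL_TYPES = {
    "ES_a": 12,
    "ES_b": 13,
    "HPC": 12,
    "Ery": 10,
    "MK": 8,
    "Bcell": 9,
    "Tcell": 6,
    "Mac": 9,
    "DC": 21,
    "MEL": 8,
}  # 108 peak sets across 10 cell types, 6-21 factors each


@dataclass
class TierSpec:
    """One planted occupancy tier and its downstream signal properties."""

    name: str
    n_loci: int
    occupancy: tuple[int, int]  # inclusive range of distinct factors
    mean_height: float = 10.0  # negative-binomial mean tag count
    motif_rate: float = 0.0
    annotation_rate: float = 0.0
    de_rate: float = 0.0
    profile: str = "monomodal"  # or "bimodal"
    profile_offset: int = 500  # bp, bimodal flank offset
    signal_amplitude: float = 1.0


def default_tiers(
    n_loci: int = 1000, hotspot_min: int = 6, max_occupancy: int = 21
) -> list[TierSpec]:
    """Study-shaped tier mix: ~52% singletons, ~47% combinatorials, 1%
    hotspots, with heights, motif/annotation rates and profile shapes
    increasing with occupancy."""
    n_hot = max(1, round(0.01 * n_loci))
    n_single = round(0.52 * n_loci)
    n_comb = n_loci - n_single - n_hot
    return [
        TierSpec(
            "singleton", n_single, (1, 1), mean_height=10.0, motif_rate=0.05,
            annotation_rate=0.02, de_rate=0.10, profile="monomodal",
            signal_amplitude=1.0,
        ),
        TierSpec(
            "combinatorial", n_comb, (2, hotspot_min - 1), mean_height=30.0,
            motif_rate=0.20, annotation_rate=0.10, de_rate=0.15,
            profile="monomodal", signal_amplitude=2.0,
        ),
        TierSpec(
            "hotspot", n_hot, (hotspot_min, max_occupancy), mean_height=80.0,
            motif_rate=0.60, annotation_rate=0.30, de_rate=0.50,
            profile="bimodal", signal_amplitude=4.0,
        ),
    ]


@dataclass
class LandscapeConfig:
    """Full specification of a synthetic landscape."""

    seed: int = 0
    chrom: str = "chrS"
    chrom_length: int = 20_000_000
    cell_types: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CELL_TYPES)
    )
    tiers: list[TierSpec] = field(default_factory=default_tiers)
    peak_width: tuple[int, int] = (200, 400)
    jitter_sd: float = 0.0
    shared_fraction: float = 0.3
    hotspot_min: int = 6

    def __post_init__(self) -> None:
        if isinstance(self.tiers and self.tiers[0], dict):  # from YAML/JSON
            self.tiers = [TierSpec(**t) for t in self.tiers]
        self.peak_width = tuple(self.peak_width)  # type: ignore[assignment]
        for tier in self.tiers:
            tier.occupancy = tuple(tier.occupancy)  # type: ignore[assignment]
            lo, hi = tier.occupancy
            if tier.name == "singleton" and (lo, hi) != (1, 1):
                raise ValueError("singleton tier must have occupancy (1, 1)")
            if tier.name == "hotspot" and lo < self.hotspot_min:
                raise ValueError(
                    "hotspot tier occupancy must start at hotspot_min"
                )
            if tier.name == "combinatorial" and not (1 < lo <= hi < self.hotspot_min):
                raise ValueError(
                    "combinatorial occupancy must lie strictly between "
                    "1 and hotspot_min"
                )
            for rate in (tier.motif_rate, tier.annotation_rate, tier.de_rate):
                if not 0 <= rate <= 1:
                    raise ValueError("tier rates must be in [0, 1]")
        wmin, wmax = self.peak_width
        if not (0 < wmin <= wmax):
            raise ValueError("peak width range invalid")
        if self.jitter_sd < 0 or self.jitter_sd >= wmin / 2:
            raise ValueError("jitter sd must be in [0, min peak width / 2)")
        if not 0 <= self.shared_fraction <= 1:
            raise ValueError("shared_fraction must be in [0, 1]")
        for ct, nf in self.cell_types.items():
            if nf < max(t.occupancy[1] if t.name != "hotspot" else t.occupancy[0]
                        for t in self.tiers):
                raise ValueError(
                    f"cell type {ct}: {nf} factors cannot realize the "
                    "configured tier occupancies"
                )

    @property
    def n_loci_per_cell_type(self) -> int:
        return sum(t.n_loci for t in self.tiers)

    def tier(self, name: str) -> TierSpec:
        for t in self.tiers:
            if t.name == name:
                return t
        raise KeyError(name)


def _rng(config_seed: int, stream: int, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng([config_seed & 0x7FFFFFFF, stream, salt])


def _spaced_positions(
    rng: np.random.Generator, length: int, n: int, min_gap: int, margin: int
) -> np.ndarray:
    """n sorted positions with pairwise gaps >= min_gap, uniform among all
    valid configurations (spacing construction)."""
    free = length - 2 * margin - (n - 1) * min_gap
    if free <= 0:
        raise ValueError(
            f"chromosome of {length} bp too short for {n} loci at min "
            f"gap {min_gap}"
        )
    u = np.sort(rng.integers(0, free, size=n))
    return margin + u + np.arange(n) * min_gap


def generate_landscape(config: LandscapeConfig) -> tuple[dict[str, list[PeakSet]], dict]:
    """Generate per-factor peak sets for every cell type plus the truth
    manifest.

    Loci are placed with a minimum center gap of twice the maximum peak
    width, so peaks of different loci can never merge; positional jitter
    is clipped at two standard deviations to preserve that guarantee.
    Byte-identical output is guaranteed for identical (config, seed).
    """
    rng = _rng(config.seed, _STREAM_LANDSCAPE)
    wmin, wmax = config.peak_width
    min_gap = 2 * wmax
    n_per_ct = config.n_loci_per_cell_type
    n_shared = int(round(config.shared_fraction * n_per_ct))
    n_private = n_per_ct - n_shared
    cts = list(config.cell_types)
    pool_size = n_shared + len(cts) * n_private
    positions = _spaced_positions(
        rng, config.chrom_length, pool_size, min_gap, margin=wmax + 100
    )
    shared_pos = positions[:n_shared]
    private_pos = positions[n_shared:]

    manifest: dict = {
        "seed": int(config.seed),
        "config": _config_dict(config),
        "chrom": config.chrom,
        "chrom_length": int(config.chrom_length),
        "hotspot_min": int(config.hotspot_min),
        "tiers": {
            t.name: {
                "n_loci": t.n_loci,
                "occupancy": list(t.occupancy),
                "mean_height": t.mean_height,
                "motif_rate": t.motif_rate,
                "annotation_rate": t.annotation_rate,
                "de_rate": t.de_rate,
                "profile": t.profile,
                "profile_offset": t.profile_offset,
                "signal_amplitude": t.signal_amplitude,
            }
            for t in config.tiers
        },
        "cell_types": {},
    }

    peak_sets: dict[str, list[PeakSet]] = {}
    for ci, ct in enumerate(cts):
        n_factors = config.cell_types[ct]
        factors = [f"TF{i + 1:02d}" for i in range(n_factors)]
        own_private = private_pos[ci * n_private : (ci + 1) * n_private]
        centers = np.sort(np.concatenate([shared_pos, own_private]))
        shared_set = set(int(p) for p in shared_pos)

        tier_labels = np.concatenate(
            [np.repeat(t.name, t.n_loci) for t in config.tiers]
        )
        rng.shuffle(tier_labels)

        sets = {f: PeakSet(f, ct) for f in factors}
        loci = []
        for li, (center, tier_name) in enumerate(zip(centers, tier_labels)):
            center = int(center)
            tier = config.tier(str(tier_name))
            lo, hi = tier.occupancy
            hi = min(hi, n_factors)
            occ = int(rng.integers(lo, hi + 1))
            chosen = sorted(rng.choice(n_factors, size=occ, replace=False))
            locus_factors = [factors[j] for j in chosen]
            for f in locus_factors:
                width = int(rng.integers(wmin, wmax + 1))
                if config.jitter_sd > 0:
                    jit = float(rng.normal(0.0, config.jitter_sd))
                    jit = int(round(np.clip(jit, -2 * config.jitter_sd,
                                            2 * config.jitter_sd)))
                else:
                    jit = 0
                c = center + jit
                start = c - width // 2
                sets[f].peaks.append(
                    PeakRecord(
                        GenomicInterval(config.chrom, start, start + width),
                        summit_offset=c - start,
                    )
                )
            loci.append(
                {
                    "id": f"{ct}_L{li:05d}",
                    "center": center,
                    "tier": str(tier_name),
                    "occupancy": occ,
                    "factors": locus_factors,
                    "shared": center in shared_set,
                }
            )
        peak_sets[ct] = [sets[f].sorted() for f in factors]
        manifest["cell_types"][ct] = {"factors": factors, "loci": loci}
    return peak_sets, manifest


def _config_dict(config: LandscapeConfig) -> dict:
    d = asdict(config)
    d["peak_width"] = list(config.peak_width)
    for t in d["tiers"]:
        t["occupancy"] = list(t["occupancy"])
    return d


def generate_tags(
    manifest: dict,
    cell_type: str,
    window: int = 400,
    dispersion: float = 5.0,
    mean_heights: dict[str, float] | None = None,
) -> TagCollection:
    """Negative-binomial tag counts per locus, uniform positions in the
    height window around each locus center.

    Tier means come from the manifest unless overridden; the defaults put
    hotspot counts well above combinatorial above singleton, emulating the
    occupancy-height correlation of real compendia. Overdispersion
    (``dispersion`` = NB shape) emulates ChIP-seq count noise.
    """
    rng = _rng(manifest["seed"], _STREAM_TAGS,
               _ct_salt(manifest, cell_type))
    chrom = manifest["chrom"]
    half = window // 2
    positions: list[int] = []
    for locus in manifest["cell_types"][cell_type]["loci"]:
        tier = locus["tier"]
        mean = (
            mean_heights[tier]
            if mean_heights is not None
            else manifest["tiers"][tier]["mean_height"]
        )
        if mean <= 0:
            continue
        p = dispersion / (dispersion + mean)
        n_tags = int(rng.negative_binomial(dispersion, p))
        if n_tags:
            c = locus["center"]
            positions.extend(
                int(x) for x in rng.integers(c - half, c + half, size=n_tags)
            )
    return TagCollection({chrom: positions})


def _ct_salt(manifest: dict, cell_type: str) -> int:
    return list(manifest["cell_types"]).index(cell_type) + 1


def generate_signal(
    manifest: dict,
    cell_type: str,
    window: int = 10_000,
    resolution: int = 50,
    bump_sd: int = 250,
    noise_sd: float = 0.0,
) -> BedGraph:
    """Enhancer-mark-like coverage: one Gaussian bump per monomodal locus,
    two flanking bumps (central dip) per bimodal locus.

    Bimodal flanks sit at the tier's ``profile_offset``; amplitudes are
    tier-scaled. The track is piecewise constant at ``resolution`` bp.
    """
    tiers = manifest["tiers"]
    for name, t in tiers.items():
        if t["profile"] == "bimodal" and t["profile_offset"] >= window // 2:
            raise ValueError(
                f"tier {name}: bimodal offset must be < window/2"
            )
    chrom = manifest["chrom"]
    length = manifest["chrom_length"]
    nbins = length // resolution + 1
    track = np.zeros(nbins)
    half = window // 2
    for locus in manifest["cell_types"][cell_type]["loci"]:
        t = tiers[locus["tier"]]
        amp = float(t["signal_amplitude"])
        if amp == 0:
            continue
        c = locus["center"]
        lo_bin = max(0, (c - half) // resolution)
        hi_bin = min(nbins, (c + half) // resolution + 1)
        x = (np.arange(lo_bin, hi_bin) + 0.5) * resolution - c
        if t["profile"] == "bimodal":
            off = float(t["profile_offset"])
            sd = max(off / 2.5, resolution)
            y = amp * (
                np.exp(-((x - off) ** 2) / (2 * sd**2))
                + np.exp(-((x + off) ** 2) / (2 * sd**2))
            )
        else:
            y = amp * np.exp(-(x**2) / (2 * bump_sd**2))
        track[lo_bin:hi_bin] += y
    if noise_sd > 0:
        rng = _rng(manifest["seed"], _STREAM_SIGNAL,
                   _ct_salt(manifest, cell_type))
        track += np.abs(rng.normal(0, noise_sd, size=track.size))
    records = []
    nz = np.flatnonzero(track > 1e-6)
    for idx in nz:
        start = int(idx) * resolution
        records.append((chrom, start, min(start + resolution, length),
                        float(track[idx])))
    return BedGraph.from_records(records)


@dataclass
class SequencePack:
    """Sequences, annotations, genes and DE lists for one cell type."""

    genome: dict[str, str]
    motif: MotifPattern
    annotation: list[GenomicInterval]
    genes: list[GeneModel]
    gene_targets: dict[str, str]  # locus id -> gene id
    de_genes: list[str]
    manifest: dict  # copy with planting records added


def generate_sequences_and_annotations(
    manifest: dict,
    cell_type: str,
    motif: MotifPattern | str = "TGASTCA",
    window: int = 400,
) -> SequencePack:
    """Random genome with planted motifs, tier-rate annotation intervals,
    nearest-gene targets and a tier-biased DE gene list.

    Background sequence is i.i.d. uniform ACGT. A concrete realization of
    the IUPAC motif is written at the center of each selected locus's
    window. Genes are placed downstream of each locus, close enough that
    the planted gene is guaranteed to be that locus's nearest gene within
    50 kb. The DE list samples each locus's gene at its tier's ``de_rate``.
    """
    if isinstance(motif, str):
        motif = MotifPattern("planted", motif)
    if len(motif.consensus) > window:
        raise ValueError("motif longer than the sequence window")
    rng = _rng(manifest["seed"], _STREAM_SEQUENCE,
               _ct_salt(manifest, cell_type))
    chrom = manifest["chrom"]
    length = manifest["chrom_length"]
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bytearray(lut[rng.integers(0, 4, size=length, dtype=np.uint8)].tobytes())

    tiers = manifest["tiers"]
    new_manifest = copy.deepcopy(manifest)
    loci = new_manifest["cell_types"][cell_type]["loci"]
    annotation: list[GenomicInterval] = []
    genes: list[GeneModel] = []
    gene_targets: dict[str, str] = {}
    de_genes: list[str] = []

    centers = [loc["center"] for loc in loci]
    for i, loc in enumerate(loci):
        t = tiers[loc["tier"]]
        c = loc["center"]
        # motif planting
        planted = bool(rng.random() < t["motif_rate"])
        if planted:
            real = "".join(
                IUPAC[l][rng.integers(0, len(IUPAC[l]))]
                for l in motif.consensus.upper()
            )
            start = c - len(real) // 2
            seq[start : start + len(real)] = real.encode()
        loc["motif_planted"] = planted
        # annotation membership
        member = bool(rng.random() < t["annotation_rate"])
        if member:
            annotation.append(GenomicInterval(chrom, max(0, c - 500), c + 500))
        loc["annotation_member"] = member
        # gene placement: downstream, close enough to win nearest-gene
        left_gap = c - centers[i - 1] if i > 0 else 10**9
        right_gap = centers[i + 1] - c if i + 1 < len(centers) else 10**9
        gap = min(left_gap, right_gap)
        tss_off = int(min(5000, max(200, 0.3 * gap)))
        gene_len = int(min(2000, max(200, 0.3 * gap)))
        gid = f"gene{cell_type}_{i:05d}"
        gstart = min(c + tss_off, length - gene_len)  # clamp at chromosome end
        genes.append(
            GeneModel(gid, GenomicInterval(chrom, gstart, gstart + gene_len, "+"))
        )
        gene_targets[loc["id"]] = gid
        loc["gene_target"] = gid
        # DE membership
        is_de = bool(rng.random() < t["de_rate"])
        if is_de:
            de_genes.append(gid)
        loc["de_gene"] = is_de
    return SequencePack(
        genome={chrom: seq.decode()},
        motif=motif,
        annotation=annotation,
        genes=genes,
        gene_targets=gene_targets,
        de_genes=de_genes,
        manifest=new_manifest,
    )


def locus_windows(
    manifest: dict, cell_type: str, genome: dict[str, str], window: int = 400
) -> dict[str, list[str]]:
    """Per-tier summit-centered sequence windows for motif/GC analysis."""
    chrom = manifest["chrom"]
    seq = genome[chrom]
    half = window // 2
    out: dict[str, list[str]] = {}
    for loc in manifest["cell_types"][cell_type]["loci"]:
        c = loc["center"]
        out.setdefault(loc["tier"], []).append(seq[c - half : c + half])
    return out


def write_landscape(
    config: LandscapeConfig,
    outdir: str,
    with_tags: bool = True,
    with_signal: bool = True,
    with_sequences: bool = False,
    motif: str = "TGASTCA",
) -> dict:
    """Generate a landscape and write all artifacts under ``outdir``.

    Writes one narrowPeak per (cell type, factor), a manifest TSV mapping
    file -> factor -> cell type, optional tag BEDs and signal bedGraphs
    per cell type, optional genome FASTA / genes BED12 / annotation BED /
    DE gene lists, and ``truth.json``. Returns the truth manifest.
    """
    os.makedirs(outdir, exist_ok=True)
    peak_sets, manifest = generate_landscape(config)
    rows = []
    for ct, sets in peak_sets.items():
        for ps in sets:
            fname = f"{ct}.{ps.factor}.narrowPeak"
            write_narrowpeak(ps, os.path.join(outdir, fname))
            rows.append((fname, ps.factor, ct))
    with open(os.path.join(outdir, "manifest.tsv"), "w") as fh:
        fh.write("path\tfactor\tcell_type\n")
        for fname, factor, ct in rows:
            fh.write(f"{fname}\t{factor}\t{ct}\n")
    with open(os.path.join(outdir, "chrom.sizes"), "w") as fh:
        fh.write(f"{config.chrom}\t{config.chrom_length}\n")
    for ct in peak_sets:
        if with_tags:
            tags = generate_tags(manifest, ct)
            write_tags(tags, os.path.join(outdir, f"{ct}.tags.bed"))
        if with_signal:
            sig = generate_signal(manifest, ct)
            sig.write(os.path.join(outdir, f"{ct}.signal.bedGraph"))
    if with_sequences:
        first_ct = next(iter(peak_sets))
        pack = generate_sequences_and_annotations(manifest, first_ct, motif)
        write_fasta(pack.genome, os.path.join(outdir, "genome.fa"))
        write_bed12(pack.genes, os.path.join(outdir, "genes.bed12"))
        write_bed(pack.annotation, os.path.join(outdir, "annotation.bed"))
        with open(os.path.join(outdir, "de_genes.txt"), "w") as fh:
            fh.write("\n".join(pack.de_genes) + "\n")
        manifest = pack.manifest
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
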