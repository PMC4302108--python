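"""Region-set, gene-set and motif enrichment plus pioneer-factor calls.

Overlap enrichment follows the standard hypergeometric scheme: with N
universe regions of which K overlap an annotation, the chance that a group
of n regions contains k or more overlapping ones is the upper tail of
Hypergeom(N, K, n); the lower tail reports depletion. Motif analysis uses
exact IUPAC consensus matching (both strands) on uniform summit-centered
windows, with a GC-content control and a two-proportion test between
groups. A factor binding more than 90% of a cell type's hotspots is
flagged as a candidate pioneer factor.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet
from .occupancy import OccupancyRegion, _self_merge
from .stats import hypergeom_tails, mann_whitney, two_proportion_test

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

PIONEER_MIN_FRACTION = 0.9  # strictly greater-than flags a pioneer


@dataclass(frozen=True)
class MotifPattern:
    """A named IUPAC consensus motif."""

    name: str
    consensus: str

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError("empty motif consensus")
        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC letters in motif: {sorted(bad)}")


@dataclass
class EnrichmentResult:
    """One query-set vs background comparison."""

    query: str
    group: str
    overlap: int  # k
    group_size: int  # n
    annotation_size: int  # K
    universe_size: int  # N
    fraction: float
    fold: float
    p_enrichment: float
    p_depletion: float
    direction: str  # enriched | depleted

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _result(query: str, group: str, k: int, n: int, K: int, N: int) -> EnrichmentResult:
    upper, lower = hypergeom_tails(k, n, K, N)
    expected = n * K / N if N else 0.0
    fold = (k / expected) if expected else float("nan")
    return EnrichmentResult(
        query=query,
        group=group,
        overlap=k,
        group_size=n,
        annotation_size=K,
        universe_size=N,
        fraction=k / n if n else float("nan"),
        fold=fold,
        p_enrichment=upper,
        p_depletion=lower,
        direction="enriched" if k >= expected else "depleted",
    )


def region_overlap_enrichment(
    groups: Mapping[str, Sequence[OccupancyRegion]],
    annotation: Sequence[GenomicInterval],
    universe: Sequence[OccupancyRegion],
    query_name: str = "annotation",
) -> list[EnrichmentResult]:
    """Hypergeometric overlap enrichment of each group vs the universe.

    A region overlaps the annotation iff it shares >=1 bp with any
    annotation interval.
    """
    if not annotation:
        raise ValueError("annotation is empty")
    universe = list(universe)
    N = len(universe)
    anno = _self_merge(list(annotation))
    anno_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    tmp: dict[str, list[tuple[int, int]]] = {}
    for iv in anno:
        tmp.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom, spans in tmp.items():
        spans.sort()
        anno_by_chrom[chrom] = (
            np.array([s for s, _ in spans]),
            np.array([e for _, e in spans]),
        )

    def hits(iv: GenomicInterval) -> bool:
        if iv.chrom not in anno_by_chrom:
            return False
        starts, ends = anno_by_chrom[iv.chrom]
        i = int(np.searchsorted(starts, iv.end, side="left"))
        return i > 0 and ends[i - 1] > iv.start

    K = sum(hits(r.interval) for r in universe)
    results = []
    for name in sorted(groups):
        regions = list(groups[name])
        n = len(regions)
        if n > N:
            raise ValueError(f"group {name} larger than universe")
        k = sum(hits(r.interval) for r in regions)
        results.append(_result(query_name, name, k, n, K, N))
    return results


def gene_set_enrichment(
    group_genes: Mapping[str, Sequence[str]],
    query: Sequence[str],
    universe: Sequence[str],
    query_name: str = "gene_set",
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of a query gene list in each group's genes.

    Ids are matched case-insensitively; query ids missing from the
    universe are dropped with a warning.
    """
    uni = {g.upper() for g in universe}
    q_raw = {g.upper() for g in query}
    q = q_raw & uni
    unmatched = len(q_raw) - len(q)
    if unmatched:
        logger.warning("%d query gene ids not in universe; dropped", unmatched)
    if not q:
        raise ValueError("query gene list empty after matching against universe")
    N, K = len(uni), len(q)
    results = []
    for name in sorted(group_genes):
        members = {g.upper() for g in group_genes[name]} & uni
        k = len(members & q)
        results.append(_result(query_name, name, k, len(members), K, N))
    return results


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _motif_regex(consensus: str) -> re.Pattern:
    # sequence N matches only motif letter N
    parts = []
    for letter in consensus.upper():
        expansion = IUPAC[letter]
        cls = expansion + ("N" if letter == "N" else "")
        parts.append(f"[{cls}]" if len(cls) > 1 else cls)
    return re.compile("(?=" + "".join(parts) + ")")


def scan_motif(sequence: str, motif: MotifPattern | str, both_strands: bool = True) -> int:
    """Count windows of ``sequence`` matching an IUPAC consensus.

    Overlapping matches count; with ``both_strands`` the reverse
    complement of the sequence is scanned too. An ``N`` in the sequence is
    matched only by the motif letter ``N``.
    """
    if isinstance(motif, str):
        motif = MotifPattern("motif", motif)
    seq = sequence.upper()
    if seq and set(seq) - set("ACGTN"):
        raise ValueError("sequence must be over A, C, G, T, N")
    pat = _motif_regex(motif.consensus)
    count = len(pat.findall(seq))
    if both_strands:
        count += len(pat.findall(reverse_complement(seq)))
    return count


def motif_group_enrichment(
    group_sequences: Mapping[str, Sequence[str]],
    motif: MotifPattern,
    both_strands: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fraction of each group's windows with >=1 motif match, plus tests.

    Returns ``(fractions, tests)``; tests are pairwise two-sided pooled
    two-proportion z-tests (symmetric, so depletion is covered). Groups
    with no sequences are skipped; if the motif is absent from every
    group, the test table is empty.
    """
    frac_rows = []
    hits: dict[str, tuple[int, int]] = {}
    for name in sorted(group_sequences):
        seqs = list(group_sequences[name])
        if not seqs:
            logger.warning("group %s has no sequences; skipped", name)
            continue
        k = sum(scan_motif(s, motif, both_strands) > 0 for s in seqs)
        hits[name] = (k, len(seqs))
        frac_rows.append(
            {
                "group": name,
                "motif": motif.name,
                "n_sequences": len(seqs),
                "n_with_motif": k,
                "fraction": k / len(seqs),
            }
        )
    fractions = pd.DataFrame(frac_rows)
    test_rows = []
    if any(k for k, _ in hits.values()):
        names = sorted(hits)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                ka, na = hits[a]
                kb, nb = hits[b]
                z, p = two_proportion_test(ka, na, kb, nb)
                test_rows.append(
                    {
                        "motif": motif.name,
                        "group_a": a,
                        "group_b": b,
                        "fraction_a": ka / na,
                        "fraction_b": kb / nb,
                        "z": z,
                        "p_value": p,
                    }
                )
    return fractions, pd.DataFrame(test_rows)


def gc_content(sequence: str) -> float:
    """GC fraction over unambiguous bases (N excluded from denominator)."""
    seq = sequence.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt


def gc_group_comparison(
    group_sequences: Mapping[str, Sequence[str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group mean GC fraction and pairwise Mann-Whitney tests.

    All-N sequences are excluded with a warning (their GC is undefined).
    """
    per_group: dict[str, np.ndarray] = {}
    rows = []
    for name in sorted(group_sequences):
        vals = [gc_content(s) for s in group_sequences[name]]
        arr = np.array([v for v in vals if not np.isnan(v)])
        if len(arr) < len(vals):
            logger.warning(
                "group %s: %d all-N sequences excluded from GC",
                name,
                len(vals) - len(arr),
            )
        if arr.size == 0:
            continue
        per_group[name] = arr
        rows.append({"group": name, "n": arr.size, "mean_gc": float(arr.mean())})
    means = pd.DataFrame(rows)
    test_rows = []
    names = sorted(per_group)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            U, p = mann_whitney(per_group[a], per_group[b])
            test_rows.append(
                {"group_a": a, "group_b": b, "U": U, "p_value": p}
            )
    return means, pd.DataFrame(test_rows)


def factor_hotspot_occupancy(
    peak_sets: Sequence[PeakSet],
    hotspots: Sequence[OccupancyRegion],
) -> pd.DataFrame:
    """Fraction of hotspots each factor's peaks overlap; pioneer flag.

    The pioneer flag requires strictly more than 90% of hotspots bound.
    Fractions are invariant to how a factor's peaks are fragmented because
    overlap is evaluated per hotspot, not per peak.
    """
    hotspots = list(hotspots)
    if not hotspots:
        raise ValueError("no hotspots supplied")
    rows = []
    for ps in sorted(peak_sets, key=lambda p: p.factor):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for p in ps.peaks:
            by_chrom.setdefault(p.interval.chrom, []).append(
                (p.interval.start, p.interval.end)
            )
        arr = {
            c: (
                np.array(sorted(s for s, _ in v)),
                np.array([e for _, e in sorted(v)]),
            )
            for c, v in by_chrom.items()
        }
        # cumulative max of ends so a single searchsorted test suffices
        arr = {
            c: (starts, np.maximum.accumulate(ends))
            for c, (starts, ends) in arr.items()
        }
        k = 0
        for h in hotspots:
            iv = h.interval
            if iv.chrom not in arr:
                continue
            starts, cum_ends = arr[iv.chrom]
            i = int(np.searchsorted(starts, iv.end, side="left"))
            if i > 0 and cum_ends[i - 1] > iv.start:
                k += 1
        frac = k / len(hotspots)
        rows.append(
            {
                "factor": ps.factor,
                "n_hotspots_bound": k,
                "n_hotspots": len(hotspots),
                "fraction": frac,
                "pioneer": frac > PIONEER_MIN_FRACTION,
            }
        )
    return pd.DataFrame(rows)
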