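"""Merge per-factor peak sets within a cell type and classify occupancy.

The central objects of the whole analysis: merged genomic regions carrying
the set of distinct transcription-related factors bound there. Regions are
classified by occupancy into *singletons* (exactly one factor),
*hotspots* (at least ``hotspot_min`` distinct factors; the default 6
encodes a "more than five factors" rule) and *combinatorials* (everything
in between).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .intervals import GenomicInterval, PeakRecord, PeakSet

GROUPS = ("singleton", "combinatorial", "hotspot")


@dataclass
class OccupancyConfig:
    """Parameters of merging and classification.

    hotspot_min
        Minimum number of distinct factors for a hotspot call. The default
        of 6 implements the "more than five factors" criterion.
    merge_gap
        Maximum allowed gap (bp) between peaks that are still merged.
        0 requires a >=1 bp overlap: bookended intervals stay separate.
    """

    hotspot_min: int = 6
    merge_gap: int = 0

    def __post_init__(self) -> None:
        if self.hotspot_min < 2:
            raise ValueError("hotspot_min must be >= 2")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")


@dataclass
class OccupancyRegion:
    """A merged region with its distinct bound factors and group label."""

    interval: GenomicInterval
    factors: set[str]
    group: str | None = None
    member_peaks: list[tuple[str, PeakRecord]] = field(default_factory=list)

    @property
    def occupancy(self) -> int:
        return len(self.factors)

    @property
    def summit(self) -> int:
        """Representative center: mean of member summits, else midpoint."""
        if self.member_peaks:
            summits = [p.summit for _, p in self.member_peaks]
            return int(round(sum(summits) / len(summits)))
        return self.interval.midpoint


def _check_peak_sets(peak_sets: Sequence[PeakSet]) -> str:
    if not peak_sets:
        raise ValueError("need at least one peak set")
    cell_types = {ps.cell_type for ps in peak_sets}
    if len(cell_types) > 1:
        raise ValueError(f"mixed cell types in merge: {sorted(cell_types)}")
    keys = [(ps.factor, ps.cell_type) for ps in peak_sets]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate (factor, cell_type) peak sets: {dupes}")
    return cell_types.pop()


def merge_peaks(
    peak_sets: Sequence[PeakSet], config: OccupancyConfig | None = None
) -> list[OccupancyRegion]:
    """Merge all factors' peaks of one cell type into disjoint regions.

    With ``merge_gap = 0`` two peaks join a region only if they share at
    least one base, so the base-pair union of the output equals that of the
    input. Each region records the distinct factors contributing at least
    one peak (a factor with several peaks in a region counts once).
    """
    config = config or OccupancyConfig()
    _check_peak_sets(peak_sets)
    items: list[tuple[str, int, int, str, PeakRecord]] = []
    for ps in peak_sets:
        for peak in ps.peaks:
            iv = peak.interval
            items.append((iv.chrom, iv.start, iv.end, ps.factor, peak))
    items.sort(key=lambda t: (t[0], t[1], t[2]))

    regions: list[OccupancyRegion] = []
    cur: dict | None = None
    for chrom, start, end, factor, peak in items:
        joins = (
            cur is not None
            and chrom == cur["chrom"]
            and (
                start < cur["end"]
                or (config.merge_gap > 0 and start - cur["end"] <= config.merge_gap)
            )
        )
        if joins:
            cur["end"] = max(cur["end"], end)
            cur["factors"].add(factor)
            cur["members"].append((factor, peak))
        else:
            if cur is not None:
                regions.append(_close(cur))
            cur = {
                "chrom": chrom,
                "start": start,
                "end": end,
                "factors": {factor},
                "members": [(factor, peak)],
            }
    if cur is not None:
        regions.append(_close(cur))
    return regions


def _close(cur: dict) -> OccupancyRegion:
    return OccupancyRegion(
        interval=GenomicInterval(cur["chrom"], cur["start"], cur["end"]),
        factors=cur["factors"],
        member_peaks=sorted(
            cur["members"], key=lambda t: (t[0], t[1].interval.start)
        ),
    )


def classify_regions(
    regions: Iterable[OccupancyRegion], config: OccupancyConfig | None = None
) -> tuple[list[OccupancyRegion], dict[str, int]]:
    """Assign each region its occupancy group; return regions and counts.

    The partition is exhaustive and exclusive: occupancy 1 -> singleton,
    occupancy >= ``hotspot_min`` -> hotspot, otherwise combinatorial.
    """
    config = config or OccupancyConfig()
    counts = {g: 0 for g in GROUPS}
    out = []
    for region in regions:
        if region.occupancy < 1:
            raise ValueError("region with no factors cannot be classified")
        if region.occupancy == 1:
            region.group = "singleton"
        elif region.occupancy >= config.hotspot_min:
            region.group = "hotspot"
        else:
            region.group = "combinatorial"
        counts[region.group] += 1
        out.append(region)
    return out, counts


def occupancy_spectrum(regions: Sequence[OccupancyRegion]) -> pd.DataFrame:
    """Tabulate region count and fraction per occupancy 1..max.

    Occupancy values with no regions appear with count 0, so the table's
    index runs contiguously from 1 to the maximum observed occupancy.
    """
    if not regions:
        return pd.DataFrame(columns=["count", "fraction"]).rename_axis("occupancy")
    occ = pd.Series([r.occupancy for r in regions])
    max_occ = int(occ.max())
    counts = occ.value_counts().reindex(range(1, max_occ + 1), fill_value=0)
    table = pd.DataFrame(
        {"count": counts, "fraction": counts / len(regions)}
    ).rename_axis("occupancy")
    return table


def consensus_peaks(
    peak_sets: Sequence[PeakSet], min_sets: int
) -> list[GenomicInterval]:
    """Bases covered by >= ``min_sets`` distinct experiments, as intervals.

    The inputs are independent experiments for the same factor; each set
    contributes coverage once per base regardless of how many of its peaks
    overlap it. Maximal runs of sufficiently-covered bases are returned.
    """
    if min_sets < 2:
        raise ValueError("min_sets must be >= 2")
    if min_sets > len(peak_sets):
        raise ValueError(
            f"min_sets={min_sets} exceeds the {len(peak_sets)} supplied sets"
        )
    # sweep over +1/-1 events of each set's self-merged intervals
    events: dict[str, list[tuple[int, int]]] = {}
    for ps in peak_sets:
        merged = _self_merge([p.interval for p in ps.peaks])
        for iv in merged:
            events.setdefault(iv.chrom, []).append((iv.start, +1))
            events.setdefault(iv.chrom, []).append((iv.end, -1))
    out: list[GenomicInterval] = []
    for chrom in sorted(events):
        evs = sorted(events[chrom])
        depth = 0
        run_start: int | None = None
        for pos, delta in evs:
            prev = depth
            depth += delta
            if prev < min_sets <= depth:
                run_start = pos
            elif prev >= min_sets > depth and run_start is not None:
                if pos > run_start:
                    out.append(GenomicInterval(chrom, run_start, pos))
                run_start = None
        # events always return depth to 0, closing any open run
    # adjacent runs split by coincident close/open events are rejoined
    return _self_merge(out) if out else []


def _self_merge(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals (overlap or bookend collapses) per chromosome."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def group_summary(counts: dict[str, int]) -> dict:
    """Counts plus fractions per group, as a JSON-ready dict."""
    total = sum(counts.values())
    return {
        "total_regions": total,
        "counts": dict(counts),
        "fractions": {
            g: (counts[g] / total if total else 0.0) for g in counts
        },
    }
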