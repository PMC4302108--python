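"""Tag-based peak heights, group comparisons, and aggregate profile shape.

Peak height is the number of sequencing-tag 5' ends in a uniform 400-bp
window centered on the peak summit -- a simple, robust proxy for binding
strength. Aggregate (metagene) profiles average binned signal over a wide
window around region centers; their shape is classified as mono- or
bimodal, the latter indicating a central nucleosome-depleted dip flanked by
signal (the enhancer-mark configuration expected at high-occupancy loci).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import BedGraph, TagCollection
from .stats import mann_whitney

logger = logging.getLogger(__name__)

DEFAULT_HEIGHT_WINDOW = 400
DEFAULT_PROFILE_WINDOW = 10_000
DEFAULT_PROFILE_BIN = 100


def peak_height(
    chrom: str, summit: int, tags: TagCollection, window: int = DEFAULT_HEIGHT_WINDOW
) -> int:
    """Tag count in the half-open window ``[summit - w/2, summit + w/2)``."""
    if window <= 0 or window % 2:
        raise ValueError("window must be even and positive")
    half = window // 2
    return tags.count(chrom, summit - half, summit + half)


def height_table(
    regions, tags: TagCollection, window: int = DEFAULT_HEIGHT_WINDOW
) -> pd.DataFrame:
    """Heights for classified regions: columns region, group, height."""
    rows = []
    for i, r in enumerate(regions):
        rows.append(
            {
                "region": f"{r.interval.chrom}:{r.interval.start}-{r.interval.end}",
                "group": r.group,
                "height": peak_height(r.interval.chrom, r.summit, tags, window),
            }
        )
    return pd.DataFrame(rows, columns=["region", "group", "height"])


def compare_heights(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney U tests between height groups.

    Empty groups are skipped with a warning. Returns one row per ordered
    pair (a < b lexicographically) with U (of group a), p, sizes and
    medians.
    """
    nonempty = {}
    for name, values in groups.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size == 0:
            logger.warning("group %s is empty; comparisons skipped", name)
            continue
        nonempty[name] = arr
    if len(nonempty) < 2:
        raise ValueError("need at least two nonempty groups")
    rows = []
    names = sorted(nonempty)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            U, p = mann_whitney(nonempty[a], nonempty[b])
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "n_a": nonempty[a].size,
                    "n_b": nonempty[b].size,
                    "U": U,
                    "p_value": p,
                    "median_a": float(np.median(nonempty[a])),
                    "median_b": float(np.median(nonempty[b])),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ProfileMatrix:
    """Per-region binned signal around region centers.

    ``matrix`` is regions x bins over a window of width ``window`` centered
    on each region's center, bin width ``bin_width``; ``truncated`` flags
    regions whose window ran off a chromosome end (padded with zeros).
    """

    matrix: np.ndarray
    window: int
    bin_width: int
    truncated: np.ndarray

    @property
    def nbins(self) -> int:
        return self.window // self.bin_width

    @property
    def aggregate(self) -> np.ndarray:
        """Unweighted per-bin column mean over all regions."""
        return self.matrix.mean(axis=0)

    def bin_centers(self) -> np.ndarray:
        """Offset (bp) of each bin center from the region center."""
        return (np.arange(self.nbins) + 0.5) * self.bin_width - self.window / 2


def average_profile(
    centers: Sequence[tuple[str, int]],
    signal: BedGraph | TagCollection,
    window: int = DEFAULT_PROFILE_WINDOW,
    bin_width: int = DEFAULT_PROFILE_BIN,
    chrom_sizes: Mapping[str, int] | None = None,
) -> ProfileMatrix:
    """Bin signal over ``[center - W/2, center + W/2)`` for every region.

    ``signal`` may be per-base coverage (bedGraph; bins take the mean
    per-base value) or raw tags (bins take the tag count). Windows
    truncated by a chromosome end are zero-padded and flagged so the
    matrix stays rectangular.
    """
    if window <= 0 or window % bin_width:
        raise ValueError("window must be a positive multiple of bin_width")
    if not centers:
        raise ValueError("no regions to profile")
    nbins = window // bin_width
    half = window // 2
    mat = np.zeros((len(centers), nbins))
    truncated = np.zeros(len(centers), dtype=bool)
    for i, (chrom, center) in enumerate(centers):
        lo = center - half
        hi = center + half
        clip_lo = max(lo, 0)
        clip_hi = hi
        if chrom_sizes is not None and chrom in chrom_sizes:
            clip_hi = min(hi, chrom_sizes[chrom])
        if clip_lo > lo or clip_hi < hi:
            truncated[i] = True
        if clip_lo >= clip_hi:
            continue
        if isinstance(signal, TagCollection):
            pos = signal.positions(chrom)
            sel = pos[(pos >= clip_lo) & (pos < clip_hi)]
            if sel.size:
                bins = (sel - lo) // bin_width
                np.add.at(mat[i], bins.astype(int), 1)
        else:
            vals = signal.values(chrom, clip_lo, clip_hi)
            row = np.zeros(window)
            row[clip_lo - lo : clip_hi - lo] = vals
            mat[i] = row.reshape(nbins, bin_width).mean(axis=1)
    return ProfileMatrix(mat, window, bin_width, truncated)


@dataclass
class ModalityCall:
    """Shape call for an aggregate profile."""

    call: str  # monomodal | bimodal | ambiguous
    left_peak_bin: int | None = None
    right_peak_bin: int | None = None
    center_value: float | None = None


def _smooth3(y: np.ndarray) -> np.ndarray:
    """Centered 3-bin moving average with shrinking edge windows."""
    kernel = np.ones(3)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y), kernel, mode="same")
    return num / den


def _local_maxima(y: np.ndarray) -> list[int]:
    """Interior local maxima, plateaus reported at their first bin."""
    peaks = []
    n = y.size
    i = 1
    while i < n - 1:
        if y[i] > y[i - 1]:
            j = i
            while j + 1 < n and y[j + 1] == y[j]:
                j += 1
            if j < n - 1 and y[j + 1] < y[j]:
                peaks.append(i)
            i = j + 1
        else:
            i += 1
    return peaks


def classify_modality(
    profile: np.ndarray,
    bin_width: int = DEFAULT_PROFILE_BIN,
    min_prominence: float = 0.1,
    min_separation: int = 200,
) -> ModalityCall:
    """Call an aggregate profile monomodal, bimodal or ambiguous.

    The profile is smoothed by a centered 3-bin moving average. *Bimodal*:
    the two highest local maxima lie on opposite sides of the window
    center, each at least ``min_separation / 2`` bp away from it, and the
    minimum between them dips to at most ``(1 - min_prominence)`` of the
    lower maximum. *Monomodal*: a global maximum whose bin contains or
    adjoins the center. Anything else -- including an all-zero profile --
    is *ambiguous*. The call is invariant to positive scaling.
    """
    y = np.asarray(profile, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("profile must be a 1-D array of >= 3 bins")
    if not np.any(y):
        return ModalityCall("ambiguous")
    s = _smooth3(y)
    nbins = y.size
    center_bins = {nbins // 2 - 1, nbins // 2}
    offsets = (np.arange(nbins) + 0.5) * bin_width - nbins * bin_width / 2

    maxima = _local_maxima(s)
    if len(maxima) >= 2:
        top2 = sorted(maxima, key=lambda i: (-s[i], i))[:2]
        a, b = sorted(top2)
        opposite = offsets[a] < 0 < offsets[b]
        far = (
            abs(offsets[a]) >= min_separation / 2
            and abs(offsets[b]) >= min_separation / 2
        )
        if opposite and far:
            valley = float(s[a : b + 1].min())
            lower = min(s[a], s[b])
            if valley <= (1 - min_prominence) * lower:
                return ModalityCall(
                    "bimodal",
                    left_peak_bin=a,
                    right_peak_bin=b,
                    center_value=valley,
                )
    g = int(np.argmax(s))
    adjoining = center_bins | {nbins // 2 - 2, nbins // 2 + 1}
    if g in adjoining:
        return ModalityCall("monomodal", center_value=float(s[g]))
    return ModalityCall("ambiguous")
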