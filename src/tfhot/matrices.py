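"""Cross-cell-type binary occupancy matrices and hierarchical clustering.

Loci classified per cell type are first unified across cell types by the
same >=1 bp-overlap merge used within a cell type; a binary peak matrix
then records, for every unified locus, presence in each (cell type, group)
column. A parallel gene-level matrix records which genes are targeted by
regions of each group. Columns are clustered by complete linkage on
``d = 1 - phi``, where phi is the Pearson correlation of 0/1 columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import map_to_gene
from .intervals import GenomicInterval, GeneModel
from .occupancy import OccupancyRegion, GROUPS

logger = logging.getLogger(__name__)


def column_label(cell_type: str, group: str) -> str:
    return f"{cell_type}|{group}"


def locus_id(iv: GenomicInterval) -> str:
    return f"{iv.chrom}:{iv.start}-{iv.end}"


def unify_loci(
    regions_by_cell_type: Mapping[str, Sequence[OccupancyRegion]],
) -> tuple[list[GenomicInterval], dict[str, list[int]]]:
    """Merge every cell type's regions into one unified locus list.

    Returns the sorted unified loci and, per cell type, the index of the
    unified locus each of its regions maps to (every region maps to exactly
    one locus because loci are a union of the inputs).
    """
    all_ivs = [
        r.interval for regions in regions_by_cell_type.values() for r in regions
    ]
    if not all_ivs:
        return [], {ct: [] for ct in regions_by_cell_type}
    # overlap-only union: self-merge collapses bookends too, so merge
    # per-chromosome with a strict-overlap sweep
    loci = _overlap_union(all_ivs)
    index: dict[str, list[tuple[int, int]]] = {}
    for i, iv in enumerate(loci):
        index.setdefault(iv.chrom, []).append((iv.start, i))
    starts = {c: np.array([s for s, _ in v]) for c, v in index.items()}
    mapping: dict[str, list[int]] = {}
    for ct, regions in regions_by_cell_type.items():
        idxs = []
        for r in regions:
            iv = r.interval
            pos = int(np.searchsorted(starts[iv.chrom], iv.start, side="right")) - 1
            idxs.append(index[iv.chrom][pos][1])
        mapping[ct] = idxs
    return loci, mapping


def _overlap_union(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Connected components under >=1 bp overlap (bookends stay apart)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s < cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def build_peak_matrix(
    loci: Sequence[GenomicInterval],
    mapping: Mapping[str, Sequence[int]],
    regions_by_cell_type: Mapping[str, Sequence[OccupancyRegion]],
) -> pd.DataFrame:
    """Binary locus x (cell type, group) matrix.

    Within one cell type the three groups partition that cell type's
    regions, so a unified locus is normally nonzero in at most one group
    column per cell type; loci widened across cell types can violate this
    and are logged, never silently altered.
    """
    cell_types = sorted(regions_by_cell_type)
    cols = [column_label(ct, g) for ct in cell_types for g in GROUPS]
    mat = np.zeros((len(loci), len(cols)), dtype=np.int8)
    col_pos = {c: j for j, c in enumerate(cols)}
    for ct in cell_types:
        regions = regions_by_cell_type[ct]
        if not regions:
            logger.warning("cell type %s has no regions; all-zero columns", ct)
            continue
        for r, li in zip(regions, mapping[ct]):
            if r.group is None:
                raise ValueError("regions must be classified before matrix build")
            mat[li, col_pos[column_label(ct, r.group)]] = 1
    df = pd.DataFrame(mat, index=[locus_id(iv) for iv in loci], columns=cols)
    for ct in cell_types:
        sub = df[[column_label(ct, g) for g in GROUPS]]
        bad = sub.sum(axis=1) > 1
        if bad.any():
            logger.warning(
                "%d unified loci span multiple %s groups (cross-cell-type widening)",
                int(bad.sum()),
                ct,
            )
    return df


def build_gene_matrix(
    regions_by_cell_type: Mapping[str, Sequence[OccupancyRegion]],
    genes: Sequence[GeneModel],
    max_distance: int = 50_000,
) -> pd.DataFrame:
    """Binary gene x (cell type, group) matrix from gene assignments.

    A gene may legitimately be hit by several groups of one cell type
    (different regions). Genes with no assigned region in any column are
    omitted, so every row has at least one nonzero entry.
    """
    cell_types = sorted(regions_by_cell_type)
    cols = [column_label(ct, g) for ct in cell_types for g in GROUPS]
    hits: dict[str, set[str]] = {}
    for ct in cell_types:
        for r in regions_by_cell_type[ct]:
            assignment = map_to_gene(r.interval, genes, max_distance)
            if assignment.gene_id is None:
                continue
            hits.setdefault(assignment.gene_id, set()).add(
                column_label(ct, r.group)
            )
    gene_ids = sorted(hits)
    mat = np.zeros((len(gene_ids), len(cols)), dtype=np.int8)
    col_pos = {c: j for j, c in enumerate(cols)}
    for i, gid in enumerate(gene_ids):
        for c in hits[gid]:
            mat[i, col_pos[c]] = 1
    return pd.DataFrame(mat, index=gene_ids, columns=cols)


def column_correlation(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of 0/1 columns (the phi coefficient).

    Zero-variance columns (all-0 or all-1) get similarity 0 against every
    other column (diagonal stays 1) so clustering always completes; such
    columns are warned about.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two columns")
    if matrix.shape[0] < 2:
        raise ValueError("need at least two rows to correlate columns")
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "%d zero-variance columns; their similarity is set to 0",
            int(degenerate.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.asarray(corr)
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return pd.DataFrame(corr, index=matrix.columns, columns=matrix.columns)


@dataclass
class Dendrogram:
    """Agglomerative merge history over labelled leaves.

    ``merges`` uses scipy-style node ids: leaf ``i`` is node ``i``; the
    k-th merge creates node ``n_leaves + k``.
    """

    labels: list[str]
    merges: list[tuple[int, int, float]]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_newick(self) -> str:
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        text = {i: _quote_newick(lab) for i, lab in enumerate(self.labels)}
        for k, (a, b, h) in enumerate(self.merges):
            node = n + k
            la = h - height[a]
            lb = h - height[b]
            text[node] = f"({text[a]}:{la:g},{text[b]}:{lb:g})"
            height[node] = h
        root = n + len(self.merges) - 1 if self.merges else 0
        return text[root] + ";"

    def cophenetic(self) -> pd.DataFrame:
        """Matrix of merge heights at which leaf pairs first join."""
        n = self.n_leaves
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        out = np.zeros((n, n))
        for k, (a, b, h) in enumerate(self.merges):
            for i in members[a]:
                for j in members[b]:
                    out[i, j] = out[j, i] = h
            members[n + k] = members.pop(a) + members.pop(b)
        return pd.DataFrame(out, index=self.labels, columns=self.labels)


def _quote_newick(label: str) -> str:
    for ch in " (),:;":
        label = label.replace(ch, "_")
    return label


def cluster_columns(similarity: pd.DataFrame) -> Dendrogram:
    """Complete-linkage clustering on distance ``d = 1 - similarity``.

    Ties are broken deterministically: among equal-distance candidate
    pairs, the pair whose (lexicographically smallest member label,
    other member label) sorts first is merged.
    """
    labels = [str(c) for c in similarity.columns]
    D = 1.0 - similarity.to_numpy(dtype=float)
    if np.isnan(D).any():
        raise ValueError("NaN distances; clean the similarity matrix first")
    if not np.allclose(D, D.T):
        raise ValueError("similarity matrix must be symmetric")
    n = len(labels)
    # active cluster id -> (node id, member leaf indices, key label)
    active: dict[int, tuple[int, list[int], str]] = {
        i: (i, [i], labels[i]) for i in range(n)
    }
    merges: list[tuple[int, int, float]] = []
    next_node = n
    while len(active) > 1:
        best = None
        ids = sorted(active)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                d = max(
                    D[i, j] for i in active[a][1] for j in active[b][1]
                )
                key = tuple(sorted((active[a][2], active[b][2])))
                cand = (d, key, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        d, key, a, b = best
        node_a, mem_a, key_a = active.pop(a)
        node_b, mem_b, key_b = active.pop(b)
        merges.append((node_a, node_b, float(d)))
        active[next_node] = (next_node, mem_a + mem_b, min(key_a, key_b))
        next_node += 1
    return Dendrogram(labels=labels, merges=merges)
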