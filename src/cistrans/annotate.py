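"""Strand-aware annotation of genomic regions.

Every region is summarised by its midpoint and annotated with

* a genomic partition label (TSS, Promoter, Exon, 3UTR, Intron, SINE,
  LINE, LTR, Intergenic), resolved by a fixed precedence order when
  partition intervals overlap;
* the signed distance from the midpoint to the nearest gene's
  transcription start site (positive = downstream of transcription);
* a proximal/distal flag (|distance| < 2 kb by default);
* candidate target genes, i.e. genes whose TSS lies within a promoter
  window of the midpoint plus genes targeted by an overlapping enhancer.

All coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

#: Partition labels in decreasing precedence; Intergenic is the fallback.
PARTITION_PRECEDENCE = (
    "TSS",
    "Promoter",
    "Exon",
    "3UTR",
    "Intron",
    "SINE",
    "LINE",
    "LTR",
    "Intergenic",
)

#: Default |distance| bin edges in bp: proximal (<2 kb), 2-50 kb, 50-500 kb, beyond.
DEFAULT_BIN_EDGES = (0, 2_000, 50_000, 500_000)

GENE_COLUMNS = ("gene_id", "chrom", "strand", "tss", "start", "end")


@dataclass
class GenomeAnnotation:
    """Genes, labelled partition intervals and (optional) enhancers.

    ``genes`` has columns (gene_id, chrom, strand, tss, start, end) with
    TSS = start on the + strand and end on the - strand. ``partitions``
    has columns (chrom, start, end, label); intervals may overlap, in
    which case :func:`assign_partition` resolves the label by precedence.
    ``enhancers`` has columns (chrom, start, end, target) where target is
    the gene_id the enhancer is wired to.
    """

    chrom_sizes: dict[str, int]
    genes: pd.DataFrame
    partitions: pd.DataFrame
    enhancers: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end", "target"])
    )

    def __post_init__(self) -> None:
        self.genes = self.genes.reset_index(drop=True)
        self.partitions = self.partitions.reset_index(drop=True)
        self.enhancers = self.enhancers.reset_index(drop=True)
        self.validate()
        self._partition_trees: dict[str, IntervalTree] | None = None
        self._enhancer_trees: dict[str, IntervalTree] | None = None
        self._tss_index: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def validate(self) -> None:
        g = self.genes
        missing = set(GENE_COLUMNS) - set(g.columns)
        if missing:
            raise ValueError(f"gene table is missing columns: {sorted(missing)}")
        if g["gene_id"].duplicated().any():
            dup = g.loc[g["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id {dup!r}")
        for _, row in g.iterrows():
            size = self.chrom_sizes.get(row.chrom)
            if size is None:
                raise ValueError(f"gene {row.gene_id!r} on unknown chromosome {row.chrom!r}")
            if not (0 <= row.start < row.end <= size):
                raise ValueError(
                    f"gene {row.gene_id!r} body [{row.start}, {row.end}) exceeds "
                    f"chromosome {row.chrom} bounds [0, {size})"
                )
            expected_tss = row.start if row.strand == "+" else row.end
            if row.tss != expected_tss:
                raise ValueError(
                    f"gene {row.gene_id!r}: TSS {row.tss} inconsistent with "
                    f"strand {row.strand} (expected {expected_tss})"
                )
        for name, tab in (("partition", self.partitions), ("enhancer", self.enhancers)):
            if len(tab) == 0:
                continue
            sizes = tab["chrom"].map(self.chrom_sizes)
            if sizes.isna().any() or (tab["start"] < 0).any() or (tab["end"] > sizes).any():
                raise ValueError(f"{name} interval outside chromosome bounds")
            if (tab["start"] >= tab["end"]).any():
                raise ValueError(f"empty or inverted {name} interval")
        bad = set(self.partitions.get("label", pd.Series(dtype=object))) - set(PARTITION_PRECEDENCE)
        if bad:
            raise ValueError(f"unknown partition labels: {sorted(bad)}")

    # Lazily built spatial indexes -------------------------------------------------
    def partition_trees(self) -> dict[str, IntervalTree]:
        if self._partition_trees is None:
            trees: dict[str, IntervalTree] = {}
            for chrom, sub in self.partitions.groupby("chrom"):
                trees[chrom] = IntervalTree.from_tuples(
                    zip(sub["start"], sub["end"], sub["label"])
                )
            self._partition_trees = trees
        return self._partition_trees

    def enhancer_trees(self) -> dict[str, IntervalTree]:
        if self._enhancer_trees is None:
            trees: dict[str, IntervalTree] = {}
            for chrom, sub in self.enhancers.groupby("chrom"):
                trees[chrom] = IntervalTree.from_tuples(
                    zip(sub["start"], sub["end"], sub["target"])
                )
            self._enhancer_trees = trees
        return self._enhancer_trees

    def tss_index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per chromosome: (sorted TSS positions, gene row indices)."""
        if self._tss_index is None:
            idx: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            for chrom, sub in self.genes.groupby("chrom"):
                order = np.argsort(sub["tss"].to_numpy(), kind="stable")
                idx[chrom] = (
                    sub["tss"].to_numpy()[order],
                    sub.index.to_numpy()[order],
                )
            self._tss_index = idx
        return self._tss_index


def region_midpoint(start: int, end: int) -> int:
    return (int(start) + int(end)) // 2


def tss_distance(region: tuple[str, int, int], gene: pd.Series) -> int:
    """Signed midpoint-to-TSS distance; positive = downstream of transcription."""
    chrom, start, end = region
    if chrom != gene["chrom"]:
        raise ValueError(
            f"region on {chrom} and gene {gene['gene_id']!r} on {gene['chrom']}: "
            "TSS distance undefined across chromosomes"
        )
    mid = region_midpoint(start, end)
    d = mid - int(gene["tss"])
    return d if gene["strand"] == "+" else -d


def assign_partition(region: tuple[str, int, int], annotation: GenomeAnnotation) -> str:
    """Label of the highest-precedence partition overlapping the region midpoint."""
    chrom, start, end = region
    tree = annotation.partition_trees().get(chrom)
    if tree is None:
        return "Intergenic"
    hits = {iv.data for iv in tree.at(region_midpoint(start, end))}
    for label in PARTITION_PRECEDENCE:
        if label in hits:
            return label
    return "Intergenic"


def candidate_targets(
    region: tuple[str, int, int],
    annotation: GenomeAnnotation,
    promoter_bp: int = 2_000,
) -> list[tuple[str, int]]:
    """Candidate target genes of a region, with signed TSS distances.

    A gene is a candidate if its TSS lies strictly within ``promoter_bp``
    of the region midpoint, or if an enhancer interval wired to it
    overlaps the region. The signed TSS distance is reported for every
    candidate; enhancer targets on another chromosome are skipped.
    """
    chrom, start, end = region
    mid = region_midpoint(start, end)
    out: dict[str, int] = {}
    idx = annotation.tss_index().get(chrom)
    if idx is not None:
        pos, rows = idx
        lo = np.searchsorted(pos, mid - promoter_bp, side="right")
        hi = np.searchsorted(pos, mid + promoter_bp, side="left")
        for row in rows[lo:hi]:
            gene = annotation.genes.loc[row]
            if abs(mid - int(gene["tss"])) < promoter_bp:
                out[gene["gene_id"]] = tss_distance(region, gene)
    etree = annotation.enhancer_trees().get(chrom)
    if etree is not None:
        gene_rows = annotation.genes.set_index("gene_id")
        for iv in etree.overlap(start, end):
            gid = iv.data
            if gid in out or gid not in gene_rows.index:
                continue
            gene = gene_rows.loc[gid]
            if gene["chrom"] == chrom:
                out[gid] = tss_distance(region, gene)
    return sorted(out.items())


def distance_bin(distance: float, bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES) -> int:
    """Half-open |distance| bin index (0-based); last bin is unbounded."""
    edges = np.asarray(bin_edges, dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("bin_edges must be strictly increasing")
    return int(np.searchsorted(edges, abs(distance), side="right") - 1)


def distance_bin_labels(bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES) -> list[str]:
    edges = list(bin_edges) + [float("inf")]

    def fmt(x: float) -> str:
        if np.isinf(x):
            return "inf"
        return f"{x / 1000:g}kb" if x >= 1000 else f"{x:g}bp"

    return [f"{fmt(a)}-{fmt(b)}" for a, b in zip(edges[:-1], edges[1:])]


def nearest_gene(
    region: tuple[str, int, int], annotation: GenomeAnnotation
) -> tuple[str | None, float]:
    """(gene_id, signed TSS distance) of the nearest-TSS gene on the chromosome."""
    chrom, start, end = region
    idx = annotation.tss_index().get(chrom)
    if idx is None:
        return None, float("nan")
    pos, rows = idx
    mid = region_midpoint(start, end)
    i = np.searchsorted(pos, mid)
    best_row, best_abs = None, None
    for j in (i - 1, i):
        if 0 <= j < len(pos):
            d = abs(mid - pos[j])
            if best_abs is None or d < best_abs:
                best_abs, best_row = d, rows[j]
    gene = annotation.genes.loc[best_row]
    return gene["gene_id"], float(tss_distance(region, gene))


def annotate_regions(
    calls: pd.DataFrame,
    annotation: GenomeAnnotation,
    promoter_bp: int = 2_000,
    max_target_distance: float = 1_000_000,
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """Annotate called regions (columns chrom/start/end) in place of a copy.

    Adds: partition, nearest_gene, tss_distance (signed bp), proximal,
    distance_bin (index) and distance_bin_label, target_gene (nearest gene
    within ``max_target_distance``, else missing) and candidates (comma-
    joined candidate target gene ids via the promoter/enhancer windows).
    """
    out = calls.copy()
    partitions, nearest, dists, targets, cands = [], [], [], [], []
    for row in out.itertuples(index=False):
        region = (row.chrom, int(row.start), int(row.end))
        partitions.append(assign_partition(region, annotation))
        gid, d = nearest_gene(region, annotation)
        nearest.append(gid)
        dists.append(d)
        targets.append(gid if gid is not None and abs(d) <= max_target_distance else None)
        cands.append(",".join(g for g, _ in candidate_targets(region, annotation, promoter_bp)))
    out["partition"] = partitions
    out["nearest_gene"] = nearest
    out["tss_distance"] = dists
    out["proximal"] = np.abs(out["tss_distance"]) < promoter_bp
    out["distance_bin"] = [
        distance_bin(d, bin_edges) if np.isfinite(d) else -1 for d in out["tss_distance"]
    ]
    labels = distance_bin_labels(bin_edges)
    out["distance_bin_label"] = [labels[b] if b >= 0 else "" for b in out["distance_bin"]]
    out["target_gene"] = targets
    out["candidates"] = cands
    return out
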