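"""Placement of bound loci relative to gene structure.

Each locus is assigned a nearest-TSS distance (from its midpoint by
default), a distance class (proximal <=10 kb, distal 10-100 kb, gene
desert >100 kb) and a genomic category with precedence
promoter > exon > intron > intergenic, where the promoter window is the
3 kb strand-aware upstream of the TSS.
"""
from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROMOTER_UPSTREAM = 3_000
PROXIMAL_MAX = 10_000
DESERT_MIN = 100_000

NO_TSS = "no_tss"

GENE_COLUMNS = ["gene_id", "chrom", "strand", "start", "end", "tss"]
EXON_COLUMNS = ["gene_id", "chrom", "start", "end"]


@dataclass
class GeneSet:
    """Gene models: one TSS per gene, plus exon intervals.

    ``genes``: gene_id, chrom, strand, start, end (0-based half-open span),
    tss (5' end respecting strand).  ``exons``: gene_id, chrom, start, end.
    """

    genes: pd.DataFrame
    exons: pd.DataFrame

    _tss_index: dict = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.genes)

    def tss_index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (sorted TSS positions, gene ids), sorted by (tss, gene_id)."""
        if self._tss_index is None:
            idx = {}
            for chrom, sub in self.genes.groupby("chrom", sort=False):
                sub = sub.sort_values(["tss", "gene_id"], kind="mergesort")
                idx[chrom] = (
                    sub["tss"].to_numpy(dtype=np.int64),
                    sub["gene_id"].to_numpy(),
                )
            self._tss_index = idx
        return self._tss_index

    # ---- GTF I/O (1-based closed on disk, 0-based half-open in memory) ----

    def write_gtf(self, path, source: str = "mkregnet") -> None:
        with open(path, "w") as fh:
            for g in self.genes.sort_values(["chrom", "start", "gene_id"]).itertuples(index=False):
                attrs = f'gene_id "{g.gene_id}";'
                fh.write(
                    f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )
                sub = self.exons[self.exons["gene_id"] == g.gene_id]
                for e in sub.sort_values("start").itertuples(index=False):
                    fh.write(
                        f"{g.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t{g.strand}\t.\t{attrs}\n"
                    )

    @classmethod
    def read_gtf(cls, path) -> "GeneSet":
        genes, exons = [], []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                chrom, feature, start, end, strand, attrs = f[0], f[2], int(f[3]), int(f[4]), f[6], f[8]
                gene_id = attrs.split('gene_id "', 1)[1].split('"', 1)[0]
                rec = {"gene_id": gene_id, "chrom": chrom, "start": start - 1, "end": end}
                if feature == "gene":
                    rec["strand"] = strand
                    rec["tss"] = start - 1 if strand == "+" else end - 1
                    genes.append(rec)
                elif feature == "exon":
                    exons.append(rec)
        gdf = pd.DataFrame(genes, columns=GENE_COLUMNS)
        edf = pd.DataFrame(exons, columns=EXON_COLUMNS)
        return cls(gdf, edf)


def nearest_tss(mid: int, chrom: str, genes: GeneSet):
    """Nearest-TSS gene and absolute distance for a locus midpoint.

    Ties (equidistant TSSs) resolve to the lexicographically smallest
    gene id.  Returns (None, None) when the chromosome carries no genes.
    """
    index = genes.tss_index()
    if chrom not in index:
        return None, None
    tss, ids = index[chrom]
    i = bisect_left(tss, mid)
    best = None
    for j in (i - 1, i):
        if 0 <= j < len(tss):
            d = abs(int(tss[j]) - mid)
            if best is None or d < best[0]:
                best = (d, ids[j])
    d = best[0]
    # gather every TSS at exactly the best distance (both sides, duplicates)
    lo, hi = mid - d, mid + d
    cands = [
        ids[j]
        for j in range(bisect_left(tss, lo), bisect_right(tss, hi))
        if abs(int(tss[j]) - mid) == d
    ]
    return min(cands), d


class _IntervalStabber:
    """Point-membership queries against a static interval set (per chromosome)."""

    def __init__(self, df: pd.DataFrame):
        self.by_chrom = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            order = np.argsort(starts, kind="mergesort")
            starts, ends = starts[order], ends[order]
            self.by_chrom[chrom] = (starts, np.maximum.accumulate(ends))

    def contains(self, chrom: str, pos: int) -> bool:
        if chrom not in self.by_chrom:
            return False
        starts, cummax_end = self.by_chrom[chrom]
        i = np.searchsorted(starts, pos, side="right")
        return i > 0 and cummax_end[i - 1] > pos


def _promoter_intervals(genes: pd.DataFrame, upstream: int) -> pd.DataFrame:
    """Strand-aware upstream promoter windows as half-open intervals.

    For a + gene the window (TSS-upstream, TSS] becomes [TSS-upstream+1,
    TSS+1); mirrored for - genes.
    """
    plus = genes["strand"].to_numpy() == "+"
    tss = genes["tss"].to_numpy(dtype=np.int64)
    start = np.where(plus, tss - upstream + 1, tss)
    end = np.where(plus, tss + 1, tss + upstream)
    return pd.DataFrame({"chrom": genes["chrom"], "start": np.maximum(start, 0), "end": end})


def distance_class(distance: float) -> str:
    """Map an absolute TSS distance to proximal / distal / gene_desert."""
    if distance is None or (isinstance(distance, float) and np.isnan(distance)):
        return NO_TSS
    if distance < 0:
        raise ValueError("distance must be non-negative")
    if distance <= PROXIMAL_MAX:
        return "proximal"
    if distance <= DESERT_MIN:
        return "distal"
    return "gene_desert"


def annotate_loci(
    loci: pd.DataFrame,
    genes: GeneSet,
    promoter_upstream: int = PROMOTER_UPSTREAM,
    point: str = "midpoint",
) -> pd.DataFrame:
    """Annotate each locus with nearest gene, TSS distance, class and category.

    ``point`` selects the locus reference point: "midpoint" (default) or
    "summit".
    """
    if point == "midpoint":
        ref = ((loci["start"] + loci["end"]) // 2).to_numpy(dtype=np.int64)
    elif point == "summit":
        ref = loci["summit"].to_numpy(dtype=np.int64)
    else:
        raise ValueError(f"unknown reference point {point!r}")

    promoters = _IntervalStabber(_promoter_intervals(genes.genes, promoter_upstream))
    exons = _IntervalStabber(genes.exons)
    bodies = _IntervalStabber(genes.genes)

    rows = []
    for (locus, mid) in zip(loci.itertuples(index=False), ref):
        gene, dist = nearest_tss(int(mid), locus.chrom, genes)
        if promoters.contains(locus.chrom, mid):
            category = "promoter"
        elif exons.contains(locus.chrom, mid):
            category = "exon"
        elif bodies.contains(locus.chrom, mid):
            category = "intron"
        else:
            category = "intergenic"
        rows.append(
            {
                "locus_id": locus.locus_id,
                "chrom": locus.chrom,
                "midpoint": int(mid),
                "nearest_gene": gene,
                "tss_distance": dist if dist is not None else np.nan,
                "distance_class": distance_class(dist if dist is not None else np.nan),
                "category": category,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "locus_id", "chrom", "midpoint", "nearest_gene",
            "tss_distance", "distance_class", "category",
        ],
    )


def summarize_distribution(annotated: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions per genomic category and per distance class."""
    rows = []
    for partition, col in (("category", "category"), ("distance_class", "distance_class")):
        sub = annotated if partition == "category" else annotated[annotated[col] != NO_TSS]
        counts = sub[col].value_counts()
        total = int(counts.sum())
        for value, count in counts.items():
            rows.append(
                {
                    "partition": partition,
                    "value": value,
                    "count": int(count),
                    "fraction": count / total if total else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=["partition", "value", "count", "fraction"])
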