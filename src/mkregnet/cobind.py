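"""TF / coactivator co-occupancy: locus-set intersection, Venn counts,
gene assignment and cross-tabulation against expression response classes."""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .annotate import GeneSet, nearest_tss


def _is_sorted(df: pd.DataFrame) -> bool:
    for _, sub in df.groupby("chrom", sort=False):
        if not sub["start"].is_monotonic_increasing:
            return False
    return True


def _sort(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def overlap_loci(
    set_a: pd.DataFrame, set_b: pd.DataFrame, min_overlap: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Intersect two locus sets.

    Returns (pairwise intersections, merged co-bound regions, Venn dict).
    A pair co-binds iff the interval overlap is >= min_overlap bp.  Venn
    "both" counts are reported for both orientations (A loci with >= 1
    overlapping B locus, and vice versa); the merged-region count is the
    primary co-bound region number.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    for name, df in (("A", set_a), ("B", set_b)):
        if not _is_sorted(df):
            warnings.warn(f"locus set {name} not sorted; sorting", stacklevel=2)
    set_a, set_b = _sort(set_a), _sort(set_b)

    pairs = []
    hit_a: set = set()
    hit_b: set = set()
    for chrom in set_a["chrom"].unique():
        a = set_a[set_a["chrom"] == chrom]
        b = set_b[set_b["chrom"] == chrom]
        if b.empty:
            continue
        b_start = b["start"].to_numpy(dtype=np.int64)
        b_end = b["end"].to_numpy(dtype=np.int64)
        b_ids = b["locus_id"].to_numpy()
        b_cov = b["max_coverage"].to_numpy()
        for row in a.itertuples(index=False):
            hits = np.flatnonzero(
                (np.minimum(b_end, row.end) - np.maximum(b_start, row.start)) >= min_overlap
            )
            for j in hits:
                pairs.append(
                    {
                        "chrom": chrom,
                        "start": int(max(row.start, b_start[j])),
                        "end": int(min(row.end, b_end[j])),
                        "locus_a": row.locus_id,
                        "locus_b": b_ids[j],
                        "max_coverage_a": row.max_coverage,
                        "max_coverage_b": b_cov[j],
                    }
                )
                hit_a.add(row.locus_id)
                hit_b.add(b_ids[j])
    pair_df = pd.DataFrame(
        pairs,
        columns=["chrom", "start", "end", "locus_a", "locus_b", "max_coverage_a", "max_coverage_b"],
    )
    merged = merge_intervals(pair_df)
    venn = {
        "n_a": int(len(set_a)),
        "n_b": int(len(set_b)),
        "both_a": len(hit_a),
        "both_b": len(hit_b),
        "a_only": int(len(set_a)) - len(hit_a),
        "b_only": int(len(set_b)) - len(hit_b),
        "cobound_regions": int(len(merged)),
    }
    return pair_df, merged, venn


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent intervals per chromosome."""
    rows = []
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur_s = cur_e = None
        for r in sub.itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e = r.start, r.end
            elif r.start <= cur_e:
                cur_e = max(cur_e, r.end)
            else:
                rows.append({"chrom": chrom, "start": int(cur_s), "end": int(cur_e)})
                cur_s, cur_e = r.start, r.end
        if cur_s is not None:
            rows.append({"chrom": chrom, "start": int(cur_s), "end": int(cur_e)})
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    out.insert(0, "region_id", [f"cobound_{i:05d}" for i in range(len(out))])
    return out


def assign_to_genes(
    tf_loci: pd.DataFrame,
    cobound_regions: pd.DataFrame,
    genes: GeneSet,
    classes: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene counts of bound loci and co-bound regions (nearest-TSS rule)."""
    table = pd.DataFrame(index=genes.genes["gene_id"])
    table["n_bound"] = 0
    table["n_cobound"] = 0
    for df, col in ((tf_loci, "n_bound"), (cobound_regions, "n_cobound")):
        for r in df.itertuples(index=False):
            mid = (int(r.start) + int(r.end)) // 2
            gene, _ = nearest_tss(mid, r.chrom, genes)
            if gene is not None:
                table.loc[gene, col] += 1
    table["response_class"] = (
        classes.reindex(table.index) if classes is not None else "unknown"
    )
    table.index.name = "gene_id"
    return table.reset_index()


def cobinding_response_fractions(gene_table: pd.DataFrame) -> dict:
    """Fraction of responsive genes that are co-bound, and of co-bound
    genes that are nonresponsive (with numerators/denominators)."""
    responsive = gene_table["response_class"].isin(["activated", "repressed"])
    cobound = gene_table["n_cobound"] > 0
    out = {
        "n_responsive": int(responsive.sum()),
        "n_cobound_genes": int(cobound.sum()),
        "n_responsive_cobound": int((responsive & cobound).sum()),
        "n_cobound_nonresponsive": int((cobound & ~responsive).sum()),
    }
    out["frac_responsive_cobound"] = (
        out["n_responsive_cobound"] / out["n_responsive"] if out["n_responsive"] else None
    )
    out["frac_cobound_nonresponsive"] = (
        out["n_cobound_nonresponsive"] / out["n_cobound_genes"] if out["n_cobound_genes"] else None
    )
    return out
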