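"""Percentile-threshold peak calling on binned ChIP-seq coverage.

The caller mirrors a deliberately simple, auditable scheme: mapped tag 5'
ends are deduplicated, extended to the mean fragment length according to
strand, piled up in fixed-width genomic bins (default 50 bp), and bins in
the extreme upper tail of the genome-wide coverage distribution (default
top 0.1 percentile) are merged into bound loci.  A control
(non-immune-serum) track binned on the same grid removes loci that carry
significant background coverage (default top 1.0 percentile of the control
distribution).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TAG_COLUMNS = ["chrom", "pos5", "strand"]


@dataclass
class ThresholdSpec:
    """Percentile thresholds for signal and control coverage distributions."""

    signal_percentile: float = 99.9
    control_percentile: float = 99.0
    include_zero_bins: bool = True

    def __post_init__(self):
        for p in (self.signal_percentile, self.control_percentile):
            if not 0.0 < p < 100.0:
                raise ValueError(f"percentile must be in (0, 100), got {p}")


@dataclass
class BinnedCoverage:
    """Per-chromosome fragment counts on a fixed bin grid.

    ``counts[chrom][k]`` is the number of extended fragments overlapping
    bin ``[k*bin_size, (k+1)*bin_size)`` by at least one bp.
    """

    bin_size: int
    chrom_sizes: dict[str, int]
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def all_counts(self) -> np.ndarray:
        if not self.counts:
            return np.zeros(0, dtype=np.int64)
        return np.concatenate([np.asarray(v) for v in self.counts.values()])

    def same_grid(self, other: "BinnedCoverage") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.chrom_sizes == other.chrom_sizes
        )


def read_tags(path, chrom_sizes: dict[str, int]) -> pd.DataFrame:
    """Read mapped tags from BED6 or minimal SAM into (chrom, pos5, strand).

    For minus-strand records the 5' position is the interval end - 1.
    Unknown chromosomes and malformed lines raise ValueError.
    """
    path = Path(path)
    if path.suffix.lower() == ".sam":
        tags = _read_tags_sam(path)
    else:
        tags = _read_tags_bed(path)
    if len(tags):
        unknown = sorted(set(tags["chrom"]) - set(chrom_sizes))
        if unknown:
            raise ValueError(f"tags reference unknown chromosomes: {unknown}")
        bad = tags["pos5"] >= tags["chrom"].map(chrom_sizes)
        bad |= tags["pos5"] < 0
        if bad.any():
            raise ValueError(f"{int(bad.sum())} tags fall outside chromosome bounds")
    return tags


def _read_tags_bed(path) -> pd.DataFrame:
    rows = {"chrom": [], "pos5": [], "strand": []}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = parts[5] if len(parts) >= 6 else "+"
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            rows["chrom"].append(parts[0])
            rows["pos5"].append(start if strand == "+" else end - 1)
            rows["strand"].append(strand)
    return pd.DataFrame(rows, columns=TAG_COLUMNS)


def _read_tags_sam(path) -> pd.DataFrame:
    import pysam

    rows = {"chrom": [], "pos5": [], "strand": []}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            if rec.is_reverse:
                rows["pos5"].append(rec.reference_end - 1)
                rows["strand"].append("-")
            else:
                rows["pos5"].append(rec.reference_start)
                rows["strand"].append("+")
            rows["chrom"].append(rec.reference_name)
    return pd.DataFrame(rows, columns=TAG_COLUMNS)


def dedupe_tags(tags: pd.DataFrame) -> pd.DataFrame:
    """Collapse exact (chrom, pos5, strand) duplicates to a single tag."""
    out = tags.drop_duplicates(subset=TAG_COLUMNS, ignore_index=True)
    removed = len(tags) - len(out)
    if removed:
        logger.info("dedupe_tags: removed %d duplicate tags of %d", removed, len(tags))
    return out


def extend_tags(tags: pd.DataFrame, chrom_sizes: dict[str, int], frag_len: int = 200) -> pd.DataFrame:
    """Extend tags to fragment intervals in the 3' direction of their strand.

    A + tag at p becomes [p, p+frag_len); a - tag at p becomes
    [p-frag_len+1, p+1).  Intervals are clipped to chromosome bounds.
    """
    if frag_len <= 0:
        raise ValueError("frag_len must be positive")
    plus = tags["strand"].to_numpy() == "+"
    pos = tags["pos5"].to_numpy(dtype=np.int64)
    start = np.where(plus, pos, pos - frag_len + 1)
    end = np.where(plus, pos + frag_len, pos + 1)
    limit = tags["chrom"].map(chrom_sizes).to_numpy(dtype=np.int64)
    return pd.DataFrame(
        {
            "chrom": tags["chrom"].to_numpy(),
            "start": np.clip(start, 0, limit),
            "end": np.clip(end, 0, limit),
        }
    )


def bin_coverage(intervals: pd.DataFrame, chrom_sizes: dict[str, int], bin_size: int = 50) -> BinnedCoverage:
    """Count, per fixed-width bin, fragments overlapping the bin by >=1 bp."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    cov = BinnedCoverage(bin_size=bin_size, chrom_sizes=dict(chrom_sizes))
    for chrom, size in chrom_sizes.items():
        n_bins = math.ceil(size / bin_size)
        diff = np.zeros(n_bins + 1, dtype=np.int64)
        sub = intervals[intervals["chrom"] == chrom]
        if len(sub):
            start = sub["start"].to_numpy(dtype=np.int64)
            end = sub["end"].to_numpy(dtype=np.int64)
            keep = end > start
            start, end = start[keep], end[keep]
            first = start // bin_size
            last = (end - 1) // bin_size
            np.add.at(diff, first, 1)
            np.add.at(diff, np.minimum(last + 1, n_bins), 1 * -1)
        cov.counts[chrom] = np.cumsum(diff)[:-1]
    return cov


def percentile_threshold(cov: BinnedCoverage, percentile: float, include_zero_bins: bool = True) -> int:
    """Smallest integer c such that frac(bins with coverage >= c) <= (100-p)/100.

    Bins are "above threshold" iff coverage >= c.  With
    ``include_zero_bins=False``, zero-coverage bins are excluded from the
    distribution before the fraction is computed.
    """
    if not 0.0 < percentile < 100.0:
        raise ValueError(f"percentile must be in (0, 100), got {percentile}")
    vals = cov.all_counts()
    if not include_zero_bins:
        vals = vals[vals > 0]
    if vals.size == 0:
        raise ValueError("no bins to threshold")
    uniq, cnt = np.unique(vals, return_counts=True)
    if len(uniq) == 1:
        raise ValueError("degenerate coverage distribution (all bins equal)")
    # compare integer tail counts against the allowed count, with a tiny
    # tolerance absorbing float error in (100 - percentile)
    allowed = (100.0 - percentile) / 100.0 * vals.size + 1e-9
    tail = np.cumsum(cnt[::-1])[::-1]  # tail[i] = #bins >= uniq[i], decreasing
    ok = np.flatnonzero(tail <= allowed)
    if ok.size == 0:
        return int(uniq[-1]) + 1  # nothing qualifies: threshold above max
    i = ok[0]
    # any c in (uniq[i-1], uniq[i]] has the same tail fraction; take smallest
    return int(uniq[i - 1]) + 1 if i > 0 else int(uniq[0])


def call_loci(cov: BinnedCoverage, threshold: int, max_gap_bins: int = 0) -> pd.DataFrame:
    """Merge runs of above-threshold bins into bound loci.

    Runs separated by <= max_gap_bins below-threshold bins are merged.
    Each locus records its maximum bin coverage (binding level) and summit
    (center of the leftmost maximal bin).
    """
    rows = []
    b = cov.bin_size
    for chrom in cov.chrom_sizes:
        counts = np.asarray(cov.counts[chrom])
        above = np.flatnonzero(counts >= threshold)
        if above.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(above) > max_gap_bins + 1)
        run_starts = np.concatenate([[0], breaks + 1])
        run_ends = np.concatenate([breaks, [above.size - 1]])
        for rs, re in zip(run_starts, run_ends):
            first_bin, last_bin = above[rs], above[re]
            seg = counts[first_bin : last_bin + 1]
            max_cov = int(seg.max())
            summit_bin = first_bin + int(np.argmax(seg))
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(first_bin * b),
                    "end": int((last_bin + 1) * b),
                    "max_coverage": max_cov,
                    "summit": int(summit_bin * b + b // 2),
                }
            )
    loci = pd.DataFrame(rows, columns=["chrom", "start", "end", "max_coverage", "summit"])
    loci.insert(0, "locus_id", [f"locus_{i:05d}" for i in range(len(loci))])
    return loci


def filter_by_control(
    loci: pd.DataFrame,
    control_cov: BinnedCoverage,
    spec: ThresholdSpec,
    signal_cov: BinnedCoverage | None = None,
) -> pd.DataFrame:
    """Remove loci with any bin at/above the control track's percentile threshold."""
    if signal_cov is not None and not signal_cov.same_grid(control_cov):
        raise ValueError("signal and control coverage are binned on different grids")
    thr = percentile_threshold(
        control_cov, spec.control_percentile, include_zero_bins=spec.include_zero_bins
    )
    b = control_cov.bin_size
    keep = []
    for row in loci.itertuples(index=False):
        ctrl = control_cov.counts[row.chrom][row.start // b : (row.end + b - 1) // b]
        keep.append(not bool((ctrl >= thr).any()))
    out = loci[np.asarray(keep, dtype=bool)].reset_index(drop=True)
    logger.info(
        "filter_by_control: removed %d of %d loci (control threshold %d)",
        len(loci) - len(out), len(loci), thr,
    )
    return out


def call_peaks(
    tags: pd.DataFrame,
    chrom_sizes: dict[str, int],
    control_tags: pd.DataFrame | None = None,
    spec: ThresholdSpec | None = None,
    frag_len: int = 200,
    bin_size: int = 50,
    max_gap_bins: int = 0,
    dedupe: bool = True,
) -> tuple[pd.DataFrame, BinnedCoverage, dict]:
    """Full caller: dedupe -> extend -> bin -> threshold -> merge -> control filter.

    Returns (loci, signal coverage, log dict).
    """
    spec = spec or ThresholdSpec()
    if dedupe:
        tags = dedupe_tags(tags)
    cov = bin_coverage(extend_tags(tags, chrom_sizes, frag_len), chrom_sizes, bin_size)
    thr = percentile_threshold(cov, spec.signal_percentile, spec.include_zero_bins)
    loci = call_loci(cov, thr, max_gap_bins)
    info = {
        "n_tags": int(len(tags)),
        "signal_threshold": int(thr),
        "n_loci_prefilter": int(len(loci)),
    }
    if control_tags is not None:
        if dedupe:
            control_tags = dedupe_tags(control_tags)
        ctrl_cov = bin_coverage(
            extend_tags(control_tags, chrom_sizes, frag_len), chrom_sizes, bin_size
        )
        loci = filter_by_control(loci, ctrl_cov, spec, signal_cov=cov)
    info["n_loci"] = int(len(loci))
    return loci, cov, info


def pooled_vs_single_loci(tag_sets, chrom_sizes, **kwargs):
    """Call loci on each replicate tag set alone and on the pooled tags.

    Returns (per-replicate locus frames, pooled locus frame).  Pooling is
    the default replicate policy; an intersect mode is offered downstream.
    """
    singles = [call_peaks(t, chrom_sizes, **kwargs)[0] for t in tag_sets]
    pooled = call_peaks(pd.concat(tag_sets, ignore_index=True), chrom_sizes, **kwargs)[0]
    return singles, pooled
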