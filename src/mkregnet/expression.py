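"""Knockout-expression integration with TF occupancy.

The per-gene knockout effect is the difference of mean log2 expression
between knockout and control replicates; genes moving at least 1.5-fold
with Benjamini-Hochberg FDR < 0.05 are classified as activated (down in
the knockout) or repressed (up).  Bound-locus density as a function of
TSS distance, averaged within each response class, quantifies enrichment
of potential regulatory sites near responsive genes.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotate import GeneSet

logger = logging.getLogger(__name__)

FOLD_THRESHOLD = 1.5
Q_THRESHOLD = 0.05
DENSITY_BIN = 20_000
DENSITY_MAX = 200_000

CLASSES = ["activated", "repressed", "nonresponsive"]


def compute_effect(
    matrix: pd.DataFrame,
    control_cols: list[str],
    knockout_cols: list[str],
) -> pd.DataFrame:
    """Per-gene knockout effect (log2), Welch-free two-sample t p-value, BH q.

    ``matrix`` is genes x samples in log2.  Genes with missing values are
    dropped with a warning.  Degenerate genes (zero variance in both
    conditions) get p = 1 when the means agree, p = 0 otherwise.
    """
    if len(control_cols) < 2 or len(knockout_cols) < 2:
        raise ValueError("need >=2 replicates per condition")
    sub = matrix[list(control_cols) + list(knockout_cols)]
    missing = sub.isna().any(axis=1)
    if missing.any():
        logger.warning("dropping %d genes with missing values", int(missing.sum()))
        sub = sub[~missing]
    ctrl = sub[list(control_cols)].to_numpy(dtype=float)
    ko = sub[list(knockout_cols)].to_numpy(dtype=float)
    effect = ko.mean(axis=1) - ctrl.mean(axis=1)
    import warnings as _warnings

    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        # constant genes trigger scipy's precision-loss warning; their NaN
        # p-values are resolved explicitly below
        _warnings.simplefilter("ignore", RuntimeWarning)
        t = stats.ttest_ind(ko, ctrl, axis=1)
        p = np.asarray(t.pvalue, dtype=float)
    degenerate = np.isnan(p)
    p[degenerate & (np.abs(effect) < 1e-12)] = 1.0
    p[degenerate & (np.abs(effect) >= 1e-12)] = 0.0
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene_id": sub.index,
            "mean_log2_control": ctrl.mean(axis=1),
            "mean_log2_knockout": ko.mean(axis=1),
            "effect": effect,
            "p_value": p,
            "fdr_q": q,
        }
    ).set_index("gene_id")


def classify_response(
    records: pd.DataFrame,
    fold_thresh: float = FOLD_THRESHOLD,
    q_thresh: float = Q_THRESHOLD,
) -> pd.Series:
    """Assign activated / repressed / nonresponsive per gene.

    A gene is activated by the factor when its expression drops in the
    knockout (effect <= -log2(fold)) at FDR < q; repressed when it rises
    symmetrically.
    """
    cut = math.log2(fold_thresh)
    effect = records["effect"]
    sig = records["fdr_q"] < q_thresh
    cls = pd.Series("nonresponsive", index=records.index, name="response_class")
    cls[(effect <= -cut) & sig] = "activated"
    cls[(effect >= cut) & sig] = "repressed"
    return cls


@dataclass
class DensityProfile:
    """Bound-locus density (loci per gene per distance bin) by response class."""

    bin_width: int
    max_distance: int
    counts: pd.DataFrame      # bins x classes, raw locus counts
    class_sizes: dict[str, int]

    @property
    def density(self) -> pd.DataFrame:
        dens = self.counts.astype(float).copy()
        for cls in dens.columns:
            n = self.class_sizes.get(cls, 0)
            dens[cls] = dens[cls] / n if n else np.nan
        return dens


def peak_density_profile(
    loci: pd.DataFrame,
    genes: GeneSet,
    classes: pd.Series,
    bin_width: int = DENSITY_BIN,
    max_distance: int = DENSITY_MAX,
    mode: str = "all",
) -> DensityProfile:
    """Count loci per TSS-distance bin for each gene response class.

    ``mode="all"`` (default): every (gene, locus) pair within
    ``max_distance`` counts, so one locus can contribute to several genes.
    ``mode="nearest"``: a locus counts only toward its nearest-TSS gene.
    """
    n_bins = max_distance // bin_width
    edges = np.arange(n_bins + 1) * bin_width
    mids_by_chrom = {
        chrom: np.sort(((sub["start"] + sub["end"]) // 2).to_numpy(dtype=np.int64))
        for chrom, sub in loci.groupby("chrom", sort=False)
    }
    counts = {cls: np.zeros(n_bins, dtype=np.int64) for cls in CLASSES}
    class_sizes = {cls: int((classes == cls).sum()) for cls in CLASSES}
    for cls in CLASSES:
        if class_sizes[cls] == 0:
            logger.warning("peak_density_profile: empty class %r", cls)

    if mode == "nearest":
        from .annotate import nearest_tss

        gene_cls = classes.to_dict()
        for chrom, mids in mids_by_chrom.items():
            for mid in mids:
                gene, dist = nearest_tss(int(mid), chrom, genes)
                if gene is None or dist >= max_distance:
                    continue
                cls = gene_cls.get(gene)
                if cls in counts:
                    counts[cls][dist // bin_width] += 1
    elif mode == "all":
        for g in genes.genes.itertuples(index=False):
            cls = classes.get(g.gene_id)
            if cls not in counts:
                continue
            mids = mids_by_chrom.get(g.chrom)
            if mids is None:
                continue
            tss = int(g.tss)
            # absolute distance in [lo, hi) <=> mid in (tss-hi, tss-lo] u [tss+lo, tss+hi)
            right = np.searchsorted(mids, tss + edges, side="left")
            left = np.searchsorted(mids, tss - edges, side="right")
            # a locus exactly at the TSS belongs to the right side only
            left[0] = np.searchsorted(mids, tss, side="left")
            per_bin = (right[1:] - right[:-1]) + (left[:-1] - left[1:])
            counts[cls] += per_bin
    else:
        raise ValueError(f"unknown mode {mode!r}")

    counts_df = pd.DataFrame(counts, index=pd.Index(edges[:-1], name="bin_start"))
    return DensityProfile(bin_width, max_distance, counts_df, class_sizes)


def enrichment_test(
    profile: DensityProfile,
    cls: str,
    window: tuple[int, int],
    background_class: str = "nonresponsive",
) -> dict:
    """Fold enrichment of per-gene locus density in a TSS-distance window.

    fold = (class count / class size) / (background count / background
    size) over the window.  The p-value is the exact conditional binomial
    comparison of the two Poisson rates: given the total count, the class
    count is Binomial(total, n_class/(n_class+n_background)) under the
    null of equal per-gene rates.
    """
    lo, hi = window
    if lo % profile.bin_width or hi % profile.bin_width:
        raise ValueError("window edges must align to the bin grid")
    sel = (profile.counts.index >= lo) & (profile.counts.index < hi)
    k_c = int(profile.counts.loc[sel, cls].sum())
    k_b = int(profile.counts.loc[sel, background_class].sum())
    n_c = profile.class_sizes[cls]
    n_b = profile.class_sizes[background_class]
    result = {
        "window": [int(lo), int(hi)],
        "class": cls,
        "count_class": k_c,
        "count_background": k_b,
        "n_genes_class": n_c,
        "n_genes_background": n_b,
    }
    if k_b == 0 or n_b == 0 or n_c == 0:
        result.update(fold=np.nan, p_value=np.nan, flag="zero_background")
        return result
    result["fold"] = (k_c / n_c) / (k_b / n_b)
    test = stats.binomtest(k_c, k_c + k_b, n_c / (n_c + n_b), alternative="two-sided")
    result["p_value"] = float(test.pvalue)
    return result


def enrichment_test_permutation(
    loci: pd.DataFrame,
    genes: GeneSet,
    classes: pd.Series,
    cls: str,
    window: tuple[int, int],
    n_rounds: int = 10_000,
    seed: int = 0,
    bin_width: int = DENSITY_BIN,
    max_distance: int = DENSITY_MAX,
) -> dict:
    """Gene-label permutation alternative to the binomial enrichment test."""
    rng = np.random.default_rng(seed)
    observed = enrichment_test(
        peak_density_profile(loci, genes, classes, bin_width, max_distance), cls, window
    )
    labels = classes.to_numpy().copy()
    index = classes.index
    hits = 0
    for _ in range(n_rounds):
        rng.shuffle(labels)
        perm = enrichment_test(
            peak_density_profile(loci, genes, pd.Series(labels, index=index), bin_width, max_distance),
            cls,
            window,
        )
        if not np.isnan(perm["fold"]) and perm["fold"] >= observed["fold"]:
            hits += 1
    observed["p_permutation"] = (hits + 1) / (n_rounds + 1)
    observed["n_rounds"] = n_rounds
    return observed
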