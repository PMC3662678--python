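"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates the study design downstream stages expect: a
random genome with annotated genes, a knockout expression matrix in
which activated/repressed genes move by at least 1.5-fold (log2 >=
~0.585), planted TF binding sites whose density is elevated 2.6-fold
within 20 kb of activated-gene TSSs and 1.4-fold within 60-100 kb of
repressed-gene TSSs, consensus motifs (RUNX TGTGGTT, ETS CAGGAAG, GATA
GATAAG) written into the sequence at site centers, and ChIP tag tracks
(TF, a p300-like cofactor restricted to co-bound sites, and a
non-immune-serum control) sampled from ~200 bp fragments.

Every operation is deterministic for a fixed ``SimConfig.seed``; each
stage derives an independent stream from the seed so changing one knob
does not scramble unrelated stages.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotate import GeneSet, GENE_COLUMNS, EXON_COLUMNS
from .io import Genome, revcomp
from .motifs import RUNX_CONSENSUS, ETS_CONSENSUS, GATA_CONSENSUS, AP1_CONSENSUS

MIN_EFFECT_LOG2 = math.log2(1.5)

MOTIF_CONSENSUS = {
    "RUNX": RUNX_CONSENSUS,
    "ETS": ETS_CONSENSUS,
    "GATA": GATA_CONSENSUS,
    "AP1": AP1_CONSENSUS,
}

# per-stage salts for independent deterministic RNG streams
_SALTS = {
    "genome": 11, "annotation": 13, "classes": 17, "sites": 19,
    "expression": 23, "chip_tf": 29, "chip_cofactor": 31, "control": 37,
}

TRACKS = ("chip_tf", "chip_cofactor", "control")


@dataclass
class SimConfig:
    """Study conditions for the simulator (defaults = emulation targets)."""

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 10_000_000
    n_genes: int = 200
    frac_activated: float = 0.2
    frac_repressed: float = 0.2
    effect_min_log2: float = MIN_EFFECT_LOG2
    effect_max_log2: float = 2.0
    n_sites: int = 100
    site_strength_sigma: float = 0.5
    enrichment_pi: float = 0.5
    frag_len_mean: int = 200
    frag_len_sd: float = 40.0
    frag_len_min: int = 50
    frag_len_max: int = 500
    tag_len: int = 36
    n_tags: int = 1_000_000
    replicate_count: int = 3
    noise_sd_log2: float = 0.25
    proximal_density_fold: float = 2.6
    distal_density_fold: float = 1.4
    cobound_fraction: float = 0.13
    proximal_window: int = 20_000
    distal_window: tuple = (60_000, 100_000)
    # per-site motif label probabilities (RUNX, ETS, GATA, none)
    motif_probs: tuple = (0.60, 0.35, 0.05, 0.0)
    motif_strand_random: bool = False
    min_tss_gap: int = 2_000

    def __post_init__(self):
        props = {
            "frac_activated": self.frac_activated,
            "frac_repressed": self.frac_repressed,
            "enrichment_pi": self.enrichment_pi,
            "cobound_fraction": self.cobound_fraction,
        }
        for name, v in props.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_activated + self.frac_repressed > 1.0:
            raise ValueError("frac_activated + frac_repressed must be <= 1")
        if self.effect_min_log2 < MIN_EFFECT_LOG2 - 1e-9:
            raise ValueError(f"effect_min_log2 must be >= log2(1.5) ~ {MIN_EFFECT_LOG2:.3f}")
        if self.effect_max_log2 < self.effect_min_log2:
            raise ValueError("effect_max_log2 < effect_min_log2")
        if self.chrom_length < 10 * self.frag_len_mean:
            raise ValueError("chrom_length must be >= 10 x frag_len_mean")
        if self.n_chrom <= 0 or self.chrom_length <= 0:
            raise ValueError("n_chrom and chrom_length must be positive")
        if self.proximal_density_fold < 1.0 or self.distal_density_fold < 1.0:
            raise ValueError("density folds must be >= 1 (use 1.0 for the null)")
        if abs(sum(self.motif_probs) - 1.0) > 1e-9 or min(self.motif_probs) < 0:
            raise ValueError("motif_probs must be a distribution over 4 labels")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, _SALTS[stage]]))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["distal_window"] = list(self.distal_window)
        d["motif_probs"] = list(self.motif_probs)
        return d


# ---------------------------------------------------------------------------
# genome & annotation

def make_genome(config: SimConfig) -> Genome:
    """I.i.d. uniform A/C/G/T sequences, one per chromosome."""
    rng = config.rng("genome")
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = {
        f"chr{i + 1}": bases[rng.integers(0, 4, size=config.chrom_length)]
        for i in range(config.n_chrom)
    }
    return Genome(seqs)


def make_annotation(chrom_sizes: dict[str, int], config: SimConfig) -> GeneSet:
    """Random gene models with pairwise TSS gaps >= min_tss_gap.

    When a chromosome is long enough (>= 480 kb) its final 120 kb is kept
    gene-free so that some loci can sit more than 100 kb from any TSS.
    """
    rng = config.rng("annotation")
    chroms = list(chrom_sizes)
    n_per = _split_counts(config.n_genes, len(chroms))
    genes, exons = [], []
    gi = 0
    for chrom, n in zip(chroms, n_per):
        size = chrom_sizes[chrom]
        desert = 120_000 if size >= 480_000 else 0
        usable_end = size - desert
        margin = 1_000
        gap = config.min_tss_gap
        span = usable_end - 2 * margin - (n - 1) * gap if n else 0
        if n and span <= 0:
            raise ValueError(
                f"{chrom} ({size} bp) too short for {n} genes with {gap} bp TSS gaps"
            )
        if n == 0:
            continue
        raw = np.sort(rng.integers(0, span, size=n))
        tss = margin + raw + np.arange(n) * gap
        for t in tss:
            strand = "+" if rng.random() < 0.5 else "-"
            gene_len = int(rng.integers(2_000, 20_001))
            if strand == "+":
                start, end = int(t), min(int(t) + gene_len, size)
            else:
                start, end = max(int(t) + 1 - gene_len, 0), int(t) + 1
            gene_id = f"gene_{gi:04d}"
            genes.append(
                {"gene_id": gene_id, "chrom": chrom, "strand": strand,
                 "start": start, "end": end, "tss": int(t)}
            )
            exons.extend(_make_exons(gene_id, chrom, strand, start, end, rng))
            gi += 1
    gdf = pd.DataFrame(genes, columns=GENE_COLUMNS)
    edf = pd.DataFrame(exons, columns=EXON_COLUMNS)
    return GeneSet(gdf, edf)


def _make_exons(gene_id, chrom, strand, start, end, rng) -> list[dict]:
    """1-4 exons built outward from the TSS, truncated at the gene end."""
    n_ex = int(rng.integers(1, 5))
    exons = []
    pos = start if strand == "+" else end
    for _ in range(n_ex):
        ex_len = int(rng.integers(100, 501))
        intron = int(rng.integers(500, 3_001))
        if strand == "+":
            ex_start, ex_end = pos, min(pos + ex_len, end)
            pos = ex_end + intron
            if ex_end <= ex_start or ex_start >= end:
                break
        else:
            ex_end, ex_start = pos, max(pos - ex_len, start)
            pos = ex_start - intron
            if ex_end <= ex_start or ex_end <= start:
                break
        exons.append({"gene_id": gene_id, "chrom": chrom, "start": ex_start, "end": ex_end})
        if strand == "+" and pos >= end:
            break
        if strand == "-" and pos <= start:
            break
    if not exons:  # degenerate draw: one minimal exon at the TSS
        exons = [{"gene_id": gene_id, "chrom": chrom, "start": start, "end": min(start + 100, end)}]
    return exons


def _split_counts(total: int, k: int) -> list[int]:
    base = total // k
    out = [base] * k
    for i in range(total - base * k):
        out[i] += 1
    return out


# ---------------------------------------------------------------------------
# response classes & expression

def assign_gene_classes(genes: GeneSet, config: SimConfig) -> pd.DataFrame:
    """Per-gene response class and true knockout effect (log2).

    Activated genes get negative knockout-vs-control effects (expression
    falls without the factor), repressed genes positive, magnitudes
    uniform in [effect_min_log2, effect_max_log2].
    """
    rng = config.rng("classes")
    ids = genes.genes["gene_id"].to_numpy()
    n = len(ids)
    n_act = round(config.frac_activated * n)
    n_rep = round(config.frac_repressed * n)
    classes = np.array(["nonresponsive"] * n, dtype=object)
    order = rng.permutation(n)
    classes[order[:n_act]] = "activated"
    classes[order[n_act : n_act + n_rep]] = "repressed"
    magnitude = rng.uniform(config.effect_min_log2, config.effect_max_log2, size=n)
    effect = np.where(
        classes == "activated", -magnitude, np.where(classes == "repressed", magnitude, 0.0)
    )
    return pd.DataFrame(
        {"gene_id": ids, "response_class": classes, "true_effect_log2": effect}
    ).set_index("gene_id")


def simulate_expression(classes: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Log2 expression matrix: control and knockout replicate columns.

    Control replicates ~ Normal(gene baseline, noise_sd_log2); knockout
    replicates are shifted by the true effect.
    """
    if config.replicate_count < 2:
        raise ValueError("replicate_count must be >= 2 for the downstream test")
    rng = config.rng("expression")
    n = len(classes)
    k = config.replicate_count
    baseline = rng.normal(8.0, 1.5, size=n)
    ctrl = baseline[:, None] + rng.normal(0.0, config.noise_sd_log2, size=(n, k))
    ko = (
        baseline[:, None]
        + classes["true_effect_log2"].to_numpy()[:, None]
        + rng.normal(0.0, config.noise_sd_log2, size=(n, k))
    )
    cols = [f"control_{i + 1}" for i in range(k)] + [f"knockout_{i + 1}" for i in range(k)]
    return pd.DataFrame(np.hstack([ctrl, ko]), index=classes.index, columns=cols)


# ---------------------------------------------------------------------------
# binding sites

TRUTH_COLUMNS = [
    "site_id", "chrom", "position", "strength", "motif_label",
    "cobound_flag", "linked_gene", "linked_distance", "n_motif_copies",
]


def plant_sites(
    genome: Genome | None,
    genes: GeneSet,
    classes: pd.DataFrame,
    config: SimConfig,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Place TF binding sites with class-dependent TSS-distance densities.

    Background sites are uniform over the genome; additional sites fall
    within ``proximal_window`` of activated-gene TSSs so the expected
    density there is ``proximal_density_fold`` x background, and within
    the ``distal_window`` annulus of repressed-gene TSSs at
    ``distal_density_fold`` x background.  A ``cobound_fraction`` of
    sites is flagged for the cofactor track.  When a genome is supplied,
    the site's motif consensus is written into the sequence at the site
    center (strong sites get extra copies nearby so motif multiplicity
    co-varies with occupancy).
    """
    sizes = chrom_sizes or (genome.sizes if genome is not None else None)
    if sizes is None:
        raise ValueError("need a genome or chrom_sizes")
    rng = config.rng("sites")

    chroms = list(sizes)
    lengths = np.array([sizes[c] for c in chroms], dtype=np.int64)
    G = int(lengths.sum())

    gene_rows = genes.genes.set_index("gene_id")
    act = classes.index[classes["response_class"] == "activated"]
    rep = classes.index[classes["response_class"] == "repressed"]
    prox_windows = _tss_windows(gene_rows.loc[act], 0, config.proximal_window, sizes)
    d_lo, d_hi = config.distal_window
    dist_windows = _tss_windows(gene_rows.loc[rep], d_lo, d_hi, sizes)
    L_p = int(sum(e - s for _, s, e in prox_windows))
    L_d = int(sum(e - s for _, s, e in dist_windows))

    fp, fd = config.proximal_density_fold, config.distal_density_fold
    denom = G + (fp - 1.0) * L_p + (fd - 1.0) * L_d
    p_prox = (fp - 1.0) * L_p / denom
    p_dist = (fd - 1.0) * L_d / denom
    if fp > 1.0 and len(act) and L_p == 0:
        raise ValueError("proximal density target unattainable: activated windows have zero length")
    if fd > 1.0 and len(rep) and L_d == 0:
        raise ValueError("distal density target unattainable: repressed windows have zero length")
    n_prox, n_dist = rng.multinomial(config.n_sites, [p_prox, p_dist, 1 - p_prox - p_dist])[:2]
    n_bg = config.n_sites - n_prox - n_dist

    rows = []
    # background: uniform over the concatenated genome
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    for pos in rng.integers(0, G, size=n_bg):
        ci = int(np.searchsorted(offsets, pos, side="right") - 1)
        rows.append((chroms[ci], int(pos - offsets[ci]), None, None))
    rows.extend(_targeted_sites(prox_windows, n_prox, gene_rows, rng))
    rows.extend(_targeted_sites(dist_windows, n_dist, gene_rows, rng))

    n = len(rows)
    strength = rng.lognormal(0.0, config.site_strength_sigma, size=n)
    labels = np.array(["RUNX", "ETS", "GATA", "none"], dtype=object)[
        rng.choice(4, size=n, p=list(config.motif_probs))
    ]
    cobound = rng.random(n) < config.cobound_fraction
    # motif multiplicity co-varies with strength (top strength terciles)
    q70, q90 = np.quantile(strength, [0.70, 0.90]) if n else (0, 0)
    copies = 1 + (strength > q70).astype(int) + (strength > q90).astype(int)

    sites = pd.DataFrame(
        {
            "site_id": [f"site_{i:05d}" for i in range(n)],
            "chrom": [r[0] for r in rows],
            "position": [r[1] for r in rows],
            "strength": strength,
            "motif_label": labels,
            "cobound_flag": cobound,
            "linked_gene": [r[2] for r in rows],
            "linked_distance": [r[3] for r in rows],
            "n_motif_copies": copies,
        },
        columns=TRUTH_COLUMNS,
    )
    # keep site centers clear of chromosome edges so motifs/fragments fit
    margin = 30
    limit = sites["chrom"].map(sizes)
    sites["position"] = np.minimum(np.maximum(sites["position"], margin), limit - margin)

    if genome is not None:
        _write_motifs(genome, sites, rng, config)
    return sites


def _tss_windows(gene_rows: pd.DataFrame, lo: int, hi: int, sizes) -> list[tuple]:
    """Clipped (chrom, start, end) windows at distance [lo, hi) around TSSs."""
    wins = []
    for g in gene_rows.itertuples():
        size = sizes[g.chrom]
        if lo == 0:
            s, e = max(0, g.tss - hi), min(size, g.tss + hi)
            if e > s:
                wins.append((g.Index, s, e))
        else:
            s, e = max(0, g.tss - hi), max(0, g.tss - lo)
            if e > s:
                wins.append((g.Index, s, e))
            s, e = min(size, g.tss + lo), min(size, g.tss + hi)
            if e > s:
                wins.append((g.Index, s, e))
    return wins


def _targeted_sites(windows, count, gene_rows, rng):
    if count == 0 or not windows:
        return []
    lens = np.array([e - s for _, s, e in windows], dtype=float)
    picks = rng.choice(len(windows), size=count, p=lens / lens.sum())
    out = []
    for w in picks:
        gene, s, e = windows[w]
        pos = int(rng.integers(s, e))
        g = gene_rows.loc[gene]
        out.append((g["chrom"], pos, gene, abs(pos - int(g["tss"]))))
    return out


def _write_motifs(genome: Genome, sites: pd.DataFrame, rng, config: SimConfig) -> None:
    offsets = (0, -12, 12, -24)  # primary copy at center, extras nearby
    for s in sites.itertuples(index=False):
        if s.motif_label == "none":
            continue
        consensus = MOTIF_CONSENSUS[s.motif_label]
        for c in range(int(s.n_motif_copies)):
            seq = consensus
            if config.motif_strand_random and rng.random() < 0.5:
                seq = revcomp(seq)
            center = s.position + offsets[min(c, len(offsets) - 1)]
            start = center - len(seq) // 2
            arr = genome.seqs[s.chrom]
            if 0 <= start and start + len(seq) <= len(arr):
                arr[start : start + len(seq)] = np.frombuffer(seq.encode(), dtype=np.uint8)


# ---------------------------------------------------------------------------
# tags

def simulate_tags(
    sites: pd.DataFrame,
    chrom_sizes: dict[str, int],
    config: SimConfig,
    track: str = "chip_tf",
    n_tags: int | None = None,
) -> pd.DataFrame:
    """Sample mapped tags (chrom, pos5, strand) for one ChIP/control track.

    Each tag comes from a strength-weighted planted site with probability
    ``enrichment_pi`` (fragment center jittered by Normal(0, frag_len_sd),
    fragment length ~ Normal(frag_len_mean, frag_len_sd) truncated to
    [frag_len_min, frag_len_max], the tag being the fragment 5' end on a
    random strand) and from the uniform background otherwise.  The
    control track uses enrichment_pi = 0; the cofactor track samples only
    cobound-flagged sites.
    """
    if track not in TRACKS:
        raise ValueError(f"unknown track {track!r}")
    n = config.n_tags if n_tags is None else n_tags
    if n <= 0:
        raise ValueError("n_tags must be positive")
    rng = config.rng(track)
    pi = 0.0 if track == "control" else config.enrichment_pi
    pool = sites[sites["cobound_flag"]] if track == "chip_cofactor" else sites
    if len(pool) == 0:
        pi = 0.0

    chroms = list(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    G = int(lengths.sum())

    from_site = rng.random(n) < pi
    n_site = int(from_site.sum())
    n_bg = n - n_site

    out_chrom = np.empty(n, dtype=object)
    out_pos = np.empty(n, dtype=np.int64)
    out_strand = np.where(rng.random(n) < 0.5, "+", "-")

    if n_bg:
        flat = rng.integers(0, G, size=n_bg)
        ci = np.searchsorted(offsets, flat, side="right") - 1
        out_chrom[~from_site] = np.array(chroms, dtype=object)[ci]
        out_pos[~from_site] = flat - offsets[ci]
    if n_site:
        w = pool["strength"].to_numpy(dtype=float)
        idx = rng.choice(len(pool), size=n_site, p=w / w.sum())
        centers = pool["position"].to_numpy(dtype=np.int64)[idx]
        site_chrom = pool["chrom"].to_numpy(dtype=object)[idx]
        frag_center = centers + np.rint(rng.normal(0, config.frag_len_sd, size=n_site)).astype(np.int64)
        frag_len = np.clip(
            np.rint(rng.normal(config.frag_len_mean, config.frag_len_sd, size=n_site)),
            config.frag_len_min,
            config.frag_len_max,
        ).astype(np.int64)
        start = frag_center - frag_len // 2
        end = start + frag_len
        plus = out_strand[from_site] == "+"
        pos5 = np.where(plus, start, end - 1)
        limit = np.array([chrom_sizes[c] for c in site_chrom], dtype=np.int64)
        out_chrom[from_site] = site_chrom
        out_pos[from_site] = np.clip(pos5, 0, limit - 1)
    return pd.DataFrame({"chrom": out_chrom, "pos5": out_pos, "strand": out_strand})


def tags_to_bed(tags: pd.DataFrame, chrom_sizes: dict[str, int], tag_len: int = 36) -> pd.DataFrame:
    """Render tags as BED6 reads whose 5' end sits at pos5."""
    plus = tags["strand"].to_numpy() == "+"
    pos = tags["pos5"].to_numpy(dtype=np.int64)
    start = np.where(plus, pos, pos - tag_len + 1)
    end = np.where(plus, pos + tag_len, pos + 1)
    limit = tags["chrom"].map(chrom_sizes).to_numpy(dtype=np.int64)
    return pd.DataFrame(
        {
            "chrom": tags["chrom"],
            "start": np.clip(start, 0, limit),
            "end": np.clip(end, 0, limit),
            "name": [f"tag_{i}" for i in range(len(tags))],
            "score": 0,
            "strand": tags["strand"],
        }
    )


# ---------------------------------------------------------------------------
# whole-world convenience

@dataclass
class SyntheticWorld:
    """Everything one simulated study produces, in memory."""

    config: SimConfig
    genome: Genome
    genes: GeneSet
    classes: pd.DataFrame
    sites: pd.DataFrame
    expression: pd.DataFrame
    tags: dict[str, pd.DataFrame] = field(default_factory=dict)


def simulate_world(config: SimConfig, with_tags: bool = True) -> SyntheticWorld:
    genome = make_genome(config)
    genes = make_annotation(genome.sizes, config)
    classes = assign_gene_classes(genes, config)
    sites = plant_sites(genome, genes, classes, config)
    expression = simulate_expression(classes, config)
    tags = {}
    if with_tags:
        for track in TRACKS:
            tags[track] = simulate_tags(sites, genome.sizes, config, track)
    return SyntheticWorld(config, genome, genes, classes, sites, expression, tags)
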