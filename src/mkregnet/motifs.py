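"""PWM binding-energy scoring and de-novo discriminative motif discovery.

The match of a PWM to a region is summarised by its *approximated binding
energy*: the log of the summed multiplicative likelihood-ratio
contributions of every window on both strands,

    E = log  sum_{i, strand}  prod_j  P_j(base_ij) / Q(base_ij).

Because the inner model is multiplicative, one consensus-quality site
dominates E, while several weak sites can still combine into a medium
binding potential.  Discovery is discriminative: k-mer seeds are ranked
by foreground/background log-odds, refined by hard EM over the foreground
regions, and ranked by mean foreground-minus-background energy.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import spearmanr

from .io import Genome, encode, revcomp

BASES = "ACGT"

RUNX_CONSENSUS = "TGTGGTT"
ETS_CONSENSUS = "CAGGAAG"
GATA_CONSENSUS = "GATAAG"
# The AP-1 TPA-response element (TGACTCA) is used as the negative-control
# motif; the study reports poor AP-1 enrichment without printing a
# sequence, so the canonical TRE consensus is adopted here.
AP1_CONSENSUS = "TGACTCA"

PSEUDOCOUNT = 0.01


class PWM:
    """Position probability matrix with background frequencies.

    ``probs`` is (w, 4) over A,C,G,T; every cell is positive after
    pseudocount smoothing so log-odds are finite.
    """

    def __init__(self, probs: np.ndarray, background: np.ndarray | None = None, name: str = ""):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("PWM probs must have shape (w, 4)")
        if np.any(probs <= 0):
            raise ValueError("PWM entries must be positive (apply pseudocounts)")
        self.probs = probs / probs.sum(axis=1, keepdims=True)
        self.background = (
            np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
        )
        self.background = self.background / self.background.sum()
        self.name = name

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    @classmethod
    def from_counts(cls, counts: np.ndarray, pseudocount: float = PSEUDOCOUNT, **kw) -> "PWM":
        counts = np.asarray(counts, dtype=float) + pseudocount
        return cls(counts, **kw)

    @classmethod
    def from_consensus(cls, consensus: str, p: float = 0.97, **kw) -> "PWM":
        w = len(consensus)
        probs = np.full((w, 4), (1 - p) / 3)
        for j, base in enumerate(consensus.upper()):
            probs[j, BASES.index(base)] = p
        return cls(probs, **kw)

    @classmethod
    def from_sites(cls, sites: list[str], pseudocount: float = PSEUDOCOUNT, **kw) -> "PWM":
        if not sites:
            raise ValueError("no sites")
        w = len(sites[0])
        counts = np.zeros((w, 4))
        for s in sites:
            enc = encode(s)
            for j, b in enumerate(enc):
                if b < 4:
                    counts[j, b] += 1
        return cls.from_counts(counts, pseudocount, **kw)

    def log_odds(self) -> np.ndarray:
        """(w, 5) log(P/Q) lookup; column 4 (N) contributes 0."""
        lo = np.zeros((self.width, 5))
        lo[:, :4] = np.log(self.probs) - np.log(self.background)[None, :]
        return lo

    def reverse_complement(self) -> "PWM":
        return PWM(self.probs[::-1, ::-1], self.background, name=self.name)

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits against the background."""
        return np.sum(self.probs * (np.log2(self.probs) - np.log2(self.background)[None, :]), axis=1)

    def to_meme(self) -> str:
        lines = [f"MOTIF {self.name or self.consensus}", ""]
        lines.append(f"letter-probability matrix: alength= 4 w= {self.width}")
        for row in self.probs:
            lines.append("  " + "  ".join(f"{x:.6f}" for x in row))
        lines.append("")
        return "\n".join(lines)


def write_meme(pwms: list[PWM], path) -> None:
    """Emit PWMs in MEME minimal text format."""
    header = (
        "MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n"
        "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for pwm in pwms:
            fh.write(pwm.to_meme() + "\n")


def _window_scores(enc: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Per-start-position sums of log-odds for one strand."""
    w = log_odds.shape[0]
    n = len(enc) - w + 1
    if n <= 0:
        return np.zeros(0)
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    return log_odds[np.arange(w)[None, :], windows].sum(axis=1)


def binding_energy(pwm: PWM, sequence: str) -> float:
    """Approximated binding energy of a region (nats): log-sum over all
    window positions on both strands of the PWM likelihood ratio."""
    enc = encode(sequence)
    if len(enc) < pwm.width:
        raise ValueError(f"sequence shorter than PWM width {pwm.width}")
    fwd = _window_scores(enc, pwm.log_odds())
    rev = _window_scores(enc, pwm.reverse_complement().log_odds())
    return float(logsumexp(np.concatenate([fwd, rev])))


def binding_energies(pwm: PWM, sequences: list[str]) -> np.ndarray:
    return np.array([binding_energy(pwm, s) for s in sequences])


def score_site_mutation(pwm: PWM, sequence: str, position: int, old: str, new: str):
    """Binding energy before and after a targeted site edit.

    Raises ValueError when ``old`` does not match the sequence content at
    ``position``; returns (E_before, E_after).
    """
    if sequence[position : position + len(old)].upper() != old.upper():
        raise ValueError(
            f"sequence at {position} is {sequence[position:position+len(old)]!r}, expected {old!r}"
        )
    if len(new) != len(old):
        raise ValueError("replacement must preserve length")
    mutated = sequence[:position] + new + sequence[position + len(old) :]
    return binding_energy(pwm, sequence), binding_energy(pwm, mutated)


def extract_regions(genome: Genome, loci: pd.DataFrame, half_width: int = 250) -> list[str]:
    """Fixed-width sequences centered on locus summits, clipped at bounds."""
    return [
        genome.fetch(l.chrom, l.summit - half_width, l.summit + half_width)
        for l in loci.itertuples(index=False)
    ]


def extract_flanks(
    genome: Genome, loci: pd.DataFrame, offset: int = 1_000, half_width: int = 250
) -> list[str]:
    """Background sequences from both flanks at ``offset`` from each summit.

    The offset must exceed 2x half_width so background windows are
    disjoint from foreground windows.
    """
    if offset <= 2 * half_width:
        raise ValueError("flank offset must exceed the foreground window (overlap)")
    out = []
    for l in loci.itertuples(index=False):
        for center in (l.summit - offset, l.summit + offset):
            seq = genome.fetch(l.chrom, center - half_width, center + half_width)
            if len(seq) >= 2 * half_width:
                out.append(seq)
    return out


def energy_by_occupancy(
    loci: pd.DataFrame,
    genome: Genome,
    pwm: PWM,
    n_groups: int = 10,
    half_width: int = 250,
):
    """Stratify motif binding energy by ChIP binding level.

    Loci are split into ``n_groups`` quantile groups of max bin coverage;
    returns (per-group summary DataFrame, Spearman rho of coverage vs
    energy, its p-value).
    """
    energies = binding_energies(pwm, extract_regions(genome, loci, half_width))
    coverage = loci["max_coverage"].to_numpy(dtype=float)
    if len(loci) < n_groups:
        n_groups = max(1, len(loci))
    ranks = pd.Series(coverage).rank(method="first")
    groups = pd.qcut(ranks, n_groups, labels=False)
    df = pd.DataFrame({"group": groups, "coverage": coverage, "energy": energies})
    summary = (
        df.groupby("group")
        .agg(
            n=("energy", "size"),
            coverage_median=("coverage", "median"),
            energy_q25=("energy", lambda x: x.quantile(0.25)),
            energy_median=("energy", "median"),
            energy_q75=("energy", lambda x: x.quantile(0.75)),
        )
        .reset_index()
    )
    if np.ptp(coverage) == 0 or np.ptp(energies) == 0:
        rho, pval = 0.0, 1.0
    else:
        rho, pval = spearmanr(coverage, energies)
    return summary, float(rho), float(pval)


@dataclass
class MotifDiscoveryConfig:
    """Knobs for discriminative discovery on fixed-width peak regions."""

    half_width: int = 250
    flank_offset: int = 1_000
    k_min: int = 6
    k_max: int = 8
    seeds_kept: int = 50
    em_iterations: int = 10
    min_fg_regions: int = 50
    trim_ic_bits: float = 0.3
    min_width: int = 5

    def __post_init__(self):
        if self.flank_offset <= 2 * self.half_width:
            raise ValueError("flank offset must exceed foreground window width")


@dataclass
class DiscoveredMotif:
    pwm: PWM
    consensus: str
    seed: str
    score: float          # mean fg energy - mean bg energy (nats)
    seed_log_odds: float

    def __repr__(self):
        return f"DiscoveredMotif({self.consensus}, score={self.score:.2f})"


def _kmer_counts(encoded: list[np.ndarray], k: int) -> tuple[dict, dict, int]:
    """Count k-mers over both strands of every region (N-containing skipped).

    Returns (double-strand counts, forward-strand-only counts, total
    windows counted).  Double-strand counting makes counts[kmer] ==
    counts[revcomp(kmer)]; the forward-strand counts break orientation
    ties when a seed is reported.
    """
    counts: dict[str, int] = {}
    fwd_counts: dict[str, int] = {}
    total = 0
    for enc in encoded:
        for is_fwd, strand_enc in ((True, enc), (False, 3 - enc[::-1])):  # complement is 3-x
            seq = "".join(BASES[b] if b < 4 else "N" for b in strand_enc)
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                counts[kmer] = counts.get(kmer, 0) + 1
                if is_fwd:
                    fwd_counts[kmer] = fwd_counts.get(kmer, 0) + 1
                total += 1
    return counts, fwd_counts, total


def _hamming_occurrences(encoded: list[np.ndarray], seed_enc: np.ndarray, max_mm: int = 1) -> list[str]:
    """All windows (oriented to the seed strand) within Hamming distance."""
    k = len(seed_enc)
    rc = 3 - seed_enc[::-1]
    sites = []
    for enc in encoded:
        if len(enc) < k:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(enc, k)
        for target, flip in ((seed_enc, False), (rc, True)):
            mm = (windows != target[None, :]).sum(axis=1)
            for i in np.flatnonzero(mm <= max_mm):
                win = windows[i]
                if win.max() >= 4:
                    continue
                if flip:
                    win = 3 - win[::-1]
                sites.append("".join(BASES[b] for b in win))
    return sites


def _best_sites(encoded: list[np.ndarray], pwm: PWM) -> list[str]:
    """Best-scoring window per region (either strand), for hard-EM refits."""
    lo_f = pwm.log_odds()
    lo_r = pwm.reverse_complement().log_odds()
    sites = []
    for enc in encoded:
        if len(enc) < pwm.width:
            continue
        sf = _window_scores(enc, lo_f)
        sr = _window_scores(enc, lo_r)
        i_f, i_r = int(np.argmax(sf)), int(np.argmax(sr))
        if sf[i_f] >= sr[i_r]:
            win = enc[i_f : i_f + pwm.width]
        else:
            win = 3 - enc[i_r : i_r + pwm.width][::-1]
        if win.max() < 4:
            sites.append("".join(BASES[b] for b in win))
    return sites


def _trim_pwm(pwm: PWM, ic_bits: float, min_width: int) -> PWM:
    """Drop uninformative edge columns (IC below threshold)."""
    ic = pwm.information_content()
    lo, hi = 0, pwm.width
    while hi - lo > min_width and ic[lo] < ic_bits:
        lo += 1
    while hi - lo > min_width and ic[hi - 1] < ic_bits:
        hi -= 1
    if (lo, hi) == (0, pwm.width):
        return pwm
    return PWM(pwm.probs[lo:hi], pwm.background, name=pwm.name)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _redundant(consensus: str, kept: list[str]) -> bool:
    for other in kept:
        for c in (consensus, revcomp(consensus)):
            if len(c) == len(other) and _hamming(c, other) <= 1:
                return True
            if c in other or other in c:
                return True
    return False


def discover_motifs(
    fg_regions: list[str],
    bg_regions: list[str],
    config: MotifDiscoveryConfig | None = None,
) -> list[DiscoveredMotif]:
    """Discriminative de-novo motif discovery.

    Seeds are k-mers (k in [k_min, k_max], both strands) ranked by
    log((fg_freq+eps)/(bg_freq+eps)); for the top seeds a PWM is built
    from foreground occurrences within Hamming distance 1 and refined by
    hard EM (best site per region, <= em_iterations refits).  Motifs are
    ranked by mean foreground minus mean background binding energy, edge
    columns with near-zero information content are trimmed, and redundant
    consensuses (Hamming <= 1 or substring, either strand) collapse onto
    the better-ranked motif.  Fully deterministic for fixed inputs.
    """
    config = config or MotifDiscoveryConfig()
    if len(fg_regions) < config.min_fg_regions:
        raise ValueError(f"need >= {config.min_fg_regions} foreground regions")
    fg_enc = [encode(s) for s in fg_regions]
    bg_enc = [encode(s) for s in bg_regions]

    # --- seed ranking ---
    seeds: list[tuple[float, str]] = []
    for k in range(config.k_min, config.k_max + 1):
        fg_counts, fg_fwd, fg_total = _kmer_counts(fg_enc, k)
        bg_counts, _, bg_total = _kmer_counts(bg_enc, k)
        fg_total, bg_total = max(fg_total, 1), max(bg_total, 1)
        for kmer, c_fg in fg_counts.items():
            rc = revcomp(kmer)
            if rc < kmer:
                continue  # enumerate each strand pair once
            c_bg = bg_counts.get(kmer, 0)
            score = np.log((c_fg + 1) / fg_total) - np.log((c_bg + 1) / bg_total)
            # report the orientation seen more often on the forward strand
            if fg_fwd.get(rc, 0) > fg_fwd.get(kmer, 0):
                kmer = rc
            seeds.append((score, kmer))
    seeds.sort(key=lambda t: (-t[0], t[1]))
    seeds = seeds[: config.seeds_kept]

    # --- refinement ---
    candidates: list[DiscoveredMotif] = []
    for seed_score, kmer in seeds:
        seed_enc = encode(kmer)
        sites = _hamming_occurrences(fg_enc, seed_enc, max_mm=1)
        if not sites:
            continue
        pwm = PWM.from_sites(sites)
        consensus = pwm.consensus
        for _ in range(config.em_iterations):
            best = _best_sites(fg_enc, pwm)
            if not best:
                break
            pwm = PWM.from_sites(best)
            if pwm.consensus == consensus:
                break
            consensus = pwm.consensus
        pwm = _trim_pwm(pwm, config.trim_ic_bits, config.min_width)
        score = float(
            np.mean(binding_energies(pwm, fg_regions)) - np.mean(binding_energies(pwm, bg_regions))
        )
        candidates.append(
            DiscoveredMotif(pwm=pwm, consensus=pwm.consensus, seed=kmer,
                            score=score, seed_log_odds=float(seed_score))
        )

    # --- final rank + redundancy pruning ---
    candidates.sort(key=lambda m: (-m.score, m.consensus))
    kept: list[DiscoveredMotif] = []
    kept_consensus: list[str] = []
    for cand in candidates:
        if _redundant(cand.consensus, kept_consensus):
            continue
        kept.append(cand)
        kept_consensus.append(cand.consensus)
    return kept


def discovery_null_sd(
    fg_regions: list[str],
    bg_regions: list[str],
    config: MotifDiscoveryConfig | None = None,
    n_rounds: int = 10,
    seed: int = 0,
) -> float:
    """SD of top discovery scores when fg/bg labels are shuffled (null scale)."""
    rng = np.random.default_rng(seed)
    pool = list(fg_regions) + list(bg_regions)
    n_fg = len(fg_regions)
    tops = []
    for _ in range(n_rounds):
        perm = rng.permutation(len(pool))
        fg = [pool[i] for i in perm[:n_fg]]
        bg = [pool[i] for i in perm[n_fg:]]
        found = discover_motifs(fg, bg, config)
        tops.append(found[0].score if found else 0.0)
    return float(np.std(tops))
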