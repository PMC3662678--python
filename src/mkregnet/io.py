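"""File-format helpers: FASTA genomes, chromosome-size tables, BED intervals.

All genomic coordinates are 0-based half-open internally; conversions to
1-based conventions happen only at file boundaries (GTF, SAM).
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)

# ASCII -> 0..4 (A,C,G,T,N); anything unknown maps to N
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i  # lowercase

# ASCII complement table (uppercasing)
_COMP = np.full(256, ord("N"), dtype=np.uint8)
for _a, _b in zip(b"ACGTacgt", b"TGCATGCA"):
    _COMP[_a] = _b


def encode(seq) -> np.ndarray:
    """Encode a sequence (str or uint8 ASCII array) as ints 0..3 (ACGT), 4 for N."""
    if isinstance(seq, str):
        seq = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENC[seq]


def revcomp_array(seq: np.ndarray) -> np.ndarray:
    """Reverse-complement an ASCII uint8 array."""
    return _COMP[seq][::-1]


def revcomp(seq: str) -> str:
    return revcomp_array(np.frombuffer(seq.encode("ascii"), dtype=np.uint8)).tobytes().decode("ascii")


class Genome:
    """In-memory genome: uppercase sequences held as uint8 ASCII arrays.

    Chromosome order is preserved (insertion order of ``seqs``).
    """

    def __init__(self, seqs: dict[str, np.ndarray]):
        self.seqs = {c: np.asarray(s, dtype=np.uint8) for c, s in seqs.items()}

    @property
    def sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.seqs.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return sequence [start, end), clipped to chromosome bounds."""
        s = self.seqs[chrom]
        start = max(0, int(start))
        end = min(len(s), int(end))
        if end <= start:
            return ""
        return s[start:end].tobytes().decode("ascii")

    def write_fasta(self, path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for chrom, s in self.seqs.items():
                fh.write(f">{chrom}\n")
                raw = s.tobytes().decode("ascii")
                for i in range(0, len(raw), width):
                    fh.write(raw[i : i + width] + "\n")

    @classmethod
    def read_fasta(cls, path) -> "Genome":
        fa = Fasta(str(path), sequence_always_upper=True)
        seqs = {
            name: np.frombuffer(str(fa[name][:]).encode("ascii"), dtype=np.uint8)
            for name in fa.keys()
        }
        fa.close()
        return cls(seqs)


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_bed6(df: pd.DataFrame, path) -> None:
    """Write a BED6 file from a DataFrame with the canonical six columns."""
    df.loc[:, BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    """Read a BED file (3-6 columns), returning canonical column names."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df.columns = BED6_COLUMNS[: df.shape[1]]
    return df


def loci_to_bed(loci: pd.DataFrame) -> pd.DataFrame:
    """Bound loci -> BED6 (name = locus id, score = max coverage)."""
    return pd.DataFrame(
        {
            "chrom": loci["chrom"],
            "start": loci["start"],
            "end": loci["end"],
            "name": loci["locus_id"],
            "score": loci["max_coverage"],
            "strand": ".",
        }
    )


def read_loci_bed(path) -> pd.DataFrame:
    bed = read_bed(path)
    loci = pd.DataFrame(
        {
            "locus_id": bed["name"] if "name" in bed else [f"locus_{i}" for i in range(len(bed))],
            "chrom": bed["chrom"],
            "start": bed["start"],
            "end": bed["end"],
            "max_coverage": bed["score"] if "score" in bed else 0,
        }
    )
    loci["summit"] = (loci["start"] + loci["end"]) // 2
    return loci


def write_bedgraph(cov, path) -> None:
    """Write binned coverage as fixed-step bedGraph (one line per non-zero run)."""
    with open(path, "w") as fh:
        for chrom, counts in cov.counts.items():
            size = cov.chrom_sizes[chrom]
            b = cov.bin_size
            # collapse runs of equal value to keep files small
            counts = np.asarray(counts)
            if len(counts) == 0:
                continue
            change = np.flatnonzero(np.diff(counts)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(counts)]])
            for s, e in zip(starts, ends):
                val = int(counts[s])
                if val == 0:
                    continue
                fh.write(f"{chrom}\t{s * b}\t{min(e * b, size)}\t{val}\n")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
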