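"""End-to-end orchestration: synth -> callpeaks -> annotate -> integrate ->
motifs -> cobind, with a run manifest and machine-readable report."""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import annotate as ann
from . import cobind as cb
from . import expression as expr
from . import io
from . import motifs as mot
from . import peaks as pk
from . import synth

logger = logging.getLogger(__name__)

STAGES = ["synth", "callpeaks", "annotate", "integrate", "motifs", "cobind"]


@dataclass
class PipelineConfig:
    """All module parameters with the study's defaults, plus a global seed."""

    seed: int = 0
    # peak calling
    frag_len: int = 200
    bin_size: int = 50
    signal_percentile: float = 99.9
    control_percentile: float = 99.0
    max_gap_bins: int = 0
    use_control: bool = True
    dedupe: bool = True
    # expression integration
    fold_threshold: float = 1.5
    q_threshold: float = 0.05
    density_bin: int = 20_000
    density_max: int = 200_000
    proximal_window: tuple = (0, 20_000)
    distal_window: tuple = (60_000, 100_000)
    # annotation
    promoter_upstream: int = 3_000
    # motifs
    motif_half_width: int = 250
    motif_flank_offset: int = 1_000
    motif_top_n: int = 5
    max_motif_regions: int = 500
    # cobind
    min_overlap: int = 1
    # simulation
    sim: synth.SimConfig = field(default_factory=synth.SimConfig)

    def __post_init__(self):
        for p in (self.signal_percentile, self.control_percentile):
            if not 0.0 < p < 100.0:
                raise ValueError(f"percentile must be in (0, 100), got {p}")
        if self.fold_threshold < 1.0:
            raise ValueError("fold_threshold must be >= 1")
        if not 0.0 < self.q_threshold < 1.0:
            raise ValueError("q_threshold must be in (0, 1)")
        if isinstance(self.sim, dict):
            self.sim = synth.SimConfig(**self.sim)
        if self.sim.seed != self.seed:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        d["proximal_window"] = list(self.proximal_window)
        d["distal_window"] = list(self.distal_window)
        return d


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run all stages on synthetic data; write outputs + manifest to out_dir."""
    out = io.ensure_dir(out_dir)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "stages": {},
    }

    def stage_done(name: str, t0: float, **counts):
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3), **counts}
        logger.info("stage %s done in %.2fs %s", name, time.time() - t0, counts)

    try:
        # ---- synth ----
        t0 = time.time()
        world = synth.simulate_world(config.sim)
        sizes = world.genome.sizes
        world.genome.write_fasta(out / "genome.fa")
        io.write_chrom_sizes(sizes, out / "chrom.sizes")
        world.genes.write_gtf(out / "genes.gtf")
        world.sites.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
        world.classes.to_csv(out / "truth_classes.tsv", sep="\t")
        world.expression.to_csv(out / "expression.tsv", sep="\t")
        for track, tags in world.tags.items():
            io.write_bed6(synth.tags_to_bed(tags, sizes, config.sim.tag_len), out / f"{track}.bed")
        stage_done("synth", t0, n_genes=len(world.genes), n_sites=len(world.sites),
                   n_tags_per_track=config.sim.n_tags)

        # ---- callpeaks ----
        t0 = time.time()
        spec = pk.ThresholdSpec(config.signal_percentile, config.control_percentile)
        control = world.tags["control"] if config.use_control else None
        loci, cov, info_tf = pk.call_peaks(
            world.tags["chip_tf"], sizes, control_tags=control, spec=spec,
            frag_len=config.frag_len, bin_size=config.bin_size,
            max_gap_bins=config.max_gap_bins, dedupe=config.dedupe,
        )
        cof_loci, _, info_cof = pk.call_peaks(
            world.tags["chip_cofactor"], sizes, control_tags=control, spec=spec,
            frag_len=config.frag_len, bin_size=config.bin_size,
            max_gap_bins=config.max_gap_bins, dedupe=config.dedupe,
        )
        io.write_bed6(io.loci_to_bed(loci), out / "tf_loci.bed")
        io.write_bed6(io.loci_to_bed(cof_loci), out / "cofactor_loci.bed")
        io.write_bedgraph(cov, out / "tf_coverage.bedgraph")
        stage_done("callpeaks", t0, tf=info_tf, cofactor=info_cof)

        # ---- annotate ----
        t0 = time.time()
        annotated = ann.annotate_loci(loci, world.genes, config.promoter_upstream)
        annotated.to_csv(out / "tf_loci_annotated.tsv", sep="\t", index=False)
        summary = ann.summarize_distribution(annotated)
        summary.to_csv(out / "tf_loci_distribution.tsv", sep="\t", index=False)
        stage_done("annotate", t0, n_annotated=len(annotated))

        # ---- integrate ----
        t0 = time.time()
        k = config.sim.replicate_count
        records = expr.compute_effect(
            world.expression,
            [f"control_{i + 1}" for i in range(k)],
            [f"knockout_{i + 1}" for i in range(k)],
        )
        classes = expr.classify_response(records, config.fold_threshold, config.q_threshold)
        records.assign(response_class=classes).to_csv(out / "gene_classification.tsv", sep="\t")
        profile = expr.peak_density_profile(
            loci, world.genes, classes, config.density_bin, config.density_max
        )
        profile.density.to_csv(out / "density_profile.tsv", sep="\t")
        enrichment = {
            "activated_proximal": expr.enrichment_test(
                profile, "activated", tuple(config.proximal_window)
            ),
            "repressed_distal": expr.enrichment_test(
                profile, "repressed", tuple(config.distal_window)
            ),
        }
        with open(out / "enrichment.json", "w") as fh:
            json.dump(enrichment, fh, indent=2, default=_jsonable)
        stage_done("integrate", t0,
                   n_activated=int((classes == "activated").sum()),
                   n_repressed=int((classes == "repressed").sum()))

        # ---- motifs ----
        t0 = time.time()
        top_loci = loci.nlargest(config.max_motif_regions, "max_coverage")
        fg = mot.extract_regions(world.genome, top_loci, config.motif_half_width)
        bg = mot.extract_flanks(
            world.genome, top_loci, config.motif_flank_offset, config.motif_half_width
        )
        discovered = []
        if len(fg) >= mot.MotifDiscoveryConfig().min_fg_regions:
            discovered = mot.discover_motifs(fg, bg)[: config.motif_top_n]
            mot.write_meme([m.pwm for m in discovered], out / "motifs.meme")
        runx = mot.PWM.from_consensus(mot.RUNX_CONSENSUS, name="RUNX")
        strat, rho, rho_p = mot.energy_by_occupancy(loci, world.genome, runx)
        strat.to_csv(out / "energy_by_occupancy.tsv", sep="\t", index=False)
        stage_done("motifs", t0, n_motifs=len(discovered),
                   top_consensus=discovered[0].consensus if discovered else None,
                   runx_energy_spearman=round(float(rho), 4))

        # ---- cobind ----
        t0 = time.time()
        pair_df, merged, venn = cb.overlap_loci(loci, cof_loci, config.min_overlap)
        pd.DataFrame(
            {
                "chrom": merged["chrom"], "start": merged["start"], "end": merged["end"],
                "name": merged["region_id"], "score": 0, "strand": ".",
            }
        ).to_csv(out / "cobound_regions.bed", sep="\t", header=False, index=False)
        gene_table = cb.assign_to_genes(loci, merged, world.genes, classes)
        gene_table.to_csv(out / "cobind_gene_table.tsv", sep="\t", index=False)
        fractions = cb.cobinding_response_fractions(gene_table)
        with open(out / "cobind.json", "w") as fh:
            json.dump({"venn": venn, "fractions": fractions}, fh, indent=2, default=_jsonable)
        stage_done("cobind", t0, **venn)
    except Exception as exc:
        failed = [s for s in STAGES if s not in manifest["stages"]]
        raise RuntimeError(f"stage {failed[0] if failed else '?'} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonable)
    return out


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def make_report(result_dir, plots: bool = False) -> dict:
    """Summarize a completed run into report.json (+ optional figure)."""
    out = Path(result_dir)
    report: dict = {"result_dir": str(out), "missing": []}

    def load_json(name):
        p = out / name
        if not p.exists():
            report["missing"].append(name)
            return None
        with open(p) as fh:
            return json.load(fh)

    manifest = load_json("manifest.json")
    if manifest:
        report["seed"] = manifest["seed"]
        report["stage_counts"] = {k: v for k, v in manifest["stages"].items()}
    if (out / "tf_loci.bed").exists():
        report["n_tf_loci"] = int(len(io.read_bed(out / "tf_loci.bed")))
    else:
        report["missing"].append("tf_loci.bed")
    if (out / "tf_loci_distribution.tsv").exists():
        dist = pd.read_csv(out / "tf_loci_distribution.tsv", sep="\t")
        report["category_fractions"] = {
            r["value"]: r["fraction"]
            for _, r in dist[dist["partition"] == "category"].iterrows()
        }
        report["distance_class_fractions"] = {
            r["value"]: r["fraction"]
            for _, r in dist[dist["partition"] == "distance_class"].iterrows()
        }
    else:
        report["missing"].append("tf_loci_distribution.tsv")
    enr = load_json("enrichment.json")
    if enr:
        report["enrichment"] = {
            k: {"fold": v.get("fold"), "p_value": v.get("p_value")} for k, v in enr.items()
        }
    cob = load_json("cobind.json")
    if cob:
        report["venn"] = cob["venn"]
        report["cobind_fractions"] = cob["fractions"]
    if (out / "motifs.meme").exists():
        consensuses = []
        with open(out / "motifs.meme") as fh:
            for line in fh:
                if line.startswith("MOTIF"):
                    consensuses.append(line.split()[1])
        report["top_motifs"] = consensuses
    else:
        report["missing"].append("motifs.meme")

    if plots and (out / "density_profile.tsv").exists():
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        dens = pd.read_csv(out / "density_profile.tsv", sep="\t", index_col=0)
        fig, ax = plt.subplots(figsize=(6, 4))
        for cls, color in (("activated", "green"), ("repressed", "red"), ("nonresponsive", "black")):
            if cls in dens:
                ax.plot(dens.index / 1000, dens[cls], label=cls, color=color)
        ax.set_xlabel("distance from TSS (kb)")
        ax.set_ylabel("bound loci per gene per bin")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "density_profile.png", dpi=120)
        plt.close(fig)
        report["plots"] = ["density_profile.png"]

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    return report


def site_recovery(loci: pd.DataFrame, sites: pd.DataFrame, tol: int = 200) -> dict:
    """Sensitivity/precision of called loci against planted truth sites.

    A truth site is recovered when it lies within a called locus extended
    by ``tol`` bp on each side; a locus is a true positive when it
    contains a truth site under the same tolerance.
    """
    by_chrom = {
        chrom: np.sort(sub["position"].to_numpy(dtype=np.int64))
        for chrom, sub in sites.groupby("chrom", sort=False)
    }
    locus_hit = []
    site_hit = {chrom: np.zeros(len(v), dtype=bool) for chrom, v in by_chrom.items()}
    for r in loci.itertuples(index=False):
        pos = by_chrom.get(r.chrom)
        if pos is None:
            locus_hit.append(False)
            continue
        lo = np.searchsorted(pos, r.start - tol, side="left")
        hi = np.searchsorted(pos, r.end + tol, side="right")
        locus_hit.append(hi > lo)
        site_hit[r.chrom][lo:hi] = True
    n_sites = int(len(sites))
    n_loci = int(len(loci))
    recovered = int(sum(v.sum() for v in site_hit.values()))
    true_pos = int(sum(locus_hit))
    return {
        "n_sites": n_sites,
        "n_loci": n_loci,
        "sensitivity": recovered / n_sites if n_sites else np.nan,
        "precision": true_pos / n_loci if n_loci else np.nan,
    }
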