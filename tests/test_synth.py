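"""Generator contracts: determinism, planted structure, truth-table recounts."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mkregnet import synth
from mkregnet.annotate import GeneSet
from mkregnet.io import revcomp
from mkregnet.motifs import RUNX_CONSENSUS


def test_genome_composition_and_determinism():
    cfg = synth.SimConfig(seed=7, n_chrom=1, chrom_length=2_000, n_genes=0, n_sites=0)
    g1 = synth.make_genome(cfg)
    g2 = synth.make_genome(cfg)
    seq = g1.seqs["chr1"]
    assert len(seq) == 2_000
    for base in b"ACGT":
        assert 0.15 <= (seq == base).mean() <= 0.35
    assert np.array_equal(seq, g2.seqs["chr1"])


@pytest.mark.parametrize(
    "bad",
    [
        dict(chrom_length=0),
        dict(n_chrom=0),
        dict(frac_activated=0.7, frac_repressed=0.7),
        dict(effect_min_log2=0.1),
        dict(enrichment_pi=1.5),
        dict(proximal_density_fold=0.5),
    ],
)
def test_config_validation(bad):
    with pytest.raises(ValueError):
        synth.SimConfig(**bad)


def test_annotation_tss_gaps_and_determinism(tmp_path):
    cfg = synth.SimConfig(seed=3, n_chrom=1, chrom_length=2_000_000, n_genes=50)
    genes = synth.make_annotation({"chr1": 2_000_000}, cfg)
    assert len(genes) == 50
    tss = np.sort(genes.genes["tss"].to_numpy())
    assert np.diff(tss).min() >= cfg.min_tss_gap
    assert (genes.exons.groupby("gene_id").size() >= 1).all()
    # byte-identical GTF for a fixed seed
    genes.write_gtf(tmp_path / "a.gtf")
    synth.make_annotation({"chr1": 2_000_000}, cfg).write_gtf(tmp_path / "b.gtf")
    assert (tmp_path / "a.gtf").read_bytes() == (tmp_path / "b.gtf").read_bytes()


def test_annotation_empty_and_too_small():
    cfg = synth.SimConfig(seed=1, n_genes=0)
    assert len(synth.make_annotation({"chr1": 100_000}, cfg)) == 0
    crowded = synth.SimConfig(seed=1, n_genes=100, n_chrom=1, chrom_length=150_000)
    with pytest.raises(ValueError, match="too short"):
        synth.make_annotation({"chr1": 150_000}, crowded)


def test_gtf_round_trip(tmp_path, small_world):
    genes = small_world.genes
    genes.write_gtf(tmp_path / "genes.gtf")
    back = GeneSet.read_gtf(tmp_path / "genes.gtf")
    lhs = genes.genes.sort_values("gene_id").reset_index(drop=True)
    rhs = back.genes.sort_values("gene_id").reset_index(drop=True)
    pd.testing.assert_frame_equal(lhs, rhs, check_dtype=False)
    assert len(back.exons) == len(genes.exons)


def test_gene_class_split_and_effect_bounds():
    cfg = synth.SimConfig(seed=5, n_chrom=1, chrom_length=2_000_000, n_genes=100)
    genes = synth.make_annotation({"chr1": 2_000_000}, cfg)
    classes = synth.assign_gene_classes(genes, cfg)
    counts = classes["response_class"].value_counts()
    assert counts["activated"] == 20 and counts["repressed"] == 20
    assert counts["nonresponsive"] == 60
    responsive = classes[classes["response_class"] != "nonresponsive"]
    assert (responsive["true_effect_log2"].abs() >= math.log2(1.5) - 1e-12).all()
    assert (classes.loc[classes["response_class"] == "activated", "true_effect_log2"] < 0).all()
    assert (classes.loc[classes["response_class"] == "repressed", "true_effect_log2"] > 0).all()
    again = synth.assign_gene_classes(genes, cfg)
    pd.testing.assert_frame_equal(classes, again)


def test_null_fold_places_sites_uniformly():
    cfg = synth.SimConfig(
        seed=11, n_chrom=1, chrom_length=5_000_000, n_genes=50, n_sites=500,
        proximal_density_fold=1.0, distal_density_fold=1.0,
    )
    sizes = {"chr1": 5_000_000}
    genes = synth.make_annotation(sizes, cfg)
    classes = synth.assign_gene_classes(genes, cfg)
    sites = synth.plant_sites(None, genes, classes, cfg, chrom_sizes=sizes)
    assert sites["linked_gene"].isna().all()
    # uniformity of positions (KS against uniform)
    stat = stats.kstest(sites["position"] / 5_000_000, "uniform")
    assert stat.pvalue > 0.01


def _density_ratio(sites: pd.DataFrame, genes: GeneSet, classes: pd.DataFrame,
                   window: tuple, cls: str, sizes: dict) -> tuple:
    """Brute-force truth-table recount: (count in class windows, window length)."""
    tss = genes.genes.set_index("gene_id")["tss"]
    chrom_of = genes.genes.set_index("gene_id")["chrom"]
    target = classes.index[classes["response_class"] == cls]
    lo, hi = window
    in_win = np.zeros(len(sites), dtype=bool)
    pos = sites["position"].to_numpy()
    chroms = sites["chrom"].to_numpy()
    for g in target:
        d = np.abs(pos - tss[g])
        in_win |= (chroms == chrom_of[g]) & (d >= lo) & (d < hi)
    # union length of the windows
    segs = []
    for g in target:
        t = tss[g]
        if lo == 0:
            segs.append((chrom_of[g], max(0, t - hi), min(sizes[chrom_of[g]], t + hi)))
        else:
            segs.append((chrom_of[g], max(0, t - hi), max(0, t - lo)))
            segs.append((chrom_of[g], min(sizes[chrom_of[g]], t + lo), min(sizes[chrom_of[g]], t + hi)))
    length = 0
    for chrom in set(c for c, _, _ in segs):
        ivs = sorted((s, e) for c, s, e in segs if c == chrom and e > s)
        cur_s, cur_e = None, None
        for s, e in ivs:
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                length += cur_e - cur_s
                cur_s, cur_e = s, e
        if cur_s is not None:
            length += cur_e - cur_s
    return int(in_win.sum()), length


def test_proximal_density_fold_recovered():
    """Planted 2.6x density within 20 kb of activated TSSs, recounted from truth."""
    ratios = []
    for seed in range(10):
        cfg = synth.SimConfig(
            seed=seed, n_chrom=2, chrom_length=40_000_000, n_genes=400,
            frac_activated=0.5, frac_repressed=0.25, n_sites=2_000,
        )
        sizes = {f"chr{i+1}": cfg.chrom_length for i in range(cfg.n_chrom)}
        genes = synth.make_annotation(sizes, cfg)
        classes = synth.assign_gene_classes(genes, cfg)
        sites = synth.plant_sites(None, genes, classes, cfg, chrom_sizes=sizes)
        k_in, L_in = _density_ratio(sites, genes, classes, (0, 20_000), "activated", sizes)
        G = sum(sizes.values())
        k_out = len(sites) - k_in
        dens_in = k_in / L_in
        dens_out = k_out / (G - L_in)
        ratios.append(dens_in / dens_out)
    assert 2.3 <= np.mean(ratios) <= 2.9


def test_runx_motif_written_at_site_center(small_world):
    sites = small_world.sites
    genome = small_world.genome
    runx = sites[sites["motif_label"] == "RUNX"]
    assert len(runx) > 0
    for s in runx.itertuples(index=False):
        ctx = genome.fetch(s.chrom, s.position - 7, s.position + 7)
        assert RUNX_CONSENSUS in ctx or revcomp(RUNX_CONSENSUS) in ctx


def test_tags_uniform_under_null_enrichment():
    """enrichment_pi = 0 yields uniform tag positions (KS, 100 seeds)."""
    nonsig = 0
    empty_sites = pd.DataFrame(columns=synth.TRUTH_COLUMNS)
    for seed in range(100):
        cfg = synth.SimConfig(seed=seed, n_chrom=1, chrom_length=1_000_000,
                              n_genes=0, n_sites=0, enrichment_pi=0.0, n_tags=2_000)
        tags = synth.simulate_tags(empty_sites, {"chr1": 1_000_000}, cfg, "chip_tf")
        p = stats.kstest(tags["pos5"] / 1_000_000, "uniform").pvalue
        nonsig += p > 0.01
    assert nonsig >= 95
    assert set(tags["strand"]) <= {"+", "-"}


def test_tags_concentrate_at_single_site():
    cfg = synth.SimConfig(seed=2, n_chrom=1, chrom_length=1_000_000, n_genes=0,
                          n_sites=1, enrichment_pi=0.5, n_tags=10_000)
    sites = pd.DataFrame(
        [{"site_id": "site_00000", "chrom": "chr1", "position": 500_000, "strength": 1.0,
          "motif_label": "RUNX", "cobound_flag": False, "linked_gene": None,
          "linked_distance": None, "n_motif_copies": 1}]
    )
    tags = synth.simulate_tags(sites, {"chr1": 1_000_000}, cfg, "chip_tf")
    near = ((tags["pos5"] - 500_000).abs() <= 500).sum()
    assert near >= 4_500


def test_cofactor_track_samples_only_cobound_sites():
    cfg = synth.SimConfig(seed=9, n_chrom=1, chrom_length=1_000_000, n_genes=0,
                          n_sites=2, enrichment_pi=1.0, n_tags=5_000, frag_len_sd=20)
    sites = pd.DataFrame(
        [
            {"site_id": "a", "chrom": "chr1", "position": 200_000, "strength": 1.0,
             "motif_label": "none", "cobound_flag": False, "linked_gene": None,
             "linked_distance": None, "n_motif_copies": 1},
            {"site_id": "b", "chrom": "chr1", "position": 800_000, "strength": 1.0,
             "motif_label": "none", "cobound_flag": True, "linked_gene": None,
             "linked_distance": None, "n_motif_copies": 1},
        ]
    )
    tags = synth.simulate_tags(sites, {"chr1": 1_000_000}, cfg, "chip_cofactor")
    assert ((tags["pos5"] - 800_000).abs() < 2_000).all()


def test_expression_exact_without_noise():
    cfg = synth.SimConfig(seed=4, n_chrom=1, chrom_length=2_000_000, n_genes=50,
                          noise_sd_log2=0.0)
    genes = synth.make_annotation({"chr1": 2_000_000}, cfg)
    classes = synth.assign_gene_classes(genes, cfg)
    mat = synth.simulate_expression(classes, cfg)
    ctrl = mat[[c for c in mat if c.startswith("control")]].mean(axis=1)
    ko = mat[[c for c in mat if c.startswith("knockout")]].mean(axis=1)
    np.testing.assert_allclose(ko - ctrl, classes["true_effect_log2"], atol=1e-12)
    nonresp = classes["response_class"] == "nonresponsive"
    assert (ko - ctrl)[nonresp].abs().max() == 0.0


def test_expression_requires_replicates():
    cfg = synth.SimConfig(seed=1, replicate_count=1)
    classes = pd.DataFrame({"gene_id": ["g1"], "response_class": ["nonresponsive"],
                            "true_effect_log2": [0.0]}).set_index("gene_id")
    with pytest.raises(ValueError, match="replicate_count"):
        synth.simulate_expression(classes, cfg)


def test_expression_detection_power():
    """Two-sample t at alpha=0.05 detects a 2-fold effect with power >= 0.8
    at noise 0.3 and n=3, matching the analytic noncentral-t oracle."""
    cfg = synth.SimConfig(seed=6, replicate_count=3, noise_sd_log2=0.3)
    n = 1_000
    classes = pd.DataFrame(
        {"gene_id": [f"g{i}" for i in range(n)],
         "response_class": ["repressed"] * n,
         "true_effect_log2": [1.0] * n}
    ).set_index("gene_id")
    mat = synth.simulate_expression(classes, cfg)
    ctrl = mat[[c for c in mat if c.startswith("control")]].to_numpy()
    ko = mat[[c for c in mat if c.startswith("knockout")]].to_numpy()
    p = stats.ttest_ind(ko, ctrl, axis=1).pvalue
    power = (p < 0.05).mean()
    # analytic oracle: noncentral t with df=4, ncp = 1 / (0.3 * sqrt(2/3))
    ncp = 1.0 / (0.3 * math.sqrt(2 / 3))
    crit = stats.t.ppf(0.975, df=4)
    expected = 1 - stats.nct.cdf(crit, df=4, nc=ncp) + stats.nct.cdf(-crit, df=4, nc=ncp)
    assert power >= 0.8
    assert abs(power - expected) < 0.05


def test_world_outputs_byte_identical(tmp_path, small_config):
    def render(d):
        w = synth.simulate_world(small_config)
        d.mkdir(exist_ok=True)
        w.genome.write_fasta(d / "genome.fa")
        w.genes.write_gtf(d / "genes.gtf")
        w.sites.to_csv(d / "sites.tsv", sep="\t", index=False)
        w.expression.to_csv(d / "expr.tsv", sep="\t")
        for track, tags in w.tags.items():
            synth.tags_to_bed(tags, w.genome.sizes).to_csv(d / f"{track}.bed", sep="\t", index=False)
        return d

    a, b = render(tmp_path / "a"), render(tmp_path / "b")
    for f in sorted(p.name for p in a.iterdir()):
        assert (a / f).read_bytes() == (b / f).read_bytes(), f
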