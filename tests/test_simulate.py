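"""Generator contracts: determinism, mixture calibration, knockout rules."""

import numpy as np
import pytest
from scipy import stats

from conftest import small_config
from hogseq import (
    build_toy_genome,
    build_ground_truth,
    extend_reads,
    simulate_chip_reads,
    simulate_expression_table,
    simulate_mnase_fragments,
)
from hogseq.genome import promoter_of
from hogseq.simulate import CLASSES, ConfigError, ScenarioConfig


def uniform_multipliers(value=1.0):
    table = {c: value for c in CLASSES}
    return {s: {c: dict(table) for c in ("unstressed", "stress")} for s in ("wt", "hog1")}


class TestToyGenome:
    def test_tiling_arithmetic(self):
        cfg = small_config(n_per_class=2, gene_length=2000, spacing=4000)
        genome, genes = build_toy_genome(cfg)
        assert genome.length_of(cfg.chrom_name) == 11 * 4000  # 10 genes -> 44 kb
        assert len(genes) == 10
        starts = [g.orf.start for g in genes]
        assert all(b - a == 4000 for a, b in zip(starts, starts[1:]))
        assert [g.strand for g in genes[:4]] == ["+", "-", "+", "-"]
        # every gene keeps at least flank_bp of intergenic room and the TSS
        # sits tss_offset upstream of the ORF on the gene's own strand
        for g in genes:
            if g.strand == "+":
                assert g.orf.start - g.tss == cfg.tss_offset
            else:
                assert g.tss - (g.orf.end - 1) == cfg.tss_offset

    def test_zero_genes_gives_minimal_chromosome(self):
        cfg = small_config(n_per_class=0)
        genome, genes = build_toy_genome(cfg)
        assert genes == []
        assert genome.length_of(cfg.chrom_name) == cfg.spacing

    def test_insufficient_spacing_is_config_error(self):
        with pytest.raises(ConfigError, match="spacing"):
            small_config(spacing=3000, gene_length=2000, flank_bp=1000)

    def test_same_seed_reproduces_everything(self):
        a, b = small_config(seed=11), small_config(seed=11)
        _, genes_a = build_toy_genome(a)
        _, genes_b = build_toy_genome(b)
        assert genes_a == genes_b
        truth_a = build_ground_truth(genes_a, a)
        truth_b = build_ground_truth(genes_b, b)
        assert truth_a.equals(truth_b)
        reads_a = simulate_chip_reads("polii", "wt", "stress", genes_a, truth_a, a)
        reads_b = simulate_chip_reads("polii", "wt", "stress", genes_b, truth_b, b)
        assert reads_a.df.equals(reads_b.df)


class TestChipSimulator:
    def test_depth_conservation_and_tag_validation(self):
        cfg = small_config()
        _, genes = build_toy_genome(cfg)
        truth = build_ground_truth(genes, cfg)
        reads = simulate_chip_reads("hog1", "wt", "stress", genes, truth, cfg)
        assert len(reads) == cfg.chip_depth
        with pytest.raises(ConfigError):
            simulate_chip_reads("tfiib", "wt", "stress", genes, truth, cfg)
        with pytest.raises(ConfigError):
            simulate_chip_reads("polii", "wt", "salt", genes, truth, cfg)

    def test_uniform_multipliers_give_uniform_density(self):
        """Null case: all multipliers 1 -> no region stands out (chi-square GOF)."""
        cfg = small_config(seed=3, depth=100_000,
                           polii_multipliers=uniform_multipliers(1.0))
        genome, genes = build_toy_genome(cfg)
        truth = build_ground_truth(genes, cfg)
        reads = simulate_chip_reads("polii", "wt", "unstressed", genes, truth, cfg)
        frags = extend_reads(reads, cfg.chip_fragment_length, genome)
        mids = frags.midpoints
        L = genome.length_of(cfg.chrom_name)
        interior = mids[(mids >= 1000) & (mids < L - 1000)]
        counts, _ = np.histogram(interior, bins=40, range=(1000, L - 1000))
        assert stats.chisquare(counts).pvalue > 0.01

    def test_mixture_expectation_matches_closed_form(self):
        """A multiplier-16 gene draws 16*L_fg / sum(w*L) of the fragments."""
        mult = uniform_multipliers(1.0)
        for strain in ("wt", "hog1"):
            mult[strain]["stress"]["hog1_dependent"] = 16.0
        cfg = small_config(seed=5, n_per_class=2, depth=200_000,
                           polii_multipliers=mult)
        genome, genes = build_toy_genome(cfg)
        truth = build_ground_truth(genes, cfg)
        reads = simulate_chip_reads("polii", "wt", "stress", genes, truth, cfg)
        frags = extend_reads(reads, cfg.chip_fragment_length, genome)
        mids = frags.midpoints

        dep_ids = set(truth.loc[truth["class"] == "hog1_dependent", "gene_id"])
        fg_len = 0
        in_fg = np.zeros(len(mids), dtype=bool)
        for g in genes:
            if g.gene_id not in dep_ids:
                continue
            prom = promoter_of(g, genome, cfg.promoter_length)
            for iv in (prom, g.orf):
                fg_len += len(iv)
                in_fg |= (mids >= iv.start) & (mids < iv.end)
        L = genome.length_of(cfg.chrom_name)
        expected = 16.0 * fg_len / (L + (16.0 - 1.0) * fg_len)
        observed = in_fg.mean()
        se = np.sqrt(expected * (1 - expected) / len(mids))
        assert abs(observed - expected) < 4 * se

    def test_hog1_factor_absent_in_knockout_strain(self):
        """ChIP of Hog1 in the hog1 strain shows no gene-localized excess."""
        cfg = small_config(seed=9, depth=100_000)
        genome, genes = build_toy_genome(cfg)
        truth = build_ground_truth(genes, cfg)
        reads = simulate_chip_reads("hog1", "hog1", "stress", genes, truth, cfg)
        mids = extend_reads(reads, cfg.chip_fragment_length, genome).midpoints
        fg_len = 0
        in_fg = np.zeros(len(mids), dtype=bool)
        for g in genes:
            prom = promoter_of(g, genome, cfg.promoter_length)
            for iv in (prom, g.orf):
                fg_len += len(iv)
                in_fg |= (mids >= iv.start) & (mids < iv.end)
        L = genome.length_of(cfg.chrom_name)
        expected = fg_len / L
        se = np.sqrt(expected * (1 - expected) / len(mids))
        assert abs(in_fg.mean() - expected) < 4 * se


class TestMnaseSimulator:
    def test_zero_jitter_zero_eviction_centres_on_grid(self):
        cfg = small_config(seed=2, depth=20_000, jitter_sd=0.0,
                           mnase_background_fraction=0.0)
        genome, genes = build_toy_genome(cfg)
        truth = build_ground_truth(genes, cfg)
        frags = simulate_mnase_fragments("wt", "unstressed", genes, truth, cfg)
        centres = frags.df["start"].to_numpy() + cfg.mnase_fragment_length // 2
        grid = set()
        for g in genes:
            for o in cfg.nucleosome_offsets:
                grid.add(g.tss + o if g.strand == "+" else g.tss - o)
        assert set(centres.tolist()) <= grid
        assert len(frags) == cfg.mnase_depth

    def test_plus_one_eviction_thins_proportionally(self):
        """Eviction 0.5 restricted to the +1 nucleosome halves its fragments
        relative to the zero-eviction run, up to the fixed-depth dilution."""
        no_evic = {s: {c: 0.0 for c in CLASSES} for s in ("wt", "hog1")}
        evic = {
            "wt": {c: (0.5 if c == "hog1_dependent" else 0.0) for c in CLASSES},
            "hog1": {c: 0.0 for c in CLASSES},
        }
        base = dict(seed=4, n_per_class=10, depth=200_000, jitter_sd=0.0,
                    mnase_background_fraction=0.0, evicted_offsets=(50,))
        cfg0 = small_config(**base, eviction=no_evic)
        cfg1 = small_config(**base, eviction=evic)
        genome, genes = build_toy_genome(cfg0)
        truth0 = build_ground_truth(genes, cfg0)
        truth1 = build_ground_truth(genes, cfg1)
        dep = set(truth1.loc[truth1["class"] == "hog1_dependent", "gene_id"])

        def plus_one_count(cfg, truth):
            frags = simulate_mnase_fragments("wt", "stress", genes, truth, cfg)
            centres = frags.df["start"].to_numpy() + cfg.mnase_fragment_length // 2
            total = 0
            for g in genes:
                if g.gene_id not in dep:
                    continue
                c = g.tss + 50 if g.strand == "+" else g.tss - 50
                total += int(np.sum(centres == c))
            return total

        n0 = plus_one_count(cfg0, truth0)
        n1 = plus_one_count(cfg1, truth1)
        # fixed total depth: halving the 10 dependent +1 weights removes 5 of
        # the 250 nucleosome weight units and renormalizes the remainder
        n_nuc = len(genes) * len(cfg0.nucleosome_offsets)
        dilution = n_nuc / (n_nuc - 0.5 * len(dep))
        expected = 0.5 * dilution * n0
        assert abs(n1 - expected) < 4 * np.sqrt(expected)

    def test_knockout_strain_dependent_genes_not_evicted(self):
        """hog1-strain stress leaves dependent-gene nucleosomes untouched."""
        cfg = small_config(seed=6, depth=100_000)
        genome, genes = build_toy_genome(cfg)
        truth = build_ground_truth(genes, cfg)
        dep = set(truth.loc[truth["class"] == "hog1_dependent", "gene_id"])
        windows = []
        for g in genes:
            if g.gene_id in dep:
                lo = g.tss if g.strand == "+" else g.tss - 199
                windows.append((lo, lo + 200))

        def count_in_windows(condition):
            frags = simulate_mnase_fragments("hog1", condition, genes, truth, cfg)
            centres = frags.df["start"].to_numpy() + cfg.mnase_fragment_length // 2
            return sum(int(np.sum((centres >= lo) & (centres < hi))) for lo, hi in windows)

        n_stress, n_rest = count_in_windows("stress"), count_in_windows("unstressed")
        table = np.array([[n_stress, cfg.mnase_depth - n_stress],
                          [n_rest, cfg.mnase_depth - n_rest]])
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01


class TestExpressionSimulator:
    def test_noiseless_means_respect_class_rules(self):
        cfg = small_config(fc_noise_sd=0.0)
        _, genes = build_toy_genome(cfg)
        truth = build_ground_truth(genes, cfg)
        table = simulate_expression_table(genes, truth, cfg)
        merged = table.merge(truth[["gene_id", "class"]], on="gene_id")
        dep = merged[merged["class"] == "hog1_dependent"]
        assert (dep["fc_wt"] > 1.75).all()
        assert (dep["fc_hog1"] / dep["fc_wt"] <= 0.75).all()
        hk = merged[merged["class"] == "housekeeping"]
        assert hk["fc_wt"].between(1.0, 1.1).all()
        down = merged[merged["class"] == "down_regulated"]
        assert (down["fc_wt"] <= 0.5).all()

    def test_same_seed_identical_table(self):
        cfg = small_config(seed=13)
        _, genes = build_toy_genome(cfg)
        truth = build_ground_truth(genes, cfg)
        a = simulate_expression_table(genes, truth, cfg)
        b = simulate_expression_table(genes, truth, small_config(seed=13))
        assert a.equals(b)
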