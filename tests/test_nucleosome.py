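"""TSS profiles, nucleosome peak calling and occupancy/eviction statistics."""

import numpy as np
import pytest

from conftest import small_config
from hogseq import (
    GenomeBuild,
    GenomicInterval,
    GeneModel,
    call_nucleosomes,
    compare_eviction,
    occupancy_percent,
    tss_profile,
)
from hogseq.coverage import CoverageTrack, dedup_reads, pileup, to_rpm
from hogseq.simulate import build_ground_truth, build_toy_genome, simulate_mnase_fragments


def make_track(values, n_reads=1000, norm="rpm"):
    return CoverageTrack({"chrI": np.asarray(values, dtype=float)}, n_reads, norm)


def gene(gene_id="g1", strand="+", tss=5000, chrom="chrI"):
    orf = (tss + 50, tss + 2050) if strand == "+" else (tss - 2050, tss - 49)
    return GeneModel(gene_id, GenomicInterval(chrom, *orf, strand), tss, strand)


class TestTssProfile:
    def test_uniform_track_flat_profile(self):
        track = make_track(np.full(20_000, 3.5))
        prof = tss_profile(track, [gene()], flank=1000)
        np.testing.assert_allclose(prof.mean_profile, 3.5)
        assert prof.offsets[0] == -1000 and prof.offsets[-1] == 1000

    def test_minus_strand_delta_lands_at_offset_zero(self):
        values = np.zeros(20_000)
        values[5000] = 9.0
        prof = tss_profile(make_track(values), [gene(strand="-")], flank=1000)
        assert prof.mean_profile[np.where(prof.offsets == 0)[0][0]] == 9.0
        assert prof.mean_profile.sum() == 9.0

    def test_minus_strand_row_is_reversed(self):
        values = np.zeros(20_000)
        values[5000 - 10] = 1.0  # 10 bp downstream of a minus-strand TSS
        prof = tss_profile(make_track(values), [gene(strand="-")], flank=1000)
        assert prof.matrix[0, np.where(prof.offsets == 10)[0][0]] == 1.0

    def test_edge_genes_dropped_with_warning(self):
        track = make_track(np.zeros(3000))
        near_edge = gene(tss=500)
        with pytest.warns(UserWarning, match="dropped 1 genes"):
            with pytest.raises(ValueError):
                tss_profile(track, [near_edge], flank=1000)

    def test_phased_fragments_recover_grid_peaks(self):
        cfg = small_config(seed=21, depth=200_000, jitter_sd=20.0)
        genome, genes = build_toy_genome(cfg)
        truth = build_ground_truth(genes, cfg)
        frags = simulate_mnase_fragments("wt", "unstressed", genes, truth, cfg)
        track = to_rpm(pileup(dedup_reads(frags), genome))
        prof = tss_profile(track, genes, flank=1000)
        calls = call_nucleosomes(prof.mean_profile, prof.offsets)
        centers = sorted(c.center for c in calls)
        assert len(centers) == len(cfg.nucleosome_offsets)
        for found, expected in zip(centers, sorted(cfg.nucleosome_offsets)):
            assert abs(found - expected) <= 10


class TestCallNucleosomes:
    def test_single_gaussian_bump(self):
        x = np.arange(-1000, 1001)
        y = np.exp(-0.5 * ((x - 50) / 30.0) ** 2)
        calls = call_nucleosomes(y, offsets=x)
        assert len(calls) == 1
        assert abs(calls[0].center - 50) <= 5
        assert 0.0 < calls[0].score <= 1.0

    def test_flat_profile_no_calls(self):
        assert call_nucleosomes(np.full(2001, 2.0)) == []
        assert call_nucleosomes(np.zeros(2001)) == []

    def test_noise_only_profile_no_calls(self):
        rng = np.random.default_rng(0)
        noisy = 100.0 + rng.normal(0, 1.0, size=2001)  # 1% flat noise
        assert call_nucleosomes(noisy) == []

    @pytest.mark.parametrize("gap,expected", [(300, 2), (60, 1)])
    def test_merge_rule(self, gap, expected):
        x = np.arange(-1000, 1001)
        y = np.exp(-0.5 * ((x + gap / 2) / 30.0) ** 2)
        y += 0.9 * np.exp(-0.5 * ((x - gap / 2) / 30.0) ** 2)
        assert len(call_nucleosomes(y, offsets=x)) == expected

    def test_calls_do_not_overlap(self):
        x = np.arange(-1000, 1001)
        y = sum(np.exp(-0.5 * ((x - c) / 40.0) ** 2) for c in (-200, 50, 215, 380))
        calls = call_nucleosomes(y, offsets=x)
        spans = sorted((c.center - c.width // 2, c.center + c.width // 2) for c in calls)
        for (_, end_a), (start_b, _) in zip(spans, spans[1:]):
            assert end_a <= start_b


class TestOccupancy:
    def test_identity_gives_full_occupancy(self):
        track = make_track(np.full(20_000, 5.0))
        res = occupancy_percent(track, track, [gene()], normalize="none")
        assert res.per_gene["occupancy_pct"].iloc[0] == pytest.approx(100.0)
        assert res.per_gene["eviction_pct"].iloc[0] == pytest.approx(0.0)

    def test_halved_window_signal_gives_fifty_percent(self):
        g = gene()
        untreated = np.full(20_000, 4.0)
        treated = untreated.copy()
        treated[g.tss:g.tss + 200] = 2.0
        res = occupancy_percent(make_track(treated), make_track(untreated), [g],
                                normalize="none")
        assert res.per_gene["occupancy_pct"].iloc[0] == pytest.approx(50.0)

    def test_occupancy_invariant_to_common_rescale(self):
        g = gene()
        rng = np.random.default_rng(1)
        u = rng.uniform(1, 5, size=20_000)
        t = 0.7 * u
        r1 = occupancy_percent(make_track(t), make_track(u), [g], normalize="none")
        r2 = occupancy_percent(make_track(3 * t), make_track(3 * u), [g], normalize="none")
        assert r1.per_gene["occupancy_pct"].iloc[0] == pytest.approx(
            r2.per_gene["occupancy_pct"].iloc[0]
        )

    def test_eviction_plus_occupancy_is_hundred(self):
        g = gene()
        rng = np.random.default_rng(2)
        u = make_track(rng.uniform(1, 5, size=20_000))
        t = make_track(rng.uniform(1, 5, size=20_000))
        res = occupancy_percent(t, u, [g], normalize="none")
        total = res.per_gene["occupancy_pct"] + res.per_gene["eviction_pct"]
        np.testing.assert_allclose(total, 100.0)

    def test_minus_strand_window_is_upstream_mirrored(self):
        g = gene(strand="-")
        untreated = np.full(20_000, 4.0)
        treated = untreated.copy()
        treated[g.tss - 199:g.tss + 1] = 1.0  # the 200 bp downstream on '-' strand
        res = occupancy_percent(make_track(treated), make_track(untreated), [g],
                                normalize="none")
        assert res.per_gene["occupancy_pct"].iloc[0] == pytest.approx(25.0)

    def test_plus_one_only_eviction_matches_dilution_oracle(self):
        """Thinning only the +1 nucleosome: the 200-bp window mixes +1 with
        flanking signal, so measured eviction equals the overlap-weighted
        expectation, not the raw eviction fraction."""
        evic = {"wt": {c: (0.51 if c == "hog1_dependent" else 0.0)
                       for c in ("hog1_dependent", "hog1_independent", "housekeeping",
                                 "down_regulated", "unchanged")},
                "hog1": {c: 0.0 for c in ("hog1_dependent", "hog1_independent",
                                          "housekeeping", "down_regulated", "unchanged")}}
        cfg = small_config(seed=31, n_per_class=20, depth=500_000,
                           eviction=evic, evicted_offsets=(50,))
        genome, genes = build_toy_genome(cfg)
        truth = build_ground_truth(genes, cfg)
        t_track = to_rpm(pileup(simulate_mnase_fragments("wt", "stress", genes, truth, cfg), genome))
        u_track = to_rpm(pileup(simulate_mnase_fragments("wt", "unstressed", genes, truth, cfg), genome))
        dep_genes = [g for g in genes
                     if truth.set_index("gene_id").loc[g.gene_id, "class"] == "hog1_dependent"]
        res = occupancy_percent(t_track, u_track, dep_genes, normalize="none")

        # numerical oracle: expected window coverage share of each nucleosome
        frag, sd = cfg.mnase_fragment_length, cfg.jitter_sd
        from scipy import stats as ss
        window = np.arange(0, 200)

        def expected_window_mass(offset):
            # E[overlap of fragment around offset+jitter with [0, 200)]
            centres = np.arange(offset - 200, offset + 201)
            probs = ss.norm.pdf(centres, loc=offset, scale=sd)
            probs /= ss.norm.pdf(centres, loc=offset, scale=sd).sum()
            mass = 0.0
            for c, p in zip(centres, probs):
                lo, hi = c - frag // 2, c - frag // 2 + frag
                mass += p * max(0, min(hi, 200) - max(lo, 0))
            return mass

        ov = {o: expected_window_mass(o) for o in cfg.nucleosome_offsets}
        total_ov = sum(ov.values())
        f = 0.51
        n_nuc = len(genes) * len(cfg.nucleosome_offsets)
        bg = cfg.mnase_background_fraction
        bg_weight = bg / (1 - bg) * n_nuc
        L = genome.length_of(cfg.chrom_name)
        bg_window_mass = bg_weight * frag * 200 / L
        w_unstressed = bg_weight + n_nuc
        w_stressed = w_unstressed - f * len(dep_genes)  # fixed depth redistributes
        expected_occ = 100.0 * (w_unstressed / w_stressed) * (
            (total_ov - f * ov[50] + bg_window_mass) / (total_ov + bg_window_mass)
        )
        measured = res.per_gene["occupancy_pct"].mean()
        assert abs(measured - expected_occ) <= 5.0

    def test_empty_gene_group_rejected(self):
        track = make_track(np.zeros(100))
        with pytest.raises(ValueError):
            occupancy_percent(track, track, [], normalize="none")


class TestCompareEviction:
    def test_identical_vectors(self):
        t, p = compare_eviction(np.array([10.0, 20.0, 30.0]), np.array([10.0, 20.0, 30.0]))
        assert (t, p) == (0.0, 1.0)

    def test_closed_form_paired_t(self):
        """d = {5,10,15}: t = 10 / (5 / sqrt(3)) = 3.4641 with df = 2."""
        t, p = compare_eviction(np.array([10.0, 20.0, 30.0]), np.array([5.0, 10.0, 15.0]))
        assert t == pytest.approx(3.4641, abs=1e-4)
        import scipy.stats as ss
        assert p == pytest.approx(2 * ss.t.sf(3.4641016, df=2), rel=1e-4)

    def test_needs_three_pairs(self):
        with pytest.raises(ValueError):
            compare_eviction(np.array([1.0, 2.0]), np.array([0.0, 1.0]))

    def test_strong_eviction_difference_is_significant(self):
        rng = np.random.default_rng(3)
        wt = 50.0 + rng.normal(0, 5, size=100)
        ko = 0.0 + rng.normal(0, 5, size=100)
        _, p = compare_eviction(wt, ko)
        assert p < 0.01
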