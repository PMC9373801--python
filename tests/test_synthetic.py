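import numpy as np
import pytest

import multimotif as mm
from multimotif.synthetic import _mixture_consensuses, generating_pfm


class TestMakeGenome:
    def test_pure_at_genome(self):
        g = mm.make_genome(1, 5000, 1.0, seed=1)
        assert set(g.chromosomes["chr1"]) <= {"A", "T"}

    def test_empirical_at_tracks_target(self):
        g = mm.make_genome(1, 1_000_000, 0.6, seed=2)
        assert abs(mm.at_fraction(g.chromosomes["chr1"]) - 0.6) < 0.01

    def test_same_seed_same_genome(self):
        a = mm.make_genome(2, 1000, 0.5, seed=3)
        b = mm.make_genome(2, 1000, 0.5, seed=3)
        assert a.chromosomes == b.chromosomes


class TestSampleSites:
    def test_coupled_pair_has_high_mi(self):
        spec = mm.ImplantSpec(kind="coupled", length=12,
                              coupled_pairs=[(2, 10)], seed=4)
        sites = mm.sample_sites(spec, 1000)
        assert mm.mutual_information(sites, 2, 10) >= 0.9

    def test_pfm_sites_are_pairwise_independent(self):
        ok = 0
        for seed in range(20):
            spec = mm.ImplantSpec(kind="pfm", length=8, seed=seed)
            sites = mm.sample_sites(spec, 1000)
            m = mm.mi_matrix(sites)
            iu = np.triu_indices(8, k=1)
            ok += (m[iu] < 0.05).all()
        assert ok >= 19

    def test_pfm_information_content_near_target(self):
        spec = mm.ImplantSpec(kind="pfm", length=12, ic_target=13.0, seed=6)
        probs = generating_pfm(spec)
        with np.errstate(divide="ignore"):
            h = -np.where(probs > 0, probs * np.log2(probs), 0).sum(axis=1)
        assert (2 - h).sum() == pytest.approx(13.0, abs=1e-6)

    def test_mixture_recoverable_by_partitioning(self):
        spec = mm.ImplantSpec(kind="mixture", length=12, seed=8)
        sites = mm.sample_sites(spec, 600)
        tree = mm.partition_alignment(sites)
        assert not tree.is_leaf

    def test_first_order_adjacent_dependency_present(self):
        spec = mm.ImplantSpec(kind="first_order", length=12, seed=9)
        sites = mm.sample_sites(spec, 2000)
        m = mm.mi_matrix(sites)
        adjacent = [m[j, j + 1] for j in range(0, 11, 2)]
        assert min(adjacent) > 0.2


class TestImplantPeaks:
    def test_zero_rate_gives_empty_truth(self):
        genome = mm.make_genome(1, 100_000, 0.5, seed=10)
        sites = ["ACGTACGTACGT"]
        _, peaks, truth = mm.implant_peaks(genome, sites, 50, 151, 0.0,
                                           seed=10)
        assert truth.empty
        assert len(peaks) == 50

    def test_exact_allocation_count(self):
        genome = mm.make_genome(1, 300_000, 0.5, seed=11)
        sites = mm.sample_sites(mm.ImplantSpec(kind="pfm", seed=11), 400)
        _, peaks, truth = mm.implant_peaks(genome, sites, 100, 151, 0.8,
                                           seed=11)
        assert len(truth) == 80  # floor(0.8 * 100), exact

    def test_truth_bookkeeping_identity(self):
        ds = mm.make_dataset(mm.ImplantSpec(kind="pfm", seed=12),
                             n_peaks=60, seed=12)
        seq_of = {f"peak_{iv.rank}": ds.genome.fetch(iv)
                  for iv in ds.peaks}
        for _, row in ds.truth.iterrows():
            window = seq_of[row.peak_id][row.offset:row.offset + 12]
            if row.strand == "-":
                window = mm.revcomp(window)
            assert window == row.site

    def test_peaks_never_overlap(self):
        ds = mm.make_dataset(mm.ImplantSpec(kind="pfm", seed=13),
                             n_peaks=80, seed=13)
        ivs = sorted(ds.peaks, key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            assert a.end <= b.start

    def test_insufficient_genome_raises(self):
        genome = mm.make_genome(1, 1000, 0.5, seed=14)
        with pytest.raises(ValueError, match="too small"):
            mm.implant_peaks(genome, ["ACGTACGT"], 100, 151, 0.5, seed=14)

    def test_determinism(self):
        a = mm.make_dataset(mm.ImplantSpec(kind="coupled", seed=15),
                            n_peaks=40, seed=15)
        b = mm.make_dataset(mm.ImplantSpec(kind="coupled", seed=15),
                            n_peaks=40, seed=15)
        assert a.genome.chromosomes == b.genome.chromosomes
        assert a.truth.equals(b.truth)


class TestAnnotationFixture:
    def test_flanked_genes_never_collide(self, gene_fixture):
        _, genes, _ = gene_fixture
        ivs = sorted((g.interval for g in genes), key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            assert a.end + 2500 <= b.start - 2500

    def test_designated_term_fe_matches_construction(self, gene_fixture):
        _, genes, ann = gene_fixture
        term_genes = set(ann.loc[ann.term_id == "TERM:0001", "gene_id"])
        all_ids = {g.gene_id for g in genes}
        res = mm.enrich(term_genes, all_ids,
                        {"TERM:0001": term_genes})[0]
        # foreground = exactly the target set: FE = Total/Count by algebra
        assert res.fold_enrichment == pytest.approx(
            len(all_ids) / len(term_genes))

    def test_background_terms_rarely_significant(self, gene_fixture, rng):
        _, genes, ann = gene_fixture
        all_ids = sorted(g.gene_id for g in genes)
        terms = {t: set(g.gene_id for _, g in sub.iterrows())
                 for t, sub in ann.groupby("term_id") if t != "TERM:0001"}
        terms = {t: {r for r in ann.loc[ann.term_id == t, "gene_id"]}
                 for t in terms}
        false_calls = []
        for rep in range(10):
            fg = set(rng.choice(all_ids, size=20, replace=False))
            res = mm.enrich(fg, set(all_ids), terms)
            false_calls.append(np.mean([r.p_adj < 0.05 for r in res]))
        assert float(np.mean(false_calls)) <= 0.05 + 2 * np.sqrt(
            0.05 * 0.95 / (10 * max(len(terms), 1)))

    def test_spacing_infeasible_raises(self):
        genome = mm.make_genome(1, 10_000, 0.5, seed=20)
        with pytest.raises(ValueError, match="too short"):
            mm.make_annotation_fixture(genome, "chr1", 50, 5, "T:1", seed=20)
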