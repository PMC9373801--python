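import math

import numpy as np
import pytest

import multimotif as mm
from multimotif.enrichment import ContingencyTable, read_annotations, results_to_table
from multimotif.seq_core import GeneModel, Interval


def _gene(gid, start, end, chrom="chr1"):
    return GeneModel(gid, Interval(chrom, start, end), "+")


class TestMapToGenes:
    genes = [_gene("g1", 10_000, 12_000), _gene("g2", 30_000, 32_000)]

    def test_hit_inside_flank_is_included(self):
        # flank region is [7500, 14500); one bp inside the boundary
        assert mm.map_to_genes([Interval("chr1", 7500, 7501)],
                               self.genes) == {"g1"}

    def test_hit_at_flank_edge_is_excluded(self):
        # half-open: [14500, x) shares nothing with [7500, 14500)
        assert mm.map_to_genes([Interval("chr1", 14500, 14600)],
                               self.genes) == set()

    def test_matches_brute_force_all_pairs(self, rng):
        genes = [_gene(f"g{i}", 10_000 * i + 5000, 10_000 * i + 7000)
                 for i in range(1, 12)]
        ivs = [Interval("chr1", int(s), int(s) + 50)
               for s in rng.integers(0, 120_000, size=60)]
        got = mm.map_to_genes(ivs, genes)
        expect = set()
        for g in genes:
            lo, hi = g.interval.start - 2500, g.interval.end + 2500
            for iv in ivs:
                if min(hi, iv.end) - max(max(lo, 0), iv.start) >= 1:
                    expect.add(g.gene_id)
        assert got == expect

    def test_set_semantics(self):
        ivs = [Interval("chr1", 10_500, 10_550),
               Interval("chr1", 11_000, 11_050)]
        assert mm.map_to_genes(ivs, self.genes) == {"g1"}


class TestFoldEnrichment:
    def test_table_one_arithmetic(self):
        t = ContingencyTable(30, 100, 300, 3000)
        assert mm.fold_enrichment(t) == pytest.approx(3.0)

    def test_equal_frequencies_give_unity(self):
        t = ContingencyTable(10, 100, 100, 1000)
        assert mm.fold_enrichment(t) == pytest.approx(1.0)

    def test_algebraic_maximum(self):
        # foreground exactly the term's gene set
        t = ContingencyTable(40, 40, 40, 800)
        assert mm.fold_enrichment(t) == pytest.approx(800 / 40)

    def test_zero_denominator_is_undefined(self):
        with pytest.raises(ValueError):
            mm.fold_enrichment(ContingencyTable(0, 0, 5, 10))

    def test_random_foreground_concentrates_near_unity(self, rng):
        all_genes = {f"g{i}" for i in range(1000)}
        term = set(rng.choice(sorted(all_genes), size=200, replace=False))
        fes = []
        for _ in range(30):
            fg = set(rng.choice(sorted(all_genes), size=300, replace=False))
            t = ContingencyTable(len(fg & term), len(fg), len(term),
                                 len(all_genes))
            fes.append(mm.fold_enrichment(t))
        assert abs(float(np.mean(fes)) - 1.0) < 0.1

    def test_inconsistent_table_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(50, 40, 60, 100)


class TestEnrich:
    def test_hypergeometric_tail_matches_combinatorial_oracle(self):
        all_genes = {f"g{i}" for i in range(40)}
        term_genes = {f"g{i}" for i in range(8)}
        fg = {f"g{i}" for i in range(10)}  # contains the whole term
        res = mm.enrich(fg, all_genes, {"T": term_genes})[0]
        # oracle: P[X >= 8] by direct combinatorics
        def C(n, k):
            return math.comb(n, k)
        p = sum(C(8, k) * C(32, 10 - k) for k in range(8, 9)) / C(40, 10)
        assert res.p_raw == pytest.approx(p, rel=1e-12)
        assert res.table.count_obs_plus == 8

    def test_type_one_error_calibration(self, rng):
        all_genes = [f"g{i}" for i in range(400)]
        terms = {f"T{t}": set(rng.choice(all_genes, size=40, replace=False))
                 for t in range(40)}
        rates = []
        for rep in range(15):
            fg = set(rng.choice(all_genes, size=60, replace=False))
            res = mm.enrich(fg, set(all_genes), terms)
            rates.append(np.mean([r.p_raw < 0.05 for r in res]))
        rate = float(np.mean(rates))
        se = np.sqrt(0.05 * 0.95 / (15 * 40))
        assert abs(rate - 0.05) < 2 * se + 0.01

    def test_bh_adjustment_matches_brute_force(self):
        # p-vector (0.01, 0.02, 0.04), m=3 -> (0.03, 0.03, 0.04)
        all_genes = {f"g{i}" for i in range(30)}
        import multimotif.enrichment as enr
        from unittest.mock import patch
        # drive BH through the public path with controlled raw p-values
        with patch.object(enr.hypergeom, "sf",
                          side_effect=[0.01, 0.02, 0.04]):
            res = mm.enrich({"g1"}, all_genes,
                            {"A": {"g1"}, "B": {"g2"}, "C": {"g3"}})
        padj = {r.term_id: r.p_adj for r in res}
        raw = {r.term_id: r.p_raw for r in res}
        order = sorted(raw, key=raw.get)
        expected = dict(zip(order, [0.03, 0.03, 0.04]))
        for t in padj:
            assert padj[t] == pytest.approx(expected[t], rel=1e-12)
        for r in res:
            assert r.p_adj >= r.p_raw

    def test_bh_invariant_to_input_order(self, rng):
        all_genes = {f"g{i}" for i in range(100)}
        terms = {f"T{t}": set(rng.choice(sorted(all_genes), size=10,
                                         replace=False)) for t in range(12)}
        fg = set(rng.choice(sorted(all_genes), size=20, replace=False))
        a = mm.enrich(fg, all_genes, terms)
        b = mm.enrich(fg, all_genes, dict(reversed(list(terms.items()))))
        assert {(r.term_id, r.p_adj) for r in a} == \
        {(r.term_id, r.p_adj) for r in b}

    def test_foreground_must_be_subset(self):
        with pytest.raises(ValueError):
            mm.enrich({"x"}, {"a"}, {"T": {"a"}})


class TestCompareModels:
    def _result(self, term, fe, p_adj):
        t = ContingencyTable(5, 10, 50, 100)
        return mm.EnrichmentResult(term, t, fe, p_adj / 2, p_adj)

    def test_identical_gene_sets_yield_zero_wins(self):
        res = {m: [self._result("T1", 2.0, 0.01)] for m in ("a", "b")}
        df = mm.compare_models_fe(res)
        assert df.attrs["wins"][("a", "b")] == 0
        assert df.attrs["wins"][("b", "a")] == 0

    def test_superset_model_has_higher_fe_and_wins(self):
        res = {"a": [self._result("T1", 2.0, 0.01)],
               "b": [self._result("T1", 3.0, 0.01)]}
        df = mm.compare_models_fe(res)
        assert df.attrs["wins"][("b", "a")] == 1

    def test_only_jointly_significant_terms_survive(self):
        res = {"a": [self._result("T1", 2.0, 0.01),
                     self._result("T2", 2.0, 0.01)],
               "b": [self._result("T1", 2.5, 0.01),
                     self._result("T2", 2.5, 0.2)]}
        df = mm.compare_models_fe(res)
        assert df["term_id"].tolist() == ["T1"]


def test_annotation_reader_roundtrip(tmp_path):
    p = tmp_path / "ann.tsv"
    p.write_text("g1\tT1\ng2\tT1\ng1\tT2\n")
    ann = read_annotations(p)
    assert ann == {"T1": {"g1", "g2"}, "T2": {"g1"}}


def test_results_table_schema():
    t = ContingencyTable(3, 10, 30, 100)
    res = [mm.EnrichmentResult("T", t, 1.0, 0.5, 0.6)]
    df = results_to_table(res)
    assert df.loc[0, "term_id"] == "T"
    assert df.loc[0, "p_adj"] == 0.6
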