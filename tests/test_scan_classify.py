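import numpy as np
import pytest

import multimotif as mm
from multimotif.scan_classify import DEFAULT_ERR_BINS, Hit, hits_to_bed_rows
from multimotif.seq_core import SeqRecord, SequenceSet


def _hit(model, peak, off, err=1e-4, L=10, score=5.0, strand="+"):
    return Hit(model, peak, off, strand, L, score, err)


def _peaks(n=4):
    return SequenceSet([SeqRecord(f"p{i}", "ACGT" * 20) for i in range(n)])


class TestScanPeaks:
    @pytest.fixture(scope="class")
    def scanned(self, trained_pwm, pfm_fg, pfm_dataset, pfm_bg):
        genes_genome = mm.make_genome(1, 2000 + 60 * 8000 + 2000, 0.6, seed=41,
                                      prefix="chrG")
        genes, _ = mm.make_annotation_fixture(genes_genome, "chrG1", 60, 5,
                                              "TERM:0001", seed=42)
        calib = mm.build_calibration_set(genes_genome, genes)
        err_map = mm.compute_err_map(trained_pwm.pwm, calib)
        thresholds = {name: mm.threshold_for_err(err_map, q)
                      for name, q in mm.ERR_LADDER.items()}
        hits = {name: mm.scan_peaks(
            {"pwm": (trained_pwm.pwm, thr, err_map)}, pfm_fg)
            for name, thr in thresholds.items()}
        return trained_pwm.pwm, thresholds, err_map, hits

    def test_hits_pass_threshold_and_fit_inside_peaks(self, scanned, pfm_fg):
        model, thresholds, err_map, hits = scanned
        peak_len = {r.id: len(r.seq) for r in pfm_fg}
        for name, hs in hits.items():
            for h in hs:
                assert h.score >= thresholds[name]
                assert h.offset + h.length <= peak_len[h.peak_id]
                assert h.err == pytest.approx(err_map.err_of(h.score))

    def test_hit_sets_nest_with_loosening_stringency(self, scanned):
        _, _, _, hits = scanned
        key = lambda h: (h.peak_id, h.offset, h.strand)
        s = {name: {key(h) for h in hs} for name, hs in hits.items()}
        assert s["stringent"] <= s["medium"] <= s["mild"]

    def test_scan_equals_brute_force_window_filter(self, scanned, pfm_fg):
        model, thresholds, err_map, hits = scanned
        from multimotif.scanning import scan_sequence
        expect = set()
        for rec in pfm_fg:
            for o, strand, score in scan_sequence(model, rec.seq):
                if score >= thresholds["medium"]:
                    expect.add((rec.id, o, strand))
        got = {(h.peak_id, h.offset, h.strand) for h in hits["medium"]}
        assert got == expect

    def test_threshold_above_max_score_gives_zero_hits(self, trained_pwm,
                                                       pfm_fg):
        too_high = trained_pwm.pwm.max_score() + 1.0
        hits = mm.scan_peaks({"pwm": (trained_pwm.pwm, too_high, None)},
                             pfm_fg)
        assert hits == []


class TestClassification:
    def test_no_hits_puts_all_peaks_in_none(self):
        peaks = _peaks(5)
        cls = mm.classify_peaks([], ["a", "b"], peaks)
        assert cls.category_counts[frozenset()] == 5
        assert cls.covered() == 0

    def test_counts_sum_to_peak_count_and_match_brute_force(self, rng):
        peaks = _peaks(30)
        models = ["a", "b", "c"]
        hits = []
        presence = {}
        for rec in peaks:
            present = frozenset(m for m in models if rng.random() < 0.5)
            presence[rec.id] = present
            hits.extend(_hit(m, rec.id, 0) for m in present)
        cls = mm.classify_peaks(hits, models, peaks)
        assert sum(cls.category_counts.values()) == 30
        brute = {}
        for cat in presence.values():
            brute[cat] = brute.get(cat, 0) + 1
        assert cls.category_counts == brute
        for m in models:
            assert cls.marginal(m) == sum(1 for c in presence.values()
                                          if m in c)
        assert cls.to_table()["count"].sum() == 30

    def test_identical_hit_sets_have_empty_exclusive_categories(self):
        peaks = _peaks(4)
        hits = [_hit(m, p, 3) for m in ("a", "b") for p in ("p0", "p2")]
        cls = mm.classify_peaks(hits, ["a", "b"], peaks)
        assert cls.category_counts.get(frozenset({"a"}), 0) == 0
        assert cls.category_counts.get(frozenset({"b"}), 0) == 0
        assert cls.category_counts[frozenset({"a", "b"})] == 2

    def test_unknown_peak_reference_is_an_error(self):
        with pytest.raises(ValueError, match="unknown peak"):
            mm.classify_peaks([_hit("a", "ghost", 0)], ["a"], _peaks(2))

    def test_union_coverage_bounds_single_model_coverage(self, rng):
        peaks = _peaks(25)
        models = ["a", "b", "c"]
        hits = [
            _hit(m, rec.id, 0)
            for rec in peaks for m in models if rng.random() < 0.3
        ]
        cls = mm.classify_peaks(hits, models, peaks)
        assert cls.covered() >= max(cls.marginal(m) for m in models)


class TestPairwiseOverlap:
    def test_one_bp_overlap_counts(self):
        peaks = _peaks(1)
        df = mm.pairwise_overlap([_hit("a", "p0", 10, L=12)],
                                 [_hit("b", "p0", 15, L=12)], peaks)
        assert df.attrs["n_overlapped"] == 1

    def test_half_open_adjacency_does_not_count(self):
        peaks = _peaks(1)
        df = mm.pairwise_overlap([_hit("a", "p0", 0, L=12)],
                                 [_hit("b", "p0", 12, L=12)], peaks)
        assert df.attrs["n_both"] == 1
        assert df.attrs["n_overlapped"] == 0

    def test_matches_exhaustive_pair_check(self, rng):
        peaks = _peaks(20)
        hits_a = [_hit("a", f"p{i}", int(rng.integers(0, 70)))
                  for i in range(20) if rng.random() < 0.7]
        hits_b = [_hit("b", f"p{i}", int(rng.integers(0, 70)))
                  for i in range(20) if rng.random() < 0.7]
        df = mm.pairwise_overlap(hits_a, hits_b, peaks)
        expect = {}
        for a in hits_a:
            for b in hits_b:
                if a.peak_id == b.peak_id:
                    ov = min(a.end, b.end) - max(a.offset, b.offset) >= 1
                    expect[a.peak_id] = expect.get(a.peak_id, False) or ov
        got = dict(zip(df["peak_id"], df["overlapped"]))
        assert got == expect


class TestScorePairTable:
    def test_total_equals_brute_force_pair_count(self, rng):
        hits_a = [_hit("a", "p0", int(rng.integers(0, 50)),
                       err=float(rng.uniform(2e-5, 9e-4))) for _ in range(15)]
        hits_b = [_hit("b", "p0", int(rng.integers(0, 50)),
                       err=float(rng.uniform(2e-5, 9e-4))) for _ in range(15)]
        table = mm.score_pair_table(hits_a, hits_b)
        n_pairs = sum(
            1 for a in hits_a for b in hits_b
            if min(a.end, b.end) - max(a.offset, b.offset) >= 1
            and DEFAULT_ERR_BINS[0] <= a.err <= DEFAULT_ERR_BINS[-1]
            and DEFAULT_ERR_BINS[0] <= b.err <= DEFAULT_ERR_BINS[-1]
        )
        assert table.sum() == n_pairs

    def test_identical_scorers_fill_the_diagonal(self):
        hits_a = [_hit("a", "p0", i * 3, err=e) for i, e in
                  enumerate([2e-5, 8e-5, 3e-4])]
        hits_b = [Hit("b", h.peak_id, h.offset, h.strand, h.length,
                      h.score, h.err) for h in hits_a]
        table = mm.score_pair_table(hits_a, hits_b)
        # self-pairs land on the diagonal; the off-diagonal mass comes only
        # from distinct overlapping hit pairs
        assert np.trace(table) >= len(hits_a) - 1

    def test_rejects_unsorted_bins(self):
        with pytest.raises(ValueError):
            mm.score_pair_table([], [], err_bins=np.array([1e-3, 1e-4]))


def test_bed_rows_schema():
    rows = hits_to_bed_rows([_hit("a", "p0", 5, L=8)])
    assert list(rows.columns) == ["chrom", "start", "end", "name", "score",
                                  "strand", "err"]
    assert rows.loc[0, "end"] == 13
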