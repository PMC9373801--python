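import numpy as np
import pytest

import multimotif as mm
from multimotif.pwm import (
    PFM,
    _seed_to_pfm,
    background_letter_freqs,
    build_pfm,
    em_refine_zoops,
)
from multimotif.scanning import scan_sequence
from multimotif.seq_core import SeqRecord, SequenceSet


def test_build_pfm_counts_letters():
    pfm = build_pfm(["AC", "AC"])
    assert np.array_equal(pfm.counts, [[2, 0, 0, 0], [0, 2, 0, 0]])
    pfm = build_pfm(["AG", "CG"])
    assert np.array_equal(pfm.counts[0], [1, 1, 0, 0])


def test_build_pfm_is_order_invariant():
    sites = ["ACGT", "TTTT", "ACGG", "CCCC"]
    a = build_pfm(sites)
    b = build_pfm(sites[::-1])
    assert np.array_equal(a.counts, b.counts)


def test_build_pfm_rejects_ragged_or_n():
    with pytest.raises(ValueError):
        build_pfm(["AC", "ACG"])
    with pytest.raises(ValueError):
        build_pfm(["AN", "AC"])


def test_log_odds_sign_matches_frequency_vs_background():
    pfm = build_pfm(["AA", "AC", "AG", "AT"])  # col0 pure A, col1 uniform
    pwm = mm.pfm_to_pwm(pfm, [0.25] * 4)
    assert pwm.weights[0, 0] > 0          # above background
    assert np.allclose(pwm.weights[1], 0)  # at background -> weight 0
    assert pwm.weights[0, 1] < 0          # absent letter below background


def test_pseudocount_vanishes_in_the_limit():
    pfm = build_pfm(["AC", "AC", "AG", "AT"])
    f = pfm.freqs()
    pwm = mm.pfm_to_pwm(pfm, [0.25] * 4, pseudocount_weight=1e-9)
    expect = np.log2(f[0, 0] / 0.25)
    assert pwm.weights[0, 0] == pytest.approx(expect, abs=1e-6)


def test_score_is_sum_of_column_weights():
    pfm = build_pfm(["ACGT", "ACGT", "AAGT"])
    pwm = mm.pfm_to_pwm(pfm, [0.25] * 4)
    w = pwm.weights
    assert pwm.score_window("ACGT") == pytest.approx(
        w[0, 0] + w[1, 1] + w[2, 2] + w[3, 3])
    # swapping one letter moves the score by that column's weight delta only
    delta = pwm.score_window("ACGA") - pwm.score_window("ACGT")
    assert delta == pytest.approx(w[3, 0] - w[3, 3])


def test_scan_counts_and_strand_symmetry(rng):
    pwm = mm.pfm_to_pwm(_seed_to_pfm("ACGTACGTAC"), [0.25] * 4)
    seq = "".join(rng.choice(list("ACGT"), size=109))
    hits = scan_sequence(pwm, seq)
    assert len(hits) == 2 * (109 - 10 + 1)
    # scanning the reverse complement swaps strands and mirrors offsets
    rc_hits = scan_sequence(pwm, mm.revcomp(seq))
    mapped = sorted((len(seq) - 10 - o, "+-"[s == "+"], round(x, 9))
                    for o, s, x in rc_hits)
    assert mapped == sorted((o, s, round(x, 9)) for o, s, x in hits)


def test_scan_equals_naive_rescoring(rng):
    pwm = mm.pfm_to_pwm(_seed_to_pfm("ACGTAC"), [0.25] * 4)
    seq = "".join(rng.choice(list("ACGTN"), size=60, p=[.24, .24, .24, .24, .04]))
    got = {(o, s): x for o, s, x in scan_sequence(pwm, seq)}
    L = 6
    expect = {}
    for o in range(len(seq) - L + 1):
        win = seq[o:o + L]
        if "N" in win:
            continue
        expect[(o, "+")] = pwm.score_window(win)
        expect[(o, "-")] = pwm.score_window(mm.revcomp(win))
    assert got.keys() == expect.keys()
    for k in expect:
        assert got[k] == pytest.approx(expect[k], abs=1e-9)


def test_windows_containing_n_are_excluded():
    pwm = mm.pfm_to_pwm(_seed_to_pfm("ACGT"), [0.25] * 4)
    hits = scan_sequence(pwm, "ACGTNACGT")
    offsets = {o for o, s, _ in hits if s == "+"}
    assert offsets == {0, 5}


class TestZoopsEM:
    def _data(self, gamma=0.8, n=120, seed=3):
        spec = mm.ImplantSpec(kind="pfm", length=8, implant_rate=gamma,
                              seed=seed)
        ds = mm.make_dataset(spec, n_peaks=n, peak_len=80, seed=seed)
        fg = ds.peaks.extract(ds.genome)
        bg = mm.sample_background(ds.genome, ds.peaks,
                                  mm.BackgroundConfig(seed=seed + 1))
        return ds, fg, bg

    def test_loglik_trace_is_monotone(self):
        _, fg, bg = self._data()
        res = em_refine_zoops(_seed_to_pfm("ACGTACGT"), fg, bg, max_iter=25)
        diffs = np.diff(res.loglik_trace)
        assert (diffs >= -1e-6).all()

    def test_generating_pfm_is_near_fixed_point(self):
        ds, fg, bg = self._data()
        from multimotif.synthetic import generating_pfm
        probs = generating_pfm(ds.spec)
        init = PFM(probs * 100, n_sites=100)
        res = em_refine_zoops(init, fg, bg, max_iter=1)
        # one iteration from the truth moves the columns only slightly
        assert np.abs(res.pfm.freqs() - probs).max() < 0.12

    def test_gamma_recovered_near_implant_rate(self):
        _, fg, bg = self._data(gamma=0.8)
        res = em_refine_zoops(_seed_to_pfm("ACGTACGT"), fg, bg, max_iter=60)
        # EM may land on a shifted variant; gamma still tracks site presence
        assert 0.5 <= res.gamma <= 1.0


def test_discovery_duplication_invariance(pfm_fg, pfm_bg):
    doubled = SequenceSet(
        [SeqRecord(r.id, r.seq) for r in pfm_fg]
        + [SeqRecord(r.id + "_copy", r.seq) for r in pfm_fg],
        role="foreground",
    )
    a = mm.discover_pwm(pfm_fg, pfm_bg, 12, seed=5, n_seeds=6, em_max_iter=20)
    b = mm.discover_pwm(doubled, pfm_bg, 12, seed=5, n_seeds=6, em_max_iter=20)
    assert np.allclose(a.pfm.freqs(), b.pfm.freqs(), atol=5e-2)


def test_discovery_recovers_planted_motif(trained_pwm, pfm_dataset):
    from multimotif.experiments import pfm_recovery_correlation
    from multimotif.synthetic import generating_pfm
    r = pfm_recovery_correlation(trained_pwm.pfm,
                                 generating_pfm(pfm_dataset.spec))
    assert r >= 0.9


def test_no_signal_discovery_is_within_permutation_null(rng):
    """Discovery on label-permuted data brackets the no-signal result.

    Foreground and background are drawn from the same process, so the
    discovered motif's discrimination should sit inside the band of
    rediscovery results under random relabellings of the same sequences.
    """
    genome = mm.make_genome(1, 300_000, 0.6, seed=31)
    from multimotif.seq_core import Interval, SeqRecord, SequenceSet, rank_peaks
    from multimotif.scanning import WindowStack, pauc_from_scores
    ivs = [Interval("chr1", i * 600, i * 600 + 150, score=float(100 - i))
           for i in range(60)]
    peaks = rank_peaks(ivs)
    fg = peaks.extract(genome)
    bg = mm.sample_background(genome, peaks,
                              mm.BackgroundConfig(max_per_peak=2, seed=32))

    def discovery_pauc(fg_set, bg_set):
        disc = mm.discover_pwm(fg_set, bg_set, 8, n_seeds=4, em_max_iter=8,
                               n_refine=2)
        return pauc_from_scores(
            WindowStack(fg_set.sequences(), 8).best_per_seq(disc.pwm),
            WindowStack(bg_set.sequences(), 8).all_scores(disc.pwm), 0.05)

    observed = discovery_pauc(fg, bg)
    pool = fg.sequences() + bg.sequences()
    null = []
    for rep in range(9):
        perm = rng.permutation(len(pool))
        f = SequenceSet([SeqRecord(f"f{i}", pool[j])
                         for i, j in enumerate(perm[:len(fg)])])
        b = SequenceSet([SeqRecord(f"b{i}", pool[j])
                         for i, j in enumerate(perm[len(fg):])],
                        role="background")
        null.append(discovery_pauc(f, b))
    assert observed <= max(null) + 1e-12
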