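"""Position frequency/weight matrices and seed + ZOOPS-EM de novo discovery.

The PWM assumes positional independence: a window's score is the sum of
per-position log2-odds of the observed letter against a background letter
distribution.  Discovery enumerates discriminative L-mer seeds from the
foreground, refines each with a zero-or-one-occurrence-per-sequence (ZOOPS)
EM, and keeps the candidate with the best partial AUC against the
background.  Raw scores are model-specific; downstream comparison across
model families goes through ERR calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .seq_core import encode, revcomp
from .scanning import (
    best_window,
    pauc_from_scores,
    valid_windows,
)

logger = logging.getLogger(__name__)

BASES = "ACGT"

#: internal FPR cut used to rank discovery candidates; wider than the
#: reporting cut so that small training sets still resolve an ordering
SELECTION_FPR_MAX = 0.02


@dataclass
class PFM:
    """Position frequency matrix: counts[j, a] over columns A,C,G,T."""

    counts: np.ndarray  # (L, 4) non-negative reals
    n_sites: float

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("PFM counts must be (L, 4)")
        if (self.counts < 0).any():
            raise ValueError("PFM counts must be non-negative")

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    def freqs(self) -> np.ndarray:
        return self.counts / self.counts.sum(axis=1, keepdims=True)

    def information_content(self) -> float:
        """Total IC in bits, Σ_j (2 - H_j), no small-sample correction."""
        f = self.freqs()
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.where(f > 0, f * np.log2(f), 0.0).sum(axis=1)
        return float((2.0 - h).sum())

    def consensus(self) -> str:
        return "".join(BASES[a] for a in self.counts.argmax(axis=1))


def build_pfm(sites: list[str]) -> PFM:
    """Tally aligned, equal-length, N-free sites into a PFM."""
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    L = len(sites[0])
    if any(len(s) != L for s in sites):
        raise ValueError("sites must have equal lengths")
    counts = np.zeros((L, 4))
    for s in sites:
        codes = encode(s)
        if (codes == 4).any():
            raise ValueError(f"site {s!r} contains N")
        for j in range(L):
            counts[j, codes[j]] += 1
    return PFM(counts, n_sites=len(sites))


@dataclass
class PWM:
    """Log2-odds matrix against a background letter distribution."""

    weights: np.ndarray          # (L, 4)
    background_freqs: np.ndarray  # (4,), sums to 1
    model_id: str = "pwm"

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.background_freqs = np.asarray(self.background_freqs, dtype=float)
        if not np.isfinite(self.weights).all():
            raise ValueError("PWM weights must be finite")

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    def score_windows(self, codes: np.ndarray) -> np.ndarray:
        codes = np.atleast_2d(codes)
        return self.weights[np.arange(self.length), codes].sum(axis=1)

    def score_window(self, window: str) -> float:
        codes = encode(window)
        if len(codes) != self.length:
            raise ValueError(
                f"window length {len(codes)} != motif length {self.length}"
            )
        if (codes == 4).any():
            raise ValueError("window contains N")
        return float(self.weights[np.arange(self.length), codes].sum())

    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())

    def to_json(self) -> dict:
        return {
            "kind": "pwm",
            "model_id": self.model_id,
            "weights": self.weights.tolist(),
            "background_freqs": self.background_freqs.tolist(),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "PWM":
        return cls(np.array(obj["weights"]), np.array(obj["background_freqs"]),
                   model_id=obj.get("model_id", "pwm"))


def pfm_to_pwm(pfm: PFM, background_freqs, pseudocount_weight: float = 0.25,
               model_id: str = "pwm") -> PWM:
    """weights[j, a] = log2((f_ja + eps*b_a) / ((1 + eps) * b_a)).

    The additive pseudocount eps*b_a keeps zero-count columns finite; any
    fixed convention is admissible because scores are re-calibrated to ERR.
    """
    b = np.asarray(background_freqs, dtype=float)
    if (b <= 0).any():
        raise ValueError("background frequencies must be positive")
    b = b / b.sum()
    eps = pseudocount_weight
    f = pfm.freqs()
    weights = np.log2((f + eps * b) / ((1.0 + eps) * b))
    return PWM(weights, b, model_id=model_id)


def background_letter_freqs(seqs) -> np.ndarray:
    """Letter frequencies over sequences, N excluded, +1 pseudocount."""
    counts = np.ones(4)
    for s in seqs:
        codes = encode(s)
        counts += np.bincount(codes[codes < 4], minlength=4)
    return counts / counts.sum()


def write_meme_minimal(path, pfms: dict[str, PFM], background_freqs=None):
    """MEME minimal motif format (letter-probability matrices)."""
    bg = (np.full(4, 0.25) if background_freqs is None
          else np.asarray(background_freqs, dtype=float))
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{c} {v:.5f}" for c, v in zip(BASES, bg)) + "\n\n")
        for name, pfm in pfms.items():
            f = pfm.freqs()
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pfm.length} "
                f"nsites= {pfm.n_sites:g} E= 0\n"
            )
            for row in f:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# ZOOPS EM


@dataclass
class EMResult:
    pfm: PFM
    gamma: float
    loglik_trace: list[float]
    converged: bool


def _seq_windows_both(seq: str, L: int):
    """Stacked N-free windows of seq on + and - strands."""
    wf, _ = valid_windows(encode(seq), L)
    wr, _ = valid_windows(encode(revcomp(seq)), L)
    if wf.shape[0] + wr.shape[0] == 0:
        return None
    return np.vstack([w for w in (wf, wr) if w.shape[0]])


def em_refine_zoops(init_pfm: PFM, fg, bg, max_iter: int = 100,
                    tol: float = 1e-4, gamma0: float = 0.5,
                    pseudocount: float = 0.1) -> EMResult:
    """ZOOPS EM refinement of a PFM on foreground sequences.

    Each sequence carries zero or one site, uniformly positioned over its
    N-free windows on both strands; the site-presence prior gamma is
    re-estimated each step.  Background letter probabilities come from
    *bg* and stay fixed, so the observed-data log-likelihood (up to the
    constant background term) is non-decreasing across iterations.
    """
    L = init_pfm.length
    seqs = fg.sequences() if hasattr(fg, "sequences") else list(fg)
    bgseqs = bg.sequences() if hasattr(bg, "sequences") else list(bg)
    b = background_letter_freqs(bgseqs)
    logb = np.log(b)

    windows = []
    for s in seqs:
        if len(s) < L:
            continue
        w = _seq_windows_both(s, L)
        if w is not None:
            windows.append(w)
    if not windows:
        raise ValueError("no foreground sequence is scannable at this length")

    all_win = np.vstack(windows)
    sizes = np.array([w.shape[0] for w in windows])
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    pos_idx = np.arange(L)
    bg_ll = logb[all_win].sum(axis=1)  # per-window background loglik

    theta = init_pfm.freqs()
    theta = (theta + 1e-3) / (theta + 1e-3).sum(axis=1, keepdims=True)
    gamma = gamma0
    seq_of_window = np.repeat(np.arange(len(sizes)), sizes)
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        log_theta = np.log(theta)
        llr = log_theta[pos_idx, all_win].sum(axis=1) - bg_ll
        # per sequence: log P(no site)=log(1-gamma); site at w: log(gamma/W)+llr_w
        lw = np.log(gamma / sizes)[seq_of_window] + llr
        l0 = np.log1p(-gamma)
        m = np.maximum(np.maximum.reduceat(lw, bounds[:-1]), l0)
        expw = np.exp(lw - m[seq_of_window])
        denom = np.exp(l0 - m) + np.add.reduceat(expw, bounds[:-1])
        ll_total = float((m + np.log(denom)).sum())
        z = expw / denom[seq_of_window]
        z_sum_total = float(z.sum())
        new_counts = np.empty((L, 4))
        for j in range(L):
            new_counts[j] = np.bincount(all_win[:, j], weights=z, minlength=4)
        trace.append(ll_total)
        gamma = min(max(z_sum_total / len(sizes), 1e-4), 1 - 1e-4)
        new_theta = new_counts + pseudocount * b
        new_theta /= new_theta.sum(axis=1, keepdims=True)
        delta = np.abs(new_theta - theta).max()
        theta = new_theta
        if delta < tol:
            converged = True
            break
    if not converged:
        # short burn-in runs are not expected to converge; stay quiet there
        log = logger.warning if max_iter > 10 else logger.debug
        log("ZOOPS EM: no convergence in %d iterations", max_iter)
    n_eff = max(z_sum_total, 2.0)
    pfm = PFM(theta * n_eff, n_sites=n_eff)
    return EMResult(pfm, gamma, trace, converged)


# ---------------------------------------------------------------------------
# discovery


def _enumerate_seeds(fg_seqs, bg_seqs, L: int, n_seeds: int = 20,
                     max_fg: int = 100, max_bg: int = 200) -> list[str]:
    """Top N-free L-mers by smoothed fg/bg frequency ratio (both strands).

    Subsampling takes the leading sequences so that exact duplication of
    the input leaves the seed list (and hence the discovery) unchanged.
    """
    def kmer_counts(seqs):
        counts: dict[str, int] = {}
        total = 0
        for s in seqs:
            for strand_seq in (s, revcomp(s)):
                for i in range(len(strand_seq) - L + 1):
                    k = strand_seq[i:i + L]
                    if "N" in k:
                        continue
                    counts[k] = counts.get(k, 0) + 1
                    total += 1
        return counts, max(total, 1)

    fg_sub = list(fg_seqs)[:max_fg]
    bg_sub = list(bg_seqs)[:max_bg]

    fc, ft = kmer_counts(fg_sub)
    bc, bt = kmer_counts(bg_sub)
    scored = sorted(
        ((k, (c / ft + 1e-9) / (bc.get(k, 0) / bt + 1.0 / bt)) for k, c in
         fc.items() if c >= 2),
        key=lambda t: (-t[1], t[0]),
    )
    seeds: list[str] = []
    for k, _ in scored:
        if k in seeds or revcomp(k) in seeds:
            continue
        seeds.append(k)
        if len(seeds) >= n_seeds:
            break
    if not seeds and fc:
        seeds = [max(fc, key=lambda k: (fc[k], k))]
    return seeds


def _seed_to_pfm(seed: str, match_prob: float = 0.7, n: float = 10.0) -> PFM:
    L = len(seed)
    counts = np.full((L, 4), n * (1 - match_prob) / 3)
    codes = encode(seed)
    for j in range(L):
        counts[j, codes[j]] = n * match_prob
    return PFM(counts, n_sites=n)


@dataclass
class PWMDiscovery:
    """Fitted result of PWM discovery: model plus training metadata."""

    pwm: PWM
    pfm: PFM
    gamma: float
    seed_kmers: list[str] = field(default_factory=list)
    selection_pauc: float = 0.0


def discover_pwm(fg, bg, L: int, seed: int = 0, n_seeds: int = 20,
                 em_max_iter: int = 50, n_refine: int = 5) -> PWMDiscovery:
    """Seed + ZOOPS-EM de novo PWM discovery.

    Enumerates discriminative L-mer seeds on a foreground subsample, gives
    every seed a short EM burn-in, fully refines the *n_refine* most
    discriminative candidates, and returns the one with the highest
    partial AUC (peak best-score vs background windows) on the training
    split.  Deterministic given *seed*.
    """
    from .scanning import WindowStack

    fg_seqs = fg.sequences() if hasattr(fg, "sequences") else list(fg)
    bg_seqs = bg.sequences() if hasattr(bg, "sequences") else list(bg)
    if all(len(s) < L for s in fg_seqs):
        raise ValueError(f"no foreground sequence reaches motif length {L}")
    b = background_letter_freqs(bg_seqs)
    fg_stack = WindowStack(fg_seqs, L)
    bg_stack = WindowStack(bg_seqs, L)

    def selection_pauc(model) -> float:
        return pauc_from_scores(fg_stack.best_per_seq(model),
                                bg_stack.all_scores(model),
                                fpr_max=SELECTION_FPR_MAX)

    seeds = _enumerate_seeds(fg_seqs, bg_seqs, L, n_seeds=n_seeds)
    burnin = []
    for kmer in seeds:
        em = em_refine_zoops(_seed_to_pfm(kmer), fg, bg,
                             max_iter=min(5, em_max_iter))
        cand = pfm_to_pwm(em.pfm, b)
        burnin.append((selection_pauc(cand), kmer))
    burnin.sort(key=lambda t: -t[0])

    best = None
    for _, kmer in burnin[:n_refine]:
        em = em_refine_zoops(_seed_to_pfm(kmer), fg, bg, max_iter=em_max_iter)
        cand = pfm_to_pwm(em.pfm, b)
        p = selection_pauc(cand)
        if best is None or p > best.selection_pauc:
            best = PWMDiscovery(cand, em.pfm, em.gamma, seeds, p)
    assert best is not None
    best.pwm.model_id = f"pwm_L{L}"
    return best


def extract_site_alignment(model, seqs) -> list[str]:
    """Best window (motif-strand orientation) per scannable sequence."""
    sites = []
    for s in seqs:
        if len(s) < model.length:
            continue
        hit = best_window(model, s)
        if hit is not None:
            sites.append(hit[3])
    return sites
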