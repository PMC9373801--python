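"""Inhomogeneous Markov motif model of order k with lower-order interpolation.

The model extends the PWM with dependencies between nearby positions: the
letter at motif position j is conditioned on the preceding min(j, k)
letters.  Conditional tables are estimated with recursive interpolation
toward the lower order,

    P_j(a | c) = (n_j(c, a) + alpha * P_j^(m-1)(a | c')) / (n_j(c) + alpha),

down to order 0 (plain column frequencies with an additive pseudocount of
1), where c' drops the oldest letter of context c.  Windows are scored as a
log2 likelihood ratio against a homogeneous background Markov chain trained
on the background sequence set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .seq_core import encode
from .pwm import discover_pwm, extract_site_alignment

logger = logging.getLogger(__name__)


def _context_index(codes: np.ndarray, j: int, m: int) -> np.ndarray:
    """Index of the length-m context preceding position j; oldest letter is
    the highest base-4 digit, so dropping it is a modulo."""
    idx = np.zeros(codes.shape[0], dtype=np.intp)
    for t in range(1, m + 1):
        idx += codes[:, j - t].astype(np.intp) * (4 ** (t - 1))
    return idx


def _sites_to_codes(sites: list[str]) -> np.ndarray:
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    L = len(sites[0])
    if any(len(s) != L for s in sites):
        raise ValueError("sites must have equal lengths")
    codes = np.vstack([encode(s) for s in sites])
    if (codes == 4).any():
        raise ValueError("sites must be N-free")
    return codes


@dataclass
class MarkovMotif:
    """Position-specific conditional tables; tables[j] has shape (4^m_j, 4)
    with m_j = min(j, order)."""

    length: int
    order: int
    tables: list[np.ndarray]
    alpha: float = 20.0
    model_id: str = "markov"

    def __post_init__(self):
        for j, t in enumerate(self.tables):
            if not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"conditional table at position {j} not normalized")
            if (t <= 0).any():
                raise ValueError(f"zero probability in table {j}")
        self._log_tables = [np.log2(t) for t in self.tables]

    def log2_prob_windows(self, codes: np.ndarray) -> np.ndarray:
        codes = np.atleast_2d(codes)
        scores = np.zeros(codes.shape[0])
        for j in range(self.length):
            m = min(j, self.order)
            idx = _context_index(codes, j, m)
            scores += self._log_tables[j][idx, codes[:, j]]
        return scores

    def to_json(self) -> dict:
        return {
            "kind": "markov",
            "model_id": self.model_id,
            "length": self.length,
            "order": self.order,
            "alpha": self.alpha,
            "tables": [t.tolist() for t in self.tables],
        }

    @classmethod
    def from_json(cls, obj: dict) -> "MarkovMotif":
        return cls(obj["length"], obj["order"],
                   [np.array(t) for t in obj["tables"]],
                   alpha=obj.get("alpha", 20.0),
                   model_id=obj.get("model_id", "markov"))


@dataclass
class BackgroundMarkov:
    """Homogeneous background chain of order k_bg with +1 pseudocounts;
    positions before index k_bg use the lower-order homogeneous tables."""

    order: int
    tables: list[np.ndarray]  # tables[m] shape (4^m, 4), m = 0..order

    @classmethod
    def train(cls, seqs, order: int = 2) -> "BackgroundMarkov":
        counts = [np.ones((4 ** m, 4)) for m in range(order + 1)]
        for s in seqs:
            codes = encode(s)
            ok = codes < 4
            for m in range(order + 1):
                if len(codes) <= m:
                    continue
                ctx = np.zeros(len(codes) - m, dtype=np.intp)
                valid = ok[m:].copy()
                for t in range(1, m + 1):
                    ctx += codes[m - t:len(codes) - t].astype(np.intp) * (4 ** (t - 1))
                    valid &= ok[m - t:len(codes) - t]
                tgt = codes[m:]
                flat = ctx[valid] * 4 + tgt[valid]
                counts[m] += np.bincount(flat, minlength=4 ** m * 4).reshape(
                    4 ** m, 4)
        tables = [c / c.sum(axis=1, keepdims=True) for c in counts]
        return cls(order, tables)

    def log2_prob_windows(self, codes: np.ndarray) -> np.ndarray:
        codes = np.atleast_2d(codes)
        scores = np.zeros(codes.shape[0])
        log_tables = [np.log2(t) for t in self.tables]
        for j in range(codes.shape[1]):
            m = min(j, self.order)
            idx = _context_index(codes, j, m)
            scores += log_tables[m][idx, codes[:, j]]
        return scores


def train_markov(sites: list[str], k: int, alpha: float = 20.0) -> MarkovMotif:
    """Interpolated order-k tables from aligned N-free sites (see module
    docstring for the recursion)."""
    codes = _sites_to_codes(sites)
    L = codes.shape[1]
    # order 0: plain column frequencies, +1 pseudocount
    per_order: list[list[np.ndarray]] = []
    order0 = []
    for j in range(L):
        c = np.bincount(codes[:, j], minlength=4).astype(float) + 1.0
        order0.append((c / c.sum()).reshape(1, 4))
    per_order.append(order0)
    for m in range(1, k + 1):
        tier = []
        for j in range(L):
            mj = min(j, m)
            if mj < m:
                tier.append(per_order[m - 1][j])
                continue
            idx = _context_index(codes, j, m)
            n_ca = np.zeros((4 ** m, 4))
            np.add.at(n_ca, (idx, codes[:, j]), 1.0)
            n_c = n_ca.sum(axis=1, keepdims=True)
            lower = per_order[m - 1][j]  # (4^(m-1), 4)
            # context idx -> suffix idx by dropping the oldest (highest) digit
            suffix = np.arange(4 ** m) % (4 ** (m - 1))
            p = (n_ca + alpha * lower[suffix]) / (n_c + alpha)
            tier.append(p)
        per_order.append(tier)
    tables = [per_order[min(j, k)][j] for j in range(L)]
    return MarkovMotif(L, k, tables, alpha=alpha)


@dataclass
class MarkovScorer:
    """Bundles motif + background into the shared window-scoring contract."""

    motif: MarkovMotif
    background: BackgroundMarkov
    model_id: str = "markov"

    @property
    def length(self) -> int:
        return self.motif.length

    def score_windows(self, codes: np.ndarray) -> np.ndarray:
        return (self.motif.log2_prob_windows(codes)
                - self.background.log2_prob_windows(codes))

    def score_window(self, window: str) -> float:
        codes = encode(window)
        if len(codes) != self.length or (codes == 4).any():
            raise ValueError("window must be N-free and of motif length")
        return float(self.score_windows(codes[None, :])[0])

    def to_json(self) -> dict:
        return {
            "kind": "markov_scorer",
            "model_id": self.model_id,
            "motif": self.motif.to_json(),
            "background_order": self.background.order,
            "background_tables": [t.tolist() for t in self.background.tables],
        }

    @classmethod
    def from_json(cls, obj: dict) -> "MarkovScorer":
        bgm = BackgroundMarkov(obj["background_order"],
                               [np.array(t) for t in obj["background_tables"]])
        return cls(MarkovMotif.from_json(obj["motif"]), bgm,
                   model_id=obj.get("model_id", "markov"))


def score_window_markov(motif: MarkovMotif, background: BackgroundMarkov,
                        window: str) -> float:
    return MarkovScorer(motif, background).score_window(window)


@dataclass
class MarkovDiscovery:
    scorer: MarkovScorer
    sites: list[str] = field(default_factory=list)
    n_iterations: int = 0
    stabilized: bool = False


def discover_markov(fg, bg, L: int, k: int, seed: int = 0,
                    alpha: float = 20.0, max_rounds: int = 20,
                    bg_order: int = 2, pwm_init=None) -> MarkovDiscovery:
    """Order-k Markov discovery initialized from the PWM site alignment.

    Alternates (retrain tables at order k on the current site set) with
    (rescan the foreground for each peak's best window) until the site set
    is stable or *max_rounds* rounds elapse.  *pwm_init* can supply an
    already-fitted PWM discovery to share the seed alignment across model
    families.
    """
    fg_seqs = fg.sequences() if hasattr(fg, "sequences") else list(fg)
    bg_seqs = bg.sequences() if hasattr(bg, "sequences") else list(bg)
    if pwm_init is None:
        pwm_init = discover_pwm(fg, bg, L, seed=seed)
    sites = extract_site_alignment(pwm_init.pwm, fg_seqs)
    background = BackgroundMarkov.train(bg_seqs, order=bg_order)

    stabilized = False
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        motif = train_markov(sites, k, alpha=alpha)
        scorer = MarkovScorer(motif, background, model_id=f"markov_L{L}_k{k}")
        new_sites = extract_site_alignment(scorer, fg_seqs)
        if new_sites == sites:
            stabilized = True
            sites = new_sites
            break
        sites = new_sites
    motif = train_markov(sites, k, alpha=alpha)
    scorer = MarkovScorer(motif, background, model_id=f"markov_L{L}_k{k}")
    if not stabilized:
        logger.warning("markov discovery: site set not stable after %d rounds",
                       max_rounds)
    return MarkovDiscovery(scorer, sites, rounds, stabilized)
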