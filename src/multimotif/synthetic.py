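"""Synthetic genomes, peaks with implanted motifs, genes and term
annotations: the download-free test bed.

The generator emulates ChIP-seq peak sets from an AT-rich plant genome:
an i.i.d. background genome (default A+T fraction 0.6), a ranked peak set
in which a fixed fraction of peaks carries exactly one implanted site, and
gene models tiled far enough apart that promoter flanks never collide.
Four site classes control the dependency structure a model family can or
cannot exploit:

``pfm``
    independent columns at a target total information content;
``first_order``
    adjacent-position dependencies: odd positions copy a permuted version
    of their left neighbour with high probability, so marginal column
    frequencies stay weak while the adjacent joint is strong;
``coupled``
    one or more distal position pairs jointly switch between two letter
    pairs (1 bit of pure pairwise MI per pair, weak independent core
    otherwise);
``mixture``
    an equal mixture of two sharp sub-consensuses differing at a few
    linked positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .seq_core import (
    Genome,
    GeneModel,
    Interval,
    PeakSet,
    rank_peaks,
    revcomp,
)

BASES = "ACGT"

#: default study conditions for the desk-scale fixture
DEFAULT_N_PEAKS = 500
DEFAULT_PEAK_LEN = 201
DEFAULT_IMPLANT_RATE = 0.8
DEFAULT_AT = 0.6
DEFAULT_IC_STRONG = 13.0   # bits, high-information independent motif
DEFAULT_IC_WEAK_CORE = 6.0  # bits, handicapped core for dependency classes


def make_genome(n_chrom: int, length: int, at_fraction: float,
                seed: int = 0, prefix: str = "chr") -> Genome:
    """i.i.d. genome with P(A)=P(T)=at/2 and P(C)=P(G)=(1-at)/2."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not (0 < at_fraction <= 1):
        raise ValueError("at_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([at_fraction / 2, (1 - at_fraction) / 2,
                  (1 - at_fraction) / 2, at_fraction / 2])
    chroms = {}
    for i in range(n_chrom):
        codes = rng.choice(4, size=length, p=p)
        chroms[f"{prefix}{i + 1}"] = "".join(BASES[c] for c in codes)
    return Genome(chroms)


def _column_prob_for_ic(ic_bits: float) -> float:
    """Consensus probability c whose column IC (2 - H) equals ic_bits."""
    ic_bits = min(max(ic_bits, 1e-6), 2.0 - 1e-9)

    def f(c):
        h = -c * np.log2(c) - (1 - c) * np.log2((1 - c) / 3)
        return (2.0 - h) - ic_bits

    return brentq(f, 0.25 + 1e-9, 1 - 1e-12)


@dataclass
class ImplantSpec:
    """Recipe for one implanted motif class."""

    kind: str = "pfm"            # pfm | first_order | coupled | mixture
    length: int = 12
    implant_rate: float = DEFAULT_IMPLANT_RATE
    ic_target: float = DEFAULT_IC_STRONG
    coupled_pairs: list[tuple[int, int]] = field(default_factory=lambda: [(2, 10)])
    seed: int = 0

    def __post_init__(self):
        if self.kind not in {"pfm", "first_order", "coupled", "mixture"}:
            raise ValueError(f"unknown motif kind {self.kind!r}")
        if not (0 <= self.implant_rate <= 1):
            raise ValueError("implant_rate must be in [0, 1]")
        if self.kind == "coupled":
            for p, q in self.coupled_pairs:
                if not (0 <= p < q < self.length):
                    raise ValueError("coupled pair outside motif")


def generating_pfm(spec: ImplantSpec) -> np.ndarray:
    """(L, 4) column distributions of the independent part of the motif.

    For ``pfm`` this is the full generating model (total IC = ic_target);
    for ``coupled`` it covers the non-coupled core positions at
    DEFAULT_IC_WEAK_CORE total bits (coupled columns are returned as their
    uniform-over-two-letters marginals).
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    probs = np.full((L, 4), 0.25)
    if spec.kind == "pfm":
        c = _column_prob_for_ic(spec.ic_target / L)
        for j in range(L):
            cons = rng.integers(0, 4)
            probs[j] = (1 - c) / 3
            probs[j, cons] = c
    elif spec.kind == "coupled":
        coupled_pos = {p for pair in spec.coupled_pairs for p in pair}
        core = [j for j in range(L) if j not in coupled_pos]
        ic = min(spec.ic_target, DEFAULT_IC_WEAK_CORE)
        c = _column_prob_for_ic(ic / max(len(core), 1))
        for j in core:
            cons = rng.integers(0, 4)
            probs[j] = (1 - c) / 3
            probs[j, cons] = c
        for p, q in spec.coupled_pairs:
            probs[p] = [0.5, 0.5, 0.0, 0.0]  # A or C
            probs[q] = [0.0, 0.0, 0.5, 0.5]  # G or T (jointly with p)
    else:
        raise ValueError(f"generating_pfm undefined for kind {spec.kind!r}")
    return probs


def _first_order_tables(spec: ImplantSpec, copy_prob: float = 0.9):
    """Anchor columns on even positions, permutation-copy chain on odd."""
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    c_anchor = _column_prob_for_ic(DEFAULT_IC_WEAK_CORE / (L / 2))
    anchors = {}
    perms = {}
    for j in range(L):
        if j % 2 == 0:
            anchors[j] = int(rng.integers(0, 4))
        else:
            perms[j] = rng.permutation(4)
    return c_anchor, anchors, perms, copy_prob


def _mixture_consensuses(spec: ImplantSpec, n_diff: int = 3):
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    x = rng.integers(0, 4, size=L)
    y = x.copy()
    diff_pos = rng.choice(L, size=n_diff, replace=False)
    for j in diff_pos:
        y[j] = (x[j] + 1 + rng.integers(0, 3)) % 4
    return x, y, sorted(int(j) for j in diff_pos)


def sample_sites(spec: ImplantSpec, n: int,
                 rng: np.random.Generator | None = None) -> list[str]:
    """Draw n sites of the spec's dependency class (motif strand)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    L = spec.length
    sites = np.empty((n, L), dtype=np.intp)
    if spec.kind in ("pfm", "coupled"):
        probs = generating_pfm(spec)
        for j in range(L):
            p = probs[j]
            if p.sum() == 0:
                continue
            sites[:, j] = rng.choice(4, size=n, p=p / p.sum())
        if spec.kind == "coupled":
            for p_pos, q_pos in spec.coupled_pairs:
                state = rng.random(n) < 0.5
                sites[state, p_pos] = 0   # A
                sites[state, q_pos] = 2   # G
                sites[~state, p_pos] = 1  # C
                sites[~state, q_pos] = 3  # T
    elif spec.kind == "first_order":
        c_anchor, anchors, perms, copy_prob = _first_order_tables(spec)
        for j in range(L):
            if j % 2 == 0:
                cons = anchors[j]
                p = np.full(4, (1 - c_anchor) / 3)
                p[cons] = c_anchor
                sites[:, j] = rng.choice(4, size=n, p=p)
            else:
                perm = perms[j]
                copied = perm[sites[:, j - 1]]
                rand = rng.integers(0, 4, size=n)
                take = rng.random(n) < copy_prob
                sites[:, j] = np.where(take, copied, rand)
    elif spec.kind == "mixture":
        x, y, _ = _mixture_consensuses(spec)
        c = 0.85
        which = rng.random(n) < 0.5
        for j in range(L):
            px = np.full(4, (1 - c) / 3); px[x[j]] = c
            py = np.full(4, (1 - c) / 3); py[y[j]] = c
            col = np.where(which, rng.choice(4, size=n, p=px),
                           rng.choice(4, size=n, p=py))
            sites[:, j] = col
    return ["".join(BASES[c] for c in row) for row in sites]


def implant_peaks(genome: Genome, sites: list[str], n_peaks: int,
                  peak_len: int, implant_rate: float, seed: int = 0,
                  min_gap: int = 50) -> tuple[Genome, PeakSet, pd.DataFrame]:
    """Place non-overlapping peaks and implant sites into an exact-count
    random subset of them.

    Exactly floor(implant_rate * n_peaks) peaks receive one site at a
    uniform offset on a uniform strand.  Returns the modified genome, the
    ranked peak set (scores descending in placement order) and a truth
    table with one row per implant (peak_id, offset, strand, site).
    """
    if not sites:
        raise ValueError("need at least one site to implant")
    L = len(sites[0])
    if peak_len <= L:
        raise ValueError("peak_len must exceed motif length")
    rng = np.random.default_rng(seed)

    # enumerate non-overlapping slots across chromosomes
    slots: list[tuple[str, int]] = []
    stride = peak_len + min_gap
    for chrom, seq in genome.chromosomes.items():
        for start in range(0, len(seq) - peak_len + 1, stride):
            slots.append((chrom, start))
    if len(slots) < n_peaks:
        raise ValueError(
            f"genome too small: {len(slots)} slots for {n_peaks} peaks")
    chosen = rng.choice(len(slots), size=n_peaks, replace=False)
    chosen = sorted(int(i) for i in chosen)
    placements = [slots[i] for i in chosen]
    order = rng.permutation(n_peaks)  # score order independent of position

    n_implant = int(np.floor(implant_rate * n_peaks))
    implant_ix = set(int(i) for i in
                     rng.choice(n_peaks, size=n_implant, replace=False))

    chrom_arrays = {c: bytearray(s.encode()) for c, s in
                    genome.chromosomes.items()}
    intervals = []
    truth_rows = []
    site_cursor = 0
    for k in range(n_peaks):
        chrom, start = placements[k]
        score = float(n_peaks - order[k])
        iv = Interval(chrom, start, start + peak_len, score=score)
        intervals.append(iv)
        if k in implant_ix:
            site = sites[site_cursor % len(sites)]
            site_cursor += 1
            off = int(rng.integers(0, peak_len - L + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            written = site if strand == "+" else revcomp(site)
            chrom_arrays[chrom][start + off:start + off + L] = written.encode()
            truth_rows.append({"chrom": chrom, "peak_start": start,
                               "offset": off, "strand": strand, "site": site})
    new_genome = Genome({c: bytes(a).decode() for c, a in chrom_arrays.items()})
    peaks = rank_peaks(intervals)
    # attach peak ids to truth rows via coordinates
    rank_of = {(iv.chrom, iv.start): iv.rank for iv in peaks}
    for row in truth_rows:
        row["peak_id"] = f"peak_{rank_of[(row['chrom'], row['peak_start'])]}"
    truth = pd.DataFrame(truth_rows,
                         columns=["peak_id", "chrom", "peak_start", "offset",
                                  "strand", "site"])
    return new_genome, peaks, truth


def make_annotation_fixture(genome: Genome, chrom: str, n_genes: int,
                            n_terms: int, enriched_term: str,
                            target_genes: list[str] | None = None,
                            n_targets: int = 30, seed: int = 0,
                            gene_len: int = 2000, spacing: int = 6000,
                            background_rate: float = 0.05
                            ) -> tuple[list[GeneModel], pd.DataFrame]:
    """Tile genes along *chrom* and build a term-annotation table.

    Genes are separated by a >= 6,000 bp gap so that +-2,500 bp flanks
    never collide.  The designated term annotates the target genes only;
    every other term annotates each gene independently at
    ``background_rate``.
    """
    rng = np.random.default_rng(seed)
    clen = genome.length(chrom)
    # leave room for a 1.5 kb upstream region before the first gene
    first = 2000
    stride = gene_len + spacing
    need = first + n_genes * stride
    if need > clen:
        raise ValueError(f"chromosome {chrom} too short: need {need} bp")
    genes = []
    for i in range(n_genes):
        start = first + i * stride
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"gene_{i + 1:04d}",
                               Interval(chrom, start, start + gene_len),
                               strand))
    gene_ids = [g.gene_id for g in genes]
    if target_genes is None:
        idx = rng.choice(n_genes, size=n_targets, replace=False)
        target_genes = [gene_ids[i] for i in sorted(idx)]
    rows = [{"gene_id": g, "term_id": enriched_term} for g in target_genes]
    for t in range(n_terms):
        term = f"TERM:{t + 1:04d}"
        if term == enriched_term:
            continue
        for g in gene_ids:
            if rng.random() < background_rate:
                rows.append({"gene_id": g, "term_id": term})
    annotations = pd.DataFrame(rows, columns=["gene_id", "term_id"])
    return genes, annotations


@dataclass
class SyntheticDataset:
    """Bundle produced by :func:`make_dataset`."""

    genome: Genome
    peaks: PeakSet
    truth: pd.DataFrame
    spec: ImplantSpec
    sites: list[str]


def make_dataset(spec: ImplantSpec, n_peaks: int = DEFAULT_N_PEAKS,
                 peak_len: int = DEFAULT_PEAK_LEN,
                 genome_len: int | None = None,
                 at_fraction: float = DEFAULT_AT,
                 seed: int = 0) -> SyntheticDataset:
    """Genome + ranked peak set with implanted sites, ready for discovery."""
    if genome_len is None:
        genome_len = max(4 * n_peaks * (peak_len + 50), 200_000)
    genome = make_genome(1, genome_len, at_fraction, seed=seed)
    n_implant = int(np.floor(spec.implant_rate * n_peaks))
    sites = sample_sites(spec, max(n_implant, 1),
                         rng=np.random.default_rng(seed + 7))
    genome, peaks, truth = implant_peaks(
        genome, sites, n_peaks, peak_len, spec.implant_rate, seed=seed + 13)
    return SyntheticDataset(genome, peaks, truth, spec, sites)
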