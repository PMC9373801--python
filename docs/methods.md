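# Methods

## Scope and model families

`multimotif` discovers transcription-factor binding-site (TFBS) motifs in
ranked ChIP-seq-like peak sets under three methodologically distinct model
families and makes their predictions directly comparable:

1. **PWM** — the classical position weight matrix: a window of length L is
   scored as the sum over positions of log2 odds of the observed letter
   against a background letter distribution.  Positions are assumed
   independent.
2. **Markov motif of order k** — position-specific conditional
   distributions P_j(a | preceding min(j, k) letters), interpolated toward
   lower orders; captures dependencies between nearby motif positions.
3. **LPD discriminant (SiteGA-style)** — a ridge-regularized Fisher linear
   discriminant over N features, each the frequency of one dinucleotide
   type inside a sub-window of the motif (a locally positioned
   dinucleotide, LPD); the feature set is selected by a genetic algorithm.

All three expose one scoring contract (`length`, `score_windows`), so
threshold calibration, evaluation, scanning, classification, dependency
analysis and enrichment are model-agnostic.

## Background sequence sampling

For each peak, candidate intervals of identical length are drawn uniformly
from the genome (chromosome chosen proportional to length).  A candidate
is accepted when its A+T fraction is within 0.01 of the peak's and it
shares zero bp with any foreground peak; at most 5 accepted draws per peak
(10 for the LPD model) within 500 attempts.  Duplicate background
intervals are rejected; overlap between distinct background draws is
allowed.  A+T matching is per paired peak, the stricter reading of
composition matching, and windows containing N never enter scanning or
calibration counts (ambiguity handling is our choice; exclusion avoids
assigning arbitrary scores).

## Discovery

**PWM.** All L-mers of the leading 100 foreground sequences (both strands)
are ranked by smoothed foreground/background frequency ratio; the top 20
seeds get a 5-iteration ZOOPS EM burn-in, the 5 most discriminative are
refined to convergence (tolerance 1e-4 on the maximum column-probability
change, cap 50 iterations), and the candidate with the best partial AUC
(peak best-score vs background windows, internal selection cut FPR <=
0.02) wins.  The ZOOPS model: each sequence carries zero or one site,
uniformly positioned over its N-free windows on both strands, site-presence
prior gamma re-estimated each step; the background letter model is fixed,
so the observed-data log-likelihood is non-decreasing.  Subsampling takes
leading sequences rather than random ones so that exact duplication of the
input provably leaves the discovery unchanged.

**Markov.** Initialized from the PWM's best-window-per-peak alignment;
conditional tables of order k are estimated with recursive interpolation

    P_j(a | c) = (n_j(c, a) + alpha * P_j^(m-1)(a | c')) / (n_j(c) + alpha)

down to order 0 (column frequencies, +1 pseudocount), alpha = 20 fixed for
robustness at small site counts.  The model alternately retrains and
rescans for best windows until the site set is stable (cap 20 rounds).
Windows are scored as log2 likelihood ratios against a homogeneous
order-2 Markov background trained on the background sequence set, which
keeps the mean background window score near zero.

**LPD discriminant.** The candidate pool contains every (dinucleotide,
sub-window) combination, 16·L(L−1)/2 features.  GA individuals are N-LPD
subsets (N in {40, 60, 80, 100}); fitness is two-fold cross-validated
partial AUC of the fitted discriminant on a 50/50 split of training
windows (internal cut FPR <= 0.05 — window-level background sets are small,
so a wider cut than the reporting one keeps the fitness resolved);
selection is tournament of size 3, crossover uniform, mutation replaces
one LPD, elitism keeps the best 2, so the best-fitness trace is
non-decreasing.  The discriminant solves (S_w + 1e-3·I) w = mu_fg − mu_bg
on the pooled within-class covariance, escalating the ridge tenfold (up to
1.0) if singular.  Because the Fisher solution for any feature subset
needs only class means and a submatrix of the full-pool scatter, scatter
matrices are precomputed once per GA run — this is an exact algebraic
shortcut, not an approximation.

## Calibration to expected recognition rates (ERR)

Raw scores are mapped to empirical tail frequencies over every N-free
window (both strands) of a calibration set of strand-oriented 1,500 bp
regions immediately upstream of protein-coding gene starts; regions
clipped at chromosome edges are discarded, and no masking is applied.
ERR(s) = #(windows scoring >= s) / #windows, counted per window.  The
stringent / medium / mild thresholds are the smallest scores with ERR <=
1e-4 / 2.5e-4 / 5e-4.  A target below 1/#windows is refused with advice to
enlarge the calibration set.

## Evaluation

Peaks are split into odd and even ranks (rank = descending peak-caller
score, coordinate tie-break), each fold serving once for training and once
for testing; no resampling is involved.  TPR is the fraction of test peaks
whose best window score (both strands) passes the threshold; FPR is the
per-window frequency over all background windows.  Model quality is the
standard partial area under the ROC curve for FPR in [0, 1e-3]
(trapezoidal, linearly interpolated at the cut; maximum 1e-3), the regime
where genome-wide thresholds operate.  Grid selection (motif length in
{8, 12, 16, 20}; Markov order in {1, 2, 3}; LPD count in {40, 60, 80,
100}) maximizes the mean pAUC over the two folds.

## Dependency analysis

Pairwise dependencies between positions of a predicted-site alignment are
quantified by plug-in mutual information in bits (no bias correction).
A pair is "dependent" when MI > 0.05 bits — the threshold is applied to
raw MI.  The dependency-logo-style partitioner recursively selects the
position with the largest total MI to all others (leftmost on ties),
splits the alignment by its nucleotide, and stops at max depth 3, subsets
smaller than 20, or maximal pairwise MI <= 0.05.  Sequence-logo data are
IC_j = 2 − H_j without small-sample correction.

## Gene mapping and enrichment

An interval selects a gene when it intersects the gene body extended by
2,500 bp on each side by at least 1 bp (clipped at zero).  Per term the
2×2 counts (term-positive foreground genes, foreground genes,
term-positive genes, all genes) give fold enrichment = (k/n)/(K/N), a
one-sided hypergeometric p-value, and Benjamini–Hochberg adjusted p
across the tested terms; significance is p_adj < 0.05.  Annotations come
from a generic 2-column TSV; no ontology-graph propagation is performed,
and the default universe is all supplied genes.

## Synthetic data generator

The generator emulates ChIP-seq peaks from an AT-rich plant genome: an
i.i.d. background genome at A+T = 0.6, non-overlapping 201 bp peaks, and
exactly floor(0.8·n) peaks carrying one implanted site at a uniform
offset and strand (exact-count implantation removes binomial noise from
recovery tests).  Site classes:

- **pfm** — independent columns, total information content 13 bits by
  default (a well-conserved motif);
- **first_order** — anchor columns on even positions (6 bits total) and a
  permutation-copy dependence on odd positions with copy probability 0.9,
  yielding ≈11 bits of marginal IC plus ≈4 bits of adjacent
  mutual information at L = 12 (a dependency-compensated weak consensus);
- **coupled** — one distal position pair jointly switching between two
  letter pairs (exactly 1 bit of pairwise MI), weak independent core of
  6 bits (a deliberately PWM-handicapped motif);
- **mixture** — an equal mixture of two sharp sub-consensuses differing
  at 3 linked positions.

Gene models are tiled with a ≥6,000 bp inter-gene gap so ±2,500 bp flanks
never collide; one designated term annotates a target gene set, all other
terms annotate genes at a 5% background rate.

What the generator does **not** emulate: composition heterogeneity
(isochores, repeats), peak-length variation, multiple sites per peak,
position preference of sites within peaks, and ontology structure among
terms.  Passing tests therefore demonstrate correctness of the machinery
and the qualitative model-family ordering under controlled dependency
structure — not performance on real chromatin data.

## Validation experiments and their problem sizes

- PWM recovery: 10 seeded replicates of 500 peaks; the discovered PFM
  must correlate with the generating columns at mean Pearson r >= 0.9 (up
  to reverse complement and ±1 bp shift) in >= 8/10.
- Paired family comparisons: 500 peaks per seed, both CV folds trained
  and tested with roles exchanged and the fold pAUCs averaged — the
  averaging uses the evaluation design itself to halve the seed-level
  noise that would otherwise mask the ~10% family effects.  Sign tests
  are one-sided binomial over seeds.  The GA runs with the reduced budget
  (population 30, 60 generations, 2 discovery rounds).
- Calibration guarantee: realized rate <= target on the calibration set
  (exact by construction) and within 3 binomial SE of the target on a
  fresh same-process genome.

## Known limitations

- The LPD discriminant is linear in adjacent-dinucleotide features.
  Every such feature is a sum of adjacent-pair indicators, so the score
  carries no information about a joint distribution of two *distant*
  positions beyond its marginals.  On synthetic data whose only
  dependency is one distal coupled pair, the discriminant therefore does
  not outperform the PWM; its advantage is real only where dependencies
  have an adjacent footprint (where its features can express the joint),
  and even there the GA budget recovers only part of what the
  order-k Markov model extracts from the same alignments.  The package's
  dependency-capture test accordingly uses adjacent-coupled data.
- Plug-in MI is positively biased at small alignment sizes; the 0.05-bit
  threshold is calibrated for alignments of ~1,000 sites.
- ZOOPS EM assumes at most one site per sequence; tandem sites bias gamma
  upward and dilute column estimates.
- pAUC at FPR <= 1e-3 needs enough background windows (>= ~10^4) to be
  resolved; smaller background sets quantize the curve.
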