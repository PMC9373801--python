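"""Gene mapping and per-term enrichment statistics.

Peaks or predicted sites are mapped to genes whose body extended by a
2,500 bp flank on each side they intersect by at least 1 bp.  Per term the
2x2 contingency counts (term-positive foreground genes / foreground genes /
term-positive genes / all genes) give a fold enrichment and a one-sided
hypergeometric p-value, Benjamini-Hochberg adjusted across the tested
terms; terms are reported significant at adjusted p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .seq_core import GeneModel, Interval

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 2500


def map_to_genes(intervals: list[Interval], genes: list[GeneModel],
                 flank: int = DEFAULT_FLANK) -> set[str]:
    """Genes whose flanked body shares >= 1 bp with any interval.

    The flanked region is [gene.start - flank, gene.end + flank), clipped
    at zero; set semantics (each gene reported once).
    """
    selected: set[str] = set()
    by_chrom: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for g in genes:
        ivs = by_chrom.get(g.interval.chrom)
        if not ivs:
            continue
        gs = max(0, g.interval.start - flank)
        ge = g.interval.end + flank
        for iv in ivs:
            if min(ge, iv.end) - max(gs, iv.start) >= 1:
                selected.add(g.gene_id)
                break
    return selected


@dataclass
class ContingencyTable:
    """Table-1-style counts for one term."""

    count_obs_plus: int   # foreground genes with the term
    total_obs: int        # foreground gene count
    count_exp_plus: int   # all genes with the term
    total_exp: int        # all gene count

    def __post_init__(self):
        ok = (0 <= self.count_obs_plus
              <= min(self.total_obs, self.count_exp_plus)
              and self.total_obs <= self.total_exp)
        if not ok:
            raise ValueError(f"inconsistent contingency table: {self}")


def fold_enrichment(table: ContingencyTable) -> float:
    """(Count_Obs+/Total_Obs) / (Count_Exp+/Total_Exp)."""
    if table.total_obs == 0 or table.count_exp_plus == 0:
        raise ValueError("fold enrichment undefined for zero denominators")
    return (table.count_obs_plus / table.total_obs) / (
        table.count_exp_plus / table.total_exp)


@dataclass
class EnrichmentResult:
    term_id: str
    table: ContingencyTable
    fold_enrichment: float
    p_raw: float
    p_adj: float

    @property
    def significant(self) -> bool:
        return self.p_adj < 0.05


def read_annotations(path) -> dict[str, set[str]]:
    """2-column TSV (gene_id, term_id) -> {term: gene set}."""
    ann: dict[str, set[str]] = {}
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term_id"],
                     dtype=str, comment="#")
    for gene, term in zip(df["gene_id"], df["term_id"]):
        ann.setdefault(term, set()).add(gene)
    return ann


def enrich(fg_genes: set[str], all_genes: set[str],
           term_annotations: dict[str, set[str]]) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of every annotated term, BH-adjusted.

    p_raw = P[X >= Count_Obs+] with population Total_Exp, Count_Exp+
    successes and Total_Obs draws.  Terms with zero annotated genes in the
    universe are skipped.  Results sorted by adjusted p.
    """
    if not fg_genes <= all_genes:
        raise ValueError("foreground genes must be a subset of all genes")
    rows = []
    for term, genes in sorted(term_annotations.items()):
        in_universe = genes & all_genes
        if not in_universe:
            continue
        k = len(in_universe & fg_genes)
        table = ContingencyTable(k, len(fg_genes), len(in_universe),
                                 len(all_genes))
        p = float(hypergeom.sf(k - 1, len(all_genes), len(in_universe),
                               len(fg_genes)))
        try:
            fe = fold_enrichment(table)
        except ValueError:
            logger.info("term %s skipped: undefined fold enrichment", term)
            continue
        rows.append((term, table, fe, p))
    if not rows:
        return []
    _, p_adj, _, _ = multipletests([r[3] for r in rows], method="fdr_bh")
    results = [EnrichmentResult(t, tab, fe, p, float(pa))
               for (t, tab, fe, p), pa in zip(rows, p_adj)]
    results.sort(key=lambda r: (r.p_adj, r.p_raw, r.term_id))
    return results


_RESULT_COLUMNS = ["term_id", "count_obs_plus", "total_obs",
                   "count_exp_plus", "total_exp", "fold_enrichment",
                   "p_raw", "p_adj"]


def results_to_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"term_id": r.term_id,
         "count_obs_plus": r.table.count_obs_plus,
         "total_obs": r.table.total_obs,
         "count_exp_plus": r.table.count_exp_plus,
         "total_exp": r.table.total_exp,
         "fold_enrichment": r.fold_enrichment,
         "p_raw": r.p_raw, "p_adj": r.p_adj}
        for r in results
    ], columns=_RESULT_COLUMNS)


def compare_models_fe(results_per_model: dict[str, list[EnrichmentResult]]
                      ) -> pd.DataFrame:
    """Fold-enrichment table over terms significant in every model.

    Also attaches pairwise win counts (#terms where one model's FE exceeds
    the other's) in ``.attrs['wins']``.
    """
    if len(results_per_model) < 2:
        raise ValueError("need at least 2 models to compare")
    sig_sets = {
        m: {r.term_id for r in res if r.significant}
        for m, res in results_per_model.items()
    }
    common = set.intersection(*sig_sets.values())
    fe = {
        m: {r.term_id: r.fold_enrichment for r in res}
        for m, res in results_per_model.items()
    }
    rows = [{"term_id": t, **{m: fe[m][t] for m in results_per_model}}
            for t in sorted(common)]
    df = pd.DataFrame(rows, columns=["term_id", *results_per_model])
    if not rows:
        logger.info("no term significant in all models")
    wins: dict[tuple[str, str], int] = {}
    models = list(results_per_model)
    for i, a in enumerate(models):
        for b in models[i + 1:]:
            wins[(a, b)] = sum(1 for t in common if fe[a][t] > fe[b][t])
            wins[(b, a)] = sum(1 for t in common if fe[b][t] > fe[a][t])
    df.attrs["wins"] = wins
    return df
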