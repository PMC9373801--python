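"""End-to-end orchestration: background -> grid CV -> training ->
calibration -> scanning -> classification -> dependency -> enrichment.

All randomness flows from one master seed through named substreams, so a
rerun with the same config and inputs reproduces every numeric artifact
bit for bit.  Each stage writes its TSV/JSON outputs into the run
directory; a manifest records the seed, input checksums and the artifact
list.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .seq_core import read_genome, read_bed, read_gff_genes
from .background import BackgroundConfig, sample_background
from .pwm import discover_pwm, extract_site_alignment
from .markov import discover_markov
from .sitega import discover_sitega
from .calibration import (
    ERR_LADDER,
    build_calibration_set,
    compute_err_map,
    thresholds_for_ladder,
)
from .evaluation import select_params, split_odd_even
from .scan_classify import (
    classify_peaks,
    hits_to_bed_rows,
    pairwise_overlap,
    scan_peaks,
)
from .dependency import count_dependent_pairs, logo_data, mi_matrix
from .enrichment import enrich, map_to_genes, read_annotations, results_to_table
from .synthetic import (
    ImplantSpec,
    make_annotation_fixture,
    make_dataset,
    make_genome,
)

logger = logging.getLogger(__name__)

STAGES = ["background", "grid_cv", "training", "calibration", "thresholds",
          "scan", "classify", "dependency", "enrichment"]


@dataclass
class PipelineConfig:
    """Declarative run configuration.

    When ``fasta``/``bed`` are omitted the pipeline generates the default
    synthetic fixture (500 peaks of 201 bp, implant rate 0.8) instead of
    loading files, so the full workflow is runnable download-free.
    """

    outdir: str = "run"
    fasta: str | None = None
    bed: str | None = None
    gff: str | None = None
    annotations: str | None = None
    seed: int = 0
    # model grids; one model per family is trained with the pAUC-best setting
    pwm_lengths: list[int] = field(default_factory=lambda: [12])
    markov_lengths: list[int] = field(default_factory=lambda: [12])
    markov_orders: list[int] = field(default_factory=lambda: [1])
    sitega_lengths: list[int] = field(default_factory=lambda: [12])
    sitega_lpd_counts: list[int] = field(default_factory=lambda: [40])
    families: list[str] = field(default_factory=lambda: ["pwm", "markov", "sitega"])
    # background sampling
    bg_per_peak: int = 5
    bg_per_peak_sitega: int = 10
    bg_attempts: int = 500
    at_tolerance: float = 0.01
    # GA / EM budgets (desk-scale defaults)
    ga_pop: int = 30
    ga_generations: int = 40
    ga_rounds: int = 2
    em_max_iter: int = 50
    # calibration / enrichment
    up_len: int = 1500
    flank: int = 2500
    ladder: dict = field(default_factory=lambda: dict(ERR_LADDER))
    scan_stringency: str = "medium"
    # synthetic fixture knobs (used only without fasta/bed)
    synthetic_kind: str = "pfm"
    synthetic_n_peaks: int = 500
    synthetic_n_genes: int = 120
    synthetic_n_terms: int = 40

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _substreams(seed: int, names: list[str]) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31 - 1))
            for n, c in zip(names, children)}


def _load_or_simulate(config: PipelineConfig, seeds: dict):
    if config.fasta and config.bed:
        genome = read_genome(config.fasta)
        peaks = read_bed(config.bed, genome)
        genes = read_gff_genes(config.gff) if config.gff else []
        annotations = (read_annotations(config.annotations)
                       if config.annotations else {})
        return genome, peaks, genes, annotations
    # synthetic fixture: peaks on chr1, genes on a dedicated chromosome,
    # plus one promoter-proximal peak per designated-term target gene so
    # the enrichment stage has real signal to find
    from .seq_core import Interval, rank_peaks, revcomp
    from .synthetic import sample_sites

    spec = ImplantSpec(kind=config.synthetic_kind, seed=seeds["sites"])
    ds = make_dataset(spec, n_peaks=config.synthetic_n_peaks,
                      seed=seeds["dataset"])
    gene_chrom_len = 2000 + config.synthetic_n_genes * 8000 + 2000
    gene_genome = make_genome(1, gene_chrom_len, 0.6,
                              seed=seeds["gene_genome"], prefix="chrG")
    genome = type(ds.genome)({**ds.genome.chromosomes,
                              **gene_genome.chromosomes})
    genes, ann_df = make_annotation_fixture(
        genome, "chrG1", config.synthetic_n_genes, config.synthetic_n_terms,
        enriched_term="TERM:0001", seed=seeds["annotations"])
    annotations: dict[str, set] = {}
    for g, t in zip(ann_df["gene_id"], ann_df["term_id"]):
        annotations.setdefault(t, set()).add(g)

    target_ids = sorted(annotations.get("TERM:0001", set()))
    gene_by_id = {g.gene_id: g for g in genes}
    rng = np.random.default_rng(seeds["promoter_peaks"])
    peak_len = 201
    L = spec.length
    extra_sites = sample_sites(spec, max(len(target_ids), 1),
                               rng=np.random.default_rng(
                                   seeds["promoter_peaks"] + 1))
    chrom = bytearray(genome.chromosomes["chrG1"].encode())
    extra = []
    for i, gid in enumerate(target_ids):
        g = gene_by_id[gid]
        if g.strand == "+":
            start = g.interval.start - 1300
        else:
            start = g.interval.end + 1099
        off = int(rng.integers(0, peak_len - L + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        site = extra_sites[i]
        written = site if strand == "+" else revcomp(site)
        chrom[start + off:start + off + L] = written.encode()
        extra.append(Interval("chrG1", start, start + peak_len, score=0.0))
    genome = type(genome)({**genome.chromosomes,
                           "chrG1": bytes(chrom).decode()})
    peaks = rank_peaks(list(ds.peaks) + extra)
    return genome, peaks, genes, annotations


def _family_trainer(family: str, config: PipelineConfig, seed: int):
    def factory(params):
        def train(fg, bg):
            if family == "pwm":
                return discover_pwm(fg, bg, params["length"], seed=seed,
                                    em_max_iter=config.em_max_iter).pwm
            if family == "markov":
                return discover_markov(fg, bg, params["length"], params["order"],
                                       seed=seed).scorer
            if family == "sitega":
                return discover_sitega(
                    fg, bg, params["length"], params["lpd_count"], seed=seed,
                    pop=config.ga_pop, generations=config.ga_generations,
                    max_rounds=config.ga_rounds).model
            raise ValueError(f"unknown family {family!r}")
        return train
    return factory


def _family_grid(family: str, config: PipelineConfig) -> list[dict]:
    if family == "pwm":
        return [{"length": L} for L in config.pwm_lengths]
    if family == "markov":
        return [{"length": L, "order": k} for L in config.markov_lengths
                for k in config.markov_orders]
    if family == "sitega":
        return [{"length": L, "lpd_count": N} for L in config.sitega_lengths
                for N in config.sitega_lpd_counts]
    raise ValueError(f"unknown family {family!r}")


def run_pipeline(config: PipelineConfig) -> Path:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _substreams(config.seed, [
        "sites", "dataset", "gene_genome", "annotations",
        "background", "background_sitega", "pwm", "markov", "sitega",
        "promoter_peaks",
    ])
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": {}, "inputs": {}}
    for key in ("fasta", "bed", "gff", "annotations"):
        p = getattr(config, key)
        if p:
            manifest["inputs"][key] = _sha256(Path(p))

    genome, peaks, genes, annotations = _load_or_simulate(config, seeds)
    fg = peaks.extract(genome)
    manifest["n_peaks"] = len(peaks)

    # --- background ---------------------------------------------------
    bg_cfg = BackgroundConfig(config.bg_per_peak, config.bg_attempts,
                              config.at_tolerance, seed=seeds["background"])
    bg = sample_background(genome, peaks, bg_cfg)
    bg_sitega = bg
    if config.bg_per_peak_sitega != config.bg_per_peak:
        bg_sitega = sample_background(
            genome, peaks,
            BackgroundConfig(config.bg_per_peak_sitega, config.bg_attempts,
                             config.at_tolerance,
                             seed=seeds["background_sitega"]))
    bg_path = outdir / "background.tsv"
    pd.DataFrame([{"id": r.id, "length": len(r.seq)} for r in bg]).to_csv(
        bg_path, sep="\t", index=False)
    manifest["stages"]["background"] = [bg_path.name]

    # --- grid CV ------------------------------------------------------
    fg_folds_peaks = split_odd_even(peaks)
    fg_folds = tuple(p.extract(genome) for p in fg_folds_peaks)
    half = len(bg) // 2
    from .seq_core import SequenceSet
    bg_folds = (SequenceSet(list(bg)[:half], role="background"),
                SequenceSet(list(bg)[half:], role="background"))
    cv_rows = []
    selected: dict[str, dict] = {}
    for family in config.families:
        bgf = bg_folds
        res = select_params(family, _family_trainer(family, config,
                                                    seeds[family]),
                            _family_grid(family, config), fg_folds, bgf)
        selected[family] = res.params
        t = res.table.copy()
        t.insert(0, "family", family)
        cv_rows.append(t)
        manifest["stages"].setdefault("grid_cv", [])
    cv_table = pd.concat(cv_rows, ignore_index=True)
    cv_path = outdir / "grid_cv.tsv"
    cv_table.to_csv(cv_path, sep="\t", index=False)
    manifest["stages"]["grid_cv"] = [cv_path.name]

    # --- final training on all peaks ---------------------------------
    models: dict[str, object] = {}
    for family in config.families:
        bg_used = bg_sitega if family == "sitega" else bg
        trainer = _family_trainer(family, config, seeds[family])(
            selected[family])
        models[family] = trainer(fg, bg_used)
    model_path = outdir / "models.json"
    with open(model_path, "w") as fh:
        json.dump({f: m.to_json() for f, m in models.items()}, fh, indent=1)
    manifest["stages"]["training"] = [model_path.name]

    # --- calibration & thresholds ------------------------------------
    calib = build_calibration_set(genome, genes, up_len=config.up_len)
    err_maps = {f: compute_err_map(m, calib) for f, m in models.items()}
    thresholds = {f: thresholds_for_ladder(em, config.ladder)
                  for f, em in err_maps.items()}
    cal_files = []
    for f, em in err_maps.items():
        p = outdir / f"err_map_{f}.tsv"
        em.to_table().to_csv(p, sep="\t", index=False)
        cal_files.append(p.name)
    manifest["stages"]["calibration"] = cal_files
    thr_path = outdir / "thresholds.json"
    with open(thr_path, "w") as fh:
        json.dump(thresholds, fh, indent=1)
    manifest["stages"]["thresholds"] = [thr_path.name]

    # --- scanning & classification ------------------------------------
    stringency = config.scan_stringency
    scan_spec = {f: (models[f], thresholds[f][stringency], err_maps[f])
                 for f in config.families}
    hits = scan_peaks(scan_spec, fg)
    hits_path = outdir / "hits.tsv"
    hits_to_bed_rows(hits).to_csv(hits_path, sep="\t", index=False)
    manifest["stages"]["scan"] = [hits_path.name]

    classification = classify_peaks(hits, config.families, fg)
    cls_path = outdir / "classification.tsv"
    classification.to_table().to_csv(cls_path, sep="\t", index=False)
    overlap_rows = []
    for i, a in enumerate(config.families):
        for b in config.families[i + 1:]:
            ov = pairwise_overlap([h for h in hits if h.model_id == a],
                                  [h for h in hits if h.model_id == b], fg)
            overlap_rows.append({"model_a": a, "model_b": b,
                                 "n_both": ov.attrs["n_both"],
                                 "n_overlapped": ov.attrs["n_overlapped"]})
    ov_path = outdir / "pairwise_overlap.tsv"
    pd.DataFrame(overlap_rows).to_csv(ov_path, sep="\t", index=False)
    manifest["stages"]["classify"] = [cls_path.name, ov_path.name]

    # --- dependency analysis ------------------------------------------
    dep_files = []
    dep_summary = []
    for f, m in models.items():
        model_hits = [h for h in hits if h.model_id == f]
        sites = _hit_alignment(model_hits, fg, m.length)
        if len(sites) < 20:
            sites = extract_site_alignment(m, fg.sequences())
        mim = mi_matrix(sites)
        p = outdir / f"mi_matrix_{f}.tsv"
        pd.DataFrame(mim).to_csv(p, sep="\t", index=False, header=False)
        dep_files.append(p.name)
        lp = outdir / f"logo_{f}.tsv"
        logo_data(sites).to_csv(lp, sep="\t", index=False)
        dep_files.append(lp.name)
        dep_summary.append({"family": f, "n_sites": len(sites),
                            "dependent_pairs": count_dependent_pairs(mim)})
    dp = outdir / "dependency_summary.tsv"
    pd.DataFrame(dep_summary).to_csv(dp, sep="\t", index=False)
    dep_files.append(dp.name)
    manifest["stages"]["dependency"] = dep_files

    # --- enrichment ----------------------------------------------------
    enr_files = []
    if genes and annotations:
        all_gene_ids = {g.gene_id for g in genes}
        # map whole peaks and per-model hit-bearing peaks to genes
        peak_intervals = list(peaks)
        for f in config.families:
            covered = {h.peak_id for h in hits if h.model_id == f}
            ivs = [iv for iv, rec in zip(peak_intervals, fg)
                   if rec.id in covered]
            fg_genes = map_to_genes(ivs, genes, flank=config.flank)
            res = enrich(fg_genes, all_gene_ids, annotations)
            p = outdir / f"enrichment_{f}.tsv"
            results_to_table(res).to_csv(p, sep="\t", index=False)
            enr_files.append(p.name)
    manifest["stages"]["enrichment"] = enr_files

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return outdir


def _hit_alignment(hits, fg, L: int) -> list[str]:
    """Best hit per peak as an aligned site list (motif orientation)."""
    from .seq_core import revcomp
    by_peak: dict[str, list] = {}
    for h in hits:
        by_peak.setdefault(h.peak_id, []).append(h)
    seq_of = {r.id: r.seq for r in fg}
    sites = []
    for pid, hs in sorted(by_peak.items()):
        best = max(hs, key=lambda h: (h.score, -h.offset))
        w = seq_of[pid][best.offset:best.offset + L]
        if best.strand == "-":
            w = revcomp(w)
        if "N" not in w and len(w) == L:
            sites.append(w)
    return sites
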