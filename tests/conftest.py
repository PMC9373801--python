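"""Shared fixtures: one small synthetic dataset and trained models.

Session scope keeps the expensive pieces (background sampling, PWM
discovery, calibration) trained once and reused read-only by many tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import multimotif as mm


@pytest.fixture(scope="session")
def pfm_dataset():
    """120 peaks with a 12-bp high-information independent implant."""
    spec = mm.ImplantSpec(kind="pfm", length=12, seed=11)
    return mm.make_dataset(spec, n_peaks=120, seed=11)


@pytest.fixture(scope="session")
def pfm_fg(pfm_dataset):
    return pfm_dataset.peaks.extract(pfm_dataset.genome)


@pytest.fixture(scope="session")
def pfm_bg(pfm_dataset):
    return mm.sample_background(pfm_dataset.genome, pfm_dataset.peaks,
                                mm.BackgroundConfig(seed=12))


@pytest.fixture(scope="session")
def trained_pwm(pfm_fg, pfm_bg):
    return mm.discover_pwm(pfm_fg, pfm_bg, 12, seed=13, n_seeds=10,
                           em_max_iter=30)


@pytest.fixture(scope="session")
def gene_fixture():
    """Genome with tiled genes plus a term annotation table."""
    genome = mm.make_genome(1, 2000 + 80 * 8000 + 2000, 0.6, seed=21,
                            prefix="chrG")
    genes, ann = mm.make_annotation_fixture(
        genome, "chrG1", n_genes=80, n_terms=30,
        enriched_term="TERM:0001", n_targets=20, seed=22)
    return genome, genes, ann


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
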