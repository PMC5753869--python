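"""Shared fixtures: scaled scenario configs and pre-computed study runs."""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pytest

from drivescan.config import (
    CnvEvent,
    ConversionTract,
    PopulationConfig,
    SimulationConfig,
    default_config,
)
from drivescan.pseudot import build_consensus_sequences, extract_pseudo_haplotype
from drivescan.phylo import classify_windows
from drivescan.simulate import simulate_cohort, simulate_reference_and_genes
from drivescan.variants import apply_filter_procedure

DATA_DIR = os.path.join(os.path.dirname(__file__), "data")


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A 400-kb scenario for fast unit and property tests."""
    base = dict(
        seed=seed,
        chrom_length=400_000,
        driver_region=(50_000, 350_000),
        n_genes=60,
        cds_fraction=0.10,
        populations={
            "dom": PopulationConfig(n_noncarriers=4, n_carriers=2),
            "mus": PopulationConfig(n_noncarriers=4, n_carriers=1),
            "cas": PopulationConfig(n_noncarriers=4, n_carriers=1),
        },
        n_outgroup=2,
        conversion_tracts=[
            ConversionTract(100_000, 110_000, "very_recent", "dom"),
            ConversionTract(150_000, 160_000, "old", "dom"),
            ConversionTract(200_000, 210_000, "very_recent", "mus"),
            ConversionTract(250_000, 260_000, "old", "cas"),
        ],
        cnv_events=[
            CnvEvent(10_000, 20_000, 4, False),
            CnvEvent(60_000, 70_000, 1, True),
            CnvEvent(300_000, 310_000, 3, True),
            CnvEvent(360_000, 370_000, 0, False),
        ],
    )
    base.update(overrides)
    cfg = SimulationConfig(**base)
    cfg.validate()
    return cfg


@dataclass
class StudyRun:
    """One simulated study plus the standard downstream products."""

    config: SimulationConfig
    reference: np.ndarray
    annotation: object
    cohort: object
    filtered: object
    pseudo_sets: list
    consensus: object
    window_classes: object  # DataFrame


def build_run(cfg: SimulationConfig, classify: bool = True) -> StudyRun:
    ref, ann = simulate_reference_and_genes(cfg)
    cohort = simulate_cohort(cfg, ref, ann)
    filtered, _ = apply_filter_procedure(cohort.table, 1)
    sets = [
        extract_pseudo_haplotype(filtered, c)
        for c in filtered.samples_with_role("carrier")
    ]
    others = filtered.samples_with_role("noncarrier") + filtered.samples_with_role("outgroup")
    consensus = build_consensus_sequences(
        ref, cfg.driver_region, pseudo_sets=sets, table=filtered, table_samples=others
    )
    frame = None
    if classify:
        frame = classify_windows(consensus, cohort.truth.windows, list(cfg.populations))
    return StudyRun(cfg, ref, ann, cohort, filtered, sets, consensus, frame)


@pytest.fixture(scope="session")
def small_run() -> StudyRun:
    """A single fully analysed small-scenario study."""
    return build_run(small_config(seed=7))


@pytest.fixture(scope="session")
def default_runs() -> list[StudyRun]:
    """Ten seeds of the default desk-scale scenario, fully analysed.

    Shared by the recovery-style acceptance tests to keep the suite within
    its runtime budget.
    """
    return [build_run(default_config(seed=s)) for s in range(10)]


@pytest.fixture
def filter_fixture_paths():
    return (
        os.path.join(DATA_DIR, "filter_suite.vcf"),
        os.path.join(DATA_DIR, "filter_samples.tsv"),
        os.path.join(DATA_DIR, "filter_mask.bed"),
    )
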