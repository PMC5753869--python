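"""Study configuration for the synthetic cohort and the analysis pipeline.

The default scenario is a desk-scale analog of a deeply diverged meiotic
driver carried heterozygously on one chromosome: a 2 Mb chromosome whose
[0.2, 1.8) Mb interval plays the role of the driver (t-like) region, three
ingroup subspecies plus one outgroup species, driver-standard divergence
around 1% and individual heterozygosity around 0.1%, so that carriers show
a roughly ten-fold excess of heterozygous SNP density inside the region.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

VERY_RECENT = "very_recent"
OLD = "old"

CARRIER = "carrier"
NONCARRIER = "noncarrier"
OUTGROUP = "outgroup"


@dataclass
class ConversionTract:
    """A driver segment overwritten by standard-lineage sequence.

    ``recency`` controls the copy source: ``very_recent`` tracts copy the
    carrier's own standard homolog (homologous gene conversion, essentially
    no post-conversion divergence); ``old`` tracts copy the subspecies-
    ancestral standard sequence and then accumulate private driver
    substitutions.  ``population`` is the subspecies whose driver lineage
    carries the tract.
    """

    start: int
    end: int
    recency: str
    population: str

    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class CnvEvent:
    """A copy-number event. ``copy_number`` is the total copy count of the
    affected samples (carriers only, when ``driver_specific``)."""

    start: int
    end: int
    copy_number: int
    driver_specific: bool

    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class PopulationConfig:
    n_noncarriers: int
    n_carriers: int


@dataclass
class BranchDivergences:
    """Per-branch substitution probabilities per site.

    ``outgroup``: stem of the outgroup species from the ancestral root.
    ``ingroup_radiation``: the ingroup stem between the driver split and the
    subspecies radiation - the internal branch that makes the standard
    (noncarrier) lineages a clade excluding the driver.
    ``sister``: extra branch shared by the two sister subspecies (the
    noncarrier species tree is ((sister pair), third)).
    ``subspecies``: stem of each ingroup subspecies.
    ``lineage``: each edge of the random within-population genealogy.
    ``driver``: the driver stem, splitting from the ingroup ancestor before
    the subspecies radiation (applies inside the driver region only).
    ``driver_subspecies`` / ``driver_carrier``: per-subspecies and terminal
    per-carrier driver branches.  ``old_tract_post``: substitutions accrued
    on an old conversion tract after the copy event.
    """

    outgroup: float = 0.008
    ingroup_radiation: float = 0.001
    sister: float = 0.0006
    subspecies: float = 0.0012
    lineage: float = 0.0001
    driver: float = 0.009
    driver_subspecies: float = 0.0004
    driver_carrier: float = 0.0002
    old_tract_post: float = 0.002

    def all_probabilities(self) -> list[float]:
        return list(asdict(self).values())


@dataclass
class ExpressionConfig:
    n_carrier_samples: int = 4
    n_noncarrier_samples: int = 8
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.2
    noise_log_sd: float = 0.2


@dataclass
class SimulationConfig:
    seed: int = 0
    chrom: str = "chrSim"
    chrom_length: int = 2_000_000
    driver_region: tuple[int, int] = (200_000, 1_800_000)
    n_genes: int = 300
    cds_fraction: float = 0.10
    populations: dict[str, PopulationConfig] = field(
        default_factory=lambda: {
            "dom": PopulationConfig(n_noncarriers=6, n_carriers=4),
            "mus": PopulationConfig(n_noncarriers=6, n_carriers=2),
            "cas": PopulationConfig(n_noncarriers=6, n_carriers=2),
        }
    )
    outgroup_name: str = "spr"
    n_outgroup: int = 4
    sister_clade: tuple[str, str] = ("mus", "cas")
    branch_divergences: BranchDivergences = field(default_factory=BranchDivergences)
    ts_tv_ratio: float = 2.0
    conversion_tracts: list[ConversionTract] = field(
        default_factory=lambda: [
            ConversionTract(300_000, 400_000, VERY_RECENT, "dom"),
            ConversionTract(500_000, 600_000, OLD, "dom"),
            ConversionTract(700_000, 800_000, VERY_RECENT, "mus"),
            ConversionTract(900_000, 1_000_000, OLD, "mus"),
            ConversionTract(1_100_000, 1_200_000, VERY_RECENT, "cas"),
            ConversionTract(1_300_000, 1_400_000, OLD, "cas"),
        ]
    )
    driver_ns_excess: float = 3.0
    cnv_events: list[CnvEvent] = field(
        default_factory=lambda: [
            CnvEvent(60_000, 100_000, 4, False),
            CnvEvent(240_000, 290_000, 1, True),
            CnvEvent(1_450_000, 1_530_000, 3, True),
            CnvEvent(1_900_000, 1_930_000, 0, False),
        ]
    )
    coverage_mean: float = 100.0
    coverage_window: int = 1_000
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        a, b = self.driver_region
        if not (0 <= a < b <= self.chrom_length):
            raise ValueError("driver_region must lie within [0, chrom_length)")
        if self.driver_ns_excess < 1:
            raise ValueError("driver_ns_excess must be >= 1")
        for p in self.branch_divergences.all_probabilities():
            if not (0.0 <= p <= 0.5):
                raise ValueError(f"substitution probability {p} outside [0, 0.5]")
        for t in self.conversion_tracts:
            if not (a <= t.start < t.end <= b):
                raise ValueError(
                    f"conversion tract ({t.start}, {t.end}) outside driver region {self.driver_region}"
                )
            if t.recency not in (VERY_RECENT, OLD):
                raise ValueError(f"unknown tract recency {t.recency!r}")
            if t.population not in self.populations:
                raise ValueError(f"tract population {t.population!r} not in populations")
        for c in self.cnv_events:
            if not (0 <= c.start < c.end <= self.chrom_length):
                raise ValueError(f"CNV event ({c.start}, {c.end}) outside chromosome")
            if c.copy_number not in (0, 1, 3, 4):
                raise ValueError("copy_number must be one of 0, 1, 3, 4")
        if not (0.0 <= self.cds_fraction <= 1.0):
            raise ValueError("cds_fraction must be in [0, 1]")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["driver_region"] = list(self.driver_region)
        d["sister_clade"] = list(self.sister_clade)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "driver_region" in d:
            d["driver_region"] = tuple(d["driver_region"])
        if "sister_clade" in d:
            d["sister_clade"] = tuple(d["sister_clade"])
        if "populations" in d:
            d["populations"] = {
                k: PopulationConfig(**v) if not isinstance(v, PopulationConfig) else v
                for k, v in d["populations"].items()
            }
        if "branch_divergences" in d and not isinstance(d["branch_divergences"], BranchDivergences):
            d["branch_divergences"] = BranchDivergences(**d["branch_divergences"])
        if "conversion_tracts" in d:
            d["conversion_tracts"] = [
                ConversionTract(**t) if not isinstance(t, ConversionTract) else t
                for t in d["conversion_tracts"]
            ]
        if "cnv_events" in d:
            d["cnv_events"] = [
                CnvEvent(**c) if not isinstance(c, CnvEvent) else c for c in d["cnv_events"]
            ]
        if "expression" in d and not isinstance(d["expression"], ExpressionConfig):
            d["expression"] = ExpressionConfig(**d["expression"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default desk-scale scenario."""
    cfg = SimulationConfig(seed=seed, **overrides)
    cfg.validate()
    return cfg


def expression_benchmark_config(seed: int = 0) -> SimulationConfig:
    """Scenario for expression-contrast benchmarking.

    More genes, and six 100-kb driver-specific duplications so that both the
    CNV-overlapping and non-overlapping groups hold at least 50 expressed
    genes (the default layout is calibrated for coverage-based CNV recovery
    instead and covers too few genes for a well-powered rank test).
    """
    cnvs = [CnvEvent(s, s + 100_000, 3, True) for s in range(250_000, 1_750_000, 250_000)]
    cfg = SimulationConfig(seed=seed, n_genes=400, cnv_events=cnvs)
    cfg.validate()
    return cfg
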