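"""Synthetic cohort generator with truth tables.

The generator produces an internally consistent study of a deeply diverged
driver haplotype carried heterozygously: a random reference chromosome with
non-overlapping CDS genes, haplotypes evolved down a fixed species tree
(one outgroup species; three ingroup subspecies whose driver lineage splits
from the ingroup ancestor *before* the subspecies radiation), conversion
tracts that overwrite driver segments with standard-lineage sequence, an
excess of nonsynonymous substitutions on unconverted driver segments,
driver-specific CNVs with matching coverage tracks, and CNV-driven
expression shifts.  Every stochastic choice derives from ``config.seed``.

Model choices
-------------
* Substitutions are independent per site with a 2:1 transition:transversion
  mix and no indels.  Shared ancestral polymorphism is not simulated; each
  branch mutates independently from its parent sequence.
* Within each population, haplotypes descend from the subspecies ancestor
  through a random bifurcating genealogy (uniform random joins) with a
  constant per-edge substitution probability, giving individuals realistic
  heterozygosity and making carrier-private standard variants rare.
* ``very_recent`` conversion tracts copy the carrier's own standard
  homolog (homologous gene conversion); ``old`` tracts copy the
  subspecies-ancestral sequence and then accumulate private substitutions.
* Carriers are heterozygous driver/standard inside the driver region and
  carry two standard haplotypes outside it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coding import CODON_AA, BASES, CdsSegment, CodingAnnotation
from .config import (
    CARRIER,
    NONCARRIER,
    OUTGROUP,
    OLD,
    VERY_RECENT,
    SimulationConfig,
)
from .intervals import write_bed
from .variants import (
    CohortVariantTable,
    SampleMeta,
    write_sample_sheet,
    write_vcf,
)

_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TRANSITION = np.array([2, 3, 0, 1])  # A<->G, C<->T
_STOP_CODONS = {"TAA", "TAG", "TGA"}

WINDOW_SIZE = 5_000  # truth (and analysis) window for recombination classes


def _stream(config: SimulationConfig, name: str) -> np.random.Generator:
    """Deterministic per-purpose random stream derived from the config seed."""
    import zlib

    h = zlib.crc32(name.encode()) % (2**31)
    return np.random.default_rng([int(config.seed) % (2**31), h])


# ---------------------------------------------------------------------------
# reference + genes
# ---------------------------------------------------------------------------

def simulate_reference_and_genes(
    config: SimulationConfig,
) -> tuple[np.ndarray, CodingAnnotation]:
    """Uniform-random reference (integer codes 0..3) plus CDS annotation.

    Genes are non-overlapping, length divisible by 3, start with ATG and
    contain no in-frame stop on the coding strand (minus-strand genes are
    written into the genome as the reverse complement of their coding
    sequence).
    """
    config.validate()
    rng = _stream(config, "reference")
    L = config.chrom_length
    ref = rng.integers(0, 4, size=L, dtype=np.int8).astype(np.uint8)

    n = config.n_genes
    if n == 0:
        return ref, CodingAnnotation([], chrom=config.chrom)
    gene_len = max(30, (int(config.cds_fraction * L) // n) // 3 * 3)
    if n * gene_len > L:
        raise ValueError(
            f"cannot place {n} non-overlapping genes of {gene_len} bp on a "
            f"{L} bp chromosome (total CDS exceeds chromosome length)"
        )
    free = L - n * gene_len
    cuts = np.sort(rng.integers(0, free + 1, size=n))
    starts = cuts + gene_len * np.arange(n)
    strands = np.where(rng.random(n) < 0.5, "+", "-")

    non_stop = [c for c in range(64) if CODON_AA[c] != "*"]
    segments = []
    for i in range(n):
        start, strand = int(starts[i]), str(strands[i])
        codons = rng.choice(non_stop, size=gene_len // 3)
        codes = np.empty(gene_len, dtype=np.uint8)
        codes[0::3], codes[1::3], codes[2::3] = codons // 16, (codons // 4) % 4, codons % 4
        codes[:3] = [0, 3, 2]  # ATG
        if strand == "-":
            codes = 3 - codes[::-1]  # reverse complement of the coding sequence
        ref[start : start + gene_len] = codes
        segments.append(CdsSegment(f"g{i:04d}", start, start + gene_len, strand, 0))
    return ref, CodingAnnotation(segments, chrom=config.chrom)


def reference_to_str(ref_codes: np.ndarray) -> str:
    return _BASE_CODES[ref_codes].tobytes().decode()


def write_fasta(path, chrom: str, ref_codes: np.ndarray, width: int = 60) -> None:
    seq = reference_to_str(ref_codes)
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# branch mutation machinery
# ---------------------------------------------------------------------------

def _mutate_codes(rng: np.random.Generator, cur: np.ndarray, ts_tv: float) -> np.ndarray:
    """Mutate base codes with a given transition:transversion ratio."""
    p_ts = ts_tv / (ts_tv + 1.0)
    u = rng.random(cur.shape)
    is_ts = u < p_ts
    out = np.where(is_ts, _TRANSITION[cur], 0)
    # transversion: two candidates per base, neither the base nor its transition
    tv_choice = (rng.random(cur.shape) < 0.5).astype(np.int8)
    tv_opts = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])  # complements/others
    out = np.where(is_ts, out, tv_opts[cur, tv_choice])
    return out.astype(np.uint8)


def _apply_branch(
    rng: np.random.Generator,
    parent: dict[int, int],
    p: float,
    ref: np.ndarray,
    region: tuple[int, int],
    ts_tv: float,
) -> dict[int, int]:
    """One branch of independent per-site substitutions over *region*."""
    child = dict(parent)
    a, b = region
    span = b - a
    if p <= 0 or span <= 0:
        return child
    n = rng.binomial(span, p)
    if n == 0:
        return child
    positions = rng.choice(span, size=n, replace=False) + a
    cur = np.array([child.get(int(q), int(ref[q])) for q in positions], dtype=np.uint8)
    new = _mutate_codes(rng, cur, ts_tv)
    for q, nb in zip(positions, new):
        q = int(q)
        if nb == ref[q]:
            child.pop(q, None)
        else:
            child[q] = int(nb)
    return child


class _NsContext:
    """Codon lookup used to bias driver-branch substitutions toward
    nonsynonymous changes (classification is reference-codon based, matching
    the downstream effect classifier)."""

    def __init__(self, ref: np.ndarray, annotation: CodingAnnotation, region: tuple[int, int]):
        pos_chunks, cs_chunks, ci_chunks, mi_chunks = [], [], [], []
        for seg in annotation.segments:
            a, b = max(seg.start, region[0]), min(seg.end, region[1])
            if a >= b:
                continue
            qs = np.arange(a, b, dtype=np.int64)
            if seg.strand == "+":
                off = qs - seg.start
                cs = seg.start + 3 * (off // 3)
                ci = off % 3
                mi = np.zeros(len(qs), dtype=bool)
            else:
                off = seg.end - 1 - qs
                cend = seg.end - 3 * (off // 3)
                cs = cend - 3
                ci = (cend - 1) - qs
                mi = np.ones(len(qs), dtype=bool)
            pos_chunks.append(qs)
            cs_chunks.append(cs)
            ci_chunks.append(ci.astype(np.int8))
            mi_chunks.append(mi)
        if pos_chunks:
            self.positions = np.concatenate(pos_chunks)
            order = np.argsort(self.positions)
            self.positions = self.positions[order]
            self.codon_start = np.concatenate(cs_chunks)[order]
            self.codon_idx = np.concatenate(ci_chunks)[order]
            self.minus = np.concatenate(mi_chunks)[order]
        else:
            self.positions = np.zeros(0, dtype=np.int64)
            self.codon_start = np.zeros(0, dtype=np.int64)
            self.codon_idx = np.zeros(0, dtype=np.int8)
            self.minus = np.zeros(0, dtype=bool)
        self.ref = ref

    def is_nonsynonymous(self, i: int, alt_code: int) -> bool:
        cs = int(self.codon_start[i])
        codon = self.ref[cs : cs + 3].copy()
        alt_codon = codon.copy()
        if self.minus[i]:
            codon, alt_codon = 3 - codon[::-1], 3 - alt_codon[::-1]
            alt_codon[int(self.codon_idx[i])] = 3 - alt_code
        else:
            alt_codon[int(self.codon_idx[i])] = alt_code
        ia = int(codon[0]) * 16 + int(codon[1]) * 4 + int(codon[2])
        ib = int(alt_codon[0]) * 16 + int(alt_codon[1]) * 4 + int(alt_codon[2])
        return CODON_AA[ia] != CODON_AA[ib]


def _apply_driver_branch(
    rng: np.random.Generator,
    parent: dict[int, int],
    p: float,
    ref: np.ndarray,
    region: tuple[int, int],
    ts_tv: float,
    ns_ctx: _NsContext,
    ns_excess: float,
    ns_exclude: list[tuple[int, int]] | None = None,
) -> dict[int, int]:
    """Driver-lineage branch: background substitutions plus an extra pass of
    accepted-if-nonsynonymous candidates, multiplying the nonsynonymous
    substitution probability by ``ns_excess`` in CDS.  The excess pass skips
    *ns_exclude* intervals (converted segments evolve at background rates)."""
    child = _apply_branch(rng, parent, p, ref, region, ts_tv)
    extra = p * (ns_excess - 1.0)
    m = len(ns_ctx.positions)
    if extra <= 0 or m == 0:
        return child
    n = rng.binomial(m, extra)
    if n == 0:
        return child
    picks = rng.choice(m, size=n, replace=False)
    for i in picks:
        q = int(ns_ctx.positions[i])
        if q in child:
            continue
        if ns_exclude and any(a <= q < b for a, b in ns_exclude):
            continue
        cur = np.array([ref[q]], dtype=np.uint8)
        nb = int(_mutate_codes(rng, cur, ts_tv)[0])
        if ns_ctx.is_nonsynonymous(int(i), nb):
            child[q] = nb
    return child


def _random_genealogy(rng: np.random.Generator, n_leaves: int):
    """Random bifurcating topology by uniform sequential joins.

    Returns nested tuples over leaf indices 0..n-1.
    """
    nodes: list = list(range(n_leaves))
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append((a, b))
    return nodes[0]


def _evolve_genealogy(
    rng: np.random.Generator,
    topology,
    ancestor: dict[int, int],
    p_edge: float,
    ref: np.ndarray,
    region: tuple[int, int],
    ts_tv: float,
    out: dict[int, dict[int, int]],
) -> None:
    node_seq = _apply_branch(rng, ancestor, p_edge, ref, region, ts_tv)
    if isinstance(topology, int):
        out[topology] = node_seq
    else:
        for child in topology:
            _evolve_genealogy(rng, child, node_seq, p_edge, ref, region, ts_tv, out)


# ---------------------------------------------------------------------------
# truth tables
# ---------------------------------------------------------------------------

@dataclass
class TruthTables:
    conversion_tracts: list          # ConversionTract
    cnv_events: list                 # CnvEvent
    driver_snps: dict[str, dict[int, str]]  # carrier -> {1-based pos: alt base}
    windows: list[tuple[int, int]]   # 5-kb windows tiling the driver region
    window_true_class: dict[str, np.ndarray]  # population -> per-window 'A'/'B'/'C'

    def write(self, outdir, chrom: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        write_bed(
            os.path.join(outdir, "truth_conversion_tracts.bed"),
            [(t.start, t.end) for t in self.conversion_tracts],
            chrom,
            [[t.recency, t.population] for t in self.conversion_tracts],
        )
        write_bed(
            os.path.join(outdir, "truth_cnv.bed"),
            [(c.start, c.end) for c in self.cnv_events],
            chrom,
            [[c.copy_number, int(c.driver_specific)] for c in self.cnv_events],
        )
        with open(os.path.join(outdir, "truth_driver_snps.tsv"), "w") as fh:
            fh.write("carrier\tpos\talt\n")
            for carrier, snps in self.driver_snps.items():
                for p in sorted(snps):
                    fh.write(f"{carrier}\t{p}\t{snps[p]}\n")
        with open(os.path.join(outdir, "truth_window_class.tsv"), "w") as fh:
            fh.write("start\tend\t" + "\t".join(self.window_true_class) + "\n")
            for w, (a, b) in enumerate(self.windows):
                cls = "\t".join(str(self.window_true_class[p][w]) for p in self.window_true_class)
                fh.write(f"{a}\t{b}\t{cls}\n")


def _true_window_classes(config: SimulationConfig) -> tuple[list, dict[str, np.ndarray]]:
    a, b = config.driver_region
    windows = [(s, min(s + WINDOW_SIZE, b)) for s in range(a, b, WINDOW_SIZE)]
    classes: dict[str, np.ndarray] = {}
    for pop in config.populations:
        cls = np.full(len(windows), "C", dtype="U1")
        for w, (ws, we) in enumerate(windows):
            span = we - ws
            vr = sum(
                max(0, min(we, t.end) - max(ws, t.start))
                for t in config.conversion_tracts
                if t.population == pop and t.recency == VERY_RECENT
            )
            old = sum(
                max(0, min(we, t.end) - max(ws, t.start))
                for t in config.conversion_tracts
                if t.population == pop and t.recency == OLD
            )
            if vr >= span / 2:
                cls[w] = "A"
            elif old >= span / 2:
                cls[w] = "B"
        classes[pop] = cls
    return windows, classes


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    config: SimulationConfig
    reference: np.ndarray
    annotation: CodingAnnotation
    table: CohortVariantTable
    haplotypes: dict[str, tuple[dict[int, int], dict[int, int]]]
    truth: TruthTables


def simulate_cohort(
    config: SimulationConfig,
    reference: np.ndarray,
    annotation: CodingAnnotation,
) -> SyntheticCohort:
    """Evolve the cohort and assemble the multi-sample variant table."""
    config.validate()
    region = config.driver_region
    if region[1] - region[0] < WINDOW_SIZE:
        raise ValueError(f"driver region smaller than one {WINDOW_SIZE} bp window")
    ref = reference
    L = config.chrom_length
    whole = (0, L)
    tstv = config.ts_tv_ratio
    div = config.branch_divergences
    rng = _stream(config, "cohort")
    ns_ctx = _NsContext(ref, annotation, region)

    root: dict[int, int] = {}
    haplotypes: dict[str, tuple[dict, dict]] = {}
    samples: list[SampleMeta] = []

    # outgroup species
    out_anc = _apply_branch(rng, root, div.outgroup, ref, whole, tstv)
    n_out_leaves = 2 * config.n_outgroup
    out_leaves: dict[int, dict] = {}
    _evolve_genealogy(
        rng, _random_genealogy(rng, n_out_leaves), out_anc, div.lineage, ref, whole, tstv, out_leaves
    )
    for i in range(config.n_outgroup):
        name = f"{config.outgroup_name}_o{i + 1}"
        haplotypes[name] = (out_leaves[2 * i], out_leaves[2 * i + 1])
        samples.append(SampleMeta(name, config.outgroup_name, OUTGROUP, config.coverage_mean))

    # driver lineage splits from the ingroup ancestor before the radiation
    driver_anc = _apply_driver_branch(
        rng, root, div.driver, ref, region, tstv, ns_ctx, config.driver_ns_excess
    )

    # ingroup stem after the driver split: the internal branch that makes
    # the standard lineages a clade excluding the driver
    radiation_anc = _apply_branch(rng, root, div.ingroup_radiation, ref, whole, tstv)
    sister = set(config.sister_clade) & set(config.populations)
    sister_anc = (
        _apply_branch(rng, radiation_anc, div.sister, ref, whole, tstv)
        if len(sister) == 2
        else radiation_anc
    )

    for pop, pc in config.populations.items():
        parent = sister_anc if pop in sister else radiation_anc
        pop_anc = _apply_branch(rng, parent, div.subspecies, ref, whole, tstv)
        n_leaves = 2 * pc.n_noncarriers + 2 * pc.n_carriers
        leaves: dict[int, dict] = {}
        _evolve_genealogy(
            rng, _random_genealogy(rng, n_leaves), pop_anc, div.lineage, ref, whole, tstv, leaves
        )

        # subspecies driver lineage; old conversions predate the carrier split
        t_pop = _apply_driver_branch(
            rng, driver_anc, div.driver_subspecies, ref, region, tstv, ns_ctx,
            config.driver_ns_excess,
        )
        for tract in config.conversion_tracts:
            if tract.population != pop or tract.recency != OLD:
                continue
            iv = tract.interval()
            t_pop = {q: v for q, v in t_pop.items() if not iv[0] <= q < iv[1]}
            t_pop.update({q: v for q, v in pop_anc.items() if iv[0] <= q < iv[1]})
            post = _apply_branch(rng, {}, div.old_tract_post, ref, iv, tstv)
            for q, v in post.items():
                if v == ref[q]:
                    t_pop.pop(q, None)
                else:
                    t_pop[q] = v

        for i in range(pc.n_noncarriers):
            name = f"{pop}_n{i + 1}"
            haplotypes[name] = (leaves[2 * i], leaves[2 * i + 1])
            samples.append(SampleMeta(name, pop, NONCARRIER, config.coverage_mean))

        vr_tracts = [
            t.interval()
            for t in config.conversion_tracts
            if t.population == pop and t.recency == VERY_RECENT
        ]
        pop_tracts = [
            t.interval() for t in config.conversion_tracts if t.population == pop
        ]
        for j in range(pc.n_carriers):
            name = f"{pop}_c{j + 1}"
            std = leaves[2 * pc.n_noncarriers + 2 * j]
            outside = leaves[2 * pc.n_noncarriers + 2 * j + 1]
            t_carrier = _apply_driver_branch(
                rng, t_pop, div.driver_carrier, ref, region, tstv, ns_ctx,
                config.driver_ns_excess, ns_exclude=pop_tracts,
            )
            # very recent conversion: copy this carrier's standard homolog
            for iv in vr_tracts:
                t_carrier = {q: v for q, v in t_carrier.items() if not iv[0] <= q < iv[1]}
                t_carrier.update({q: v for q, v in std.items() if iv[0] <= q < iv[1]})
            driver_hap = {q: v for q, v in t_carrier.items() if region[0] <= q < region[1]}
            driver_hap.update(
                {q: v for q, v in outside.items() if q < region[0] or q >= region[1]}
            )
            haplotypes[name] = (std, driver_hap)
            samples.append(SampleMeta(name, pop, CARRIER, config.coverage_mean))

    table = _assemble_table(config, ref, haplotypes, samples)

    windows, classes = _true_window_classes(config)
    driver_snps = {
        s.name: {
            q + 1: BASES[v]
            for q, v in haplotypes[s.name][1].items()
            if region[0] <= q < region[1]
        }
        for s in samples
        if s.role == CARRIER
    }
    truth = TruthTables(
        conversion_tracts=list(config.conversion_tracts),
        cnv_events=list(config.cnv_events),
        driver_snps=driver_snps,
        windows=windows,
        window_true_class=classes,
    )
    return SyntheticCohort(config, ref, annotation, table, haplotypes, truth)


def _sample_copy_profile(config: SimulationConfig, samples, positions: np.ndarray) -> np.ndarray:
    """(n_sites, n_samples) copy numbers at given 0-based positions."""
    copy = np.full((len(positions), len(samples)), 2.0)
    for ev in config.cnv_events:
        inside = (positions >= ev.start) & (positions < ev.end)
        if not inside.any():
            continue
        for j, s in enumerate(samples):
            if ev.driver_specific and s.role != CARRIER:
                continue
            copy[inside, j] = ev.copy_number
    return copy


def _assemble_table(config, ref, haplotypes, samples) -> CohortVariantTable:
    rng = _stream(config, "sequencing")
    names = [s.name for s in samples]
    key_arrays = [
        np.fromiter(hap.keys(), dtype=np.int64, count=len(hap))
        for name in names
        for hap in haplotypes[name]
    ]
    pos0 = (
        np.unique(np.concatenate(key_arrays))
        if any(len(k) for k in key_arrays)
        else np.zeros(0, dtype=np.int64)
    )
    n_sites, n_samp = len(pos0), len(samples)

    alleles = np.tile(ref[pos0][:, None], (1, 2 * n_samp)) if n_sites else np.zeros((0, 2 * n_samp), np.uint8)
    for j, name in enumerate(names):
        for k, hap in enumerate(haplotypes[name]):
            col = 2 * j + k
            if not hap:
                continue
            qs = np.fromiter(hap.keys(), dtype=np.int64, count=len(hap))
            vs = np.fromiter(hap.values(), dtype=np.uint8, count=len(hap))
            alleles[np.searchsorted(pos0, qs), col] = vs

    ref_codes = ref[pos0]
    present = np.zeros((n_sites, 4), dtype=bool)
    rows_idx = np.arange(n_sites)
    for col in range(2 * n_samp):
        present[rows_idx, alleles[:, col]] = True
    present_nonref = present.copy()
    present_nonref[rows_idx, ref_codes] = False
    n_alts = present_nonref.sum(axis=1)
    keep = n_alts > 0

    a = alleles[:, 0::2]
    b = alleles[:, 1::2]
    r = ref_codes[:, None]
    gt = np.where((a == r) & (b == r), 0, np.where(a == b, 2, 1)).astype(np.int8)

    alt_str = np.empty(n_sites, dtype=object)
    single = keep & (n_alts == 1)
    single_alt = present_nonref[single].argmax(axis=1)
    alt_str[single] = [BASES[c] for c in single_alt]
    for i in np.nonzero(keep & (n_alts > 1))[0]:
        alt_str[i] = ",".join(BASES[c] for c in np.nonzero(present_nonref[i])[0])

    pos0 = pos0[keep]
    alt_str = alt_str[keep]
    gt = gt[keep]
    ref_codes = ref_codes[keep]
    allele_codes = np.stack([a[keep], b[keep]], axis=2).astype(np.int8)
    n_sites = len(pos0)

    copy = _sample_copy_profile(config, samples, pos0)
    lam = config.coverage_mean * copy / 2.0
    dp = rng.poisson(lam).astype(np.int32)
    het = gt == 1
    alt_reads = np.where(het, rng.binomial(np.maximum(dp, 0), 0.5), 0).astype(np.int32)
    ad_alt = np.where(gt == 2, dp, np.where(het, alt_reads, 0)).astype(np.int32)
    ad_ref = (dp - ad_alt).astype(np.int32)

    return CohortVariantTable(
        chrom=config.chrom,
        pos=pos0 + 1,
        ref=np.array([BASES[int(c)] for c in ref_codes], dtype=object),
        alt=alt_str,
        filter=np.array(["PASS"] * n_sites, dtype=object),
        gt=gt,
        dp=dp,
        ad_ref=ad_ref,
        ad_alt=ad_alt,
        samples=list(samples),
        allele_codes=allele_codes,
    )


# ---------------------------------------------------------------------------
# coverage tracks
# ---------------------------------------------------------------------------

def simulate_coverage_tracks(config: SimulationConfig, truth: TruthTables | None = None) -> pd.DataFrame:
    """Per-sample windowed read depth (Poisson around coverage_mean x copy/2).

    Driver-specific CNVs alter carriers only.  Returns a long DataFrame with
    columns sample, population, role, chrom, window_start, depth.
    """
    if config.coverage_mean <= 0:
        raise ValueError("coverage_mean must be positive")
    rng = _stream(config, "coverage")
    w = config.coverage_window
    n_win = config.chrom_length // w
    starts = np.arange(n_win) * w

    rows = []
    events = truth.cnv_events if truth is not None else config.cnv_events
    for pop, pc in list(config.populations.items()) + [(config.outgroup_name, None)]:
        if pc is None:
            sample_roles = [(f"{pop}_o{i + 1}", OUTGROUP) for i in range(config.n_outgroup)]
        else:
            sample_roles = [(f"{pop}_n{i + 1}", NONCARRIER) for i in range(pc.n_noncarriers)]
            sample_roles += [(f"{pop}_c{j + 1}", CARRIER) for j in range(pc.n_carriers)]
        for name, role in sample_roles:
            copy = np.full(n_win, 2.0)
            for ev in events:
                if ev.driver_specific and role != CARRIER:
                    continue
                ov = np.minimum(starts + w, ev.end) - np.maximum(starts, ev.start)
                frac = np.clip(ov, 0, None) / w
                copy += frac * (ev.copy_number - 2)
            depth = rng.poisson(config.coverage_mean * copy / 2.0)
            rows.append(
                pd.DataFrame(
                    {
                        "sample": name,
                        "population": pop,
                        "role": role,
                        "chrom": config.chrom,
                        "window_start": starts,
                        "depth": depth,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression_matrix(
    config: SimulationConfig,
    truth: TruthTables | None,
    annotation: CodingAnnotation,
    cnv_effect: bool = True,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Genes x samples TPM matrix plus a sample->role map.

    Per-gene baselines are log-normal; per-sample noise is multiplicative
    log-normal.  Genes overlapping a driver-specific CNV get the expected
    dosage fold (carrier copies / 2) in carriers only; non-driver-specific
    CNVs scale both groups alike.
    """
    if len(annotation) == 0:
        raise ValueError("expression simulation needs at least one gene")
    ec = config.expression
    if ec.n_carrier_samples < 1 or ec.n_noncarrier_samples < 1:
        raise ValueError("each expression group needs at least one sample")
    rng = _stream(config, "expression")
    genes = annotation.gene_intervals()
    gene_ids = sorted(genes)
    n_g = len(gene_ids)
    carriers = [f"carrier_{i + 1}" for i in range(ec.n_carrier_samples)]
    controls = [f"noncarrier_{i + 1}" for i in range(ec.n_noncarrier_samples)]
    cols = carriers + controls
    roles = {c: CARRIER for c in carriers} | {c: NONCARRIER for c in controls}

    baseline = np.exp(rng.normal(ec.baseline_log_mean, ec.baseline_log_sd, size=n_g))
    noise = np.exp(rng.normal(0.0, ec.noise_log_sd, size=(n_g, len(cols))))
    values = baseline[:, None] * noise

    events = truth.cnv_events if truth is not None else config.cnv_events
    if cnv_effect:
        for gi, gid in enumerate(gene_ids):
            a, b = genes[gid]
            for ev in events:
                if min(b, ev.end) - max(a, ev.start) <= 0:
                    continue
                fold = ev.copy_number / 2.0
                if ev.driver_specific:
                    values[gi, : len(carriers)] *= fold
                else:
                    values[gi, :] *= fold
    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=cols)
    return df, roles


# ---------------------------------------------------------------------------
# full-study emission
# ---------------------------------------------------------------------------

def simulate_study(config: SimulationConfig, outdir) -> dict[str, str]:
    """Run every generator and write the complete study to *outdir*.

    Returns a manifest of the files written.
    """
    os.makedirs(outdir, exist_ok=True)
    ref, annotation = simulate_reference_and_genes(config)
    cohort = simulate_cohort(config, ref, annotation)
    coverage = simulate_coverage_tracks(config, cohort.truth)
    expr, roles = simulate_expression_matrix(config, cohort.truth, annotation)

    paths = {
        "reference": os.path.join(outdir, "reference.fa"),
        "annotation": os.path.join(outdir, "annotation.gff3"),
        "vcf": os.path.join(outdir, "cohort.vcf"),
        "sample_sheet": os.path.join(outdir, "samples.tsv"),
        "coverage": os.path.join(outdir, "coverage.tsv"),
        "expression": os.path.join(outdir, "expression.tsv"),
        "expression_roles": os.path.join(outdir, "expression_samples.tsv"),
        "truth_dir": os.path.join(outdir, "truth"),
    }
    write_fasta(paths["reference"], config.chrom, ref)
    annotation.write_gff3(paths["annotation"], chrom_length=config.chrom_length)
    write_vcf(cohort.table, paths["vcf"], contig_length=config.chrom_length)
    write_sample_sheet(paths["sample_sheet"], cohort.table.samples)
    coverage.to_csv(paths["coverage"], sep="\t", index=False)
    expr.to_csv(paths["expression"], sep="\t")
    with open(paths["expression_roles"], "w") as fh:
        fh.write("sample\trole\n")
        for s, r in roles.items():
            fh.write(f"{s}\t{r}\n")
    cohort.truth.write(paths["truth_dir"], config.chrom)
    return paths


def reconstruct_haplotype(ref: np.ndarray, hap: dict[int, int]) -> np.ndarray:
    """Apply a sparse haplotype to the reference (used by conservation checks)."""
    seq = ref.copy()
    for q, v in hap.items():
        seq[q] = v
    return seq
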