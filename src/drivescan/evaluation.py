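"""Recovery benchmarks: the package analysing its own simulator's truth.

Each function runs one end-to-end experiment — simulate a study under known
conditions, push it through the analysis stages, and score the result
against the simulator's truth tables or an analytic oracle.  They back both
the acceptance-style tests and the reproduction script, so the numbers they
return are always recomputed from scratch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from . import coding as coding_mod
from .cnv import (
    contrast_cnv_calls,
    coverage_to_copy_number_calls,
    CoverageTrack,
    pool_tracks,
    union_cnv_mask,
)
from .config import SimulationConfig, default_config, expression_benchmark_config
from .expression import (
    classify_genes_by_context,
    compare_divergence_groups,
    gene_divergence_track,
)
from .hetscan import carrier_control_ratio_track, het_density_track, mean_ratio_in
from .intervals import merge_intervals, overlap_length, total_length
from .phylo import classify_windows, neighbor_joining_tree
from .pseudot import build_consensus_sequences, extract_pseudo_haplotype
from .simulate import (
    simulate_cohort,
    simulate_coverage_tracks,
    simulate_expression_matrix,
    simulate_reference_and_genes,
)
from .variants import apply_filter_procedure


# ---------------------------------------------------------------------------
# shared study construction
# ---------------------------------------------------------------------------

@dataclass
class StudyArtifacts:
    config: SimulationConfig
    reference: np.ndarray
    annotation: object
    cohort: object
    filtered: object
    pseudo_sets: list
    consensus: object
    window_classes: object


def build_study(cfg: SimulationConfig, classify: bool = True) -> StudyArtifacts:
    ref, ann = simulate_reference_and_genes(cfg)
    cohort = simulate_cohort(cfg, ref, ann)
    filtered, _ = apply_filter_procedure(cohort.table, 1)
    sets = [
        extract_pseudo_haplotype(filtered, c)
        for c in filtered.samples_with_role("carrier")
    ]
    others = filtered.samples_with_role("noncarrier") + filtered.samples_with_role(
        "outgroup"
    )
    consensus = build_consensus_sequences(
        ref, cfg.driver_region, pseudo_sets=sets, table=filtered, table_samples=others
    )
    frame = None
    if classify:
        frame = classify_windows(consensus, cohort.truth.windows, list(cfg.populations))
    return StudyArtifacts(cfg, ref, ann, cohort, filtered, sets, consensus, frame)


def build_default_studies(seeds, classify: bool = True) -> list[StudyArtifacts]:
    return [build_study(default_config(seed=int(s)), classify=classify) for s in seeds]


# ---------------------------------------------------------------------------
# 1. neighbor-joining oracle
# ---------------------------------------------------------------------------

def random_additive_tree(rng: np.random.Generator, n: int) -> TreeNode:
    nodes = [TreeNode(name=f"t{i}", length=round(rng.uniform(0.1, 2.0), 4)) for i in range(n)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(TreeNode(children=[a, b], length=round(rng.uniform(0.1, 2.0), 4)))
    nodes[0].length = None
    return nodes[0]


def nj_topology_recovery(n_matrices: int = 100, seed: int = 0, max_taxa: int = 8) -> float:
    """% of random additive matrices (n <= max_taxa) whose generating
    topology is recovered exactly (unrooted RF distance 0)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_matrices):
        n = int(rng.integers(4, max_taxa + 1))
        true = random_additive_tree(rng, n)
        est = neighbor_joining_tree(true.tip_tip_distances())
        hits += est.compare_rfd(true, rooted=False) == 0.0
    return 100.0 * hits / n_matrices


# ---------------------------------------------------------------------------
# 2. effect-classifier enumeration
# ---------------------------------------------------------------------------

# frozen copy of the standard nuclear code (the enumeration oracle)
_ORACLE_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def effect_classifier_agreement() -> tuple[float, int]:
    """% agreement with codon-table enumeration over all 64 x 9 single-base
    codon changes on both strands; also returns the number of cases."""
    bases = "ACGT"
    agree = total = 0
    for c0 in bases:
        for c1 in bases:
            for c2 in bases:
                codon = c0 + c1 + c2
                for strand in "+-":
                    genomic = (
                        codon if strand == "+" else "".join(_COMP[b] for b in reversed(codon))
                    )
                    ref = "CC" + genomic + "CC"
                    ann = coding_mod.CodingAnnotation(
                        [coding_mod.CdsSegment("g", 2, 5, strand)]
                    )
                    for ci in range(3):
                        gpos0 = 2 + ci if strand == "+" else 4 - ci
                        ref_base = ref[gpos0]
                        for alt_base in bases.replace(ref_base, ""):
                            got = coding_mod.classify_snp_effect(
                                gpos0 + 1, ref_base, alt_base, ann, ref
                            )
                            alt_codon = (
                                codon[:ci]
                                + (alt_base if strand == "+" else _COMP[alt_base])
                                + codon[ci + 1:]
                            )
                            want = (
                                "synonymous"
                                if _ORACLE_CODE[codon] == _ORACLE_CODE[alt_codon]
                                else "nonsynonymous"
                            )
                            agree += got == want
                            total += 1
    return 100.0 * agree / total, total


# ---------------------------------------------------------------------------
# 3. Yates chi-square suite
# ---------------------------------------------------------------------------

YATES_SUITE = [
    [[10, 10], [10, 10]], [[30, 10], [10, 30]], [[1, 0], [0, 1]],
    [[12, 7], [5, 21]], [[100, 1], [1, 100]], [[3, 3], [3, 4]],
    [[50, 60], [70, 20]], [[2, 9], [11, 4]], [[8, 8], [9, 7]],
    [[1, 2], [3, 4]], [[40, 2], [2, 40]], [[15, 0], [3, 12]],
    [[7, 13], [13, 7]], [[33, 44], [55, 22]], [[5, 5], [5, 6]],
    [[0, 10], [10, 0]], [[6, 1], [1, 6]], [[25, 25], [24, 26]],
    [[9, 2], [2, 9]], [[18, 3], [4, 17]], [[60, 40], [35, 65]],
    [[2, 2], [2, 3]], [[14, 6], [7, 13]],
]


def yates_suite_errors() -> tuple[float, float, int]:
    """Max |error| of the statistic vs. the written-out formula and of the
    p-value vs. the erfc closed form of the chi-square(1) tail."""
    max_stat_err = max_p_err = 0.0
    for table in YATES_SUITE:
        obs = np.asarray(table, dtype=float)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        manual = sum(
            max(abs(obs[i, j] - expected[i, j]) - 0.5, 0.0) ** 2 / expected[i, j]
            for i in range(2)
            for j in range(2)
        )
        stat, p = coding_mod.yates_chi_square(table)
        max_stat_err = max(max_stat_err, abs(stat - manual))
        max_p_err = max(max_p_err, abs(p - math.erfc(math.sqrt(stat / 2.0))))
    return max_stat_err, max_p_err, len(YATES_SUITE)


# ---------------------------------------------------------------------------
# 4. pseudo-haplotype recovery
# ---------------------------------------------------------------------------

def pseudo_haplotype_recovery(studies: list[StudyArtifacts]) -> dict[str, float]:
    """Per-carrier recall/precision of extracted driver SNPs against truth,
    evaluated inside the driver region (where driver truth is defined)."""
    recalls, precisions = [], []
    for st in studies:
        a, b = st.config.driver_region
        for ps in st.pseudo_sets:
            want = set(st.cohort.truth.driver_snps[ps.carrier])
            got = {p for p in ps.snps if a <= p - 1 < b}
            tp = len(got & want)
            recalls.append(tp / len(want))
            precisions.append(tp / len(got))
    return {
        "recall_min": 100.0 * min(recalls),
        "recall_mean": 100.0 * float(np.mean(recalls)),
        "precision_min": 100.0 * min(precisions),
        "precision_mean": 100.0 * float(np.mean(precisions)),
        "n_carriers": len(recalls),
    }


# ---------------------------------------------------------------------------
# 5. window-class recovery
# ---------------------------------------------------------------------------

def window_class_recovery(studies: list[StudyArtifacts]) -> dict[str, float]:
    accs = []
    for st in studies:
        for pop in st.config.populations:
            truth = st.cohort.truth.window_true_class[pop]
            pred = st.window_classes[pop].to_numpy()
            accs.append(float((pred == truth).mean()))
    return {
        "accuracy_min": 100.0 * min(accs),
        "accuracy_mean": 100.0 * float(np.mean(accs)),
        "n": len(accs),
    }


# ---------------------------------------------------------------------------
# 6. coding-deterioration recovery
# ---------------------------------------------------------------------------

def _truth_strata(cohort, positions: np.ndarray, focal: str) -> np.ndarray:
    starts = np.array([w[0] for w in cohort.truth.windows])
    ends = np.array([w[1] for w in cohort.truth.windows])
    cls = cohort.truth.window_true_class[focal]
    pos0 = np.asarray(positions) - 1
    w = np.searchsorted(starts, pos0, side="right") - 1
    ok = (w >= 0) & (pos0 < ends[np.clip(w, 0, len(ends) - 1)])
    out = np.full(len(positions), "out", dtype=object)
    out[ok] = cls[w[ok]]
    return out


def _driver_spectrum(seed: int, excess: float, focal: str = "dom"):
    cfg = default_config(seed=seed)
    cfg.driver_ns_excess = excess
    st = build_study(cfg, classify=False)
    table = st.filtered
    sets = [s for s in st.pseudo_sets if s.carrier.startswith(focal)]
    idx = np.nonzero(table.is_biallelic_snp())[0]
    effects = coding_mod.classify_effects(
        table.pos[idx], table.ref[idx], table.alt[idx], st.annotation, st.reference
    )
    counts = np.array([sum(int(table.pos[i]) in ps.snps for ps in sets) for i in idx])
    strata = _truth_strata(st.cohort, table.pos[idx], focal)
    fixed = len(sets)
    sp_c = coding_mod.ns_s_spectrum(
        effects, counts, fixed, strata=strata, stratum="C",
        class_bounds=coding_mod.per_count_bounds(fixed),
    )
    ns_r = s_r = 0
    for stm in ("A", "B"):
        sp = coding_mod.ns_s_spectrum(
            effects, counts, fixed, strata=strata, stratum=stm,
            class_bounds=coding_mod.per_count_bounds(fixed),
        )
        ns_r += sp.ns.sum()
        s_r += sp.s.sum()
    fixed_ratio = sp_c.ratio(fixed)
    _, p = coding_mod.yates_chi_square(
        [[int(sp_c.ns.sum()), int(sp_c.s.sum())], [int(ns_r), int(s_r)]]
    )
    return fixed_ratio, p


def deterioration_recovery(n_pairs: int = 20, seed0: int = 100) -> dict[str, float]:
    """Paired simulations at driver_ns_excess 3 vs 1: how often the
    nonrecombined fixed-class NS/S is higher under 3, and the power of the
    nonrecombined-vs-recombined chi-square contrast at excess 3."""
    higher = significant = 0
    for k in range(n_pairs):
        r3, p3 = _driver_spectrum(seed0 + k, 3.0)
        r1, _ = _driver_spectrum(seed0 + k, 1.0)
        higher += r3 > r1
        significant += p3 < 0.05
    return {
        "sign_recovery_pct": 100.0 * higher / n_pairs,
        "chi2_power_pct": 100.0 * significant / n_pairs,
        "n_pairs": n_pairs,
    }


# ---------------------------------------------------------------------------
# 7. divergence-scan contrast
# ---------------------------------------------------------------------------

def divergence_scan_contrast(
    studies: list[StudyArtifacts], window_bp: int = 50_000
) -> dict[str, float]:
    inside, outside, perm_extreme = [], [], []
    for st in studies:
        cfg = st.config
        table = st.filtered
        carriers = table.samples_with_role("carrier", "dom")
        controls = table.samples_with_role("noncarrier", "dom")
        ca = het_density_track(table, carriers, cfg.chrom_length, window_bp=window_bp)
        co = het_density_track(table, controls, cfg.chrom_length, window_bp=window_bp)
        df = carrier_control_ratio_track(ca, co)
        a, b = cfg.driver_region
        inside.append(mean_ratio_in(df, (a, b)))
        flanks = [mean_ratio_in(df, (0, a)), mean_ratio_in(df, (b, cfg.chrom_length))]
        outside.append(float(np.nanmean(flanks)))
        # permutation null: split the full noncarrier panel into two halves,
        # stratified by population so both groups average over the three
        # independent subspecies genealogies
        g1_names: list[str] = []
        g2_names: list[str] = []
        for pop in cfg.populations:
            ncs = table.samples_with_role("noncarrier", pop)
            half = len(ncs) // 2
            g1_names += ncs[:half]
            g2_names += ncs[half:]
        g1 = het_density_track(table, g1_names, cfg.chrom_length, window_bp=window_bp)
        g2 = het_density_track(table, g2_names, cfg.chrom_length, window_bp=window_bp)
        pr = carrier_control_ratio_track(g1, g2)["ratio"].dropna()
        perm_extreme.append(float(max(pr.max(), 1.0 / pr.min())))
    return {
        "driver_region_ratio_mean": float(np.mean(inside)),
        "flank_ratio_mean": float(np.mean(outside)),
        "flank_ratio_max": float(np.max(outside)),
        "permutation_ratio_extreme": float(np.max(perm_extreme)),
        "n_seeds": len(studies),
    }


# ---------------------------------------------------------------------------
# 8. CNV mask recovery
# ---------------------------------------------------------------------------

def cnv_mask_recovery(seeds) -> dict[str, float]:
    captured_fracs, fp_fracs = [], []
    for s in seeds:
        cfg = default_config(seed=int(s))
        truth = merge_intervals([(c.start, c.end) for c in cfg.cnv_events])
        cov = simulate_coverage_tracks(cfg)
        calls = []
        tracks = {}
        for sample, sub in cov.groupby("sample"):
            sub = sub.sort_values("window_start")
            t = CoverageTrack(
                str(sample), cfg.chrom, cfg.coverage_window,
                sub["window_start"].to_numpy(), sub["depth"].to_numpy(),
            )
            tracks[str(sample)] = (t, sub["role"].iloc[0], sub["population"].iloc[0])
            calls.extend(coverage_to_copy_number_calls(t))
        for pop in cfg.populations:
            carr = [t for t, r, p in tracks.values() if r == "carrier" and p == pop]
            ctrl = [t for t, r, p in tracks.values() if r == "noncarrier" and p == pop]
            cc, _ = contrast_cnv_calls(pool_tracks(carr), pool_tracks(ctrl))
            calls.extend(cc)
        mask = union_cnv_mask(calls)
        truth_bp = total_length(truth)
        captured = sum(overlap_length(iv, mask) for iv in truth)
        mask_bp = total_length(mask)
        captured_fracs.append(captured / truth_bp)
        fp_fracs.append((mask_bp - captured) / mask_bp if mask_bp else 0.0)
    return {
        "captured_pct_min": 100.0 * min(captured_fracs),
        "captured_pct_mean": 100.0 * float(np.mean(captured_fracs)),
        "false_positive_pct_max": 100.0 * max(fp_fracs),
        "n_seeds": len(list(seeds)),
    }


# ---------------------------------------------------------------------------
# 9. expression-contrast recovery
# ---------------------------------------------------------------------------

def expression_contrast_recovery(
    n_seeds: int = 20, n_null: int = 50, seed0: int = 0
) -> dict[str, float]:
    import pandas as pd
    from scipy import stats as sps

    base = expression_benchmark_config(seed=seed0)
    ref, ann = simulate_reference_and_genes(base)
    intervals = ann.gene_intervals()
    mask = [(c.start, c.end) for c in base.cnv_events]
    dummy_classes = pd.DataFrame({"start": [0], "end": [0], "dom": ["C"]})
    labels = classify_genes_by_context(intervals, dummy_classes, mask, "dom")

    def contrast(seed, effect):
        cfg = expression_benchmark_config(seed=seed)
        matrix, roles = simulate_expression_matrix(cfg, None, ann, cnv_effect=effect)
        res = gene_divergence_track(matrix, roles, intervals)
        con = compare_divergence_groups(res.per_gene, labels)
        return con[con.contrast == "cnv_vs_other"].iloc[0]

    higher = significant = 0
    n_cnv = n_other = 0
    for k in range(n_seeds):
        row = contrast(seed0 + k, True)
        higher += row["median_a"] > row["median_b"]
        significant += row["p_value"] < 0.01
        n_cnv, n_other = int(row["n_a"]), int(row["n_b"])
    null_p = [float(contrast(seed0 + 1000 + k, False)["p_value"]) for k in range(n_null)]
    ks = sps.kstest(null_p, "uniform")
    return {
        "median_higher_pct": 100.0 * higher / n_seeds,
        "rank_test_power_pct": 100.0 * significant / n_seeds,
        "null_ks_p": float(ks.pvalue),
        "genes_cnv": n_cnv,
        "genes_other": n_other,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# 10. filter-suite fixture
# ---------------------------------------------------------------------------

FILTER_FIXTURE_EXPECTED = {
    1: {100, 300, 350, 400, 450, 500, 1000, 1201, 1300},
    2: {100, 300, 400, 450, 500, 1000, 1201, 1300},
    3: {100, 300, 400, 450, 1000, 1201, 1300},
    "mask": {100, 300, 350, 400, 450, 500, 1201, 1300},
    "nulled_proc2": {(300, "B")},
    # site 500 is dropped at procedure 3 (its only non-ref call lost its AD),
    # so its nulled genotype no longer appears in the surviving table
    "nulled_proc3": {(300, "B"), (400, "B")},
}


def filter_fixture_agreement(vcf_path, sheet_path, mask_path) -> tuple[float, int]:
    """Fraction of filter-suite checks (survivor sets and per-sample
    nulling) that match the hand-derived expectation."""
    from .intervals import read_bed
    from .variants import MISSING, load_cohort_vcf

    table = load_cohort_vcf(vcf_path, sheet_path)
    mask = read_bed(mask_path)
    checks = []
    tables = {}
    for proc in (1, 2, 3):
        out, _ = apply_filter_procedure(table, proc)
        tables[proc] = out
        checks.append(set(out.pos.tolist()) == FILTER_FIXTURE_EXPECTED[proc])
    masked, _ = apply_filter_procedure(table, 1, cnv_mask=mask)
    checks.append(set(masked.pos.tolist()) == FILTER_FIXTURE_EXPECTED["mask"])
    for proc, key in ((2, "nulled_proc2"), (3, "nulled_proc3")):
        out = tables[proc]
        nulled = {
            (int(out.pos[i]), out.samples[j].name)
            for i in range(out.n_sites)
            for j in range(out.n_samples)
            if out.gt[i, j] == MISSING
        }
        checks.append(nulled == FILTER_FIXTURE_EXPECTED[key])
    return 100.0 * sum(checks) / len(checks), len(checks)
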