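"""End-to-end orchestration of the analysis stages on a run directory.

Stage order mirrors the analysis design: simulate (optional) -> filter ->
cnv -> mask -> hetscan -> pseudot -> phylo -> nss -> expr.  Each stage's
outputs land under the run directory; a JSON manifest records inputs,
parameters, seed and per-stage status.  A stage failure aborts the run with
the stage name attached; partial outputs are retained.  The expression
stage is skipped with a warning when no expression matrix is available.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cnv as cnv_mod
from . import coding as coding_mod
from . import expression as expr_mod
from . import hetscan as hetscan_mod
from . import phylo as phylo_mod
from . import pseudot as pseudot_mod
from .config import CARRIER, NONCARRIER, SimulationConfig
from .intervals import write_bed
from .simulate import (
    WINDOW_SIZE,
    simulate_cohort,
    simulate_reference_and_genes,
    simulate_study,
)
from .variants import apply_filter_procedure, write_vcf

logger = logging.getLogger("drivescan")


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    out_dir: str = "drivescan_run"
    filter_procedure: int = 1
    distance_model: str = phylo_mod.P_DISTANCE
    segment_size: int = 500_000
    hetscan_window_bp: int = 50_000
    min_variant_columns: int = 1
    run_expression: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        sim = SimulationConfig.from_dict(d.pop("simulation", {}))
        return cls(simulation=sim, **d)


@dataclass
class PipelineResult:
    manifest: dict
    out_dir: str


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    os.makedirs(config.out_dir, exist_ok=True)
    cfg = config.simulation
    manifest = {
        "seed": cfg.seed,
        "parameters": {
            "filter_procedure": config.filter_procedure,
            "distance_model": config.distance_model,
            "segment_size": config.segment_size,
            "hetscan_window_bp": config.hetscan_window_bp,
        },
        "stages": [],
    }
    state: dict = {}

    stages = [
        ("simulate", _stage_simulate),
        ("filter", _stage_filter),
        ("cnv", _stage_cnv),
        ("mask", _stage_mask),
        ("hetscan", _stage_hetscan),
        ("pseudot", _stage_pseudot),
        ("phylo", _stage_phylo),
        ("nss", _stage_nss),
        ("expr", _stage_expr),
    ]
    for name, fn in stages:
        entry = {"stage": name, "status": "ok", "outputs": []}
        try:
            outputs = fn(config, state)
            entry["outputs"] = outputs or []
            if outputs is None:
                entry["status"] = "skipped"
                logger.warning("stage %s skipped", name)
        except Exception as exc:
            entry["status"] = f"failed: {exc}"
            manifest["stages"].append(entry)
            _write_manifest(config.out_dir, manifest)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"].append(entry)
        logger.info("stage %s: %s", name, entry["status"])

    _write_manifest(config.out_dir, manifest)
    return PipelineResult(manifest, config.out_dir)


def _write_manifest(out_dir, manifest) -> None:
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _stage_simulate(config: PipelineConfig, state: dict):
    cfg = config.simulation
    ref, annotation = simulate_reference_and_genes(cfg)
    cohort = simulate_cohort(cfg, ref, annotation)
    sim_dir = os.path.join(config.out_dir, "simulated")
    paths = simulate_study(cfg, sim_dir)
    state.update(reference=ref, annotation=annotation, cohort=cohort)
    return list(paths.values())


def _stage_filter(config: PipelineConfig, state: dict):
    cohort = state["cohort"]
    table, log = apply_filter_procedure(cohort.table, config.filter_procedure)
    path = os.path.join(config.out_dir, "filtered.vcf")
    write_vcf(table, path, contig_length=config.simulation.chrom_length)
    log.write_tsv(os.path.join(config.out_dir, "filter_log.tsv"))
    state["filtered"] = table
    return [path]


def _stage_cnv(config: PipelineConfig, state: dict):
    from .simulate import simulate_coverage_tracks

    cfg = config.simulation
    coverage = simulate_coverage_tracks(cfg, state["cohort"].truth)
    calls = []
    tracks = {}
    for sample, sub in coverage.groupby("sample"):
        sub = sub.sort_values("window_start")
        track = cnv_mod.CoverageTrack(
            str(sample), cfg.chrom, cfg.coverage_window,
            sub["window_start"].to_numpy(), sub["depth"].to_numpy(),
        )
        tracks[str(sample)] = (track, sub["role"].iloc[0], sub["population"].iloc[0])
        calls.extend(cnv_mod.coverage_to_copy_number_calls(track))
    for pop in cfg.populations:
        carr = [t for t, role, p in tracks.values() if role == CARRIER and p == pop]
        ctrl = [t for t, role, p in tracks.values() if role == NONCARRIER and p == pop]
        if carr and ctrl:
            pooled_c = cnv_mod.pool_tracks(carr, f"{pop}_carriers")
            pooled_n = cnv_mod.pool_tracks(ctrl, f"{pop}_controls")
            contrast, _ = cnv_mod.contrast_cnv_calls(pooled_c, pooled_n)
            calls.extend(contrast)
    mask = cnv_mod.union_cnv_mask(calls)
    calls_path = os.path.join(config.out_dir, "cnv_calls.tsv")
    mask_path = os.path.join(config.out_dir, "cnv_mask.bed")
    cnv_mod.calls_to_frame(calls).to_csv(calls_path, sep="\t", index=False)
    write_bed(mask_path, mask, cfg.chrom)
    state["cnv_mask"] = mask
    return [calls_path, mask_path]


def _stage_mask(config: PipelineConfig, state: dict):
    from .variants import mask_intervals

    table, log = mask_intervals(state["filtered"], state["cnv_mask"])
    state["masked"] = table
    log.write_tsv(os.path.join(config.out_dir, "mask_log.tsv"))
    return [os.path.join(config.out_dir, "mask_log.tsv")]


def _stage_hetscan(config: PipelineConfig, state: dict):
    cfg = config.simulation
    table = state["filtered"]  # unmasked, as the divergence figure uses raw PASS SNPs
    carriers = table.samples_with_role(CARRIER)
    controls = table.samples_with_role(NONCARRIER)
    ca = hetscan_mod.het_density_track(
        table, carriers, cfg.chrom_length, window_bp=config.hetscan_window_bp
    )
    co = hetscan_mod.het_density_track(
        table, controls, cfg.chrom_length, window_bp=config.hetscan_window_bp
    )
    ratio = hetscan_mod.carrier_control_ratio_track(ca, co)
    path = os.path.join(config.out_dir, "het_ratio.tsv")
    ratio.to_csv(path, sep="\t", index=False, na_rep="NA")
    state["het_ratio"] = ratio
    return [path]


def _stage_pseudot(config: PipelineConfig, state: dict):
    table = state["masked"]
    sets = [
        pseudot_mod.extract_pseudo_haplotype(table, c)
        for c in table.samples_with_role(CARRIER)
    ]
    path = os.path.join(config.out_dir, "pseudo_haplotypes.tsv")
    with open(path, "w") as fh:
        fh.write("carrier\tpos\tref\talt\n")
        for ps in sets:
            for p in sorted(ps.snps):
                r, a = ps.snps[p]
                fh.write(f"{ps.carrier}\t{p}\t{r}\t{a}\n")
    # per-carrier single-sample VCFs of the driver-attributed SNPs
    vcf_dir = os.path.join(config.out_dir, "pseudo_vcf")
    os.makedirs(vcf_dir, exist_ok=True)
    outputs = [path]
    for ps in sets:
        j = table.sample_index(ps.carrier)
        keep = np.isin(table.pos, sorted(ps.snps))
        sub = table.subset_sites(keep)
        sub = type(sub)(
            chrom=sub.chrom, pos=sub.pos, ref=sub.ref, alt=sub.alt,
            filter=sub.filter, gt=sub.gt[:, [j]], dp=sub.dp[:, [j]],
            ad_ref=sub.ad_ref[:, [j]], ad_alt=sub.ad_alt[:, [j]],
            samples=[table.samples[j]],
            allele_codes=sub.allele_codes[:, [j]] if sub.allele_codes is not None else None,
        )
        p_vcf = os.path.join(vcf_dir, f"{ps.carrier}.vcf")
        write_vcf(sub, p_vcf, contig_length=config.simulation.chrom_length)
        outputs.append(p_vcf)
    state["pseudo_sets"] = sets
    return outputs


def _stage_phylo(config: PipelineConfig, state: dict):
    cfg = config.simulation
    table = state["masked"]
    others = table.samples_with_role(NONCARRIER) + table.samples_with_role("outgroup")
    consensus = pseudot_mod.build_consensus_sequences(
        state["reference"], cfg.driver_region,
        pseudo_sets=state["pseudo_sets"], table=table, table_samples=others,
    )
    a, b = cfg.driver_region
    windows = [(s, min(s + WINDOW_SIZE, b)) for s in range(a, b, WINDOW_SIZE)]
    pops = list(cfg.populations)
    frame = phylo_mod.classify_windows(
        consensus, windows, pops, model=config.distance_model,
        min_variant_columns=config.min_variant_columns,
    )
    summary = phylo_mod.aggregate_window_classes(frame, pops, config.segment_size)
    class_path = os.path.join(config.out_dir, "window_classes.tsv")
    frame.drop(columns=["newick"]).to_csv(class_path, sep="\t", index=False)
    with open(os.path.join(config.out_dir, "window_trees.nwk"), "w") as fh:
        for _, row in frame.iterrows():
            fh.write(f"{row['start']}\t{row['end']}\t{row['newick']}\n")
    seg_path = os.path.join(config.out_dir, "segment_fractions.tsv")
    summary.segment_fractions.to_csv(seg_path, sep="\t", index=False)
    write_bed(os.path.join(config.out_dir, "no_recombination_windows.bed"),
              summary.all_c_windows, cfg.chrom)
    consensus.write_fasta(os.path.join(config.out_dir, "consensus.fa"))
    state["window_classes"] = frame
    state["class_summary"] = summary
    state["consensus"] = consensus
    # concatenated global tree over the no-recombination window set
    if summary.all_c_windows:
        alns = [phylo_mod.window_alignment(consensus, w) for w in summary.all_c_windows]
        concat = phylo_mod.concatenate_alignments(alns)
        _write_concatenated_fasta(
            os.path.join(config.out_dir, "no_recombination_concat.fa"),
            consensus, summary.all_c_windows,
        )
        dm = phylo_mod.distance_matrix(concat, model=config.distance_model)
        tree = phylo_mod.neighbor_joining_tree(dm)
        rooted = phylo_mod.root_at_outgroup(tree, concat.outgroup_tips())
        with open(os.path.join(config.out_dir, "global_tree.nwk"), "w") as fh:
            fh.write(str(rooted if rooted is not None else tree).strip() + "\n")
        # which subspecies roots the others, per tip class, over all-C windows
        trees = []
        for i in summary.all_c_indices:
            nwk = frame["newick"].iloc[i]
            if nwk:
                import io as _io

                from skbio import TreeNode

                trees.append(TreeNode.read(_io.StringIO(nwk)))
        if trees:
            tally = pd.DataFrame(
                {
                    tip_class: phylo_mod.outgroup_subspecies_tally(
                        trees, consensus.meta, pops, tip_class
                    )
                    for tip_class in ("driver", "noncarrier")
                }
            )
            tally.to_csv(
                os.path.join(config.out_dir, "outgroup_tally.tsv"), sep="\t",
                index_label="population",
            )
    else:
        logger.warning("no all-C windows; global concatenated tree skipped")
    return [class_path, seg_path]


def _write_concatenated_fasta(path, consensus, windows) -> None:
    a0, _ = consensus.interval
    with open(path, "w") as fh:
        for name in consensus.names:
            full = consensus.sequence(name)
            seq = "".join(full[w[0] - a0 : w[1] - a0] for w in windows)
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _stage_nss(config: PipelineConfig, state: dict):
    cfg = config.simulation
    table = state["masked"]
    annotation = state["annotation"]
    ref = state["reference"]
    frame = state["window_classes"]
    pops = list(cfg.populations)
    focal = pops[0]

    snp = table.is_biallelic_snp()
    idx = np.nonzero(snp)[0]
    effects = coding_mod.classify_effects(
        table.pos[idx], table.ref[idx], table.alt[idx], annotation, ref
    )
    strata = _site_strata(table.pos[idx], frame, focal)

    spectra = []
    # pseudo-driver spectrum of the focal population
    sets = [s for s in state["pseudo_sets"] if s.carrier.startswith(focal)]
    if sets:
        counts = np.array(
            [sum(int(table.pos[i]) in ps.snps for ps in sets) for i in idx]
        )
        bounds = (
            coding_mod.frequency_class_bounds(len(sets))
            if len(sets) % 4 == 0
            else coding_mod.per_count_bounds(len(sets))
        )
        for stratum in ["all", "C", "B", "A"]:
            spectra.append(
                coding_mod.ns_s_spectrum(
                    effects, counts, len(sets), group=f"t-{focal}",
                    strata=strata, stratum=stratum, class_bounds=bounds,
                ).to_frame()
            )
    # noncarrier and outgroup spectra
    for group_name, role, pop in ((focal, NONCARRIER, focal), ("outgroup", "outgroup", None)):
        names = table.samples_with_role(role, pop)
        cols = [table.sample_index(s) for s in names]
        counts = np.array(
            [coding_mod.site_frequency_counts(table.gt[i], cols) for i in idx]
        )
        for stratum in ["all", "C", "B", "A"]:
            spectra.append(
                coding_mod.ns_s_spectrum(
                    effects, counts, 2 * len(names), group=group_name,
                    strata=strata, stratum=stratum,
                ).to_frame()
            )
    path = os.path.join(config.out_dir, "ns_s_spectra.tsv")
    spectrum_frame = pd.concat(spectra, ignore_index=True)
    spectrum_frame.to_csv(path, sep="\t", index=False)

    # Yates chi-square contrasts: nonrecombined vs recombined, per group
    totals = (
        spectrum_frame.groupby(["group", "stratum"])[["ns", "s"]].sum().reset_index()
    )
    tests = []
    for group, sub in totals.groupby("group"):
        by = {r["stratum"]: (int(r["ns"]), int(r["s"])) for _, r in sub.iterrows()}
        if "C" not in by:
            continue
        ns_r = sum(by.get(k, (0, 0))[0] for k in ("A", "B"))
        s_r = sum(by.get(k, (0, 0))[1] for k in ("A", "B"))
        rec = {
            "group": group,
            "contrast": "nonrecombined_vs_recombined",
            "ns_nonrec": by["C"][0], "s_nonrec": by["C"][1],
            "ns_recomb": ns_r, "s_recomb": s_r,
            "chi2": np.nan, "p_value": np.nan,
        }
        try:
            rec["chi2"], rec["p_value"] = coding_mod.yates_chi_square(
                [[by["C"][0], by["C"][1]], [ns_r, s_r]]
            )
        except ValueError:
            pass  # a zero margin: contrast undefined, left as NaN
        tests.append(rec)
    tests_path = os.path.join(config.out_dir, "ns_s_tests.tsv")
    pd.DataFrame(tests).to_csv(tests_path, sep="\t", index=False)
    return [path, tests_path]


def _site_strata(positions, class_frame: pd.DataFrame, focal: str) -> np.ndarray:
    strata = np.full(len(positions), "U", dtype=object)
    starts = class_frame["start"].to_numpy()
    ends = class_frame["end"].to_numpy()
    classes = class_frame[focal].to_numpy()
    pos0 = np.asarray(positions) - 1
    w = np.searchsorted(starts, pos0, side="right") - 1
    ok = (w >= 0) & (pos0 < ends[np.clip(w, 0, len(ends) - 1)])
    strata[ok] = classes[w[ok]]
    return strata


def _stage_expr(config: PipelineConfig, state: dict):
    if not config.run_expression:
        return None
    from .simulate import simulate_expression_matrix

    cfg = config.simulation
    annotation = state["annotation"]
    if len(annotation) == 0:
        return None
    matrix, roles = simulate_expression_matrix(cfg, state["cohort"].truth, annotation)
    intervals = annotation.gene_intervals()
    result = expr_mod.gene_divergence_track(matrix, roles, intervals)
    labels = expr_mod.classify_genes_by_context(
        intervals, state["window_classes"], state["cnv_mask"], list(cfg.populations)[0]
    )
    contrasts = expr_mod.compare_divergence_groups(result.per_gene, labels)
    p1 = os.path.join(config.out_dir, "expression_divergence.tsv")
    p2 = os.path.join(config.out_dir, "expression_contrasts.tsv")
    result.per_gene.merge(labels, on=["gene_id", "start", "end"]).to_csv(p1, sep="\t", index=False)
    contrasts.to_csv(p2, sep="\t", index=False)
    return [p1, p2]
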