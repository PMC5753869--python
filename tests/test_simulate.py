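"""Synthetic-cohort generator: determinism, truth consistency, model limits."""

import numpy as np
import pytest

from conftest import small_config
from drivescan.config import ConversionTract
from drivescan.simulate import (
    reconstruct_haplotype,
    simulate_cohort,
    simulate_coverage_tracks,
    simulate_expression_matrix,
    simulate_reference_and_genes,
    simulate_study,
)
from drivescan.variants import HET, HOM_ALT


class TestReferenceAndGenes:
    def test_same_seed_gives_byte_identical_outputs(self, tmp_path):
        cfg = small_config(seed=3)
        p1, p2 = tmp_path / "a", tmp_path / "b"
        simulate_study(cfg, p1)
        simulate_study(cfg, p2)
        for name in ("reference.fa", "annotation.gff3", "cohort.vcf", "coverage.tsv",
                     "expression.tsv", "samples.tsv"):
            assert (p1 / name).read_bytes() == (p2 / name).read_bytes(), name

    def test_no_genes_yields_empty_annotation(self):
        cfg = small_config(n_genes=0)
        ref, ann = simulate_reference_and_genes(cfg)
        assert len(ref) == cfg.chrom_length
        assert len(ann) == 0

    def test_infeasible_gene_placement_raises(self):
        # total requested CDS (at the 30-bp minimum gene length) exceeds the
        # chromosome, so non-overlapping placement is impossible
        cfg = small_config(n_genes=20_000, cds_fraction=0.5)
        with pytest.raises(ValueError, match="place"):
            simulate_reference_and_genes(cfg)

    def test_genes_start_with_atg_and_avoid_inframe_stops(self):
        cfg = small_config(seed=11)
        ref, ann = simulate_reference_and_genes(cfg)
        stops = {"TAA", "TAG", "TGA"}
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for seg in ann.segments:
            geno = "".join("ACGT"[b] for b in ref[seg.start:seg.end])
            cds = geno if seg.strand == "+" else "".join(comp[b] for b in reversed(geno))
            assert cds[:3] == "ATG"
            assert len(cds) % 3 == 0
            assert not any(cds[i:i + 3] in stops for i in range(0, len(cds), 3))


class TestCohort:
    def test_zero_divergence_yields_no_variants(self):
        cfg = small_config(seed=1)
        for f in (
            "outgroup", "ingroup_radiation", "sister", "subspecies", "lineage",
            "driver", "driver_subspecies", "driver_carrier", "old_tract_post",
        ):
            setattr(cfg.branch_divergences, f, 0.0)
        ref, ann = simulate_reference_and_genes(cfg)
        cohort = simulate_cohort(cfg, ref, ann)
        assert cohort.table.n_sites == 0

    def test_no_tracts_means_all_windows_class_c(self):
        cfg = small_config(conversion_tracts=[])
        ref, ann = simulate_reference_and_genes(cfg)
        cohort = simulate_cohort(cfg, ref, ann)
        for pop, cls in cohort.truth.window_true_class.items():
            assert set(cls) == {"C"}

    def test_full_window_tract_is_class_a_for_its_population_only(self):
        cfg = small_config(
            conversion_tracts=[ConversionTract(100_000, 105_000, "very_recent", "dom")]
        )
        ref, ann = simulate_reference_and_genes(cfg)
        cohort = simulate_cohort(cfg, ref, ann)
        w = [i for i, (a, b) in enumerate(cohort.truth.windows) if a == 100_000][0]
        assert cohort.truth.window_true_class["dom"][w] == "A"
        assert cohort.truth.window_true_class["mus"][w] == "C"

    def test_driver_region_smaller_than_window_raises(self):
        cfg = small_config()
        cfg.driver_region = (50_000, 52_000)
        cfg.conversion_tracts = []
        ref, ann = simulate_reference_and_genes(cfg)
        with pytest.raises(ValueError, match="window"):
            simulate_cohort(cfg, ref, ann)

    def test_haplotypes_reconstruct_from_vcf_genotypes(self, small_run):
        """Conservation: reference + emitted genotypes reproduce each
        sample's two haplotype sequences exactly."""
        cohort = small_run.cohort
        table = cohort.table
        idx0 = table.pos - 1
        for name in list(cohort.haplotypes)[::5]:
            j = table.sample_index(name)
            for k in range(2):
                expected = reconstruct_haplotype(cohort.reference, cohort.haplotypes[name][k])
                rebuilt = cohort.reference.copy()
                codes = table.allele_codes[:, j, k]
                valid = codes >= 0
                rebuilt[idx0[valid]] = codes[valid].astype(np.uint8)
                assert np.array_equal(rebuilt, expected), (name, k)

    def test_truth_driver_snps_lie_in_driver_region(self, small_run):
        a, b = small_run.config.driver_region
        for snps in small_run.cohort.truth.driver_snps.values():
            assert all(a < p <= b for p in snps)

    def test_carrier_het_sites_are_driver_or_standard_variants(self, small_run):
        """Consistency: every carrier-het site in the driver region is a
        truth driver SNP or a standard-lineage variant, and standard
        variants private to the carrier (the contaminating class the
        subtraction cannot remove) stay below 10%."""
        cohort = small_run.cohort
        table = cohort.table
        a, b = small_run.config.driver_region
        nc_cols = [table.sample_index(s) for s in table.samples_with_role("noncarrier")]
        for carrier in table.samples_with_role("carrier"):
            j = table.sample_index(carrier)
            het = (table.gt[:, j] == HET) & (table.pos - 1 >= a) & (table.pos - 1 < b)
            idx = np.nonzero(het)[0]
            truth = cohort.truth.driver_snps[carrier]
            std = cohort.haplotypes[carrier][0]
            private_standard = 0
            for i in idx:
                p = int(table.pos[i])
                if p in truth:
                    continue
                assert (p - 1) in std  # must come from the standard homolog
                shared = (table.gt[i, nc_cols] > 0).any()
                if not shared:
                    private_standard += 1
            assert private_standard / max(len(idx), 1) < 0.10

    def test_ns_excess_monotonically_increases_fixed_ns(self):
        """More relaxed selection on the driver means more nonsynonymous
        driver substitutions, averaged over 20 seeds."""
        from drivescan.coding import classify_effects

        def ns_count(seed, excess):
            cfg = small_config(seed=seed, conversion_tracts=[])
            cfg.driver_ns_excess = excess
            ref, ann = simulate_reference_and_genes(cfg)
            cohort = simulate_cohort(cfg, ref, ann)
            carrier = "dom_c1"
            snps = cohort.truth.driver_snps[carrier]
            pos = np.array(sorted(snps))
            effects = classify_effects(
                pos, ["ACGT"[ref[p - 1]] for p in pos], [snps[p] for p in pos], ann, ref
            )
            return (effects == "nonsynonymous").sum()

        lo = [ns_count(s, 1.0) for s in range(20)]
        hi = [ns_count(s, 3.0) for s in range(20)]
        assert np.mean(hi) > np.mean(lo)
        assert np.mean([h > l for h, l in zip(hi, lo)]) >= 0.9


class TestCoverageAndExpression:
    def test_mean_depth_matches_model_without_cnvs(self):
        cfg = small_config(cnv_events=[], chrom_length=1_000_000)
        cov = simulate_coverage_tracks(cfg)
        # law of large numbers over >= 1e4 windows pooled across samples
        assert len(cov) >= 10_000
        assert abs(cov["depth"].mean() - cfg.coverage_mean) / cfg.coverage_mean < 0.02

    def test_homozygous_deletion_gives_zero_depth(self):
        cfg = small_config()
        cov = simulate_coverage_tracks(cfg)
        ev = [c for c in cfg.cnv_events if c.copy_number == 0][0]
        sub = cov[(cov.window_start >= ev.start) & (cov.window_start < ev.end)]
        assert (sub["depth"] == 0).all()

    def test_driver_specific_duplication_raises_carrier_depth_1point5x(self):
        cfg = small_config()
        cov = simulate_coverage_tracks(cfg)
        ev = [c for c in cfg.cnv_events if c.driver_specific and c.copy_number == 3][0]
        sub = cov[(cov.window_start >= ev.start) & (cov.window_start < ev.end)]
        ca = sub[sub.role == "carrier"]["depth"].mean()
        nc = sub[sub.role == "noncarrier"]["depth"].mean()
        assert ca / nc == pytest.approx(1.5, rel=0.05)

    def test_zero_coverage_mean_is_an_error(self):
        cfg = small_config(coverage_mean=0.0)
        with pytest.raises(ValueError, match="coverage_mean"):
            simulate_coverage_tracks(cfg)

    def test_noise_free_expression_matches_dosage(self):
        cfg = small_config()
        cfg.expression.noise_log_sd = 0.0
        ref, ann = simulate_reference_and_genes(cfg)
        matrix, roles = simulate_expression_matrix(cfg, None, ann)
        carriers = [s for s, r in roles.items() if r == "carrier"]
        controls = [s for s, r in roles.items() if r == "noncarrier"]
        dup = [c for c in cfg.cnv_events if c.driver_specific and c.copy_number == 3][0]
        intervals = ann.gene_intervals()
        for gid, (a, b) in intervals.items():
            ratio = matrix.loc[gid, carriers].mean() / matrix.loc[gid, controls].mean()
            overlaps_dup = min(b, dup.end) - max(a, dup.start) > 0
            overlaps_any_driver = any(
                c.driver_specific and min(b, c.end) - max(a, c.start) > 0
                for c in cfg.cnv_events
            )
            if overlaps_dup:
                assert ratio == pytest.approx(1.5)
            elif not overlaps_any_driver:
                assert ratio == pytest.approx(1.0)

    def test_empty_expression_group_is_an_error(self):
        cfg = small_config()
        cfg.expression.n_carrier_samples = 0
        ref, ann = simulate_reference_and_genes(cfg)
        with pytest.raises(ValueError, match="group"):
            simulate_expression_matrix(cfg, None, ann)


def test_carriers_are_heterozygous_inside_region_only(small_run):
    """Carriers pair a driver with a standard haplotype inside the driver
    region and two standard haplotypes outside, so their excess
    heterozygosity is confined to the region."""
    table = small_run.cohort.table
    a, b = small_run.config.driver_region
    inside = (table.pos - 1 >= a) & (table.pos - 1 < b)
    j = table.sample_index("dom_c1")
    k = table.sample_index("dom_n1")
    het_c_in = (table.gt[inside, j] == HET).sum() / (b - a)
    het_n_in = (table.gt[inside, k] == HET).sum() / (b - a)
    out_len = small_run.config.chrom_length - (b - a)
    het_c_out = (table.gt[~inside, j] == HET).sum() / out_len
    assert het_c_in / het_n_in > 4
    assert het_c_out / max(het_n_in, 1e-9) < 3
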