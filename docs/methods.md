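# Methods

## The analysis problem

A meiotic driver such as the mouse *t*-haplotype occupies a large,
inversion-bound region of one chromosome and recombines only rarely with
its standard homolog. Homozygotes are inviable or sterile, so sequencing
data come from heterozygous carriers: every observation about the driver
chromosome is entangled with the carrier's standard chromosome.
`drivescan` implements the standard decomposition of this problem:

* heterozygous SNP density in carriers, normalized by noncarrier
  heterozygosity, measures driver–standard divergence along the chromosome;
* subtracting noncarrier variation from a carrier's SNP list attributes the
  remainder to the driver ("pseudo-driver haplotype");
* per-window phylogenies of pseudo-driver and noncarrier consensus
  sequences, rooted with an outgroup species, reveal where the driver has
  exchanged sequence with the standard chromosome;
* nonsynonymous/synonymous spectra stratified by that recombination map
  quantify coding deterioration and its rescue by gene conversion;
* coverage-based CNV calls both mask unreliable SNPs and explain
  carrier/noncarrier expression differences.

## Subtraction procedure

For carrier *c* with noncarrier panel *P* (all ingroup noncarriers; the
outgroup is never in the panel):

* **standard mode** — keep every homozygous-alt SNP of *c* (it is on both
  chromosomes, hence on the driver, even if shared with *P*); keep a
  heterozygous SNP only if no sample in *P* carries the allele.
* **strict mode** — keep only SNPs (het or hom) absent from all of *P*.

The homozygous-keep rule matters more than it looks: segments of the driver
that were recently overwritten by standard sequence are homozygous in the
carrier across the converted tract, and those shared alleles are exactly
the evidence that places the pseudo-driver tip inside its subspecies clade.
Strict mode sacrifices that signal for robustness against shared
polymorphism.

Known error modes (both bounded in the validation suite): a driver SNP
segregating in the panel is lost (recall), and a carrier-private standard
polymorphism survives subtraction (precision). Both scale with diversity
over divergence and stay below ~2% each at the default calibration.

## Window classification

Nonoverlapping 5-kb windows over the driver region give per-window
alignments (consensus sequences on the reference background; noncarrier
heterozygous sites resolve to the alt allele by default, an IUPAC option
exists). Distances are p-distances or Jukes–Cantor corrected
(d = −(3/4)·ln(1 − 4p/3); p ≥ 0.75 capped at `d_max`, default 5.0). Trees
are built by neighbor joining (scikit-bio's implementation, negative branch
lengths clamped to zero); determinism under tip-order permutation is
enforced by sorting matrix ids lexicographically before agglomeration.
Trees are rooted on the branch to the outgroup MRCA; a non-monophyletic
outgroup is rooted at its MRCA from an ingroup-tip vantage, and windows
whose outgroup MRCA spans the whole tree are unclassifiable.

With M_sub = MRCA(focal noncarriers) and M_all = MRCA(all ingroup
noncarriers), the class of a window for a focal subspecies is **A** if any
focal pseudo-driver tip descends from M_sub, else **B** if any descends
from M_all, else **C**; **U** when the window is invariant
(`min_variant_columns`, default 1), truncated preconditions fail, or the
tree cannot be rooted. Bootstrap support (column resampling over the full
window length, NJ per replicate) is available but not used by the
classifier.

Aggregations: per-500-kb class fractions (the segment summaries), the
all-C window set (class C for every subspecies) whose concatenation feeds
the global tree, and per-window tallies of which subspecies' tips form the
outgroup to the other two (computed separately for driver and noncarrier
tips, ignoring tips of the other kind).

## Coding deterioration

SNP effects are classified by substituting the alternate base into the
reference codon on the coding strand (reverse complement for minus-strand
CDS) and comparing translations under the standard nuclear code; a stop is
an ordinary residue symbol, and a SNP in several transcripts is
nonsynonymous if nonsynonymous in any. Allele counts use het = 1,
hom = 2; frequency classes are quartiles of the group's chromosome count
(explicit bounds, e.g. one class per count, for groups not divisible by 4).
The Yates-corrected χ² uses statistic Σ max(|O−E|−0.5, 0)²/E with
margin-product expectations — the correction clamps at zero when
|O−E| < 0.5 — and the upper χ²(1) tail. (scipy's `chi2_contingency`
implements the correction as a sign shift that overshoots for |O−E| < 0.5,
so the statistic is computed directly; scipy supplies only the χ² tail.)

## Expression divergence

Per gene: 100·|mean TPM(carriers) − mean TPM(noncarriers)| /
mean TPM(noncarriers), over genes with noncarrier mean > 10 TPM ("> 10"
is read as the group mean, one filter value per gene). The positional
track is a sliding mean over 20 consecutive retained genes ordered by
start coordinate (ties by gene id). Genes are labelled by any-overlap with
the CNV union mask and by the recombination class covering ≥ 80% of their
5-kb windows (U-class windows never label a gene). Contrasts use the
two-sided Mann–Whitney test — exact below a combined n of 12 when untied,
normal approximation otherwise; the choice of a rank test is this
package's decision where the upstream analysis left the test unnamed.

## The synthetic cohort

The generator's defaults define the study conditions; they are chosen once
to mirror the biological situation at desk scale and are not tuned per
experiment.

**Scenario.** One 2 Mb chromosome; driver region [0.2, 1.8) Mb; 300
non-overlapping single-CDS genes covering 10% of the chromosome (ATG
start, no in-frame stops, random strand); three ingroup subspecies
(dom: 6 noncarriers + 4 carriers; mus, cas: 6 + 2) and 4 outgroup
individuals.

**Species tree and rates** (substitution probabilities per site per
branch; independent sites, ts:tv = 2:1, no indels, no shared ancestral
polymorphism across branches):

| branch | default | meaning |
|---|---|---|
| outgroup stem | 0.008 | outgroup species divergence |
| ingroup radiation stem | 0.001 | internal branch between the driver split and the subspecies radiation |
| sister stem | 0.0006 | extra branch shared by the two sister subspecies (mus, cas) |
| subspecies stem | 0.0012 | each subspecies from the radiation |
| genealogy edge | 0.0001 | each edge of the random within-population genealogy |
| driver stem | 0.009 | driver lineage from the ingroup ancestor (driver region only) |
| driver subspecies / carrier | 0.0004 / 0.0002 | later driver branches |
| old-tract post-conversion | 0.002 | driver substitutions accrued on an old tract after the copy |

This puts driver–standard divergence near 1.1%, individual heterozygosity
near 0.1%, and the carrier/noncarrier heterozygosity ratio near 10 inside
the driver region — the ten-fold contrast characteristic of a deeply
diverged driver. The ingroup radiation stem exists because classification
needs the standard lineages to be a clade excluding the driver; without
it the true class-C topology is a polytomy and no method could recover it.

**Within-population genealogies.** Haplotypes (two per noncarrier; the
carrier's standard homolog plus its non-driver-region second haplotype)
descend from the subspecies ancestor through a random bifurcating
genealogy with a constant per-edge rate. This gives individuals realistic
heterozygosity, makes most standard variation shared (so the subtraction
removes it), and leaves only terminal-edge variants as potential
pseudo-haplotype false positives.

**Conversion tracts** (per tract: interval, recency, affected subspecies;
defaults: one 100-kb `very_recent` and one 100-kb `old` tract per
subspecies, aligned to 5-kb windows, at distinct locations). `very_recent`
copies the carrier's own standard homolog — the homologous-gene-conversion
mechanism — which is also the only copy source under which the
homozygous-keep subtraction rule preserves the class-A evidence; copying a
panel noncarrier would make every informative SNP heterozygous and shared,
and the subtraction would erase it. `old` copies the subspecies-ancestral
sequence into the subspecies driver lineage and then adds private
substitutions, producing class-B placement. Truth classes: a window is A
(B) for a subspecies when ≥ 50% of its bp lie in that subspecies'
very-recent (old) tracts, else C.

**NS excess.** On driver-lineage branches, an extra pass proposes
candidate substitutions in CDS at rate p·(excess − 1) and accepts only
nonsynonymous ones (classified against the reference codon, like the
downstream classifier), multiplying the nonsynonymous substitution
probability by `driver_ns_excess` (default 3) while leaving synonymous
rates untouched; converted tracts are excluded (they evolve at background
rates).

**CNVs, coverage, expression.** CNV events carry a total copy number
(0/1/3/4) and a driver-specific flag (affecting carriers only; carrier
copies = standard + driver copies). Coverage tracks draw per-1-kb-window
depths from Poisson(mean × copy/2) at a default mean of 100 reads/window —
high enough that the declared call thresholds (copies ≤ 1.5 / ≥ 2.5,
contrast ratio ≤ 0.75 / ≥ 1.25, ≥ 3 windows, 1-window gap tolerance)
operate well above the noise floor. VCF DP/AD are drawn from the same
model (AD ~ Binomial(DP, ½) at het sites). Expression: per-gene log-normal
baselines (log-mean 3.0, log-sd 1.2), multiplicative log-normal sample
noise (log-sd 0.2), dosage folds (copy/2) applied to carriers for
driver-specific CNVs and to everyone otherwise; 4 carrier vs 8 noncarrier
samples. A separate *expression benchmark* configuration (400 genes, six
100-kb driver-specific duplications) provides ≥ 50 expressed genes in both
the CNV and non-CNV groups for well-powered rank tests; the default CNV
layout is calibrated for coverage-based recovery instead.

**What the simulator does not emulate** — and hence what passing recovery
tests do not establish about real data: linkage and recombination within
standard chromosomes, coalescent site-frequency structure, shared
ancestral polymorphism between driver and standard lineages, indels,
alignment and genotyping artefacts, GC/mappability coverage biases, and
drive transmission dynamics. The benchmarks demonstrate that each
implemented procedure recovers the signal it targets when that signal is
planted under its own model assumptions.

## Numerical and procedural choices

* Coordinates are 0-based half-open internally and in BED; VCF/GFF3 are
  1-based. All tabular outputs are TSV with headers.
* Smoothing for the divergence scan: densities are smoothed first, then
  divided (the ratio-then-smooth order is available as an option; the two
  differ at sparse bins and smooth-then-ratio is more stable). Windows
  truncated at chromosome ends use the available bins. The smoothing
  window scales with the chromosome: 1 Mb at a ~40 Mb region, 50 kb
  (the same 2.5%) in the 2 Mb default scenario.
* Filtering thresholds: the coverage rule is strictly "<" (exactly half
  the mean is kept); the allele-balance rule is inclusive (exactly 30% is
  kept). Procedures 2–3 null individual genotypes; a site is dropped only
  when no non-reference call remains. Multiallelic records are removed by
  procedure 1 with a logged count; a heterozygous genotype lacking AD is
  nulled under procedure 3 and counted separately.
* Deterioration benchmarks stratify SNPs by the simulator's truth window
  classes rather than re-inferred trees, isolating the spectrum statistic
  from classifier error (which is measured separately).
* Recovery of driver SNPs is scored inside the driver region, where driver
  truth is defined; outside it the carrier has no driver chromosome.
* Single-chromosome scope: tables and tracks model one chromosome (the
  driver's), matching the analysis design; multi-chromosome inputs should
  be processed per chromosome.

## Validation benchmarks and problem sizes

The test suite and `scripts/acceptance.py` run, at the default scenario
(2 Mb, 30 samples, 320 windows): 10-seed recoveries of pseudo-haplotype
SNPs, window classes, the divergence-scan contrast and the CNV mask
(the scan's negative control splits the full noncarrier panel into two
halves stratified by population, so neither half carries subspecies
structure the other lacks);
20 seed-pair comparisons for the NS-excess sign and χ² power; 20 + 50
seeds for the expression contrast and its null; 100 random additive
matrices for the neighbor-joining oracle; the exhaustive 64 × 9 × 2 codon
enumeration; a 23-table Yates suite (statistic exact, p within 1e-10 of
the erfc tail); and the 12-record filter fixture with hand-derived
survivor sets.
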