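"""Typed multi-sample variant table and SNP-filtering procedures.

The table holds per-site, per-sample genotype, depth and allele-depth
records for one chromosome, together with population/carrier metadata from
a sample sheet.  Three nested filtering procedures are provided:

1. keep biallelic SNP records whose FILTER is PASS;
2. additionally null a sample's genotype where its depth is below half of
   that sample's average coverage (a depth of exactly half is kept);
3. additionally null a heterozygous genotype unless each allele is
   supported by at least 30% of the reads (exactly 30% is kept).

Procedures 2-3 act per sample; a site is dropped only when no non-reference
called genotype remains.  Interval masking removes sites inside 0-based
half-open intervals (typically a CNV mask).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .config import CARRIER, NONCARRIER, OUTGROUP
from .intervals import normalize_intervals, point_in_intervals

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


@dataclass
class SampleMeta:
    name: str
    population: str
    role: str  # carrier | noncarrier | outgroup
    mean_coverage: float

    def __post_init__(self):
        if self.role not in (CARRIER, NONCARRIER, OUTGROUP):
            raise ValueError(f"unknown role {self.role!r} for sample {self.name}")


@dataclass
class FilterLog:
    """Per-rule removal counts produced by a filtering step."""

    counts: dict[str, int] = field(default_factory=dict)

    def add(self, rule: str, n: int) -> None:
        self.counts[rule] = self.counts.get(rule, 0) + int(n)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"rule": list(self.counts), "removed": list(self.counts.values())}
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class CohortVariantTable:
    """Per-site, per-sample genotype/depth records plus sample metadata.

    ``gt`` holds codes (0 hom_ref, 1 het, 2 hom_alt, -1 missing); ``dp`` and
    ``ad_ref``/``ad_alt`` hold -1 where the field is absent.
    """

    chrom: str
    pos: np.ndarray        # (n_sites,) int64, 1-based
    ref: np.ndarray        # (n_sites,) object (str)
    alt: np.ndarray        # (n_sites,) object (str; comma-joined if multiallelic)
    filter: np.ndarray     # (n_sites,) object (str, "PASS" for passing records)
    gt: np.ndarray         # (n_sites, n_samples) int8
    dp: np.ndarray         # (n_sites, n_samples) int32
    ad_ref: np.ndarray     # (n_sites, n_samples) int32
    ad_alt: np.ndarray     # (n_sites, n_samples) int32
    samples: list[SampleMeta]
    allele_codes: np.ndarray | None = None  # (n_sites, n_samples, 2) int8 base codes, -1 missing

    # -- basic queries ------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_names(self) -> list[str]:
        return [s.name for s in self.samples]

    def sample_index(self, name: str) -> int:
        for i, s in enumerate(self.samples):
            if s.name == name:
                return i
        raise KeyError(f"sample {name!r} not in table")

    def samples_with_role(self, role: str, population: str | None = None) -> list[str]:
        return [
            s.name
            for s in self.samples
            if s.role == role and (population is None or s.population == population)
        ]

    def is_biallelic_snp(self) -> np.ndarray:
        """Mask of records that are single-nucleotide, biallelic variants."""
        if self.n_sites == 0:
            return np.zeros(0, dtype=bool)
        refs = self.ref.astype("U16")
        alts = self.alt.astype("U16")
        bases = np.array(list("ACGT"))
        return (
            np.isin(refs, bases)
            & np.isin(alts, bases)
            & (refs != alts)
        )

    def subset_sites(self, mask) -> "CohortVariantTable":
        mask = np.asarray(mask)
        return replace(
            self,
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            filter=self.filter[mask],
            gt=self.gt[mask],
            dp=self.dp[mask],
            ad_ref=self.ad_ref[mask],
            ad_alt=self.ad_alt[mask],
            allele_codes=self.allele_codes[mask] if self.allele_codes is not None else None,
        )

    def alt_positions(self, sample: str, het_policy: str = "alt") -> dict[int, str]:
        """0-based position -> substituted allele for a consensus sequence.

        Heterozygous genotypes resolve to the alt allele by default
        (``het_policy='alt'``); ``'iupac'`` emits the two-allele ambiguity
        code instead, ``'ref'`` drops them.
        """
        j = self.sample_index(sample)
        out: dict[int, str] = {}
        snp = self.is_biallelic_snp()
        for i in np.nonzero(snp & (self.gt[:, j] > 0))[0]:
            g = self.gt[i, j]
            if g == HOM_ALT:
                out[int(self.pos[i]) - 1] = self.alt[i]
            elif g == HET:
                if het_policy == "alt":
                    out[int(self.pos[i]) - 1] = self.alt[i]
                elif het_policy == "iupac":
                    out[int(self.pos[i]) - 1] = _iupac(self.ref[i], self.alt[i])
                # 'ref': skip
        return out


_IUPAC = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("AC"): "M",
    frozenset("GT"): "K", frozenset("AT"): "W", frozenset("CG"): "S",
}


def _iupac(a: str, b: str) -> str:
    return _IUPAC[frozenset((a, b))]


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def load_sample_sheet(path) -> list[SampleMeta]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"sample", "population", "role"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    cov = df["mean_coverage"] if "mean_coverage" in df.columns else [float("nan")] * len(df)
    return [
        SampleMeta(str(r), str(p), str(role), float(c))
        for r, p, role, c in zip(df["sample"], df["population"], df["role"], cov)
    ]


def write_sample_sheet(path, samples: Sequence[SampleMeta]) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\trole\tmean_coverage\n")
        for s in samples:
            fh.write(f"{s.name}\t{s.population}\t{s.role}\t{s.mean_coverage:g}\n")


# ---------------------------------------------------------------------------
# VCF IO
# ---------------------------------------------------------------------------

def load_cohort_vcf(vcf_path, sample_sheet) -> CohortVariantTable:
    """Load a multi-sample VCF (FORMAT GT:DP:AD) into a table.

    *sample_sheet* is a path or a list of :class:`SampleMeta`.  Every sample
    in the VCF must appear in the sheet.  Non-SNP records are retained and
    flagged (procedure 1 removes them).
    """
    from cyvcf2 import VCF

    sheet = load_sample_sheet(sample_sheet) if not isinstance(sample_sheet, list) else sample_sheet
    by_name = {s.name: s for s in sheet}

    vcf = VCF(str(vcf_path), gts012=False)
    missing = [s for s in vcf.samples if s not in by_name]
    if missing:
        raise ValueError(f"sample(s) {missing} present in VCF but absent from sample sheet")
    samples = [by_name[s] for s in vcf.samples]
    n = len(samples)

    pos, ref, alt, filt = [], [], [], []
    gts, dps, adr, ada, allele_code_rows = [], [], [], [], []
    chrom = None
    for irec, v in enumerate(vcf):
        try:
            chrom = v.CHROM if chrom is None else chrom
            pos.append(v.POS)
            ref.append(v.REF)
            alt.append(",".join(v.ALT) if v.ALT else ".")
            filt.append(v.FILTER if v.FILTER is not None else "PASS")
            g = np.full(n, MISSING, dtype=np.int8)
            codes = np.full((n, 2), -1, dtype=np.int8)
            allele_bases = [v.REF] + list(v.ALT)
            for j, call in enumerate(v.genotypes):
                alleles = [a for a in call[:-1] if a is not None]
                if not alleles or any(a < 0 for a in alleles):
                    g[j] = MISSING
                elif all(a == 0 for a in alleles):
                    g[j] = HOM_REF
                elif len(set(alleles)) == 1:
                    g[j] = HOM_ALT
                else:
                    g[j] = HET
                if g[j] != MISSING:
                    for k, a in enumerate(alleles[:2]):
                        base = allele_bases[a]
                        codes[j, k] = "ACGT".index(base) if base in "ACGT" else -1
                    if len(alleles) == 1:
                        codes[j, 1] = codes[j, 0]
            gts.append(g)
            allele_code_rows.append(codes)
            dps.append(_format_field(v, "DP", n, 1))
            ad = _format_field(v, "AD", n, 2)
            adr.append(ad[:, 0] if ad.ndim == 2 else np.full(n, -1, np.int32))
            ada.append(ad[:, 1] if ad.ndim == 2 and ad.shape[1] > 1 else np.full(n, -1, np.int32))
        except Exception as exc:  # pragma: no cover - malformed input path
            raise ValueError(f"malformed VCF record #{irec + 1} in {vcf_path}: {exc}") from exc
    vcf.close()

    n_sites = len(pos)
    return CohortVariantTable(
        chrom=chrom if chrom is not None else "NA",
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        filter=np.asarray(filt, dtype=object),
        gt=np.vstack(gts) if n_sites else np.zeros((0, n), np.int8),
        dp=np.vstack(dps).astype(np.int32) if n_sites else np.zeros((0, n), np.int32),
        ad_ref=np.vstack(adr).astype(np.int32) if n_sites else np.zeros((0, n), np.int32),
        ad_alt=np.vstack(ada).astype(np.int32) if n_sites else np.zeros((0, n), np.int32),
        samples=samples,
        allele_codes=np.stack(allele_code_rows) if n_sites else np.zeros((0, n, 2), np.int8),
    )


def _format_field(v, key, n, width):
    arr = v.format(key)
    if arr is None:
        return np.full((n, width) if width > 1 else n, -1, dtype=np.int32)
    arr = np.asarray(arr)
    arr = np.where((arr < 0) | (arr > 2**30), -1, arr)  # cyvcf2 missing sentinel
    if width == 1:
        return arr.reshape(n, -1)[:, 0].astype(np.int32)
    return arr.reshape(n, -1).astype(np.int32)


def write_vcf(table: CohortVariantTable, path, contig_length: int | None = None) -> None:
    """Write the table as a VCF v4.2 with FORMAT GT:DP:AD."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_length is not None:
            fh.write(f"##contig=<ID={table.chrom},length={contig_length}>\n")
        else:
            fh.write(f"##contig=<ID={table.chrom}>\n")
        fh.write('##FILTER=<ID=LowQual,Description="Low quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(table.sample_names) + "\n")
        for i in range(table.n_sites):
            allele_list = [table.ref[i]] + table.alt[i].split(",")
            cells = []
            for j in range(table.n_samples):
                pair = (
                    table.allele_codes[i, j]
                    if table.allele_codes is not None and table.gt[i, j] != MISSING
                    else None
                )
                if pair is not None and all(
                    c >= 0 and "ACGT"[c] in allele_list for c in pair
                ):
                    gt = "/".join(str(allele_list.index("ACGT"[c])) for c in pair)
                else:
                    gt = _GT_STRINGS[int(table.gt[i, j])]
                dp = table.dp[i, j]
                dp_s = str(dp) if dp >= 0 else "."
                if table.ad_ref[i, j] >= 0 and table.ad_alt[i, j] >= 0:
                    ad_s = f"{table.ad_ref[i, j]},{table.ad_alt[i, j]}"
                else:
                    ad_s = "."
                cells.append(f"{gt}:{dp_s}:{ad_s}")
            fh.write(
                f"{table.chrom}\t{table.pos[i]}\t.\t{table.ref[i]}\t{table.alt[i]}\t.\t"
                f"{table.filter[i]}\t.\tGT:DP:AD\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def mask_intervals(
    table: CohortVariantTable, intervals: Sequence[tuple[int, int]]
) -> tuple[CohortVariantTable, FilterLog]:
    """Remove sites whose 0-based position falls inside the intervals."""
    log = FilterLog()
    if not list(intervals):
        log.add("masked_in_intervals", 0)
        return table, log
    ivs = normalize_intervals(intervals)
    inside = point_in_intervals(table.pos - 1, ivs)
    log.add("masked_in_intervals", int(inside.sum()))
    return table.subset_sites(~inside), log


def apply_filter_procedure(
    table: CohortVariantTable,
    procedure: int,
    cnv_mask: Sequence[tuple[int, int]] | None = None,
) -> tuple[CohortVariantTable, FilterLog]:
    """Apply SNP filtering procedure 1, 2 or 3 (nested), then optional masking.

    Returns a new table and a log of per-rule removal counts (genotype
    nulling is counted per genotype; site drops per site).
    """
    if procedure not in (1, 2, 3):
        raise ValueError("procedure must be 1, 2 or 3")
    log = FilterLog()

    snp = table.is_biallelic_snp()
    passing = np.array([f == "PASS" for f in table.filter])
    multi = np.array([("," in a) for a in table.alt])
    log.add("removed_non_pass", int((~passing).sum()))
    log.add("removed_non_snp", int((passing & ~snp & ~multi).sum()))
    log.add("removed_multiallelic", int((passing & multi).sum()))
    out = table.subset_sites(passing & snp)

    if procedure >= 2:
        if np.all(out.dp < 0):
            raise ValueError("procedure 2 requires per-sample DP")
        mean_cov = np.array([s.mean_coverage for s in out.samples])
        if np.any(~np.isfinite(mean_cov)):
            raise ValueError("procedure 2 requires mean_coverage for every sample")
        called = out.gt != MISSING
        low = called & (out.dp >= 0) & (out.dp < (mean_cov[None, :] / 2.0))
        nodp = called & (out.dp < 0)
        gt = out.gt.copy()
        gt[low | nodp] = MISSING
        log.add("genotypes_nulled_low_coverage", int(low.sum()))
        log.add("genotypes_nulled_missing_dp", int(nodp.sum()))
        out = replace(out, gt=gt)

    if procedure >= 3:
        if np.all((out.ad_ref < 0) & (out.ad_alt < 0)):
            raise ValueError("procedure 3 requires per-sample AD")
        het = out.gt == HET
        has_ad = (out.ad_ref >= 0) & (out.ad_alt >= 0)
        denom = np.where(out.dp > 0, out.dp, 1).astype(float)
        minfrac = np.minimum(out.ad_ref, out.ad_alt) / denom
        unbalanced = het & has_ad & ((out.dp <= 0) | (minfrac < 0.30))
        noad = het & ~has_ad
        gt = out.gt.copy()
        gt[unbalanced | noad] = MISSING
        log.add("genotypes_nulled_allele_balance", int(unbalanced.sum()))
        log.add("genotypes_nulled_missing_ad", int(noad.sum()))
        out = replace(out, gt=gt)

    if out.allele_codes is not None:
        ac = out.allele_codes.copy()
        ac[out.gt == MISSING] = -1
        out = replace(out, allele_codes=ac)

    if procedure >= 2:
        # a site with no remaining non-reference call carries no variant
        has_variant = (out.gt > 0).any(axis=1)
        log.add("sites_dropped_no_remaining_call", int((~has_variant).sum()))
        out = out.subset_sites(has_variant)

    if cnv_mask is not None:
        out, mlog = mask_intervals(out, cnv_mask)
        log.counts.update(mlog.counts)
    return out, log
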