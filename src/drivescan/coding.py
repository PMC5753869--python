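"""SNP effect classification and coding-deterioration statistics.

SNPs falling in annotated CDS are classified synonymous/nonsynonymous by
substituting the alternate base into the reference codon on the coding
strand and comparing translations (a stop codon is just another residue
symbol; any amino-acid mismatch is nonsynonymous).  Spectra tally NS and S
counts per allele-frequency class (quartiles of the group's chromosome
count, with a heterozygous genotype contributing 1 and a homozygous one 2)
and per recombination stratum, and are contrasted with Yates-corrected
chi-square tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from scipy import stats

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
NONCODING = "noncoding"

BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# 64-entry codon -> amino acid map (stops as '*'), index = 16*b0 + 4*b1 + b2
CODON_AA = np.array(
    [
        standard_dna_table.forward_table.get(
            BASES[i] + BASES[j] + BASES[k], "*"
        )
        for i in range(4)
        for j in range(4)
        for k in range(4)
    ],
    dtype="U1",
)


def translate_codon(codon: str) -> str:
    i = BASES.index(codon[0]) * 16 + BASES.index(codon[1]) * 4 + BASES.index(codon[2])
    return str(CODON_AA[i])


def reverse_complement(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

@dataclass
class CdsSegment:
    gene_id: str
    start: int   # 0-based
    end: int     # half-open
    strand: str  # '+' | '-'
    phase: int = 0


class CodingAnnotation:
    """CDS segments of one chromosome with positional lookup."""

    def __init__(self, segments: Sequence[CdsSegment], chrom: str = "NA"):
        self.chrom = chrom
        self.segments = sorted(segments, key=lambda s: (s.start, s.gene_id))
        for s in self.segments:
            if (s.end - s.start - s.phase) % 3 != 0:
                raise ValueError(f"CDS {s.gene_id} length (net of phase) not divisible by 3")

    def __len__(self) -> int:
        return len(self.segments)

    def segments_at(self, pos0: int) -> list[CdsSegment]:
        return [s for s in self.segments if s.start <= pos0 < s.end]

    def gene_intervals(self) -> dict[str, tuple[int, int]]:
        out: dict[str, tuple[int, int]] = {}
        for s in self.segments:
            if s.gene_id in out:
                a, b = out[s.gene_id]
                out[s.gene_id] = (min(a, s.start), max(b, s.end))
            else:
                out[s.gene_id] = (s.start, s.end)
        return out

    def cds_positions(self, region: tuple[int, int] | None = None) -> np.ndarray:
        """Sorted unique 0-based CDS positions, optionally within *region*."""
        chunks = []
        for s in self.segments:
            a, b = s.start, s.end
            if region is not None:
                a, b = max(a, region[0]), min(b, region[1])
            if a < b:
                chunks.append(np.arange(a, b))
        if not chunks:
            return np.array([], dtype=np.int64)
        return np.unique(np.concatenate(chunks))

    # -- GFF3 ---------------------------------------------------------------

    @classmethod
    def from_gff3(cls, path) -> "CodingAnnotation":
        segments, chrom = [], "NA"
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "CDS":
                    continue
                chrom = f[0]
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                gene = attrs.get("gene_id") or attrs.get("Parent") or attrs.get("ID", "NA")
                phase = int(f[7]) if f[7] not in (".", "") else 0
                segments.append(
                    CdsSegment(gene, int(f[3]) - 1, int(f[4]), f[6], phase)
                )
        return cls(segments, chrom=chrom)

    def write_gff3(self, path, chrom_length: int | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            if chrom_length is not None:
                fh.write(f"##sequence-region {self.chrom} 1 {chrom_length}\n")
            for s in self.segments:
                gid = s.gene_id
                fh.write(
                    f"{self.chrom}\tdrivescan\tgene\t{s.start + 1}\t{s.end}\t.\t{s.strand}\t.\t"
                    f"ID=gene:{gid}\n"
                )
                fh.write(
                    f"{self.chrom}\tdrivescan\tCDS\t{s.start + 1}\t{s.end}\t.\t{s.strand}\t{s.phase}\t"
                    f"ID=cds:{gid};Parent=gene:{gid};gene_id={gid}\n"
                )


# ---------------------------------------------------------------------------
# effect classification
# ---------------------------------------------------------------------------

def _codon_change(seg: CdsSegment, pos0: int, ref_base: str, alt_base: str, reference) -> tuple[str, str]:
    """Reference and alternate codons on the coding strand."""
    if seg.strand == "+":
        offset = pos0 - seg.start - seg.phase
        if offset < 0:
            raise ValueError(f"position {pos0 + 1} precedes the reading frame of {seg.gene_id}")
        cstart = seg.start + seg.phase + 3 * (offset // 3)
        codon = "".join(_base_at(reference, p) for p in range(cstart, cstart + 3))
        idx = pos0 - cstart
        ref_c, alt_c = ref_base, alt_base
    else:
        offset = (seg.end - 1 - pos0) - seg.phase
        if offset < 0:
            raise ValueError(f"position {pos0 + 1} precedes the reading frame of {seg.gene_id}")
        cend = seg.end - seg.phase - 3 * (offset // 3)  # genomic end of codon (exclusive)
        genomic = "".join(_base_at(reference, p) for p in range(cend - 3, cend))
        codon = reverse_complement(genomic)
        idx = (cend - 1) - pos0
        ref_c, alt_c = _COMP[ref_base], _COMP[alt_base]
    if codon[idx] != ref_c:
        raise ValueError(
            f"reference mismatch at position {pos0 + 1}: annotation codon has "
            f"{codon[idx]!r}, variant REF implies {ref_c!r}"
        )
    return codon, codon[:idx] + alt_c + codon[idx + 1:]


def _base_at(reference, pos0: int) -> str:
    if isinstance(reference, str):
        return reference[pos0]
    return BASES[int(reference[pos0])]


def classify_snp_effect(
    pos: int, ref_base: str, alt_base: str, annotation: CodingAnnotation, reference
) -> str:
    """Classify a biallelic SNP (1-based *pos*) against the annotation.

    Returns 'synonymous', 'nonsynonymous' or 'noncoding'.  A SNP overlapping
    several transcripts is nonsynonymous if nonsynonymous in any of them.
    *reference* is a string or an integer-coded (0..3 = ACGT) array.
    """
    pos0 = pos - 1
    segs = annotation.segments_at(pos0)
    if not segs:
        return NONCODING
    effects = []
    for seg in segs:
        ref_codon, alt_codon = _codon_change(seg, pos0, ref_base, alt_base, reference)
        effects.append(
            NONSYNONYMOUS
            if translate_codon(ref_codon) != translate_codon(alt_codon)
            else SYNONYMOUS
        )
    return NONSYNONYMOUS if NONSYNONYMOUS in effects else SYNONYMOUS


def classify_effects(
    positions: Iterable[int], refs: Iterable[str], alts: Iterable[str],
    annotation: CodingAnnotation, reference,
) -> np.ndarray:
    """Vector version of :func:`classify_snp_effect` (1-based positions)."""
    return np.array(
        [
            classify_snp_effect(int(p), r, a, annotation, reference)
            for p, r, a in zip(positions, refs, alts)
        ],
        dtype=object,
    )


# ---------------------------------------------------------------------------
# frequency spectra
# ---------------------------------------------------------------------------

def site_frequency_counts(gt_row: np.ndarray, group_columns: Sequence[int]) -> int:
    """Allele count of one site in a genotype group (het=1, hom_alt=2)."""
    g = np.asarray(gt_row)[list(group_columns)]
    return int((g == 1).sum() + 2 * (g == 2).sum())


def frequency_class_bounds(n_chromosomes: int) -> list[tuple[int, int]]:
    """Quartile count classes over 1..n (e.g. 24 -> 1-6, 7-12, 13-18, 19-24)."""
    if n_chromosomes % 4 != 0:
        raise ValueError("n_chromosomes must be divisible by 4 (or supply explicit bounds)")
    q = n_chromosomes // 4
    return [(1 + i * q, (i + 1) * q) for i in range(4)]


def per_count_bounds(n_chromosomes: int) -> list[tuple[int, int]]:
    """One class per allele count (used for small haplotype groups)."""
    return [(i, i) for i in range(1, n_chromosomes + 1)]


def assign_frequency_class(count: int, n_chromosomes: int,
                           bounds: Sequence[tuple[int, int]] | None = None) -> int:
    """1-based frequency class of an allele count (0 counts raise)."""
    if count < 1 or count > n_chromosomes:
        raise ValueError(f"allele count {count} outside 1..{n_chromosomes}")
    bounds = bounds if bounds is not None else frequency_class_bounds(n_chromosomes)
    for k, (lo, hi) in enumerate(bounds, start=1):
        if lo <= count <= hi:
            return k
    raise ValueError(f"count {count} not covered by class bounds {bounds}")


@dataclass
class SiteEffectSpectrum:
    """NS and S counts per frequency class for one group and stratum."""

    group: str
    stratum: str
    n_chromosomes: int
    ns: np.ndarray  # (4,) counts per frequency class
    s: np.ndarray

    def ratio(self, freq_class: int | None = None) -> float:
        ns = self.ns[freq_class - 1] if freq_class else self.ns.sum()
        s = self.s[freq_class - 1] if freq_class else self.s.sum()
        return float(ns) / s if s > 0 else float("nan")

    def to_frame(self) -> pd.DataFrame:
        k = len(self.ns)
        return pd.DataFrame(
            {
                "group": self.group,
                "stratum": self.stratum,
                "freq_class": np.arange(1, k + 1),
                "ns": self.ns,
                "s": self.s,
                "ns_s": [self.ns[i] / self.s[i] if self.s[i] else np.nan for i in range(k)],
            }
        )


def ns_s_spectrum(
    effects: Sequence[str],
    counts: Sequence[int],
    n_chromosomes: int,
    group: str = "group",
    strata: Sequence[str] | None = None,
    stratum: str = "all",
    class_bounds: Sequence[tuple[int, int]] | None = None,
) -> SiteEffectSpectrum:
    """Tally coding SNPs into a 4-class spectrum.

    *effects* and *counts* are per-site; sites with count 0, or whose
    stratum (when *strata* is given) differs from *stratum*, or that are
    noncoding, are ignored.  ``stratum='all'`` with *strata* given keeps
    every stratum.
    """
    n_classes = len(class_bounds) if class_bounds is not None else 4
    ns = np.zeros(n_classes, dtype=int)
    s = np.zeros(n_classes, dtype=int)
    for i, (eff, cnt) in enumerate(zip(effects, counts)):
        if eff not in (SYNONYMOUS, NONSYNONYMOUS) or cnt == 0:
            continue
        if strata is not None and stratum != "all" and strata[i] != stratum:
            continue
        k = assign_frequency_class(int(cnt), n_chromosomes, class_bounds) - 1
        if eff == NONSYNONYMOUS:
            ns[k] += 1
        else:
            s[k] += 1
    return SiteEffectSpectrum(group, stratum, n_chromosomes, ns, s)


# ---------------------------------------------------------------------------
# Yates-corrected chi-square
# ---------------------------------------------------------------------------

def yates_chi_square(table_2x2) -> tuple[float, float]:
    """Yates continuity-corrected chi-square for a 2x2 table.

    statistic = sum over cells of max(|O - E| - 0.5, 0)^2 / E with the usual
    margin-product expectations; p is the upper tail of chi-square(1).
    Correction terms clamp to zero when |O - E| < 0.5.
    """
    obs = np.asarray(table_2x2, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (obs < 0).any():
        raise ValueError("cell counts must be non-negative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    total = obs.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("both margins must be positive")
    expected = np.outer(rows, cols) / total
    term = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    stat = float((term**2 / expected).sum())
    p = float(stats.chi2.sf(stat, df=1))
    return stat, p
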