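"""Pseudo-driver-haplotype extraction and consensus-sequence construction.

A heterozygous carrier's variant list mixes driver-derived SNPs with
polymorphisms of its standard homolog.  The subtraction procedure
attributes SNPs to the driver as follows (standard mode): homozygous
carrier SNPs are kept unconditionally (they are on both chromosomes, hence
on the driver, even when shared with noncarriers); heterozygous SNPs are
kept only when no ingroup noncarrier carries the allele.  Strict mode keeps
only SNPs - het or hom - absent from every noncarrier, trading recall for
robustness against shared polymorphism.  The outgroup never enters the
subtraction panel.

Consensus sequences substitute each sample's SNP alleles into the reference
background, yielding equal-length per-sample sequences for windowed
phylogenetics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import NONCARRIER
from .variants import CARRIER, HET, HOM_ALT, CohortVariantTable

STANDARD = "standard"
STRICT = "strict"


@dataclass
class PseudoHaplotypeSet:
    """Driver-attributed SNPs of one carrier: {1-based pos: (ref, alt)}."""

    carrier: str
    mode: str
    snps: dict[int, tuple[str, str]]

    def positions0(self) -> np.ndarray:
        return np.asarray(sorted(p - 1 for p in self.snps), dtype=np.int64)

    def alt_positions(self) -> dict[int, str]:
        """0-based position -> alt base (consensus substitution map)."""
        return {p - 1: alt for p, (_, alt) in self.snps.items()}


def extract_pseudo_haplotype(
    table: CohortVariantTable,
    carrier: str,
    noncarrier_panel: list[str] | None = None,
    mode: str = STANDARD,
) -> PseudoHaplotypeSet:
    """Subtract standard-chromosome variation from a carrier's SNP list.

    *noncarrier_panel* defaults to every ingroup noncarrier in the table.
    Only biallelic SNP records are considered (filter first).
    """
    if mode not in (STANDARD, STRICT):
        raise ValueError(f"mode must be '{STANDARD}' or '{STRICT}'")
    ci = table.sample_index(carrier)
    if table.samples[ci].role != CARRIER:
        raise ValueError(f"sample {carrier!r} does not have role carrier")
    if noncarrier_panel is None:
        noncarrier_panel = table.samples_with_role(NONCARRIER)
    if not noncarrier_panel:
        raise ValueError("noncarrier panel is empty")
    panel_cols = [table.sample_index(s) for s in noncarrier_panel]

    snp = table.is_biallelic_snp()
    g = table.gt[:, ci]
    panel = table.gt[:, panel_cols]
    in_panel = ((panel == HET) | (panel == HOM_ALT)).any(axis=1)

    if mode == STANDARD:
        keep = snp & ((g == HOM_ALT) | ((g == HET) & ~in_panel))
    else:
        keep = snp & ((g == HOM_ALT) | (g == HET)) & ~in_panel

    snps = {
        int(table.pos[i]): (str(table.ref[i]), str(table.alt[i]))
        for i in np.nonzero(keep)[0]
    }
    return PseudoHaplotypeSet(carrier=carrier, mode=mode, snps=snps)


# ---------------------------------------------------------------------------
# consensus sequences
# ---------------------------------------------------------------------------

class ConsensusSet:
    """Equal-length per-sample consensus sequences on one interval.

    Stored sparsely as substitution maps over the reference; sequences are
    materialized on demand.  ``meta`` maps each name to (population, role,
    is_driver).
    """

    def __init__(
        self,
        reference: np.ndarray | str,
        interval: tuple[int, int],
        substitutions: dict[str, dict[int, str]],
        meta: dict[str, tuple[str, str, bool]],
    ):
        self.interval = (int(interval[0]), int(interval[1]))
        a, b = self.interval
        ref_str = reference if isinstance(reference, str) else None
        if ref_str is not None:
            if not (0 <= a < b <= len(ref_str)):
                raise ValueError("interval outside reference")
            self.ref_seq = ref_str[a:b]
        else:
            if not (0 <= a < b <= len(reference)):
                raise ValueError("interval outside reference")
            self.ref_seq = bytes(
                np.frombuffer(b"ACGT", dtype=np.uint8)[reference[a:b]]
            ).decode()
        self.subs = {
            name: {p: base for p, base in sub.items() if a <= p < b}
            for name, sub in substitutions.items()
        }
        self.meta = meta

    @property
    def names(self) -> list[str]:
        return sorted(self.subs)

    def sequence(self, name: str) -> str:
        a, _ = self.interval
        seq = list(self.ref_seq)
        for p, base in self.subs[name].items():
            seq[p - a] = base
        return "".join(seq)

    def write_fasta(self, path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = [SeqRecord(Seq(self.sequence(n)), id=n, description="") for n in self.names]
        seqio_write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path, meta: dict[str, tuple[str, str, bool]], interval: tuple[int, int]):
        """Load aligned consensus sequences; the first record whose name is
        '__reference__' (if present) is used as the background, otherwise the
        consensus columns themselves define the reference copy."""
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        ref = seqs.pop("__reference__", None)
        if ref is None:
            ref = next(iter(seqs.values()))
        a, b = interval
        if any(len(s) != b - a for s in seqs.values()):
            raise ValueError("consensus sequences have mismatched lengths")
        subs = {
            name: {a + i: s[i] for i in range(len(s)) if s[i] != ref[i]}
            for name, s in seqs.items()
        }
        obj = cls.__new__(cls)
        obj.interval = (a, b)
        obj.ref_seq = ref
        obj.subs = subs
        obj.meta = meta
        return obj


def build_consensus_sequences(
    reference: np.ndarray | str,
    interval: tuple[int, int],
    pseudo_sets: list[PseudoHaplotypeSet] | None = None,
    table: CohortVariantTable | None = None,
    table_samples: list[str] | None = None,
    het_policy: str = "alt",
    validate_ref: bool = True,
) -> ConsensusSet:
    """Assemble per-sample consensus sequences on the reference background.

    Pseudo-driver sets contribute tips named ``t-<carrier>``; table samples
    (noncarriers/outgroup, het resolved per *het_policy*) contribute tips
    under their own names.  SNPs outside *interval* are ignored; a SNP whose
    stored REF disagrees with the reference base is an error.
    """
    subs: dict[str, dict[int, str]] = {}
    meta: dict[str, tuple[str, str, bool]] = {}
    a, b = interval

    def check_ref(pos0: int, expected: str, who: str) -> None:
        base = (
            reference[pos0]
            if isinstance(reference, str)
            else "ACGT"[int(reference[pos0])]
        )
        if base != expected:
            raise ValueError(
                f"REF mismatch for {who} at position {pos0 + 1}: reference has "
                f"{base!r}, variant record says {expected!r}"
            )

    for ps in pseudo_sets or []:
        name = f"t-{ps.carrier}"
        sub = {}
        for pos, (ref_base, alt_base) in ps.snps.items():
            p0 = pos - 1
            if not (a <= p0 < b):
                continue
            if validate_ref:
                check_ref(p0, ref_base, name)
            sub[p0] = alt_base
        subs[name] = sub
        meta[name] = ("", CARRIER, True)

    if table is not None:
        names = table_samples if table_samples is not None else table.sample_names
        for s in names:
            sm = table.samples[table.sample_index(s)]
            sub_all = table.alt_positions(s, het_policy=het_policy)
            subs[s] = {p: v for p, v in sub_all.items() if a <= p < b}
            meta[s] = (sm.population, sm.role, False)

    # fill population metadata of driver tips from their carrier sample
    if table is not None:
        for ps in pseudo_sets or []:
            sm = table.samples[table.sample_index(ps.carrier)]
            meta[f"t-{ps.carrier}"] = (sm.population, sm.role, True)

    return ConsensusSet(reference, interval, subs, meta)
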