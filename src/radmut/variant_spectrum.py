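"""Classification of small mutations (SBSs and InDels < 100 bp).

Covers the per-record classifiers used for mutation-spectrum summaries in
irradiated mutant lines:

* zygosity from the mutant-read fraction (>= 0.80 homozygous, [0.25, 0.80)
  heterozygous, below 0.25 not called);
* transition vs transversion for single-base substitutions;
* InDel kind and length class (1 bp / 2-9 bp / 10-99 bp);
* homopolymer / polynucleotide-repeat context at InDel junctions;
* CDS vs non-coding placement against single-transcript gene models;
* coding consequence (silent, missense, premature stop, start loss,
  in-frame InDel, frameshift);

and `summarize_spectrum`, which aggregates them into group-level counts and
per-bp frequencies (count / (genome length x individuals)).

Coordinates are 1-based inclusive throughout; VCF-style anchored alleles are
accepted and left-normalised on ingest when the genome is available.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from ._util import round_half_up

__all__ = [
    "VariantRecord",
    "GeneModel",
    "SpectrumSummary",
    "classify_zygosity",
    "classify_substitution",
    "classify_indel",
    "junction_context",
    "region_class",
    "consequence",
    "summarize_spectrum",
    "read_variants_tsv",
    "read_variants_vcf",
    "read_genes_tsv",
    "left_normalize",
]

HOMOZYGOUS_MIN_FRACTION = 0.80
HETEROZYGOUS_MIN_FRACTION = 0.25
MAX_INDEL_LENGTH = 99

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
BASES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantRecord:
    """One called small mutation with its supporting read fraction."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    fraction: float
    sample: str = ""

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if not (set(self.ref) <= BASES and set(self.alt) <= BASES):
            raise ValueError(f"non-ACGT allele in {self.ref}>{self.alt}")
        if not 0 <= self.fraction <= 1:
            raise ValueError(f"mutant read fraction out of [0,1]: {self.fraction}")
        if self.indel_length >= 100:
            raise ValueError("InDels >= 100 bp are structural variants, not small InDels")

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    @property
    def is_sbs(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return self.indel_length > 0

    @property
    def end(self) -> int:
        """Last reference base covered (1-based inclusive)."""
        return self.pos + len(self.ref) - 1


@dataclass(frozen=True)
class GeneModel:
    """Single-transcript protein-coding gene: ordered CDS intervals, 1-based inclusive."""

    name: str
    chrom: str
    strand: str
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        ivs = sorted(self.cds)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping CDS intervals in {self.name}")
        for s, e in ivs:
            if e < s:
                raise ValueError("CDS interval end before start")
        if self.cds_length % 3 != 0:
            raise ValueError(f"CDS length of {self.name} not divisible by 3")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def coding_sequence(self, genome: dict[str, str]) -> str:
        seq = "".join(genome[self.chrom][s - 1 : e] for s, e in sorted(self.cds))
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def cds_index(self, pos: int) -> int:
        """0-based position within the coding sequence of a genomic position."""
        offset = 0
        for s, e in sorted(self.cds):
            if s <= pos <= e:
                idx = offset + (pos - s)
                if self.strand == "-":
                    return self.cds_length - 1 - idx
                return idx
            offset += e - s + 1
        raise ValueError(f"position {pos} not in CDS of {self.name}")

    def contains(self, start: int, end: int) -> bool:
        return any(s <= end and start <= e for s, e in self.cds)


def classify_zygosity(fraction: float) -> str:
    """Zygosity call from the mutant-read fraction (boundaries inclusive per
    the >=80% / >=25% rules)."""
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction out of [0,1]: {fraction}")
    if fraction >= HOMOZYGOUS_MIN_FRACTION:
        return "homozygous"
    if fraction >= HETEROZYGOUS_MIN_FRACTION:
        return "heterozygous"
    return "not_called"


def classify_substitution(ref: str, alt: str) -> str:
    """'transition' for purine<->purine or pyrimidine<->pyrimidine, else 'transversion'."""
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"substitution bases must be ACGT, got {ref}>{alt}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    same_class = ({ref, alt} <= PURINES) or ({ref, alt} <= PYRIMIDINES)
    return "transition" if same_class else "transversion"


def classify_indel(record: VariantRecord) -> tuple[str, str]:
    """(kind, length class) with classes '1 bp', '2-9 bp', '10-99 bp'."""
    length = record.indel_length
    if length == 0 or length > MAX_INDEL_LENGTH:
        raise ValueError(f"not a small InDel (length {length})")
    kind = "deletion" if len(record.ref) > len(record.alt) else "insertion"
    if length == 1:
        cls = "1 bp"
    elif length <= 9:
        cls = "2-9 bp"
    else:
        cls = "10-99 bp"
    return kind, cls


def _tandem_run_spans(context: str, lo: int, hi: int, unit_min: int, unit_max: int) -> bool:
    """True if a tandem repeat (unit unit_min..unit_max, >= 2 full copies)
    covers context[lo:hi] and keeps at least one full unit outside it."""
    n = len(context)
    for k in range(unit_min, unit_max + 1):
        for start in range(0, n - 2 * k + 1):
            # maximal periodic run with period k starting at `start`
            if start > 0 and start + k <= n and context[start - 1] == context[start + k - 1]:
                continue  # not the leftmost start of this run
            end = start + k
            while end < n and context[end] == context[end - k]:
                end += 1
            run_len = end - start
            if run_len < 2 * k:
                continue
            if start <= lo and end >= hi and run_len - (hi - lo) >= k:
                return True
    return False


def junction_context(
    left_flank: str,
    indel_seq: str,
    right_flank: str,
    min_run: int = 3,
    unit_min: int = 2,
    unit_max: int = 6,
) -> str:
    """Classify the sequence context at an InDel junction.

    'homopolymer' when the InDel allele plus adjacent flank bases form a
    single-base run of at least ``min_run``; otherwise
    'polynucleotide_repeat' when a tandem repeat (unit 2-6 bp, >= 2 full
    copies) spans the junction with at least one full unit left in the
    flanks; else 'none'. Homopolymer takes precedence. Flanks are the
    reference bases adjacent to the event (for a deletion, around the
    deleted tract; for an insertion, around the insertion point).
    """
    if len(left_flank) < 10 or len(right_flank) < 10:
        raise ValueError("need >= 10 bp of flank on each side of the InDel")
    if not indel_seq:
        raise ValueError("empty InDel sequence")
    base = indel_seq[0]
    if all(b == base for b in indel_seq):
        run = len(indel_seq)
        i = len(left_flank) - 1
        while i >= 0 and left_flank[i] == base:
            run += 1
            i -= 1
        j = 0
        while j < len(right_flank) and right_flank[j] == base:
            run += 1
            j += 1
        if run >= min_run:
            return "homopolymer"
    context = left_flank + indel_seq + right_flank
    lo, hi = len(left_flank), len(left_flank) + len(indel_seq)
    if _tandem_run_spans(context, lo, hi, unit_min, unit_max):
        return "polynucleotide_repeat"
    return "none"


def _cds_tree(genes: list[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.chrom, IntervalTree())
        for s, e in g.cds:
            tree.addi(s, e + 1, g)  # intervaltree is half-open
    return trees


def region_class(
    record: VariantRecord,
    genes: list[GeneModel],
    chromosomes: set[str] | None = None,
) -> str:
    """'CDS' iff any affected reference base overlaps a CDS interval, else 'non-coding'."""
    known = chromosomes if chromosomes is not None else {g.chrom for g in genes}
    if known and record.chrom not in known:
        raise ValueError(f"unknown chromosome {record.chrom!r}")
    tree = _cds_tree(genes).get(record.chrom)
    if tree is not None and tree.overlap(record.pos, record.end + 1):
        return "CDS"
    return "non-coding"


STOP = "*"


def consequence(record: VariantRecord, gene: GeneModel, genome: dict[str, str]) -> str:
    """Coding consequence of a variant overlapping the gene's CDS.

    SBS: the affected codon is translated before and after the change
    (silent / missense / premature_stop; start_loss inside codon 1).
    InDel: frameshift iff length mod 3 != 0, else in-frame insertion or
    deletion. InDels are required to lie wholly inside the CDS.
    """
    if record.is_sbs:
        if not gene.contains(record.pos, record.pos):
            raise ValueError("record outside gene CDS")
        idx = gene.cds_index(record.pos)
        cds = gene.coding_sequence(genome)
        codon_i = idx // 3
        ref_base, alt_base = record.ref, record.alt
        if gene.strand == "-":
            ref_base = str(Seq(ref_base).reverse_complement())
            alt_base = str(Seq(alt_base).reverse_complement())
        if cds[idx] != ref_base:
            raise ValueError(
                f"ref allele mismatch at {record.chrom}:{record.pos} "
                f"(genome {cds[idx]}, record {ref_base})"
            )
        codon = cds[codon_i * 3 : codon_i * 3 + 3]
        new_codon = codon[: idx % 3] + alt_base + codon[idx % 3 + 1 :]
        if codon_i == 0:
            return "start_loss"
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq(new_codon).translate())
        if aa_alt == aa_ref:
            return "silent"
        if aa_alt == STOP and aa_ref != STOP:
            return "premature_stop"
        return "missense"
    # anchored InDel: changed bases start after the anchor base
    length = record.indel_length
    if len(record.ref) > len(record.alt):
        start, end = record.pos + 1, record.pos + length
        if not gene.contains(start, end):
            raise ValueError("record outside gene CDS")
        return "frameshift" if length % 3 else "in-frame_deletion"
    if not gene.contains(record.pos, record.pos + 1):
        raise ValueError("record outside gene CDS")
    return "frameshift" if length % 3 else "in-frame_insertion"


@dataclass
class SpectrumSummary:
    """Aggregated mutation-spectrum counts and per-bp frequencies."""

    n_records: int
    zygosity: Counter = field(default_factory=Counter)
    n_transitions: int = 0
    n_transversions: int = 0
    indel_classes: Counter = field(default_factory=Counter)
    n_insertions: int = 0
    n_deletions: int = 0
    contexts: Counter = field(default_factory=Counter)
    regions: Counter = field(default_factory=Counter)
    consequences: Counter = field(default_factory=Counter)
    frequencies: dict = field(default_factory=dict)

    @property
    def titv_ratio(self) -> float | None:
        if self.n_transversions == 0:
            return None
        return self.n_transitions / self.n_transversions

    @property
    def deletion_insertion_ratio(self) -> float | None:
        """Deletion:insertion ratio rounded half-up to 2 decimals (e.g. 3.63)."""
        if self.n_insertions == 0:
            return None
        return round_half_up(self.n_deletions / self.n_insertions, 2)


def summarize_spectrum(
    records: list[VariantRecord],
    genes: list[GeneModel],
    genome_length: int,
    n_individuals: int,
    genome: dict[str, str] | None = None,
    flank: int = 10,
) -> SpectrumSummary:
    """Aggregate per-record classifications into a group-level spectrum.

    Per-bp frequencies are count / (genome length x n individuals); the CDS
    frequency divides CDS-overlapping counts by total CDS length instead.
    Junction contexts are classified only when the genome sequence is given.
    """
    if not records:
        raise ValueError("empty record list")
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    if n_individuals <= 0:
        raise ValueError("n individuals must be positive")

    s = SpectrumSummary(n_records=len(records))
    n_sbs = 0
    n_indel = 0
    for rec in records:
        s.zygosity[classify_zygosity(rec.fraction)] += 1
        region = region_class(rec, genes)
        s.regions[region] += 1
        if rec.is_sbs:
            n_sbs += 1
            kind = classify_substitution(rec.ref, rec.alt)
            if kind == "transition":
                s.n_transitions += 1
            else:
                s.n_transversions += 1
        elif rec.is_indel:
            n_indel += 1
            kind, cls = classify_indel(rec)
            s.indel_classes[(kind, cls)] += 1
            if kind == "deletion":
                s.n_deletions += 1
            else:
                s.n_insertions += 1
            if genome is not None:
                chrom_seq = genome[rec.chrom]
                if kind == "deletion":
                    seq = rec.ref[len(rec.alt) :]
                    left = chrom_seq[max(0, rec.pos - flank) : rec.pos]
                    right = chrom_seq[rec.end : rec.end + flank]
                else:
                    seq = rec.alt[len(rec.ref) :]
                    left = chrom_seq[max(0, rec.pos - flank + 1) : rec.pos + 1]
                    right = chrom_seq[rec.pos + 1 : rec.pos + 1 + flank]
                s.contexts[junction_context(left, seq, right)] += 1
        if region == "CDS":
            gene = next(g for g in genes if g.chrom == rec.chrom and g.contains(rec.pos, rec.end))
            try:
                s.consequences[consequence(rec, gene, genome)] += 1
            except (ValueError, TypeError):
                s.consequences["unclassified"] += 1

    denom = genome_length * n_individuals
    cds_length = sum(g.cds_length for g in genes)
    s.frequencies = {
        "all_per_bp": len(records) / denom,
        "sbs_per_bp": n_sbs / denom,
        "indel_per_bp": n_indel / denom,
    }
    if cds_length:
        s.frequencies["cds_per_bp"] = s.regions["CDS"] / (cds_length * n_individuals)
        noncoding = genome_length - cds_length
        if noncoding > 0:
            s.frequencies["non_coding_per_bp"] = s.regions["non-coding"] / (
                noncoding * n_individuals
            )
    return s


def left_normalize(record: VariantRecord, genome: dict[str, str]) -> VariantRecord:
    """Shift an anchored InDel to its smallest coordinate representation."""
    if not record.is_indel or len(record.alt) == 0 or len(record.ref) == 0:
        return record
    chrom = genome[record.chrom]
    ref, alt, pos = record.ref, record.alt, record.pos
    # canonical anchored form: single anchor base + inserted/deleted tract
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    is_del = len(ref) > len(alt)
    changed = ref[1:] if is_del else alt[1:]
    while pos > 1 and changed and changed[-1] == chrom[pos - 1]:
        # tract's last base equals the anchor base: rotate and shift left
        changed = chrom[pos - 1] + changed[:-1]
        pos -= 1
    anchor = chrom[pos - 1]
    if is_del:
        ref, alt = anchor + changed, anchor
    else:
        ref, alt = anchor, anchor + changed
    return VariantRecord(record.chrom, pos, ref, alt, record.fraction, record.sample)


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    """Read variants from a TSV with columns chrom, pos, ref, alt, fraction[, sample]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    records = []
    for row in df.itertuples(index=False):
        records.append(
            VariantRecord(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                fraction=float(row.fraction),
                sample=str(getattr(row, "sample", "")),
            )
        )
    return records


def read_variants_vcf(path: str | Path, fraction_field: str = "AF") -> list[VariantRecord]:
    """Read a minimal VCF (CHROM, POS, REF, ALT and an AF-like INFO field)."""
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            frac = rec.info.get(fraction_field)
            if isinstance(frac, tuple):
                frac = frac[0]
            for alt in rec.alts or ():
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        fraction=float(frac),
                        sample="",
                    )
                )
    return records


def read_genes_tsv(path: str | Path) -> list[GeneModel]:
    """Read gene models from a TSV with columns gene, chrom, strand, cds_start, cds_end.

    Multi-exon genes repeat the gene name over several rows.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    genes = []
    for name, grp in df.groupby("gene", sort=False):
        genes.append(
            GeneModel(
                name=str(name),
                chrom=str(grp["chrom"].iloc[0]),
                strand=str(grp["strand"].iloc[0]),
                cds=tuple(
                    (int(r.cds_start), int(r.cds_end)) for r in grp.itertuples(index=False)
                ),
            )
        )
    return genes
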