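"""Ground-truth synthetic data for every pipeline stage.

Generates, with known truth and full seed determinism:

* a random genome (configurable length and GC) carrying non-overlapping
  single-transcript genes (ATG start, in-frame, stop codon);
* dose-survival datasets drawn binomially around a multitarget curve
  (defaults follow the reference assay: 4 replicates x 50 seeds on the
  100 MeV proton-beam dose grid);
* small-variant tables with planted zygosity (homozygous sites at mutant
  allele probability 1.0, heterozygous at 0.5) and read fractions sampled
  binomially at fixed depth;
* inversion junction cases across the four junction classes with planted
  microhomology (2-23 bp), on-tract and adjacent deletions (adjacent up to
  61 bp) and occasional insertions, whose flanks are rejection-sampled to be
  repeat-free so the junction analyzer can recover every planted quantity
  exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import dose_response, sv_junction
from .dose_response import SurvivalDataset, survival_fraction
from .sv_junction import (
    JunctionCase,
    JunctionReport,
    JunctionSideReport,
    build_inversion_product,
    junction_microhomology,
)
from .variant_spectrum import GeneModel, VariantRecord

__all__ = [
    "GeneratorConfig",
    "gen_genome_and_genes",
    "gen_survival_dataset",
    "gen_variant_table",
    "gen_junction_cases",
    "write_simulation",
]

BASES = np.array(list("ACGT"))
STOP_CODONS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# proton-beam dose grid of the reference survival assay (Gy)
DEFAULT_DOSE_GRID = (
    113.7, 190.3, 280.6, 393.4, 493.4, 574.0, 682.1, 786.9, 994.9, 1188.4,
)


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic-data generator.

    Defaults emulate the reference study conditions: the proton-beam dose
    grid with 4 replicates of 50 seeds; sequencing depth 40x; an SBS share
    of 0.68 with deletions outnumbering insertions 4:1; a junction-class mix
    of (A, B, C, D) = (3, 12, 6, 4) per 25 inversions; microhomology 2-23 bp
    and adjacent deletions up to 61 bp.
    """

    seed: int = 0
    # genome
    genome_length: int = 100_000
    gc_fraction: float = 0.36
    n_genes: int = 40
    cds_codons_min: int = 60
    cds_codons_max: int = 300
    # survival assay
    d0: float = 631.0
    m: float = 3.3
    dose_grid: tuple[float, ...] = DEFAULT_DOSE_GRID
    replicates: int = 4
    seeds_per_replicate: int = 50
    # variant table
    n_variants: int = 200
    sbs_fraction: float = 0.68
    homozygous_fraction: float = 0.65
    deletion_fraction: float = 0.8  # of InDels
    depth: int = 40
    # junction cases
    n_junction_cases: int = 25
    class_weights: tuple[float, float, float, float] = (3.0, 12.0, 6.0, 4.0)
    mh_range: tuple[int, int] = (2, 23)
    adjacent_small_range: tuple[int, int] = (1, 10)
    adjacent_large_range: tuple[int, int] = (11, 61)
    insertion_fraction: float = 0.1
    prefix_len: int = 160
    inverted_len: int = 280
    suffix_len: int = 160
    screen_flanks: bool = True

    def __post_init__(self) -> None:
        if not 2 <= self.mh_range[0] <= self.mh_range[1] <= 23:
            raise ValueError("microhomology range must lie within [2, 23]")
        if self.n_variants < 0 or self.n_junction_cases < 0 or self.n_genes < 0:
            raise ValueError("counts must be non-negative")


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng((config.seed, stream))


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=n, p=p))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + stop codon."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(BASES, size=3))
        if c not in STOP_CODONS and c != "ATG":
            codons.append(c)
    codons.append(["TAA", "TAG", "TGA"][rng.integers(3)])
    return "".join(codons)


def gen_genome_and_genes(config: GeneratorConfig) -> tuple[dict[str, str], list[GeneModel]]:
    """Random genome with planted non-overlapping single-transcript genes."""
    rng = _rng(config, 1)
    seq = list(_random_seq(rng, config.genome_length, config.gc_fraction))
    genes: list[GeneModel] = []
    max_len = 3 * config.cds_codons_max
    slots_needed = config.n_genes * (max_len + 40)
    if slots_needed > config.genome_length:
        raise ValueError(
            f"infeasible packing: {config.n_genes} genes of up to {max_len} bp "
            f"do not fit in {config.genome_length} bp"
        )
    stride = config.genome_length // max(config.n_genes, 1)
    for i in range(config.n_genes):
        n_codons = int(rng.integers(config.cds_codons_min, config.cds_codons_max + 1))
        cds = _random_cds(rng, n_codons)
        start = i * stride + int(rng.integers(0, max(1, stride - len(cds) - 20)))
        strand = "+" if rng.random() < 0.5 else "-"
        insert = cds if strand == "+" else _revcomp(cds)
        seq[start : start + len(cds)] = insert
        genes.append(
            GeneModel(
                name=f"gene{i:03d}",
                chrom="chr1",
                strand=strand,
                cds=((start + 1, start + len(cds)),),
            )
        )
    return {"chr1": "".join(seq)}, genes


def gen_survival_dataset(config: GeneratorConfig, noise: bool = True) -> SurvivalDataset:
    """Binomial seed-survival counts around the configured multitarget curve.

    With ``noise=False`` the counts are the rounded expectations at full
    replicate pooling, so recovered fractions equal the model exactly up to
    count quantisation; tests that need exact fractions use the model
    directly.
    """
    rng = _rng(config, 2)
    doses, survived, total = [], [], []
    for d in config.dose_grid:
        p = survival_fraction(d, config.d0, config.m)
        for _ in range(config.replicates):
            n = config.seeds_per_replicate
            s = int(rng.binomial(n, p)) if noise else int(round(n * p))
            doses.append(float(d))
            survived.append(s)
            total.append(n)
    return SurvivalDataset(doses=tuple(doses), survived=tuple(survived), total=tuple(total))


def noiseless_fractions(
    dose_grid: tuple[float, ...], d0: float, m: float, scale: int = 10**6
) -> SurvivalDataset:
    """Exact model fractions encoded as counts over a large denominator."""
    survived = [int(round(scale * survival_fraction(d, d0, m))) for d in dose_grid]
    return SurvivalDataset(
        doses=tuple(float(d) for d in dose_grid),
        survived=tuple(survived),
        total=tuple(scale for _ in dose_grid),
    )


def gen_variant_table(
    config: GeneratorConfig,
    genome: dict[str, str],
    genes: list[GeneModel],
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Plant SBSs and InDels with known zygosity; read fractions are
    Binomial(depth, p)/depth with p = 1.0 (hom) or 0.5 (het).

    Returns the records and a truth table (position, kind, zygosity,
    indel length).
    """
    rng = _rng(config, 3)
    chrom = "chr1"
    seq = genome[chrom]
    spacing = 120  # keeps events non-overlapping with free context windows
    capacity = (len(seq) - 2 * spacing) // spacing
    if config.n_variants > capacity:
        raise ValueError(
            f"variant count {config.n_variants} exceeds genome capacity {capacity}"
        )
    slots = rng.choice(capacity, size=config.n_variants, replace=False)
    records, truth = [], []
    for i, slot in enumerate(np.sort(slots)):
        pos = spacing + int(slot) * spacing + int(rng.integers(0, 40))  # 1-based
        refbase = seq[pos - 1]
        zyg = "homozygous" if rng.random() < config.homozygous_fraction else "heterozygous"
        p = 1.0 if zyg == "homozygous" else 0.5
        frac = float(rng.binomial(config.depth, p)) / config.depth
        if rng.random() < config.sbs_fraction:
            alt = str(rng.choice([b for b in "ACGT" if b != refbase]))
            rec = VariantRecord(chrom, pos, refbase, alt, frac, sample=f"sim{i:04d}")
            kind, length = "sbs", 0
        else:
            length = int(rng.choice([1, 1, 1, 2, 3, 5, 8, 15, 40], p=None))
            if rng.random() < config.deletion_fraction:
                ref = seq[pos - 1 : pos + length]
                rec = VariantRecord(chrom, pos, ref, refbase, frac, sample=f"sim{i:04d}")
                kind = "deletion"
            else:
                ins = "".join(rng.choice(BASES, size=length))
                rec = VariantRecord(chrom, pos, refbase, refbase + ins, frac, sample=f"sim{i:04d}")
                kind = "insertion"
        records.append(rec)
        truth.append(
            {"pos": pos, "kind": kind, "zygosity": zyg, "indel_length": length, "fraction": frac}
        )
    return records, pd.DataFrame(truth)


@dataclass(frozen=True)
class _PlantedJunction:
    """Planted truth for one generated inversion case."""

    fig_class: str
    mh_len: int  # at the left junction (right junction kept clean)
    on_overlap: int
    adjacent: int
    insertion_len: int


def _plant_case(
    rng: np.random.Generator, config: GeneratorConfig, case_id: str
) -> tuple[JunctionCase, _PlantedJunction]:
    classes = np.array(["A", "B", "C", "D"])
    w = np.asarray(config.class_weights, dtype=float)
    fig = str(rng.choice(classes, p=w / w.sum()))
    lo, hi = config.mh_range
    mh = int(rng.integers(lo, hi + 1)) if fig != "A" else 0
    on_overlap = adjacent = ins_len = 0
    if fig == "C":
        if mh > 2 and rng.random() < 0.5:
            on_overlap = int(rng.integers(1, min(3, mh - 2) + 1))
        else:
            adjacent = int(rng.integers(*config.adjacent_small_range) + 0)
    elif fig == "D":
        a_lo, a_hi = config.adjacent_large_range
        adjacent = int(rng.integers(a_lo, a_hi + 1))
    if fig == "B" and rng.random() < config.insertion_fraction:
        ins_len = int(rng.integers(1, 9))
    planted = _PlantedJunction(fig, mh, on_overlap, adjacent, ins_len)

    bp1 = config.prefix_len
    bp2 = config.prefix_len + config.inverted_len
    total = bp1 + config.inverted_len + config.suffix_len
    for _attempt in range(500):
        ref = list(_random_seq(rng, total, config.gc_fraction))
        if mh:
            # left-junction tract: prefix tail equals revcomp of mid tail
            tract = _random_seq(rng, mh, config.gc_fraction)
            ref[bp1 - mh : bp1] = tract
            ref[bp2 - mh : bp2] = _revcomp(tract)
        ref_s = "".join(ref)
        ins = _random_seq(rng, ins_len, config.gc_fraction) if ins_len else ""
        product = build_inversion_product(
            ref_s,
            bp1,
            bp2,
            use_microhomology=mh > 0,
            resection=(on_overlap, adjacent, 0, 0),
            insertion=ins,
        )
        if not config.screen_flanks or _screen(ref_s, product, bp1, bp2, planted):
            case = JunctionCase(
                case_id=case_id,
                reference=ref_s,
                product=product,
                breakpoint1=bp1,
                breakpoint2=bp2,
                svtype="inversion",
            )
            return case, planted
    raise RuntimeError(
        "rejection sampling failed after 500 attempts; use a longer segment"
    )


def _screen(ref: str, product: str, bp1: int, bp2: int, planted: _PlantedJunction) -> bool:
    """Repeat-free flank screen: the planted microhomology must be the only
    junction overlap, extension stop points must be unambiguous, and the
    anchor 20-mers must be unique."""
    prefix, mid, suffix = ref[:bp1], ref[bp1:bp2], ref[bp2:]
    inv = _revcomp(mid)
    if junction_microhomology(prefix, inv) != planted.mh_len:
        return False
    if junction_microhomology(inv, suffix) >= sv_junction.MIN_MICROHOMOLOGY:
        return False
    # extension stop points must land exactly on the planted anatomy
    qa = _expected_left_match(bp1, planted)
    if _lcp(prefix, product) != qa:
        return False
    c = max(sv_junction.MIN_ANCHOR, len(inv) // 2 - sv_junction.MIN_ANCHOR // 2)
    anchor = inv[c : c + sv_junction.MIN_ANCHOR]
    if product.count(anchor) != 1 or ref.count(anchor) + _revcomp(ref).count(anchor) != 1:
        return False
    # right junction is planted clean: suffix must align exactly
    if not product.endswith(suffix):
        return False
    idx = product.find(anchor)
    seg1 = product[: idx + sv_junction.MIN_ANCHOR]
    s = _lcs(inv[: c + sv_junction.MIN_ANCHOR], seg1)
    if len(inv[: c + sv_junction.MIN_ANCHOR]) - s != _expected_right_miss(planted):
        return False
    return True


def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _lcs(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[-1 - i] == b[-1 - i]:
        i += 1
    return i


def _expected_left_match(bp1: int, p: _PlantedJunction) -> int:
    if p.adjacent:
        return bp1 - p.mh_len - p.adjacent
    return bp1 - p.on_overlap


def _expected_right_miss(p: _PlantedJunction) -> int:
    # unmatched bases at the start of the inverted-segment source
    if p.adjacent:
        return p.on_overlap
    if p.on_overlap or p.insertion_len:
        return p.mh_len
    return 0


def _truth_report(case_id: str, p: _PlantedJunction) -> JunctionReport:
    mh_obs = p.mh_len - p.on_overlap
    j1 = JunctionSideReport(
        microhomology_len=mh_obs if mh_obs >= sv_junction.MIN_MICROHOMOLOGY else 0,
        microhomology_seq="",
        deletion_on_overlap=p.on_overlap,
        deletion_adjacent_left=p.adjacent,
        deletion_adjacent_right=0,
        insertion_len=p.insertion_len,
        insertion_seq="",
    )
    j2 = JunctionSideReport(0, "", 0, 0, 0, 0, "")
    return JunctionReport(case_id=case_id, svtype="inversion", junctions=(j1, j2))


def gen_junction_cases(
    config: GeneratorConfig,
) -> tuple[list[JunctionCase], list[JunctionReport]]:
    """Inversion junction cases across classes A-D with planted anatomy.

    Flank screening guarantees the analyzer recovers every planted quantity
    exactly; truth reports (sequences omitted) are emitted alongside.
    """
    rng = _rng(config, 4)
    cases, truths = [], []
    for i in range(config.n_junction_cases):
        case, planted = _plant_case(rng, config, f"case{i:04d}")
        cases.append(case)
        truths.append(_truth_report(case.case_id, planted))
    return cases, truths


def write_simulation(config: GeneratorConfig, outdir: str | Path) -> None:
    """Write a full simulated input set (FASTA, variant/survival/case TSVs
    plus truth tables) into a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome, genes = gen_genome_and_genes(config)
    with open(out / "genome.fa", "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    pd.DataFrame(
        [
            {"gene": g.name, "chrom": g.chrom, "strand": g.strand, "cds_start": s, "cds_end": e}
            for g in genes
            for s, e in g.cds
        ]
    ).to_csv(out / "genes.tsv", sep="\t", index=False)

    survival = gen_survival_dataset(config)
    survival.to_frame().to_csv(out / "survival.tsv", sep="\t", index=False)

    records, truth = gen_variant_table(config, genome, genes)
    pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "fraction": r.fraction,
                "sample": r.sample,
            }
            for r in records
        ]
    ).to_csv(out / "variants.tsv", sep="\t", index=False)
    truth.to_csv(out / "variants_truth.tsv", sep="\t", index=False)

    cases, truths = gen_junction_cases(config)
    with open(out / "junction_cases.fa", "w") as fh:
        for case in cases:
            fh.write(f">{case.case_id}|ref\n{case.reference}\n")
            fh.write(f">{case.case_id}|product\n{case.product}\n")
    pd.DataFrame(
        [
            {
                "case_id": c.case_id,
                "breakpoint1": c.breakpoint1,
                "breakpoint2": c.breakpoint2,
                "svtype": c.svtype,
                "offset": c.offset,
            }
            for c in cases
        ]
    ).to_csv(out / "junction_cases.tsv", sep="\t", index=False)
    sv_junction.write_reports_tsv(truths, out / "junction_truth.tsv")
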