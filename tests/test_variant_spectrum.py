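"""Small-mutation classifiers: zygosity, Ti/Tv, InDel classes, junction
context, region and coding consequence."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given
from hypothesis import strategies as st

from radmut import variant_spectrum as vs


@pytest.mark.parametrize(
    "fraction,expected",
    [
        (0.80, "homozygous"),  # boundary inclusive
        (1.0, "homozygous"),
        (0.25, "heterozygous"),  # boundary inclusive
        (0.799, "heterozygous"),
        (0.10, "not_called"),
        (0.0, "not_called"),
    ],
)
def test_zygosity_thresholds(fraction, expected):
    assert vs.classify_zygosity(fraction) == expected


@given(st.floats(0, 1))
def test_zygosity_partitions_unit_interval(fraction):
    assert vs.classify_zygosity(fraction) in {"homozygous", "heterozygous", "not_called"}


def test_zygosity_rejects_out_of_range():
    with pytest.raises(ValueError):
        vs.classify_zygosity(1.2)


@pytest.mark.parametrize(
    "ref,alt,expected",
    [
        ("A", "G", "transition"),
        ("G", "A", "transition"),
        ("C", "T", "transition"),
        ("C", "A", "transversion"),
        ("T", "G", "transversion"),
    ],
)
def test_substitution_classes(ref, alt, expected):
    assert vs.classify_substitution(ref, alt) == expected


def test_substitution_rejects_ambiguity_codes():
    with pytest.raises(ValueError):
        vs.classify_substitution("N", "A")


def test_random_substitutions_have_titv_half():
    """Uniform random substitutions give expected Ti/Tv = 0.5 (one transition
    among three alternatives per base)."""
    rng = np.random.default_rng(2024)
    n = 100_000
    refs = rng.choice(list("ACGT"), size=n)
    ti = 0
    for ref in refs:
        alt = rng.choice([b for b in "ACGT" if b != ref])
        if vs.classify_substitution(ref, alt) == "transition":
            ti += 1
    p_hat = ti / n
    p = 1 / 3  # one transition among the three alternatives of each base
    se = np.sqrt(p * (1 - p) / n)
    assert abs(p_hat - p) < 3 * se  # Ti fraction 1/3 <=> Ti/Tv = 0.5


@pytest.mark.parametrize(
    "ref,alt,expected",
    [
        ("AT", "A", ("deletion", "1 bp")),
        ("A", "ACGTC", ("insertion", "2-9 bp")),
        ("ACGTACGTACGT", "A", ("deletion", "10-99 bp")),
    ],
)
def test_indel_classes(ref, alt, expected):
    rec = vs.VariantRecord("chr1", 100, ref, alt, 0.5)
    assert vs.classify_indel(rec) == expected


def test_indel_class_rejects_sbs_and_large():
    with pytest.raises(ValueError):
        vs.classify_indel(vs.VariantRecord("chr1", 1, "A", "G", 0.5))
    with pytest.raises(ValueError):
        vs.VariantRecord("chr1", 1, "A" + "C" * 120, "A", 0.5)


def _brute_force_context(left, seq, right):
    """Independent exhaustive scan for a qualifying run or tandem repeat."""
    base = seq[0]
    if all(b == base for b in seq):
        run = len(seq)
        run += len(left) - len(left.rstrip(base))
        run += len(right) - len(right.lstrip(base))
        if run >= 3:
            return "homopolymer"
    ctx = left + seq + right
    lo, hi = len(left), len(left) + len(seq)
    for k in range(2, 7):
        for start in range(len(ctx)):
            for end in range(start + 2 * k, len(ctx) + 1):
                window = ctx[start:end]
                periodic = all(window[i] == window[i - k] for i in range(k, len(window)))
                if periodic and start <= lo and end >= hi and len(window) - (hi - lo) >= k:
                    return "polynucleotide_repeat"
    return "none"


@pytest.mark.parametrize(
    "left,seq,right,expected",
    [
        ("CCCCCCCCCA", "A", "AAGGGGGGGG", "homopolymer"),  # run of 4 A's
        ("GGGGGGGGGAT", "AT", "ATCCCCCCCC", "polynucleotide_repeat"),  # AT x3
        ("TTGCCTGAACT", "G", "CATCGGATCC", "none"),
        ("CCCCCCCAAA", "AAA", "GGGGGGGGGG", "homopolymer"),
        ("ACGTACGTAC", "CAT", "TTTTTTTTTT", "none"),
    ],
)
def test_junction_context_examples(left, seq, right, expected):
    assert vs.junction_context(left, seq, right) == expected
    assert _brute_force_context(left, seq, right) == expected


@given(st.data())
def test_junction_context_agrees_with_exhaustive_scan(data):
    rng_seq = st.text(alphabet="ACGT", min_size=10, max_size=14)
    left = data.draw(rng_seq)
    right = data.draw(rng_seq)
    seq = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=6))
    assert vs.junction_context(left, seq, right) == _brute_force_context(left, seq, right)


def test_junction_context_requires_flanks():
    with pytest.raises(ValueError):
        vs.junction_context("ACGT", "A", "ACGTACGTACGT")


def test_region_class_any_overlap_rule():
    genes = [vs.GeneModel("g", "chr1", "+", ((101, 199),))]
    inside = vs.VariantRecord("chr1", 150, "A", "G", 0.9)
    spanning = vs.VariantRecord("chr1", 198, "ACGTACG", "A", 0.9)  # crosses the boundary
    outside = vs.VariantRecord("chr1", 500, "A", "G", 0.9)
    assert vs.region_class(inside, genes) == "CDS"
    assert vs.region_class(spanning, genes) == "CDS"
    assert vs.region_class(outside, genes) == "non-coding"
    with pytest.raises(ValueError):
        vs.region_class(vs.VariantRecord("chrX", 5, "A", "G", 0.9), genes)


def _mutant_protein(record, gene, genome):
    """Oracle: rebuild the full mutant CDS and translate it."""
    chrom = genome[gene.chrom]
    mutated = chrom[: record.pos - 1] + record.alt + chrom[record.pos - 1 + len(record.ref) :]
    shift = len(record.alt) - len(record.ref)
    cds = []
    for s, e in sorted(gene.cds):
        s2 = s + shift if s > record.pos else s
        e2 = e + shift if e >= record.pos else e
        cds.append(mutated[s2 - 1 : e2])
    seq = "".join(cds)
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return str(Seq(seq[: 3 * (len(seq) // 3)]).translate())


def test_consequence_examples():
    genome = {"chr1": "TTTTT" + "ATG" + "GGA" + "CTT" + "TAA" + "TTTTT"}
    gene = vs.GeneModel("g", "chr1", "+", ((6, 17),))
    silent = vs.VariantRecord("chr1", 11, "A", "G", 1.0)  # GGA -> GGG (Gly)
    assert vs.consequence(silent, gene, genome) == "silent"
    inframe = vs.VariantRecord("chr1", 8, "GGGA", "G", 1.0)  # 3-bp deletion
    assert vs.consequence(inframe, gene, genome) == "in-frame_deletion"
    fs = vs.VariantRecord("chr1", 10, "GA", "G", 1.0)  # 1-bp deletion
    assert vs.consequence(fs, gene, genome) == "frameshift"
    start = vs.VariantRecord("chr1", 6, "A", "C", 1.0)
    assert vs.consequence(start, gene, genome) == "start_loss"
    missense = vs.VariantRecord("chr1", 12, "C", "T", 1.0)  # CTT -> TTT (Leu -> Phe)
    assert vs.consequence(missense, gene, genome) == "missense"


def test_sbs_consequence_agrees_with_translation_oracle(toy_genome_genes):
    """Every SBS consequence call matches a brute-force rebuild-and-translate
    of the mutant CDS, on both strands."""
    genome, genes = toy_genome_genes
    rng = np.random.default_rng(7)
    checked = 0
    for gene in genes:
        s, e = gene.cds[0]
        for _ in range(15):
            pos = int(rng.integers(s, e + 1))
            ref = genome["chr1"][pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            rec = vs.VariantRecord("chr1", pos, ref, alt, 1.0)
            call = vs.consequence(rec, gene, genome)
            ref_prot = str(Seq(gene.coding_sequence(genome)).translate())
            mut_prot = _mutant_protein(rec, gene, genome)
            if call == "silent":
                assert mut_prot == ref_prot
            elif call == "start_loss":
                assert not mut_prot.startswith("M") or gene.cds_index(pos) < 3
            elif call == "premature_stop":
                assert "*" in mut_prot[:-1]
            else:  # missense
                assert len(mut_prot) == len(ref_prot)
                assert mut_prot != ref_prot
                assert "*" not in mut_prot[:-1]
            checked += 1
    assert checked > 100


def test_consequence_on_minus_strand_gene():
    cds = "ATGGGACTTTAA"
    rc = str(Seq(cds).reverse_complement())
    genome = {"chr1": "CCCCC" + rc + "CCCCC"}
    gene = vs.GeneModel("g", "chr1", "-", ((6, 17),))
    assert gene.coding_sequence(genome) == cds
    # genomic base complementary to the GGA codon's third position
    # cds index 5 (A of GGA) maps to genomic position 6 + (12-1-5) = 12
    rec = vs.VariantRecord("chr1", 12, genome["chr1"][11], "C", 1.0)
    assert vs.consequence(rec, gene, genome) in {"silent", "missense"}
    oracle = _mutant_protein(rec, gene, genome)
    expected = "silent" if oracle == str(Seq(cds).translate()) else "missense"
    assert vs.consequence(rec, gene, genome) == expected


def test_summary_counts_conserved_and_permutation_invariant(toy_genome_genes):
    from radmut.synthetic_data import GeneratorConfig, gen_variant_table

    genome, genes = toy_genome_genes
    config = GeneratorConfig(seed=9, genome_length=60_000, n_genes=20, n_variants=150)
    records, _ = gen_variant_table(config, genome, genes)
    length = len(genome["chr1"])
    s1 = vs.summarize_spectrum(records, genes, length, 6, genome=genome)
    s2 = vs.summarize_spectrum(records[::-1], genes, length, 6, genome=genome)
    assert sum(s1.zygosity.values()) == len(records)
    assert sum(s1.regions.values()) == len(records)
    n_indel = s1.n_insertions + s1.n_deletions
    assert s1.n_transitions + s1.n_transversions + n_indel == len(records)
    assert sum(s1.indel_classes.values()) == n_indel
    assert sum(s1.contexts.values()) == n_indel
    assert s1.zygosity == s2.zygosity
    assert s1.indel_classes == s2.indel_classes
    assert s1.frequencies == s2.frequencies


def test_summary_frequency_definition_and_ratio_rounding():
    genes = []
    records = [
        vs.VariantRecord("chr1", 10 * i + 10, "A", "G", 1.0) for i in range(6)
    ]
    s = vs.summarize_spectrum(records, genes, genome_length=10**6, n_individuals=1)
    assert s.frequencies["all_per_bp"] == pytest.approx(6e-6)
    # deletion/insertion rounding: 29/8 = 3.625 -> 3.63
    s.n_deletions, s.n_insertions = 29, 8
    assert s.deletion_insertion_ratio == 3.63
    with pytest.raises(ValueError):
        vs.summarize_spectrum(records, genes, genome_length=0, n_individuals=1)
    with pytest.raises(ValueError):
        vs.summarize_spectrum([], genes, genome_length=100, n_individuals=1)


def test_titv_from_counts():
    s = vs.SpectrumSummary(n_records=9, n_transitions=5, n_transversions=4)
    assert s.titv_ratio == pytest.approx(1.25)


def test_left_normalization_shifts_indel_to_smallest_coordinate():
    genome = {"chr1": "GGCAAAATGG"}
    # deletion of one A written at the right edge of the A-run
    rec = vs.VariantRecord("chr1", 6, "AA", "A", 1.0)
    norm = vs.left_normalize(rec, genome)
    assert (norm.pos, norm.ref, norm.alt) == (3, "CA", "C")
    # insertion of A inside the run shifts likewise
    ins = vs.VariantRecord("chr1", 6, "A", "AA", 1.0)
    norm_ins = vs.left_normalize(ins, genome)
    assert (norm_ins.pos, norm_ins.ref, norm_ins.alt) == (3, "C", "CA")


def test_tsv_and_vcf_readers(tmp_path):
    import pandas as pd

    df = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "pos": [10, 20],
            "ref": ["A", "CT"],
            "alt": ["G", "C"],
            "fraction": [0.9, 0.4],
            "sample": ["s1", "s1"],
        }
    )
    tsv = tmp_path / "v.tsv"
    df.to_csv(tsv, sep="\t", index=False)
    recs = vs.read_variants_tsv(tsv)
    assert len(recs) == 2 and recs[1].indel_length == 1

    vcf = tmp_path / "v.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=AF,Number=A,Type=Float,Description="allele fraction">\n'
        "##contig=<ID=chr1,length=1000>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr1\t10\t.\tA\tG\t.\t.\tAF=0.9\n"
        "chr1\t20\t.\tCT\tC\t.\t.\tAF=0.4\n"
    )
    recs_vcf = vs.read_variants_vcf(vcf)
    assert [(r.chrom, r.pos, r.ref, r.alt) for r in recs_vcf] == [
        (r.chrom, r.pos, r.ref, r.alt) for r in recs
    ]
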