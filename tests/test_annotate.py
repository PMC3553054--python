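"""Effect annotation against gene models, checked against naive oracles."""

import random

import pytest
from Bio.Seq import Seq

from gbskit.annotate import (
    DEFAULT_FLANK,
    SPLICE_WINDOW,
    annotate_variants,
    annotation_summary,
    classify_snp,
    coding_effect,
    parse_gff3,
)
from gbskit.enzymes import revcomp
from gbskit.variants import VariantRecord


def snp(chrom, pos, ref="A", alt="G"):
    return VariantRecord(chrom, pos, ref, (alt,), "SNP", {})


# --- fixture genome: one + strand and one - strand multi-exon gene ----------

CDS_PLUS = "ATGGCTTGCGGATTCAAA"  # M A C G F K (18 nt)


def build_fixture(tmp_path, flip=False):
    """A 12 kb contig with one 3-exon + strand gene and one - strand gene.

    When ``flip`` is true the whole genome and annotation are reverse
    complemented (strand-symmetry checks).
    """
    rng = random.Random(5)
    seq = list(rng.choices("ACGT", k=12_000))
    # + strand gene g1 at [6000, 6400): exons [6000,6100),[6150,6250),[6300,6400)
    # CDS [6050,6068)+[6150,6159)... keep it simple: CDS wholly in exon 2
    # exon1 = 5' UTR, exon3 = 3' UTR, CDS occupies [6150, 6168)
    seq[6150:6168] = CDS_PLUS
    genome = "".join(seq)
    gff_rows = [
        ("chr1", "gene", 6001, 6400, "+", "ID=g1"),
        ("chr1", "mRNA", 6001, 6400, "+", "ID=m1;Parent=g1"),
        ("chr1", "exon", 6001, 6100, "+", "Parent=m1"),
        ("chr1", "exon", 6151, 6250, "+", "Parent=m1"),
        ("chr1", "exon", 6301, 6400, "+", "Parent=m1"),
        ("chr1", "CDS", 6151, 6168, "+", "0;phase0", "Parent=m1"),
    ]
    # - strand gene g2 at [1000, 1300): single exon, CDS [1100,1118) on minus
    seq2 = list(genome)
    seq2[1100:1118] = revcomp(CDS_PLUS)
    genome = "".join(seq2)
    gff = ["##gff-version 3"]
    gff.append("chr1\t.\tgene\t6001\t6400\t.\t+\t.\tID=g1")
    gff.append("chr1\t.\tmRNA\t6001\t6400\t.\t+\t.\tID=m1;Parent=g1")
    gff.append("chr1\t.\texon\t6001\t6100\t.\t+\t.\tParent=m1")
    gff.append("chr1\t.\texon\t6151\t6250\t.\t+\t.\tParent=m1")
    gff.append("chr1\t.\texon\t6301\t6400\t.\t+\t.\tParent=m1")
    gff.append("chr1\t.\tCDS\t6151\t6168\t.\t+\t0\tParent=m1")
    gff.append("chr1\t.\tgene\t1001\t1300\t.\t-\t.\tID=g2")
    gff.append("chr1\t.\tmRNA\t1001\t1300\t.\t-\t.\tID=m2;Parent=g2")
    gff.append("chr1\t.\texon\t1001\t1300\t.\t-\t.\tParent=m2")
    gff.append("chr1\t.\tCDS\t1101\t1118\t.\t-\t0\tParent=m2")
    if flip:
        L = len(genome)
        genome = revcomp(genome)
        flipped = ["##gff-version 3"]
        for line in gff[1:]:
            f = line.split("\t")
            start, end = int(f[3]), int(f[4])
            f[3], f[4] = str(L - end + 1), str(L - start + 1)
            f[6] = "-" if f[6] == "+" else "+"
            flipped.append("\t".join(f))
        gff = flipped
    path = tmp_path / ("flip.gff3" if flip else "fix.gff3")
    path.write_text("\n".join(gff) + "\n")
    return {"chr1": genome}, path


@pytest.fixture(scope="module")
def fixture(tmp_path_factory):
    ref, gff = build_fixture(tmp_path_factory.mktemp("annot"))
    return ref, parse_gff3(gff)


# --- naive oracles -----------------------------------------------------------


def naive_category(pos, models, flank=DEFAULT_FLANK):
    """Per-base scan of every gene segment, mirroring the priority rules."""
    best = None
    order = {
        "SPLICE_SITE": 0,
        "UTR5": 1,
        "UTR3": 2,
        "EXON": 3,
        "INTRON": 4,
    }
    for m in models:
        if not (m.start <= pos < m.end):
            continue
        cats = set()
        for a, b in m.introns:
            if a <= pos < b:
                near = pos < a + SPLICE_WINDOW or pos >= b - SPLICE_WINDOW
                cats.add("SPLICE_SITE" if near else "INTRON")
        for a, b in m.utr5:
            if a <= pos < b:
                cats.add("UTR5")
        for a, b in m.utr3:
            if a <= pos < b:
                cats.add("UTR3")
        if not cats & {"UTR5", "UTR3"}:
            for a, b in m.exons:
                if a <= pos < b:
                    cats.add("EXON")
        if not cats:
            cats.add("INTRON")
        cat = min(cats, key=lambda c: order[c])
        if best is None or order[cat] < order[best]:
            best = cat
    if best:
        return best
    dists = []
    for m in models:
        if pos < m.start:
            d, cat = m.start - pos, ("UPSTREAM_5KB" if m.strand == "+" else "DOWNSTREAM_5KB")
        else:
            d, cat = pos - (m.end - 1), ("DOWNSTREAM_5KB" if m.strand == "+" else "UPSTREAM_5KB")
        if d <= flank:
            dists.append((d, m.gene_id, cat))
    return min(dists)[2] if dists else "INTERGENIC"


def naive_effect(variant, model, reference):
    """Translate the full mutant CDS and diff the protein."""
    mutated = dict(reference)
    chrom_seq = list(mutated[variant.chrom])
    chrom_seq[variant.pos] = variant.alts[0]
    mutated[variant.chrom] = "".join(chrom_seq)
    ref_prot = str(Seq(model.cds_sequence(reference)).translate())
    alt_prot = str(Seq(model.cds_sequence(mutated)).translate())
    if ref_prot == alt_prot:
        return "SYNONYMOUS"
    for a, b in zip(ref_prot, alt_prot):
        if a != b:
            return "STOP_GAINED" if b == "*" else "NONSYNONYMOUS"
    return "NONSYNONYMOUS"


# --- tests -------------------------------------------------------------------


class TestParseGff3:
    def test_three_exon_gene_has_two_introns(self, fixture):
        _, models = fixture
        g1 = next(m for m in models if m.gene_id == "g1")
        assert len(g1.exons) == 3
        assert g1.introns == [(6100, 6150), (6250, 6300)]
        assert g1.cds == [(6150, 6168, 0)]
        assert not g1.partial

    def test_noncoding_gene_has_no_utrs(self, tmp_path):
        gff = tmp_path / "nc.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\t.\tgene\t11\t50\t.\t+\t.\tID=nc\n"
            "chr1\t.\tmRNA\t11\t50\t.\t+\t.\tID=ncm;Parent=nc\n"
            "chr1\t.\texon\t11\t50\t.\t+\t.\tParent=ncm\n"
        )
        (model,) = parse_gff3(gff)
        assert model.cds == [] and model.utr5 == [] and model.utr3 == []
        ann = classify_snp(snp("chr1", 20), [model])
        assert ann.category == "EXON" and ann.coding_effect == "NA"

    def test_empty_file(self, tmp_path):
        gff = tmp_path / "e.gff3"
        gff.write_text("##gff-version 3\n")
        assert parse_gff3(gff) == []

    def test_longest_cds_isoform_chosen(self, tmp_path):
        gff = tmp_path / "iso.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\t.\tgene\t1\t100\t.\t+\t.\tID=g\n"
            "chr1\t.\tmRNA\t1\t100\t.\t+\t.\tID=short;Parent=g\n"
            "chr1\t.\texon\t1\t100\t.\t+\t.\tParent=short\n"
            "chr1\t.\tCDS\t10\t15\t.\t+\t0\tParent=short\n"
            "chr1\t.\tmRNA\t1\t100\t.\t+\t.\tID=long;Parent=g\n"
            "chr1\t.\texon\t1\t100\t.\t+\t.\tParent=long\n"
            "chr1\t.\tCDS\t10\t30\t.\t+\t0\tParent=long\n"
        )
        (model,) = parse_gff3(gff)
        assert model.cds_length == 21


class TestClassifySnp:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            (6100, "SPLICE_SITE"),  # first intron base
            (6101, "SPLICE_SITE"),  # second intron base
            (6102, "INTRON"),  # third intron base, outside the window
            (6149, "SPLICE_SITE"),  # last intron base
            (6050, "UTR5"),
            (6350, "UTR3"),
            (6155, "EXON"),
            (5990, "UPSTREAM_5KB"),
            (11_350, "DOWNSTREAM_5KB"),
        ],
    )
    def test_structural_categories(self, fixture, pos, expected):
        _, models = fixture
        assert classify_snp(snp("chr1", pos), models).category == expected

    def test_flank_boundary_inclusive_at_5kb(self, fixture):
        _, models = fixture
        g1 = [m for m in models if m.gene_id == "g1"]
        assert classify_snp(snp("chr1", 6000 - 4999), g1).category == "UPSTREAM_5KB"
        assert classify_snp(snp("chr1", 6000 - 5000), g1).category == "UPSTREAM_5KB"
        assert classify_snp(snp("chr1", 6000 - 5001), g1).category == "INTERGENIC"

    def test_flank_is_strand_aware_on_minus_gene(self, fixture):
        _, models = fixture
        g2 = [m for m in models if m.gene_id == "g2"]
        # 3' of a minus-strand gene span (lower coordinates) is downstream
        assert classify_snp(snp("chr1", 500), g2).category == "DOWNSTREAM_5KB"
        assert classify_snp(snp("chr1", 1500), g2).category == "UPSTREAM_5KB"

    def test_unknown_chromosome_is_intergenic(self, fixture):
        _, models = fixture
        assert classify_snp(snp("chrZ", 5), models).category == "INTERGENIC"

    def test_matches_naive_oracle_everywhere(self, fixture):
        _, models = fixture
        rng = random.Random(1)
        positions = (
            list(range(990, 1320))
            + list(range(5990, 6410))
            + [rng.randrange(12_000) for _ in range(300)]
        )
        for pos in positions:
            got = classify_snp(snp("chr1", pos), models).category
            assert got == naive_category(pos, models), pos


class TestCodingEffect:
    def test_third_position_synonymous(self, fixture):
        ref, models = fixture
        g1 = next(m for m in models if m.gene_id == "g1")
        # codon 2 GCT at [6153,6156): T->C is Ala->Ala
        assert ref["chr1"][6155] == "T"
        assert coding_effect(snp("chr1", 6155, "T", "C"), g1, ref) == "SYNONYMOUS"

    def test_stop_gained(self, fixture):
        ref, models = fixture
        g1 = next(m for m in models if m.gene_id == "g1")
        # codon 3 TGC at [6156,6159): C->A gives TGA
        assert coding_effect(snp("chr1", 6158, "C", "A"), g1, ref) == "STOP_GAINED"

    def test_minus_strand_recomputed_on_coding_strand(self, fixture):
        ref, models = fixture
        g2 = next(m for m in models if m.gene_id == "g2")
        # CDS occupies [1100,1118) on the minus strand; genomic base
        # complementing codon-2 third position: cds index 5 -> genome 1112
        pos = 1117 - 5
        assert coding_effect(
            snp("chr1", pos, ref["chr1"][pos], "G"), g2, ref
        ) == naive_effect(snp("chr1", pos, ref["chr1"][pos], "G"), g2, ref)

    @pytest.mark.parametrize("gene", ["g1", "g2"])
    def test_agrees_with_full_translation_oracle(self, fixture, gene):
        ref, models = fixture
        model = next(m for m in models if m.gene_id == gene)
        for a, b, _ in model.cds:
            for pos in range(a, b):
                for alt in "ACGT":
                    if alt == ref["chr1"][pos]:
                        continue
                    v = snp("chr1", pos, ref["chr1"][pos], alt)
                    assert coding_effect(v, model, ref) == naive_effect(v, model, ref), (
                        pos,
                        alt,
                    )

    def test_partial_cds_gives_na(self, tmp_path):
        gff = tmp_path / "p.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\t.\tgene\t1\t50\t.\t+\t.\tID=g\n"
            "chr1\t.\tmRNA\t1\t50\t.\t+\t.\tID=m;Parent=g\n"
            "chr1\t.\texon\t1\t50\t.\t+\t.\tParent=m\n"
            "chr1\t.\tCDS\t10\t20\t.\t+\t0\tParent=m\n"  # 11 nt: partial
        )
        (model,) = parse_gff3(gff)
        assert model.partial
        ref = {"chr1": "A" * 50}
        assert coding_effect(snp("chr1", 12), model, ref) == "NA"


class TestStrandSymmetry:
    def test_categories_invariant_under_genome_reverse_complement(self, tmp_path):
        ref_f, gff_f = build_fixture(tmp_path, flip=False)
        ref_r, gff_r = build_fixture(tmp_path, flip=True)
        models_f = parse_gff3(gff_f)
        models_r = parse_gff3(gff_r)
        L = len(ref_f["chr1"])
        rng = random.Random(2)
        positions = list(range(5990, 6410, 7)) + [rng.randrange(L) for _ in range(120)]
        for pos in positions:
            a = classify_snp(snp("chr1", pos), models_f).category
            b = classify_snp(snp("chr1", L - 1 - pos), models_r).category
            assert a == b, pos

    def test_effects_invariant_under_reverse_complement(self, tmp_path):
        ref_f, gff_f = build_fixture(tmp_path, flip=False)
        ref_r, gff_r = build_fixture(tmp_path, flip=True)
        g1_f = next(m for m in parse_gff3(gff_f) if m.gene_id == "g1")
        g1_r = next(m for m in parse_gff3(gff_r) if m.gene_id == "g1")
        L = len(ref_f["chr1"])
        for pos in range(6150, 6168):
            base = ref_f["chr1"][pos]
            for alt in "ACGT":
                if alt == base:
                    continue
                eff_f = coding_effect(snp("chr1", pos, base, alt), g1_f, ref_f)
                flip_pos = L - 1 - pos
                eff_r = coding_effect(
                    snp("chr1", flip_pos, revcomp(base), revcomp(alt)), g1_r, ref_r
                )
                assert eff_f == eff_r, (pos, alt)


class TestAnnotationSummary:
    def test_all_intergenic(self, fixture):
        _, models = fixture
        anns = [classify_snp(snp("chr1", 11_990 - i), models) for i in range(3)]
        table = annotation_summary(anns)
        row = table[(table.partition == "category") & (table.label == "INTERGENIC")]
        assert row.percent.iloc[0] == 100.0

    def test_syn_nonsyn_split(self, fixture):
        ref, models = fixture
        variants = [
            snp("chr1", 6155, "T", "C"),  # synonymous
            snp("chr1", 6154, "C", "T"),  # GCT->GTT nonsynonymous
            snp("chr1", 6158, "C", "A"),  # stop gained
            snp("chr1", 6152, "G", "T"),  # ATG->ATT nonsynonymous
        ]
        anns = annotate_variants(variants, models, ref)
        table = annotation_summary(anns)
        coding = table[table.partition == "coding"].set_index("label")
        assert coding.loc["SYNONYMOUS", "percent"] == 25.0
        assert coding.loc["NONSYNONYMOUS_OR_STOP", "percent"] == 75.0

    def test_compartment_partition_sums_to_100(self, fixture):
        _, models = fixture
        anns = [classify_snp(snp("chr1", p), models) for p in range(6000, 6400, 13)]
        table = annotation_summary(anns)
        comp = table[table.partition == "compartment"]
        assert comp.percent.sum() == pytest.approx(100.0)

    def test_empty_input(self):
        assert annotation_summary([]).empty
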