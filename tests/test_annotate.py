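"""Region classification, codon consequences, polarity and BLOSUM scoring."""

import itertools

import pytest
from Bio.Seq import Seq

from editscan.annotate import (
    DEFAULT_POLARITY_TABLE,
    aa_substitution_spectrum,
    annotate_sites,
    blosum_fraction,
    cds_consequence,
    classify_region,
    classify_region_for_model,
    load_blosum80,
    polarity_change,
    reachable_substitutions,
)
from editscan.editing_caller import EditingSite
from editscan.seqio import GeneModel, revcomp


def _site(pos, strand="+", chrom="chr1"):
    ref, alt = ("A", "G") if strand == "+" else ("T", "C")
    return EditingSite(chrom, pos, strand, ref, alt, 0.5, 50)


# ---------------------------------------------------------------------------
# Region classification
# ---------------------------------------------------------------------------

# two-exon coding gene: exon1 [0,120), intron [120,220), exon2 [220,400);
# CDS [30,120)+[220,330); UTR5 [0,30); UTR3 [330,400)
TWO_EXON = GeneModel(
    "g", "g.1", "chr1", "+",
    exons=[(0, 120), (220, 400)],
    cds=[(30, 120), (220, 330)],
)


@pytest.mark.parametrize(
    "pos,expected",
    [
        (121, "splicing"),  # 2nd intronic nt after the donor junction
        (120, "splicing"),
        (219, "splicing"),  # intronic side of the acceptor
        (118, "splicing"),  # terminal 2 exonic nt
        (221, "splicing"),
        (75, "exonic"),  # mid-CDS
        (10, "UTR5"),
        (350, "UTR3"),
        (170, "intronic"),
        (500, "intergenic"),
        (117, "exonic"),  # 3 nt from the junction: outside the window
        (122, "intronic"),
    ],
)
def test_region_classes_with_splice_window(pos, expected):
    assert classify_region_for_model(pos, TWO_EXON) == expected


def test_ncrna_exon_class():
    nc = GeneModel("n", "n.1", "chr1", "+", [(0, 100)], [], biotype="ncRNA")
    assert classify_region_for_model(50, nc) == "ncRNA"


def test_multi_transcript_reduction_uses_precedence():
    nc = GeneModel("n", "n.1", "chr1", "+", [(60, 90)], [], biotype="ncRNA")
    cls, model = classify_region(_site(75), [TWO_EXON, nc])
    assert cls == "exonic"  # exonic(CDS) beats ncRNA
    assert model.transcript_id == "g.1"


def test_region_classes_partition():
    """Every position of the gene body gets exactly one class."""
    counts = {}
    for pos in range(0, 400):
        cls = classify_region_for_model(pos, TWO_EXON)
        counts[cls] = counts.get(cls, 0) + 1
    assert sum(counts.values()) == 400
    # splicing: 4 positions per junction boundary x 2 junctions
    assert counts["splicing"] == 8
    assert counts["intronic"] == 100 - 4  # minus two intronic dinucleotides
    assert "intergenic" not in counts


# ---------------------------------------------------------------------------
# Codon consequences: the canonical recoding examples
# ---------------------------------------------------------------------------


def _gene_for_codons(codons, strand="+"):
    """Single-exon gene whose CDS is ATG + codons + TAA, on chr1 at 0."""
    cds = "ATG" + "".join(codons) + "TAA"
    if strand == "+":
        genome = {"chr1": cds + "ACGT" * 5}
        model = GeneModel("g", "g.1", "chr1", "+", [(0, len(cds))], [(0, len(cds))])
    else:
        genome = {"chr1": "ACGT" * 5 + revcomp(cds)}
        model = GeneModel(
            "g", "g.1", "chr1", "-", [(20, 20 + len(cds))], [(20, 20 + len(cds))]
        )
    return genome, model, cds


@pytest.mark.parametrize(
    "codon,offset,aa_change,cls",
    [
        ("AGT", 0, "S>G", "nonsynonymous"),
        ("AGC", 0, "S>G", "nonsynonymous"),
        ("AAA", 1, "K>R", "nonsynonymous"),
        ("AAA", 0, "K>E", "nonsynonymous"),
        ("TAT", 1, "Y>C", "nonsynonymous"),
        ("ATA", 0, "I>V", "nonsynonymous"),
        ("CCA", 2, "P>P", "synonymous"),
        ("ACA", 2, "T>T", "synonymous"),
    ],
)
def test_recoding_examples_plus_strand(codon, offset, aa_change, cls):
    genome, model, cds = _gene_for_codons([codon])
    pos = 3 + offset  # codon sits after ATG
    c = cds_consequence(_site(pos), model, genome)
    assert c.substitution == aa_change
    assert c.consequence == cls
    assert c.codon_index == 1


def test_recoding_examples_minus_strand():
    genome, model, cds = _gene_for_codons(["AGT"], strand="-")
    # transcript-strand A at CDS index 3 maps to genome pos 20 + len-1 - 3
    gpos = 20 + len(cds) - 1 - 3
    c = cds_consequence(_site(gpos, strand="-"), model, genome)
    assert c.substitution == "S>G"
    assert c.consequence == "nonsynonymous"


def test_startloss_at_initiator_atg():
    genome, model, _ = _gene_for_codons(["CCC"])
    c = cds_consequence(_site(0), model, genome)
    assert c.codon_before == "ATG" and c.codon_after == "GTG"
    assert c.consequence == "startloss"


@pytest.mark.parametrize("stop", ["TAG", "TGA"])
def test_stoploss_at_terminal_stop(stop):
    cds = "ATG" + "CCC" + stop
    genome = {"chr1": cds + "ACGTACGT"}
    model = GeneModel("g", "g.1", "chr1", "+", [(0, 9)], [(0, 9)])
    a_offset = stop.index("A")
    c = cds_consequence(_site(6 + a_offset), model, genome)
    assert c.consequence == "stoploss"
    assert c.codon_after == "TGG"  # both stops become Trp


def test_taa_to_tga_remains_stop_synonymous():
    cds = "ATGCCCTAA"
    genome = {"chr1": cds + "ACGTACGT"}
    model = GeneModel("g", "g.1", "chr1", "+", [(0, 9)], [(0, 9)])
    c = cds_consequence(_site(7), model, genome)  # TAA -> TGA
    assert c.consequence == "synonymous"
    assert c.aa_after == "*"


def test_non_a_position_rejected():
    genome, model, _ = _gene_for_codons(["CTA"])
    with pytest.raises(ValueError, match="not A"):
        cds_consequence(_site(4), model, genome)  # T at codon offset 1


def test_synonymy_agrees_with_brute_force_translator():
    """All 64 codons x editable A offsets, against independent translation."""
    for codon in ("".join(c) for c in itertools.product("ACGT", repeat=3)):
        for off, base in enumerate(codon):
            if base != "A":
                continue
            genome, model, cds = _gene_for_codons([codon])
            c = cds_consequence(_site(3 + off), model, genome)
            after = codon[:off] + "G" + codon[off + 1 :]
            aa_b = str(Seq(codon).translate())
            aa_a = str(Seq(after).translate())
            assert c.codon_after == after
            assert (c.consequence == "synonymous") == (aa_b == aa_a)


def test_reachable_substitution_closure():
    reachable = reachable_substitutions()
    # observed substitutions on arbitrary codon input stay inside the closure
    for codon in ("AGT", "AAA", "TAT", "ATA", "GAT", "CAT"):
        for off, base in enumerate(codon):
            if base != "A":
                continue
            genome, model, _ = _gene_for_codons([codon])
            c = cds_consequence(_site(3 + off), model, genome)
            if c.consequence != "synonymous":
                assert c.substitution in reachable
    assert "S>G" in reachable and "K>R" in reachable and "K>E" in reachable


# ---------------------------------------------------------------------------
# Polarity and BLOSUM
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "a,b,verdict",
    [("K", "R", "Same"), ("S", "G", "Change"), ("I", "V", "Same"), ("Y", "C", "Same")],
)
def test_polarity_verdicts(a, b, verdict):
    assert polarity_change(a, b) == verdict


def test_polarity_table_covers_20_residues_and_stops_are_na():
    assert len(DEFAULT_POLARITY_TABLE) == 20
    assert polarity_change("*", "W") == "NA"
    with pytest.raises(KeyError):
        polarity_change("X", "A")


def test_blosum80_symmetric_positive_diagonal_and_signs():
    m = load_blosum80()
    assert m["K", "R"] > 0  # conserved substitution
    assert m["S", "G"] <= 0  # not conserved
    assert m["Y", "C"] < 0


def test_blosum_fraction_arithmetic():
    from editscan.annotate import CodingConsequence

    def cc(a, b):
        return CodingConsequence("t", 0, "NNN", "NNN", a, b, "nonsynonymous")

    frac, scores = blosum_fraction([cc("K", "R"), cc("S", "G"), cc("I", "V"), cc("Y", "C")])
    assert frac == pytest.approx(2 / 4)  # K>R and I>V positive under BLOSUM80
    assert scores["K>R"] > 0 and scores["Y>C"] < 0


def test_substitution_spectrum_frequencies():
    from editscan.annotate import CodingConsequence

    def cc(a, b):
        return CodingConsequence("t", 0, "NNN", "NNN", a, b, "nonsynonymous")

    spec = aa_substitution_spectrum([cc("S", "G")] * 3 + [cc("K", "R")])
    assert spec["S>G"]["frequency"] == pytest.approx(0.75)
    assert sum(v["count"] for v in spec.values()) == 4
    assert aa_substitution_spectrum([]) == {}


def test_annotate_sites_tolerates_wrong_strand_call():
    """A +-strand call inside a minus-strand CDS keeps its region but gets no
    codon consequence."""
    genome = {"chr1": revcomp("ATG" + "CCC" * 5 + "TAA") + "ACGT"}
    model = GeneModel("g", "g.1", "chr1", "-", [(0, 21)], [(0, 21)])
    out = annotate_sites([_site(5, strand="+")], [model], genome)
    assert out[0].region == "exonic"
    assert out[0].consequence is None
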