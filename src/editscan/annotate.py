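"""Gene-based annotation of editing sites and coding-consequence analysis.

A site is classified into exactly one region class per transcript (splicing
beats everything, then CDS, UTR5, UTR3, intron, ncRNA, intergenic); the
splicing window is +/-2 nt around each exon-intron junction, i.e. the first
and last two intronic nucleotides of an intron plus the terminal two exonic
nucleotides on either side of it.

For CDS sites the edited codon is reconstructed from the spliced CDS on the
coding strand, the A->G change applied at the in-codon offset and translated
with the standard genetic code; consequences are synonymous / nonsynonymous /
start-loss / stop-loss.  Recoding events are further scored by amino-acid
polarity (Same/Change) and by their BLOSUM80 entry, whose positive scores
mark substitutions common among related proteins.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .editing_caller import EditingSite
from .seqio import GeneModel

REGION_PRECEDENCE = [
    "splicing",
    "exonic",
    "UTR5",
    "UTR3",
    "intronic",
    "ncRNA",
    "intergenic",
]

#: Default amino-acid polarity categories (config-replaceable).
DEFAULT_POLARITY_TABLE: dict[str, str] = {
    **{aa: "nonpolar" for aa in "GAVLIPFMW"},
    **{aa: "polar-uncharged" for aa in "STCYNQ"},
    **{aa: "basic" for aa in "KRH"},
    **{aa: "acidic" for aa in "DE"},
}

SPLICE_WINDOW = 2


def load_blosum80():
    """BLOSUM80 in the standard half-bit integer scaling; symmetry and a
    strictly positive diagonal are asserted at load."""
    m = substitution_matrices.load("BLOSUM80")
    for a in "ACDEFGHIKLMNPQRSTVWY":
        for b in "ACDEFGHIKLMNPQRSTVWY":
            assert m[a, b] == m[b, a], "BLOSUM80 must be symmetric"
        assert m[a, a] > 0, "BLOSUM80 diagonal must be positive"
    return m


@dataclass
class CodingConsequence:
    transcript_id: str
    codon_index: int
    codon_before: str
    codon_after: str
    aa_before: str  # one-letter; '*' for stop
    aa_after: str
    consequence: str  # synonymous | nonsynonymous | startloss | stoploss
    polarity_verdict: str = "NA"  # Same | Change | NA
    blosum80: int | None = None

    @property
    def substitution(self) -> str:
        return f"{self.aa_before}>{self.aa_after}"


@dataclass
class AnnotatedSite:
    site: EditingSite
    region: str
    transcript_id: str | None = None
    consequence: CodingConsequence | None = None


# ---------------------------------------------------------------------------
# Region classification
# ---------------------------------------------------------------------------


def _splice_positions(model: GeneModel) -> set[int]:
    pos: set[int] = set()
    for istart, iend in model.introns:
        # intronic dinucleotides on both sides of the junction
        pos.update(range(istart, min(istart + SPLICE_WINDOW, iend)))
        pos.update(range(max(iend - SPLICE_WINDOW, istart), iend))
        # terminal two exonic nucleotides flanking the junction
        pos.update(range(istart - SPLICE_WINDOW, istart))
        pos.update(range(iend, iend + SPLICE_WINDOW))
    return pos


def _in(intervals: Sequence[tuple[int, int]], pos: int) -> bool:
    return any(s <= pos < e for s, e in intervals)


def classify_region_for_model(pos: int, model: GeneModel) -> str:
    s, e = model.span
    if not (s <= pos < e):
        return "intergenic"
    if pos in _splice_positions(model):
        return "splicing"
    if model.biotype == "ncRNA":
        return "ncRNA" if _in(model.exons, pos) else "intronic"
    if _in(model.cds, pos):
        return "exonic"
    if _in(model.utr5, pos):
        return "UTR5"
    if _in(model.utr3, pos):
        return "UTR3"
    if not _in(model.exons, pos):
        return "intronic"
    return "exonic"  # coding exon without CDS annotation


def classify_region(
    site: EditingSite, gene_models: Sequence[GeneModel]
) -> tuple[str, GeneModel | None]:
    """Classify a site, reducing over transcripts by the fixed precedence;
    returns the winning class and the transcript that produced it."""
    best = ("intergenic", None)
    best_rank = REGION_PRECEDENCE.index("intergenic")
    for model in gene_models:
        if model.chrom != site.chrom:
            continue
        cls = classify_region_for_model(site.pos, model)
        rank = REGION_PRECEDENCE.index(cls)
        if rank < best_rank:
            best, best_rank = (cls, model), rank
    return best


# ---------------------------------------------------------------------------
# Coding consequence
# ---------------------------------------------------------------------------


def _cds_index(model: GeneModel, pos: int) -> int | None:
    """Index of a genomic position within the spliced CDS (coding strand)."""
    offset = 0
    hit = None
    for s, e in model.cds:
        if s <= pos < e:
            hit = offset + (pos - s)
        offset += e - s
    if hit is None:
        return None
    return offset - 1 - hit if model.strand == "-" else hit


def cds_consequence(
    site: EditingSite, model: GeneModel, genome: Mapping[str, str]
) -> CodingConsequence:
    """Codon-level effect of the A->G edit in one transcript's CDS."""
    idx = _cds_index(model, site.pos)
    if idx is None:
        raise ValueError(f"site {site.key} is not in the CDS of {model.transcript_id}")
    cds = model.cds_sequence(genome)
    if len(cds) % 3 != 0:
        raise ValueError(f"{model.transcript_id}: CDS length not divisible by 3")
    if cds[idx] != "A":
        raise ValueError(
            f"site {site.key}: coding-strand base is {cds[idx]!r}, not A"
        )
    codon_index, offset = divmod(idx, 3)
    before = cds[codon_index * 3 : codon_index * 3 + 3]
    after = before[:offset] + "G" + before[offset + 1 :]
    aa_before = str(Seq(before).translate())
    aa_after = str(Seq(after).translate())

    n_codons = len(cds) // 3
    if codon_index == 0 and before == "ATG" and after != "ATG":
        consequence = "startloss"
    elif codon_index == n_codons - 1 and aa_before == "*" and aa_after != "*":
        consequence = "stoploss"
    elif aa_before == aa_after:
        consequence = "synonymous"
    else:
        consequence = "nonsynonymous"
    return CodingConsequence(
        transcript_id=model.transcript_id,
        codon_index=codon_index,
        codon_before=before,
        codon_after=after,
        aa_before=aa_before,
        aa_after=aa_after,
        consequence=consequence,
    )


def annotate_sites(
    sites: Sequence[EditingSite],
    gene_models: Sequence[GeneModel],
    genome: Mapping[str, str],
    polarity_table: Mapping[str, str] | None = None,
) -> list[AnnotatedSite]:
    """Full annotation: region class plus, for CDS sites, the coding
    consequence with polarity verdict and BLOSUM80 score."""
    table = polarity_table or DEFAULT_POLARITY_TABLE
    blosum = load_blosum80()
    out = []
    for site in sites:
        region, model = classify_region(site, gene_models)
        cons = None
        if region == "exonic" and model is not None and model.cds:
            try:
                cons = cds_consequence(site, model, genome)
            except ValueError:
                # e.g. a +-strand call landing in a minus-strand CDS, where
                # the coding-strand base is not A; region stays exonic but no
                # codon consequence can be assigned
                cons = None
            if cons is not None:
                cons.polarity_verdict = polarity_change(
                    cons.aa_before, cons.aa_after, table
                )
                if "*" not in (cons.aa_before, cons.aa_after):
                    cons.blosum80 = int(blosum[cons.aa_before, cons.aa_after])
        out.append(
            AnnotatedSite(
                site=site,
                region=region,
                transcript_id=model.transcript_id if model else None,
                consequence=cons,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Summaries over consequences
# ---------------------------------------------------------------------------


def aa_substitution_spectrum(
    consequences: Iterable[CodingConsequence],
) -> dict[str, dict[str, float]]:
    """Counts and relative frequencies of amino-acid substitution types among
    recoding (nonsynonymous/startloss/stoploss) consequences."""
    counts = Counter(
        c.substitution
        for c in consequences
        if c.consequence in ("nonsynonymous", "startloss", "stoploss")
    )
    total = sum(counts.values())
    return {
        sub: {"count": n, "frequency": n / total if total else 0.0}
        for sub, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    }


def reachable_substitutions() -> set[str]:
    """All amino-acid substitutions reachable by editing one A in any codon,
    enumerated exhaustively over the 64 codons (recoding only)."""
    subs = set()
    for codon in ("".join(c) for c in itertools.product("ACGT", repeat=3)):
        for i, base in enumerate(codon):
            if base != "A":
                continue
            after = codon[:i] + "G" + codon[i + 1 :]
            a, b = str(Seq(codon).translate()), str(Seq(after).translate())
            if a != b:
                subs.add(f"{a}>{b}")
    return subs


def polarity_change(
    aa_before: str, aa_after: str, table: Mapping[str, str] | None = None
) -> str:
    """'Same' iff both residues share a polarity category; stop-involving
    substitutions are 'NA'."""
    table = table or DEFAULT_POLARITY_TABLE
    if aa_before == "*" or aa_after == "*":
        return "NA"
    for aa in (aa_before, aa_after):
        if aa not in table:
            raise KeyError(f"unknown residue {aa!r}")
    return "Same" if table[aa_before] == table[aa_after] else "Change"


def blosum_fraction(
    consequences: Iterable[CodingConsequence], matrix=None
) -> tuple[float, dict[str, int]]:
    """Fraction of nonsynonymous substitutions with a positive BLOSUM80 score
    (evolutionarily common substitutions), plus per-substitution scores."""
    matrix = matrix if matrix is not None else load_blosum80()
    scores = {}
    n_pos = n_tot = 0
    for c in consequences:
        if c.consequence != "nonsynonymous":
            continue
        if "*" in (c.aa_before, c.aa_after):
            continue
        score = int(matrix[c.aa_before, c.aa_after])
        scores[c.substitution] = score
        n_tot += 1
        if score > 0:
            n_pos += 1
    return (n_pos / n_tot if n_tot else float("nan")), scores
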