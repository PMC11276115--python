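"""Readers/writers for the standard formats the pipeline touches.

Single source of coordinate conventions: everything public (FASTA headers
aside, i.e. SAM, GFF3, VCF, site TSVs) is 1-based; every internal interval is
0-based half-open. Converting in and back out is the identity.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

DNA_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: CIGAR operations understood by the pipeline.  Sufficient for spliced
#: RNA-seq (M = aligned, I/D = indel, N = intron skip, S = soft clip).
SUPPORTED_CIGAR_OPS = set("MIDNS")

_CIGAR_RE = re.compile(r"(\d+)([A-Z=])")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(DNA_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeSequence:
    """A chromosome: a name plus an uppercase DNA string over {A,C,G,T,N}."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"sequence {self.name!r} is empty")
        self.seq = self.seq.upper()
        if set(self.seq) - set("ACGTN"):
            bad = sorted(set(self.seq) - set("ACGTN"))
            raise ValueError(f"sequence {self.name!r} has non-ACGTN letters: {bad}")

    def __len__(self) -> int:
        return len(self.seq)


Interval = tuple[int, int]  # 0-based half-open


@dataclass
class GeneModel:
    """One transcript model: exon/CDS intervals in genomic coordinates.

    ``exons`` and ``cds`` are sorted, non-overlapping, 0-based half-open
    genomic intervals (ascending regardless of strand).  UTRs are derived as
    exon minus CDS; for minus-strand models the 5' UTR is the right-hand
    (higher-coordinate) flank.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str  # "+" or "-"
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    biotype: str = "coding"  # "coding" | "ncRNA"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        for name, ivals in (("exons", self.exons), ("cds", self.cds)):
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError(f"{self.transcript_id}: overlapping {name}")
        # CDS must lie within the exon union; divisibility by 3 is checked by
        # validate_coding (parsed models are flagged, not rejected)
        for c in self.cds:
            if not any(e[0] <= c[0] and c[1] <= e[1] for e in self.exons):
                raise ValueError(f"{self.transcript_id}: CDS outside exons")

    # -- interval arithmetic ------------------------------------------------

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def introns(self) -> list[Interval]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    def _exon_minus_cds(self) -> list[Interval]:
        """Exonic intervals not covered by CDS, sorted ascending."""
        out: list[Interval] = []
        for es, ee in self.exons:
            cur = es
            for cs, ce in self.cds:
                if ce <= es or cs >= ee:
                    continue
                if cs > cur:
                    out.append((cur, cs))
                cur = max(cur, ce)
            if cur < ee:
                out.append((cur, ee))
        return out

    @property
    def utr5(self) -> list[Interval]:
        if not self.cds:
            return []
        cds_start, cds_end = self.cds[0][0], self.cds[-1][1]
        utr = self._exon_minus_cds()
        if self.strand == "+":
            return [iv for iv in utr if iv[1] <= cds_start]
        return [iv for iv in utr if iv[0] >= cds_end]

    @property
    def utr3(self) -> list[Interval]:
        if not self.cds:
            return []
        cds_start, cds_end = self.cds[0][0], self.cds[-1][1]
        utr = self._exon_minus_cds()
        if self.strand == "+":
            return [iv for iv in utr if iv[0] >= cds_end]
        return [iv for iv in utr if iv[1] <= cds_start]

    # -- sequence access ----------------------------------------------------

    def spliced_sequence(self, genome: dict[str, str]) -> str:
        """Mature transcript sequence on the transcript strand."""
        chrom = genome[self.chrom]
        s = "".join(chrom[a:b] for a, b in self.exons)
        return revcomp(s) if self.strand == "-" else s

    def cds_sequence(self, genome: dict[str, str]) -> str:
        """Spliced CDS on the coding strand (starts ATG, ends at a stop)."""
        chrom = genome[self.chrom]
        s = "".join(chrom[a:b] for a, b in self.cds)
        return revcomp(s) if self.strand == "-" else s

    def transcript_to_genome(self) -> list[int]:
        """Genomic position of each mature-transcript base (transcript order)."""
        pos = [p for a, b in self.exons for p in range(a, b)]
        return pos[::-1] if self.strand == "-" else pos

    def validate_coding(self, genome: dict[str, str]) -> list[str]:
        """Return a list of problems with the coding annotation (empty = ok)."""
        problems = []
        if self.biotype != "coding" or not self.cds:
            return problems
        cds = self.cds_sequence(genome)
        if len(cds) % 3 != 0:
            problems.append("CDS length not divisible by 3")
            return problems
        if not cds.startswith("ATG"):
            problems.append("CDS does not start with ATG")
        if str(Seq(cds[-3:]).translate()) != "*":
            problems.append("CDS does not end with a stop codon")
        return problems


@dataclass
class AlignedRead:
    """A (possibly spliced) alignment; ``pos`` is 0-based leftmost internally."""

    read_id: str
    chrom: str
    pos: int
    is_reverse: bool
    cigar: list[tuple[str, int]]
    seq: str
    qual: str  # Phred+33

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("negative position")
        bad = {op for op, _ in self.cigar} - SUPPORTED_CIGAR_OPS
        if bad:
            raise ValueError(f"unsupported CIGAR op(s) {sorted(bad)} in {self.read_id}")
        qlen = sum(n for op, n in self.cigar if op in "MIS")
        if qlen != len(self.seq):
            raise ValueError(
                f"{self.read_id}: CIGAR query length {qlen} != seq length {len(self.seq)}"
            )
        if len(self.qual) != len(self.seq):
            raise ValueError(f"{self.read_id}: qual/seq length mismatch")

    @property
    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)

    def reference_span(self) -> Interval:
        length = sum(n for op, n in self.cigar if op in "MDN")
        return (self.pos, self.pos + length)

    def aligned_blocks(self) -> list[tuple[int, int, int]]:
        """M-op blocks as (ref_start, ref_end, query_start) triples."""
        blocks = []
        rpos, qpos = self.pos, 0
        for op, n in self.cigar:
            if op == "M":
                blocks.append((rpos, rpos + n, qpos))
                rpos += n
                qpos += n
            elif op in "DN":
                rpos += n
            elif op in "IS":
                qpos += n
        return blocks


@dataclass
class FastqRecord:
    read_id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"{self.read_id}: seq/qual length mismatch")


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    if cigar in ("", "*"):
        raise ValueError("missing CIGAR")
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if "".join(f"{n}{op}" for op, n in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return ops


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence name {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(GenomeSequence(rec.id, str(rec.seq)))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def write_fasta(seqs: Iterable[GenomeSequence], path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.name}\n")
            for i in range(0, len(s.seq), width):
                fh.write(s.seq[i : i + width] + "\n")
    return path


def genome_dict(seqs: Iterable[GenomeSequence]) -> dict[str, str]:
    return {s.name: s.seq for s in seqs}


def read_fastq(path: str | Path) -> list[FastqRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(FastqRecord(rec.id, str(rec.seq).upper(), qual))
    return out


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual}\n")
    return path


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_TRANSCRIPT_TYPES = {"mRNA": "coding", "ncRNA": "ncRNA"}


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse a minimal GFF3 dialect (gene / mRNA|ncRNA / exon / CDS).

    Required attribute keys: ID and Parent; gene_id falls back to the
    feature's ID.  1-based inclusive GFF coordinates are converted to the
    internal 0-based half-open convention.  Models with invalid coding
    annotation raise.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for ttype, biotype in _TRANSCRIPT_TYPES.items():
        for tx in db.features_of_type(ttype):
            parents = list(db.parents(tx, featuretype="gene"))
            gene_id = parents[0].id if parents else tx.id
            exons = [(f.start - 1, f.end) for f in db.children(tx, featuretype="exon")]
            cds = [(f.start - 1, f.end) for f in db.children(tx, featuretype="CDS")]
            if not exons:
                raise ValueError(f"transcript {tx.id} has no exons")
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    transcript_id=tx.id,
                    chrom=tx.seqid,
                    strand=tx.strand,
                    exons=exons,
                    cds=cds,
                    biotype=biotype,
                )
            )
    models.sort(key=lambda m: (m.chrom, m.span))
    return models


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda m: (m.chrom, m.span)):
            s, e = m.span
            ttype = "mRNA" if m.biotype == "coding" else "ncRNA"
            fh.write(
                f"{m.chrom}\tsim\tgene\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            fh.write(
                f"{m.chrom}\tsim\t{ttype}\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={m.transcript_id};Parent={m.gene_id}\n"
            )
            for a, b in m.exons:
                fh.write(
                    f"{m.chrom}\tsim\texon\t{a + 1}\t{b}\t.\t{m.strand}\t.\t"
                    f"ID={m.transcript_id}.exon.{a};Parent={m.transcript_id}\n"
                )
            for a, b in m.cds:
                fh.write(
                    f"{m.chrom}\tsim\tCDS\t{a + 1}\t{b}\t.\t{m.strand}\t0\t"
                    f"ID={m.transcript_id}.cds.{a};Parent={m.transcript_id}\n"
                )
    return path


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


def read_sam(path: str | Path) -> list[AlignedRead]:
    """Read a SAM text file; unmapped reads are skipped with a logged count."""
    reads = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=True) as fh:
        for a in fh:
            if a.is_unmapped or a.cigarstring is None:
                skipped += 1
                continue
            reads.append(
                AlignedRead(
                    read_id=a.query_name,
                    chrom=a.reference_name,
                    pos=a.reference_start,
                    is_reverse=a.is_reverse,
                    cigar=parse_cigar(a.cigarstring),
                    seq=a.query_sequence.upper(),
                    qual="".join(chr(q + 33) for q in a.query_qualities),
                )
            )
    if skipped:
        logger.info("read_sam(%s): skipped %d unmapped reads", path, skipped)
    return reads


def write_sam(
    reads: Iterable[AlignedRead], references: dict[str, int], path: str | Path
) -> Path:
    """Write reads as SAM text with an @SQ header built from ``references``."""
    path = Path(path)
    names = list(references)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": n, "LN": references[n]} for n in names],
        }
    )
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for r in reads:
            if r.chrom not in tid:
                raise ValueError(f"read {r.read_id}: chrom {r.chrom} not in header")
            a = pysam.AlignedSegment(header)
            a.query_name = r.read_id
            a.flag = 16 if r.is_reverse else 0
            a.reference_id = tid[r.chrom]
            a.reference_start = r.pos
            a.mapping_quality = 60
            a.cigarstring = r.cigar_string
            a.query_sequence = r.seq
            a.query_qualities = pysam.qualitystring_to_array(r.qual)
            fh.write(a)
    return path


# ---------------------------------------------------------------------------
# Site tables (TSV / VCF)
# ---------------------------------------------------------------------------

SITE_TSV_COLUMNS = [
    "chrom",
    "pos",  # 1-based in the file
    "strand",
    "ref",
    "alt",
    "level",
    "depth",
    "gene_id",
]


def write_sites_tsv(sites: Iterable, path: str | Path) -> Path:
    """Write editing sites as TSV; positions are emitted 1-based."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(SITE_TSV_COLUMNS) + "\n")
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.pos + 1}\t{s.strand}\t{s.ref}\t{s.alt}\t"
                f"{s.level:.6g}\t{s.depth}\t{getattr(s, 'gene_id', '') or ''}\n"
            )
    return path


def read_sites_tsv(path: str | Path) -> list:
    from .editing_caller import EditingSite

    sites = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != SITE_TSV_COLUMNS:
            raise ValueError(f"unexpected site TSV header in {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            sites.append(
                EditingSite(
                    chrom=f[0],
                    pos=int(f[1]) - 1,
                    strand=f[2],
                    ref=f[3],
                    alt=f[4],
                    level=float(f[5]),
                    depth=int(f[6]),
                    gene_id=f[7] or None,
                )
            )
    return sites


def write_sites_vcf(sites: Iterable, genome: dict[str, int], path: str | Path) -> Path:
    """Minimal VCF 4.2 writer; editing level and strand go in INFO."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in genome.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=EL,Number=1,Type=Float,Description="Editing level">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Filtered depth">\n')
        fh.write('##INFO=<ID=STRAND,Number=1,Type=String,Description="Transcript strand">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.pos + 1}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t"
                f"EL={s.level:.6g};DP={s.depth};STRAND={s.strand}\n"
            )
    return path
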