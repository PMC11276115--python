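"""Synthetic two-strain editing experiment with ground truth.

Generates a small multi-gene genome (both strands, UTR/intron/CDS structure),
plants A-to-I editing sites in mature transcripts with configurable 5'/3'
neighbor-preference weights (default 5' U > A > C > G, 3' G favored), draws
per-site editing levels from a truncated Beta, and simulates paired-end
RNA-seq reads with truth alignments for an editing ("case") strain and a
non-editing control strain that shares all non-editing variation (homozygous
SNPs injected into the reads of both strains, so control subtraction — not
alignment — removes them).

Everything is deterministic given the config (including its seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import seqio
from .seqio import AlignedRead, FastqRecord, GeneModel, GenomeSequence, revcomp

BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}

# role codes along a gene's genomic footprint
_R_UTR5, _R_CDS, _R_UTR3, _R_INTRON, _R_NC = 0, 1, 2, 3, 4


def _default_w5() -> dict[str, float]:
    # 5' nearest-neighbor preference U > A > C > G (T in DNA space)
    return {"T": 0.6, "A": 0.2, "C": 0.15, "G": 0.05}


def _default_w3() -> dict[str, float]:
    # 3' nearest neighbor favors G
    return {"G": 0.5, "C": 0.2, "A": 0.2, "T": 0.1}


@dataclass
class SimConfig:
    seed: int
    n_chroms: int = 2
    chrom_length: int = 40_000
    n_genes: int = 40
    fraction_minus_strand: float = 0.5
    ncrna_fraction: float = 0.1
    intron_rate: float = 0.8  # expected introns per gene (Poisson, capped at 3)
    n_edit_sites: int = 200
    context_weights_5p: dict = field(default_factory=_default_w5)
    context_weights_3p: dict = field(default_factory=_default_w3)
    level_alpha: float = 2.0
    level_beta: float = 2.0
    level_min: float = 0.05
    read_length: int = 150
    mean_depth: float = 30.0
    seq_error_rate: float = 0.005
    shared_snp_count: int = 30
    #: sd of log expression; ~7-fold middle-95% spread keeps nearly all
    #: transcripts above the depth-10 call filter at 30x mean depth
    expression_sigma: float = 0.5

    def __post_init__(self) -> None:
        for w in (self.context_weights_5p, self.context_weights_3p):
            if set(w) != set(BASES) or any(v < 0 for v in w.values()) or sum(w.values()) <= 0:
                raise ValueError("context weights must cover ACGT with non-negative sum > 0")
        if not (0 < self.seq_error_rate < 0.1):
            raise ValueError("seq_error_rate must be in (0, 0.1)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")

    def normalized_w5(self) -> dict[str, float]:
        t = sum(self.context_weights_5p.values())
        return {b: v / t for b, v in self.context_weights_5p.items()}

    def normalized_w3(self) -> dict[str, float]:
        t = sum(self.context_weights_3p.values())
        return {b: v / t for b, v in self.context_weights_3p.items()}


@dataclass
class TruthEditSite:
    chrom: str
    pos: int  # 0-based genomic
    strand: str  # transcript strand
    gene_id: str
    tpos: int  # position in the mature transcript
    true_level: float
    context: str  # -15..+15 on the transcript strand

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)


@dataclass
class StrainDataset:
    label: str  # "case" | "control"
    genome_path: Path
    gff3_path: Path
    sam_path: Path
    fastq1_path: Path
    fastq2_path: Path
    truth_path: Path


def _rng(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng([seed, salt])


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=n)])


# ---------------------------------------------------------------------------
# Genome and gene models
# ---------------------------------------------------------------------------


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons-2) sense codons + one stop."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_dna(rng, 3)
        if c not in _STOPS:
            codons.append(c)
    codons.append(("TAA", "TAG", "TGA")[rng.integers(0, 3)])
    return "".join(codons)


def _build_gene(rng: np.random.Generator, config: SimConfig):
    """Return (genomic_seq, roles) for one gene, oriented to the + strand."""
    coding = rng.random() >= config.ncrna_fraction
    if coding:
        utr5 = int(rng.integers(40, 150))
        n_codons = int(rng.integers(100, 400))
        utr3 = int(rng.integers(80, 250))
        mature = _random_dna(rng, utr5) + _random_cds(rng, n_codons) + _random_dna(rng, utr3)
        roles = [_R_UTR5] * utr5 + [_R_CDS] * (3 * n_codons) + [_R_UTR3] * utr3
    else:
        n = int(rng.integers(300, 800))
        mature = _random_dna(rng, n)
        roles = [_R_NC] * n

    n_introns = min(int(rng.poisson(config.intron_rate)), 3)
    cuts = sorted(rng.choice(np.arange(30, len(mature) - 30), size=n_introns, replace=False)) if n_introns else []
    seq_parts, role_parts = [], []
    prev = 0
    for cut in cuts:
        seq_parts.append(mature[prev:cut])
        role_parts.extend(roles[prev:cut])
        ilen = int(rng.integers(60, 200))
        seq_parts.append("GT" + _random_dna(rng, ilen - 4) + "AG")
        role_parts.extend([_R_INTRON] * ilen)
        prev = cut
    seq_parts.append(mature[prev:])
    role_parts.extend(roles[prev:])
    gseq = "".join(seq_parts)
    groles = np.array(role_parts, dtype=np.int8)

    strand = "-" if rng.random() < config.fraction_minus_strand else "+"
    if strand == "-":
        gseq = revcomp(gseq)
        groles = groles[::-1]
    return gseq, groles, strand, coding


def _intervals_from_mask(mask: np.ndarray, offset: int) -> list[tuple[int, int]]:
    out = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return out
    start = prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            out.append((offset + start, offset + prev + 1))
            start = i
        prev = i
    out.append((offset + start, offset + prev + 1))
    return out


def generate_genome_and_genes(
    config: SimConfig,
) -> tuple[list[GenomeSequence], list[GeneModel]]:
    """Genes tile the genome without overlap, separated by random intergenic
    gaps; every coding model translates ATG..stop by construction."""
    rng = _rng(config.seed, 0)
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1

    chroms: list[GenomeSequence] = []
    models: list[GeneModel] = []
    gene_no = 0
    for ci in range(config.n_chroms):
        name = f"chr{ci + 1}"
        parts: list[str] = []
        pos = 0
        for _ in range(per_chrom[ci]):
            gap = int(rng.integers(200, 600))
            parts.append(_random_dna(rng, gap))
            pos += gap
            gseq, groles, strand, coding = _build_gene(rng, config)
            if pos + len(gseq) + 200 > config.chrom_length:
                raise ValueError(
                    f"genome too small: {name} cannot fit gene {gene_no} "
                    f"({config.n_genes} genes requested for "
                    f"{config.n_chroms}x{config.chrom_length} nt)"
                )
            gid = f"g{gene_no:03d}"
            models.append(
                GeneModel(
                    gene_id=gid,
                    transcript_id=f"{gid}.1",
                    chrom=name,
                    strand=strand,
                    exons=_intervals_from_mask(groles != _R_INTRON, pos),
                    cds=_intervals_from_mask(groles == _R_CDS, pos),
                    biotype="coding" if coding else "ncRNA",
                )
            )
            parts.append(gseq)
            pos += len(gseq)
            gene_no += 1
        tail = config.chrom_length - pos
        parts.append(_random_dna(rng, tail))
        chroms.append(GenomeSequence(name, "".join(parts)))
    return chroms, models


# ---------------------------------------------------------------------------
# Planting editing sites
# ---------------------------------------------------------------------------


def plant_editing_sites(
    genome: Sequence[GenomeSequence] | Mapping[str, str],
    genes: Sequence[GeneModel],
    config: SimConfig,
) -> list[TruthEditSite]:
    """Sample adenosines in mature transcripts without replacement with
    probability proportional to w5(base at -1) * w3(base at +1); levels are
    Beta(alpha, beta) truncated to >= level_min."""
    gdict = genome if isinstance(genome, Mapping) else seqio.genome_dict(genome)
    rng = _rng(config.seed, 1)
    w5, w3 = config.normalized_w5(), config.normalized_w3()

    cand: list[tuple[str, int, float]] = []  # (gene_id, tpos, weight)
    mature: dict[str, str] = {}
    tmaps: dict[str, list[int]] = {}
    by_id: dict[str, GeneModel] = {}
    for g in genes:
        mature[g.gene_id] = g.spliced_sequence(gdict)
    # strain-shared SNP positions are not valid editing-site hosts
    snp_tpos = {
        (gid, t)
        for gid, d in _shared_snps(genes, mature, config).items()
        for t in d
    }
    for g in genes:
        seq = mature[g.gene_id]
        tmaps[g.gene_id] = g.transcript_to_genome()
        by_id[g.gene_id] = g
        for t in range(1, len(seq) - 1):
            if seq[t] == "A" and (g.gene_id, t) not in snp_tpos:
                w = w5[seq[t - 1]] * w3[seq[t + 1]]
                if w > 0:
                    cand.append((g.gene_id, t, w))
    if len(cand) < config.n_edit_sites:
        raise ValueError(
            f"only {len(cand)} candidate adenosines for {config.n_edit_sites} sites"
        )

    # weighted sampling without replacement (Efraimidis-Spirakis keys)
    weights = np.array([w for _, _, w in cand])
    keys = rng.random(len(cand)) ** (1.0 / weights)
    chosen = np.argsort(keys)[::-1][: config.n_edit_sites]

    sites = []
    for idx in sorted(chosen):
        gid, t, _ = cand[idx]
        seq = mature[gid]
        level = 0.0
        while level < config.level_min:
            level = float(rng.beta(config.level_alpha, config.level_beta))
        lo = t - 15
        ctx = (
            "N" * max(0, -lo)
            + seq[max(0, lo) : t + 16]
            + "N" * max(0, t + 16 - len(seq))
        )
        g = by_id[gid]
        sites.append(
            TruthEditSite(
                chrom=g.chrom,
                pos=tmaps[gid][t],
                strand=g.strand,
                gene_id=gid,
                tpos=t,
                true_level=level,
                context=ctx,
            )
        )
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return sites


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _shared_snps(
    genes: Sequence[GeneModel],
    mature: Mapping[str, str],
    config: SimConfig,
) -> dict[str, dict[int, str]]:
    """Homozygous SNPs in transcript coordinates, drawn from the seed alone
    so both strains inject the identical set (site planting avoids them)."""
    rng = _rng(config.seed, 4)
    pool = [
        (g.gene_id, t) for g in genes for t in range(len(mature[g.gene_id]))
    ]
    idx = rng.choice(len(pool), size=min(config.shared_snp_count, len(pool)), replace=False)
    snps: dict[str, dict[int, str]] = {}
    for i in sorted(idx):
        gid, t = pool[i]
        ref = mature[gid][t]
        alt = rng.choice([b for b in BASES if b != ref])
        snps.setdefault(gid, {})[t] = str(alt)
    return snps


def _cigar_from_positions(gpos: list[int]) -> tuple[int, list[tuple[str, int]]]:
    """Ascending genomic positions -> (leftmost pos, CIGAR with M/N ops)."""
    start = gpos[0]
    cigar: list[tuple[str, int]] = []
    run_start = prev = gpos[0]
    for p in gpos[1:]:
        if p != prev + 1:
            cigar.append(("M", prev - run_start + 1))
            cigar.append(("N", p - prev - 1))
            run_start = p
        prev = p
    cigar.append(("M", prev - run_start + 1))
    return start, cigar


def simulate_reads(
    genome: Sequence[GenomeSequence],
    genes: Sequence[GeneModel],
    truth: Sequence[TruthEditSite],
    config: SimConfig,
    label: str,
    outdir: str | Path,
) -> StrainDataset:
    """Paired FASTQ plus a truth SAM with exact spliced alignments.

    Each read carries G at a covered truth site with probability true_level
    (independently per read), shared SNPs always, and uniform substitution
    errors at seq_error_rate on top.
    """
    if label not in ("case", "control"):
        raise ValueError("label must be 'case' or 'control'")
    if label == "control" and truth:
        raise ValueError("control dataset must have an empty truth table")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gdict = seqio.genome_dict(genome)
    rng = _rng(config.seed, 2 if label == "case" else 3)

    mature = {g.gene_id: g.spliced_sequence(gdict) for g in genes}
    tmaps = {g.gene_id: g.transcript_to_genome() for g in genes}
    truth_by_gene: dict[str, list[TruthEditSite]] = {}
    for s in truth:
        truth_by_gene.setdefault(s.gene_id, []).append(s)
    snps = _shared_snps(genes, mature, config)

    L = config.read_length
    qual = chr(33 + 37) * L  # constant Q37
    # log-normal expression, normalized so the mean transcript depth is
    # mean_depth; drawn from the seed alone so case and control share the
    # expression profile (they share everything but the editing machinery),
    # keeping control coverage informative at every case-covered position
    expr = np.exp(
        _rng(config.seed, 5).normal(0.0, config.expression_sigma, size=len(genes))
    )
    expr /= math.exp(config.expression_sigma**2 / 2)

    reads: list[AlignedRead] = []
    fq1: list[FastqRecord] = []
    fq2: list[FastqRecord] = []
    for g, rel in zip(genes, expr):
        gid = g.gene_id
        tx = list(mature[gid])
        for t, alt in snps.get(gid, {}).items():
            tx[t] = alt
        tx = "".join(tx)
        tlen = len(tx)
        if tlen < L:
            raise ValueError(f"read_length {L} exceeds transcript length of {gid}")
        tmap = tmaps[gid]
        gene_truth = truth_by_gene.get(gid, [])
        depth = config.mean_depth * rel
        n_pairs = int(round(depth * tlen / (2 * L)))
        for p in range(n_pairs):
            frag = int(rng.integers(250, 401))
            frag = max(L, min(frag, tlen))
            # fragmentation also yields the molecule's terminal pieces, so
            # fragment placement may overhang either end (clipped to the
            # transcript, never below one read length); this keeps coverage
            # near-uniform instead of ramping down over the last read length
            s0 = int(rng.integers(-(frag - L), tlen - L + 1))
            a, b = max(0, s0), min(tlen, s0 + frag)
            windows = ((a, a + L), (b - L, b))
            mate_seqs = []
            for a, b in windows:
                w = list(tx[a:b])
                for s in gene_truth:
                    if a <= s.tpos < b and rng.random() < s.true_level:
                        w[s.tpos - a] = "G"
                err = np.flatnonzero(rng.random(b - a) < config.seq_error_rate)
                for e in err:
                    w[e] = str(rng.choice([x for x in BASES if x != w[e]]))
                mate_seqs.append("".join(w))
            rid = f"{label}.{gid}.{p}"
            fq1.append(FastqRecord(rid, mate_seqs[0], qual))
            fq2.append(FastqRecord(rid, revcomp(mate_seqs[1]), qual))
            for mate, ((a, b), wseq) in enumerate(zip(windows, mate_seqs), start=1):
                gpos = tmap[a:b]
                if g.strand == "-":
                    gpos = gpos[::-1]
                    fwd_seq = revcomp(wseq)
                else:
                    fwd_seq = wseq
                pos0, cigar = _cigar_from_positions(gpos)
                sequenced_reverse = (mate == 2) != (g.strand == "-")
                reads.append(
                    AlignedRead(
                        read_id=f"{rid}/{mate}",
                        chrom=g.chrom,
                        pos=pos0,
                        is_reverse=sequenced_reverse,
                        cigar=cigar,
                        seq=fwd_seq,
                        qual=qual,
                    )
                )

    reads.sort(key=lambda r: (r.chrom, r.pos, r.read_id))
    genome_path = seqio.write_fasta(genome, outdir / "genome.fa")
    gff3_path = seqio.write_gff3(genes, outdir / "genes.gff3")
    sam_path = seqio.write_sam(
        reads, {c.name: len(c.seq) for c in genome}, outdir / f"{label}.sam"
    )
    fastq1 = seqio.write_fastq(fq1, outdir / f"{label}_R1.fastq")
    fastq2 = seqio.write_fastq(fq2, outdir / f"{label}_R2.fastq")
    truth_path = write_truth_tsv(truth, outdir / f"{label}_truth.tsv")
    return StrainDataset(
        label=label,
        genome_path=genome_path,
        gff3_path=gff3_path,
        sam_path=sam_path,
        fastq1_path=fastq1,
        fastq2_path=fastq2,
        truth_path=truth_path,
    )


TRUTH_COLUMNS = ["chrom", "pos", "strand", "gene_id", "tpos", "true_level", "context"]


def write_truth_tsv(truth: Sequence[TruthEditSite], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for s in truth:
            fh.write(
                f"{s.chrom}\t{s.pos + 1}\t{s.strand}\t{s.gene_id}\t{s.tpos}\t"
                f"{s.true_level:.6g}\t{s.context}\n"
            )
    return path


def read_truth_tsv(path: str | Path) -> list[TruthEditSite]:
    sites = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TRUTH_COLUMNS:
            raise ValueError(f"unexpected truth TSV header in {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            sites.append(
                TruthEditSite(
                    chrom=f[0],
                    pos=int(f[1]) - 1,
                    strand=f[2],
                    gene_id=f[3],
                    tpos=int(f[4]),
                    true_level=float(f[5]),
                    context=f[6],
                )
            )
    return sites


# ---------------------------------------------------------------------------
# Recovery evaluation (the acceptance instrument)
# ---------------------------------------------------------------------------


def evaluate_recovery(
    called_sites: Sequence,
    truth: Sequence[TruthEditSite],
    min_true_level: float = 0.0,
) -> dict:
    """Precision/recall/level-RMSE of called sites against the truth table.

    Sites are matched by (chrom, pos, strand).  ``min_true_level`` restricts
    the recall denominator to truth sites at or above that level (a site
    below it that is nevertheless called still counts as a true positive,
    not a false positive).
    """
    called_by_key = {s.key: s for s in called_sites}
    truth_by_key = {s.key: s for s in truth}
    eligible = {k for k, s in truth_by_key.items() if s.true_level >= min_true_level}

    tp_keys = set(called_by_key) & set(truth_by_key)
    fp = len(called_by_key) - len(tp_keys)
    tp_eligible = len(tp_keys & eligible)
    fn = len(eligible) - tp_eligible

    precision = len(tp_keys) / len(called_by_key) if called_by_key else float("nan")
    recall = tp_eligible / len(eligible) if eligible else float("nan")
    matched = pd.DataFrame(
        [
            {
                "chrom": k[0],
                "pos": k[1],
                "strand": k[2],
                "true_level": truth_by_key[k].true_level,
                "called_level": called_by_key[k].level,
                "depth": called_by_key[k].depth,
            }
            for k in sorted(tp_keys)
        ]
    )
    if len(matched):
        rmse = float(
            np.sqrt(np.mean((matched.called_level - matched.true_level) ** 2))
        )
    else:
        rmse = float("nan")
    return {
        "n_called": len(called_by_key),
        "n_truth": len(truth_by_key),
        "n_truth_eligible": len(eligible),
        "tp": len(tp_keys),
        "fp": fp,
        "fn": fn,
        "precision": precision,
        "recall": recall,
        "level_rmse": rmse,
        "matched": matched,
    }


def audit_false_negatives(
    truth: Sequence[TruthEditSite],
    called_keys: set,
    pileup,
    control_positions: set,
    min_depth: int = 10,
    min_rate: float = 0.10,
) -> pd.DataFrame:
    """Attribute every missed truth site to a concrete filter: low depth,
    sub-threshold observed rate, or a control-collision.  Anything else is
    labeled 'unexplained' (the pipeline invariant is that none are)."""
    from .readqc_pileup import BASES as PILEUP_BASES

    rows = []
    for s in truth:
        if s.key in called_keys:
            continue
        arr = pileup.counts[s.chrom][:, s.pos]
        depth = int(arr.sum())
        alt_base = "G" if s.strand == "+" else "C"
        alt = int(arr[PILEUP_BASES.index(alt_base)])
        rate = alt / depth if depth else 0.0
        if (s.chrom, s.pos) in control_positions:
            reason = "control-collision"
        elif depth < min_depth:
            reason = "low-depth"
        elif rate < min_rate:
            reason = "low-rate"
        else:
            reason = "unexplained"
        rows.append(
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "strand": s.strand,
                "true_level": s.true_level,
                "depth": depth,
                "observed_rate": rate,
                "reason": reason,
            }
        )
    return pd.DataFrame(rows)
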