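"""Read preprocessing, base-quality-filtered pileup and variant calling.

The stages mirror a standard RNA-editing discovery pipeline: a fixed 5' trim
(the first sequencing cycles are error-prone), exact duplicate-pair removal,
a sliding-window 3' quality trim, then a pileup restricted to bases with
Phred quality >= 20 and a pure count-based variant caller whose "variance
rate" is the fraction of reads carrying the variant base at the site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .seqio import AlignedRead, FastqRecord

BASES = "ACGT"
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_INDEX[ord(_b)] = _i

#: The 12 possible single-base substitutions, in fixed (alphabetical) order.
VARIANT_TYPES = [f"{r}-to-{a}" for r in BASES for a in BASES if r != a]


@dataclass
class PreprocessParams:
    """Knobs of the read-cleaning stage.

    first_base_to_keep=11 drops sequencing cycles 1-10; the 3' end is trimmed
    back to the last position where the mean quality over a 10-nt window is
    >= min_window_quality, and pairs are dropped when either mate ends up
    shorter than min_length_after_trim or contains an N.
    """

    first_base_to_keep: int = 11
    min_window_quality: int = 30
    window: int = 10
    min_length_after_trim: int = 50
    dedupe: bool = True

    def __post_init__(self) -> None:
        if self.first_base_to_keep < 1:
            raise ValueError("first_base_to_keep must be >= 1")
        if self.min_window_quality < 0 or self.min_length_after_trim < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class PileupSite:
    chrom: str
    pos: int  # 0-based internal
    ref_base: str
    counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class VariantCall:
    chrom: str
    pos: int  # 0-based internal
    ref: str
    alt: str
    alt_count: int
    depth: int

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValueError("alt equals ref")

    @property
    def variance_rate(self) -> float:
        """Fraction of reads at the site carrying the variant base."""
        return self.alt_count / self.depth

    @property
    def type_label(self) -> str:
        return f"{self.ref}-to-{self.alt}"


# ---------------------------------------------------------------------------
# Read preprocessing
# ---------------------------------------------------------------------------


def _quality_trim_3p(qual: str, window: int, threshold: int) -> int:
    """Return the kept length after the sliding-mean 3' quality trim.

    The read is cut back to the last position where the mean Phred quality of
    the length-``window`` window ending there is >= threshold (windows
    shorter than ``window`` at the read start use the available bases).
    """
    if not qual:
        return 0
    q = np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int64) - 33
    csum = np.concatenate([[0], np.cumsum(q)])
    n = len(q)
    keep = 0
    for end in range(1, n + 1):
        start = max(0, end - window)
        if (csum[end] - csum[start]) / (end - start) >= threshold:
            keep = end
    return keep


def preprocess_reads(
    pairs: Sequence[tuple[FastqRecord, FastqRecord]],
    params: PreprocessParams | None = None,
) -> tuple[list[tuple[FastqRecord, FastqRecord]], dict[str, int]]:
    """Clean read pairs: 5' trim, duplicate removal, 3' quality trim.

    Returns the surviving pairs and a report counting each removal class.
    """
    params = params or PreprocessParams()
    report = {
        "input_pairs": len(pairs),
        "duplicates_removed": 0,
        "dropped_short": 0,
        "dropped_n": 0,
        "output_pairs": 0,
    }

    cut = params.first_base_to_keep - 1
    trimmed = [
        (
            FastqRecord(r1.read_id, r1.seq[cut:], r1.qual[cut:]),
            FastqRecord(r2.read_id, r2.seq[cut:], r2.qual[cut:]),
        )
        for r1, r2 in pairs
    ]

    if params.dedupe:
        seen: set[tuple[str, str]] = set()
        unique = []
        for r1, r2 in trimmed:
            key = (r1.seq, r2.seq)
            if key in seen:
                report["duplicates_removed"] += 1
                continue
            seen.add(key)
            unique.append((r1, r2))
        trimmed = unique

    out = []
    for r1, r2 in trimmed:
        mates = []
        ok = True
        for r in (r1, r2):
            keep = _quality_trim_3p(r.qual, params.window, params.min_window_quality)
            seq, qual = r.seq[:keep], r.qual[:keep]
            if keep < params.min_length_after_trim:
                report["dropped_short"] += 1
                ok = False
                break
            if "N" in seq:
                report["dropped_n"] += 1
                ok = False
                break
            mates.append(FastqRecord(r.read_id, seq, qual))
        if ok:
            out.append((mates[0], mates[1]))
    report["output_pairs"] = len(out)
    return out, report


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------


class Pileup:
    """Per-position base counts after base-quality filtering.

    Backed by one (4, chrom_length) integer array per chromosome; exposes a
    PileupSite iterator over covered positions (reference N sites excluded).
    """

    def __init__(self, genome: dict[str, str], min_base_quality: int = 20):
        self.genome = genome
        self.min_base_quality = min_base_quality
        self.counts: dict[str, np.ndarray] = {
            name: np.zeros((4, len(seq)), dtype=np.int32) for name, seq in genome.items()
        }

    def add_read(self, read: AlignedRead) -> None:
        if read.chrom not in self.counts:
            raise KeyError(f"read {read.read_id} references unknown chromosome {read.chrom}")
        arr = self.counts[read.chrom]
        qual = np.frombuffer(read.qual.encode(), dtype=np.uint8).astype(np.int32) - 33
        seq_idx = _BASE_INDEX[np.frombuffer(read.seq.encode(), dtype=np.uint8)]
        for ref_start, ref_end, qstart in read.aligned_blocks():
            n = ref_end - ref_start
            bidx = seq_idx[qstart : qstart + n]
            bqual = qual[qstart : qstart + n]
            keep = (bidx >= 0) & (bqual >= self.min_base_quality)
            positions = np.arange(ref_start, ref_end)[keep]
            np.add.at(arr, (bidx[keep].astype(np.intp), positions), 1)

    def sites(self) -> Iterator[PileupSite]:
        for chrom, arr in self.counts.items():
            ref = self.genome[chrom]
            covered = np.flatnonzero(arr.sum(axis=0) > 0)
            for pos in covered:
                rb = ref[pos]
                if rb == "N":
                    continue
                yield PileupSite(
                    chrom=chrom,
                    pos=int(pos),
                    ref_base=rb,
                    counts={b: int(arr[i, pos]) for i, b in enumerate(BASES)},
                )


def build_pileup(
    reads: Iterable[AlignedRead], genome: dict[str, str], min_base_quality: int = 20
) -> Pileup:
    """Accumulate a base-quality-filtered pileup over all aligned reads.

    Spliced (N), soft-clipped and inserted segments contribute nothing;
    deletions contribute nothing to the positions they span.
    """
    pileup = Pileup(genome, min_base_quality)
    for read in reads:
        pileup.add_read(read)
    return pileup


# ---------------------------------------------------------------------------
# Variant calling
# ---------------------------------------------------------------------------


def call_variants(pileup: Pileup | Iterable[PileupSite]) -> list[VariantCall]:
    """Emit a VariantCall for every non-reference base with count >= 1.

    The variance rate is alt_count / filtered depth; multiple alt bases at
    one site yield one call each.  Downstream depth/rate filters do the real
    discrimination.
    """
    sites = pileup.sites() if isinstance(pileup, Pileup) else pileup
    calls = []
    for s in sites:
        depth = s.depth
        if depth == 0:
            continue
        for base in BASES:
            if base != s.ref_base and s.counts.get(base, 0) >= 1:
                calls.append(
                    VariantCall(
                        chrom=s.chrom,
                        pos=s.pos,
                        ref=s.ref_base,
                        alt=base,
                        alt_count=s.counts[base],
                        depth=depth,
                    )
                )
    return calls


def variant_spectrum(variants: Iterable[VariantCall]) -> dict[str, int]:
    """Counts over the 12 ordered ref->alt substitution types."""
    spectrum = {t: 0 for t in VARIANT_TYPES}
    for v in variants:
        spectrum[v.type_label] += 1
    return spectrum
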