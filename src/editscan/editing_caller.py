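"""High-confidence A-to-I editing site calling from case/control variants.

Four criteria turn raw variant calls into editing sites: (1) control
subtraction — any position with a variant in the non-editing control strain
is removed; (2) coverage depth >= 10; (3) variance rate >= 10%; (4) only
A-to-G changes, where a genomic T-to-C inside an annotated minus-strand
transcript is interpreted as A-to-G on the transcript strand ("strand
collapse": inosine in an antisense transcript reads T-to-C against the
reference).  The editing level of a site is its variance rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .readqc_pileup import VariantCall
from .seqio import GeneModel


@dataclass
class EditingFilterParams:
    min_depth: int = 10
    min_rate: float = 0.10
    collapse_minus_strand: bool = True
    #: subtraction keyed by (chrom, pos) when False (conservative default);
    #: (chrom, pos, alt) when True.
    subtract_by_allele: bool = False

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not (0 < self.min_rate <= 1):
            raise ValueError("min_rate must be in (0, 1]")


@dataclass
class EditingSite:
    """A strand-resolved A-to-I site: on the transcript strand the change
    reads A->G; ``ref``/``alt`` stay in genome (+ strand) space."""

    chrom: str
    pos: int  # 0-based internal
    strand: str  # transcript strand
    ref: str  # genomic: A (plus) or T (minus)
    alt: str  # genomic: G (plus) or C (minus)
    level: float
    depth: int
    gene_id: str | None = None
    ambiguous_strand: bool = False

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)


def subtract_control(
    case_variants: Sequence[VariantCall],
    control_variants: Sequence[VariantCall],
    by_allele: bool = False,
) -> list[VariantCall]:
    """Remove case variants whose position has any variant call in control.

    By default any control variant at the position suffices (conservative:
    the position shows genomic variation or systematic noise); with
    ``by_allele`` only a matching alt allele removes the case variant.
    """
    if by_allele:
        ctrl = {(v.chrom, v.pos, v.alt) for v in control_variants}
        return [v for v in case_variants if (v.chrom, v.pos, v.alt) not in ctrl]
    ctrl_pos = {(v.chrom, v.pos) for v in control_variants}
    return [v for v in case_variants if (v.chrom, v.pos) not in ctrl_pos]


def _minus_strand_index(gene_models: Sequence[GeneModel]):
    """Transcript spans on each strand, for strand resolution of T-to-C."""
    minus, plus = {}, {}
    for m in gene_models:
        d = minus if m.strand == "-" else plus
        d.setdefault(m.chrom, []).append((m.span, m.gene_id))
    return plus, minus


def _containing_gene(index: Mapping[str, list], chrom: str, pos: int) -> str | None:
    for (s, e), gid in index.get(chrom, []):
        if s <= pos < e:
            return gid
    return None


def filter_editing_sites(
    variants: Sequence[VariantCall],
    params: EditingFilterParams | None = None,
    gene_models: Sequence[GeneModel] | None = None,
) -> list[EditingSite]:
    """Apply the depth / rate / A-to-G criteria to control-subtracted variants.

    A-to-G variants are kept anywhere (reported on the + strand); T-to-C
    variants are kept only when the position lies inside an annotated
    minus-strand transcript, reported on the - strand.  A position covered by
    genes on both strands takes the A-to-G (+ strand) interpretation with an
    ambiguity flag.
    """
    params = params or EditingFilterParams()
    if params.collapse_minus_strand and gene_models is None:
        raise ValueError("gene models required when collapse_minus_strand is on")
    plus_idx, minus_idx = _minus_strand_index(gene_models or [])

    sites = []
    for v in variants:
        if v.depth < params.min_depth or v.variance_rate < params.min_rate:
            continue
        if v.ref == "A" and v.alt == "G":
            gid = _containing_gene(plus_idx, v.chrom, v.pos)
            on_minus = _containing_gene(minus_idx, v.chrom, v.pos) is not None
            sites.append(
                EditingSite(
                    chrom=v.chrom,
                    pos=v.pos,
                    strand="+",
                    ref="A",
                    alt="G",
                    level=v.variance_rate,
                    depth=v.depth,
                    gene_id=gid,
                    ambiguous_strand=on_minus and gid is not None,
                )
            )
        elif (
            v.ref == "T"
            and v.alt == "C"
            and params.collapse_minus_strand
        ):
            gid = _containing_gene(minus_idx, v.chrom, v.pos)
            if gid is None:
                continue  # strand undecidable without an antisense transcript
            sites.append(
                EditingSite(
                    chrom=v.chrom,
                    pos=v.pos,
                    strand="-",
                    ref="T",
                    alt="C",
                    level=v.variance_rate,
                    depth=v.depth,
                    gene_id=gid,
                )
            )
    return sites


# ---------------------------------------------------------------------------
# Site-set comparison (Venn data) and common-site level comparison
# ---------------------------------------------------------------------------


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention behind printed percentages)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def shared_percentages(set_sizes: Mapping[str, int], n_common: int) -> dict[str, float]:
    """Percent of each set accounted for by the common intersection,
    rounded half away from zero to one decimal."""
    return {
        label: round_half_up(100.0 * n_common / size) for label, size in set_sizes.items()
    }


@dataclass
class SetComparison:
    sizes: dict[str, int]
    pairwise: dict[tuple[str, str], int]
    n_common: int
    shared_pct: dict[str, float]
    common_keys: list


def compare_site_sets(site_sets: Mapping[str, Sequence[EditingSite]]) -> SetComparison:
    """Pairwise and k-way intersections of labeled site sets keyed by
    (chrom, pos, strand), with each set's shared fraction of the k-way core."""
    if len(site_sets) < 2:
        raise ValueError("need at least two labeled site sets")
    keysets = {}
    for label, sites in site_sets.items():
        keys = [s.key for s in sites]
        if len(keys) != len(set(keys)):
            raise ValueError(f"duplicate site keys in set {label!r}")
        keysets[label] = set(keys)
    labels = list(keysets)
    pairwise = {
        (a, b): len(keysets[a] & keysets[b]) for a, b in combinations(labels, 2)
    }
    common = set.intersection(*keysets.values())
    sizes = {label: len(keys) for label, keys in keysets.items()}
    return SetComparison(
        sizes=sizes,
        pairwise=pairwise,
        n_common=len(common),
        shared_pct=shared_percentages(sizes, len(common)),
        common_keys=sorted(common),
    )


def classify_level_difference(
    common_sites: Iterable[tuple],
    levels_by_label: Mapping[str, Mapping[tuple, float]],
    delta: float = 0.10,
) -> dict[tuple, str]:
    """Per common site: 'higher-in-A' iff level_A - level_B > delta,
    'higher-in-B' symmetrically, else 'similar'.  Exactly two labels."""
    labels = list(levels_by_label)
    if len(labels) != 2:
        raise ValueError("exactly two labels required")
    a, b = labels
    out = {}
    for key in common_sites:
        la, lb = levels_by_label[a][key], levels_by_label[b][key]
        if la - lb > delta:
            out[key] = f"higher-in-{a}"
        elif lb - la > delta:
            out[key] = f"higher-in-{b}"
        else:
            out[key] = "similar"
    return out
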