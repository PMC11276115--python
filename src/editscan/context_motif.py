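"""Strand-aware sequence context extraction and position probability matrices.

The neighbor preference of an ADAR enzyme (classically 5' U > A > C > G and a
3' G bias) shows up as skewed base frequencies in the columns of a position
probability matrix built from the +/-15-nt windows around its editing sites —
the data behind a probability sequence logo.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .editing_caller import EditingSite
from .seqio import revcomp

BASES = "ACGT"


@dataclass
class ContextWindow:
    """A transcript-strand window centered on the edited A.

    Length 2*flank+1; positions beyond the contig are N-padded so the center
    stays at index ``flank``.
    """

    site_key: tuple
    sequence: str
    flank: int = 15

    def __post_init__(self) -> None:
        if len(self.sequence) != 2 * self.flank + 1:
            raise ValueError("window length must be 2*flank+1")
        if self.sequence[self.flank] != "A":
            raise ValueError(
                f"window center for {self.site_key} is "
                f"{self.sequence[self.flank]!r}, not A"
            )


@dataclass
class PositionProbabilityMatrix:
    """(2*flank+1, 4) base probabilities; columns renormalize over non-N
    observations so edge padding does not distort frequencies."""

    probs: np.ndarray  # shape (positions, 4), ACGT order
    n_sequences: int
    flank: int

    @property
    def information_content(self) -> np.ndarray:
        """Per-position IC in bits: 2 - Shannon entropy (no small-sample
        correction)."""
        p = self.probs
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        return 2.0 + plogp.sum(axis=1)

    def position_labels(self) -> list[str]:
        """-flank..-1, 'site', +1..+flank (no position 0)."""
        return (
            [str(-i) for i in range(self.flank, 0, -1)]
            + ["site"]
            + [f"+{i}" for i in range(1, self.flank + 1)]
        )

    def column(self, offset: int) -> dict[str, float]:
        """Probabilities at a signed offset from the site (offset != 0)."""
        if offset == 0:
            raise ValueError("the center is addressed as offset 'site'")
        idx = self.flank + offset
        return {b: float(self.probs[idx, i]) for i, b in enumerate(BASES)}


def extract_context(
    site: EditingSite, genome: Mapping[str, str], flank: int = 15
) -> ContextWindow:
    """Window on the transcript strand: the genomic substring for + sites,
    its reverse complement for - sites; out-of-contig positions become N."""
    chrom = genome[site.chrom]
    lo, hi = site.pos - flank, site.pos + flank + 1
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(chrom))
    window = "N" * left_pad + chrom[max(lo, 0) : min(hi, len(chrom))] + "N" * right_pad
    if site.strand == "-":
        window = revcomp(window)
    return ContextWindow(site_key=site.key, sequence=window, flank=flank)


def build_ppm(windows: Sequence[ContextWindow]) -> PositionProbabilityMatrix:
    if not windows:
        raise ValueError("cannot build a PPM from zero windows")
    flank = windows[0].flank
    length = 2 * flank + 1
    counts = np.zeros((length, 4), dtype=np.int64)
    base_idx = {b: i for i, b in enumerate(BASES)}
    for w in windows:
        if w.flank != flank:
            raise ValueError("mixed window sizes")
        for j, base in enumerate(w.sequence):
            if base in base_idx:
                counts[j, base_idx[base]] += 1
    denom = counts.sum(axis=1, keepdims=True)  # non-N observations
    probs = np.divide(counts, denom, out=np.zeros_like(counts, float), where=denom > 0)
    return PositionProbabilityMatrix(probs=probs, n_sequences=len(windows), flank=flank)


def motif_compare(
    ppm_a: PositionProbabilityMatrix, ppm_b: PositionProbabilityMatrix
) -> list[dict]:
    """Per-position comparison: each matrix's most probable base and the
    per-base probability difference (a - b).  No significance testing."""
    if ppm_a.probs.shape != ppm_b.probs.shape:
        raise ValueError("PPM dimension mismatch")
    labels = ppm_a.position_labels()
    out = []
    for j, label in enumerate(labels):
        delta = ppm_a.probs[j] - ppm_b.probs[j]
        out.append(
            {
                "position": label,
                "argmax_a": BASES[int(np.argmax(ppm_a.probs[j]))],
                "argmax_b": BASES[int(np.argmax(ppm_b.probs[j]))],
                **{f"delta_{b}": float(delta[i]) for i, b in enumerate(BASES)},
            }
        )
    return out


def ppm_table(ppm: PositionProbabilityMatrix) -> "pandas.DataFrame":  # noqa: F821
    import pandas as pd

    df = pd.DataFrame(ppm.probs, columns=list(BASES))
    df.insert(0, "position", ppm.position_labels())
    df["information_bits"] = ppm.information_content
    return df
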