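"""Pipeline orchestration, expression quantification and report assembly.

``run_pipeline`` wires the whole analysis together on a simulated two-strain
experiment: simulate -> pileup -> variants -> control subtraction -> editing
filters -> annotation -> motif -> folding -> report, all deterministic given
the config (which embeds the seed).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import annotate as annotate_mod
from . import context_motif, editing_caller, readqc_pileup, seqio, simdata, structure_fold
from .editing_caller import EditingFilterParams
from .simdata import SimConfig


# ---------------------------------------------------------------------------
# Expression (TPM)
# ---------------------------------------------------------------------------


def tpm(counts: Mapping[str, float], effective_lengths: Mapping[str, float]) -> pd.DataFrame:
    """Transcripts-per-million: rate_i = count_i / length_i,
    TPM_i = 1e6 * rate_i / sum(rate).  All-zero counts give all-zero TPM."""
    ids = list(counts)
    c = np.array([counts[i] for i in ids], dtype=float)
    lengths = np.array([effective_lengths[i] for i in ids], dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("effective lengths must be positive")
    rate = c / lengths
    total = rate.sum()
    values = np.zeros_like(rate) if total == 0 else 1e6 * rate / total
    return pd.DataFrame(
        {
            "transcript_id": ids,
            "read_count": c,
            "effective_length": lengths,
            "tpm": values,
        }
    )


def count_reads_per_transcript(
    reads: Sequence[seqio.AlignedRead], models: Sequence[seqio.GeneModel]
) -> dict[str, float]:
    """Assign each read to the transcript whose exons contain its leftmost
    aligned block; ambiguous assignments split equally."""
    by_chrom: dict[str, list[seqio.GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    counts = {m.transcript_id: 0.0 for m in models}
    for r in reads:
        blocks = r.aligned_blocks()
        if not blocks:
            continue
        s, e, _ = blocks[0]
        hits = [
            m.transcript_id
            for m in by_chrom.get(r.chrom, [])
            if any(a <= s and e <= b for a, b in m.exons)
        ]
        for t in hits:
            counts[t] += 1.0 / len(hits)
    return counts


# ---------------------------------------------------------------------------
# Region / consequence summaries
# ---------------------------------------------------------------------------

REGION_BINS = [
    "CDS_nonsynonymous",
    "CDS_synonymous",
    "UTR5",
    "UTR3",
    "splicing",
    "intronic",
    "ncRNA",
    "intergenic",
]


def region_distribution(
    annotated: Sequence[annotate_mod.AnnotatedSite],
) -> dict[str, dict[str, float]]:
    """Counts and proportions over the genome-distribution bins; CDS sites
    split into synonymous vs nonsynonymous (start/stop-loss count as
    nonsynonymous: the protein changes)."""
    if not annotated:
        return {}
    counts = {b: 0 for b in REGION_BINS}
    for a in annotated:
        if a.region == "exonic" and a.consequence is not None:
            if a.consequence.consequence == "synonymous":
                counts["CDS_synonymous"] += 1
            else:
                counts["CDS_nonsynonymous"] += 1
        elif a.region == "exonic":
            counts["CDS_nonsynonymous"] += 1  # CDS without resolvable codon
        else:
            counts[a.region] += 1
    total = sum(counts.values())
    return {
        b: {"count": n, "proportion": n / total}
        for b, n in counts.items()
        if n > 0 or b in REGION_BINS[:4]
    }


# ---------------------------------------------------------------------------
# Pipeline config and run
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    sim: SimConfig
    filters: EditingFilterParams = field(default_factory=EditingFilterParams)
    min_base_quality: int = 20
    #: control variants enter the subtraction set only above this noise
    #: floor, emulating the likelihood caller used on the control strain
    #: (a single mismatching read is not evidence of genomic variation)
    control_min_alt_count: int = 2
    control_min_rate: float = 0.05
    motif_flank: int = 15
    fold_flank: int = 100
    temperatures: tuple = (20.0, 30.0, 35.0)
    max_fold_sites: int = 200
    outdir: str = "editscan_out"

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def control_subtraction_set(
    control_variants: Sequence[readqc_pileup.VariantCall],
    min_alt_count: int = 2,
    min_rate: float = 0.05,
) -> list[readqc_pileup.VariantCall]:
    return [
        v
        for v in control_variants
        if v.alt_count >= min_alt_count and v.variance_rate >= min_rate
    ]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis on a simulated two-strain experiment and
    return the machine-readable report bundle (also written to report.json)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # re-raise with the failing stage named
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrap

    # -- simulate -----------------------------------------------------------
    genome, genes = stage("simulate")(simdata.generate_genome_and_genes, config.sim)
    truth = stage("simulate")(simdata.plant_editing_sites, genome, genes, config.sim)
    case = stage("simulate")(
        simdata.simulate_reads, genome, genes, truth, config.sim, "case", outdir
    )
    control = stage("simulate")(
        simdata.simulate_reads, genome, genes, [], config.sim, "control", outdir
    )
    gdict = seqio.genome_dict(genome)

    # -- preprocess (read QC report; truth alignments drive the pileup) ----
    pre_params = readqc_pileup.PreprocessParams()
    case_pairs = list(zip(seqio.read_fastq(case.fastq1_path), seqio.read_fastq(case.fastq2_path)))
    _, preprocess_report = stage("preprocess")(
        readqc_pileup.preprocess_reads, case_pairs, pre_params
    )

    # -- pileup and variants ------------------------------------------------
    case_reads = stage("pileup")(seqio.read_sam, case.sam_path)
    control_reads = stage("pileup")(seqio.read_sam, control.sam_path)
    case_pileup = stage("pileup")(
        readqc_pileup.build_pileup, case_reads, gdict, config.min_base_quality
    )
    control_pileup = stage("pileup")(
        readqc_pileup.build_pileup, control_reads, gdict, config.min_base_quality
    )
    case_variants = stage("variants")(readqc_pileup.call_variants, case_pileup)
    control_variants = stage("variants")(readqc_pileup.call_variants, control_pileup)
    spectrum = readqc_pileup.variant_spectrum(case_variants)
    control_spectrum = readqc_pileup.variant_spectrum(control_variants)

    # -- editing sites ------------------------------------------------------
    ctrl_set = control_subtraction_set(
        control_variants, config.control_min_alt_count, config.control_min_rate
    )
    subtracted = stage("call")(
        editing_caller.subtract_control,
        case_variants,
        ctrl_set,
        config.filters.subtract_by_allele,
    )
    sites = stage("call")(
        editing_caller.filter_editing_sites, subtracted, config.filters, genes
    )
    seqio.write_sites_tsv(sites, outdir / "sites.tsv")
    seqio.write_sites_vcf(sites, {c.name: len(c.seq) for c in genome}, outdir / "sites.vcf")

    # -- recovery vs truth --------------------------------------------------
    recovery = stage("evaluate")(simdata.evaluate_recovery, sites, truth, 0.2)
    audit = stage("evaluate")(
        simdata.audit_false_negatives,
        truth,
        {s.key for s in sites},
        case_pileup,
        {(v.chrom, v.pos) for v in ctrl_set},
        config.filters.min_depth,
        config.filters.min_rate,
    )

    # -- annotation ---------------------------------------------------------
    annotated = stage("annotate")(annotate_mod.annotate_sites, sites, genes, gdict)
    regions = region_distribution(annotated)
    consequences = [a.consequence for a in annotated if a.consequence is not None]
    cons_counts = {
        c: sum(1 for x in consequences if x.consequence == c)
        for c in ("synonymous", "nonsynonymous", "startloss", "stoploss")
    }
    n_cons = sum(cons_counts.values())
    substitutions = annotate_mod.aa_substitution_spectrum(consequences)
    polarity = {
        v: sum(1 for x in consequences if x.polarity_verdict == v)
        for v in ("Same", "Change", "NA")
    }
    blosum_pos_fraction, _ = annotate_mod.blosum_fraction(consequences)

    # -- motif --------------------------------------------------------------
    windows = [
        context_motif.extract_context(s.site, gdict, config.motif_flank)
        for s in annotated
    ]
    ppm = stage("motif")(context_motif.build_ppm, windows) if windows else None
    if ppm is not None:
        context_motif.ppm_table(ppm).to_csv(outdir / "ppm.tsv", sep="\t", index=False)

    # -- folding ------------------------------------------------------------
    fold_sites = sites[: config.max_fold_sites]
    fold_rows = stage("fold")(
        structure_fold.fold_windows,
        fold_sites,
        gdict,
        config.temperatures,
        config.fold_flank,
    )
    fold_df = pd.DataFrame(fold_rows)
    if len(fold_df):
        fold_df.to_csv(outdir / "mfe.tsv", sep="\t", index=False)
        mfe_by_temp = {
            f"{t:g}C": fold_df.loc[fold_df.temperature == t, "mfe"].tolist()
            for t in config.temperatures
        }
        mw = structure_fold.compare_mfe_distributions(mfe_by_temp)
        mfe_summary = {
            label: {
                "n": len(v),
                "mean": float(np.mean(v)),
                "median": float(np.median(v)),
            }
            for label, v in mfe_by_temp.items()
        }
        mw_json = {f"{a} vs {b}": d for (a, b), d in mw.items()}
    else:
        mfe_summary, mw_json = {}, {}

    # -- expression ---------------------------------------------------------
    tx_counts = stage("report")(count_reads_per_transcript, case_reads, genes)
    lengths = {
        m.transcript_id: sum(e - s for s, e in m.exons) for m in genes
    }
    expression = tpm(tx_counts, lengths)
    expression.to_csv(outdir / "tpm.tsv", sep="\t", index=False)

    bundle = {
        "metadata": {
            "package_version": __version__,
            "seed": config.sim.seed,
            "config_hash": config.config_hash(),
            "config": asdict(config),
        },
        "preprocess": preprocess_report,
        "variant_spectrum": {"case": spectrum, "control": control_spectrum},
        "n_editing_sites": len(sites),
        "recovery": {k: v for k, v in recovery.items() if k != "matched"},
        "false_negative_reasons": (
            audit["reason"].value_counts().to_dict() if len(audit) else {}
        ),
        "region_distribution": regions,
        "consequence_classes": {
            c: {"count": n, "proportion": n / n_cons if n_cons else 0.0}
            for c, n in cons_counts.items()
        },
        "aa_substitution_spectrum": substitutions,
        "polarity": polarity,
        "blosum_positive_fraction": blosum_pos_fraction,
        "motif": (
            {
                "n_windows": ppm.n_sequences,
                "center": ppm.probs[config.motif_flank].tolist(),
                "minus1": ppm.column(-1),
                "plus1": ppm.column(+1),
            }
            if ppm is not None
            else {}
        ),
        "mfe_summary": mfe_summary,
        "mann_whitney": mw_json,
        "tpm_total": float(expression.tpm.sum()),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True, default=str)
    return bundle
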