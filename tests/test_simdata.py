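"""Simulator contracts: determinism, truth consistency, neighbor weights,
editing-level sampling and the recovery evaluator."""

import math

import numpy as np
import pytest

from editscan import seqio, simdata
from editscan.editing_caller import EditingSite
from editscan.simdata import SimConfig, TruthEditSite, evaluate_recovery


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(seed=1, seq_error_rate=0.5)
    with pytest.raises(ValueError):
        SimConfig(seed=1, mean_depth=0)
    with pytest.raises(ValueError):
        SimConfig(seed=1, context_weights_5p={"A": 1.0})


def test_genome_determinism_byte_identical(tmp_path, small_config):
    genome1, genes1 = simdata.generate_genome_and_genes(small_config)
    genome2, genes2 = simdata.generate_genome_and_genes(small_config)
    f1 = seqio.write_fasta(genome1, tmp_path / "a.fa").read_bytes()
    f2 = seqio.write_fasta(genome2, tmp_path / "b.fa").read_bytes()
    assert f1 == f2
    g1 = seqio.write_gff3(genes1, tmp_path / "a.gff3").read_bytes()
    g2 = seqio.write_gff3(genes2, tmp_path / "b.gff3").read_bytes()
    assert g1 == g2


def test_genes_tile_without_overlap_and_validate(small_world):
    genome, genes, _ = small_world
    gdict = seqio.genome_dict(genome)
    by_chrom = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g.span)
        assert g.validate_coding(gdict) == []
    for spans in by_chrom.values():
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2
    assert {g.strand for g in genes} == {"+", "-"}


def test_all_plus_strand_when_fraction_zero():
    cfg = SimConfig(seed=3, n_chroms=1, chrom_length=15_000, n_genes=6,
                    fraction_minus_strand=0.0, n_edit_sites=10)
    _, genes = simdata.generate_genome_and_genes(cfg)
    assert all(g.strand == "+" for g in genes)


def test_too_many_genes_errors():
    cfg = SimConfig(seed=1, n_chroms=1, chrom_length=3000, n_genes=10, n_edit_sites=1)
    with pytest.raises(ValueError, match="genome too small"):
        simdata.generate_genome_and_genes(cfg)


# ---------------------------------------------------------------------------
# Site planting
# ---------------------------------------------------------------------------


def test_truth_sites_are_adenosines_on_transcript_strand(small_world):
    genome, genes, truth = small_world
    gdict = seqio.genome_dict(genome)
    assert len(truth) == 30
    assert len({s.key for s in truth}) == len(truth)
    for s in truth:
        base = gdict[s.chrom][s.pos]
        assert base == ("A" if s.strand == "+" else "T")
        assert s.context[15] == "A"
        assert s.true_level >= 0.05


def test_degenerate_5p_weights_force_t_neighbor(small_config):
    cfg = SimConfig(
        seed=11, n_chroms=1, chrom_length=15_000, n_genes=8, n_edit_sites=25,
        context_weights_5p={"T": 1.0, "A": 0.0, "C": 0.0, "G": 0.0},
    )
    genome, genes = simdata.generate_genome_and_genes(cfg)
    truth = simdata.plant_editing_sites(genome, genes, cfg)
    assert all(s.context[14] == "T" for s in truth)


def test_uniform_weights_match_background_within_3_sigma():
    cfg = SimConfig(
        seed=5, n_genes=60, n_edit_sites=600, chrom_length=60_000, n_chroms=2,
        context_weights_5p={b: 0.25 for b in "ACGT"},
        context_weights_3p={b: 0.25 for b in "ACGT"},
    )
    genome, genes = simdata.generate_genome_and_genes(cfg)
    truth = simdata.plant_editing_sites(genome, genes, cfg)
    # background -1 base distribution among all transcript adenosines
    gdict = seqio.genome_dict(genome)
    bg = {b: 0 for b in "ACGT"}
    for g in genes:
        seq = g.spliced_sequence(gdict)
        for t in range(1, len(seq) - 1):
            if seq[t] == "A":
                bg[seq[t - 1]] += 1
    total_bg = sum(bg.values())
    n = len(truth)
    for b in "ACGT":
        p = bg[b] / total_bg
        observed = sum(1 for s in truth if s.context[14] == b)
        sigma = math.sqrt(n * p * (1 - p))
        assert abs(observed - n * p) <= 3 * sigma


def test_zero_sites_gives_empty_truth():
    cfg = SimConfig(seed=2, n_chroms=1, chrom_length=15_000, n_genes=6, n_edit_sites=0)
    genome, genes = simdata.generate_genome_and_genes(cfg)
    assert simdata.plant_editing_sites(genome, genes, cfg) == []


def test_more_sites_than_candidates_errors():
    cfg = SimConfig(seed=2, n_chroms=1, chrom_length=15_000, n_genes=6,
                    n_edit_sites=100_000)
    genome, genes = simdata.generate_genome_and_genes(cfg)
    with pytest.raises(ValueError, match="candidate adenosines"):
        simdata.plant_editing_sites(genome, genes, cfg)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def test_simulated_reads_match_reference_without_noise(tmp_path):
    cfg = SimConfig(seed=9, n_chroms=1, chrom_length=15_000, n_genes=6,
                    n_edit_sites=0, shared_snp_count=0, seq_error_rate=1e-9)
    genome, genes = simdata.generate_genome_and_genes(cfg)
    ds = simdata.simulate_reads(genome, genes, [], cfg, "control", tmp_path)
    gdict = seqio.genome_dict(genome)
    mismatches = 0
    for r in seqio.read_sam(ds.sam_path):
        for rs, re_, qs in r.aligned_blocks():
            mismatches += sum(
                1 for a, b in zip(gdict[r.chrom][rs:re_], r.seq[qs : qs + re_ - rs])
                if a != b
            )
    assert mismatches == 0


def test_full_editing_level_shows_g_in_every_read(tmp_path):
    cfg = SimConfig(seed=9, n_chroms=1, chrom_length=15_000, n_genes=6,
                    n_edit_sites=5, shared_snp_count=0, seq_error_rate=1e-9)
    genome, genes = simdata.generate_genome_and_genes(cfg)
    truth = simdata.plant_editing_sites(genome, genes, cfg)
    for s in truth:
        s.true_level = 1.0
    ds = simdata.simulate_reads(genome, genes, truth, cfg, "case", tmp_path)
    from editscan.readqc_pileup import build_pileup

    pileup = build_pileup(seqio.read_sam(ds.sam_path), seqio.genome_dict(genome))
    for s in truth:
        arr = pileup.counts[s.chrom][:, s.pos]
        edited_base = "G" if s.strand == "+" else "C"
        ref_base = "A" if s.strand == "+" else "T"
        assert arr["ACGT".index(edited_base)] == arr.sum() > 0
        assert arr["ACGT".index(ref_base)] == 0


def test_observed_level_concentrates_around_truth(tmp_path):
    cfg = SimConfig(seed=13, n_chroms=1, chrom_length=15_000, n_genes=6,
                    n_edit_sites=8, shared_snp_count=0, seq_error_rate=1e-9,
                    mean_depth=200, expression_sigma=0.0)
    genome, genes = simdata.generate_genome_and_genes(cfg)
    truth = simdata.plant_editing_sites(genome, genes, cfg)
    for s in truth:
        s.true_level = 0.5
    ds = simdata.simulate_reads(genome, genes, truth, cfg, "case", tmp_path)
    from editscan.readqc_pileup import build_pileup

    pileup = build_pileup(seqio.read_sam(ds.sam_path), seqio.genome_dict(genome))
    for s in truth:
        arr = pileup.counts[s.chrom][:, s.pos]
        depth = arr.sum()
        g = arr["ACGT".index("G" if s.strand == "+" else "C")]
        assert depth > 50
        assert abs(g / depth - 0.5) <= 3 * math.sqrt(0.25 / depth)


def test_simulate_reads_determinism(tmp_path, small_config, small_world):
    genome, genes, truth = small_world
    d1 = simdata.simulate_reads(genome, genes, truth, small_config, "case", tmp_path / "a")
    d2 = simdata.simulate_reads(genome, genes, truth, small_config, "case", tmp_path / "b")
    assert d1.sam_path.read_bytes() == d2.sam_path.read_bytes()
    assert d1.fastq1_path.read_bytes() == d2.fastq1_path.read_bytes()


def test_control_label_requires_empty_truth(tmp_path, small_config, small_world):
    genome, genes, truth = small_world
    with pytest.raises(ValueError, match="empty truth"):
        simdata.simulate_reads(genome, genes, truth, small_config, "control", tmp_path)


def test_truth_tsv_round_trip(tmp_path, small_world):
    _, _, truth = small_world
    back = simdata.read_truth_tsv(simdata.write_truth_tsv(truth, tmp_path / "t.tsv"))
    assert [s.key for s in back] == [s.key for s in truth]
    assert [s.context for s in back] == [s.context for s in truth]
    for a, b in zip(back, truth):
        assert a.true_level == pytest.approx(b.true_level, abs=1e-6)


# ---------------------------------------------------------------------------
# Recovery evaluation
# ---------------------------------------------------------------------------


def _truth(chrom, pos, strand, level):
    return TruthEditSite(chrom, pos, strand, "g", 0, level, "N" * 31)


def _called(chrom, pos, strand, level):
    ref, alt = ("A", "G") if strand == "+" else ("T", "C")
    return EditingSite(chrom, pos, strand, ref, alt, level, 50)


def test_perfect_recovery():
    truth = [_truth("c", 5, "+", 0.4), _truth("c", 9, "-", 0.7)]
    called = [_called("c", 5, "+", 0.4), _called("c", 9, "-", 0.7)]
    r = evaluate_recovery(called, truth)
    assert r["precision"] == 1.0 and r["recall"] == 1.0 and r["level_rmse"] == 0.0


def test_empty_called_recall_zero_precision_nan():
    r = evaluate_recovery([], [_truth("c", 5, "+", 0.4)])
    assert r["recall"] == 0.0
    assert math.isnan(r["precision"])


def test_one_false_positive_in_ten():
    truth = [_truth("c", i, "+", 0.5) for i in range(9)]
    called = [_called("c", i, "+", 0.5) for i in range(9)] + [_called("c", 99, "+", 0.5)]
    r = evaluate_recovery(called, truth)
    assert r["precision"] == pytest.approx(0.9)
    assert r["recall"] == 1.0


def test_min_true_level_restricts_recall_denominator_only():
    truth = [_truth("c", 1, "+", 0.05), _truth("c", 2, "+", 0.5)]
    called = [_called("c", 1, "+", 0.1), _called("c", 2, "+", 0.5)]
    r = evaluate_recovery(called, truth, min_true_level=0.2)
    # the low-level site is still a true positive, not a false positive
    assert r["precision"] == 1.0
    assert r["recall"] == 1.0
    assert r["n_truth_eligible"] == 1
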