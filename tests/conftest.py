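"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from editscan import report, simdata
from editscan.structure_fold import EnergyModel, encode_rna, structure_energy


# ---------------------------------------------------------------------------
# Simulated datasets
# ---------------------------------------------------------------------------

#: the study conditions of the recovery check: 30x mean depth, 0.5% error,
#: 200 planted sites, fixed seed
STUDY_SEED = 1


@pytest.fixture(scope="session")
def study_config() -> simdata.SimConfig:
    return simdata.SimConfig(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def small_config() -> simdata.SimConfig:
    """A miniature experiment for fast unit tests."""
    return simdata.SimConfig(
        seed=7,
        n_chroms=1,
        chrom_length=15_000,
        n_genes=8,
        n_edit_sites=30,
        shared_snp_count=8,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    genome, genes = simdata.generate_genome_and_genes(small_config)
    truth = simdata.plant_editing_sites(genome, genes, small_config)
    return genome, genes, truth


@pytest.fixture(scope="session")
def pipeline_bundle(study_config, tmp_path_factory):
    """One full pipeline run at the study conditions, shared across tests."""
    outdir = tmp_path_factory.mktemp("pipeline")
    cfg = report.PipelineConfig(sim=study_config, outdir=str(outdir))
    return report.run_pipeline(cfg)


# ---------------------------------------------------------------------------
# Folding oracle: exhaustive enumeration of all legal structures
# ---------------------------------------------------------------------------


def enumerate_structures(seq: str, model: EnergyModel):
    """Yield every legal set of non-crossing pairs (legal pair letters, no
    hairpin loop under the minimum).  Independent of the DP: a plain
    recursive enumeration over index sets."""
    s = encode_rna(seq)
    pt = model.pair_type_matrix()

    def rec(positions):
        if not positions:
            yield {}
            return
        i = positions[0]
        rest = positions[1:]
        for st in rec(rest):  # i unpaired
            yield st
        for j in rest:
            if j - i - 1 >= model.min_hairpin and pt[s[i], s[j]] >= 0:
                inside = tuple(p for p in rest if p < j)
                outside = tuple(p for p in rest if p > j)
                for st_in in rec(inside):
                    for st_out in rec(outside):
                        d = {i: j}
                        d.update(st_in)
                        d.update(st_out)
                        yield d

    yield from rec(tuple(range(len(seq))))


def brute_force_mfe(seq: str, celsius: float, model: EnergyModel) -> float:
    """Minimum energy over every enumerated structure (empty structure = 0)."""
    best = 0.0
    for pairs in enumerate_structures(seq, model):
        e = structure_energy(seq, pairs, celsius, model)
        if e < best:
            best = e
    return best


def random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, n)])
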