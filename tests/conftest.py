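"""Shared fixtures: one full-size synthetic study computed once per session,
plus a tiny configuration for fast structural tests."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

import sirenscan as ss


@dataclass
class Study:
    """A simulated study with its filtered libraries and called clusters."""

    truth: ss.SyntheticTruth
    wt_reads: list          # filtered wild-type ReadSets
    mut_reads: list         # filtered mutant ReadSets
    clusters: ss.ClusterSet  # wild-type, default parameters


def build_study(config: ss.SimulationConfig) -> Study:
    truth = ss.simulate_genome(config)
    structural = truth.loci_of("structural")
    wt = [
        ss.filter_reads(r, structural=structural)
        for r in ss.simulate_reads(truth, "wild_type")
    ]
    mut = [
        ss.filter_reads(r, structural=structural)
        for r in ss.simulate_reads(truth, "mutant")
    ]
    return Study(truth=truth, wt_reads=wt, mut_reads=mut, clusters=ss.cluster_pipeline(wt))


@pytest.fixture(scope="session")
def default_config() -> ss.SimulationConfig:
    return ss.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def study(default_config) -> Study:
    """Default-scale study (2 x 50 Mb, 2 x 1e6 reads): the concentrated regime."""
    return build_study(default_config)


@pytest.fixture(scope="session")
def small_truth() -> ss.SyntheticTruth:
    """A small genome for placement/annotation tests (no reads generated)."""
    return ss.simulate_genome(
        ss.SimulationConfig(
            n_chromosomes=2,
            chrom_length=400_000,
            n_bill_loci=3,
            n_pau_loci=20,
            total_reads=30_000,
            structural_rna_loci=3,
            n_background_cytosines=500,
            n_genes=60,
            seed=7,
        )
    )
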