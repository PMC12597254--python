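"""Shared fixtures: simulated genomes at two scales."""

from __future__ import annotations

import numpy as np
import pytest

from plastokit import simulate as sim
from plastokit.genome_io import detect_quadripartite


def small_config(seed: int = 0) -> sim.SimConfig:
    """A compact plastome (~53 kb) carrying every planted feature class."""
    return sim.SimConfig(
        seed=seed,
        region_lengths={"lsc": 30000, "irb": 8000, "ssc": 7000},
        region_gc={"lsc": 0.33, "irb": 0.43, "ssc": 0.28},
        gene_plan=[
            sim.GenePlan("psbA", "lsc", 1062, "-"),
            sim.GenePlan("matK", "lsc", 1530, "-"),
            sim.GenePlan("rbcL", "lsc", 1428, "+"),
            sim.GenePlan("rps2", "lsc", 711, "-"),
            sim.GenePlan("petA", "lsc", 963, "+"),
            sim.GenePlan("rps19", "lsc", 279, "-", junction=("JLB", 45)),
            sim.GenePlan("rpl2", "irb", 825, "-"),
            sim.GenePlan("ndhF", "ssc", 1200, "-", junction=("JSB", 1100)),
            sim.GenePlan("rpl32", "ssc", 171, "+"),
            sim.GenePlan("ycf1", "ssc", 1800, "+", junction=("JSA", 600)),
            sim.GenePlan("trnN-GUU", "ssc", 72, "-", kind="tRNA"),
        ],
        ssr_plan=sim.default_ssr_plan(),
        dispersed_plan=sim.default_dispersed_plan(),
        tandem_plan=sim.default_tandem_plan(),
        accession="SIMSMALL1",
    )


@pytest.fixture(scope="session")
def small_genome():
    record, manifest = sim.simulate_plastome(small_config(seed=11))
    return record, manifest


@pytest.fixture(scope="session")
def small_partition(small_genome):
    record, _ = small_genome
    return detect_quadripartite(record)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.4) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), p=probs, size=n))
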