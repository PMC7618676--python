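import numpy as np
import pandas as pd
import pytest

from pirnascape import simulate as sm
from pirnascape import smallrna as sr


@pytest.fixture(scope="session")
def demo_config():
    """A moderate multi-feature genome: planted TE families spanning the
    activity boundary, two clusters (uni+ and dual), genes and CpG islands,
    TE/background reads with ping-pong partners."""
    return sm.SimConfig(
        seed=11,
        genome_length=300_000,
        te_plan=[
            sm.TEPlan("Gypsy", "LTR", 2000, 5,
                      divergence=[0.0, 0.02, 0.08, 0.03, 0.12],
                      truncation=[0.0, 0.0, 0.0, 0.5, 0.0]),
            sm.TEPlan("L1", "LINE", 3000, 3, divergence=0.01),
        ],
        cluster_plan=[
            sm.ClusterPlan("chr1", 40_000, 48_000, "uni+", 1500),
            sm.ClusterPlan("chr1", 120_000, 130_000, "dual", 1200),
        ],
        gene_plan=sm.GenePlan(n_genes=8),
        cgi_plan=sm.CGIPlan(n=3),
        te_read_mass=2000,
        background_read_mass=300,
    )


@pytest.fixture(scope="session")
def demo_sim(demo_config):
    return sm.simulate_genome(demo_config)


@pytest.fixture(scope="session")
def demo_reads(demo_config, demo_sim):
    return sm.simulate_small_rna(demo_config, demo_sim)


@pytest.fixture(scope="session")
def demo_alignments(demo_reads, demo_sim):
    collapsed = sr.collapse(demo_reads["seq"].tolist())
    return sr.toy_map(collapsed, demo_sim.genome)


@pytest.fixture(scope="session")
def demo_methylome(demo_config, demo_sim):
    return sm.simulate_methylome(demo_config, demo_sim)


def truth_alignments(reads: pd.DataFrame) -> pd.DataFrame:
    """Unit-weight alignment table built directly from simulator truth rows."""
    df = reads[["read_id", "seq", "chrom", "start", "end", "strand"]].copy()
    df["n_hits"] = 1
    df["count"] = 1
    df["weight"] = 1.0
    return df


def jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union else 0.0
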