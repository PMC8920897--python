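import numpy as np
import pandas as pd
import pytest

from polygamete.pap import PAPMatrix
from polygamete.pipeline import PipelineConfig, run_pipeline
from polygamete.simulate import (SimConfig, simulate_gametes, simulate_genome,
                                 simulate_marker_counts)


def pap_from_strings(patterns: dict[str, str], classes: dict[str, int],
                     contig_bp: int = 120_000) -> PAPMatrix:
    """Build a PAPMatrix from literal genotype strings (one marker per contig)."""
    marker_rows = []
    geno = []
    for name, pattern in patterns.items():
        marker_rows.append((f"{name}:0-{contig_bp}", name, 0, contig_bp,
                            classes.get(name, 1), contig_bp))
        geno.append([int(ch) for ch in pattern])
    markers = pd.DataFrame(
        marker_rows,
        columns=["marker_id", "contig_id", "start", "end", "copy_class", "W"])
    n_g = len(next(iter(patterns.values())))
    gametes = [f"g{i}" for i in range(n_g)]
    normalizers = pd.DataFrame({
        "gamete_id": gametes, "N": 1000, "m_r": 1.0,
        "n_informative": len(patterns), "usable": True})
    return PAPMatrix(markers=markers, genotypes=np.array(geno),
                     gamete_ids=gametes, normalizers=normalizers,
                     dropped_gametes=[])


@pytest.fixture(scope="session")
def small_genome():
    cfg = SimConfig(n_chromosomes=2, chrom_length_bp=600_000, n_gametes=300,
                    seed=11)
    return simulate_genome(cfg)


@pytest.fixture(scope="session")
def small_gametes(small_genome):
    return simulate_gametes(small_genome)


@pytest.fixture(scope="session")
def small_counts(small_genome, small_gametes):
    return simulate_marker_counts(small_genome, small_gametes)


@pytest.fixture(scope="session")
def small_pipeline(tmp_path_factory):
    """One mid-size simulated pipeline run shared across tests (3 chr x 1 Mb)."""
    out = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(
        outdir=out, seed=7,
        sim=SimConfig(n_chromosomes=3, chrom_length_bp=1_000_000,
                      n_gametes=400),
        n_reads=4000)
    result = run_pipeline(cfg)
    return cfg, result, out
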