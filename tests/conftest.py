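import numpy as np
import pandas as pd
import pytest

from methdiff.core import MethylomeSample
from methdiff.simulate import default_simulation, simulate_gene_models, simulate_methylome_pair


def make_sample(rows, sample_id="S", r=0.0, chrom_sizes=None):
    """Build a MethylomeSample from (chrom, pos, strand, m, u, ctx, tri) tuples."""
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "tricontext"]
    )
    return MethylomeSample(
        sample_id=sample_id, records=df, nonconversion_rate=r, chrom_sizes=chrom_sizes or {}
    )


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated pair with planted DMRs, shared across tests."""
    config = default_simulation(seed=11, chrom_length=120_000, n_genes=24, n_dmrs=8)
    sample_a, sample_b, truth = simulate_methylome_pair(config)
    genes = simulate_gene_models(config)
    return {"config": config, "a": sample_a, "b": sample_b, "truth": truth, "genes": genes}
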