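import numpy as np
import pandas as pd
import pytest

from methclime.simulate import (
    SimConfig,
    simulate_annotations,
    simulate_genotypes,
    simulate_methylomes,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(
        n_accessions=60,
        n_snps=2000,
        genome_length=1_000_000,
        n_chromosomes=5,
        n_genes=80,
        n_tes=80,
        site_spacing=60,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    g = simulate_genotypes(small_cfg)
    annot = simulate_annotations(small_cfg)
    counts, truth = simulate_methylomes(g, annot, small_cfg)
    return {"cfg": small_cfg, "genotypes": g, "annotations": annot,
            "methylomes": counts, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_counts(sites: pd.DataFrame, meth: np.ndarray, total: np.ndarray,
                samples: pd.DataFrame | None = None):
    """Build a MethylCounts from raw arrays (single-sample default)."""
    from methclime.datatypes import MethylCounts

    if meth.ndim == 1:
        meth = meth[:, None]
        total = total[:, None]
    if samples is None:
        samples = pd.DataFrame(
            {"accession": [f"s{i}" for i in range(meth.shape[1])],
             "environment": ["10C"] * meth.shape[1]})
    return MethylCounts(sites=sites.reset_index(drop=True),
                        meth=np.asarray(meth, np.int32),
                        total=np.asarray(total, np.int32),
                        samples=samples)
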