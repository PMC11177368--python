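import numpy as np
import pytest

from equigen.core_io import GenotypeMatrix, VariantInfo, compute_maf
from equigen.simulate import CausalVariant, SimConfig, TraitSpec, simulate_dataset


def make_matrix(codes, chrom="1", spacing=10_000, start=10_000, samples=None):
    """GenotypeMatrix from a literal codes array; MAF filled from the data."""
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    samples = samples or [f"s{i}" for i in range(n)]
    dummy = [VariantInfo(f"v{j}", chrom, start + j * spacing, "A", "C", 0.0)
             for j in range(m)]
    G = GenotypeMatrix(samples, dummy, codes, validate=False)
    maf = compute_maf(G, allow_all_missing=True)
    from dataclasses import replace
    G.variants = [replace(v, maf=float(f) if np.isfinite(f) else 0.0)
                  for v, f in zip(G.variants, maf)]
    return G


def small_cohort_config(seed=0, n=400, **kwargs):
    """Scaled-down study conditions for fast unit tests."""
    defaults = dict(
        n_individuals=n,
        chromosomes=[("1", 300, 60_000_000), ("2", 300, 60_000_000),
                     ("3", 300, 120_000_000)],
        causal_spec=[CausalVariant(chrom="3", pos=107_558_421,
                                   target_maf=0.45, beta=2.68,
                                   consequence_tag="stop_gained",
                                   n_window_variants=150)],
        seed=seed,
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def default_sim():
    """One full-size simulated cohort shared by read-only tests."""
    cfg = SimConfig(seed=101)
    G, pheno, truth = simulate_dataset(cfg)
    return cfg, G, pheno, truth


@pytest.fixture(scope="session")
def small_sim():
    cfg = small_cohort_config(seed=7)
    G, pheno, truth = simulate_dataset(cfg)
    return cfg, G, pheno, truth
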