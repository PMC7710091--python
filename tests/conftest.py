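import numpy as np
import pandas as pd
import pytest

from doeqtl import genotype, pipeline, simulate


@pytest.fixture(scope="session")
def small_config() -> simulate.SimulationConfig:
    """A compact DO cohort with planted cis and trans effects for reuse."""
    return simulate.SimulationConfig(
        seed=11,
        n_per_sex=50,
        chromosomes=(("1", 100_000_000, 40), ("2", 100_000_000, 40)),
        causal_effects=(
            simulate.CausalEffect(
                "g_cast", "chr1_m0020", (0, 0, 0, 0, 0, 2.0, 0, 0),
                sex_multiplier=(1.0, 0.2), sex_effect=1.5,
            ),
            simulate.CausalEffect(
                "g_nzo", "chr2_m0010", (0, 0, 0, 0, -2.0, 0, 0, 0),
                sex_multiplier=(0.1, 1.0), sex_effect=-1.5,
            ),
            simulate.CausalEffect("g_129", "chr1_m0030", (0, 0, 2.0, 0, 0, 0, 0, 0)),
        ),
        n_null_genes=4,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config) -> pipeline.Bundle:
    return pipeline.bundle_from_config(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_simplex_tensor(rng: np.random.Generator, n_s: int, n_m: int) -> np.ndarray:
    """Random valid diplotype probability tensor (Dirichlet rows)."""
    raw = rng.gamma(1.0, size=(n_s, n_m, 36))
    return raw / raw.sum(axis=-1, keepdims=True)


def toy_marker_map(positions_by_chrom: dict[str, list[int]], measured=None) -> pd.DataFrame:
    rows = []
    k = 0
    for chrom, positions in positions_by_chrom.items():
        for p in positions:
            rows.append(
                {
                    "marker_id": f"m{k}",
                    "chrom": chrom,
                    "pos_bp": p,
                    "measured": True if measured is None else measured[k],
                }
            )
            k += 1
    return genotype.validate_marker_map(pd.DataFrame(rows))
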