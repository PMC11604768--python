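import numpy as np
import pytest

from trescreen import design, motifs, simulate


def dp_levenshtein(a: str, b: str) -> int:
    """Plain dynamic-programming Levenshtein distance (test oracle)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


@pytest.fixture(scope="session")
def design_config():
    return design.DesignConfig()


@pytest.fixture(scope="session")
def small_catalog():
    cfg = simulate.SimulationConfig(n_motifs=6)
    seeds, _ = simulate.simulate_catalog(cfg, seed=7)
    return motifs.build_catalog(seeds)


@pytest.fixture(scope="session")
def small_screen(design_config, small_catalog):
    """A tiny error-free end-to-end screen shared across read-level tests."""
    cfg = simulate.SimulationConfig(
        n_motifs=3,
        n_barcodes_per_promoter=5,
        dna_depth=50,
        rna_depth=50,
        substitution_error_rate=0.0,
    )
    catalog = small_catalog[:3]
    units, _, _ = design.generate_library(catalog, config=design_config, rng_seed=7)
    return simulate.simulate_screen(units, design_config, cfg, seed=7), units
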