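"""Shared fixtures: a tiny toy genome and a full-scale founder state.

The full-scale state (3,000 inbred founders, 12 chromosomes, 360 QTN /
996 SNP, calibrated trait) is built once per session and reused by every
test that needs realistic study conditions.
"""

from __future__ import annotations

import numpy as np
import pytest

from rrsim import (GenomeConfig, build_genome_map, calibrate_trait,
                   initialize_base_population, sample_effects,
                   simulate_founder_panel)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_map():
    """Two small chromosomes, 40 sites each, 8 QTN + 12 SNP per chromosome."""
    cfg = GenomeConfig(chromosomes=2, length_cM=100.0, n_sites=40, n_qtn=8,
                       n_snp=12, seed=7)
    return build_genome_map(cfg)


@pytest.fixture(scope="session")
def small_genome_config():
    """Reduced founder generator for fast scheme-level tests."""
    return GenomeConfig(n_founders=400, wf_size=100, wf_generations=60,
                        n_sites=150, seed=11)


@pytest.fixture(scope="session")
def full_state():
    """Full-scale founder panel with a calibrated trait (shared, read-only)."""
    cfg = GenomeConfig(seed=2024)
    rng = np.random.default_rng(2024)
    gmap = build_genome_map(cfg, rng)
    founders = simulate_founder_panel(gmap, cfg.n_founders, rng, config=cfg)
    arch = sample_effects(gmap.qtn_indices.size, rng=rng)
    arch = calibrate_trait(arch, founders, gmap, target_var_g=1.0, target_H2=0.53)
    return gmap, founders, arch


@pytest.fixture(scope="session")
def base_pools(full_state):
    """Cycle-zero heterotic pools built from the full-scale panel."""
    gmap, founders, arch = full_state
    return initialize_base_population(founders, arch, gmap,
                                      np.random.default_rng(77))
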