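"""Shared fixtures: small synthetic configurations reused across the suite."""

from __future__ import annotations

import pytest

from plastcomp.synth import SynthConfig, generate_family, generate_plastome

# A compact quadripartite genome without junction-spanning genes (they need
# full-size SSC/IR): fast enough for repeated IR-detection scans.
SMALL = SynthConfig(
    lsc_len=6000,
    irb_len=1800,
    ssc_len=1100,
    n_lsc_genes=4,
    n_ssc_genes=1,
    n_ir_genes=1,
    n_trna=2,
    n_rrna=0,
    gene_codon_range=(100, 150),
    junction_genes=False,
    hotspots=(),
    seed=101,
)

# Mid-size genome with the three junction-spanning genes and an IR rRNA.
MID = SynthConfig(
    lsc_len=20000,
    irb_len=9000,
    ssc_len=8000,
    n_lsc_genes=6,
    n_ssc_genes=1,
    n_ir_genes=1,
    n_trna=2,
    n_rrna=1,
    gene_codon_range=(100, 160),
    junction_genes=True,
    hotspots=(),
    seed=11,
)


@pytest.fixture(scope="session")
def small_plastome():
    return generate_plastome(SMALL)


@pytest.fixture(scope="session")
def mid_plastome():
    return generate_plastome(MID)


@pytest.fixture(scope="session")
def default_plastome():
    return generate_plastome(SynthConfig(seed=42))


@pytest.fixture(scope="session")
def default_family():
    return generate_family(SynthConfig(seed=42))


@pytest.fixture(scope="session")
def divergent_family():
    return generate_family(SynthConfig(seed=42, divergent_leaves=("D",)))
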