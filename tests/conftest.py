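"""Shared fixtures.

The expensive end-to-end pipeline runs (full default planted fixture, its
sequence-only ablation, and the matched null fixture) are session-scoped so
the acceptance suite computes each of them once.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from multippi import (RFConfig, SynthConfig, WalkConfig, build_graph,
                      generate, load_physchem_table, normalize_table)
from multippi.pipeline import run_pipeline


@pytest.fixture(scope="session")
def table():
    return normalize_table(load_physchem_table())


@pytest.fixture(scope="session")
def tiny_config():
    return SynthConfig(n_proteins=60, n_mirna=20, n_lncrna=20, n_drug=20,
                       n_disease=20, n_positive_pairs=100, seed=3)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_config):
    return generate(tiny_config)


@pytest.fixture(scope="session")
def tiny_graph(tiny_bundle):
    return build_graph(tiny_bundle.edges.values())


@pytest.fixture(scope="session")
def planted_bundle():
    """The default planted fixture: 300 proteins, full network signal, seed 7."""
    return generate(SynthConfig())


@pytest.fixture(scope="session")
def planted_result(planted_bundle):
    """Full end-to-end run (combined features) on the planted fixture."""
    return run_pipeline(planted_bundle, mode="combined", seed=7)


@pytest.fixture(scope="session")
def seqonly_result(planted_bundle):
    """Sequence-only ablation on the same planted fixture."""
    return run_pipeline(planted_bundle, mode="sequence_only", seed=7)


@pytest.fixture(scope="session")
def null_result():
    """End-to-end run with all planted signal switched off."""
    bundle = generate(dataclasses.replace(SynthConfig(), ppi_signal=0.0,
                                          seq_signal=0.0))
    return run_pipeline(bundle, mode="combined", seed=7)
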