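"""Shared fixtures: small simulated selection studies and helpers."""

from __future__ import annotations

import pytest

from phageselect import (
    FitnessModel,
    NNKLibrarySpec,
    PeptideCountTable,
    SelectionConfig,
    build_nnk_codon_table,
    sample_naive_pool,
    simulate_selection,
    simulate_study,
)


@pytest.fixture(scope="session")
def nnk_table():
    return build_nnk_codon_table()


@pytest.fixture(scope="session")
def small_spec():
    return NNKLibrarySpec(pool_size=2_000)


@pytest.fixture(scope="session")
def small_cfg():
    return SelectionConfig(reads_per_round=5_000, error_rate=0.0, seed=11)


@pytest.fixture(scope="session")
def small_pool(small_spec):
    return sample_naive_pool(small_spec, seed=7)


@pytest.fixture(scope="session")
def small_rounds(small_pool, small_cfg):
    model = FitnessModel(seed=13)
    return simulate_selection(small_pool, model, small_cfg)


@pytest.fixture(scope="session")
def small_study():
    """A reduced 13-sample study (naive + 3 arms x rounds 2-5)."""
    return simulate_study(
        seed=5,
        spec=NNKLibrarySpec(pool_size=4_000),
        cfg=SelectionConfig(reads_per_round=10_000, error_rate=0.0),
    )


def make_table(counts: dict[str, int], sample_id: str = "s", **kwargs) -> PeptideCountTable:
    return PeptideCountTable.from_counts(counts, sample_id=sample_id, **kwargs)
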