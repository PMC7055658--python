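"""Shared fixtures: synthetic datasets and pipeline runs reused across tests."""

import pandas as pd
import pytest

import gradloc as gl

#: Scaled-down class sizes for fast tests (same proportions as the defaults).
SMALL_CLASSES = dict(
    n_im=60,
    n_om=24,
    n_soluble=80,
    n_imcyto_membrane=12,
    n_imcyto_soluble=24,
    n_transenvelope=4,
    n_dual=4,
)


def mem_config(**overrides) -> gl.RunConfig:
    """A RunConfig for in-memory analysis (paths unused)."""
    base = dict(
        rep1_path="",
        rep2_path="",
        annotation_path="",
        out_dir="",
        seed=1,
        make_plots=False,
    )
    base.update(overrides)
    return gl.RunConfig(**base)


@pytest.fixture(scope="session")
def small_data() -> gl.SimulatedData:
    return gl.simulate_dataset(gl.GeneratorConfig(seed=7, **SMALL_CLASSES))


@pytest.fixture(scope="session")
def small_result(small_data) -> gl.PipelineResult:
    return gl.analyze(*small_data.replicates, small_data.annotation, mem_config(seed=7))


@pytest.fixture(scope="session")
def default_data() -> gl.SimulatedData:
    """The generator's default study conditions, seed 1."""
    return gl.simulate_dataset(gl.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_result(default_data) -> gl.PipelineResult:
    return gl.analyze(*default_data.replicates, default_data.annotation, mem_config(seed=1))


def method_accuracy(result: gl.PipelineResult, truth: pd.DataFrame, column: str) -> float:
    """Fraction of core-class (IM/OM/soluble ground truth) calls that are correct."""
    frame = result.calls.frame
    core = truth["true_class"].isin(["IM", "OM", "soluble"]).reindex(frame.index, fill_value=False)
    expected = truth["expected_localization"].reindex(frame.index)
    called = frame[column].notna() & core
    if column == "consensus_call":
        called &= frame["high_confidence"].astype(bool)
    return float((frame.loc[called, column] == expected[called]).mean())
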