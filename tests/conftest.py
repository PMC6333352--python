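"""Shared fixtures: small planted cohorts and toy graphs, generated at test time."""

import warnings

import numpy as np
import pandas as pd
import pytest

from coexprio import simulate as sim


@pytest.fixture(autouse=True)
def _quiet_path_warnings():
    """Per-path concordance warnings are expected noise in graph-wide tests."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*fewer than 2 measured genes.*")
        yield


@pytest.fixture(scope="session")
def small_cohort():
    """Default-scale planted cohort shared by read-only tests."""
    design = sim.CohortDesign(rng_seed=7)
    ctl, scz, truth = sim.generate_expression(design)
    return design, ctl, scz, truth


@pytest.fixture(scope="session")
def small_study(small_cohort):
    """Cohort plus its PPI scaffold, seeds and reference sets."""
    design, ctl, scz, truth = small_cohort
    graph, seeds = sim.generate_ppi(sim.PpiDesign(rng_seed=8), design)
    refs = sim.generate_reference_sets(sim.ReferenceDesign(rng_seed=9), truth)
    return design, ctl, scz, truth, graph, seeds, refs


def toy_expression(values: dict[str, list[float]], samples=None) -> pd.DataFrame:
    """Tiny genes x samples frame from a dict of per-gene value lists."""
    df = pd.DataFrame(values).T
    df.columns = samples or [f"s{i}" for i in range(df.shape[1])]
    return df
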