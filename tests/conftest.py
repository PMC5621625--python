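"""Shared fixtures: small synthetic worlds and a fitted posterior.

Session scope keeps the expensive simulate/fit work to one pass; tests that
need isolation build their own tiny inputs inline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spatnut import model, synthetic
from spatnut.exposure import build_exposure_matrix


@pytest.fixture(scope="session")
def small_world():
    """Geography, adjacency and a conflict stream for a 6x5-cluster world."""
    truth = synthetic.TruthParams()
    geography, adjacency = synthetic.generate_geography(6, 5, seed=11)
    events = synthetic.simulate_conflict_events(
        geography, truth, "2007-01-01", "2010-12-31", seed=12)
    return {"truth": truth, "geography": geography, "adjacency": adjacency,
            "events": events}


@pytest.fixture(scope="session")
def small_survey(small_world):
    """Simulated survey (n=1500, 3 rounds) plus its exposure matrix."""
    dates = pd.date_range("2008-02-01", "2010-08-01", periods=3)
    dataset = synthetic.simulate_survey(
        small_world["geography"], small_world["adjacency"],
        small_world["events"], small_world["truth"], 1500, dates, seed=13)
    survey_index = dataset.records[["cluster_id", "survey_date"]].drop_duplicates()
    exposure = build_exposure_matrix(
        small_world["events"], small_world["geography"].clusters, survey_index)
    return {"dataset": dataset, "exposure": exposure, **small_world}


@pytest.fixture(scope="session")
def fitted_small(small_survey):
    """Variant-B design and posterior fitted on the small survey."""
    design = model.build_design(
        small_survey["dataset"], small_survey["exposure"],
        small_survey["geography"], variant="B", outcome="wasted")
    posterior = model.fit_model(
        design, small_survey["adjacency"], chains=2, iterations=600,
        burnin=250, thinning=1, seed=21)
    return {"design": design, "posterior": posterior, **small_survey}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
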