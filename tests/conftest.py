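"""Shared fixtures: synthetic study runs reused across test modules."""

import numpy as np
import pytest

from mirforge.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """One full zero-noise pipeline run on the default study conditions
    (100 kb genome, 20 planted hairpins, 3 tissues): the workhorse fixture
    for end-to-end recovery, expression and summary checks."""
    outdir = tmp_path_factory.mktemp("study")
    config = RunConfig(seed=1)
    summary = run_pipeline(config, outdir)
    return {"config": config, "outdir": outdir, "summary": summary}
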