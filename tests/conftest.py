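"""Shared fixtures: a small simulated input bundle and its pipeline run.

The bundle is generated once per session; tests treat it as read-only.
"""

import pytest

from fusionscan.pipeline import run_pipeline
from fusionscan.simulate import default_plan, simulate_bundle


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """The canonical planted-fusion bundle (10 species, 8 events)."""
    out = tmp_path_factory.mktemp("bundle")
    return simulate_bundle(default_plan(seed=11), out)


@pytest.fixture(scope="session")
def pipeline_run(bundle, tmp_path_factory):
    """A full pipeline run over the session bundle."""
    out = tmp_path_factory.mktemp("pipeline_out")
    manifest, ctx = run_pipeline(bundle.config, out)
    return bundle, manifest, ctx
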