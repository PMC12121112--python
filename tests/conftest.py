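import pytest

from c2t.pipeline import RunConfig, run_pipeline
from c2t.sim import SimConfig


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the reference synthetic experiment
    (300 genes x 4 cells, ~50k read pairs, seed 42), shared across tests."""
    out = tmp_path_factory.mktemp("default_run") / "run"
    manifest = run_pipeline(RunConfig(out_dir=str(out), sim=SimConfig()))
    return {"dir": out, "manifest": manifest}
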