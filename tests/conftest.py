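import json

import pytest

from crev2g.pipeline import RunConfig, run_all
from crev2g.simulate import SyntheticConfig, generate


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    """The default synthetic differentiation dataset, generated once."""
    d = tmp_path_factory.mktemp("sim")
    generate(SyntheticConfig(seed=1), d)
    return d


@pytest.fixture(scope="session")
def manifest(sim_dir):
    with open(sim_dir / "manifest.json") as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def pipeline_result(sim_dir, tmp_path_factory):
    """Full pipeline run on the synthetic dataset (atlas .. enrichment)."""
    out = tmp_path_factory.mktemp("out")
    cfg = RunConfig(input_dir=str(sim_dir), out_dir=str(out), seed=1)
    report = run_all(cfg)
    return {"cfg": cfg, "out": out, "report": report}
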