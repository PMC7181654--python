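import json
import logging
from pathlib import Path

import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

logging.getLogger("lncstage").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory) -> dict:
    """The default synthetic study bundle (seed 0), shared across tests."""
    from lncstage.simulate import simulate_bundle

    outdir = tmp_path_factory.mktemp("bundle")
    return simulate_bundle(outdir, seed=0)


@pytest.fixture(scope="session")
def pipeline_run(bundle, tmp_path_factory):
    """One full pipeline run on the bundle: (report, outdir, report bytes
    of an identical rerun for the determinism contract)."""
    from lncstage.pipeline import config_from_bundle, run_pipeline

    outdir = tmp_path_factory.mktemp("run")
    cfg = config_from_bundle(bundle, outdir)
    report = run_pipeline(cfg)
    first = (Path(outdir) / "report.json").read_bytes()
    run_pipeline(config_from_bundle(bundle, outdir))
    second = (Path(outdir) / "report.json").read_bytes()
    return report, Path(outdir), (first, second)
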