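import numpy as np
import pandas as pd
import pytest

from deepscreen import pipeline, synthcell


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One 50-clone zero-noise screen shared across test modules."""
    outdir = tmp_path_factory.mktemp("demo") / "run"
    manifest = pipeline.run_screen({"n_clones": 50, "seed": 3}, outdir=str(outdir))
    return {"outdir": outdir, "manifest": manifest,
            "truth": pd.read_csv(outdir / "sim" / "truth.csv"),
            "hits": pd.read_csv(outdir / "hits.csv")}


@pytest.fixture()
def small_clones():
    return synthcell.make_library(5, kd_range=(1e-9, 1e-7), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
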