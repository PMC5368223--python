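import numpy as np
import pytest

from hljdopt.pipeline import RunConfig, run_pipeline, run_hashes


#: reduced study configuration shared by the pipeline/acceptance tests;
#: small n and coarse ppm grid keep the full run at desk speed.
def small_run_config(out_dir, seed=11):
    return RunConfig(
        out_dir=str(out_dir),
        n_per_group=5,
        ppm_step=0.005,
        n_permutations=20,
        cv_repeats=5,
        permutation_cv_repeats=2,
        seed=seed,
    )


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One reduced end-to-end run, shared across tests."""
    out = tmp_path_factory.mktemp("pipeline") / "run"
    cfg = small_run_config(out)
    summary = run_pipeline(cfg)
    return {"config": cfg, "summary": summary, "out": out,
            "hashes": run_hashes(out)}


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_cloud():
    """Well-separated two-class data (planted 5-sigma shift on one feature)."""
    rng = np.random.default_rng(3)
    X = rng.normal(size=(40, 20))
    X[:20, 0] += 5.0
    y = np.array(["a"] * 20 + ["b"] * 20)
    return X, y
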