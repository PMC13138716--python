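import pytest

from steptraj.generate import default_config, generate_population
from steptraj.lcmm import SeriesSet, fit_lcmm
from steptraj.preprocess import preprocess

RECOVERY_SEED = 73


@pytest.fixture(scope="session")
def default_population():
    """One default synthetic cohort (N=400, 52 weeks) shared across tests."""
    cfg = default_config(n_participants=400, seed=RECOVERY_SEED)
    steps, shc, truth = generate_population(cfg)
    return {"config": cfg, "steps": steps, "shc": shc, "truth": truth}


@pytest.fixture(scope="session")
def preprocessed(default_population):
    return preprocess(default_population["steps"], default_population["shc"])


@pytest.fixture(scope="session")
def g4_fit(preprocessed):
    """The 4-class fit on the default cohort (parameter-recovery workhorse)."""
    series = SeriesSet.from_frame(preprocessed.weekly)
    return fit_lcmm(series, 4, n_starts=2, seed=RECOVERY_SEED)


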