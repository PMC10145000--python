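import numpy as np
import pytest

from relcap import (
    AnalysisConfig,
    AssayTable,
    CalibrationFit,
    ProcessScenario,
    SpecLimits,
    StabilityTable,
    VarianceComponents,
)

# Single pre-committed seed for every stochastic check in the suite.
SEED = 12345


@pytest.fixture(scope="session")
def spec() -> SpecLimits:
    """95%/105% specification around the 1.454 µg/mL label claim."""
    return SpecLimits(1.454)


@pytest.fixture(scope="session")
def config(spec) -> AnalysisConfig:
    return AnalysisConfig(spec, bootstrap_reps=500, seed=SEED)


@pytest.fixture(scope="session")
def hplc_fit() -> CalibrationFit:
    """Published calibration summary: 7 levels (2-8 µg/mL) x 4 replicates."""
    return CalibrationFit(b0=-5.936, b1=9.294, s_r=0.9029, n=28, x_bar=5.0, sxx=112.0)


@pytest.fixture(scope="session")
def reported_vc() -> VarianceComponents:
    """Published random-effects estimates for the capability batches."""
    return VarianceComponents(mu=1.4625, sigma_batch=0.0015891, sigma_within=0.0087035)


@pytest.fixture()
def scenario() -> ProcessScenario:
    """Default synthetic process: three batches, ICH sampling times."""
    return ProcessScenario(seed=SEED)


@pytest.fixture()
def assay_table(scenario) -> AssayTable:
    from relcap import gen_time_zero

    return gen_time_zero(scenario)


@pytest.fixture()
def stability_table(scenario) -> StabilityTable:
    from relcap import gen_stability

    return gen_stability(scenario)


def make_assay(k: int, n: int, mu: float, sa: float, se: float, seed: int) -> AssayTable:
    """Direct one-way random-effects sample, independent of relcap.simulate."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(k):
        a = rng.normal(0.0, sa) if sa else 0.0
        for v in mu + a + rng.normal(0.0, se, size=n):
            rows.append((f"b{i:03d}", float(v)))
    return AssayTable.from_records(rows)
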