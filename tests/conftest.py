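import numpy as np
import pytest

from nmrasca import SyntheticConfig, simulate_cohort

#: compact grid used by most simulated fixtures (300 raw buckets, no windows)
SMALL_GRID = dict(region=(1.0, 4.0), exclusions=(), width=0.01)


def small_config(**kw) -> SyntheticConfig:
    """Study-shaped (5x5, 6-10/cell) cohort on a compact grid."""
    base = dict(n_metabolites=20, seed=0, **SMALL_GRID)
    base.update(kw)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded cohort at the default effect sizes."""
    return simulate_cohort(small_config(seed=11))


@pytest.fixture(scope="session")
def single_time_classes():
    """Samples of one time level with dose labels: PLS-DA style input."""
    matrix, design, truth = simulate_cohort(
        small_config(seed=5, n_times=2, dose_amplitude=0.8,
                     affected_fraction_dose=0.6, sigma=0.1)
    )
    mask = np.asarray([t == design.time_levels[0] for t in design.time])
    sub = matrix.subset(mask)
    return sub, np.asarray(sub.design.dose), truth
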