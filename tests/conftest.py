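import numpy as np
import pytest

from lethalmap import simpop


def tiny_population_config(p: float = 0.128, n_offspring: int = 300,
                           n_founder_m: int = 60, n_founder_f: int = 240,
                           n_markers_50k: int = 60, n_in_del: int = 2,
                           **kwargs) -> simpop.PopulationConfig:
    """A single-breed, 50K-only cohort small enough for per-test simulation."""
    return simpop.PopulationConfig(
        breeds=[simpop.BreedConfig("RED", n_founder_m, n_founder_f,
                                   n_offspring, p)],
        n_generations=1,
        n_markers_50k=n_markers_50k,
        n_markers_in_deletion_50k=n_in_del,
        n_markers_hd=0,
        n_markers_in_deletion_hd=0,
        **kwargs,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Shared small cohort with the deletion segregating at p = 0.128."""
    cfg = tiny_population_config()
    return simpop.simulate_population(cfg, seed=101)


@pytest.fixture(scope="session")
def small_cohort_array(small_cohort):
    arr = simpop.emit_array_signals(
        small_cohort.phased, small_cohort.markers, small_cohort.deletion,
        small_cohort.config.noise, seed=202)
    return arr


@pytest.fixture(scope="session")
def study_scale_cohort():
    """~2,000 live animals at p = 0.128 (array-evidence tests)."""
    cfg = tiny_population_config(n_offspring=1400, n_founder_m=150,
                                 n_founder_f=600, n_markers_50k=600,
                                 n_in_del=5)
    cohort = simpop.simulate_population(cfg, seed=303)
    cohort.array = simpop.emit_array_signals(
        cohort.phased, cohort.markers, cohort.deletion, cfg.noise, seed=404)
    return cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
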