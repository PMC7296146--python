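import numpy as np
import pandas as pd
import pytest

from phenodrought.design import ExperimentDesign
from phenodrought.simulate import (EffectProfileArchetype, SimulationScenario,
                                   TraitScenario, simulate_experiment)


@pytest.fixture
def small_design() -> ExperimentDesign:
    return ExperimentDesign(n_genotypes=12, n_carriers_per_condition=2,
                            n_plants_per_carrier=3, n_days=8,
                            drought_start_day=3, drought_end_day=6)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def one_day_scenario(n_genotypes: int, g: np.ndarray, carrier_sd: float,
                     seed: int, archetype: EffectProfileArchetype | None = None,
                     baseline: float = 100.0,
                     deviation_sd: float = 0.0) -> SimulationScenario:
    """Single-trait, single-day scenario used by the REML harnesses."""
    design = ExperimentDesign(n_genotypes=n_genotypes, n_days=1,
                              drought_start_day=1, drought_end_day=1,
                              n_plants_per_carrier=1)
    arch = archetype or EffectProfileArchetype("null")
    ts = TraitScenario("t", baseline, arch, np.asarray(g, dtype=float),
                       deviation_sd=deviation_sd)
    return SimulationScenario(design, [ts], carrier_sd=carrier_sd,
                              plant_sd_control=0.0, plant_sd_drought=0.0,
                              seed=seed)


def carrier_means_one_day(n_genotypes: int, g: np.ndarray, carrier_sd: float,
                          seed: int, **kw) -> pd.DataFrame:
    """Balanced carrier-mean slice for one trait/day."""
    sc = one_day_scenario(n_genotypes, g, carrier_sd, seed, **kw)
    obs, _, _ = simulate_experiment(sc)
    return (obs.groupby(["genotype", "treatment", "carrier", "day", "trait"],
                        as_index=False)["value"].mean())
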