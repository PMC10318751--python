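import numpy as np
import pytest

from alrpipe import compositional as comp
from alrpipe.simulate import SimulationDesign, generate_counts


def make_scaled(design: SimulationDesign):
    """Design -> (count table, truth, scaled ALR table, label vector)."""
    table, truth = generate_counts(design)
    filtered = comp.add_pseudocount(comp.filter_features(table))
    ref, _ = comp.select_reference(filtered)
    scaled = comp.autoscale(comp.alr_transform(filtered, ref))
    y = np.asarray([str(x) for x in scaled.population])
    return table, truth, scaled, y


@pytest.fixture(scope="session")
def strong_bundle():
    """34+28 samples, 30/200 planted features at 2 within-SD effects."""
    design = SimulationDesign(n_pop1=34, n_pop2=28, n_features=200,
                              n_differential=30, effect_sizes=2.0, seed=3)
    return make_scaled(design)


@pytest.fixture(scope="session")
def moderate_bundle():
    """34+28 samples, 30/200 planted features at 1 within-SD effects."""
    design = SimulationDesign(n_pop1=34, n_pop2=28, n_features=200,
                              n_differential=30, effect_sizes=1.0, seed=1)
    return make_scaled(design)
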