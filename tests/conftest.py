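import numpy as np
import pytest

from minkedemog import pregnancy, synth


@pytest.fixture(scope="session")
def default_population():
    """Study-scale population (69 individuals) under default conditions."""
    return synth.gen_population(synth.CohortConfig(seed=101))


@pytest.fixture(scope="session")
def calibrated_model():
    """Pregnancy model fitted on a self-bounded reference drawn from the
    bimodal progesterone defaults (B kept moderate for test speed)."""
    cc = synth.CohortConfig(n_individuals=200, seed=202)
    pop = synth.gen_population(cc)
    conc = np.array([p.progesterone for p in pop if p.sex == "F"])
    ref = pregnancy.build_reference(conc, "self_bounded")
    return pregnancy.fit_pregnancy_model(ref, B=500, seed=303)
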