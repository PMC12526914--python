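import numpy as np
import pytest
from scipy.optimize import brentq

from cosmokin import AssemblyTimeSeries, eval_assembly_curve

#: the assay's sampling schedule, minutes
ASSAY_SCHEDULE = (0.0, 5.0, 10.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0)


def calibrate_rate(n_steps: int, c_max: float, t30: float, threshold: float = 0.30) -> float:
    """Rate constant for which the n-step curve crosses ``threshold`` at
    ``t30`` minutes (independent bisection on the gamma-CDF oracle)."""
    from scipy.special import gammainc

    return brentq(
        lambda k: c_max * gammainc(n_steps, k * t30) - threshold, 1e-8, 1e4, xtol=1e-13
    )


def exact_series(
    n_steps: int,
    k: float,
    c_max: float,
    n_dna: float = 3000,
    n_replicates: int = 3,
    timepoints=ASSAY_SCHEDULE,
) -> AssemblyTimeSeries:
    """Noise-free series sampled exactly from the generating curve."""
    ts, reps, fr = [], [], []
    for rep in range(n_replicates):
        for t in timepoints:
            ts.append(t)
            reps.append(rep)
            fr.append(eval_assembly_curve(n_steps, k, c_max, t))
    return AssemblyTimeSeries.from_fractions(ts, reps, fr, n_dna=n_dna)


@pytest.fixture
def rng():
    return np.random.default_rng(20230915)
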