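import numpy as np
import pytest

from relearnn import ModelParams, WeightSet


@pytest.fixture
def prm():
    """Default dynamics constants with a tight tolerance for math checks."""
    return ModelParams(tol=1e-10, max_steps=50_000)


def random_mixed_net(
    rng: np.random.Generator,
    n: int = 8,
    n_inp: int = 3,
    density: float = 0.4,
    all_plastic: bool = True,
) -> tuple[WeightSet, np.ndarray]:
    """A small random network containing all three connection classes.

    Weight magnitudes are kept moderate so the dynamics settle into a
    stable fixed point.  Every structural connection is marked plastic
    (the gradient oracle probes plastic entries).
    """
    W_inp = rng.uniform(0.1, 0.5, (n_inp, n)) * (rng.random((n_inp, n)) < 0.6)
    W_ex = rng.uniform(0.05, 0.3, (n, n)) * (rng.random((n, n)) < density)
    W_inh = rng.uniform(0.05, 0.3, (n, n)) * (rng.random((n, n)) < density * 0.75)
    W_mod = rng.uniform(0.05, 0.3, (n, n)) * (rng.random((n, n)) < density * 0.75)
    for W in (W_ex, W_inh, W_mod):
        np.fill_diagonal(W, 0.0)
        if not W.any():  # guarantee every connection class is present
            i = int(rng.integers(0, n - 1))
            W[i, i + 1] = rng.uniform(0.05, 0.3)
    if not W_inp.any():
        W_inp[0, 0] = rng.uniform(0.1, 0.5)
    masks = {}
    if all_plastic:
        masks = dict(
            plastic_inp=W_inp > 0,
            plastic_ex=W_ex > 0,
            plastic_inh=W_inh > 0,
            plastic_mod=W_mod > 0,
        )
    weights = WeightSet.from_dense(W_inp, W_ex, W_inh, W_mod, **masks)
    I_inp = rng.uniform(0.2, 1.0, n_inp)
    return weights, I_inp
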