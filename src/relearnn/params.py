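"""Scalar constants of the shunting unit model and the learning machinery.

The membrane potential of every model unit obeys

    dp/dt = -alpha * p + (beta - p) * I_ex * (1 + gamma * I_mod)
                       - (zeta + p) * I_inh

so ``alpha`` sets the passive decay rate, ``beta`` the maximal potential,
``-zeta`` the minimal potential and ``gamma`` the gain of multiplicative
(modulatory) input.  The firing-rate nonlinearity ``g(p)`` is linear above
zero and decays exponentially below it with curvature constant ``a``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class ModelParams:
    """Shared scalar constants of the unit dynamics.

    Parameters
    ----------
    alpha : float
        Decay rate of the membrane potential (> 0).
    beta : float
        Maximal potential; excitation drives ``p`` towards ``beta`` (> 0).
    gamma : float
        Gain of modulatory input; modulation multiplies the excitatory
        drive by ``1 + gamma * I_mod`` (> 0).
    zeta : float
        Magnitude of the minimal potential; inhibition drives ``p``
        towards ``-zeta`` (>= 0).
    a : float
        Rate-function constant; ``g(0) = a`` and the exponential branch is
        ``a * exp(p / a)`` for negative potentials (> 0).
    dt : float or None
        Explicit-Euler integration step.  ``None`` selects a per-call step
        from a conservative stability bound on the local decay rates.
    tol : float
        Convergence threshold on ``max |dp/dt|``.
    max_steps : int
        Iteration cap for a single relaxation.
    """

    alpha: float = 0.2
    beta: float = 1.0
    gamma: float = 5.0
    zeta: float = 1.0
    a: float = 0.001
    dt: float | None = None
    tol: float = 1e-6
    max_steps: int = 5000

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.zeta < 0:
            raise ValueError(f"zeta must be >= 0, got {self.zeta}")
        if self.a <= 0:
            raise ValueError(f"a must be > 0, got {self.a}")
        if self.dt is not None and self.dt <= 0:
            raise ValueError(f"dt must be > 0 or None, got {self.dt}")
        if self.tol <= 0:
            raise ValueError(f"tol must be > 0, got {self.tol}")
        if self.max_steps < 1:
            raise ValueError(f"max_steps must be >= 1, got {self.max_steps}")

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)
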