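"""Action selection, accessory-network credit assignment and plasticity.

After the network has converged (phase 1), an action is sampled from a
softmax over the motor potentials.  In phase 2 the winning output unit
injects unit activity into the *accessory network*, a parallel set of
linear units whose connections are reciprocal to the linearized regular
network at its fixed point.  The accessory activity of unit ``l``
converges to ``Delta_p_l = -(L^{-1})_{la}``, the influence of unit ``l``
on the winning unit's potential, where ``L`` is the transpose of the
Jacobian of the dynamics at the fixed point.  In phase 3 a globally
broadcast reward-prediction error ``delta`` gates a three-factor Hebbian
update

    dW_kl = eta * delta * Delta_p_l * f_l(p_l) * r_k

with a connection-class specific postsynaptic factor ``f``.  This update
equals gradient descent on the squared reward-prediction error; the
package's finite-difference oracle enforces the equivalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .dynamics import NetworkState, firing_rate, firing_rate_deriv
from .params import ModelParams
from .weights import WeightSet

logger = logging.getLogger(__name__)


@dataclass
class ActionOutcome:
    """Softmax probabilities, the chosen action, and (once known) reward and RPE."""

    probabilities: np.ndarray
    chosen: int
    reward: float | None = None
    rpe: float | None = None


@dataclass
class AccessoryState:
    """Accessory-unit activities encoding each unit's influence on the winner."""

    delta_p: np.ndarray
    winner: int
    converged: bool


@dataclass
class AdjointSystem:
    """Linearization of the full dynamics at a converged fixed point.

    ``jacobian[m, n] = dF_m/dp_n`` where ``F`` is the right-hand side of
    the dynamics.  The accessory (adjoint) matrix is its transpose.
    """

    jacobian: np.ndarray | sp.spmatrix
    n_units: int

    @property
    def is_sparse(self) -> bool:
        return sp.issparse(self.jacobian)


class SingularLinearization(RuntimeError):
    """The Jacobian at the fixed point is singular or ill-conditioned."""


def select_action_softmax(
    output_potentials: np.ndarray,
    tau: float,
    rng: np.random.Generator | None = None,
    greedy: bool = False,
) -> ActionOutcome:
    """Sample an action from ``phi_a = exp(p_a/tau) / sum_j exp(p_j/tau)``.

    With ``greedy=True`` the most active output unit is chosen
    deterministically (ties broken by lowest index); the probabilities are
    still the softmax values.
    """
    p = np.asarray(output_potentials, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("output potentials must be a non-empty vector")
    if tau <= 0:
        raise ValueError(f"temperature must be > 0, got {tau}")
    z = p / tau
    z = z - np.max(z)
    e = np.exp(z)
    phi = e / np.sum(e)
    if greedy:
        chosen = int(np.argmax(p))
    else:
        if rng is None:
            raise ValueError("a seeded rng is required for stochastic selection")
        chosen = int(rng.choice(len(p), p=phi))
    return ActionOutcome(probabilities=phi, chosen=chosen)


def reward_prediction_error(reward: float, chosen_potential: float) -> float:
    """SARSA-style prediction error for immediate reward: ``delta = rho - p_a``."""
    return float(reward) - float(chosen_potential)


def linearize_at_fixed_point(
    state: NetworkState,
    weights: WeightSet,
    prm: ModelParams,
    sparse: bool | None = None,
) -> AdjointSystem:
    """Jacobian of the full dynamics (excitatory, inhibitory and modulatory
    terms) evaluated at the converged potentials.

    For a network with only excitatory connections the transpose equals
    the classic linearization ``L`` with entries
    ``L^T_mn = -delta_nm (alpha + I_m) + (beta - p_m) W_nm g'(p_n)``.
    """
    if state.inputs_cache is None:
        raise ValueError("state must carry cached inputs (run the dynamics first)")
    p = state.p
    I_ex, I_inh, I_mod = state.inputs_cache
    gp = firing_rate_deriv(p, prm.a)
    f_ex = (prm.beta - p) * (1.0 + prm.gamma * I_mod)
    f_mod = prm.gamma * (prm.beta - p) * I_ex
    f_inh = -(prm.zeta + p)
    diag = prm.alpha + I_ex * (1.0 + prm.gamma * I_mod) + I_inh

    n = weights.n_units
    if sparse is None:
        sparse = n > 256
    if sparse:
        Dg = sp.diags(gp)
        A = (
            sp.diags(f_ex) @ weights.WT("ex")
            + sp.diags(f_mod) @ weights.WT("mod")
            + sp.diags(f_inh) @ weights.WT("inh")
        ) @ Dg - sp.diags(diag)
        return AdjointSystem(jacobian=A.tocsr(), n_units=n)
    A = (
        f_ex[:, None] * weights.dense_T("ex")
        + f_mod[:, None] * weights.dense_T("mod")
        + f_inh[:, None] * weights.dense_T("inh")
    ) * gp[None, :]
    A[np.diag_indices(n)] -= diag
    return AdjointSystem(jacobian=A, n_units=n)


def accessory_direct_solve(adjoint: AdjointSystem, winner: int) -> np.ndarray:
    """Solve the adjoint linear system ``L Delta_p + J = 0`` directly.

    ``L`` is the transpose of the Jacobian; ``J`` is zero except
    ``J_winner = 1``, so ``Delta_p = -(L^{-1})_{:, winner}``.
    """
    n = adjoint.n_units
    J = np.zeros(n)
    J[winner] = 1.0
    try:
        if adjoint.is_sparse:
            L = adjoint.jacobian.T.tocsc()
            delta_p = spla.spsolve(L, -J)
        else:
            delta_p = np.linalg.solve(adjoint.jacobian.T, -J)
    except (np.linalg.LinAlgError, RuntimeError) as exc:
        raise SingularLinearization(str(exc)) from exc
    if not np.all(np.isfinite(delta_p)):
        raise SingularLinearization("singular adjoint system (non-finite solution)")
    return delta_p


def propagate_accessory(
    adjoint: AdjointSystem,
    winner: int,
    prm: ModelParams,
    method: str = "relax",
) -> AccessoryState:
    """Phase 2: circulate the winner's injection through the accessory network.

    ``method='relax'`` integrates ``d Delta_p/dt = L Delta_p + J`` (the
    biologically interpretable route); on non-convergence it falls back to
    the direct linear solve with a logged warning.  ``method='solve'``
    goes straight to the linear solve.
    """
    n = adjoint.n_units
    if not 0 <= winner < n:
        raise ValueError(f"winner index {winner} out of range for {n} units")
    if method == "solve":
        return AccessoryState(
            delta_p=accessory_direct_solve(adjoint, winner),
            winner=winner,
            converged=True,
        )
    if method != "relax":
        raise ValueError(f"unknown accessory method {method!r}")

    A = adjoint.jacobian  # L = A^T; relaxation uses A^T @ dp
    AT = A.T.tocsr() if adjoint.is_sparse else A.T
    if adjoint.is_sparse:
        diag = A.diagonal()
    else:
        diag = np.diagonal(A)
    # local decay rates bound the stable Euler step for the linear system
    dt = 0.5 / float(np.max(np.abs(diag)))
    J = np.zeros(n)
    J[winner] = 1.0
    dp = np.zeros(n)
    converged = False
    for _ in range(prm.max_steps):
        d = AT @ dp + J
        resid = float(np.max(np.abs(d)))
        if not np.isfinite(resid):
            break
        if resid < prm.tol:
            converged = True
            break
        dp = dp + dt * d
    if not converged:
        logger.warning(
            "accessory relaxation did not converge in %d steps; "
            "falling back to direct solve",
            prm.max_steps,
        )
        dp = accessory_direct_solve(adjoint, winner)
        converged = True
    return AccessoryState(delta_p=dp, winner=winner, converged=converged)


def plasticity_factors(
    state: NetworkState, prm: ModelParams
) -> dict[str, np.ndarray]:
    """Postsynaptic factors ``f_l`` per connection class at the fixed point.

    ``f_ex = (beta - p)(1 + gamma I_mod)``;
    ``f_mod = gamma (beta - p) I_ex``;
    ``f_inh = -(zeta + p)``.
    Input connections are excitatory and share ``f_ex``.
    """
    if state.inputs_cache is None:
        raise ValueError("state must carry cached inputs")
    p = state.p
    I_ex, I_inh, I_mod = state.inputs_cache
    f_ex = (prm.beta - p) * (1.0 + prm.gamma * I_mod)
    return {
        "ex": f_ex,
        "inp": f_ex,
        "mod": prm.gamma * (prm.beta - p) * I_ex,
        "inh": -(prm.zeta + p),
    }


def plasticity_factor(
    connection_class: str, state: NetworkState, prm: ModelParams, unit: int
) -> float:
    """Scalar postsynaptic factor for one unit and connection class."""
    return float(plasticity_factors(state, prm)[connection_class][unit])


def apply_weight_update(
    weights: WeightSet,
    state: NetworkState,
    accessory: AccessoryState,
    rpe: float,
    eta: float,
    I_inp: np.ndarray,
    prm: ModelParams,
) -> WeightSet:
    """Phase 3: three-factor update of every plastic entry, in place.

    ``dW_kl = eta * delta * Delta_p_l * f_l * r_k`` with the
    class-appropriate ``f``; input weights use the input feature
    activation as the presynaptic rate.  Updated entries are clipped at
    zero, fixed entries and structural zeros are untouched.  Returns the
    (mutated) WeightSet.
    """
    if rpe == 0.0 or eta == 0.0:
        return weights
    f = plasticity_factors(state, prm)
    r = firing_rate(state.p, prm.a)
    post = accessory.delta_p
    I_inp = np.asarray(I_inp, dtype=float)
    scale = eta * rpe
    for cls_name in ("inp", "ex", "inh", "mod"):
        rows, cols, _ = weights.plastic_entries(cls_name)
        if len(rows) == 0:
            continue
        pre = I_inp if cls_name == "inp" else r
        delta = scale * pre[rows] * (post * f[cls_name])[cols]
        weights.add_to_plastic(cls_name, delta)
    return weights
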