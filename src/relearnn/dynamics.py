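"""Shunting unit dynamics and relaxation to a stable network state.

A trial begins by presenting an input vector ``I_inp`` to the network.  The
activity then recirculates through the excitatory, inhibitory and
modulatory connections under

    dp/dt = -alpha p + (beta - p) I_ex (1 + gamma I_mod) - (zeta + p) I_inh

until ``max |dp/dt|`` falls below the convergence threshold.  The converged
potentials are the network's estimate of the action values (in the motor
layer) and the operating point around which credit assignment linearizes
the network.

Integration is explicit Euler.  By default the step is set from the
local decay rates at the initial state and then adapted during the
relaxation: it is capped by the current decay-rate bound (checked
densely while activity builds up) and halved whenever the residual
stops contracting, recovering towards the cap once contraction resumes.
Growth of the weights during learning therefore cannot destabilize the
integration, while the step stays as large as the dynamics allow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams
from .weights import WeightSet

try:  # pragma: no cover - exercised implicitly everywhere
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


class DynamicsInstability(RuntimeError):
    """Raised when potentials become non-finite during integration."""

    def __init__(self, unit: int, step: int):
        self.unit = int(unit)
        self.step = int(step)
        super().__init__(
            f"non-finite potential at unit {unit} after {step} steps "
            "(integration step too large?)"
        )


@dataclass
class NetworkState:
    """Membrane potentials of all regular units at (or en route to) the fixed point."""

    p: np.ndarray
    converged: bool
    steps_used: int
    inputs_cache: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    @property
    def I_ex(self) -> np.ndarray:
        return self.inputs_cache[0]

    @property
    def I_inh(self) -> np.ndarray:
        return self.inputs_cache[1]

    @property
    def I_mod(self) -> np.ndarray:
        return self.inputs_cache[2]


def firing_rate(p: np.ndarray, a: float) -> np.ndarray:
    """Mean spike rate ``g(p)``: ``a + p`` for ``p >= 0``, ``a exp(p/a)`` below.

    Strictly positive, strictly increasing and C1 at the branch point.
    """
    p = np.asarray(p, dtype=float)
    return np.where(p >= 0, a + p, a * np.exp(np.minimum(p, 0.0) / a))


def firing_rate_deriv(p: np.ndarray, a: float) -> np.ndarray:
    """Derivative ``g'(p)``: 1 for ``p >= 0``, ``exp(p/a)`` below."""
    p = np.asarray(p, dtype=float)
    return np.where(p >= 0, 1.0, np.exp(np.minimum(p, 0.0) / a))


def compute_inputs(
    weights: WeightSet,
    p: np.ndarray,
    I_inp: np.ndarray,
    a: float,
    I_ext: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Excitatory, inhibitory and modulatory input per unit.

    ``I_ex = W_ex^T g(p) + W_inp^T I_inp``; the inhibitory and modulatory
    components are analogous without the external term.  ``I_ext`` may
    carry a precomputed ``W_inp^T I_inp``.
    """
    I_inp = np.asarray(I_inp, dtype=float)
    if I_inp.shape[0] != weights.n_inputs:
        raise ValueError(
            f"input vector has {I_inp.shape[0]} features, expected {weights.n_inputs}"
        )
    g = firing_rate(p, a)
    if I_ext is None:
        I_ext = weights.WT("inp") @ I_inp
    I_ex = weights.WT("ex") @ g + I_ext
    I_inh = weights.WT("inh") @ g
    I_mod = weights.WT("mod") @ g
    return I_ex, I_inh, I_mod


def _dpdt(p, I_ex, I_inh, I_mod, prm: ModelParams) -> np.ndarray:
    return (
        -prm.alpha * p
        + (prm.beta - p) * I_ex * (1.0 + prm.gamma * I_mod)
        - (prm.zeta + p) * I_inh
    )


def stable_dt(weights: WeightSet, I_inp: np.ndarray, prm: ModelParams) -> float:
    """Conservative Euler step from an upper bound on the local decay rates.

    The effective decay rate of unit ``l`` is at most
    ``alpha + I_ex_max (1 + gamma I_mod_max) + I_inh_max`` where the input
    bounds are attained when every presynaptic unit fires at the maximal
    rate ``g(beta) = a + beta``.  The step keeps ``dt * rate < 0.5``.
    """
    r_max = np.full(weights.n_units, prm.a + prm.beta)
    I_ext = weights.W_inp.T @ np.asarray(I_inp, dtype=float)
    ex_ub = weights.W_ex.T @ r_max + I_ext
    inh_ub = weights.W_inh.T @ r_max
    mod_ub = weights.W_mod.T @ r_max
    rate = prm.alpha + ex_ub * (1.0 + prm.gamma * mod_ub) + inh_ub
    return 0.5 / float(np.max(rate))


def dynamics_step(
    state: NetworkState,
    weights: WeightSet,
    I_inp: np.ndarray,
    prm: ModelParams,
    dt: float | None = None,
) -> NetworkState:
    """One explicit-Euler step of the dynamics; returns the updated state."""
    if dt is None:
        dt = prm.dt if prm.dt is not None else stable_dt(weights, I_inp, prm)
    I_ex, I_inh, I_mod = compute_inputs(weights, state.p, I_inp, prm.a)
    dp = _dpdt(state.p, I_ex, I_inh, I_mod, prm)
    p = state.p + dt * dp
    if not np.all(np.isfinite(p)):
        raise DynamicsInstability(int(np.argmax(~np.isfinite(p))), state.steps_used + 1)
    new_inputs = compute_inputs(weights, p, I_inp, prm.a)
    resid = float(np.max(np.abs(_dpdt(p, *new_inputs, prm))))
    return NetworkState(
        p=p,
        converged=resid < prm.tol,
        steps_used=state.steps_used + 1,
        inputs_cache=new_inputs,
    )


if _HAVE_NUMBA:

    @numba.njit(cache=True, nogil=True)
    def _relax_kernel(
        ex_data, ex_indices, ex_indptr,
        inh_data, inh_indices, inh_indptr,
        mod_data, mod_indices, mod_indptr,
        I_ext, p, I_ex, I_inh, I_mod,
        dt, tol, max_steps, alpha, beta, gamma, zeta, a,
    ):  # pragma: no cover - compiled
        """Euler relaxation on CSR-transposed weight matrices.

        Mutates ``p`` and the input arrays in place; returns
        ``(steps, status)`` with status 1 converged, 0 step cap reached,
        -1 non-finite (instability).
        """
        n = p.shape[0]
        g = np.empty(n)
        dp = np.empty(n)
        resid = 0.0
        resid_mark = np.inf
        dt_cap = dt
        for step in range(max_steps):
            if step > 0 and (step < 50 or step % 25 == 0):
                # cap the Euler step by the current local decay rates
                # (recurrent input grows during the transient; checking
                # densely at first keeps the 0.5 stability margin honest)
                rate = 0.0
                for i in range(n):
                    ri = alpha + I_ex[i] * (1.0 + gamma * I_mod[i]) + I_inh[i]
                    if ri > rate:
                        rate = ri
                cand = 0.5 / rate
                if cand < dt_cap:
                    dt_cap = cand
                if dt > dt_cap:
                    dt = dt_cap
            if step > 0 and step % 50 == 0:
                # off-diagonal coupling can push the Euler limit below the
                # local-rate bound: halve the step when the residual has
                # stopped contracting (oscillation), and let it recover
                # towards the cap once contraction resumes (the residual
                # also grows transiently while activity builds up, so a
                # halving must not be permanent)
                if resid >= resid_mark:
                    dt = 0.5 * dt
                elif dt < dt_cap:
                    dt = min(1.2 * dt, dt_cap)
                resid_mark = resid
            for i in range(n):
                pi = p[i]
                g[i] = a + pi if pi >= 0.0 else a * np.exp(pi / a)
            for i in range(n):
                s = I_ext[i]
                for jj in range(ex_indptr[i], ex_indptr[i + 1]):
                    s += ex_data[jj] * g[ex_indices[jj]]
                I_ex[i] = s
                s = 0.0
                for jj in range(inh_indptr[i], inh_indptr[i + 1]):
                    s += inh_data[jj] * g[inh_indices[jj]]
                I_inh[i] = s
                s = 0.0
                for jj in range(mod_indptr[i], mod_indptr[i + 1]):
                    s += mod_data[jj] * g[mod_indices[jj]]
                I_mod[i] = s
            resid = 0.0
            for i in range(n):
                d = (
                    -alpha * p[i]
                    + (beta - p[i]) * I_ex[i] * (1.0 + gamma * I_mod[i])
                    - (zeta + p[i]) * I_inh[i]
                )
                dp[i] = d
                ad = abs(d)
                if ad > resid:
                    resid = ad
            if not np.isfinite(resid):
                return step, -1
            if resid < tol:
                return step, 1
            for i in range(n):
                p[i] += dt * dp[i]
        return max_steps, 0


def relax_to_fixed_point(
    weights: WeightSet,
    I_inp: np.ndarray,
    prm: ModelParams,
    p0: np.ndarray | None = None,
    record_units: np.ndarray | None = None,
) -> NetworkState | tuple[NetworkState, np.ndarray]:
    """Integrate the dynamics until ``max |dp/dt| < tol`` (phase 1 of a trial).

    Returns the converged state, or a non-converged state after
    ``max_steps`` (non-convergence is a reportable outcome, not an
    exception).  If ``record_units`` is given, additionally returns the
    potential trace of those units at every step, shape
    ``(steps_used + 1, len(record_units))`` including the initial state.
    """
    n = weights.n_units
    I_inp = np.asarray(I_inp, dtype=float)
    p = np.zeros(n) if p0 is None else np.array(p0, dtype=float)
    if prm.dt is not None:
        dt = prm.dt
    else:
        # start from the local decay rates at p0; the integration loop
        # tightens the step as recurrent input builds up
        I0 = compute_inputs(weights, p, I_inp, prm.a)
        rate0 = prm.alpha + I0[0] * (1.0 + prm.gamma * I0[2]) + I0[1]
        dt = 0.5 / float(np.max(rate0))

    WexT = weights.WT("ex")
    WinhT = weights.WT("inh")
    WmodT = weights.WT("mod")
    I_ext = np.asarray(weights.WT("inp") @ I_inp, dtype=float)

    if record_units is None and _HAVE_NUMBA:
        I_ex = np.empty(n)
        I_inh = np.empty(n)
        I_mod = np.empty(n)
        steps, status = _relax_kernel(
            WexT.data, WexT.indices, WexT.indptr,
            WinhT.data, WinhT.indices, WinhT.indptr,
            WmodT.data, WmodT.indices, WmodT.indptr,
            I_ext, p, I_ex, I_inh, I_mod,
            dt, prm.tol, prm.max_steps,
            prm.alpha, prm.beta, prm.gamma, prm.zeta, prm.a,
        )
        if status == -1:
            bad = np.flatnonzero(~np.isfinite(p))
            raise DynamicsInstability(int(bad[0]) if len(bad) else 0, steps)
        return NetworkState(
            p=p, converged=status == 1, steps_used=int(steps),
            inputs_cache=(I_ex, I_inh, I_mod),
        )

    trace = [] if record_units is not None else None
    if trace is not None:
        trace.append(p[record_units].copy())

    alpha, beta, gamma, zeta, a = prm.alpha, prm.beta, prm.gamma, prm.zeta, prm.a
    converged = False
    steps = 0
    I_ex = I_inh = I_mod = None
    resid = 0.0
    resid_mark = np.inf
    dt_cap = dt
    for step in range(prm.max_steps):
        if step > 0 and (step < 50 or step % 25 == 0):
            rate = float(
                np.max(alpha + I_ex * (1.0 + gamma * I_mod) + I_inh)
            )
            dt_cap = min(dt_cap, 0.5 / rate)
            dt = min(dt, dt_cap)
        if step > 0 and step % 50 == 0:
            if resid >= resid_mark:
                dt = 0.5 * dt
            elif dt < dt_cap:
                dt = min(1.2 * dt, dt_cap)
            resid_mark = resid
        g = firing_rate(p, a)
        I_ex = WexT @ g + I_ext
        I_inh = WinhT @ g
        I_mod = WmodT @ g
        dp = (
            -alpha * p
            + (beta - p) * I_ex * (1.0 + gamma * I_mod)
            - (zeta + p) * I_inh
        )
        resid = float(np.max(np.abs(dp)))
        if not np.isfinite(resid):
            bad = np.flatnonzero(~np.isfinite(dp))
            raise DynamicsInstability(int(bad[0]) if len(bad) else 0, step)
        if resid < prm.tol:
            converged = True
            steps = step
            break
        p = p + dt * dp
        steps = step + 1
        if trace is not None:
            trace.append(p[record_units].copy())
    else:
        # recompute cache for the final p
        I_ex, I_inh, I_mod = compute_inputs(weights, p, I_inp, a, I_ext=I_ext)

    state = NetworkState(
        p=p, converged=converged, steps_used=steps, inputs_cache=(I_ex, I_inh, I_mod)
    )
    if trace is not None:
        return state, np.asarray(trace)
    return state
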