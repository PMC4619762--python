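"""Independent brute-force references for the learning rule and the tasks.

The central correctness theorem of the learning rule is that the
three-factor update direction equals the gradient of the winning output
unit's fixed-point potential with respect to every plastic weight.  This
module estimates that gradient by central finite differences, re-solving
the fixed point per perturbation, and compares it entry-by-entry with the
analytic direction computed through the accessory network.  It also hosts
a 4-connectivity flood fill used to validate curve stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
import scipy.optimize

from . import learning
from .dynamics import (
    compute_inputs,
    firing_rate,
    relax_to_fixed_point,
)
from .params import ModelParams
from .weights import CLASSES, WeightSet


def exact_fixed_point(
    weights: WeightSet, I_inp: np.ndarray, prm: ModelParams
) -> np.ndarray:
    """Fixed point polished to near machine precision.

    Relaxes the dynamics, then applies a Newton solve of ``F(p) = 0``
    with the analytic Jacobian.  Intended for small test networks where
    finite-difference accuracy demands a fixed point far tighter than the
    relaxation tolerance.
    """
    state = relax_to_fixed_point(weights, I_inp, prm)
    I_inp = np.asarray(I_inp, dtype=float)

    def F(p):
        I_ex, I_inh, I_mod = compute_inputs(weights, p, I_inp, prm.a)
        return (
            -prm.alpha * p
            + (prm.beta - p) * I_ex * (1.0 + prm.gamma * I_mod)
            - (prm.zeta + p) * I_inh
        )

    def jac(p):
        I_ex, I_inh, I_mod = compute_inputs(weights, p, I_inp, prm.a)
        st = learning.NetworkState(
            p=p, converged=True, steps_used=0, inputs_cache=(I_ex, I_inh, I_mod)
        )
        return learning.linearize_at_fixed_point(st, weights, prm, sparse=False).jacobian

    sol = scipy.optimize.root(F, state.p, jac=jac, method="hybr", tol=1e-13)
    if not sol.success and float(np.max(np.abs(F(sol.x)))) > 1e-10:
        raise RuntimeError(f"Newton polish of the fixed point failed: {sol.message}")
    return sol.x


def finite_difference_gradient(
    weights: WeightSet,
    I_inp: np.ndarray,
    prm: ModelParams,
    action: int,
    h: float = 1e-5,
    classes: tuple[str, ...] = CLASSES,
    plastic_only: bool = True,
) -> dict[str, np.ndarray]:
    """Central-difference estimates of ``d p_action / d W_kl`` per weight.

    Returns, per connection class, a dense array of the same shape as the
    weight matrix with the estimate at every probed entry (zeros
    elsewhere).  Each perturbation re-solves the fixed point with the
    Newton-polished solver.  Perturbations that would drive a weight
    negative shift to a one-sided second-order stencil is *not* applied;
    instead the base weights here are assumed to be >= h (the tiny test
    networks used with this oracle satisfy that).
    """
    out: dict[str, np.ndarray] = {}
    for cls_name in classes:
        mat = weights.dense(cls_name)
        grad = np.zeros_like(mat)
        if plastic_only:
            rows, cols = np.nonzero(weights.mask(cls_name))
        else:
            rows, cols = [a.ravel() for a in np.indices(mat.shape)]
        for k, l in zip(rows, cols):
            grad[k, l] = _fd_entry(weights, I_inp, prm, action, cls_name, k, l, h)
        out[cls_name] = grad
    return out


def _fd_entry(weights, I_inp, prm, action, cls_name, k, l, h):
    vals = []
    for sign in (+1.0, -1.0):
        w = weights.copy()
        dense = w.dense(cls_name)
        dense[k, l] += sign * h
        perturbed = _replace_matrix(w, cls_name, dense)
        p = exact_fixed_point(perturbed, I_inp, prm)
        vals.append(p[action])
    return (vals[0] - vals[1]) / (2.0 * h)


def _replace_matrix(w: WeightSet, cls_name: str, dense: np.ndarray) -> WeightSet:
    mats = {c: w.dense(c) for c in CLASSES}
    mats[cls_name] = dense
    return WeightSet.from_dense(
        mats["inp"],
        mats["ex"],
        mats["inh"],
        mats["mod"],
        plastic_inp=w.plastic_inp,
        plastic_ex=w.plastic_ex,
        plastic_inh=w.plastic_inh,
        plastic_mod=w.plastic_mod,
    )


def analytic_gradient(
    weights: WeightSet,
    I_inp: np.ndarray,
    prm: ModelParams,
    action: int,
    classes: tuple[str, ...] = CLASSES,
    plastic_only: bool = True,
) -> dict[str, np.ndarray]:
    """Gradient of ``p_action`` via the accessory network (the learning rule's
    update direction with ``eta * delta`` divided out)."""
    I_inp = np.asarray(I_inp, dtype=float)
    p = exact_fixed_point(weights, I_inp, prm)
    I_cache = compute_inputs(weights, p, I_inp, prm.a)
    state = learning.NetworkState(
        p=p, converged=True, steps_used=0, inputs_cache=I_cache
    )
    adj = learning.linearize_at_fixed_point(state, weights, prm, sparse=False)
    delta_p = learning.accessory_direct_solve(adj, action)
    f = learning.plasticity_factors(state, prm)
    r = firing_rate(p, prm.a)
    out: dict[str, np.ndarray] = {}
    for cls_name in classes:
        mat_shape = weights.matrix(cls_name).shape
        grad = np.zeros(mat_shape)
        if plastic_only:
            rows, cols = np.nonzero(weights.mask(cls_name))
        else:
            rows, cols = [a.ravel() for a in np.indices(mat_shape)]
        pre = I_inp if cls_name == "inp" else r
        grad[rows, cols] = pre[rows] * (delta_p * f[cls_name])[cols]
        out[cls_name] = grad
    return out


@dataclass
class GradientReport:
    """Per-weight comparison of the analytic update direction with finite
    differences, plus summary errors."""

    analytic: dict[str, np.ndarray]
    numeric: dict[str, np.ndarray]
    rel_errors: dict[str, np.ndarray]
    max_rel_error: float
    median_rel_error: float


def gradient_report(
    weights: WeightSet,
    I_inp: np.ndarray,
    prm: ModelParams,
    action: int,
    h: float = 1e-5,
    classes: tuple[str, ...] = CLASSES,
) -> GradientReport:
    """Compare analytic and finite-difference gradients over all plastic weights.

    The relative error of an entry is ``|a - n| / max(|a|, |n|, floor)``
    with a floor of ``1e-6`` times the largest gradient magnitude in the
    network.  The floor sits above the noise floor of the central
    differences themselves (machine epsilon over ``2h``, about 1e-11 on
    potentials of order one): connections through deeply suppressed units
    have true gradients many orders below that noise, and the reference
    can only certify them as negligible, not resolve them.
    """
    ana = analytic_gradient(weights, I_inp, prm, action, classes=classes)
    num = finite_difference_gradient(weights, I_inp, prm, action, h=h, classes=classes)
    gmax = max(
        (float(np.max(np.abs(num[c]))) for c in classes if num[c].size), default=0.0
    )
    floor = max(1e-6 * gmax, 1e-10)
    rel: dict[str, np.ndarray] = {}
    errs = []
    for c in classes:
        rows, cols = np.nonzero(weights.mask(c))
        a = ana[c][rows, cols]
        n = num[c][rows, cols]
        e = np.abs(a - n) / np.maximum(np.maximum(np.abs(a), np.abs(n)), floor)
        full = np.zeros_like(ana[c])
        full[rows, cols] = e
        rel[c] = full
        errs.append(e)
    allerr = np.concatenate(errs) if errs else np.array([0.0])
    return GradientReport(
        analytic=ana,
        numeric=num,
        rel_errors=rel,
        max_rel_error=float(np.max(allerr)) if allerr.size else 0.0,
        median_rel_error=float(np.median(allerr)) if allerr.size else 0.0,
    )


_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


def flood_fill(mask: np.ndarray) -> np.ndarray:
    """4-connectivity component labels of a binary grid.

    Pixels that touch only diagonally belong to different components.
    Labels are positive integers in deterministic raster order; background
    is 0.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("flood_fill expects a 2-D grid")
    labels, _ = ndi.label(mask, structure=_CROSS)
    return labels


def n_components(mask: np.ndarray) -> int:
    """Number of 4-connected components in a binary grid."""
    return int(flood_fill(mask).max())
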