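"""Neurophysiology-style analyses of network activity and connectivity.

These utilities mimic the recordings done in awake monkeys performing the
same tasks: membrane-potential time courses of selected "recorded" units
during the relaxation, the delayed target/distractor response modulation
and its latency as a function of distance from the cue, and summaries of
the learned connectivity (axis-aligned strengthening of lateral weights,
feedforward/feedback reciprocity).  Model time is reported in dynamics
steps; no attempt is made to map steps onto cortical milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .architectures import ArchitectureSpec, ConnectionGroup
from .dynamics import relax_to_fixed_point
from .params import ModelParams
from .tasks import ORIENT_STEPS, CurveStimulus, encode_stimulus
from .weights import WeightSet


@dataclass
class ActivityTrace:
    """Per-step potentials of designated units during one relaxation."""

    potentials: np.ndarray  # (steps+1, n_probes)
    labels: list[str]
    units: np.ndarray
    converged: bool

    @property
    def steps(self) -> int:
        return self.potentials.shape[0] - 1

    def series(self, label: str) -> np.ndarray:
        return self.potentials[:, self.labels.index(label)]


def record_timecourse(
    weights: WeightSet,
    spec: ArchitectureSpec,
    stimulus,
    probe_units: np.ndarray,
    prm: ModelParams,
    labels: list[str] | None = None,
) -> ActivityTrace:
    """Record the potentials of probe units at every dynamics step."""
    probe_units = np.asarray(probe_units, dtype=np.int64)
    if np.any(probe_units < 0) or np.any(probe_units >= spec.n_units):
        raise ValueError("probe unit index out of range")
    I_inp = encode_stimulus(stimulus, spec)
    state, trace = relax_to_fixed_point(
        weights, I_inp, prm, record_units=probe_units
    )
    if labels is None:
        labels = [str(u) for u in probe_units]
    return ActivityTrace(
        potentials=trace, labels=list(labels), units=probe_units,
        converged=state.converged,
    )


def normalized_modulation(
    traces_target: np.ndarray, traces_distractor: np.ndarray
) -> np.ndarray:
    """Target-minus-distractor activity difference, normalized per position.

    ``traces_*`` have shape (steps, n_positions) and must be aligned on
    steps.  Each position's difference series is divided by its own final
    value, so every normalized series ends at 1.  A zero final difference
    leaves NaN for that position (reported, not raised).
    """
    t = np.asarray(traces_target, dtype=float)
    d = np.asarray(traces_distractor, dtype=float)
    if t.shape != d.shape:
        raise ValueError("target and distractor traces must be aligned")
    diff = t - d
    final = diff[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(final != 0, diff / final, np.nan)
    return out


def modulation_latency(
    normalized: np.ndarray, threshold: float = 0.5
) -> np.ndarray:
    """First step at which the normalized modulation exceeds the threshold.

    Returns one latency (in dynamics steps) per position; positions that
    never cross report NaN.  A series already above threshold at step 0
    has latency 0.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    norm = np.atleast_2d(np.asarray(normalized, dtype=float))
    if normalized.ndim == 1:
        norm = norm.T
    n_steps, n_pos = norm.shape
    lat = np.full(n_pos, np.nan)
    for j in range(n_pos):
        above = np.flatnonzero(norm[:, j] > threshold)
        if len(above):
            lat[j] = above[0]
    return lat


# ---------------------------------------------------------------------------
# probe helpers


def contour_center_unit(spec: ArchitectureSpec, side: int, orientation: int) -> int:
    """Linking-excitatory unit with the center bar of one aperture in its
    receptive field, tuned to the given orientation."""
    grid = spec.meta["grid"]
    n_orient = spec.meta["n_orient"]
    ctr = grid // 2
    feat = ((side * n_orient + orientation) * grid + ctr) * grid + ctr
    return spec.offset("linking_ex") + feat


def tracing_luminance_unit(spec: ArchitectureSpec, pixel: tuple[int, int]) -> int:
    """Linking-excitatory unit tuned to luminance at a pixel."""
    grid = spec.meta["grid"]
    lum = 2
    return spec.offset("linking_ex") + (lum * grid + pixel[0]) * grid + pixel[1]


def curve_modulation_traces(
    weights: WeightSet,
    spec: ArchitectureSpec,
    stimulus: CurveStimulus,
    prm: ModelParams,
    layer: str = "linking_ex",
) -> tuple[np.ndarray, np.ndarray]:
    """Aligned activity traces along the target and distractor curves.

    Position ``i`` pairs the i-th pixel of the target path (ordered from
    the cue) with the i-th pixel of the distractor path (ordered from its
    marker).  For the motor layer the probes are the motor units of the
    same pixels.  Returns ``(target_traces, distractor_traces)`` of shape
    (steps+1, path_length).
    """
    target = list(stimulus.target_path)
    if stimulus.cue_pixel is not None and target[0] != stimulus.cue_pixel:
        target = target[::-1]
    distractor = list(stimulus.distractor_path)
    if stimulus.distractor_marker_pixel is not None and (
        distractor[0] != stimulus.distractor_marker_pixel
    ):
        distractor = distractor[::-1]
    grid = spec.meta["grid"]
    if layer == "linking_ex":
        t_units = [tracing_luminance_unit(spec, px) for px in target]
        d_units = [tracing_luminance_unit(spec, px) for px in distractor]
    elif layer == "motor":
        off = spec.offset("motor")
        t_units = [off + r * grid + c for r, c in target]
        d_units = [off + r * grid + c for r, c in distractor]
    else:
        raise ValueError(f"unsupported layer {layer!r}")
    trace = record_timecourse(
        weights, spec, stimulus, np.array(t_units + d_units), prm
    )
    k = len(target)
    return trace.potentials[:, :k], trace.potentials[:, k:]


def contour_length_tuning(
    weights: WeightSet,
    spec: ArchitectureSpec,
    prm: ModelParams,
    lengths: tuple[int, ...] = (1, 3, 5, 7, 9),
    n_stimuli: int = 60,
    seed: int = 0,
    session_orientation: int = 0,
) -> dict[int, float]:
    """Mean converged potential of the center-bar linking unit per contour
    length (the length-tuning curve measured in the recordings).

    For every stimulus the probed unit is the linking excitatory unit of
    the target aperture tuned to the orientation of the bar actually
    present at the aperture center.
    """
    from .tasks import encode_contour, generate_contour_stimulus

    grid = spec.meta["grid"]
    ctr = grid // 2
    out: dict[int, float] = {}
    ss = np.random.SeedSequence(entropy=seed)
    for length in lengths:
        vals = []
        for i, child in enumerate(ss.spawn(n_stimuli)):
            rng = np.random.default_rng(child)
            stim = generate_contour_stimulus(
                length, session_orientation, 1.0, rng, grid=grid
            )
            orient = int(stim.bars[stim.target_side, ctr, ctr])
            unit = contour_center_unit(spec, stim.target_side, orient)
            state = relax_to_fixed_point(weights, encode_contour(stim, spec), prm)
            vals.append(state.p[unit])
        out[length] = float(np.mean(vals))
        ss = np.random.SeedSequence(entropy=seed + length + 1)
    return out


# ---------------------------------------------------------------------------
# connectivity summaries


def connectivity_summary(
    weights: WeightSet, spec: ArchitectureSpec, group: str
) -> pd.DataFrame:
    """Edge table of one connection group with decoded grid coordinates."""
    if group not in spec.groups:
        raise KeyError(f"unknown connection group {group!r}")
    g: ConnectionGroup = spec.groups[group]
    mat = weights.matrix(g.cls)
    w = np.asarray(mat[g.rows, g.cols]).ravel()
    return pd.DataFrame(
        {
            "source": g.rows,
            "target": g.cols,
            "class": g.cls,
            "group": group,
            "weight": w,
        }
    )


def lateral_axis_asymmetry(
    weights: WeightSet, spec: ArchitectureSpec, orientation: int, side: int = 0
) -> tuple[float, float]:
    """Mean lateral modulatory weight along vs. orthogonal to an
    orientation's contour axis, within one aperture's orientation map.

    Only nearest-neighbor links exist, so the comparison is meaningful
    for axes aligned with the grid (horizontal / vertical); for diagonal
    orientations there are no along-axis links and NaN is returned.
    """
    grid = spec.meta["grid"]
    n_orient = spec.meta["n_orient"]
    dr, dc = ORIENT_STEPS[orientation]
    g = spec.groups["lateral"]
    ex0 = spec.offset("linking_ex")
    mat = weights.matrix(g.cls)
    w = np.asarray(mat[g.rows, g.cols]).ravel()

    per_map = grid * grid
    map_idx = side * n_orient + orientation
    lo, hi = map_idx * per_map, (map_idx + 1) * per_map
    along, ortho = [], []
    for src, tgt, wij in zip(g.rows, g.cols - ex0, w):
        if not (lo <= src < hi and lo <= tgt < hi):
            continue
        r1, c1 = divmod(src - lo, grid)
        r2, c2 = divmod(tgt - lo, grid)
        step = (r2 - r1, c2 - c1)
        if step in ((dr, dc), (-dr, -dc)):
            along.append(wij)
        else:
            ortho.append(wij)
    return (
        float(np.mean(along)) if along else float("nan"),
        float(np.mean(ortho)) if ortho else float("nan"),
    )


def feedforward_feedback_correlation(
    weights: WeightSet, spec: ArchitectureSpec
) -> float:
    """Pearson correlation between linking->association feedforward weights
    and the reciprocal association->linking feedback weights."""
    ff = spec.groups["ff_assoc"]
    fb = spec.groups["feedback"]
    Wff = weights.matrix(ff.cls)
    Wfb = weights.matrix(fb.cls)
    w_ff = np.asarray(Wff[ff.rows, ff.cols]).ravel()
    # reciprocal feedback entry of (linking k -> assoc l) is (l -> k)
    w_fb = np.asarray(Wfb[ff.cols, ff.rows]).ravel()
    if np.std(w_ff) == 0 or np.std(w_fb) == 0:
        return float("nan")
    return float(np.corrcoef(w_ff, w_fb)[0, 1])
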