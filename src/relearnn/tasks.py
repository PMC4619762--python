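"""Stimulus generation, reward functions and shaping curricula.

Contour linking: two 9 x 9 apertures of oriented bars; one aperture
contains 1/3/5/7/9 collinear bars of the session orientation centered on
the aperture, all other bars have uniformly random orientations.  The
correct action is a saccade to the aperture holding the contour.

Curve tracing: a 5 x 5 pixel grid with red, green and luminance channels
containing two equally long 4-connected curves that do not touch
edge-wise (diagonal contact allowed), a red cue at one endpoint of the
target curve, a green marker at its free endpoint and another green
marker on one endpoint of the distractor.  The correct action is a
saccade to the green marker on the cued curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .architectures import ArchitectureSpec
from .oracles import flood_fill

#: bar orientation -> unit step along the contour axis (row, col).
#: 0 horizontal, 1 diagonal (down-right), 2 vertical, 3 diagonal (down-left).
ORIENT_STEPS = {0: (0, 1), 1: (1, 1), 2: (1, 0), 3: (1, -1)}

RED, GREEN, LUM = 0, 1, 2


class StimulusError(RuntimeError):
    """Raised when a stimulus cannot be generated under its constraints."""


# ---------------------------------------------------------------------------
# contour linking


@dataclass
class ContourStimulus:
    """A two-aperture display of oriented bars.

    ``bars[p, r, c]`` is the orientation index of the bar at cell
    ``(r, c)`` of aperture ``p``; ``contrast`` the per-element activation
    in (0, 1].  ``target_side`` (0 = left, 1 = right) is the correct
    action.
    """

    bars: np.ndarray
    contrast: np.ndarray
    target_side: int
    contour_length: int
    session_orientation: int

    @property
    def correct_action(self) -> int:
        return self.target_side


def contour_cells(length: int, orientation: int, grid: int = 9) -> list[tuple[int, int]]:
    """Cells of a centered collinear contour of the given length."""
    dr, dc = ORIENT_STEPS[orientation]
    ctr = grid // 2
    half = length // 2
    cells = []
    for k in range(-half, half + 1):
        r, c = ctr + k * dr, ctr + k * dc
        if not (0 <= r < grid and 0 <= c < grid):
            raise StimulusError(
                f"contour of length {length}, orientation {orientation} "
                f"does not fit a {grid}x{grid} aperture"
            )
        cells.append((r, c))
    return cells


def generate_contour_stimulus(
    length: int,
    session_orientation: int,
    contrast_bg: float,
    rng: np.random.Generator,
    grid: int = 9,
    n_orient: int = 4,
) -> ContourStimulus:
    """Draw one contour-linking display.

    Every cell of both apertures holds one bar.  The target aperture
    contains ``length`` collinear bars of the session orientation on a
    line through the aperture center at full contrast; all other bars
    have uniformly random orientations at ``contrast_bg``.  The target
    side is uniformly random.
    """
    if length % 2 == 0 or length < 1:
        raise ValueError(f"contour length must be odd and >= 1, got {length}")
    if not 0.0 < contrast_bg <= 1.0:
        raise ValueError(f"background contrast must be in (0, 1], got {contrast_bg}")
    if not 0 <= session_orientation < n_orient:
        raise ValueError(f"invalid session orientation {session_orientation}")
    bars = rng.integers(0, n_orient, size=(2, grid, grid))
    contrast = np.full((2, grid, grid), contrast_bg, dtype=float)
    side = int(rng.integers(0, 2))
    for r, c in contour_cells(length, session_orientation, grid):
        # a one-element "contour" has no orientation of its own: the bar
        # stays random and the display is indistinguishable from the
        # distractor, so chance behavior is expected at length 1
        if length > 1:
            bars[side, r, c] = session_orientation
        contrast[side, r, c] = 1.0
    return ContourStimulus(
        bars=bars,
        contrast=contrast,
        target_side=side,
        contour_length=length,
        session_orientation=session_orientation,
    )


def encode_contour(stim: ContourStimulus, spec: ArchitectureSpec) -> np.ndarray:
    """Input activations: unit (pattern, orientation, r, c) is driven at the
    element's contrast iff the bar at (pattern, r, c) has that orientation."""
    grid = spec.meta["grid"]
    n_orient = spec.meta["n_orient"]
    n_patterns = spec.meta["n_patterns"]
    I = np.zeros((n_patterns, n_orient, grid, grid))
    for p in range(n_patterns):
        for o in range(n_orient):
            I[p, o] = np.where(stim.bars[p] == o, stim.contrast[p], 0.0)
    return I.ravel()


# ---------------------------------------------------------------------------
# curve tracing


@dataclass
class CurveStimulus:
    """A curve-tracing display on a pixel grid with three feature channels."""

    channels: np.ndarray  # (3, grid, grid): red, green, luminance
    target_path: list[tuple[int, int]]
    distractor_path: list[tuple[int, int]]
    cue_pixel: tuple[int, int] | None
    target_marker_pixel: tuple[int, int]
    distractor_marker_pixel: tuple[int, int] | None
    grid: int = 5

    @property
    def correct_action(self) -> int:
        r, c = self.target_marker_pixel
        return r * self.grid + c


def _random_path(length: int, grid: int, rng: np.random.Generator):
    """One attempt at a self-avoiding 4-connected path; None if stuck."""
    r = int(rng.integers(0, grid))
    c = int(rng.integers(0, grid))
    path = [(r, c)]
    occupied = {(r, c)}
    for _ in range(length - 1):
        steps = [(dr, dc) for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1))]
        rng.shuffle(steps)
        for dr, dc in steps:
            nr, nc = path[-1][0] + dr, path[-1][1] + dc
            if 0 <= nr < grid and 0 <= nc < grid and (nr, nc) not in occupied:
                path.append((nr, nc))
                occupied.add((nr, nc))
                break
        else:
            return None
    return path


def _paths_touch(a, b) -> bool:
    """True if any pixel of a is 4-adjacent to (or equal to) a pixel of b."""
    bs = set(b)
    for r, c in a:
        if (r, c) in bs:
            return True
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            if (r + dr, c + dc) in bs:
                return True
    return False


def generate_curve_stimulus(
    length: int,
    rng: np.random.Generator,
    grid: int = 5,
    max_tries: int = 10000,
) -> CurveStimulus:
    """Rejection-sample a curve-tracing display with two equally long curves.

    The curves are simple 4-connected paths that are mutually *not*
    4-connected (they may touch diagonally).  The red cue sits at one
    endpoint of the target curve, a green marker at its other endpoint
    and a second green marker at a random endpoint of the distractor.
    The luminance channel is on for every curve pixel; the cue and
    markers are part of their curves.
    """
    if length < 2:
        raise ValueError(f"curve length must be >= 2, got {length}")
    for _ in range(max_tries):
        target = _random_path(length, grid, rng)
        if target is None:
            continue
        distractor = _random_path(length, grid, rng)
        if distractor is None or _paths_touch(target, distractor):
            continue
        if int(rng.integers(0, 2)):
            cue, marker = target[0], target[-1]
        else:
            cue, marker = target[-1], target[0]
        d_marker = distractor[0] if int(rng.integers(0, 2)) else distractor[-1]
        channels = np.zeros((3, grid, grid))
        for r, c in target + distractor:
            channels[LUM, r, c] = 1.0
        channels[RED, cue[0], cue[1]] = 1.0
        channels[GREEN, marker[0], marker[1]] = 1.0
        channels[GREEN, d_marker[0], d_marker[1]] = 1.0
        stim = CurveStimulus(
            channels=channels,
            target_path=target,
            distractor_path=distractor,
            cue_pixel=cue,
            target_marker_pixel=marker,
            distractor_marker_pixel=d_marker,
            grid=grid,
        )
        _assert_connectedness(stim)
        return stim
    raise StimulusError(
        f"could not place two disconnected curves of length {length} on a "
        f"{grid}x{grid} grid within {max_tries} attempts"
    )


def _assert_connectedness(stim: CurveStimulus) -> None:
    labels = flood_fill(stim.channels[LUM] > 0)
    if labels.max() != 2:
        raise StimulusError("luminance channel does not split into two components")
    cue_lab = labels[stim.cue_pixel]
    if labels[stim.target_marker_pixel] != cue_lab:
        raise StimulusError("target marker not connected to the cue")
    if labels[stim.distractor_marker_pixel] == cue_lab:
        raise StimulusError("distractor marker connected to the cue")


def generate_marker_stimulus(
    rng: np.random.Generator, grid: int = 5
) -> CurveStimulus:
    """Shaping phase 0: a single square with a green saccade target."""
    r = int(rng.integers(0, grid))
    c = int(rng.integers(0, grid))
    channels = np.zeros((3, grid, grid))
    channels[GREEN, r, c] = 1.0
    channels[LUM, r, c] = 1.0
    return CurveStimulus(
        channels=channels,
        target_path=[(r, c)],
        distractor_path=[],
        cue_pixel=None,
        target_marker_pixel=(r, c),
        distractor_marker_pixel=None,
        grid=grid,
    )


def encode_curve(stim: CurveStimulus, spec: ArchitectureSpec) -> np.ndarray:
    """Input activations: the flattened (channel, row, col) channel grids."""
    return stim.channels.ravel().astype(float)


def encode_stimulus(stim, spec: ArchitectureSpec) -> np.ndarray:
    if isinstance(stim, ContourStimulus):
        return encode_contour(stim, spec)
    if isinstance(stim, CurveStimulus):
        return encode_curve(stim, spec)
    raise TypeError(f"unknown stimulus type {type(stim).__name__}")


# ---------------------------------------------------------------------------
# reward


def reward_for(stimulus, chosen_action: int, reward_magnitude: float) -> float:
    """Reward of the trial: the configured magnitude for the correct action,
    nothing otherwise."""
    return float(reward_magnitude) if chosen_action == stimulus.correct_action else 0.0


# ---------------------------------------------------------------------------
# curricula


@dataclass
class Phase:
    """One curriculum phase: stimulus parameters plus an exit rule.

    Either a fixed trial count (``n_trials``) or a performance rule
    (greedy accuracy >= ``advance_threshold`` over the last
    ``advance_window`` trials).  A phase with neither runs until the
    global criterion or trial cap (the full task).
    """

    name: str
    stimulus_params: dict = field(default_factory=dict)
    n_trials: int | None = None
    advance_window: int | None = None
    advance_threshold: float | None = None


@dataclass
class Curriculum:
    phases: list[Phase]

    def __post_init__(self):
        if not self.phases:
            raise ValueError("a curriculum needs at least one phase")


def contour_curriculum(
    lengths: tuple[int, ...] = (1, 3, 5, 7, 9),
    session_orientation: int = 0,
    pretraining: bool = True,
    pretrain_trials: int = 500,
    ramp_step: float = 0.10,
    ramp_trials: int = 100,
    contrast_start: float = 0.5,
) -> Curriculum:
    """Contrast-ramp shaping for contour linking.

    500 trials with background elements at 50 % contrast, then 10-point
    contrast increments of 100 trials each up to 100 %, then the full
    task with lengths interleaved uniformly.  With ``pretraining=False``
    the full task starts at trial 1.
    """
    phases = []
    if pretraining:
        phases.append(
            Phase(
                "pretrain",
                {"lengths": lengths, "contrast_bg": contrast_start,
                 "session_orientation": session_orientation},
                n_trials=pretrain_trials,
            )
        )
        contrast = contrast_start + ramp_step
        while contrast < 1.0 + 1e-9:
            c = min(round(contrast, 10), 1.0)
            phases.append(
                Phase(
                    f"ramp-{int(round(c * 100))}",
                    {"lengths": lengths, "contrast_bg": c,
                     "session_orientation": session_orientation},
                    n_trials=ramp_trials,
                )
            )
            contrast += ramp_step
    phases.append(
        Phase(
            "full",
            {"lengths": lengths, "contrast_bg": 1.0,
             "session_orientation": session_orientation},
        )
    )
    return Curriculum(phases)


def tracing_curriculum(
    max_length: int = 5,
    shaping: bool = True,
    advance_window: int = 200,
    advance_threshold: float = 0.9,
) -> Curriculum:
    """Shaping for curve tracing: a single green square, then two-curve
    displays of growing length, then the full task with lengths 2 to
    ``max_length`` interleaved.  Phases advance once greedy accuracy over
    the last ``advance_window`` trials reaches ``advance_threshold``."""
    if max_length < 2:
        raise ValueError("max_length must be >= 2")
    phases = []
    if shaping:
        phases.append(
            Phase(
                "marker",
                {"marker_only": True},
                advance_window=advance_window,
                advance_threshold=advance_threshold,
            )
        )
        for length in range(2, max_length + 1):
            phases.append(
                Phase(
                    f"len{length}",
                    {"lengths": (length,)},
                    advance_window=advance_window,
                    advance_threshold=advance_threshold,
                )
            )
    phases.append(Phase("full", {"lengths": tuple(range(2, max_length + 1))}))
    return Curriculum(phases)


def draw_stimulus(
    task: str, phase_params: dict, rng: np.random.Generator, grid: int, **kw
):
    """Draw one stimulus for a curriculum phase of a task."""
    if task == "contour":
        lengths = phase_params["lengths"]
        length = int(lengths[rng.integers(0, len(lengths))])
        return generate_contour_stimulus(
            length,
            phase_params.get("session_orientation", 0),
            phase_params.get("contrast_bg", 1.0),
            rng,
            grid=grid,
            **kw,
        )
    if task == "tracing":
        if phase_params.get("marker_only"):
            return generate_marker_stimulus(rng, grid=grid)
        lengths = phase_params["lengths"]
        length = int(lengths[rng.integers(0, len(lengths))])
        return generate_curve_stimulus(length, rng, grid=grid)
    raise ValueError(f"unknown task {task!r}")
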