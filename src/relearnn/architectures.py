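"""Layered recurrent networks for the contour-linking and curve-tracing tasks.

Both tasks share one architecture family: an input layer of feature maps
drives a "linking layer" of excitatory units (with one-to-one disynaptic
inhibition through paired inhibitory units), excitatory units modulate
their four nearest neighbors within the same feature map and the other
features at their own location, project to an association layer, receive
modulatory feedback from it, and the association layer excites the motor
layer whose unit potentials encode action values.

Connection groups are registered with explicit coordinate lists so that
ablations, connectivity analyses and adjacency audits all address exactly
the same entries of the weight matrices.  Grid coordinates are 0-based
row-major throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .weights import WeightSet

ROLES = ("input", "linking_ex", "linking_inh", "association", "motor")

#: Default fixed-weight constants and plastic-init ranges, per task.
#: "const" entries are fixed connections; pairs are uniform init ranges.
CONTOUR_INIT = {
    "inp_ex": ("const", 1.0),
    "inp_inh": ("const", 1.0),
    "inh_ex": ("uniform", 0.2, 0.6),
    "lateral": ("uniform", 0.0, 0.05),
    "cross": ("uniform", 0.0, 0.05),
    "ff_assoc": ("uniform", 0.0, 0.01),
    "feedback": ("uniform", 0.0, 0.01),
    "assoc_motor": ("uniform", 0.0, 0.25),
}

TRACING_INIT = {
    "inp_ex": ("const", 1.0),
    "inp_inh": ("const", 1.0),
    "inh_ex": ("uniform", 0.5, 1.5),
    "lateral": ("uniform", 0.0, 0.05),
    "cross": ("uniform", 0.0, 0.05),
    "ff_assoc": ("uniform", 0.0, 0.05),
    "feedback": ("uniform", 0.0, 0.02),
    "assoc_motor": ("uniform", 0.0, 0.1),
}


@dataclass(frozen=True)
class LayerSpec:
    """One layer: a spatial grid of units (or a flat population)."""

    name: str
    size: int
    role: str
    shape: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.size <= 0:
            raise ValueError(f"layer {self.name}: size must be > 0")
        if self.role not in ROLES:
            raise ValueError(f"layer {self.name}: unknown role {self.role!r}")


@dataclass
class ConnectionGroup:
    """A named block of one weight matrix.

    ``rows`` index the presynaptic space (input features for class
    ``'inp'``, units otherwise) and ``cols`` the postsynaptic units.
    """

    name: str
    source: str
    target: str
    cls: str
    rows: np.ndarray
    cols: np.ndarray
    plastic: bool
    init: tuple

    @property
    def n_connections(self) -> int:
        return len(self.rows)


@dataclass
class ArchitectureSpec:
    """Ordered layers plus the registry of connection groups."""

    task: str
    layers: list[LayerSpec]
    groups: dict[str, ConnectionGroup]
    meta: dict = field(default_factory=dict)

    @property
    def n_inputs(self) -> int:
        return sum(l.size for l in self.layers if l.role == "input")

    @property
    def n_units(self) -> int:
        return sum(l.size for l in self.layers if l.role != "input")

    def offset(self, layer_name: str) -> int:
        """Start index of a non-input layer in unit space."""
        off = 0
        for l in self.layers:
            if l.role == "input":
                continue
            if l.name == layer_name:
                return off
            off += l.size
        raise KeyError(layer_name)

    def layer(self, layer_name: str) -> LayerSpec:
        for l in self.layers:
            if l.name == layer_name:
                return l
        raise KeyError(layer_name)

    def layer_slice(self, layer_name: str) -> slice:
        off = self.offset(layer_name)
        return slice(off, off + self.layer(layer_name).size)

    def describe(self) -> dict:
        """JSON-serializable summary (layer sizes and group audits)."""
        return {
            "task": self.task,
            "layers": [
                {"name": l.name, "size": l.size, "role": l.role, "shape": l.shape}
                for l in self.layers
            ],
            "groups": {
                name: {
                    "source": g.source,
                    "target": g.target,
                    "class": g.cls,
                    "n_connections": g.n_connections,
                    "plastic": g.plastic,
                    "init": list(g.init),
                }
                for name, g in self.groups.items()
            },
            "meta": self.meta,
        }


# ---------------------------------------------------------------------------
# index helpers


def contour_feature_index(pattern, orient, row, col, grid=9, n_orient=4):
    """Index of the (pattern, orientation, row, col) feature/linking unit."""
    return ((pattern * n_orient + orient) * grid + row) * grid + col


def tracing_feature_index(channel, row, col, grid=5):
    """Index of the (channel, row, col) feature/linking unit."""
    return (channel * grid + row) * grid + col


def _grid_neighbors(row, col, grid):
    """The 4-connected neighbors of a cell inside a grid."""
    out = []
    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        r, c = row + dr, col + dc
        if 0 <= r < grid and 0 <= c < grid:
            out.append((r, c))
    return out


# ---------------------------------------------------------------------------
# builders


def _linking_groups(
    n_maps: int,
    grid: int,
    feat_index,
    n_link: int,
    n_assoc: int,
    n_motor: int,
    init: dict,
    lateral_full: bool,
    feedforward_only: bool,
    cross_pairs,
) -> tuple[dict[str, ConnectionGroup], int]:
    """Groups shared by both task architectures.

    ``feat_index(map, row, col)`` flattens a feature coordinate;
    ``cross_pairs`` yields the modulatory partners of a unit at the same
    location.  Unit space layout: [linking_ex, linking_inh, association,
    motor]; input feature space mirrors the linking layout one-to-one.
    """
    ex0, inh0 = 0, n_link
    assoc0 = 2 * n_link
    motor0 = assoc0 + n_assoc
    idx = np.arange(n_link)
    groups = {}

    def add(name, source, target, cls, rows, cols, plastic):
        groups[name] = ConnectionGroup(
            name,
            source,
            target,
            cls,
            np.asarray(rows, dtype=np.int64),
            np.asarray(cols, dtype=np.int64),
            plastic,
            init[name],
        )

    # fixed feedforward drive and its disynaptic-inhibition pathway
    add("inp_ex", "input", "linking_ex", "inp", idx, ex0 + idx, False)
    add("inp_inh", "input", "linking_inh", "inp", idx, inh0 + idx, False)
    add("inh_ex", "linking_inh", "linking_ex", "inh", inh0 + idx, ex0 + idx, True)

    if not feedforward_only:
        lat_r, lat_c = [], []
        for m in range(n_maps):
            for r in range(grid):
                for c in range(grid):
                    src = feat_index(m, r, c)
                    if lateral_full:
                        # full connectivity stays within one stimulus group
                        # (one aperture's orientation maps / all channels)
                        for m2 in [m, *cross_pairs(m)]:
                            for r2 in range(grid):
                                for c2 in range(grid):
                                    if (m2, r2, c2) == (m, r, c):
                                        continue
                                    if (r2, c2) == (r, c):
                                        continue  # same-location pairs live in "cross"
                                    lat_r.append(src)
                                    lat_c.append(feat_index(m2, r2, c2))
                    else:
                        for r2, c2 in _grid_neighbors(r, c, grid):
                            lat_r.append(src)
                            lat_c.append(feat_index(m, r2, c2))
        add("lateral", "linking_ex", "linking_ex", "mod", lat_r, np.array(lat_c) + ex0, True)

        cr_r, cr_c = [], []
        for m in range(n_maps):
            for r in range(grid):
                for c in range(grid):
                    src = feat_index(m, r, c)
                    for m2 in cross_pairs(m):
                        cr_r.append(src)
                        cr_c.append(feat_index(m2, r, c))
        add("cross", "linking_ex", "linking_ex", "mod", cr_r, np.array(cr_c) + ex0, True)

    # linking -> association (all-to-all, plastic excitation)
    rows = np.repeat(idx, n_assoc)
    cols = assoc0 + np.tile(np.arange(n_assoc), n_link)
    add("ff_assoc", "linking_ex", "association", "ex", rows, cols, True)

    if not feedforward_only:
        rows = np.repeat(assoc0 + np.arange(n_assoc), n_link)
        cols = np.tile(ex0 + idx, n_assoc)
        add("feedback", "association", "linking_ex", "mod", rows, cols, True)

    rows = np.repeat(assoc0 + np.arange(n_assoc), n_motor)
    cols = motor0 + np.tile(np.arange(n_motor), n_assoc)
    add("assoc_motor", "association", "motor", "ex", rows, cols, True)
    return groups, motor0


def build_contour_network(
    grid: int = 9,
    n_orient: int = 4,
    n_patterns: int = 2,
    lateral_full: bool = False,
    feedforward_only: bool = False,
    init: dict | None = None,
) -> ArchitectureSpec:
    """Architecture for the two-aperture contour-linking task.

    Defaults give 648 input units (2 patterns x 4 orientations x 9 x 9
    locations), 648 linking excitatory + 648 inhibitory units, 4
    association units and 2 motor units (saccade left / right).  Lateral
    modulation links the four nearest neighbors within an orientation map
    and the other three orientations at the same location; one map per
    (pattern, orientation).
    """
    cfg = dict(CONTOUR_INIT)
    if init:
        cfg.update(init)
    n_link = n_patterns * n_orient * grid * grid
    n_assoc, n_motor = 4, n_patterns

    # a "map" is one (pattern, orientation) sheet; cross-feature partners
    # are the other orientations within the same pattern
    n_maps = n_patterns * n_orient

    def feat_index(m, r, c):
        return (m * grid + r) * grid + c

    def cross_pairs(m):
        pattern, orient = divmod(m, n_orient)
        return [pattern * n_orient + o for o in range(n_orient) if o != orient]

    groups, _ = _linking_groups(
        n_maps, grid, feat_index, n_link, n_assoc, n_motor,
        cfg, lateral_full, feedforward_only, cross_pairs,
    )
    layers = [
        LayerSpec("input", n_link, "input", (n_patterns, n_orient, grid, grid)),
        LayerSpec("linking_ex", n_link, "linking_ex", (n_patterns, n_orient, grid, grid)),
        LayerSpec("linking_inh", n_link, "linking_inh", (n_patterns, n_orient, grid, grid)),
        LayerSpec("association", n_assoc, "association"),
        LayerSpec("motor", n_motor, "motor"),
    ]
    return ArchitectureSpec(
        task="contour",
        layers=layers,
        groups=groups,
        meta={
            "grid": grid,
            "n_orient": n_orient,
            "n_patterns": n_patterns,
            "lateral_full": lateral_full,
            "feedforward_only": feedforward_only,
        },
    )


def build_tracing_network(
    grid: int = 5,
    n_channels: int = 3,
    lateral_full: bool = False,
    feedforward_only: bool = False,
    init: dict | None = None,
) -> ArchitectureSpec:
    """Architecture for the curve-tracing task.

    Defaults give a 5 x 5 grid with three feature channels (red, green,
    luminance): 75 input units, 75 linking excitatory + 75 inhibitory
    units, 25 association units and 25 motor units (one saccade target
    per grid location).
    """
    cfg = dict(TRACING_INIT)
    if init:
        cfg.update(init)
    n_link = n_channels * grid * grid
    n_assoc = grid * grid
    n_motor = grid * grid

    def feat_index(m, r, c):
        return (m * grid + r) * grid + c

    def cross_pairs(m):
        return [m2 for m2 in range(n_channels) if m2 != m]

    groups, _ = _linking_groups(
        n_channels, grid, feat_index, n_link, n_assoc, n_motor,
        cfg, lateral_full, feedforward_only, cross_pairs,
    )
    layers = [
        LayerSpec("input", n_link, "input", (n_channels, grid, grid)),
        LayerSpec("linking_ex", n_link, "linking_ex", (n_channels, grid, grid)),
        LayerSpec("linking_inh", n_link, "linking_inh", (n_channels, grid, grid)),
        LayerSpec("association", n_assoc, "association", (grid, grid)),
        LayerSpec("motor", n_motor, "motor", (grid, grid)),
    ]
    return ArchitectureSpec(
        task="tracing",
        layers=layers,
        groups=groups,
        meta={
            "grid": grid,
            "n_channels": n_channels,
            "lateral_full": lateral_full,
            "feedforward_only": feedforward_only,
        },
    )


# ---------------------------------------------------------------------------
# weights


def init_weights(spec: ArchitectureSpec, rng: np.random.Generator) -> WeightSet:
    """Draw a WeightSet for an architecture.

    Plastic entries are i.i.d. uniform from the group's configured range;
    fixed entries take the configured constant; everything else is a
    structural zero.
    """
    n, n_inp = spec.n_units, spec.n_inputs
    coords = {c: ([], [], []) for c in ("inp", "ex", "inh", "mod")}
    masks = {
        "inp": np.zeros((n_inp, n), dtype=bool),
        "ex": np.zeros((n, n), dtype=bool),
        "inh": np.zeros((n, n), dtype=bool),
        "mod": np.zeros((n, n), dtype=bool),
    }
    for g in spec.groups.values():
        if g.init[0] == "const":
            data = np.full(g.n_connections, float(g.init[1]))
        elif g.init[0] == "uniform":
            data = rng.uniform(float(g.init[1]), float(g.init[2]), g.n_connections)
        else:
            raise ValueError(f"group {g.name}: unknown init {g.init!r}")
        rows, cols, vals = coords[g.cls]
        rows.append(g.rows)
        cols.append(g.cols)
        vals.append(data)
        if g.plastic:
            masks[g.cls][g.rows, g.cols] = True

    def assemble(cls_name, shape):
        rows, cols, vals = coords[cls_name]
        if not rows:
            return sp.csr_matrix(shape)
        mat = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=shape,
        )
        mat.sort_indices()
        return mat

    return WeightSet(
        W_inp=assemble("inp", (n_inp, n)),
        W_ex=assemble("ex", (n, n)),
        W_inh=assemble("inh", (n, n)),
        W_mod=assemble("mod", (n, n)),
        plastic_inp=masks["inp"],
        plastic_ex=masks["ex"],
        plastic_inh=masks["inh"],
        plastic_mod=masks["mod"],
    )


ABLATIONS = {
    "none": (),
    "lateral": ("lateral", "cross"),
    "feedback": ("feedback",),
    "both": ("lateral", "cross", "feedback"),
}


def ablate(weights: WeightSet, spec: ArchitectureSpec, which: str) -> WeightSet:
    """Zero the named modulatory groups of a (trained) network.

    ``which``: ``'lateral'`` removes the horizontal modulation within the
    linking layer (nearest-neighbor and cross-feature), ``'feedback'``
    removes association -> linking modulation, ``'both'`` removes all
    three ("anesthesia"), ``'none'`` returns an unchanged copy.
    """
    if which not in ABLATIONS:
        raise KeyError(
            f"unknown ablation {which!r}; expected one of {sorted(ABLATIONS)}"
        )
    out = weights.copy()
    for name in ABLATIONS[which]:
        if name not in spec.groups:
            continue
        g = spec.groups[name]
        out.zero_entries(g.cls, g.rows, g.cols)
    return out


def edge_table(weights: WeightSet, spec: ArchitectureSpec, group: str) -> pd.DataFrame:
    """Edge list (source, target, class, weight) of one connection group."""
    if group not in spec.groups:
        raise KeyError(f"unknown connection group {group!r}")
    g = spec.groups[group]
    mat = weights.matrix(g.cls)
    w = np.asarray(mat[g.rows, g.cols]).ravel()
    return pd.DataFrame(
        {"source": g.rows, "target": g.cols, "class": g.cls, "weight": w}
    )
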