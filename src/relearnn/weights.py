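"""Connection matrices of the network and their plasticity masks.

A :class:`WeightSet` holds four nonnegative matrices: the input projection
``W_inp`` (feature ``k`` -> unit ``l``) and the unit-to-unit excitatory,
inhibitory and modulatory matrices (entry ``[k, l]`` is the strength of the
connection from unit ``k`` to unit ``l``).  Each matrix carries a boolean
plasticity mask; entries outside the mask never change during learning and
structural zeros (absent connections) stay zero.

Matrices are stored in CSR sparse format with an explicit sparsity pattern
that is the union of the structural connections and the plastic mask, so a
plastic connection whose current strength is zero remains addressable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

CLASSES = ("inp", "ex", "inh", "mod")


def _csr_with_pattern(dense: np.ndarray, mask: np.ndarray) -> sp.csr_matrix:
    """Build a CSR matrix whose pattern covers nonzeros *and* masked entries."""
    pattern = (dense != 0) | mask
    rows, cols = np.nonzero(pattern)
    mat = sp.csr_matrix(
        (dense[rows, cols].astype(float), (rows, cols)), shape=dense.shape
    )
    mat.sort_indices()
    return mat


def _data_positions(mat: sp.csr_matrix, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Indices into ``mat.data`` of the entries at ``(rows, cols)``.

    All requested entries must be part of the sparsity pattern.
    """
    mat.sort_indices()
    pos = np.empty(len(rows), dtype=np.int64)
    indptr, indices = mat.indptr, mat.indices
    for i, (r, c) in enumerate(zip(rows, cols)):
        lo, hi = indptr[r], indptr[r + 1]
        j = lo + np.searchsorted(indices[lo:hi], c)
        if j >= hi or indices[j] != c:
            raise ValueError(f"entry ({r}, {c}) is not in the sparsity pattern")
        pos[i] = j
    return pos


@dataclass
class WeightSet:
    """The four connection matrices plus per-matrix plasticity masks."""

    W_inp: sp.csr_matrix
    W_ex: sp.csr_matrix
    W_inh: sp.csr_matrix
    W_mod: sp.csr_matrix
    plastic_inp: np.ndarray
    plastic_ex: np.ndarray
    plastic_inh: np.ndarray
    plastic_mod: np.ndarray
    _plastic_cache: dict = field(default_factory=dict, repr=False, compare=False)
    _trans_cache: dict = field(default_factory=dict, repr=False, compare=False)
    _dirty: set = field(default_factory=set, repr=False, compare=False)

    @classmethod
    def from_dense(
        cls,
        W_inp: np.ndarray,
        W_ex: np.ndarray,
        W_inh: np.ndarray,
        W_mod: np.ndarray,
        plastic_inp: np.ndarray | None = None,
        plastic_ex: np.ndarray | None = None,
        plastic_inh: np.ndarray | None = None,
        plastic_mod: np.ndarray | None = None,
    ) -> "WeightSet":
        """Build a WeightSet from dense arrays (missing masks default to all-False)."""
        W_inp = np.asarray(W_inp, dtype=float)
        W_ex = np.asarray(W_ex, dtype=float)
        W_inh = np.asarray(W_inh, dtype=float)
        W_mod = np.asarray(W_mod, dtype=float)
        n = W_ex.shape[0]
        if W_ex.shape != (n, n) or W_inh.shape != (n, n) or W_mod.shape != (n, n):
            raise ValueError("recurrent weight matrices must be square and same shape")
        if W_inp.shape[1] != n:
            raise ValueError(
                f"W_inp maps {W_inp.shape[0]} features to {W_inp.shape[1]} units, "
                f"but the network has {n} units"
            )
        masks = []
        for W, m in zip(
            (W_inp, W_ex, W_inh, W_mod),
            (plastic_inp, plastic_ex, plastic_inh, plastic_mod),
        ):
            if np.any(W < 0):
                raise ValueError("weights must be nonnegative")
            masks.append(
                np.zeros(W.shape, dtype=bool) if m is None else np.asarray(m, dtype=bool)
            )
        return cls(
            _csr_with_pattern(W_inp, masks[0]),
            _csr_with_pattern(W_ex, masks[1]),
            _csr_with_pattern(W_inh, masks[2]),
            _csr_with_pattern(W_mod, masks[3]),
            *masks,
        )

    # -- basic properties ------------------------------------------------

    @property
    def n_units(self) -> int:
        return self.W_ex.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.W_inp.shape[0]

    def matrix(self, cls_name: str) -> sp.csr_matrix:
        return getattr(self, f"W_{cls_name}")

    def mask(self, cls_name: str) -> np.ndarray:
        return getattr(self, f"plastic_{cls_name}")

    def dense(self, cls_name: str) -> np.ndarray:
        return self.matrix(cls_name).toarray()

    def copy(self) -> "WeightSet":
        return WeightSet(
            self.W_inp.copy(),
            self.W_ex.copy(),
            self.W_inh.copy(),
            self.W_mod.copy(),
            self.plastic_inp.copy(),
            self.plastic_ex.copy(),
            self.plastic_inh.copy(),
            self.plastic_mod.copy(),
        )

    # -- plastic-entry addressing ---------------------------------------

    def plastic_entries(self, cls_name: str):
        """``(rows, cols, data_positions)`` of the plastic entries of a matrix.

        Cached; the cache survives in-place ``.data`` updates because the
        sparsity pattern never changes.
        """
        if cls_name not in self._plastic_cache:
            rows, cols = np.nonzero(self.mask(cls_name))
            pos = _data_positions(self.matrix(cls_name), rows, cols)
            self._plastic_cache[cls_name] = (rows, cols, pos)
        return self._plastic_cache[cls_name]

    def add_to_plastic(self, cls_name: str, delta: np.ndarray) -> None:
        """In-place ``W[rows, cols] += delta`` on plastic entries, clipped at 0."""
        rows, cols, pos = self.plastic_entries(cls_name)
        data = self.matrix(cls_name).data
        data[pos] = np.maximum(data[pos] + delta, 0.0)
        self._dirty.add(cls_name)

    def zero_entries(self, cls_name: str, rows: np.ndarray, cols: np.ndarray) -> None:
        """In-place set the given entries of a matrix to zero (pattern preserved)."""
        pos = _data_positions(self.matrix(cls_name), rows, cols)
        self.matrix(cls_name).data[pos] = 0.0
        self._dirty.add(cls_name)

    # -- cached transposes ----------------------------------------------
    #
    # The sparsity pattern is immutable, so the transposed matrices (used
    # on every integration step) are built once; after in-place weight
    # updates only their data vectors are refreshed through a cached
    # permutation.

    def WT(self, cls_name: str) -> sp.csr_matrix:
        """Transposed weight matrix in CSR form, kept in sync lazily."""
        if cls_name not in self._trans_cache:
            mat = self.matrix(cls_name)
            marker = mat.copy()
            marker.data = np.arange(mat.nnz, dtype=np.int64) + 0.0
            perm = marker.T.tocsr().data.astype(np.int64)
            WT = mat.T.tocsr()
            WT.data = mat.data[perm]
            self._trans_cache[cls_name] = (WT, perm)
            self._dirty.discard(cls_name)
            return WT
        WT, perm = self._trans_cache[cls_name]
        if cls_name in self._dirty:
            WT.data[:] = self.matrix(cls_name).data[perm]
            self._dirty.discard(cls_name)
        return WT

    def dense_T(self, cls_name: str) -> np.ndarray:
        """Dense transposed weight matrix (cached buffer, refreshed in place)."""
        WT = self.WT(cls_name)
        key = f"dense_{cls_name}"
        if key not in self._trans_cache:
            rows = np.repeat(np.arange(WT.shape[0]), np.diff(WT.indptr))
            buf = np.zeros(WT.shape)
            self._trans_cache[key] = (buf, rows, WT.indices)
        buf, rows, cols = self._trans_cache[key]
        buf[rows, cols] = WT.data
        return buf
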