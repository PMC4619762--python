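"""Checkpoints, run manifests and reproducible run directories."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from . import __version__
from .params import ModelParams
from .weights import WeightSet

_MATS = ("inp", "ex", "inh", "mod")


def save_checkpoint(
    path: str | Path, weights: WeightSet, prm: ModelParams, meta: dict | None = None
) -> None:
    """Serialize weights (CSR components), masks and params to one .npz archive.

    Key layout: ``<cls>_data/indices/indptr/shape`` per matrix class,
    ``<cls>_mask_rows/cols`` for the plastic masks, and a JSON string
    under ``meta`` holding the ModelParams and any extra metadata.
    """
    arrays: dict[str, np.ndarray] = {}
    for cls_name in _MATS:
        mat = weights.matrix(cls_name).tocsr()
        arrays[f"{cls_name}_data"] = mat.data
        arrays[f"{cls_name}_indices"] = mat.indices
        arrays[f"{cls_name}_indptr"] = mat.indptr
        arrays[f"{cls_name}_shape"] = np.asarray(mat.shape)
        rows, cols = np.nonzero(weights.mask(cls_name))
        arrays[f"{cls_name}_mask_rows"] = rows
        arrays[f"{cls_name}_mask_cols"] = cols
    payload = {"params": dataclasses.asdict(prm), "meta": meta or {},
               "version": __version__}
    arrays["meta"] = np.frombuffer(
        json.dumps(payload).encode("utf8"), dtype=np.uint8
    )
    np.savez_compressed(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[WeightSet, ModelParams, dict]:
    """Inverse of :func:`save_checkpoint`."""
    with np.load(path) as z:
        mats = {}
        masks = {}
        for cls_name in _MATS:
            shape = tuple(z[f"{cls_name}_shape"])
            mats[cls_name] = sp.csr_matrix(
                (
                    z[f"{cls_name}_data"],
                    z[f"{cls_name}_indices"],
                    z[f"{cls_name}_indptr"],
                ),
                shape=shape,
            )
            mask = np.zeros(shape, dtype=bool)
            mask[z[f"{cls_name}_mask_rows"], z[f"{cls_name}_mask_cols"]] = True
            masks[cls_name] = mask
        payload = json.loads(bytes(z["meta"]).decode("utf8"))
    weights = WeightSet(
        W_inp=mats["inp"], W_ex=mats["ex"], W_inh=mats["inh"], W_mod=mats["mod"],
        plastic_inp=masks["inp"], plastic_ex=masks["ex"],
        plastic_inh=masks["inh"], plastic_mod=masks["mod"],
    )
    prm = ModelParams(**payload["params"])
    return weights, prm, payload.get("meta", {})


@dataclass
class RunManifest:
    """Reproducibility record written into every run directory."""

    config: dict
    seed: int
    version: str = __version__
    started: str = ""
    finished: str = ""
    complete: bool = False
    outputs: list = field(default_factory=list)

    def start(self) -> "RunManifest":
        self.started = datetime.now(timezone.utc).isoformat()
        return self

    def finish(self, outputs: list[str]) -> "RunManifest":
        self.finished = datetime.now(timezone.utc).isoformat()
        self.outputs = outputs
        self.complete = True
        return self

    def write(self, run_dir: str | Path) -> Path:
        path = Path(run_dir) / "manifest.json"
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        return path


def load_manifest(run_dir: str | Path) -> RunManifest:
    data = json.loads((Path(run_dir) / "manifest.json").read_text())
    return RunManifest(**data)
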