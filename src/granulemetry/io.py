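"""Reading and writing: TIFF stacks, CSV tables, YAML/JSON specs.

Column schemas
--------------
``cores.csv``: id, x_nm, y_nm, z_nm, mean_grey, peak_grey, local_background,
n_voxels (one accepted core per row; the companion label TIFF stores each
core's voxel set as label id+1).

``granules.csv``: id, cell_id, x_nm, y_nm, z_nm, diameter_nm, mean_grey,
region, n_cores, core_ids (semicolon-separated indices into cores.csv).

``granule_truth.csv`` / ``spot_truth.csv``: one planted object per row with
its true parameters and pairing flags.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .coredetect import CoreDetection, EmVolume
from .geometry import VoxelGeometry
from .morphometry import GranuleRecord
from .synth.em import (
    EmPhantomSpec,
    GranulePopulationSpec,
    GreyComponent,
    GroundTruthGranule,
)
from .synth.fluor import FluorPhantomSpec, GroundTruthSpot

__all__ = [
    "read_volume",
    "write_volume",
    "write_mask",
    "read_mask",
    "cores_to_frame",
    "write_cores",
    "read_cores",
    "granules_to_frame",
    "write_granules",
    "write_granule_truth",
    "write_spot_truth",
    "em_spec_from_file",
    "fluor_spec_from_file",
    "em_spec_to_dict",
    "write_spec_sidecar",
]


# ---------------------------------------------------------------------------
# images


def write_volume(path, volume: EmVolume) -> None:
    tifffile.imwrite(path, volume.data)


def read_volume(path, geometry: VoxelGeometry, cell_id: Optional[str] = None) -> EmVolume:
    return EmVolume(data=tifffile.imread(path), geometry=geometry, cell_id=cell_id)


def write_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, mask.astype(np.uint8))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path).astype(bool)


def write_core_labels(path, cores: Sequence[CoreDetection], shape) -> None:
    labels = np.zeros(shape, dtype=np.int32)
    for i, core in enumerate(cores):
        labels[tuple(core.voxels.T)] = i + 1
    tifffile.imwrite(path, labels)


# ---------------------------------------------------------------------------
# tables


def cores_to_frame(cores: Sequence[CoreDetection]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": range(len(cores)),
            "x_nm": [c.center_nm[2] for c in cores],
            "y_nm": [c.center_nm[1] for c in cores],
            "z_nm": [c.center_nm[0] for c in cores],
            "mean_grey": [c.mean_grey for c in cores],
            "peak_grey": [c.peak_grey for c in cores],
            "local_background": [c.local_background for c in cores],
            "n_voxels": [len(c.voxels) for c in cores],
        }
    )


def write_cores(path, cores: Sequence[CoreDetection]) -> None:
    cores_to_frame(cores).to_csv(path, index=False)


def read_cores(csv_path, labels_path) -> list[CoreDetection]:
    """Rebuild core detections from the CSV and the label TIFF."""
    frame = pd.read_csv(csv_path)
    labels = tifffile.imread(labels_path)
    cores = []
    for _, row in frame.iterrows():
        voxels = np.argwhere(labels == int(row["id"]) + 1)
        cores.append(
            CoreDetection(
                center_nm=np.array([row["z_nm"], row["y_nm"], row["x_nm"]]),
                voxels=voxels,
                mean_grey=float(row["mean_grey"]),
                peak_grey=float(row["peak_grey"]),
                local_background=float(row["local_background"]),
            )
        )
    return cores


def granules_to_frame(records: Sequence[GranuleRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "cell_id": [r.cell_id for r in records],
            "x_nm": [r.center_nm[2] for r in records],
            "y_nm": [r.center_nm[1] for r in records],
            "z_nm": [r.center_nm[0] for r in records],
            "diameter_nm": [r.diameter_nm for r in records],
            "mean_grey": [r.mean_grey for r in records],
            "region": [r.region for r in records],
            "n_cores": [r.n_cores for r in records],
            "core_ids": [";".join(map(str, r.core_ids)) for r in records],
        }
    )


def write_granules(path, records: Sequence[GranuleRecord]) -> None:
    granules_to_frame(records).to_csv(path, index=False)


def read_granules(path) -> list[GranuleRecord]:
    frame = pd.read_csv(path)
    records = []
    for _, row in frame.iterrows():
        core_ids = tuple(
            int(t) for t in str(row["core_ids"]).split(";") if t not in ("", "nan")
        )
        records.append(
            GranuleRecord(
                id=str(row["id"]),
                cell_id=None if pd.isna(row["cell_id"]) else str(row["cell_id"]),
                center_nm=np.array([row["z_nm"], row["y_nm"], row["x_nm"]]),
                diameter_nm=float(row["diameter_nm"]),
                mean_grey=float(row["mean_grey"]),
                region=str(row["region"]),
                n_cores=int(row["n_cores"]),
                core_ids=core_ids,
            )
        )
    return records


def write_granule_truth(path, truths: Sequence[GroundTruthGranule]) -> None:
    pd.DataFrame(
        {
            "id": [t.id for t in truths],
            "x_nm": [t.center_nm[2] for t in truths],
            "y_nm": [t.center_nm[1] for t in truths],
            "z_nm": [t.center_nm[0] for t in truths],
            "core_diameter_nm": [t.core_diameter_nm for t in truths],
            "granule_diameter_nm": [t.granule_diameter_nm for t in truths],
            "core_grey": [t.core_grey for t in truths],
            "region": [t.region for t in truths],
            "partner_id": [t.partner_id or "" for t in truths],
        }
    ).to_csv(path, index=False)


def write_spot_truth(path, truths: Sequence[GroundTruthSpot]) -> None:
    pd.DataFrame(
        {
            "id": [t.id for t in truths],
            "channel": [t.channel for t in truths],
            "x_px": [t.x_px for t in truths],
            "y_px": [t.y_px for t in truths],
            "peak": [t.peak for t in truths],
            "partner_id": [t.partner_id or "" for t in truths],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# specs


def em_spec_to_dict(spec: EmPhantomSpec) -> dict:
    out = dataclasses.asdict(spec)
    out["geometry"] = dataclasses.asdict(spec.geometry)
    out["populations"] = {
        region: dataclasses.asdict(pop) for region, pop in spec.populations.items()
    }
    return out


def _pop_from_dict(data: dict) -> GranulePopulationSpec:
    data = dict(data)
    if "grey" in data:
        data["grey"] = tuple(
            GreyComponent(**c) if isinstance(c, dict) else GreyComponent(*c)
            for c in data["grey"]
        )
    if "diameter_bounds_nm" in data:
        data["diameter_bounds_nm"] = tuple(data["diameter_bounds_nm"])
    return GranulePopulationSpec(**data)


def em_spec_from_dict(data: dict) -> EmPhantomSpec:
    data = dict(data)
    if "geometry" in data and isinstance(data["geometry"], dict):
        data["geometry"] = VoxelGeometry(**data["geometry"])
    data["shape_zyx"] = tuple(data["shape_zyx"])
    if data.get("golgi_semiaxes_nm") is not None:
        data["golgi_semiaxes_nm"] = tuple(data["golgi_semiaxes_nm"])
    data["populations"] = {
        region: _pop_from_dict(pop) for region, pop in data.get("populations", {}).items()
    }
    return EmPhantomSpec(**data)


def _load_structured(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def em_spec_from_file(path) -> EmPhantomSpec:
    return em_spec_from_dict(_load_structured(path))


def fluor_spec_from_file(path) -> FluorPhantomSpec:
    data = _load_structured(path)
    if "shape" in data:
        data["shape"] = tuple(data["shape"])
    return FluorPhantomSpec(**data)


def write_spec_sidecar(path, spec) -> None:
    """JSON sidecar echoing the full spec (and thus the seed) for provenance."""
    if isinstance(spec, EmPhantomSpec):
        payload = em_spec_to_dict(spec)
    else:
        payload = dataclasses.asdict(spec)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
        fh.write("\n")
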