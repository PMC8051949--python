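"""File round-trips for simulated and measured data.

FRET image sets travel as multi-page TIFF (donor, acceptor, FRET page
order; 16-bit unsigned) with a JSON ground-truth/metadata sidecar; colony
maps as 16-bit label TIFF plus a CSV attribute table; profiles and Ct
tables as CSV; bleed-through models as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .colony import ColonyMap
from .fret import BleedthroughModel, FretImageSet
from .lamin import ZProfile

__all__ = [
    "save_fret_image_set",
    "load_fret_image_set",
    "save_bleedthrough",
    "load_bleedthrough",
    "save_colony_map",
    "load_colony_map",
    "save_profile",
    "load_profile",
]


def save_fret_image_set(
    image_set: FretImageSet, path, truth: list | None = None
) -> Path:
    """Write channels as a 3-page uint16 TIFF; metadata/truth to a .json sidecar."""
    path = Path(path)
    stack = np.stack([image_set.donor, image_set.acceptor, image_set.fret])
    tifffile.imwrite(
        path,
        np.clip(np.round(stack), 0, 65535).astype(np.uint16),
        photometric="minisblack",
    )
    meta = {"field_id": image_set.field_id, "pixel_size": image_set.pixel_size}
    if truth is not None:
        meta["nuclei"] = [
            {
                "nucleus_id": t.nucleus_id,
                "centroid": list(t.centroid),
                "efficiency": t.efficiency,
            }
            for t in truth
        ]
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def load_fret_image_set(path) -> FretImageSet:
    path = Path(path)
    stack = tifffile.imread(path).astype(float)
    if stack.ndim != 3 or stack.shape[0] != 3:
        raise ValueError(f"{path}: expected a 3-page (donor, acceptor, FRET) TIFF")
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return FretImageSet(
        donor=stack[0],
        acceptor=stack[1],
        fret=stack[2],
        pixel_size=float(meta.get("pixel_size", 1.0)),
        field_id=str(meta.get("field_id", path.stem)),
    )


def save_bleedthrough(model: BleedthroughModel, path) -> None:
    Path(path).write_text(json.dumps(model.__dict__, indent=2))


def load_bleedthrough(path) -> BleedthroughModel:
    return BleedthroughModel(**json.loads(Path(path).read_text()))


def save_colony_map(cmap: ColonyMap, tiff_path, csv_path) -> None:
    if cmap.label_mask is None:
        raise ValueError("colony map has no label mask")
    tifffile.imwrite(tiff_path, cmap.label_mask.astype(np.uint16))
    cmap.cells.to_csv(csv_path, index=False)


def load_colony_map(tiff_path, csv_path, colony_id: str = "") -> ColonyMap:
    mask = tifffile.imread(tiff_path).astype(np.int32)
    cells = pd.read_csv(csv_path)
    return ColonyMap(cells=cells, label_mask=mask, colony_id=colony_id or Path(tiff_path).stem)


def save_profile(profile: ZProfile, path) -> None:
    pd.DataFrame(
        {"position": profile.positions, "intensity": profile.intensities}
    ).to_csv(path, index=False)


def load_profile(path, nucleus_id: str = "", compartment: str = "unknown") -> ZProfile:
    df = pd.read_csv(path)
    return ZProfile(
        positions=df["position"].to_numpy(),
        intensities=df["intensity"].to_numpy(),
        nucleus_id=nucleus_id or Path(path).stem,
        compartment=compartment,
    )
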