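"""Periphery/interior classification of colony cells and marker-positivity summaries.

Cells come either as an integer label mask (0 = background) with a per-cell
attribute table, or as a centroid table.  A cell is *periphery* when it
touches the outside of the colony (mask mode: any of its pixels is
8-adjacent to background; centroid mode: lies on or near the convex hull of
all centroids).  Positivity is an input attribute, not computed from images.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "ColonyMap",
    "CompartmentCounts",
    "classify_compartments",
    "summarize_positivity",
    "pool_fields",
]

_S8 = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


@dataclass
class ColonyMap:
    """Labeled colony cells plus per-cell attributes.

    ``cells`` must have a ``label`` column (mask mode) or ``x``/``y``
    columns (centroid mode), plus a boolean ``positive`` column.  After
    classification it gains a ``compartment`` column.
    """

    cells: pd.DataFrame
    label_mask: np.ndarray | None = None
    colony_id: str = ""

    def __post_init__(self):
        if "positive" not in self.cells.columns:
            raise ValueError("cells table needs a 'positive' column")
        if self.label_mask is not None:
            if "label" not in self.cells.columns:
                raise ValueError("mask mode needs a 'label' column")
        elif not {"x", "y"} <= set(self.cells.columns):
            raise ValueError("centroid mode needs 'x' and 'y' columns")


@dataclass
class CompartmentCounts:
    """Both positivity normalisations for one colony/field.

    ``pct_of_positives_*`` are NaN (undefined) when there are no positive
    cells, never 0.
    """

    colony_id: str
    n_total: int
    n_positive: int
    n_positive_periphery: int
    n_positive_interior: int
    pct_positive_of_field: float
    pct_of_positives_periphery: float
    pct_of_positives_interior: float


def _classify_mask_mode(
    label_mask: np.ndarray, exclude_border: bool
) -> tuple[dict[int, str], bool]:
    """Per-label compartment via background 8-adjacency; returns (mapping, has_holes)."""
    colony = label_mask > 0
    filled = ndimage.binary_fill_holes(colony)
    has_holes = bool(np.any(filled & ~colony))
    if has_holes:
        warnings.warn("colony contains interior holes; holes count as background")

    n_comp, _ = ndimage.label(colony, structure=_S8)[1], None
    if n_comp > 1:
        warnings.warn(
            f"colony mask has {n_comp} connected components; classifying per component"
        )

    # pixels of the colony that touch background under 8-connectivity; the
    # image border counts as background (pad before dilating)
    bg_padded = np.pad(~colony, 1, constant_values=True)
    touches_bg = colony & ndimage.binary_dilation(bg_padded, structure=_S8)[1:-1, 1:-1]

    border = np.zeros_like(colony)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True

    out: dict[int, str] = {}
    for lab in np.unique(label_mask):
        if lab == 0:
            continue
        cell = label_mask == lab
        if exclude_border and np.any(cell & border):
            out[int(lab)] = "excluded"
        elif np.any(cell & touches_bg):
            out[int(lab)] = "periphery"
        else:
            out[int(lab)] = "interior"
    return out, has_holes


def _classify_centroid_mode(xy: np.ndarray) -> np.ndarray:
    """Periphery iff on the convex hull of centroids or within one median
    nearest-neighbour distance of its boundary."""
    n = len(xy)
    if n < 3:
        raise ValueError("centroid mode needs >= 3 cells")
    tree = cKDTree(xy)
    d_nn = tree.query(xy, k=2)[0][:, 1]
    tol = float(np.median(d_nn))
    hull = ConvexHull(xy)
    compartment = np.full(n, "interior", dtype=object)
    compartment[hull.vertices] = "periphery"
    # distance of each point to the hull boundary segments
    verts = xy[hull.vertices]
    for i in range(n):
        if compartment[i] == "periphery":
            continue
        p = xy[i]
        dmin = np.inf
        for j in range(len(verts)):
            a, b = verts[j], verts[(j + 1) % len(verts)]
            ab = b - a
            t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0, 1)
            dmin = min(dmin, float(np.hypot(*(p - (a + t * ab)))))
        if dmin < tol:
            compartment[i] = "periphery"
    return compartment


def classify_compartments(cmap: ColonyMap, exclude_border: bool = True) -> ColonyMap:
    """Fill the ``compartment`` column of a colony map.

    Mask mode: a cell is periphery iff any of its pixels is 8-adjacent to
    background (holes inside the colony count as background, with a
    warning).  Cells touching the image border are excluded by default.
    Centroid mode: convex-hull proximity rule.
    """
    cells = cmap.cells.copy()
    if cmap.label_mask is not None:
        mapping, _ = _classify_mask_mode(cmap.label_mask, exclude_border)
        cells["compartment"] = cells["label"].map(mapping)
        missing = cells["compartment"].isna()
        if missing.any():
            raise ValueError(
                f"labels absent from mask: {sorted(cells.loc[missing, 'label'])}"
            )
    else:
        xy = cells[["x", "y"]].to_numpy(dtype=float)
        cells["compartment"] = _classify_centroid_mode(xy)
    return replace(cmap, cells=cells)


def summarize_positivity(cmap: ColonyMap) -> CompartmentCounts:
    """Count positives overall and per compartment, with both normalisations."""
    if "compartment" not in cmap.cells.columns:
        raise ValueError("compartments not assigned; run classify_compartments first")
    cells = cmap.cells[cmap.cells["compartment"] != "excluded"]
    n_total = len(cells)
    pos = cells[cells["positive"].astype(bool)]
    n_pos = len(pos)
    n_pp = int((pos["compartment"] == "periphery").sum())
    n_pi = int((pos["compartment"] == "interior").sum())
    if n_pos > 0:
        share_p = 100.0 * n_pp / n_pos
        share_i = 100.0 * n_pi / n_pos
    else:
        share_p = share_i = float("nan")
    return CompartmentCounts(
        colony_id=cmap.colony_id,
        n_total=n_total,
        n_positive=n_pos,
        n_positive_periphery=n_pp,
        n_positive_interior=n_pi,
        pct_positive_of_field=100.0 * n_pos / n_total if n_total else float("nan"),
        pct_of_positives_periphery=share_p,
        pct_of_positives_interior=share_i,
    )


def pool_fields(
    values: "np.ndarray | list[float]",
    groups: "np.ndarray | list[str]",
    kind: str = "t_test",
) -> pd.DataFrame:
    """Per-group mean +/- SD and a two-group test on per-field summaries.

    Returns a one-row-per-group frame; the test statistic and p-value are
    attached as frame attrs ``statistic`` / ``pvalue`` (NaN with a warning
    when any group has a single field).
    """
    from .stats import group_tests

    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    rows = []
    grouped = {}
    for g in pd.unique(groups):
        v = values[groups == g]
        grouped[g] = v
        rows.append(
            {
                "group": g,
                "n_fields": len(v),
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if len(v) > 1 else float("nan"),
            }
        )
    out = pd.DataFrame(rows)
    if any(len(v) < 2 for v in grouped.values()):
        warnings.warn("a group has fewer than 2 fields; no test performed")
        out.attrs["statistic"] = float("nan")
        out.attrs["pvalue"] = float("nan")
    else:
        stat, p = group_tests(list(grouped.values()), kind=kind)
        out.attrs["statistic"] = stat
        out.attrs["pvalue"] = p
    return out
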