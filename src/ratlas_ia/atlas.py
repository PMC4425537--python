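"""Segmented bilateral atlas: integer label volume plus left/right region pairing.

Hemisphere assignment always comes from the region table (left_label /
right_label columns), never from the sign of a voxel coordinate, so a flipped
acquisition cannot silently swap sides.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LabeledAtlas", "map_voxels_to_regions", "region_side_means"]

TABLE_COLUMNS = ["region_name", "left_label", "right_label"]


@dataclass
class LabeledAtlas:
    """3D integer label volume with a bilateral region table.

    ``table`` columns: region_name, left_label, right_label.  Label 0 is
    background.  Every label present in the volume must appear in the table.
    """

    labels: np.ndarray
    table: pd.DataFrame
    voxel_size_mm: float
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be an integer volume")
        if list(self.table.columns[:3]) != TABLE_COLUMNS:
            raise ValueError(f"region table must have columns {TABLE_COLUMNS}")
        if self.affine is None:
            aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
            self.affine = aff
        tab_labels = set(self.table.left_label) | set(self.table.right_label)
        if (self.table.left_label == self.table.right_label).any():
            raise ValueError("left_label must differ from right_label")
        if len(tab_labels) != 2 * len(self.table):
            raise ValueError("duplicate labels in region table")
        present = set(np.unique(self.labels)) - {0}
        if not present <= tab_labels:
            raise ValueError(f"labels in volume missing from table: {present - tab_labels}")

    @property
    def region_names(self) -> list[str]:
        return list(self.table.region_name)

    def region_mask(self, name: str, side: str) -> np.ndarray:
        row = self.table[self.table.region_name == name]
        if row.empty:
            raise KeyError(f"unknown region {name!r}")
        label = int(row.left_label.iloc[0] if side == "left" else row.right_label.iloc[0])
        return self.labels == label

    def save(self, labels_path: str | os.PathLike, table_path: str | os.PathLike) -> None:
        from .io import save_nifti

        save_nifti(self.labels.astype(np.int16), labels_path, self.affine)
        self.table.to_csv(table_path, sep="\t", index=False)

    @classmethod
    def load(cls, labels_path: str | os.PathLike, table_path: str | os.PathLike) -> "LabeledAtlas":
        from .io import load_nifti

        labels, affine = load_nifti(labels_path)
        table = pd.read_csv(table_path, sep="\t")
        voxel = float(np.abs(affine[0, 0]))
        return cls(labels=np.rint(labels).astype(np.int32), table=table, voxel_size_mm=voxel, affine=affine)


def map_voxels_to_regions(
    index_map: np.ndarray,
    atlas: LabeledAtlas,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Collect per-region, per-side voxel values of an atlas-space index map.

    Returns a long DataFrame with columns region_name, side, n_voxels, mean,
    sd and the raw values list.  Every in-mask voxel belongs to exactly one
    region or to background (label 0); visiting order cannot matter because
    assignment is by label value.
    """
    index_map = np.asarray(index_map)
    if index_map.shape != atlas.labels.shape:
        raise ValueError(
            f"grid mismatch: map {index_map.shape} vs atlas {atlas.labels.shape}"
        )
    if mask is None:
        mask = np.ones(index_map.shape, dtype=bool)
    rows = []
    for _, r in atlas.table.iterrows():
        for side, label in (("left", r.left_label), ("right", r.right_label)):
            sel = (atlas.labels == label) & mask
            vals = index_map[sel]
            rows.append(
                {
                    "region_name": r.region_name,
                    "side": side,
                    "n_voxels": int(vals.size),
                    "mean": float(vals.mean()) if vals.size else float("nan"),
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
                    "values": vals,
                }
            )
    return pd.DataFrame(rows)


def region_side_means(
    index_map: np.ndarray, atlas: LabeledAtlas, mask: np.ndarray | None = None
) -> pd.DataFrame:
    """Wide per-region means: columns region_name, left, right."""
    long = map_voxels_to_regions(index_map, atlas, mask)
    wide = long.pivot(index="region_name", columns="side", values="mean").reset_index()
    wide.columns.name = None
    return wide[["region_name", "left", "right"]]
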