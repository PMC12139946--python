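"""Region/network parcellation: aggregation and virtual lesioning.

An :class:`Atlas` assigns every in-mask voxel to exactly one region and
every region to exactly one large-scale network. Aggregation replaces voxel
values by unweighted means over the member voxels of each region or network;
lesioning removes all voxels of one unit so downstream models can be
re-evaluated on the reduced space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .images import BrainMaps

__all__ = ["Atlas", "LesionResult", "aggregate", "lesion"]


@dataclass
class Atlas:
    """Voxel -> region and region -> network assignment.

    ``region_of_voxel`` holds a region id per voxel column of the map stack
    it describes; ``network_of_region`` a network id per region. Region ids
    index ``region_names`` and ``network_of_region``; they stay stable under
    lesioning (a removed region simply has no voxels left).
    """

    region_of_voxel: np.ndarray
    network_of_region: np.ndarray
    region_names: list[str] = field(default_factory=list)
    network_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.region_of_voxel = np.asarray(self.region_of_voxel, dtype=int)
        self.network_of_region = np.asarray(self.network_of_region, dtype=int)
        n_reg = self.network_of_region.size
        if self.region_of_voxel.min(initial=0) < 0 or (
            self.region_of_voxel.size and self.region_of_voxel.max() >= n_reg
        ):
            raise ValueError("voxel region ids outside the region table")
        if not self.region_names:
            self.region_names = [f"region_{i:03d}" for i in range(n_reg)]
        if not self.network_names:
            self.network_names = [
                f"network_{i}" for i in range(int(self.network_of_region.max()) + 1)
            ]
        if len(self.region_names) != n_reg:
            raise ValueError("one name per region required")

    @property
    def n_regions(self) -> int:
        return self.network_of_region.size

    @property
    def n_networks(self) -> int:
        return len(self.network_names)

    @property
    def network_of_voxel(self) -> np.ndarray:
        return self.network_of_region[self.region_of_voxel]

    def region_sizes(self) -> np.ndarray:
        return np.bincount(self.region_of_voxel, minlength=self.n_regions)

    def unit_id(self, unit, level: str) -> int:
        """Resolve a unit given as id or name at the requested level."""
        names = self.region_names if level == "region" else self.network_names
        if isinstance(unit, str):
            try:
                return names.index(unit)
            except ValueError:
                raise KeyError(f"unknown {level} {unit!r}") from None
        unit = int(unit)
        if not 0 <= unit < len(names):
            raise KeyError(f"unknown {level} id {unit}")
        return unit

    def voxels_of(self, unit, level: str = "region") -> np.ndarray:
        """Boolean voxel membership of a region or network."""
        uid = self.unit_id(unit, level)
        labels = self.region_of_voxel if level == "region" else self.network_of_voxel
        return labels == uid

    def select_voxels(self, index) -> "Atlas":
        """Atlas restricted to the voxel columns in ``index``."""
        return Atlas(
            region_of_voxel=self.region_of_voxel[np.asarray(index)],
            network_of_region=self.network_of_region,
            region_names=list(self.region_names),
            network_names=list(self.network_names),
        )

    def validate(self, n_voxels: int) -> None:
        if self.region_of_voxel.shape != (n_voxels,):
            raise ValueError("atlas does not cover the map voxel space")
        if np.any(self.region_sizes() == 0):
            raise ValueError("atlas contains empty regions")

    # -- serialization: integer-labelled NIfTI + JSON lookup ---------------
    def save(self, maps: BrainMaps, nifti_path, json_path) -> None:
        import nibabel as nib

        vol = np.full(maps.grid_shape, -1, dtype=np.int32)
        i, j, k = maps.voxel_coords.T
        vol[i, j, k] = self.region_of_voxel
        nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(nifti_path))
        with open(json_path, "w") as fh:
            json.dump(
                {
                    "network_of_region": self.network_of_region.tolist(),
                    "region_names": self.region_names,
                    "network_names": self.network_names,
                },
                fh,
                indent=1,
            )


@dataclass
class LesionResult:
    """Hold-out performance after removing one region or network."""

    level: str
    unit: int
    unit_name: str
    n_voxels_removed: int
    r_lesioned: float
    delta_r: float  # r_full - r_lesioned; positive = performance drop


def aggregate(maps: BrainMaps, atlas: Atlas, level: str = "region") -> pd.DataFrame:
    """Average voxel values within regions or networks.

    Returns an observations x units DataFrame whose columns are the unit
    names; unit value = unweighted mean over member voxels.
    """
    if level not in ("region", "network"):
        raise ValueError(f"unknown level {level!r}")
    atlas.validate(maps.n_voxels)
    labels = atlas.region_of_voxel if level == "region" else atlas.network_of_voxel
    n_units = atlas.n_regions if level == "region" else atlas.n_networks
    counts = np.bincount(labels, minlength=n_units)
    sums = np.zeros((maps.n_obs, n_units))
    np.add.at(sums.T, labels, maps.data.T)
    with np.errstate(invalid="ignore"):
        means = sums / counts
    names = atlas.region_names if level == "region" else atlas.network_names
    return pd.DataFrame(means, columns=names)


def lesion(maps: BrainMaps, atlas: Atlas, unit, level: str = "network") -> tuple[BrainMaps, Atlas]:
    """Remove all voxels of one region or network (virtual lesion).

    Returns the reduced maps and the correspondingly restricted atlas, so
    downstream model retraining and evaluation run on the reduced space.
    """
    atlas.validate(maps.n_voxels)
    member = atlas.voxels_of(unit, level)
    keep = ~member
    if not keep.any():
        raise ValueError("lesion would remove every voxel")
    uid = atlas.unit_id(unit, level)
    name = (atlas.region_names if level == "region" else atlas.network_names)[uid]
    return (
        maps.select_voxels(keep, tag=f"lesion:{level}:{name}"),
        atlas.select_voxels(keep),
    )
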