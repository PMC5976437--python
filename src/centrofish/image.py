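"""Calibrated multi-channel 3D image container and TIFF round-trip.

Axis order is (z, y, x) everywhere; all physical lengths are in µm.
Voxel index ``i`` along an axis with pitch ``d`` spans the physical
interval ``[i*d, (i+1)*d)`` and has its center at ``(i + 0.5) * d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

#: canonical channel names used throughout the pipeline
CHANNELS = ("mrna", "nterm", "cterm", "reference")


@dataclass
class VoxelImage:
    """A calibrated multi-channel 3D fluorescence stack.

    Parameters
    ----------
    data:
        Non-negative intensity array of shape ``(channel, z, y, x)``.
    voxel_size:
        Physical voxel pitch in µm per axis, ordered ``(z, y, x)``.
    channel_labels:
        Unique channel names; the analysis expects at least
        ``{"mrna", "nterm", "cterm", "reference"}``.
    cell_mask:
        Optional boolean or label volume of spatial shape ``(z, y, x)``.
        Nonzero voxels belong to the cell of interest.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_labels: tuple[str, ...] = CHANNELS
    cell_mask: np.ndarray | None = None
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (channel, z, y, x)")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three strictly positive µm values")
        self.channel_labels = tuple(self.channel_labels)
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel_labels must be unique")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels must match data.shape[0]")
        if self.cell_mask is not None:
            self.cell_mask = np.asarray(self.cell_mask)
            if self.cell_mask.shape != self.spatial_shape:
                raise ValueError("cell_mask shape must match spatial shape")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def extent_um(self) -> np.ndarray:
        """Physical size of the stack per axis (µm)."""
        return np.asarray(self.spatial_shape) * np.asarray(self.voxel_size)

    def channel(self, name: str) -> np.ndarray:
        """Return the 3D volume for a named channel."""
        try:
            idx = self.channel_labels.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_labels}"
            ) from None
        return self.data[idx]

    def mask_bool(self) -> np.ndarray:
        """Boolean cell mask (all-true when no mask is attached)."""
        if self.cell_mask is None:
            return np.ones(self.spatial_shape, dtype=bool)
        return self.cell_mask > 0

    # ---------------------------------------------------------------- I/O

    def save(self, path: str | Path) -> None:
        """Write a ZCYX TIFF plus a YAML sidecar with calibration.

        The sidecar (``<stem>.meta.yaml``) carries voxel size, channel
        names and cell id; the mask, if any, goes to ``<stem>.mask.tif``.
        """
        path = Path(path)
        # ZCYX layout: tifffile expects (z, c, y, x) for volumetric multichannel
        zcyx = np.moveaxis(self.data.astype(np.float32), 0, 1)
        tifffile.imwrite(path, zcyx, metadata={"axes": "ZCYX"},
                         photometric="minisblack", planarconfig="separate")
        meta = {
            "voxel_size_um": list(self.voxel_size),
            "channel_labels": list(self.channel_labels),
            "cell_id": self.cell_id,
        }
        path.with_suffix(".meta.yaml").write_text(yaml.safe_dump(meta))
        if self.cell_mask is not None:
            tifffile.imwrite(
                path.parent / (path.stem + ".mask.tif"),
                self.cell_mask.astype(np.uint16),
            )

    @classmethod
    def load(cls, path: str | Path) -> "VoxelImage":
        """Read an image written by :meth:`save`."""
        path = Path(path)
        zcyx = tifffile.imread(path)
        if zcyx.ndim != 4:
            raise ValueError(f"{path} is not a ZCYX stack")
        data = np.moveaxis(zcyx, 1, 0)
        meta_path = path.with_suffix(".meta.yaml")
        meta = yaml.safe_load(meta_path.read_text())
        mask_path = path.parent / (path.stem + ".mask.tif")
        mask = tifffile.imread(mask_path) if mask_path.exists() else None
        return cls(
            data=data,
            voxel_size=tuple(meta["voxel_size_um"]),
            channel_labels=tuple(meta["channel_labels"]),
            cell_mask=mask,
            cell_id=str(meta.get("cell_id", path.stem)),
        )


def voxel_centers_um(shape: tuple[int, int, int],
                     voxel_size: tuple[float, float, float]) -> list[np.ndarray]:
    """Per-axis physical coordinates of voxel centers."""
    return [
        (np.arange(n) + 0.5) * d for n, d in zip(shape, voxel_size)
    ]


def um_to_index(pos_um: np.ndarray, voxel_size) -> np.ndarray:
    """Nearest voxel index of a physical position (µm)."""
    return np.floor(np.asarray(pos_um) / np.asarray(voxel_size)).astype(int)
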