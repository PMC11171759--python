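"""Reading and writing image stacks and tabular results.

The unit of analysis is a single-cell 3D fluorescence z-stack (one channel,
e.g. an EEA1 immunostain), stored as TIFF / OME-TIFF with pages interpreted
as z-layers. Arrays are kept in ``(z, y, x)`` order throughout the package.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = ["ImageStack", "read_stack", "write_stack", "write_table", "write_json"]


@dataclass
class ImageStack:
    """A 3D non-negative intensity grid with voxel spacing and provenance.

    Parameters
    ----------
    data:
        Intensity array indexed ``(z, y, x)``. Must be finite and >= 0.
    spacing:
        Physical voxel size ``(dz, dy, dx)`` in micrometres. The default of
        isotropic 1.0 reproduces pixel-unit distances, matching analyses
        that treat the voxel index grid as the coordinate system.
    cell_id:
        Identifier of the imaged cell.
    group:
        Condition label, e.g. ``"WT1"``, ``"MUT2"``, ``"RhoAII"``, ``"vehicle"``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    cell_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[np.newaxis, :, :]
        if self.data.ndim != 3:
            raise ValueError(f"expected a 2D or 3D array, got ndim={self.data.ndim}")
        nz, ny, nx = self.data.shape
        if nz < 1 or ny < 8 or nx < 8:
            raise ValueError(f"stack too small: shape {self.data.shape}")
        # unsigned integer data is finite and non-negative by construction
        if not np.issubdtype(self.data.dtype, np.unsignedinteger):
            if not np.all(np.isfinite(self.data)):
                raise ValueError("stack contains non-finite intensities")
            if self.data.min() < 0:
                raise ValueError("stack contains negative intensities")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_pixels(self) -> int:
        return int(self.data.size)

    @property
    def bit_depth(self) -> int | str:
        """Bit depth for integer data, ``"float"`` otherwise."""
        if np.issubdtype(self.data.dtype, np.integer):
            return int(self.data.dtype.itemsize * 8)
        return "float"


_OME_SIZE_RE = {
    ax: re.compile(rf'PhysicalSize{ax}="([0-9.eE+-]+)"') for ax in "ZYX"
}


def _ome_spacing(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    xml = tif.ome_metadata
    if not xml:
        return None
    sizes = {}
    for ax, pattern in _OME_SIZE_RE.items():
        m = pattern.search(xml)
        if m:
            sizes[ax] = float(m.group(1))
    if not sizes:
        return None
    return (sizes.get("Z", 1.0), sizes.get("Y", 1.0), sizes.get("X", 1.0))


def read_stack(
    path: str | Path,
    spacing: Sequence[float] | None = None,
    group: str = "",
    cell_id: str | None = None,
    channel: int | None = None,
) -> ImageStack:
    """Read a single-channel TIFF / OME-TIFF z-stack.

    2D images are promoted to one-layer stacks. Multi-page TIFF pages are
    interpreted as z-layers. For multi-channel files a ``channel`` index is
    required; RGB files are rejected because the quantitative signal is
    ambiguous. OME voxel-size metadata is used only when the ``spacing``
    argument is not given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        axes = series.axes.upper()
        data = series.asarray()
        if "S" in axes:
            raise ValueError(f"{path}: RGB/multi-sample TIFF not supported")
        if "C" in axes:
            if channel is None:
                raise ValueError(f"{path}: multi-channel file requires a channel index")
            data = np.take(data, channel, axis=axes.index("C"))
            axes = axes.replace("C", "")
        # collapse singleton leading axes (T, Q, ...) beyond ZYX
        while data.ndim > 3 and data.shape[0] == 1:
            data = data[0]
        if data.ndim > 3:
            raise ValueError(f"{path}: cannot interpret axes {series.axes} as a z-stack")
        meta_spacing = _ome_spacing(tif)
    if spacing is None:
        spacing = meta_spacing if meta_spacing is not None else (1.0, 1.0, 1.0)
    if cell_id is None:
        cell_id = path.stem
    return ImageStack(data=data, spacing=tuple(spacing), cell_id=cell_id, group=group)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as OME-TIFF with voxel spacing in the metadata.

    Integer data round-trips bit-exactly; float data within dtype precision.
    """
    path = Path(path)
    dz, dy, dx = stack.spacing
    tifffile.imwrite(
        path,
        stack.data,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "ZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeY": dy,
            "PhysicalSizeX": dx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
        },
    )


def write_table(
    records: Iterable[Mapping[str, object]],
    path: str | Path,
    columns: Sequence[str] | None = None,
    float_format: str = "%.12g",
) -> None:
    """Write records as CSV with a header row and deterministic column order.

    Column order is taken from ``columns`` or, failing that, from the first
    record. Floats are rendered with at least 9 significant digits.
    """
    records = list(records)
    if columns is None:
        columns = list(records[0].keys()) if records else []
    df = pd.DataFrame.from_records(records, columns=list(columns))
    df.to_csv(path, index=False, float_format=float_format)


def write_json(obj: Mapping[str, object], path: str | Path) -> None:
    """Write run metadata / model parameters as pretty-printed JSON."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=False, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
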