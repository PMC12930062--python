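"""Calibrated multi-channel stack I/O and tabular output.

Owns the coordinate and calibration conventions used by every other module:
arrays are indexed ``(z, y, x)``, 0-based, with half-open physical extents
``[0, n*d)`` in micrometres. Intensities are kept in native units until
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "VoxelGrid",
    "StackMeta",
    "TwoChannelStack",
    "read_stack",
    "write_stack",
    "write_table",
    "read_table",
    "IMAGE_SUMMARY_COLUMNS",
]

#: Default acquisition geometry (µm): confocal z-step 0.30 µm, 60.13 nm pixels.
DEFAULT_VOXEL_SIZE = (0.30, 0.06013, 0.06013)

#: Schema of the per-image summary table emitted by the pipeline.
IMAGE_SUMMARY_COLUMNS = [
    "image_id",
    "n_pre",
    "n_post",
    "n_coloc",
    "mean_intensity_pre",
    "mean_intensity_post",
    "coloc_volume_total",
]

VALID_ROIS = ("MO", "VO")
VALID_HEMISPHERES = ("left", "right")


@dataclass(frozen=True)
class VoxelGrid:
    """A calibrated non-negative 3D intensity array, indexed ``(z, y, x)``.

    Parameters
    ----------
    values
        Intensity per voxel, shape ``(nz, ny, nx)``, finite and >= 0.
    dz, dy, dx
        Voxel edge lengths in micrometres, all > 0.
    """

    values: np.ndarray
    dz: float
    dy: float
    dx: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(
                f"VoxelGrid requires a 3D (z, y, x) array, got ndim={values.ndim}"
            )
        if values.size == 0:
            raise ValueError("VoxelGrid requires nz, ny, nx >= 1")
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError(f"VoxelGrid requires numeric values, got {values.dtype}")
        if not np.all(np.isfinite(values)):
            raise ValueError("VoxelGrid intensities must be finite")
        if np.any(values < 0):
            raise ValueError("VoxelGrid intensities must be >= 0")
        for name in ("dz", "dy", "dx"):
            d = getattr(self, name)
            if not (np.isfinite(d) and d > 0):
                raise ValueError(f"voxel size {name}={d!r} must be finite and > 0")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def nz(self) -> int:
        return self.values.shape[0]

    @property
    def ny(self) -> int:
        return self.values.shape[1]

    @property
    def nx(self) -> int:
        return self.values.shape[2]

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        """(dz, dy, dx) in µm."""
        return (self.dz, self.dy, self.dx)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return self.dz * self.dy * self.dx

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical (z, y, x) extent in µm, half-open."""
        return (self.nz * self.dz, self.ny * self.dy, self.nx * self.dx)

    def with_values(self, values: np.ndarray) -> "VoxelGrid":
        """Same calibration, new intensity array."""
        return replace(self, values=values)


@dataclass(frozen=True)
class StackMeta:
    """Provenance of one acquired image: which mouse, group, ROI, hemisphere,
    section it came from. ``hemisphere``/``section`` may be None (the image is
    then treated as one of the available replicates during aggregation)."""

    mouse: str = ""
    group: str = ""
    roi: str | None = None
    hemisphere: str | None = None
    section: int | None = None
    image_id: str = ""

    def __post_init__(self) -> None:
        if self.roi is not None and self.roi not in VALID_ROIS:
            raise ValueError(f"roi must be one of {VALID_ROIS}, got {self.roi!r}")
        if self.hemisphere is not None and self.hemisphere not in VALID_HEMISPHERES:
            raise ValueError(
                f"hemisphere must be one of {VALID_HEMISPHERES}, got {self.hemisphere!r}"
            )

    @property
    def is_complete(self) -> bool:
        """True when hemisphere and section are both recorded."""
        return self.hemisphere is not None and self.section is not None


@dataclass(frozen=True)
class TwoChannelStack:
    """A registered pre-synaptic (vGluT1) / post-synaptic (Homer1) image pair.

    Both channels must share dimensions and voxel calibration.
    """

    pre: VoxelGrid
    post: VoxelGrid
    meta: StackMeta = field(default_factory=StackMeta)

    def __post_init__(self) -> None:
        if self.pre.shape != self.post.shape:
            raise ValueError(
                f"channel shape mismatch: pre {self.pre.shape} vs post {self.post.shape}"
            )
        if self.pre.voxel_size != self.post.voxel_size:
            raise ValueError(
                "channel voxel-size mismatch: "
                f"pre {self.pre.voxel_size} vs post {self.post.voxel_size}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pre.shape

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return self.pre.voxel_size


# ---------------------------------------------------------------------------
# OME-TIFF stack I/O


def write_stack(stack: TwoChannelStack, path: str | Path) -> Path:
    """Write a two-channel stack as OME-TIFF with axes CZYX and µm calibration.

    Voxel sizes are stored in the OME physical-size fields; channel 0 is the
    pre-synaptic channel, channel 1 the post-synaptic one.
    """
    path = Path(path)
    data = np.stack([stack.pre.values, stack.post.values], axis=0)
    dz, dy, dx = stack.voxel_size
    meta = stack.meta
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": dz,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": ["pre", "post"]},
        },
        description=None,
    )
    return path


def _ome_voxel_size(tf: tifffile.TiffFile) -> tuple[float, float, float] | None:
    """Extract (dz, dy, dx) in µm from OME metadata, or None if absent."""
    if not tf.ome_metadata:
        return None
    try:
        omd = tifffile.xml2dict(tf.ome_metadata)
        image = omd["OME"]["Image"]
        if isinstance(image, list):
            image = image[0]
        pixels = image["Pixels"]
        dz = float(pixels["PhysicalSizeZ"])
        dy = float(pixels["PhysicalSizeY"])
        dx = float(pixels["PhysicalSizeX"])
    except (KeyError, TypeError, ValueError):
        return None
    for d in (dz, dy, dx):
        if not (np.isfinite(d) and d > 0):
            return None
    # OME defaults to µm; honour an explicit nm unit if present.
    units = {
        ax: pixels.get(f"PhysicalSize{ax}Unit", "µm") for ax in ("Z", "Y", "X")
    }
    scale = {"µm": 1.0, "um": 1.0, "micron": 1.0, "nm": 1e-3, "mm": 1e3}
    try:
        dz *= scale[units["Z"]]
        dy *= scale[units["Y"]]
        dx *= scale[units["X"]]
    except KeyError:
        return None
    return dz, dy, dx


def read_stack(
    path: str | Path,
    channel_map: Mapping[str, int] | None = None,
    meta: StackMeta | None = None,
    voxel_size: tuple[float, float, float] | None = None,
) -> TwoChannelStack:
    """Read a two-channel OME-TIFF/TIFF stack.

    Parameters
    ----------
    path
        TIFF file with at least two channels (axes CZYX or ZCYX).
    channel_map
        Maps the channel names ``"pre"`` and ``"post"`` to channel indices.
        Defaults to ``{"pre": 0, "post": 1}``.
    meta
        Image provenance; defaults to an empty record with the file stem as
        image id.
    voxel_size
        Explicit (dz, dy, dx) in µm. Required when the file carries no
        calibration; never silently defaulted.

    Raises
    ------
    ValueError
        Fewer than two channels, channel shape mismatch, or missing voxel
        calibration.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    channel_map = dict(channel_map) if channel_map else {"pre": 0, "post": 1}
    for key in ("pre", "post"):
        if key not in channel_map:
            raise ValueError(f"channel_map requires a {key!r} entry")

    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        file_voxel = _ome_voxel_size(tf)

    # Normalise to (C, Z, Y, X).
    if axes == "CZYX":
        pass
    elif axes == "ZCYX":
        data = np.moveaxis(data, 1, 0)
    elif axes in ("ZYX", "YX") or data.ndim < 4:
        raise ValueError(
            f"stack at {path} requires two channels, found axes {axes!r}"
        )
    else:
        raise ValueError(f"unsupported axis order {axes!r} (expected CZYX)")

    n_channels = data.shape[0]
    if n_channels < 2:
        raise ValueError(f"stack at {path} requires two channels, found {n_channels}")
    for name, idx in channel_map.items():
        if not 0 <= idx < n_channels:
            raise ValueError(f"channel_map[{name!r}]={idx} out of range 0..{n_channels - 1}")

    vs = voxel_size if voxel_size is not None else file_voxel
    if vs is None:
        raise ValueError(
            f"no voxel calibration in {path}; pass voxel_size=(dz, dy, dx) in µm"
        )
    dz, dy, dx = vs

    pre = VoxelGrid(np.asarray(data[channel_map["pre"]]), dz=dz, dy=dy, dx=dx)
    post = VoxelGrid(np.asarray(data[channel_map["post"]]), dz=dz, dy=dy, dx=dx)
    if meta is None:
        meta = StackMeta(image_id=path.stem)
    return TwoChannelStack(pre=pre, post=post, meta=meta)


# ---------------------------------------------------------------------------
# Tables


def write_table(records: pd.DataFrame, path: str | Path) -> Path:
    """Write a table as UTF-8 CSV with header and '.' decimal.

    Numeric fields round-trip at full precision (float64 via repr). A zero-row
    frame writes its header only; a frame with no columns is rejected.
    """
    if records.shape[1] == 0:
        raise ValueError("refusing to write a table with no columns")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, index=False, encoding="utf-8", float_format=None)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
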