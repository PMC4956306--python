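"""Image and table I/O with explicit physical calibration.

All geometry in this package is done in physical micrometres.  The
convention, fixed here once, is that the physical centre of the voxel with
0-based index ``i`` along an axis with spacing ``s`` lies at ``(i + 0.5) * s``.
Stacks are held in memory in ``(channel, Z, Y, X)`` order regardless of the
axis order on disk.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "DatasetManifest",
    "read_stack",
    "write_stack",
    "load_manifest",
    "CalibrationMissingError",
    "ManifestError",
]

#: Channel names treated as nuclear/DNA counterstains rather than SAC signal.
DNA_CHANNEL_NAMES = frozenset({"DNA", "DAPI", "H2B", "SYTO13"})


class CalibrationMissingError(ValueError):
    """Raised when a stack carries no voxel-size metadata and none is supplied."""


class ManifestError(ValueError):
    """Raised for structurally invalid dataset manifests."""


@dataclass
class ImageStack:
    """A multi-channel 3D intensity grid with physical voxel size.

    Parameters
    ----------
    intensities
        Non-negative array of shape ``(C, Z, Y, X)``.
    voxel_size_um
        ``(z, y, x)`` spacing in micrometres; all entries positive.
    channel_names
        Ordered unique labels, one per channel.  For quantification the
        stack must contain a channel named ``"CREST"`` (the kinetochore
        reference) and exactly one SAC channel (any channel that is neither
        CREST nor a DNA counterstain).
    """

    intensities: np.ndarray
    voxel_size_um: tuple[float, float, float]
    channel_names: tuple[str, ...]
    cell_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 4:
            raise ValueError(
                f"intensities must be (C, Z, Y, X); got shape {self.intensities.shape}"
            )
        if self.intensities.shape[0] < 2:
            raise ValueError("an ImageStack needs at least 2 channels")
        if any(d < 1 for d in self.intensities.shape[1:]):
            raise ValueError("every spatial axis must have extent >= 1")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)  # type: ignore[assignment]
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError(f"voxel_size_um must be 3 positive floats, got {self.voxel_size_um}")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.intensities.shape[0]:
            raise ValueError("one channel name per channel is required")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError(f"channel names must be unique, got {self.channel_names}")

    # -- convenience accessors -------------------------------------------------

    @property
    def shape_vox(self) -> tuple[int, int, int]:
        """Spatial grid shape ``(Z, Y, X)``."""
        return self.intensities.shape[1:]

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size ``(z, y, x)`` of the grid in micrometres."""
        return tuple(n * s for n, s in zip(self.shape_vox, self.voxel_size_um))

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's 3D array by name."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in stack (has {self.channel_names})"
            ) from None
        return self.intensities[idx]

    @property
    def sac_channel_name(self) -> str:
        """The unique channel that is neither CREST nor a DNA counterstain."""
        candidates = [
            c
            for c in self.channel_names
            if c != "CREST" and c.upper() not in DNA_CHANNEL_NAMES
        ]
        if len(candidates) != 1:
            raise ValueError(
                f"expected exactly one SAC channel, found {candidates} in {self.channel_names}"
            )
        return candidates[0]


# ---------------------------------------------------------------------------
# TIFF round trip
# ---------------------------------------------------------------------------


def write_stack(path: str | Path, stack: ImageStack) -> Path:
    """Write a stack as OME-TIFF with voxel size and channel names in metadata."""
    path = Path(path)
    data = np.ascontiguousarray(stack.intensities)
    dz, dy, dx = stack.voxel_size_um
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": list(stack.channel_names)},
        },
    )
    return path


def _parse_ome_calibration(ome_xml: str) -> tuple[tuple[float, float, float] | None, list[str]]:
    """Extract ``(z, y, x)`` voxel size and channel names from OME-XML."""
    root = ET.fromstring(ome_xml)
    ns = {"ome": root.tag.split("}")[0].strip("{")} if "}" in root.tag else {}
    pixels = root.find(".//ome:Pixels" if ns else ".//Pixels", ns)
    if pixels is None:
        return None, []
    names = [
        ch.get("Name") or f"ch{i}"
        for i, ch in enumerate(pixels.findall("ome:Channel" if ns else "Channel", ns))
    ]
    sizes = tuple(pixels.get(f"PhysicalSize{ax}") for ax in "ZYX")
    if any(s is None for s in sizes):
        return None, names
    return tuple(float(s) for s in sizes), names  # type: ignore[return-value]


def read_stack(
    path: str | Path,
    voxel_size_override: tuple[float, float, float] | None = None,
    channel_names: Sequence[str] | None = None,
    cell_id: str = "",
    condition: str = "",
) -> ImageStack:
    """Read a TIFF/OME-TIFF stack, normalising axes to ``(C, Z, Y, X)``.

    Voxel size is taken from OME metadata unless ``voxel_size_override`` is
    given; a plain TIFF without calibration and without an override raises
    :class:`CalibrationMissingError` rather than assuming a default.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes  # e.g. 'CZYX', 'ZCYX', 'QYX'
        voxel_size = None
        meta_channels: list[str] = []
        if tif.ome_metadata:
            voxel_size, meta_channels = _parse_ome_calibration(tif.ome_metadata)

    # normalise axis order to (C, Z, Y, X)
    if data.ndim != 4:
        raise ValueError(
            f"{path}: need a 4D (C,Z,Y,X)-like stack with >= 2 channels, got shape {data.shape}"
        )
    if sorted(axes) == sorted("CZYX"):
        order = [axes.index(ax) for ax in "CZYX"]
        data = np.transpose(data, order)
    # otherwise (plain TIFF with unlabeled axes) assume on-disk (C, Z, Y, X)

    if voxel_size_override is not None:
        voxel_size = tuple(float(v) for v in voxel_size_override)
    if voxel_size is None:
        raise CalibrationMissingError(
            f"{path}: no voxel-size calibration in metadata and no override given"
        )
    names = tuple(channel_names) if channel_names is not None else tuple(meta_channels)
    if len(names) != data.shape[0]:
        names = tuple(f"ch{i}" for i in range(data.shape[0]))
    return ImageStack(
        intensities=data,
        voxel_size_um=voxel_size,  # type: ignore[arg-type]
        channel_names=names,
        cell_id=cell_id,
        condition=condition,
    )


# ---------------------------------------------------------------------------
# Dataset manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("cell_id", "path", "condition", "qualifies")


@dataclass
class DatasetManifest:
    """Table of cells: id, stack path, condition label, quantification flag.

    The ``qualifies`` flag encodes the inclusion rule applied upstream (only
    properly congressed metaphase cells arrested long enough are quantified);
    non-qualifying rows are retained for bookkeeping but excluded downstream.
    """

    table: pd.DataFrame
    control_condition: str = "control"
    base_dir: Path = field(default_factory=Path)

    @property
    def qualifying(self) -> pd.DataFrame:
        return self.table[self.table["qualifies"]]

    def resolve_path(self, row: pd.Series) -> Path:
        p = Path(row["path"])
        return p if p.is_absolute() else self.base_dir / p


def load_manifest(
    path: str | Path,
    control_condition: str = "control",
    check_paths: bool = True,
) -> DatasetManifest:
    """Load and validate a CSV manifest (columns: cell_id, path, condition, qualifies)."""
    path = Path(path)
    table = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in table.columns]
    if missing:
        raise ManifestError(f"{path}: missing manifest columns {missing}")
    dupes = table["cell_id"][table["cell_id"].duplicated()].unique().tolist()
    if dupes:
        raise ManifestError(f"{path}: duplicate cell_id(s) {dupes}")
    if not (table["condition"] == control_condition).any():
        raise ManifestError(
            f"{path}: no row with control condition {control_condition!r}"
        )
    table = table.copy()
    table["qualifies"] = table["qualifies"].astype(bool)
    manifest = DatasetManifest(
        table=table, control_condition=control_condition, base_dir=path.parent
    )
    if check_paths:
        for _, row in table.iterrows():
            p = manifest.resolve_path(row)
            if not p.exists():
                raise ManifestError(f"{path}: stack file not found: {p}")
    return manifest
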