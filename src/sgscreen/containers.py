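"""Core in-memory containers: imaged fields and segmentation label sets.

A :class:`FieldImage` holds one multi-channel 2D field. Channels are named:
``nuclei`` (Hoechst nuclear stain), ``venus`` (Venus-FUS reporter) and
``mcherry`` (mCherry-G3BP1 reporter). A :class:`LabelSet` holds the integer
label maps produced by segmentation plus the granule-to-cell linkage table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

#: canonical channel order used for multi-page TIFF round-trips
CHANNELS = ("nuclei", "venus", "mcherry")

#: reporter channels carrying granules
REPORTER_CHANNELS = ("venus", "mcherry")


@dataclass
class FieldImage:
    """One imaged field: per-channel 2D intensity grids plus metadata.

    Parameters
    ----------
    channels
        Mapping of channel name to a 2D intensity array. All channels must
        share one shape and be non-negative.
    well_id, field_id
        Identifiers of the source well and field within the well.
    px_size
        Pixel size in micrometres per pixel.
    """

    channels: dict[str, np.ndarray]
    well_id: str = ""
    field_id: str = "f1"
    px_size: float = 0.65

    def __post_init__(self) -> None:
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels must share one shape, got {shapes}")
        for name, arr in self.channels.items():
            arr = np.asarray(arr)
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2D")
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} has negative intensities")
            self.channels[name] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def to_tiff(self, path: str | Path) -> None:
        """Write the field as a multi-page TIFF, one page per channel.

        Pages follow :data:`CHANNELS` order; intensities are stored as
        16-bit unsigned integers (values are clipped to the uint16 range).
        """
        pages = [
            np.clip(np.rint(self.channels[c]), 0, 65535).astype(np.uint16)
            for c in CHANNELS
            if c in self.channels
        ]
        tifffile.imwrite(str(path), np.stack(pages), photometric="minisblack")

    @classmethod
    def from_tiff(
        cls,
        path: str | Path,
        well_id: str = "",
        field_id: str = "f1",
        px_size: float = 0.65,
    ) -> "FieldImage":
        stack = tifffile.imread(str(path))
        if stack.ndim == 2:
            stack = stack[None]
        if stack.shape[0] > len(CHANNELS):
            raise ValueError(f"expected <= {len(CHANNELS)} pages, got {stack.shape[0]}")
        channels = {c: stack[i].astype(np.float64) for i, c in enumerate(CHANNELS[: stack.shape[0]])}
        return cls(channels=channels, well_id=well_id, field_id=field_id, px_size=px_size)


@dataclass
class LabelSet:
    """Integer label maps for one field plus the cell-granule linkage.

    Label 0 is background everywhere. ``cell`` labels coincide with the
    label of the nucleus each cell contains, so nucleus *i* always lies
    inside cell *i*. ``granules`` maps each reporter channel name to a
    granule label map; ``linkage`` is one table over all channels with
    columns ``granule_id, channel, cell_id, in_nucleus, area_px``
    (``cell_id`` 0 means the granule was majority-background and is
    excluded from per-cell sums).
    """

    nuclear_center: np.ndarray
    nucleus: np.ndarray
    cell: np.ndarray
    granules: dict[str, np.ndarray] = field(default_factory=dict)
    linkage: pd.DataFrame | None = None

    def write_tiffs(self, directory: str | Path, stem: str) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, arr in [
            ("nuclear_center", self.nuclear_center),
            ("nucleus", self.nucleus),
            ("cell", self.cell),
        ]:
            tifffile.imwrite(str(directory / f"{stem}_{name}.tif"), arr.astype(np.uint16))
        for chan, arr in self.granules.items():
            tifffile.imwrite(
                str(directory / f"{stem}_granules_{chan}.tif"), arr.astype(np.uint16)
            )
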