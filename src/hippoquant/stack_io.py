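"""Calibrated multi-channel z-stack I/O.

A :class:`ZStack` holds an ordered set of confocal layers for the three
immunostaining channels (NeuN for neurons, GFAP for astrocytes, IBA1 for
microglia) together with the physical calibration that every downstream
measurement depends on.  Calibration is stored per axis: an ROI of
600 x 400 um rasterised at 1024 x 1024 px is anisotropic, and all physical
quantities (areas, Feret diameters, ring widths) use the per-axis scale.

Coordinate conventions, fixed here and asserted in tests:

* pixel coordinates are 0-based, origin top-left, (row, col) order;
* physical coordinates are in micrometres, ``x`` along columns and ``y``
  along rows;
* rectangles are half-open intervals ``[x, x + width)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
import yaml

#: canonical channel order used on disk and in composites
CHANNELS = ("NeuN", "GFAP", "IBA1")

#: additive RGB primaries used when splitting/merging colour composites
COLOR_VECTORS = {
    "red": (1.0, 0.0, 0.0),
    "green": (0.0, 1.0, 0.0),
    "blue": (0.0, 0.0, 1.0),
    "cyan": (0.0, 1.0, 1.0),
    "magenta": (1.0, 0.0, 1.0),
    "yellow": (1.0, 1.0, 0.0),
}

#: default display colours: green for NeuN, cyan for GFAP, red for IBA1
DEFAULT_COLOR_MAP = {"NeuN": "green", "GFAP": "cyan", "IBA1": "red"}


class CalibrationError(ValueError):
    """No usable pixel/z calibration could be found for a stack."""


@dataclass(frozen=True)
class Calibration:
    """Physical scale of a stack: um per pixel along x and y, um per z step."""

    um_per_px_x: float
    um_per_px_y: float
    z_step_um: float

    def __post_init__(self) -> None:
        if min(self.um_per_px_x, self.um_per_px_y, self.z_step_um) <= 0:
            raise ValueError("calibration must be strictly positive")

    @property
    def px_area_um2(self) -> float:
        return self.um_per_px_x * self.um_per_px_y

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Calibration":
        return cls(
            um_per_px_x=float(d["um_per_px_x"]),
            um_per_px_y=float(d["um_per_px_y"]),
            z_step_um=float(d["z_step_um"]),
        )


@dataclass(frozen=True)
class RoiRect:
    """Axis-aligned physical rectangle, half-open: ``[x, x+width) x [y, y+height)``."""

    x_um: float
    y_um: float
    width_um: float
    height_um: float

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("RoiRect must have positive extent")

    @property
    def area_mm2(self) -> float:
        return self.width_um * self.height_um / 1.0e6


@dataclass
class ZStack:
    """Calibrated multi-channel image stack, array shape ``(layers, channels, H, W)``."""

    data: np.ndarray
    channels: tuple[str, ...]
    calibration: Calibration
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("ZStack data must be 4-D (layers, channels, H, W)")
        if self.data.shape[0] < 1:
            raise ValueError("ZStack needs at least one layer")
        if len(self.channels) != self.data.shape[1]:
            raise ValueError(
                f"channel names {self.channels} do not match data with "
                f"{self.data.shape[1]} channels"
            )
        self.channels = tuple(self.channels)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_layers(self) -> int:
        return self.data.shape[0]

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    @property
    def height_um(self) -> float:
        return self.data.shape[2] * self.calibration.um_per_px_y

    @property
    def width_um(self) -> float:
        return self.data.shape[3] * self.calibration.um_per_px_x

    @property
    def area_mm2(self) -> float:
        return self.height_um * self.width_um / 1.0e6

    def channel(self, name: str) -> np.ndarray:
        """All layers of one named channel, shape ``(layers, H, W)``."""
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channels}")
        return self.data[:, idx]

    def layer(self, layer_index: int, name: str) -> np.ndarray:
        return self.channel(name)[layer_index]

    def projection(self, name: str) -> np.ndarray:
        """Maximum-intensity projection of one channel over z."""
        return self.channel(name).max(axis=0)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def write_stack(stack: ZStack, path: str | Path, sidecar: str | Path | None = None) -> Path:
    """Write a stack as a multi-page TIFF (ZCYX page order) plus optional sidecar.

    Calibration and channel names are embedded in the TIFF's shaped metadata
    so that :func:`read_stack` round-trips without external files; a YAML
    sidecar can additionally be written for interoperability.
    """
    path = Path(path)
    meta = {
        "axes": "ZCYX",
        "channels": list(stack.channels),
        "calibration": stack.calibration.to_dict(),
    }
    tifffile.imwrite(path, stack.data, metadata=meta)
    if sidecar is not None:
        write_calibration(stack.calibration, sidecar, channels=stack.channels)
    return path


def write_calibration(
    calibration: Calibration, path: str | Path, channels: tuple[str, ...] = CHANNELS
) -> Path:
    path = Path(path)
    payload = {"calibration": calibration.to_dict(), "channels": list(channels)}
    text = (
        json.dumps(payload, indent=2)
        if path.suffix == ".json"
        else yaml.safe_dump(payload)
    )
    path.write_text(text)
    return path


def read_calibration(path: str | Path) -> tuple[Calibration, list[str] | None]:
    raw = Path(path).read_text()
    payload = json.loads(raw) if str(path).endswith(".json") else yaml.safe_load(raw)
    cal = Calibration.from_dict(payload["calibration"] if "calibration" in payload else payload)
    return cal, payload.get("channels")


def read_stack(
    path: str | Path,
    calibration: Calibration | None = None,
    sidecar: str | Path | None = None,
    channels: tuple[str, ...] | None = None,
) -> ZStack:
    """Read a TIFF/OME-TIFF stack written by :func:`write_stack` or compatible.

    Calibration resolution order: explicit argument > sidecar file > metadata
    embedded in the TIFF.  If none is available this raises
    :class:`CalibrationError` rather than guessing.  The file must carry three
    channels, or an explicit ``channels`` naming must be supplied.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}

    sidecar_channels = None
    if calibration is None and sidecar is not None:
        calibration, sidecar_channels = read_calibration(sidecar)
    if calibration is None and "calibration" in meta:
        calibration = Calibration.from_dict(meta["calibration"])
    if calibration is None:
        raise CalibrationError(
            f"{path}: no calibration supplied, in sidecar, or embedded in the file"
        )

    if channels is None:
        channels = meta.get("channels") or sidecar_channels
    if data.ndim == 3:
        # single-channel z-series or single-layer multi-channel: ambiguous,
        # resolve only when a channel naming pins it down
        if channels is not None and data.shape[0] == len(channels):
            data = data[np.newaxis, ...]
        else:
            data = data[:, np.newaxis, ...]
            channels = channels or ("channel0",)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a (Z, C, Y, X) stack, got shape {data.shape}")
    if channels is None:
        if data.shape[1] == len(CHANNELS):
            channels = CHANNELS
        else:
            raise ValueError(
                f"{path}: {data.shape[1]} channels and no channel mapping supplied"
            )
    if len(channels) != data.shape[1]:
        raise ValueError(
            f"{path}: channel mapping {channels} does not match {data.shape[1]} channels"
        )
    return ZStack(
        data=data,
        channels=tuple(channels),
        calibration=calibration,
        provenance={"source": str(path), "crop_offset_px": (0, 0)},
    )


# ---------------------------------------------------------------------------
# RGB composite splitting / merging
# ---------------------------------------------------------------------------

def _color_matrix(color_map: dict[str, str], channels: tuple[str, ...]) -> np.ndarray:
    rows = []
    for name in channels:
        try:
            rows.append(COLOR_VECTORS[color_map[name]])
        except KeyError:
            raise KeyError(f"no display colour configured for channel {name!r}")
    mat = np.array(rows, dtype=float)
    if abs(np.linalg.det(mat)) < 1e-12:
        raise ValueError(f"colour mapping {color_map} is not invertible")
    return mat


def split_rgb(
    rgb: np.ndarray, color_map: dict[str, str] | None = None,
    channels: tuple[str, ...] = CHANNELS,
) -> np.ndarray:
    """Unmix an additive RGB composite into named stain channels.

    ``rgb`` has shape ``(..., 3)``; the result has shape ``(len(channels), ...)``.
    The default mapping is the display convention green=NeuN, cyan=GFAP,
    red=IBA1, which is linearly invertible, so ``merge_rgb(split_rgb(x)) == x``.
    """
    color_map = color_map or DEFAULT_COLOR_MAP
    mat = _color_matrix(color_map, channels)
    unmixed = np.asarray(rgb, dtype=float) @ np.linalg.inv(mat)
    return np.moveaxis(unmixed, -1, 0)


def merge_rgb(
    channel_data: np.ndarray, color_map: dict[str, str] | None = None,
    channels: tuple[str, ...] = CHANNELS,
) -> np.ndarray:
    """Inverse of :func:`split_rgb`: compose channel rasters into an RGB image."""
    color_map = color_map or DEFAULT_COLOR_MAP
    mat = _color_matrix(color_map, channels)
    return np.moveaxis(np.asarray(channel_data, dtype=float), 0, -1) @ mat


# ---------------------------------------------------------------------------
# cropping
# ---------------------------------------------------------------------------

def crop_roi(stack: ZStack, rect: RoiRect) -> ZStack:
    """Crop a physical rectangle out of a stack.

    Edges are converted um -> px by rounding to the nearest pixel boundary
    (exact when the rect is aligned to the pixel grid); the crop offset is
    recorded in provenance so physical coordinates can be mapped back.
    """
    cal = stack.calibration
    c0 = int(round(rect.x_um / cal.um_per_px_x))
    c1 = int(round((rect.x_um + rect.width_um) / cal.um_per_px_x))
    r0 = int(round(rect.y_um / cal.um_per_px_y))
    r1 = int(round((rect.y_um + rect.height_um) / cal.um_per_px_y))
    h, w = stack.shape_px
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(
            f"crop {rect} -> rows {r0}:{r1}, cols {c0}:{c1} outside raster {h}x{w}"
        )
    prev = stack.provenance.get("crop_offset_px", (0, 0))
    return ZStack(
        data=stack.data[:, :, r0:r1, c0:c1].copy(),
        channels=stack.channels,
        calibration=cal,
        provenance={
            **stack.provenance,
            "crop_offset_px": (prev[0] + r0, prev[1] + c0),
        },
    )


# ---------------------------------------------------------------------------
# QC overlays
# ---------------------------------------------------------------------------

def render_overlay(
    stack: ZStack,
    contours: list[np.ndarray],
    channel: str | None = None,
    color_map: dict[str, str] | None = None,
    contour_color: tuple[int, int, int] = (255, 255, 0),
) -> np.ndarray:
    """Render a maximum-intensity projection with contour outlines burned in.

    ``contours`` are closed pixel polygons in (row, col) coordinates of this
    stack.  With ``channel`` given, only that channel is projected (grey-level
    to RGB); otherwise all channels are merged with the display colours.
    Returns a uint8 RGB array.
    """
    from skimage.draw import polygon_perimeter

    h, w = stack.shape_px
    if channel is not None:
        proj = stack.projection(channel)
        lo, hi = float(proj.min()), float(proj.max())
        scaled = (proj - lo) / (hi - lo) if hi > lo else np.zeros_like(proj)
        img = np.repeat(scaled[..., np.newaxis], 3, axis=-1)
    else:
        projs = np.stack([stack.projection(c) for c in stack.channels])
        lo, hi = float(projs.min()), float(projs.max())
        scaled = (projs - lo) / (hi - lo) if hi > lo else np.zeros_like(projs)
        img = np.clip(merge_rgb(scaled, color_map, stack.channels), 0, 1)
    img8 = (img * 255).astype(np.uint8)

    for contour in contours:
        contour = np.asarray(contour)
        rr_in = np.round(contour[:, 0]).astype(int)
        cc_in = np.round(contour[:, 1]).astype(int)
        if rr_in.min() < 0 or cc_in.min() < 0 or rr_in.max() >= h or cc_in.max() >= w:
            raise ValueError("contour outside raster bounds")
        rr, cc = polygon_perimeter(rr_in, cc_in, shape=(h, w))
        img8[rr, cc] = contour_color
    return img8


def write_overlay(
    stack: ZStack,
    contours: list[np.ndarray],
    path: str | Path,
    channel: str | None = None,
    color_map: dict[str, str] | None = None,
) -> Path:
    """Write :func:`render_overlay` output to a PNG/TIFF image file."""
    import imageio.v3 as iio

    img = render_overlay(stack, contours, channel=channel, color_map=color_map)
    path = Path(path)
    iio.imwrite(path, img)
    return path
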