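"""Labeled multimaterial build models.

A patterned object is represented the way the planner consumes it: a stack of
:class:`LayerPattern` label grids, each pixel naming the ink that should end
up there, with a physical pixel size in mm. Coordinates are x right, y up,
origin at the lower-left corner of the layer; pixel cells are half-open
``[x, x + px) x [y, y + px)``. Grid row 0 is the bottom row (label images on
disk use the usual top-row-first convention and are flipped on I/O).

Label images are single-channel PNG/PGM files whose integer pixel values map
to ink ids through a JSON sidecar — no RGB inference, so round-trips are
bit-exact. A small JSON geometry dialect (labeled rectangles painted in order
over a background ink) is accepted as an alternative source.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import UnknownLabelError
from .inks import InkSpec

__all__ = [
    "InkPalette",
    "LayerPattern",
    "BuildModel",
    "load_label_grid",
    "save_label_grid",
    "stack_layers",
    "ink_at",
]

_LABEL_DTYPE = "<U16"


@dataclass
class PaletteEntry:
    """One ink in a palette: its spec, display color and image label value."""

    spec: InkSpec
    color: str = "#808080"
    value: int = 0  # integer pixel value in label images


class InkPalette:
    """Ordered map from ink id to :class:`PaletteEntry`.

    Image label values are assigned 1, 2, 3, ... in insertion order unless
    given explicitly; value 0 is reserved for "no ink" in sparse rasters.
    """

    def __init__(self, inks=()):
        self.entries: dict[str, PaletteEntry] = {}
        for ink in inks:
            self.add(ink)

    def add(self, ink: InkSpec, color: str = "#808080", value: int | None = None):
        if ink.ink_id in self.entries:
            raise ValueError(f"duplicate ink id {ink.ink_id!r}")
        if value is None:
            value = len(self.entries) + 1
        if any(e.value == value for e in self.entries.values()):
            raise ValueError(f"duplicate label value {value}")
        self.entries[ink.ink_id] = PaletteEntry(spec=ink, color=color, value=value)
        return self

    def __contains__(self, ink_id: str) -> bool:
        return ink_id in self.entries

    def __getitem__(self, ink_id: str) -> PaletteEntry:
        try:
            return self.entries[ink_id]
        except KeyError:
            raise UnknownLabelError(ink_id) from None

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    def ink_ids(self):
        return list(self.entries)

    def value_map(self) -> dict[int, str]:
        """Map image label value -> ink id."""
        return {e.value: ink_id for ink_id, e in self.entries.items()}

    def spec(self, ink_id: str) -> InkSpec:
        return self[ink_id].spec


@dataclass
class LayerPattern:
    """A single layer: 2D grid of ink-id labels with physical placement.

    ``grid[row, col]`` holds an ink id string; row 0 is at ``origin[1]`` and
    rows increase with y. ``pixel_size`` is isotropic, mm per pixel.
    """

    grid: np.ndarray
    pixel_size: float
    origin: tuple = (0.0, 0.0)
    z: float = 0.0

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=_LABEL_DTYPE)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.grid.ndim != 2 or self.grid.size == 0:
            raise ValueError("grid must be a non-empty 2D array")

    @property
    def shape(self):
        return self.grid.shape

    @property
    def width(self) -> float:
        """Extent along x, mm."""
        return self.grid.shape[1] * self.pixel_size

    @property
    def height(self) -> float:
        """Extent along y, mm."""
        return self.grid.shape[0] * self.pixel_size

    def ink_ids(self):
        """Distinct ink ids present in the grid."""
        return sorted(set(self.grid.ravel().tolist()))

    def validate_against(self, palette: InkPalette):
        """Raise :class:`UnknownLabelError` for any label not in the palette."""
        for ink_id in self.ink_ids():
            if ink_id and ink_id not in palette:
                raise UnknownLabelError(ink_id)

    def __eq__(self, other):
        if not isinstance(other, LayerPattern):
            return NotImplemented
        return (
            self.grid.shape == other.grid.shape
            and bool(np.all(self.grid == other.grid))
            and self.pixel_size == other.pixel_size
            and tuple(self.origin) == tuple(other.origin)
            and self.z == other.z
        )


@dataclass
class BuildModel:
    """An ordered stack of congruent layers separated by ``layer_height``."""

    layers: list
    layer_height: float

    def __post_init__(self):
        if self.layer_height <= 0:
            raise ValueError("layer_height must be > 0")

    def __len__(self):
        return len(self.layers)


def stack_layers(layers, layer_height: float) -> BuildModel:
    """Stack congruent layers into a build, placing layer i at z = i * layer_height."""
    layers = list(layers)
    if not layers:
        raise ValueError("need at least one layer")
    ref = layers[0]
    stacked = []
    for i, layer in enumerate(layers):
        if layer.grid.shape != ref.grid.shape:
            raise ValueError(
                f"layer {i} shape {layer.grid.shape} != layer 0 shape {ref.grid.shape}"
            )
        if layer.pixel_size != ref.pixel_size:
            raise ValueError(f"layer {i} pixel_size differs from layer 0")
        stacked.append(
            LayerPattern(
                grid=layer.grid.copy(),
                pixel_size=layer.pixel_size,
                origin=tuple(ref.origin),
                z=i * layer_height,
            )
        )
    return BuildModel(layers=stacked, layer_height=layer_height)


def ink_at(pattern: LayerPattern, point) -> str:
    """Ink id at physical point (x, y) mm, half-open pixel-cell convention.

    A point exactly on a cell boundary belongs to the cell on its +x/+y side.
    """
    x, y = point
    ox, oy = pattern.origin
    col = int(np.floor((x - ox) / pattern.pixel_size))
    row = int(np.floor((y - oy) / pattern.pixel_size))
    nrows, ncols = pattern.grid.shape
    if not (0 <= col < ncols and 0 <= row < nrows):
        raise ValueError(f"point ({x}, {y}) outside pattern extent")
    return str(pattern.grid[row, col])


def save_label_grid(pattern: LayerPattern, path, palette: InkPalette):
    """Write a pattern as an 8-bit label image plus a JSON sidecar.

    The sidecar (``<path>.json``) records the palette value map, pixel size,
    origin and z so that :func:`load_label_grid` round-trips bit-exactly.
    """
    path = Path(path)
    pattern.validate_against(palette)
    values = np.zeros(pattern.grid.shape, dtype=np.uint8)
    for ink_id in pattern.ink_ids():
        if not ink_id:
            continue
        v = palette[ink_id].value
        if not (0 <= v <= 255):
            raise ValueError(f"label value {v} for {ink_id!r} outside uint8 range")
        values[pattern.grid == ink_id] = v
    # image row 0 is the top scanline; our row 0 is the bottom
    Image.fromarray(values[::-1, :], mode="L").save(path)
    sidecar = {
        "palette": {ink_id: palette[ink_id].value for ink_id in palette},
        "pixel_size_mm": pattern.pixel_size,
        "origin_mm": list(pattern.origin),
        "z_mm": pattern.z,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def load_label_grid(path, pixel_size: float, palette: InkPalette) -> LayerPattern:
    """Load a label image (PNG/PGM + sidecar) or JSON rectangle geometry.

    Every pixel value (or rectangle ink id) must resolve to a palette entry;
    unknown values raise :class:`UnknownLabelError` naming the value.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _load_rect_geometry(path, pixel_size, palette)

    img = Image.open(path)
    values = np.asarray(img)
    if values.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel label image")
    if values.size == 0:
        raise ValueError(f"{path}: empty image")
    values = values[::-1, :]  # back to bottom-row-first

    sidecar_path = Path(str(path) + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        value_map = {int(v): ink_id for ink_id, v in sidecar["palette"].items()}
        origin = tuple(sidecar.get("origin_mm", (0.0, 0.0)))
        z = sidecar.get("z_mm", 0.0)
    else:
        value_map = palette.value_map()
        origin, z = (0.0, 0.0), 0.0

    grid = np.empty(values.shape, dtype=_LABEL_DTYPE)
    for v in np.unique(values):
        ink_id = value_map.get(int(v))
        if ink_id is None or ink_id not in palette:
            raise UnknownLabelError(int(v))
        grid[values == v] = ink_id
    return LayerPattern(grid=grid, pixel_size=pixel_size, origin=origin, z=z)


def _load_rect_geometry(path, pixel_size: float, palette: InkPalette) -> LayerPattern:
    """JSON dialect: background ink plus rectangles painted in listed order.

    Schema: ``{"background": ink_id, "size_mm": [w, h],
    "shapes": [{"ink_id": ..., "rect": [x0, y0, x1, y1]}, ...]}``.
    """
    doc = json.loads(Path(path).read_text())
    bg = doc["background"]
    if bg not in palette:
        raise UnknownLabelError(bg)
    w, h = doc["size_mm"]
    ncols = int(round(w / pixel_size))
    nrows = int(round(h / pixel_size))
    if ncols <= 0 or nrows <= 0:
        raise ValueError("size_mm yields an empty grid at this pixel_size")
    grid = np.full((nrows, ncols), bg, dtype=_LABEL_DTYPE)
    xc = (np.arange(ncols) + 0.5) * pixel_size
    yc = (np.arange(nrows) + 0.5) * pixel_size
    for shape in doc.get("shapes", ()):
        ink_id = shape["ink_id"]
        if ink_id not in palette:
            raise UnknownLabelError(ink_id)
        x0, y0, x1, y1 = shape["rect"]
        cols = (xc >= x0 - 1e-9) & (xc < x1 - 1e-9)
        rows = (yc >= y0 - 1e-9) & (yc < y1 - 1e-9)
        grid[np.ix_(rows, cols)] = ink_id
    return LayerPattern(grid=grid, pixel_size=pixel_size)
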