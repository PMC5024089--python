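"""G-code emission and a virtual printer for plan verification.

The dialect is a minimal Mach3-compatible subset: ``G21`` (mm) and ``G90``
(absolute) preamble, axes X/Y/Z for the head and A for the plunger, feeds in
mm/min, fixed 4-decimal formatting, ``;`` comments, ``M2`` to end. Aspiration
is a negative A move over a reservoir; deposition is a simultaneous XY move
with a positive A move proportional to the extruded column.

The simulator replays a program against a machine config, tracking the
capillary as a LIFO column of (ink, length) slices: aspiration pushes at the
tip, extrusion pops from the tip. Deposition paints the popped slices onto a
raster one filament-diameter wide, so a build can be checked end-to-end with
:func:`aspireprint.slicer.fidelity` against the original pattern. Ink is
conserved exactly: per ink, deposited + waste = aspirated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import GCodeError, UnderflowError
from .pattern import LayerPattern
from .planner import AspirationPlan, MachineConfig

__all__ = ["GCodeProgram", "DepositionTrace", "emit_gcode", "simulate"]

_EPS = 1e-9
_POS_TOL = 1e-6  # mm tolerance for "head is at a reservoir"


@dataclass
class GCodeProgram:
    """An emitted program: text lines plus dialect metadata."""

    lines: list
    dialect: dict = field(default_factory=lambda: {
        "units": "mm", "mode": "absolute", "axes": "XYZA", "plunger_axis": "A",
    })

    @property
    def text(self) -> str:
        return "\n".join(self.lines) + "\n"

    def save(self, path):
        Path(path).write_text(self.text)
        return path

    @classmethod
    def load(cls, path):
        return cls(lines=Path(path).read_text().splitlines())


@dataclass
class DepositionTrace:
    """What the virtual printer observed: volumes, maps, events.

    Volumes are mm^3; ``maps`` holds one reconstructed :class:`LayerPattern`
    per deposited z, in z order. ``waste_by_reservoir`` logs contamination
    (which reservoir received expelled ink); ``waste_volume`` attributes the
    same ink by what was expelled.
    """

    aspirated_volume: dict = field(default_factory=dict)  # ink -> mm^3
    deposited_volume: dict = field(default_factory=dict)  # ink -> mm^3
    waste_volume: dict = field(default_factory=dict)  # expelled ink -> mm^3
    waste_by_reservoir: dict = field(default_factory=dict)  # reservoir ink -> mm^3
    maps: list = field(default_factory=list)
    events: list = field(default_factory=list)
    tzl_interfaces_um: list = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "aspirated_volume_mm3": self.aspirated_volume,
            "deposited_volume_mm3": self.deposited_volume,
            "waste_volume_mm3": self.waste_volume,
            "waste_by_reservoir_mm3": self.waste_by_reservoir,
            "layers": [lp.z for lp in self.maps],
            "events": self.events,
            "tzl_interfaces_um": self.tzl_interfaces_um,
        }

    def save_report(self, path):
        Path(path).write_text(json.dumps(self.to_json(), indent=1))
        return path


def _fmt(v: float) -> str:
    return f"{v:.4f}"


def emit_gcode(plans, machine: MachineConfig) -> GCodeProgram:
    """Translate aspiration plans into the declared G-code dialect.

    The plunger axis A is absolute: aspiration moves it negative by the
    segment length, waste and deposition move it positive. One deposit line
    carries the synchronized XY traverse and column extrusion at the
    deposition feed.
    """
    lines = [
        "; aspireprint program",
        "G21 ; units: millimeters",
        "G90 ; absolute coordinates",
    ]
    a = 0.0
    for pi, plan in enumerate(plans):
        fil = plan.filament
        lines.append(f"; filament {fil.index} z={_fmt(fil.z)}")
        for step in plan.steps:
            x, y, z = step.target
            if step.kind == "move_to_reservoir":
                lines.append(f"G0 X{_fmt(x)} Y{_fmt(y)} Z{_fmt(z)} ; reservoir {step.ink_id}")
            elif step.kind == "pre_extrude_waste":
                if step.plunger_displacement > 0:
                    a += step.plunger_displacement
                    lines.append(f"G1 A{_fmt(a)} F{step.speed:g} ; waste {step.ink_id}")
            elif step.kind == "aspirate":
                a -= step.plunger_displacement
                lines.append(f"G1 A{_fmt(a)} F{step.speed:g} ; aspirate {step.ink_id}")
            elif step.kind == "move_to_start":
                lines.append(f"G0 X{_fmt(x)} Y{_fmt(y)} Z{_fmt(z)} ; filament start")
            elif step.kind == "deposit":
                a += step.plunger_displacement
                lines.append(
                    f"G1 X{_fmt(x)} Y{_fmt(y)} A{_fmt(a)} F{machine.deposit_feed:g} ; deposit"
                )
            else:
                raise ValueError(f"unknown step kind {step.kind!r}")
    lines.append("M2 ; end program")
    return GCodeProgram(lines=lines)


class _Column:
    """The capillary's ink column: slices from back (index 0) to tip (end)."""

    def __init__(self):
        self.slices = []  # [ink, length_mm]

    @property
    def length(self) -> float:
        return sum(l for _, l in self.slices)

    def push(self, ink: str, length: float):
        self.slices.append([ink, length])

    def pop_tip(self, length: float):
        """Remove ``length`` mm from the tip; returns slices in pop order."""
        if length > self.length + 1e-6:
            raise UnderflowError(
                f"extrusion of {length:g} mm commanded but column holds "
                f"{self.length:g} mm"
            )
        popped, remaining = [], length
        while remaining > _EPS and self.slices:
            ink, l = self.slices[-1]
            take = min(l, remaining)
            popped.append((ink, take))
            if take >= l - _EPS:
                self.slices.pop()
            else:
                self.slices[-1][1] = l - take
            remaining -= take
        return popped


def simulate(source, machine: MachineConfig, grid_resolution: float = 0.1,
             extent=None, origin=(0.0, 0.0)) -> DepositionTrace:
    """Replay a G-code program (or plans) on the virtual printer.

    Parameters
    ----------
    source
        A :class:`GCodeProgram`, raw program text, or a list of
        :class:`~aspireprint.planner.AspirationPlan` (emitted first).
    machine
        Supplies the reservoir map (position -> ink) and capillary geometry.
    grid_resolution
        Pixel size (mm) of the reconstructed label maps.
    extent, origin
        Physical window (width, height) and lower-left corner of the
        reconstruction raster; inferred from the deposit moves when omitted.
    """
    if isinstance(source, (list, tuple)) and (not source or isinstance(source[0], AspirationPlan)):
        source = emit_gcode(source, machine)
    if isinstance(source, str):
        source = GCodeProgram(lines=source.splitlines())

    area = machine.capillary.cross_section_area
    cap_len = machine.capillary.length
    res_positions = {ink: tuple(p) for ink, p in machine.reservoirs.items()}

    trace = DepositionTrace()
    col = _Column()
    x = y = z = a = 0.0
    deposits = []  # (p0, p1, z, popped slices)

    def reservoir_at(px, py, pz):
        for ink, (rx, ry, rz) in res_positions.items():
            if abs(px - rx) < _POS_TOL and abs(py - ry) < _POS_TOL and abs(pz - rz) < _POS_TOL:
                return ink
        return None

    for lineno, raw in enumerate(source.lines, start=1):
        line = raw.split(";", 1)[0].strip()
        if not line:
            continue
        words = line.split()
        cmd = words[0].upper()
        if cmd in ("G21", "G90", "M2", "M30"):
            continue
        if cmd not in ("G0", "G1"):
            raise GCodeError(f"unsupported command {cmd!r}", lineno)
        nx, ny, nz, na = x, y, z, a
        for w in words[1:]:
            letter, val = w[0].upper(), w[1:]
            try:
                v = float(val)
            except ValueError:
                raise GCodeError(f"bad word {w!r}", lineno) from None
            if letter == "X":
                nx = v
            elif letter == "Y":
                ny = v
            elif letter == "Z":
                nz = v
            elif letter == "A":
                na = v
            elif letter == "F":
                pass
            else:
                raise GCodeError(f"unknown axis word {w!r}", lineno)
        da = na - a
        moved_xy = abs(nx - x) > _POS_TOL or abs(ny - y) > _POS_TOL
        if da < -_EPS:
            ink = reservoir_at(nx, ny, nz)
            if ink is None:
                raise GCodeError("aspiration commanded away from any reservoir", lineno)
            col.push(ink, -da)
            if col.length > cap_len + 1e-6:
                raise GCodeError(
                    f"column {col.length:g} mm exceeds capillary {cap_len:g} mm", lineno
                )
            trace.aspirated_volume[ink] = trace.aspirated_volume.get(ink, 0.0) - da * area
            trace.events.append(f"aspirate {-da:.4f} mm of {ink}")
        elif da > _EPS:
            try:
                popped = col.pop_tip(da)
            except UnderflowError as err:
                raise UnderflowError(f"line {lineno}: {err}") from None
            if moved_xy:
                deposits.append(((x, y), (nx, ny), nz, popped))
                for ink, l in popped:
                    trace.deposited_volume[ink] = (
                        trace.deposited_volume.get(ink, 0.0) + l * area
                    )
                trace.events.append(f"deposit {da:.4f} mm column")
            else:
                res_ink = reservoir_at(nx, ny, nz)
                if res_ink is None:
                    raise GCodeError("extrusion outside a reservoir without travel", lineno)
                for ink, l in popped:
                    trace.waste_volume[ink] = trace.waste_volume.get(ink, 0.0) + l * area
                trace.waste_by_reservoir[res_ink] = (
                    trace.waste_by_reservoir.get(res_ink, 0.0) + da * area
                )
                trace.events.append(f"waste {da:.4f} mm into {res_ink} reservoir")
        x, y, z, a = nx, ny, nz, na

    trace.maps = _paint(deposits, machine, grid_resolution, extent, origin)
    return trace


def _paint(deposits, machine, px, extent, origin):
    """Rasterize deposit events into per-layer label maps."""
    if not deposits:
        return []
    d = machine.capillary.inner_diameter
    if extent is None:
        xs, ys = [], []
        for (x0, y0), (x1, y1), _, _ in deposits:
            xs += [x0, x1]
            ys += [y0 - d / 2, y0 + d / 2, y1 - d / 2, y1 + d / 2]
        origin = (min(xs), min(ys))
        extent = (max(xs) - min(xs), max(ys) - min(ys))
    ox, oy = origin
    ncols = max(int(round(extent[0] / px)), 1)
    nrows = max(int(round(extent[1] / px)), 1)
    xc = (np.arange(ncols) + 0.5) * px
    yc = (np.arange(nrows) + 0.5) * px
    layers = {}
    for (x0, y0), (x1, y1), z, slices in deposits:
        if abs(x1 - x0) > _POS_TOL and abs(y1 - y0) > _POS_TOL:
            raise GCodeError("only axis-aligned deposition moves can be painted", 0)
        key = round(z, 6)
        if key not in layers:
            layers[key] = np.full((nrows, ncols), "", dtype="<U16")
        grid = layers[key]
        along_x = abs(x1 - x0) > _POS_TOL
        pos = 0.0
        for ink, length in slices:
            lo_t, hi_t = pos, pos + length
            if along_x:
                sgn = 1.0 if x1 >= x0 else -1.0
                lo = min(x0 + sgn * lo_t, x0 + sgn * hi_t) - ox
                hi = max(x0 + sgn * lo_t, x0 + sgn * hi_t) - ox
                colsel = (xc >= lo - _EPS) & (xc < hi - _EPS)
                rowsel = (yc >= (y0 - oy) - d / 2 - _EPS) & (yc < (y0 - oy) + d / 2 - _EPS)
            else:
                sgn = 1.0 if y1 >= y0 else -1.0
                lo = min(y0 + sgn * lo_t, y0 + sgn * hi_t) - oy
                hi = max(y0 + sgn * lo_t, y0 + sgn * hi_t) - oy
                rowsel = (yc >= lo - _EPS) & (yc < hi - _EPS)
                colsel = (xc >= (x0 - ox) - d / 2 - _EPS) & (xc < (x0 - ox) + d / 2 - _EPS)
            grid[np.ix_(rowsel, colsel)] = ink
            pos += length
    return [
        LayerPattern(grid=layers[k], pixel_size=px, origin=(ox, oy), z=k)
        for k in sorted(layers)
    ]
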