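"""Aspiration sequencing: turn filament segment lists into machine steps.

The dispensing head is a glass capillary (85 mm long, 500 um bore by
default) acting as a LIFO column: inks aspirated later sit nearer the tip
and exit first. A filament whose deposition order is ``s1, s2, ..., sk``
is therefore aspirated in reverse, ``sk, ..., s1``, so that ``s1`` is at
the tip when deposition starts.

The transition zone length (TZL) — the mixed-ink region at each segment
interface — is controlled by two knobs: a small pre-extrusion of the
previously aspirated ink into the next reservoir before each aspiration
(plunger displacement 0-500 um) and the plunger speed (50-100 mm/min;
100 mm/min risks turbulent flow and a much longer mixed zone).

Because the capillary bore equals the deposited filament diameter, plunger
displacement maps 1:1 onto fluid-column length: aspirating a segment means
retracting the plunger by exactly the segment's length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import CapacityError, ReservoirError
from .pattern import BuildModel
from .slicer import FilamentPlan, decompose, reverse_filament

__all__ = [
    "Capillary",
    "TZLPolicy",
    "TZLEstimate",
    "AspirationStep",
    "AspirationPlan",
    "MachineConfig",
    "segment_volume",
    "check_capacity",
    "estimate_tzl",
    "check_plunger_speed",
    "plan_filament",
    "plan_build",
    "load_machine_config",
    "save_machine_config",
]

PLUNGER_SPEED_MIN = 50.0  # mm/min
PLUNGER_SPEED_MAX = 100.0  # mm/min — turbulent-flow threshold
DEFAULT_DEPOSIT_FEED = 150.0  # mm/min
TZL_BASELINE_UM = 50.0  # placeholder calibration: minimum mixed zone
TZL_TURBULENCE_FACTOR = 4.0  # inflation of TZL at the turbulent speed


@dataclass(frozen=True)
class Capillary:
    """Glass capillary geometry. Lengths in mm."""

    length: float = 85.0
    inner_diameter: float = 0.5

    def __post_init__(self):
        if self.length <= 0 or self.inner_diameter <= 0:
            raise ValueError("capillary length and inner_diameter must be > 0")

    @property
    def cross_section_area(self) -> float:
        """Bore cross-section, mm^2 (pi d^2 / 4)."""
        return math.pi * self.inner_diameter ** 2 / 4.0


@dataclass(frozen=True)
class TZLPolicy:
    """Interface-control policy: pre-extrusion displacement and plunger speed."""

    pre_extrusion_um: float = 0.0  # plunger displacement before each re-aspiration
    plunger_speed: float = PLUNGER_SPEED_MIN  # mm/min

    def __post_init__(self):
        if not 0.0 <= self.pre_extrusion_um <= 500.0:
            raise ValueError("pre_extrusion_um must be within [0, 500] um")
        if not PLUNGER_SPEED_MIN <= self.plunger_speed <= PLUNGER_SPEED_MAX:
            raise ValueError(
                f"plunger_speed must be within [{PLUNGER_SPEED_MIN:g}, "
                f"{PLUNGER_SPEED_MAX:g}] mm/min"
            )


@dataclass(frozen=True)
class TZLEstimate:
    """Expected transition-zone length and a flow-homogeneity flag."""

    tzl_um: float
    flag: str  # "homogeneous" | "non-homogeneous" | "millimeter-scale mixing"

    @property
    def homogeneous(self) -> bool:
        return self.flag == "homogeneous"


@dataclass(frozen=True)
class AspirationStep:
    """One machine action in an aspiration/deposition sequence.

    ``kind`` is one of move_to_reservoir, pre_extrude_waste, aspirate,
    move_to_start, deposit. ``plunger_displacement`` is the column length
    moved (mm): positive magnitude; aspirate pulls ink in, waste/deposit
    push it out. ``target`` is the XYZ the head moves to/deposits toward.
    """

    kind: str
    ink_id: str | None = None
    plunger_displacement: float = 0.0
    speed: float = 0.0  # mm/min
    target: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.kind == "aspirate" and self.plunger_displacement <= 0:
            raise ValueError("aspirate displacement must be > 0")
        if self.kind == "pre_extrude_waste" and self.plunger_displacement < 0:
            raise ValueError("waste displacement must be >= 0")


@dataclass
class AspirationPlan:
    """Executable plan for one filament."""

    filament: FilamentPlan
    steps: list
    total_column_length: float  # mm of ink in the capillary at deposit time
    tzl_estimate_um: float  # per-interface expected TZL
    warnings: list = field(default_factory=list)

    def aspirated_inks(self) -> list:
        return [s.ink_id for s in self.steps if s.kind == "aspirate"]

    def deposition_inks(self) -> list:
        return list(reversed(self.aspirated_inks()))


@dataclass
class MachineConfig:
    """Printer description: capillary, reservoir layout, speeds, TZL policy."""

    capillary: Capillary = field(default_factory=Capillary)
    reservoirs: dict = field(default_factory=dict)  # ink_id -> (x, y, z) mm
    reservoir_temperature_C: float = 50.0
    deposit_feed: float = DEFAULT_DEPOSIT_FEED  # mm/min
    travel_feed: float = 1000.0  # mm/min, rapid moves
    tzl: TZLPolicy = field(default_factory=TZLPolicy)
    gap: float = 0.0  # mm between filaments
    orientation: int = 0  # scanline orientation, 0 or 90 degrees

    def reservoir(self, ink_id: str):
        try:
            return tuple(self.reservoirs[ink_id])
        except KeyError:
            raise ReservoirError(ink_id) from None


def segment_volume(length: float, capillary: Capillary) -> float:
    """Aspiration volume (mm^3) of a segment: column length x bore area."""
    if length < 0:
        raise ValueError("length must be >= 0")
    return length * capillary.cross_section_area


def check_capacity(segments, capillary: Capillary) -> float:
    """Total column length (mm) if it fits; :class:`CapacityError` otherwise."""
    total = sum(s.length for s in segments)
    if total > capillary.length + 1e-9:
        raise CapacityError(total_mm=total, capacity_mm=capillary.length)
    return total


def estimate_tzl(policy: TZLPolicy, *, baseline_um: float = TZL_BASELINE_UM,
                 turbulence_factor: float = TZL_TURBULENCE_FACTOR) -> TZLEstimate:
    """Expected transition-zone length for an interface under this policy.

    Model: TZL grows linearly with the pre-extrusion displacement on top of
    a baseline mixed zone, and is inflated by ``turbulence_factor`` at the
    turbulent plunger speed (100 mm/min). The defaults are a declared
    placeholder calibration — observations of the mixed zone are
    qualitative ("several hundreds of micrometers") — and can be replaced
    with a measured table via the keyword arguments.
    """
    tzl = baseline_um + policy.pre_extrusion_um
    if policy.plunger_speed >= PLUNGER_SPEED_MAX:
        tzl *= turbulence_factor
        flag = "millimeter-scale mixing" if tzl >= 1000.0 else "non-homogeneous"
    else:
        flag = "homogeneous"
    return TZLEstimate(tzl_um=tzl, flag=flag)


def check_plunger_speed(speed: float) -> str:
    """Validate a plunger speed: "ok" in [50, 100), "warn" at 100, raise outside.

    100 mm/min is usable but risks turbulent ink flow at the interface,
    hence the warning; speeds outside [50, 100] mm/min (or non-positive)
    are rejected.
    """
    if speed <= 0:
        raise ValueError("plunger speed must be positive")
    if speed < PLUNGER_SPEED_MIN or speed > PLUNGER_SPEED_MAX:
        raise ValueError(
            f"plunger speed {speed:g} mm/min outside [{PLUNGER_SPEED_MIN:g}, "
            f"{PLUNGER_SPEED_MAX:g}]"
        )
    if speed == PLUNGER_SPEED_MAX:
        return "warn"
    return "ok"


def plan_filament(filament: FilamentPlan, capillary: Capillary, tzl: TZLPolicy,
                  reservoirs, *, deposit_feed: float = DEFAULT_DEPOSIT_FEED,
                  filament_index=None) -> AspirationPlan:
    """Build the aspiration/deposition step sequence for one filament.

    Inks are aspirated in reverse deposition order (LIFO column). Before
    every aspiration after the first, the plunger pre-extrudes the policy
    displacement into the new reservoir — expelling a sliver of the
    previously aspirated ink from the tip, which seeds the transition zone
    and is logged as reservoir contamination. Each aspirate retracts the
    plunger by exactly the segment length. The final deposit extrudes the
    remaining column while the head traverses the filament at the
    deposition feed.
    """
    if not filament.segments:
        raise ValueError("filament has no segments")
    check_capacity(filament.segments, capillary)
    reservoirs = dict(reservoirs)
    for seg in filament.segments:
        if seg.ink_id not in reservoirs:
            raise ReservoirError(seg.ink_id, filament_index=filament_index)

    warnings = []
    status = check_plunger_speed(tzl.plunger_speed)
    if status == "warn":
        warnings.append(
            "plunger speed 100 mm/min: turbulent-flow risk, expect extended TZL"
        )
    waste_mm = tzl.pre_extrusion_um / 1000.0
    est = estimate_tzl(tzl)
    if est.flag == "millimeter-scale mixing":
        warnings.append("TZL policy implies millimeter-scale mixing at interfaces")

    steps = []
    asp_order = list(reversed(filament.segments))
    total_waste = 0.0
    for j, seg in enumerate(asp_order):
        res = tuple(reservoirs[seg.ink_id])
        steps.append(AspirationStep(kind="move_to_reservoir", ink_id=seg.ink_id,
                                    speed=0.0, target=res))
        if j > 0 and waste_mm > 0:
            # expels the tip of the column (previous ink) into this reservoir
            steps.append(AspirationStep(kind="pre_extrude_waste",
                                        ink_id=asp_order[j - 1].ink_id,
                                        plunger_displacement=waste_mm,
                                        speed=tzl.plunger_speed, target=res))
            total_waste += waste_mm
        elif j > 0:
            steps.append(AspirationStep(kind="pre_extrude_waste",
                                        ink_id=asp_order[j - 1].ink_id,
                                        plunger_displacement=0.0,
                                        speed=tzl.plunger_speed, target=res))
        steps.append(AspirationStep(kind="aspirate", ink_id=seg.ink_id,
                                    plunger_displacement=seg.length,
                                    speed=tzl.plunger_speed, target=res))
    column = filament.total_length - total_waste
    x0, y0 = filament.start
    xe, ye = _deposition_end(filament)
    steps.append(AspirationStep(kind="move_to_start", speed=0.0,
                                target=(x0, y0, filament.z)))
    steps.append(AspirationStep(kind="deposit", plunger_displacement=column,
                                speed=deposit_feed, target=(xe, ye, filament.z)))
    return AspirationPlan(
        filament=filament,
        steps=steps,
        total_column_length=column,
        tzl_estimate_um=est.tzl_um,
        warnings=warnings,
    )


def _deposition_end(filament: FilamentPlan):
    x0, y0 = filament.start
    sign = -1.0 if getattr(filament, "reversed_direction", False) else 1.0
    if filament.direction == 0:
        return (x0 + sign * filament.total_length, y0)
    return (x0, y0 + sign * filament.total_length)


def plan_build(model: BuildModel, machine: MachineConfig,
               min_segment_length: float = 0.0) -> list:
    """Plan a whole build: decompose each layer, alternate travel direction.

    Filaments are planned layer by layer in lane order; every odd-indexed
    filament is deposited in the reverse travel direction so the head
    serpentines across the layer. Capacity or reservoir errors carry the
    layer/filament index.
    """
    plans = []
    for layer in model.layers:
        filaments = decompose(
            layer,
            filament_diameter=machine.capillary.inner_diameter,
            orientation=machine.orientation,
            gap=machine.gap,
            min_segment_length=min_segment_length,
        )
        for fil in filaments:
            if fil.index % 2 == 1:
                fil = reverse_filament(fil)
            try:
                plans.append(
                    plan_filament(fil, machine.capillary, machine.tzl,
                                  machine.reservoirs,
                                  deposit_feed=machine.deposit_feed,
                                  filament_index=fil.index)
                )
            except CapacityError as err:
                raise CapacityError(err.total_mm, err.capacity_mm) from err
    return plans


# ---------------------------------------------------------------------------
# MachineConfig YAML I/O

def load_machine_config(path) -> MachineConfig:
    """Read a machine YAML (capillary, reservoirs, speeds, tzl sections)."""
    doc = yaml.safe_load(Path(path).read_text())
    cap = doc.get("capillary", {})
    speeds = doc.get("speeds", {})
    tzl_doc = doc.get("tzl", {})
    return MachineConfig(
        capillary=Capillary(
            length=cap.get("length_mm", 85.0),
            inner_diameter=cap.get("inner_diameter_mm", 0.5),
        ),
        reservoirs={k: tuple(v) for k, v in doc.get("reservoirs", {}).items()},
        reservoir_temperature_C=doc.get("temperature_C", 50.0),
        deposit_feed=speeds.get("deposit_feed", DEFAULT_DEPOSIT_FEED),
        travel_feed=speeds.get("travel", 1000.0),
        tzl=TZLPolicy(
            pre_extrusion_um=tzl_doc.get("pre_extrusion_um", 0.0),
            plunger_speed=speeds.get("plunger", PLUNGER_SPEED_MIN),
        ),
        gap=doc.get("gap_mm", 0.0),
        orientation=doc.get("orientation_deg", 0),
    )


def save_machine_config(machine: MachineConfig, path):
    doc = {
        "capillary": {
            "length_mm": machine.capillary.length,
            "inner_diameter_mm": machine.capillary.inner_diameter,
        },
        "reservoirs": {k: list(v) for k, v in machine.reservoirs.items()},
        "temperature_C": machine.reservoir_temperature_C,
        "speeds": {
            "deposit_feed": machine.deposit_feed,
            "plunger": machine.tzl.plunger_speed,
            "travel": machine.travel_feed,
        },
        "tzl": {"pre_extrusion_um": machine.tzl.pre_extrusion_um},
        "gap_mm": machine.gap,
        "orientation_deg": machine.orientation,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
    return path
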