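"""Exception types raised across the planning pipeline."""


class AspirePrintError(Exception):
    """Base class for all package-specific errors."""


class UnknownLabelError(AspirePrintError):
    """A grid value or ink id has no entry in the palette."""

    def __init__(self, label):
        self.label = label
        super().__init__(f"unknown label: {label!r}")


class CapacityError(AspirePrintError):
    """Requested ink column exceeds the capillary length.

    ``overflow_mm`` is the excess column length beyond capacity.
    """

    def __init__(self, total_mm: float, capacity_mm: float):
        self.total_mm = total_mm
        self.capacity_mm = capacity_mm
        self.overflow_mm = total_mm - capacity_mm
        super().__init__(
            f"ink column of {total_mm:g} mm exceeds capillary length "
            f"{capacity_mm:g} mm (overflow {self.overflow_mm:g} mm)"
        )


class ReservoirError(AspirePrintError):
    """An ink required by a plan has no reservoir in the machine config."""

    def __init__(self, ink_id: str, filament_index=None):
        self.ink_id = ink_id
        self.filament_index = filament_index
        where = "" if filament_index is None else f" (filament {filament_index})"
        super().__init__(f"no reservoir configured for ink {ink_id!r}{where}")


class GCodeError(AspirePrintError):
    """Unparseable or unsupported G-code, with the offending line number."""

    def __init__(self, message: str, line_no: int):
        self.line_no = line_no
        super().__init__(f"line {line_no}: {message}")


class UnderflowError(AspirePrintError):
    """Extrusion commanded beyond the ink column held in the capillary."""
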