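"""Scanline decomposition of patterned layers into multimaterial filaments.

A layer is covered by parallel filaments one capillary-diameter wide (plus an
optional gap), each filament a straight scan line along x (orientation 0) or
y (orientation 90). Along each filament centerline the pattern's labels are
run-length encoded into ordered single-ink segments — the unit the aspiration
planner converts into plunger moves. Segment boundaries sit on pixel-cell
boundaries: the label grid is the ground truth and sub-pixel edges are not
resolvable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .pattern import LayerPattern

__all__ = [
    "Segment",
    "FilamentPlan",
    "FidelityReport",
    "decompose",
    "extract_segments",
    "count_switches",
    "fidelity",
    "rasterize_filaments",
    "reverse_filament",
    "filaments_to_json",
]

#: default minimum aspiratable segment length, mm (shorter runs are merged)
DEFAULT_MIN_SEGMENT_MM = 0.5

_EPS = 1e-9


@dataclass(frozen=True)
class Segment:
    """A contiguous single-ink stretch of a filament."""

    ink_id: str
    length: float  # mm
    start: float  # mm offset along the filament axis, from the filament start

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("segment length must be > 0")


@dataclass
class FilamentPlan:
    """One deposition line: where it starts, which way it runs, its segments.

    ``direction`` is 0 (along +x) or 90 (along +y). Segments are in
    deposition order, contiguous, and sum to ``total_length``.
    """

    index: int
    start: tuple  # (x, y) mm of the deposition start point
    direction: int  # degrees: 0 or 90
    total_length: float  # mm
    segments: list = field(default_factory=list)
    z: float = 0.0

    def __post_init__(self):
        if self.direction not in (0, 90):
            raise ValueError("direction must be 0 or 90 degrees")
        if self.total_length <= 0:
            raise ValueError("total_length must be > 0")
        if self.segments:
            self.validate()

    def validate(self):
        total = sum(s.length for s in self.segments)
        if abs(total - self.total_length) > 1e-9:
            raise ValueError(
                f"segment lengths sum to {total!r}, expected {self.total_length!r}"
            )
        pos = 0.0
        for s in self.segments:
            if abs(s.start - pos) > 1e-9:
                raise ValueError("segments must be contiguous and ordered by start")
            pos += s.length

    @property
    def end(self) -> tuple:
        x, y = self.start
        if self.direction == 0:
            return (x + self.total_length, y)
        return (x, y + self.total_length)

    def ink_sequence(self) -> list:
        """Ink ids in deposition order."""
        return [s.ink_id for s in self.segments]


@dataclass(frozen=True)
class FidelityReport:
    """Agreement between a planned/printed label map and its target."""

    per_ink_agreement: dict  # ink_id -> fraction of target pixels matched
    overall_agreement: float
    jagged_edge_length: float  # mm of pixel edges bounding disagreement


def decompose(pattern: LayerPattern, filament_diameter: float, orientation: int = 0,
              gap: float = 0.0, min_segment_length: float = DEFAULT_MIN_SEGMENT_MM):
    """Cover a layer with parallel filaments and extract their segments.

    Filaments run along x for ``orientation=0`` (stacked in y) or along y for
    ``orientation=90``. Lane pitch is ``filament_diameter + gap`` and the
    first lane center sits half a pitch from the layer origin, so with zero
    gap the lanes tile the extent exactly.
    """
    if filament_diameter <= 0:
        raise ValueError("filament_diameter must be > 0")
    if gap < 0:
        raise ValueError("gap must be >= 0")
    if orientation not in (0, 90):
        raise ValueError("orientation must be 0 or 90")
    across = pattern.height if orientation == 0 else pattern.width
    along = pattern.width if orientation == 0 else pattern.height
    if filament_diameter > min(pattern.width, pattern.height) + _EPS:
        raise ValueError(
            f"filament diameter {filament_diameter} mm exceeds layer extent"
        )
    pitch = filament_diameter + gap
    n_lanes = int(np.floor(across / pitch + _EPS))
    ox, oy = pattern.origin
    filaments = []
    for i in range(n_lanes):
        c = pitch / 2 + i * pitch  # lane center, relative to origin
        if orientation == 0:
            start = (ox, oy + c)
        else:
            start = (ox + c, oy)
        fil = FilamentPlan(
            index=i,
            start=start,
            direction=orientation,
            total_length=along,
            z=pattern.z,
        )
        fil.segments = extract_segments(pattern, fil, min_segment_length)
        filaments.append(fil)
    return filaments


def extract_segments(pattern: LayerPattern, filament: FilamentPlan,
                     min_segment_length: float = 0.0) -> list:
    """Run-length encode the pattern labels along a filament centerline.

    Labels are sampled at pixel resolution, so segment boundaries land on
    pixel-cell boundaries. Runs shorter than ``min_segment_length`` are
    merged into their longer neighbor (ties go to the preceding segment),
    then equal-ink neighbors are coalesced; total length is conserved.
    """
    ox, oy = pattern.origin
    px = pattern.pixel_size
    nrows, ncols = pattern.grid.shape
    x0, y0 = filament.start
    if filament.direction == 0:
        row = int(np.floor((y0 - oy) / px + _EPS))
        if not 0 <= row < nrows:
            raise ValueError("filament centerline outside pattern extent")
        labels = pattern.grid[row, :]
        offset0 = x0 - ox
    else:
        col = int(np.floor((x0 - ox) / px + _EPS))
        if not 0 <= col < ncols:
            raise ValueError("filament centerline outside pattern extent")
        labels = pattern.grid[:, col]
        offset0 = y0 - oy
    # restrict to the pixels the filament actually crosses
    i0 = int(np.floor(offset0 / px + _EPS))
    i1 = int(np.floor((offset0 + filament.total_length) / px + _EPS))
    i1 = min(i1, len(labels))
    labels = labels[max(i0, 0):i1]
    if labels.size == 0:
        raise ValueError("filament does not cross any pixel")

    runs = _rle(labels, px)
    runs = _merge_short_runs(runs, min_segment_length)
    segments, pos = [], 0.0
    for ink_id, length in runs:
        segments.append(Segment(ink_id=str(ink_id), length=length, start=pos))
        pos += length
    return segments


def _rle(labels, px: float):
    """Run-length encode a 1D label array into (ink, length_mm) pairs."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append([labels[start], (i - start) * px])
            start = i
    return runs


def _merge_short_runs(runs, min_len: float):
    """Merge runs shorter than ``min_len`` into their longer neighbor.

    Deterministic order: always merge the leftmost shortest offending run;
    when the two neighbors are equally long the preceding one wins. Length
    is conserved exactly (the neighbor absorbs the run's length).
    """
    runs = [list(r) for r in runs]
    runs = _coalesce(runs)
    while len(runs) > 1:
        short = [i for i, r in enumerate(runs) if r[1] < min_len - _EPS]
        if not short:
            break
        i = min(short, key=lambda j: (runs[j][1], j))
        if i == 0:
            target = 1
        elif i == len(runs) - 1:
            target = i - 1
        else:
            target = i - 1 if runs[i - 1][1] >= runs[i + 1][1] else i + 1
        runs[target][1] += runs[i][1]
        del runs[i]
        runs = _coalesce(runs)
    return runs


def _coalesce(runs):
    out = []
    for ink, length in runs:
        if out and out[-1][0] == ink:
            out[-1][1] += length
        else:
            out.append([ink, length])
    return out


def count_switches(segments) -> int:
    """Number of ink changes along a filament (= segments - 1 once coalesced)."""
    segs = list(segments)
    if not segs:
        raise ValueError("empty segment list")
    return sum(1 for a, b in zip(segs, segs[1:]) if a.ink_id != b.ink_id)


def reverse_filament(filament: FilamentPlan) -> FilamentPlan:
    """Flip a filament's deposition direction (start from the far end).

    Used to alternate travel direction between neighboring filaments; the
    segment list is reversed and re-anchored so lengths and inks survive.
    """
    L = filament.total_length
    rev = []
    pos = 0.0
    for s in reversed(filament.segments):
        rev.append(Segment(ink_id=s.ink_id, length=s.length, start=pos))
        pos += s.length
    x, y = filament.start
    was_reversed = getattr(filament, "reversed_direction", False)
    sign = -1.0 if was_reversed else 1.0
    new_start = (x + sign * L, y) if filament.direction == 0 else (x, y + sign * L)
    out = FilamentPlan(
        index=filament.index,
        start=new_start,
        direction=filament.direction,
        total_length=L,
        z=filament.z,
    )
    out.segments = rev
    # when set, deposition runs toward the -axis from `start`
    out.reversed_direction = not was_reversed
    return out


def fidelity(planned: LayerPattern, target: LayerPattern) -> FidelityReport:
    """Compare a planned/reconstructed label map against the target pattern.

    Per-ink agreement is the fraction of the target's pixels of that ink that
    the planned map reproduces. ``jagged_edge_length`` totals the pixel-edge
    length separating agreeing from disagreeing pixels — a proxy for the
    stair-stepping a finite filament diameter leaves along oblique boundaries.
    """
    if planned.grid.shape != target.grid.shape:
        raise ValueError("planned and target grids must be congruent")
    if planned.pixel_size != target.pixel_size:
        raise ValueError("planned and target pixel sizes must match")
    agree = planned.grid == target.grid
    per_ink = {}
    for ink_id in target.ink_ids():
        mask = target.grid == ink_id
        per_ink[str(ink_id)] = float(np.count_nonzero(agree & mask) / np.count_nonzero(mask))
    overall = float(np.count_nonzero(agree) / agree.size)
    dis = ~agree
    px = target.pixel_size
    edges = np.count_nonzero(dis[:, 1:] != dis[:, :-1]) + np.count_nonzero(
        dis[1:, :] != dis[:-1, :]
    )
    return FidelityReport(
        per_ink_agreement=per_ink,
        overall_agreement=overall,
        jagged_edge_length=float(edges * px),
    )


def rasterize_filaments(filaments, like: LayerPattern, filament_diameter: float,
                        fill: str = "") -> LayerPattern:
    """Paint filament segments onto a grid congruent with ``like``.

    Each filament paints a band ``filament_diameter`` wide around its
    centerline; along the axis each pixel takes the ink of the segment
    containing its center (half-open intervals). Pixels no filament covers
    keep the ``fill`` label.
    """
    px = like.pixel_size
    nrows, ncols = like.grid.shape
    grid = np.full((nrows, ncols), fill, dtype=like.grid.dtype)
    ox, oy = like.origin
    xc = (np.arange(ncols) + 0.5) * px  # centers relative to origin
    yc = (np.arange(nrows) + 0.5) * px
    r = filament_diameter / 2
    for fil in filaments:
        x0, y0 = fil.start
        forward = not getattr(fil, "reversed_direction", False)
        for seg in fil.segments:
            # absolute along-axis interval covered by this segment
            if forward:
                lo = (x0 if fil.direction == 0 else y0) + seg.start
            else:
                lo = (x0 if fil.direction == 0 else y0) - seg.start - seg.length
            hi = lo + seg.length
            if fil.direction == 0:
                colsel = (xc >= lo - ox - _EPS) & (xc < hi - ox - _EPS)
                rowsel = (yc >= (y0 - oy) - r - _EPS) & (yc < (y0 - oy) + r - _EPS)
            else:
                rowsel = (yc >= lo - oy - _EPS) & (yc < hi - oy - _EPS)
                colsel = (xc >= (x0 - ox) - r - _EPS) & (xc < (x0 - ox) + r - _EPS)
            grid[np.ix_(rowsel, colsel)] = seg.ink_id
    return LayerPattern(grid=grid, pixel_size=px, origin=like.origin, z=like.z)


def filaments_to_json(filaments) -> list:
    """JSON-serializable view: one object per filament, segments as [ink, length]."""
    return [
        {
            "index": f.index,
            "start": list(f.start),
            "direction": f.direction,
            "z": f.z,
            "total_length": f.total_length,
            "segments": [[s.ink_id, s.length] for s in f.segments],
        }
        for f in filaments
    ]
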