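"""Synthetic build patterns and characterization curves.

Every pattern and measurement the rest of the package is exercised against
is generated here, parameterized and seeded, so the full pipeline is testable
without any external data:

* the nested-squares stiffness pattern (four agarose inks, whose center
  filaments carry seven segments and six ink switches),
* the three-segment AC3-AC1-AC3 conductivity filaments (24 mm total, middle
  4/8/12 mm giving heads of 10/8/6 mm),
* the gradient conductivity rectangle, the two-layer "T" build, and the
  striped cell pattern (six filaments, four of them three-segment),
* Ostwald power-law shear sweeps, gelation (G'/G'' vs T) curves with a
  constructed crossover, and linear-elastic stress-strain curves.

Exact printed dimensions of the demonstration objects are not published;
defaults reproduce the documented topology (segment and switch counts, band
order, head/middle lengths) with sizes a 500 um capillary can print.
Noise-free curves satisfy their defining equations exactly; noisy variants
are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inks import InkSpec, RheologyCurve, StressStrain
from .pattern import BuildModel, InkPalette, LayerPattern, stack_layers
from .slicer import FilamentPlan, Segment

__all__ = [
    "FixtureSpec",
    "table_inks",
    "default_palette",
    "gen_nested_squares",
    "gen_three_segment_filament",
    "gen_gradient_rectangle",
    "gen_two_layer_T",
    "gen_stripe_cell_pattern",
    "gen_powerlaw_curve",
    "gen_gelation_curve",
    "gen_stress_strain",
]

#: default raster resolution: 5 pixels across a 0.5 mm filament
DEFAULT_PIXEL_MM = 0.1

#: consistency index used for synthetic shear sweeps (the published fits
#: report only the flow index n, so K is a fixture parameter)
DEFAULT_K = 100.0

_EPS = 1e-9


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a reproducible fixture: generator name, parameters, seed."""

    name: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0


def table_inks() -> dict:
    """The twelve documented ink formulations, keyed by ink id.

    A1-A5: plain agarose at 1-5 w/v%. AC1-AC5: 2 w/v% agarose with
    0.01-0.05 w/v% SWCNT. AS3: 3 w/v% low-melting (sieve) agarose,
    gel point 35 degC, flow index 0.3. A-NIH: AS3 base carrying 1e6
    NIH 3T3 cells/mL, flow index 0.26. Moduli attached where measured
    (A1 outermost 23.6 kPa, A4 center 500.4 kPa).
    """
    inks = {}
    for c in range(1, 6):
        inks[f"A{c}"] = InkSpec(ink_id=f"A{c}", agarose_concentration=float(c))
    for i in range(1, 6):
        inks[f"AC{i}"] = InkSpec(
            ink_id=f"AC{i}", agarose_concentration=2.0, swcnt_concentration=i / 100.0
        )
    inks["A1"].youngs_modulus_E = 23.6
    inks["A4"].youngs_modulus_E = 500.4
    inks["AS3"] = InkSpec(ink_id="AS3", agarose_concentration=3.0, crossover_T=35.0)
    inks["A-NIH"] = InkSpec(
        ink_id="A-NIH", agarose_concentration=3.0, cell_density=1e6
    )
    return inks


def default_palette() -> InkPalette:
    """Palette holding every documented formulation."""
    palette = InkPalette()
    colors = {
        "A1": "#f7fbff", "A2": "#c6dbef", "A3": "#6baed6", "A4": "#2171b5",
        "A5": "#08306b", "AC1": "#fee5d9", "AC2": "#fcae91", "AC3": "#fb6a4a",
        "AC4": "#de2d26", "AC5": "#a50f15", "AS3": "#edf8e9", "A-NIH": "#238b45",
    }
    for ink_id, spec in table_inks().items():
        palette.add(spec, color=colors.get(ink_id, "#808080"))
    return palette


# ---------------------------------------------------------------------------
# Patterns

def gen_nested_squares(band_widths, inks, pixel_size: float = DEFAULT_PIXEL_MM) -> LayerPattern:
    """Concentric square bands, ``inks[0]`` outermost, ``inks[-1]`` the center.

    ``band_widths[j]`` is the width (mm) of band j measured inward; the
    innermost entry is the half-side of the center square. A filament
    through the center reads the palindrome ink_0 ... ink_{k-1} ... ink_0,
    i.e. 2k-1 segments and 2k-2 switches for k inks.
    """
    widths = [float(w) for w in band_widths]
    inks = list(inks)
    if not widths:
        raise ValueError("need at least one band")
    if len(widths) != len(inks):
        raise ValueError("band_widths and inks must have equal length")
    if any(w <= 0 for w in widths):
        raise ValueError("zero-width band")
    half = sum(widths)
    n = int(round(2 * half / pixel_size))
    xc = (np.arange(n) + 0.5) * pixel_size - half
    cx, cy = np.meshgrid(xc, xc)
    dinf = np.maximum(np.abs(cx), np.abs(cy))
    # thresholds measured from the center: t[j] is the outer edge of band j;
    # assign inward so later (inner) bands overwrite earlier ones
    t = [half - sum(widths[:j]) for j in range(len(widths))]
    grid = np.full((n, n), inks[0], dtype="<U16")
    for j in range(1, len(inks)):
        grid[dinf < t[j]] = inks[j]
    return LayerPattern(grid=grid, pixel_size=pixel_size)


def gen_three_segment_filament(total: float, middle: float, inks) -> FilamentPlan:
    """Symmetric outer-middle-outer conductivity filament.

    ``inks`` is (outer_ink, middle_ink); head and tail are each
    ``(total - middle) / 2``. With ``middle == total`` the filament
    degenerates to a single middle-ink segment.
    """
    outer, mid = inks
    if not 0 < middle <= total:
        raise ValueError("need 0 < middle <= total")
    head = (total - middle) / 2.0
    fil = FilamentPlan(index=0, start=(0.0, 0.0), direction=0, total_length=total)
    if head <= 0:
        fil.segments = [Segment(ink_id=mid, length=total, start=0.0)]
    else:
        fil.segments = [
            Segment(ink_id=outer, length=head, start=0.0),
            Segment(ink_id=mid, length=middle, start=head),
            Segment(ink_id=outer, length=head, start=head + middle),
        ]
    return fil


def gen_gradient_rectangle(inks, band_length: float, width: float,
                           pixel_size: float = DEFAULT_PIXEL_MM) -> LayerPattern:
    """Rectangle of equal-length ink bands along x (a conductivity gradient).

    Filaments sliced along x cross every band; filaments along y stay within
    one band.
    """
    inks = list(inks)
    if not inks:
        raise ValueError("need at least one ink band")
    if band_length <= 0 or width <= 0:
        raise ValueError("band_length and width must be > 0")
    ncols = int(round(len(inks) * band_length / pixel_size))
    nrows = int(round(width / pixel_size))
    grid = np.empty((nrows, ncols), dtype="<U16")
    xc = (np.arange(ncols) + 0.5) * pixel_size
    for j, ink in enumerate(inks):
        sel = (xc >= j * band_length - _EPS) & (xc < (j + 1) * band_length - _EPS)
        grid[:, sel] = ink
    return LayerPattern(grid=grid, pixel_size=pixel_size)


def gen_two_layer_T(ink_bg: str, ink_fg: str, *, width: float = 10.0,
                    height: float = 10.0, bar_thickness: float = 3.0,
                    stem_width: float = 3.0, layer_height: float = 0.5,
                    pixel_size: float = DEFAULT_PIXEL_MM) -> BuildModel:
    """Two-layer build whose foreground regions union to a "T".

    Layer 0 carries the horizontal bar (full width, ``bar_thickness`` tall,
    at the top); layer 1 carries the vertical stem (``stem_width`` wide,
    centered, full height). The two layers differ, and stacking them
    produces the T in 3D.
    """
    if bar_thickness <= 0 or stem_width <= 0:
        raise ValueError("bar_thickness and stem_width must be > 0")
    if bar_thickness > height or stem_width > width:
        raise ValueError("T features exceed the layer extent")
    ncols = int(round(width / pixel_size))
    nrows = int(round(height / pixel_size))
    xc = (np.arange(ncols) + 0.5) * pixel_size
    yc = (np.arange(nrows) + 0.5) * pixel_size

    bar = np.full((nrows, ncols), ink_bg, dtype="<U16")
    bar[yc >= height - bar_thickness - _EPS, :] = ink_fg

    stem = np.full((nrows, ncols), ink_bg, dtype="<U16")
    x0 = (width - stem_width) / 2.0
    stem[:, (xc >= x0 - _EPS) & (xc < x0 + stem_width - _EPS)] = ink_fg

    layers = [
        LayerPattern(grid=bar, pixel_size=pixel_size),
        LayerPattern(grid=stem, pixel_size=pixel_size),
    ]
    return stack_layers(layers, layer_height)


def gen_stripe_cell_pattern(matrix_ink: str, cell_ink: str, n_filaments: int = 6,
                            striped_indices=(1, 2, 3, 4),
                            segment_fractions=(0.25, 0.5, 0.25),
                            filament_diameter: float = 0.5, length: float = 12.0,
                            pixel_size: float = DEFAULT_PIXEL_MM) -> LayerPattern:
    """Cell-patterning stripe layout: some filaments carry a cell-laden middle.

    Filaments run along x, stacked in y at the filament diameter. Lanes in
    ``striped_indices`` are matrix/cell/matrix at ``segment_fractions`` of
    the length (three segments); the rest are plain matrix (one segment).
    The default emulates six filaments of which four are three-segment.
    """
    fracs = [float(f) for f in segment_fractions]
    if len(fracs) != 3 or any(f < 0 for f in fracs):
        raise ValueError("segment_fractions must be three non-negative values")
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ValueError(f"segment_fractions sum to {sum(fracs):g}, expected 1")
    if n_filaments < 1:
        raise ValueError("need at least one filament")
    bad = [i for i in striped_indices if not 0 <= i < n_filaments]
    if bad:
        raise ValueError(f"striped indices out of range: {bad}")
    nrows = int(round(n_filaments * filament_diameter / pixel_size))
    ncols = int(round(length / pixel_size))
    grid = np.full((nrows, ncols), matrix_ink, dtype="<U16")
    xc = (np.arange(ncols) + 0.5) * pixel_size
    yc = (np.arange(nrows) + 0.5) * pixel_size
    a = fracs[0] * length
    b = (fracs[0] + fracs[1]) * length
    mid = (xc >= a - _EPS) & (xc < b - _EPS)
    for i in striped_indices:
        lane = (yc >= i * filament_diameter - _EPS) & (
            yc < (i + 1) * filament_diameter - _EPS
        )
        grid[np.ix_(lane, mid)] = cell_ink
    return LayerPattern(grid=grid, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# Measurement curves

def gen_powerlaw_curve(K: float = DEFAULT_K, n: float = 0.3,
                       shear_range=(0.01, 100.0), points: int = 50,
                       noise_sd: float = 0.0, seed: int | None = None):
    """Shear sweep from the Ostwald model, eta = K * gamma_dot**(n-1).

    Shear rates are log-spaced over ``shear_range`` (default the standard
    0.01-100 1/s sweep). ``noise_sd`` applies multiplicative lognormal noise
    (SD of log-viscosity); the same seed reproduces the same sweep exactly.
    Returns (shear_rates, viscosities).
    """
    if K <= 0:
        raise ValueError("K must be > 0")
    if points < 2:
        raise ValueError("need at least 2 points")
    lo, hi = shear_range
    if lo <= 0 or hi <= lo:
        raise ValueError("shear_range must be positive and increasing")
    g = np.logspace(np.log10(lo), np.log10(hi), points)
    eta = K * g ** (n - 1.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        eta = eta * np.exp(rng.normal(0.0, noise_sd, size=points))
    return g, eta


def gen_gelation_curve(T_x: float = 35.0, slopes=(0.12, 0.04),
                       T_range=(20.0, 50.0), step: float = 0.5,
                       G_cross: float = 100.0) -> RheologyCurve:
    """Cooling sweep with log-linear G' and G'' crossing exactly at ``T_x``.

    ``log10 G' = log10 G_cross + slopes[0] * (T_x - T)`` and likewise for
    G'' with ``slopes[1]``; the storage modulus rises faster on cooling
    (``slopes[0] > slopes[1]``), so G' > G'' below the gel point and
    G' < G'' above it, crossing at ``T_x`` by construction. Complex
    viscosity is |G*| / omega at 1 Hz.
    """
    s1, s2 = slopes
    if s1 <= s2:
        raise ValueError("storage-modulus slope must exceed loss-modulus slope")
    if G_cross <= 0:
        raise ValueError("G_cross must be > 0")
    lo, hi = T_range
    T = np.arange(lo, hi + step / 2, step)
    gp = G_cross * 10.0 ** (s1 * (T_x - T))
    gpp = G_cross * 10.0 ** (s2 * (T_x - T))
    omega = 2 * np.pi * 1.0  # rad/s at 1 Hz
    eta_star = np.sqrt(gp ** 2 + gpp ** 2) / omega
    return RheologyCurve(
        temperature=tuple(T),
        G_storage=tuple(gp),
        G_loss=tuple(gpp),
        complex_viscosity=tuple(eta_star),
    )


def gen_stress_strain(E: float, max_strain: float = 0.15, points: int = 46,
                      noise_sd: float = 0.0, seed: int | None = None,
                      linear_limit: float = 0.04,
                      post_linear: str = "plateau") -> StressStrain:
    """Compression curve: Hookean (sigma = E * eps) up to ``linear_limit``.

    Beyond the linear window the stress either holds (``"plateau"``) or
    strain-hardens quadratically (``"hardening"``), emulating the departure
    from linearity real gels show past small strains. ``max_strain``
    defaults to the 15% test confinement; stress in kPa. ``noise_sd`` adds
    Gaussian noise (kPa) deterministically under ``seed``.
    """
    if E < 0:
        raise ValueError("E must be >= 0")
    if max_strain <= 0 or points < 2:
        raise ValueError("max_strain must be > 0 and points >= 2")
    eps = np.linspace(0.0, max_strain, points)
    sigma = np.where(eps <= linear_limit, E * eps, E * linear_limit)
    if post_linear == "hardening":
        over = np.clip(eps - linear_limit, 0.0, None)
        sigma = sigma + 3.0 * E * over ** 2
    elif post_linear != "plateau":
        raise ValueError("post_linear must be 'plateau' or 'hardening'")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sigma = sigma + rng.normal(0.0, noise_sd, size=points)
    return StressStrain(strain=tuple(eps), stress=tuple(sigma))
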