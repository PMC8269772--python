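"""Physical optotype geometry, screen feasibility and calibration.

logMAR sizing convention: an optotype at ``L`` logMAR viewed from distance
``d`` subtends ``5 * 10**L`` arcminutes of visual angle, so its physical
height is ``d * tan(5 * 10**L arcmin)``.  At logMAR 0.0 and 3 m this is the
familiar 4.36 mm letter.  The exact tangent is used rather than the
small-angle approximation so heights are bit-stable across distances.

Letters are modelled as 5x5 stroke-width squares (stroke width = height/5).
Crowded lines follow the linear-crowding layout used for computerised
charts: letters spaced half a letter width (2.5 stroke widths) apart and
surrounded by a crowding box one stroke width thick, separated from the
letter borders by 2.5 stroke widths.  All footprint-to-letter-height ratios
are therefore fixed constants, independent of size and distance:

* single crowded letter: 12 x 12 strokes (5 + 2*(2.5 + 1) per side),
  i.e. 2.4x the letter height;
* k-letter chunk width: ``5k + 2.5(k-1) + 7`` strokes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .errors import DomainError, UndisplayableError

ARCMIN_RAD = math.pi / (180.0 * 60.0)
#: visual angle (arcmin) subtended by a logMAR 0.0 letter
BASE_ANGLE_ARCMIN = 5.0

LETTER_STROKES = 5.0
LETTER_GAP_STROKES = 2.5
BOX_GAP_STROKES = 2.5
BOX_THICKNESS_STROKES = 1.0
_EDGE_STROKES = BOX_GAP_STROKES + BOX_THICKNESS_STROKES  # per side

MM_PER_INCH = 25.4

DEFAULT_GRID_FLOOR = -0.3
DEFAULT_GRID_CEILING = 1.6

#: implied display densities (internal units per inch) outside this window
#: flag a calibration as implausible (gross mis-measurement guard)
PLAUSIBLE_UNITS_PER_INCH = (20.0, 600.0)


def letter_height_mm(logmar: float, distance_mm: float) -> float:
    """Physical optotype height in mm at a given logMAR size and distance.

    Parameters
    ----------
    logmar
        Acuity size on the logMAR scale (0.0 = 5 arcmin letter).
    distance_mm
        Viewing distance in millimetres; must be positive.
    """
    if distance_mm <= 0:
        raise DomainError(f"viewing distance must be positive, got {distance_mm}")
    angle_rad = BASE_ANGLE_ARCMIN * (10.0 ** logmar) * ARCMIN_RAD
    return distance_mm * math.tan(angle_rad)


def stroke_width_mm(logmar: float, distance_mm: float) -> float:
    """Stroke width in mm (one fifth of the letter height)."""
    return letter_height_mm(logmar, distance_mm) / LETTER_STROKES


@dataclass(frozen=True)
class OptotypeSpec:
    """A sized optotype: logMAR value plus its physical dimensions."""

    logmar: float
    distance_mm: float
    height_mm: float
    stroke_mm: float

    @classmethod
    def at(cls, logmar: float, distance_mm: float) -> "OptotypeSpec":
        h = letter_height_mm(logmar, distance_mm)
        return cls(logmar=logmar, distance_mm=distance_mm,
                   height_mm=h, stroke_mm=h / LETTER_STROKES)


def _footprint_strokes(n_letters: int) -> tuple[float, float]:
    if not 1 <= n_letters <= 5:
        raise DomainError(f"n_letters must be in 1..5, got {n_letters}")
    width = (LETTER_STROKES * n_letters
             + LETTER_GAP_STROKES * (n_letters - 1)
             + 2 * _EDGE_STROKES)
    height = LETTER_STROKES + 2 * _EDGE_STROKES
    return width, height


@dataclass(frozen=True)
class CrowdedLayout:
    """Physical footprint of a crowded chunk of 1-5 letters, box included."""

    logmar: float
    distance_mm: float
    n_letters: int
    width_mm: float
    height_mm: float
    letter_gap_strokes: float = LETTER_GAP_STROKES
    box_gap_strokes: float = BOX_GAP_STROKES
    box_thickness_strokes: float = BOX_THICKNESS_STROKES


def crowded_footprint(logmar: float, distance_mm: float,
                      n_letters: int) -> CrowdedLayout:
    """Footprint (mm) of ``n_letters`` crowded letters including the box."""
    w_strokes, h_strokes = _footprint_strokes(n_letters)
    stroke = stroke_width_mm(logmar, distance_mm)
    return CrowdedLayout(logmar=logmar, distance_mm=distance_mm,
                         n_letters=n_letters,
                         width_mm=w_strokes * stroke,
                         height_mm=h_strokes * stroke)


@dataclass(frozen=True)
class ScreenSpec:
    """A display: diagonal, aspect ratio and the presentation-window fraction.

    ``window_fraction`` is the linear fraction of *each* screen dimension
    occupied by the shared presentation window (default 2/3, the maximised
    16:9 video-consultation window on a landscape screen).
    """

    diagonal_in: float
    aspect_w: float = 16.0
    aspect_h: float = 9.0
    window_fraction: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if self.diagonal_in <= 0:
            raise DomainError("screen diagonal must be positive")
        if self.aspect_w <= 0 or self.aspect_h <= 0:
            raise DomainError("aspect ratio terms must be positive")
        if not 0 < self.window_fraction <= 1:
            raise DomainError("window_fraction must be in (0, 1]")

    @property
    def width_mm(self) -> float:
        hyp = math.hypot(self.aspect_w, self.aspect_h)
        return self.diagonal_in * MM_PER_INCH * self.aspect_w / hyp

    @property
    def height_mm(self) -> float:
        hyp = math.hypot(self.aspect_w, self.aspect_h)
        return self.diagonal_in * MM_PER_INCH * self.aspect_h / hyp

    @property
    def window_width_mm(self) -> float:
        return self.width_mm * self.window_fraction

    @property
    def window_height_mm(self) -> float:
        return self.height_mm * self.window_fraction


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the physical calibration-cross measurement.

    The user measures, with a ruler, a cross of known length in internal
    display units; ``mm_per_unit`` converts requested sizes into physical
    millimetres on that particular screen.  A ``warning`` is set (never an
    error) when the implied display density falls outside
    :data:`PLAUSIBLE_UNITS_PER_INCH`, to catch gross mis-measurement
    without blocking unusual hardware.
    """

    nominal_units: float
    measured_mm: float
    mm_per_unit: float
    units_per_inch: float
    warning: Optional[str] = None

    @property
    def plausible(self) -> bool:
        return self.warning is None


def calibrate(nominal_units: float, measured_mm: float) -> CalibrationResult:
    """Derive the screen scale factor from a calibration-cross measurement."""
    if nominal_units <= 0 or measured_mm <= 0:
        raise DomainError("calibration inputs must be positive")
    mm_per_unit = measured_mm / nominal_units
    units_per_inch = nominal_units / (measured_mm / MM_PER_INCH)
    lo, hi = PLAUSIBLE_UNITS_PER_INCH
    warning = None
    if not lo <= units_per_inch <= hi:
        warning = (f"implied display density {units_per_inch:.1f} units/inch "
                   f"outside plausible range [{lo:g}, {hi:g}]; "
                   "check the ruler measurement")
    return CalibrationResult(nominal_units=nominal_units,
                             measured_mm=measured_mm,
                             mm_per_unit=mm_per_unit,
                             units_per_inch=units_per_inch,
                             warning=warning)


def chunk_line(logmar: float, distance_mm: float,
               window_width_mm: float, window_height_mm: float) -> list[int]:
    """Partition a five-letter line into chunks that fit the window.

    A full five-letter crowded line is presented whole when it fits.
    Otherwise the line is broken greedily into the largest chunks of
    3, 2 or 1 crowded letters whose footprint (box included) fits both
    window dimensions; five letters are always presented in total.
    """
    if window_width_mm <= 0 or window_height_mm <= 0:
        raise DomainError("window dimensions must be positive")

    def fits(k: int) -> bool:
        fp = crowded_footprint(logmar, distance_mm, k)
        return fp.width_mm <= window_width_mm and fp.height_mm <= window_height_mm

    if not fits(1):
        raise UndisplayableError(
            f"single crowded letter at {logmar:g} logMAR does not fit "
            f"a {window_width_mm:.0f}x{window_height_mm:.0f} mm window")
    if fits(5):
        return [5]
    chunks: list[int] = []
    remaining = 5
    while remaining > 0:
        for k in (3, 2, 1):
            if k <= remaining and fits(k):
                chunks.append(k)
                remaining -= k
                break
    return chunks


def max_testable_logmar(screen: ScreenSpec, distance_mm: float,
                        grid_step: float = 0.1,
                        grid_floor: float = DEFAULT_GRID_FLOOR,
                        grid_ceiling: float = DEFAULT_GRID_CEILING) -> float:
    """Largest grid-aligned logMAR testable on a given screen.

    Scans the logMAR grid from the ceiling downward and returns the first
    size whose *single* crowded-letter footprint (crowding box included)
    fits the presentation window in both dimensions.  Larger sizes are
    still testable as single-letter chunks per :func:`chunk_line`, so a
    single letter fitting is the binding constraint.
    """
    if distance_mm <= 0:
        raise DomainError("viewing distance must be positive")
    if grid_step <= 0 or grid_floor >= grid_ceiling:
        raise DomainError("invalid logMAR grid")
    w, h = screen.window_width_mm, screen.window_height_mm
    n = int(round((grid_ceiling - grid_floor) / grid_step))
    for i in range(n, -1, -1):
        level = round(grid_floor + i * grid_step, 10)
        fp = crowded_footprint(level, distance_mm, 1)
        if fp.width_mm <= w and fp.height_mm <= h:
            return level
    raise UndisplayableError(
        f"no grid size down to {grid_floor:g} logMAR fits a "
        f"{screen.diagonal_in:g}\" screen at {distance_mm:g} mm")
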