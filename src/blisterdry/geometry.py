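"""Closed-form geometry of a cold-form blister pocket.

The pocket is modeled as a sliced horizontal cylinder with spherical end
caps: a cylinder of radius ``R_b`` lying on its side, cut by a horizontal
plane at depth ``h_b`` below its axis-parallel tangent plane, with the two
ends closed by spherical caps of the same radius.  Filling the pocket to a
depth ``L`` (measured from the lowest point) gives a frozen volume composed
of a spherical cap (two half-caps, one per end) plus a circular-segment
prism over the cylindrical mid-section.

All lengths are in metres, areas in m^2, volumes in m^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property
from typing import Literal

from scipy.optimize import brentq

from .errors import GeometryError

__all__ = [
    "BlisterGeometry",
    "radius_from_chord_height",
    "chord_at_height",
    "frozen_volume",
    "sublimation_area",
    "ice_thickness_from_volume",
]


def radius_from_chord_height(chord_length: float, height: float) -> float:
    """Radius of the sliced cylinder from the chord and slice height.

    For a circular segment of chord ``c`` and height (sagitta) ``h`` the
    circle radius is ``R = (c^2/4 + h^2) / (2 h)``.  The slice must not be
    deeper than a half-circle (``h <= c/2``), otherwise the pocket would
    overhang and the height would no longer be a sagitta.
    """
    if chord_length <= 0.0 or height <= 0.0:
        raise GeometryError(
            f"chord_length and height must be positive, got "
            f"{chord_length!r}, {height!r}"
        )
    radius = (chord_length**2 / 4.0 + height**2) / (2.0 * height)
    if height > radius * (1.0 + 1e-12):
        raise GeometryError(
            f"height {height} exceeds radius {radius}: pocket deeper than a "
            "half-cylinder is not representable"
        )
    return radius


@dataclass(frozen=True)
class BlisterGeometry:
    """Dimensions of a blister pocket and derived quantities.

    Parameters
    ----------
    total_length
        Overall pocket length ``L_b`` including both end caps [m].
    chord_length
        Width of the pocket opening ``c_b`` [m].
    height
        Depth of the pocket ``h_b`` [m].
    """

    total_length: float
    chord_length: float
    height: float
    #: Multiplier of the circular-segment area in the volume formula:
    #: "cylinder" uses L_cyl,b (the end caps already cover the end regions,
    #: and the free-surface area is then the exact volume derivative);
    #: "total" uses the full pocket length L_b instead.
    segment_mode: Literal["cylinder", "total"] = "cylinder"

    def __post_init__(self) -> None:
        radius_from_chord_height(self.chord_length, self.height)  # validates
        if self.total_length < self.chord_length:
            raise GeometryError(
                f"total_length {self.total_length} smaller than chord_length "
                f"{self.chord_length}: cylindrical mid-section would be negative"
            )

    @cached_property
    def radius(self) -> float:
        """Radius ``R_b`` of the cylinder and end caps [m]."""
        return radius_from_chord_height(self.chord_length, self.height)

    @property
    def cylinder_length(self) -> float:
        """Length ``L_cyl,b = L_b - c_b`` of the cylindrical mid-section [m]."""
        return self.total_length - self.chord_length

    @property
    def segment_length(self) -> float:
        """Segment-area multiplier per ``segment_mode`` [m]."""
        if self.segment_mode == "total":
            return self.total_length
        return self.cylinder_length

    @cached_property
    def projected_area(self) -> float:
        """Horizontal projection ``A_b`` of the pocket opening [m^2].

        Equals the sublimation area at full fill: a disc of diameter
        ``c_b`` (the two end half-discs) plus the ``c_b x L_cyl,b``
        rectangle.
        """
        return sublimation_area(self.height, self)

    @cached_property
    def full_volume(self) -> float:
        """Pocket volume at full fill, ``frozen_volume(h_b)`` [m^3]."""
        return frozen_volume(self.height, self)


def _check_level(level: float, geom: BlisterGeometry) -> None:
    if not 0.0 <= level <= geom.height * (1.0 + 1e-12):
        raise GeometryError(
            f"fill level {level} outside [0, {geom.height}] m"
        )


def chord_at_height(level: float, geom: BlisterGeometry) -> float:
    """Chord width of the free surface at fill level ``level`` [m].

    ``c(L) = 2 sqrt(2 R_b L - L^2)``; at ``L = h_b`` this returns the
    pocket chord ``c_b``.
    """
    _check_level(level, geom)
    return 2.0 * math.sqrt(max(2.0 * geom.radius * level - level**2, 0.0))


def frozen_volume(
    level: float, geom: BlisterGeometry, *, segment_length: float | None = None
) -> float:
    """Volume below fill level ``level`` [m^3].

    Spherical-cap term ``pi L^2 (3 R_b - L)/3`` plus the circular-segment
    area times the mid-section length.  ``segment_length`` defaults to the
    geometry's ``segment_length``: ``L_cyl,b`` in the default "cylinder"
    mode, which makes :func:`sublimation_area` the exact derivative of
    this volume, or the full pocket length in "total" mode.
    """
    _check_level(level, geom)
    if segment_length is None:
        segment_length = geom.segment_length
    radius = geom.radius
    cap = math.pi * level**2 * (3.0 * radius - level) / 3.0
    cos_arg = min(max((radius - level) / radius, -1.0), 1.0)
    segment = radius**2 * math.acos(cos_arg) - (radius - level) * math.sqrt(
        max(2.0 * radius * level - level**2, 0.0)
    )
    return cap + segment_length * segment


def sublimation_area(
    level: float, geom: BlisterGeometry, *, segment_length: float | None = None
) -> float:
    """Horizontal free-surface area at fill level ``level`` [m^2].

    ``A(L) = pi (c(L)/2)^2 + c(L) L_cyl,b``: the two end half-discs plus
    the rectangular strip over the cylindrical mid-section.  This is the
    derivative of :func:`frozen_volume` with respect to ``level``.
    """
    _check_level(level, geom)
    if segment_length is None:
        segment_length = geom.segment_length
    chord = chord_at_height(level, geom)
    return math.pi * (chord / 2.0) ** 2 + chord * segment_length


def ice_thickness_from_volume(
    volume: float, geom: BlisterGeometry, *, segment_length: float | None = None
) -> float:
    """Fill level whose frozen volume equals ``volume`` [m].

    Inverts :func:`frozen_volume` by a bracketed root solve on
    ``[0, h_b]``; the volume is strictly increasing in the level, so the
    root is unique.
    """
    if volume < 0.0:
        raise GeometryError(f"volume must be nonnegative, got {volume}")
    full = frozen_volume(geom.height, geom, segment_length=segment_length)
    if volume > full * (1.0 + 1e-9):
        raise GeometryError(
            f"volume {volume} m^3 exceeds pocket capacity {full} m^3"
        )
    if volume == 0.0:
        return 0.0
    if volume >= full:
        return geom.height
    return brentq(
        lambda level: frozen_volume(level, geom, segment_length=segment_length)
        - volume,
        0.0,
        geom.height,
        xtol=1e-13,
    )
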