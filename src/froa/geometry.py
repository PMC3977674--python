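"""Viewing geometry: pixel <-> visual-angle conversion.

The stimulus frame is a square bitmap subtending a fixed visual angle
horizontally (default: 800 px across 18 deg, i.e. ~44.44 px/deg).  A single
linear conversion factor is used throughout; at these eccentricities the
tangent correction changes distances by well under 2% and is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ViewingGeometry:
    """Frame size in pixels and the visual angle it subtends.

    Parameters
    ----------
    frame_px:
        Side length of the (square) stimulus frame in pixels.
    frame_deg:
        Visual angle subtended by the frame horizontally, in degrees.
    """

    frame_px: int = 800
    frame_deg: float = 18.0

    def __post_init__(self) -> None:
        if self.frame_px <= 0 or self.frame_deg <= 0:
            raise ValueError("frame_px and frame_deg must be positive")

    @property
    def px_per_deg(self) -> float:
        return self.frame_px / self.frame_deg

    def px_to_deg(self, px: float) -> float:
        return px / self.px_per_deg

    def deg_to_px(self, deg: float) -> float:
        return deg * self.px_per_deg

    @property
    def frame_shape(self) -> tuple[int, int]:
        """(rows, cols) of the frame bitmap."""
        return (self.frame_px, self.frame_px)


DEFAULT_GEOMETRY = ViewingGeometry()
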