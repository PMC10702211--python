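"""Screen and stimulus geometry shared across the pipeline.

Coordinates are 0-based pixels, origin at the top-left of the screen,
x increasing rightward and y increasing downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class FaceGeometry:
    """Geometry of the face stimulus on the presentation screen.

    The default emulates a 1920x1080 px monitor showing a 900x940 px
    face image at screen center.  ``eye_box`` is the rectangle
    ``(x0, y0, x1, y1)`` used by the holistic/analytic labeling
    heuristic; by default it spans the upper-central face band where
    the eyes of a centered portrait sit.
    """

    screen: tuple[int, int] = (1920, 1080)
    stimulus: tuple[int, int] = (900, 940)
    eye_box: tuple[float, float, float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.eye_box is None:
            cx, _ = self.center
            x0, y0, x1, y1 = self.stimulus_rect
            eye_y = y0 + 0.38 * (y1 - y0)
            box = (cx - 300.0, eye_y - 70.0, cx + 300.0, eye_y + 70.0)
            object.__setattr__(self, "eye_box", box)

    @property
    def stimulus_rect(self) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) of the centered stimulus rectangle."""
        sw, sh = self.screen
        w, h = self.stimulus
        x0 = (sw - w) / 2.0
        y0 = (sh - h) / 2.0
        return (x0, y0, x0 + w, y0 + h)

    @property
    def center(self) -> tuple[float, float]:
        sw, sh = self.screen
        return (sw / 2.0, sh / 2.0)


DEFAULT_GEOMETRY = FaceGeometry()
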