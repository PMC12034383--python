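"""Cursor analysis: manual clustering via circles in phasor space.

A cursor is a circle drawn on the phasor plot; pixels whose phasor falls
inside it are highlighted in image space.  The converse direction of the
same reciprocity principle maps an image-space region onto the phasor
histogram bins its pixels occupy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .field import DEFAULT_EXTENT, PhasorField


@dataclass
class Cursor:
    """Circular phasor-space selector."""

    center: tuple[float, float]
    radius: float
    color: tuple[int, int, int] = (255, 255, 255)

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValidationError(f"cursor radius must be > 0; got {self.radius}")
        g, s = self.center
        if not (-1.5 <= g <= 1.5 and -1.5 <= s <= 1.5):
            raise ValidationError(f"cursor center {self.center} outside phasor region")

    def contains(self, g: np.ndarray, s: np.ndarray) -> np.ndarray:
        """Boundary-inclusive membership test."""
        return (g - self.center[0]) ** 2 + (s - self.center[1]) ** 2 <= self.radius**2


def select_by_cursors(
    field: PhasorField, cursors: list[Cursor], harmonic: int = 1
) -> np.ndarray:
    """Label image from an ordered cursor list (later-drawn cursor wins).

    Cursors are labelled 1..K in draw order; pixels inside no cursor, and
    invalid pixels, get label 0.
    """
    if not cursors:
        raise ValidationError("cursor list is empty")
    g, s = field.coords(harmonic)
    labels = np.zeros(field.shape, dtype=np.int32)
    for i, cur in enumerate(cursors):
        inside = cur.contains(g, s) & field.valid
        labels[inside] = i + 1
    return labels


def cursor_colors(cursors: list[Cursor]) -> dict[int, tuple[int, int, int]]:
    """Label -> RGB map for exporting cursor selections (label 0 is black)."""
    table = {0: (0, 0, 0)}
    for i, cur in enumerate(cursors):
        table[i + 1] = tuple(cur.color)
    return table


def reciprocal_select(
    field: PhasorField,
    region: np.ndarray,
    harmonic: int = 1,
    resolution: int = 256,
    extent=DEFAULT_EXTENT,
) -> np.ndarray:
    """Phasor-histogram bin mask of an image-space region.

    Returns a boolean ``(R, R)`` array marking exactly the histogram bins
    (rows = S, cols = G, same binning as :func:`~phasorlab.transform.phasor_histogram`)
    that contain at least one valid pixel of ``region``.
    """
    region = np.asarray(region, dtype=bool)
    if region.shape != field.shape:
        raise ValidationError(
            f"region shape {region.shape} != image shape {field.shape}"
        )
    # local import avoids a cycle at module load
    from .transform import phasor_histogram

    sub = field.copy()
    sub.valid = field.valid & region
    hist = phasor_histogram(sub, harmonic, resolution=resolution, extent=extent)
    return hist.counts > 0
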