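"""Phasor-space containers: per-harmonic coordinate images and histograms."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ValidationError

#: Default phasor-plot window.
DEFAULT_EXTENT = ((-1.0, 1.0), (-1.0, 1.0))


@dataclass
class PhasorField:
    """Per-harmonic phasor coordinate images with intensity and validity.

    Attributes
    ----------
    harmonics : tuple of int
        Harmonic numbers, one per leading slice of ``g`` / ``s``.
    g, s : ndarray, shape (n_harmonics, H, W)
        Cosine and sine phasor coordinates.
    intensity : ndarray, shape (H, W)
        Per-pixel total counts of the originating stack.
    valid : ndarray of bool, shape (H, W)
        Pixels that carry meaningful phasor coordinates.  Zero-intensity
        pixels are always invalid; thresholding and external masks only
        ever shrink this mask.
    frequency : float or None
        Laser repetition frequency in Hz for lifetime data; ``None`` for
        spectral data (spectral phasors carry no time axis).
    calibrated : bool
        Whether an instrument correction has been applied.
    """

    harmonics: tuple[int, ...]
    g: np.ndarray
    s: np.ndarray
    intensity: np.ndarray
    valid: np.ndarray
    frequency: float | None = None
    calibrated: bool = False
    calibration_tag: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.harmonics = tuple(int(n) for n in self.harmonics)
        if len(self.harmonics) == 0:
            raise ValidationError("harmonics must be non-empty")
        if any(n < 1 for n in self.harmonics):
            raise ValidationError(f"harmonics must be >= 1; got {self.harmonics}")
        self.g = np.asarray(self.g, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.g.shape != self.s.shape or self.g.ndim != 3:
            raise ValidationError("g and s must both have shape (n_harmonics, H, W)")
        if self.g.shape[0] != len(self.harmonics):
            raise ValidationError(
                f"{len(self.harmonics)} harmonics but {self.g.shape[0]} coordinate planes"
            )
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.intensity.shape != self.g.shape[1:] or self.valid.shape != self.g.shape[1:]:
            raise ValidationError("intensity/valid shape does not match coordinate images")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    def index(self, harmonic: int) -> int:
        try:
            return self.harmonics.index(int(harmonic))
        except ValueError:
            raise ValidationError(
                f"harmonic {harmonic} not in field (has {self.harmonics})"
            ) from None

    def coords(self, harmonic: int) -> tuple[np.ndarray, np.ndarray]:
        """(G, S) images for one harmonic."""
        i = self.index(harmonic)
        return self.g[i], self.s[i]

    def phasor(self, harmonic: int) -> np.ndarray:
        """Complex G + iS image for one harmonic."""
        i = self.index(harmonic)
        return self.g[i] + 1j * self.s[i]

    def omega(self, harmonic: int) -> float:
        """Physical angular frequency 2*pi*f*n in rad/s (lifetime fields only)."""
        if self.frequency is None:
            raise ValidationError("field has no repetition frequency (spectral data?)")
        return 2.0 * np.pi * self.frequency * int(harmonic)

    def features(
        self, harmonics: tuple[int, ...] | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Stack valid-pixel coordinates into a feature matrix.

        Returns ``(X, pixel_index)`` where ``X`` has one row per valid pixel
        and columns ``(G, S)`` per requested harmonic, and ``pixel_index`` is
        the flat index of each row's pixel.
        """
        if harmonics is None:
            harmonics = self.harmonics
        idx = np.flatnonzero(self.valid.ravel())
        cols = []
        for n in harmonics:
            i = self.index(n)
            cols.append(self.g[i].ravel()[idx])
            cols.append(self.s[i].ravel()[idx])
        return np.column_stack(cols) if cols else np.empty((idx.size, 0)), idx

    def copy(self) -> "PhasorField":
        return replace(
            self,
            g=self.g.copy(),
            s=self.s.copy(),
            intensity=self.intensity.copy(),
            valid=self.valid.copy(),
        )


@dataclass
class Histogram2D:
    """2-D phasor-space histogram.

    ``counts[row, col]`` bins S along rows and G along columns, half-open
    bins except the last (numpy convention).  ``scale`` only affects
    :meth:`display_values`; stored counts are always raw.
    """

    counts: np.ndarray
    extent: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_EXTENT
    scale: str = "linear"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValidationError("histogram counts must be square (R, R)")
        if self.scale not in ("linear", "log"):
            raise ValidationError(f"scale must be 'linear' or 'log'; got {self.scale!r}")

    @property
    def resolution(self) -> int:
        return self.counts.shape[0]

    def display_values(self) -> np.ndarray:
        """Counts on the selected display scale (log uses log1p)."""
        if self.scale == "log":
            return np.log1p(self.counts.astype(float))
        return self.counts.astype(float)

    def bin_index(self, g: float, s: float) -> tuple[int, int]:
        """(row, col) bin holding phasor coordinate (g, s)."""
        (gmin, gmax), (smin, smax) = self.extent
        r = self.resolution
        col = min(int((g - gmin) / (gmax - gmin) * r), r - 1)
        row = min(int((s - smin) / (smax - smin) * r), r - 1)
        return row, col
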