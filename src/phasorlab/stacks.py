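"""In-memory containers for raw photon-count stacks.

A stack is a ``(B, H, W)`` array of per-pixel photon-count histograms:
``B`` time bins (lifetime data) or wavelength bins (spectral data), with the
bin axis first and image coordinates row-major, 0-based.  Counts are
non-negative; they may be floats for noiseless synthetic data (expected
values rather than Poisson draws).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError


def _validate_counts(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts)
    if counts.ndim != 3:
        raise ValidationError(
            f"counts must have shape (bins, rows, cols); got ndim={counts.ndim}"
        )
    if counts.shape[0] < 2:
        raise ValidationError(f"need at least 2 bins; got {counts.shape[0]}")
    if counts.size and counts.min() < 0:
        raise ValidationError("negative photon counts")
    return counts


@dataclass
class DecayStack:
    """Time-resolved photon-count stack.

    Parameters
    ----------
    counts : ndarray, shape (B, H, W)
        Photon counts per time bin and pixel.
    frequency : float
        Laser repetition frequency in Hz.  The excitation period is
        ``T = 1/frequency`` and bin ``k`` spans ``[k, k+1) * T/B``.
    """

    counts: np.ndarray
    frequency: float
    calibration_tag: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.counts = _validate_counts(self.counts)
        if not self.frequency > 0:
            raise ValidationError(f"frequency must be positive; got {self.frequency}")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def period(self) -> float:
        """Excitation period T in seconds."""
        return 1.0 / self.frequency

    @property
    def shape(self) -> tuple[int, int]:
        """Image shape (rows, cols)."""
        return self.counts.shape[1:]

    @property
    def intensity(self) -> np.ndarray:
        """Per-pixel total counts."""
        return self.counts.sum(axis=0)


@dataclass
class SpectralStack:
    """Hyperspectral photon-count stack.

    ``band = (lambda0, lambda1)`` is the detection bandwidth in nm; bin ``k``
    spans ``[lambda0 + k*d, lambda0 + (k+1)*d)`` with ``d = (lambda1-lambda0)/B``.
    """

    counts: np.ndarray
    band: tuple[float, float]
    calibration_tag: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.counts = _validate_counts(self.counts)
        lam0, lam1 = self.band
        if not lam1 > lam0:
            raise ValidationError(f"band must satisfy lambda1 > lambda0; got {self.band}")
        self.band = (float(lam0), float(lam1))

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[1:]

    @property
    def intensity(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def wavelengths(self) -> np.ndarray:
        """Bin-center wavelengths in nm."""
        lam0, lam1 = self.band
        d = (lam1 - lam0) / self.n_bins
        return lam0 + (np.arange(self.n_bins) + 0.5) * d
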