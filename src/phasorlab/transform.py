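"""The discrete phasor transform and phasor-space operations.

Each pixel's photon-count histogram ``I(k)``, ``k = 0..B-1``, maps to the
harmonic-``n`` phasor coordinates

    G = sum_k I(k) cos(2*pi*n*k/B) / sum_k I(k)
    S = sum_k I(k) sin(2*pi*n*k/B) / sum_k I(k)

i.e. the normalized discrete Fourier coefficient at harmonic ``n``, using
bin left edges (``k``, not ``k + 1/2``).  The half-bin offset and any
instrument response are rotations/scalings of the phasor and are absorbed
by calibration, which real measurements require anyway.  The identical
formula serves lifetime and spectral stacks; for spectral data ``k`` starts
at the first bin of the detection band.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import AliasingError, ValidationError
from .field import DEFAULT_EXTENT, Histogram2D, PhasorField
from .stacks import DecayStack, SpectralStack


def theoretical_single_exp_phasor(
    tau: float | np.ndarray, frequency: float, harmonic: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form phasor of a single-exponential decay.

    With ``omega = 2*pi*frequency*harmonic``:

        G = 1 / (1 + (omega*tau)^2),   S = omega*tau / (1 + (omega*tau)^2)

    which lies exactly on the universal circle ``S^2 = G - G^2``.  ``tau``
    may be an array; ``tau = 0`` gives (1, 0) and ``tau -> inf`` gives (0, 0).
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValidationError("lifetime tau must be >= 0")
    if not frequency > 0:
        raise ValidationError("frequency must be positive")
    if int(harmonic) < 1:
        raise ValidationError("harmonic must be >= 1")
    wt = 2.0 * np.pi * frequency * int(harmonic) * tau
    denom = 1.0 + wt * wt
    with np.errstate(invalid="ignore"):
        g = np.where(np.isinf(wt), 0.0, 1.0 / denom)
        s = np.where(np.isinf(wt), 0.0, wt / denom)
    if g.ndim == 0:
        return float(g), float(s)
    return g, s


def phasor_transform(
    stack: DecayStack | SpectralStack, harmonics: tuple[int, ...] = (1, 2)
) -> PhasorField:
    """Discrete phasor transform of a stack at the given harmonics.

    Zero-intensity pixels are flagged invalid and carry (G, S) = (0, 0);
    no sentinel value propagates into downstream statistics (every
    operation honors the validity mask).
    """
    harmonics = tuple(int(n) for n in harmonics)
    if len(harmonics) == 0:
        raise ValidationError("harmonics must be non-empty")
    if any(n < 1 for n in harmonics):
        raise ValidationError(f"harmonics must be >= 1; got {harmonics}")
    counts = stack.counts
    B = counts.shape[0]
    for n in harmonics:
        if n >= B:
            raise AliasingError(f"harmonic {n} >= number of bins {B}")
    total = counts.sum(axis=0, dtype=float)
    valid = total > 0
    safe_total = np.where(valid, total, 1.0)

    k = np.arange(B)
    g = np.empty((len(harmonics),) + counts.shape[1:])
    s = np.empty_like(g)
    flat = counts.reshape(B, -1).astype(float)
    for i, n in enumerate(harmonics):
        theta = 2.0 * np.pi * n * k / B
        g[i] = (np.cos(theta) @ flat).reshape(counts.shape[1:]) / safe_total
        s[i] = (np.sin(theta) @ flat).reshape(counts.shape[1:]) / safe_total
    g[:, ~valid] = 0.0
    s[:, ~valid] = 0.0

    frequency = stack.frequency if isinstance(stack, DecayStack) else None
    return PhasorField(
        harmonics=harmonics,
        g=g,
        s=s,
        intensity=total,
        valid=valid,
        frequency=frequency,
        calibration_tag=getattr(stack, "calibration_tag", None),
    )


class PhasorTransformer(BaseEstimator, TransformerMixin):
    """Estimator wrapper around :func:`phasor_transform`.

    Stateless; ``fit`` only validates parameters so the transformer can sit
    in sklearn pipelines.

    Parameters
    ----------
    harmonics : tuple of int, default (1, 2)
        Harmonic numbers to compute.
    """

    def __init__(self, harmonics: tuple[int, ...] = (1, 2)):
        self.harmonics = harmonics

    def fit(self, X=None, y=None):
        harmonics = tuple(int(n) for n in self.harmonics)
        if len(harmonics) == 0 or any(n < 1 for n in harmonics):
            raise ValidationError(f"invalid harmonics {self.harmonics!r}")
        self.harmonics_ = harmonics
        return self

    def transform(self, stack: DecayStack | SpectralStack) -> PhasorField:
        if not hasattr(self, "harmonics_"):
            self.fit()
        return phasor_transform(stack, self.harmonics_)


def filter_phasor(field: PhasorField, kernel_size: int = 3, repeats: int = 1) -> PhasorField:
    """Box-filter the per-pixel G/S maps of every harmonic.

    A uniform ``kernel_size x kernel_size`` mean filter is convolved over
    each coordinate image ``repeats`` times.  Invalid pixels are excluded
    from every neighborhood average (the kernel is renormalized by the
    number of valid neighbors), which also handles image edges.  Intensity
    and validity are unchanged: filtering smooths phasor coordinates, it
    does not create or destroy pixels.
    """
    kernel_size = int(kernel_size)
    repeats = int(repeats)
    if kernel_size < 3 or kernel_size % 2 == 0:
        raise ValidationError(f"kernel_size must be an odd integer >= 3; got {kernel_size}")
    if repeats < 1:
        raise ValidationError(f"repeats must be >= 1; got {repeats}")

    out = field.copy()
    w = field.valid.astype(float)
    wsum = ndimage.uniform_filter(w, size=kernel_size, mode="constant")
    # pixels with no valid neighbor keep their value (they are invalid anyway)
    safe = np.where(wsum > 0, wsum, 1.0)
    for i in range(len(field.harmonics)):
        for img in (out.g, out.s):
            plane = img[i]
            for _ in range(repeats):
                plane = np.where(
                    field.valid,
                    ndimage.uniform_filter(plane * w, size=kernel_size, mode="constant")
                    / safe,
                    plane,
                )
            img[i] = plane
    return out


class PhasorFilter(BaseEstimator, TransformerMixin):
    """Estimator wrapper around :func:`filter_phasor`."""

    def __init__(self, kernel_size: int = 3, repeats: int = 1):
        self.kernel_size = kernel_size
        self.repeats = repeats

    def fit(self, X=None, y=None):
        if int(self.kernel_size) % 2 == 0 or int(self.kernel_size) < 3:
            raise ValidationError(f"kernel_size must be odd >= 3; got {self.kernel_size}")
        return self

    def transform(self, field: PhasorField) -> PhasorField:
        return filter_phasor(field, self.kernel_size, self.repeats)


def intensity_mask(
    field: PhasorField,
    tmin: float = 0.0,
    tmax: float = np.inf,
    external: np.ndarray | None = None,
) -> PhasorField:
    """Restrict the validity mask by an intensity window and an external mask.

    ``valid <- valid & (tmin <= intensity <= tmax) & external`` (bounds
    inclusive).  Returns a new field; coordinates are untouched.
    """
    if tmin > tmax:
        raise ValidationError(f"tmin ({tmin}) > tmax ({tmax})")
    out = field.copy()
    keep = (field.intensity >= tmin) & (field.intensity <= tmax)
    if external is not None:
        external = np.asarray(external, dtype=bool)
        if external.shape != field.shape:
            raise ValidationError(
                f"external mask shape {external.shape} != image shape {field.shape}"
            )
        keep &= external
    out.valid = field.valid & keep
    return out


def phasor_histogram(
    field: PhasorField,
    harmonic: int = 1,
    resolution: int = 256,
    extent: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_EXTENT,
    scale: str = "linear",
) -> Histogram2D:
    """Bin the valid pixels of one harmonic into an R x R phasor histogram.

    Rows bin S, columns bin G.  The total count equals the number of valid
    pixels whose coordinates fall inside ``extent``.
    """
    resolution = int(resolution)
    if resolution < 2:
        raise ValidationError(f"resolution must be >= 2; got {resolution}")
    i = field.index(harmonic)
    gv = field.g[i][field.valid]
    sv = field.s[i][field.valid]
    (gmin, gmax), (smin, smax) = extent
    counts, _, _ = np.histogram2d(
        sv, gv, bins=resolution, range=[[smin, smax], [gmin, gmax]]
    )
    return Histogram2D(counts=counts.astype(np.int64), extent=extent, scale=scale)
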