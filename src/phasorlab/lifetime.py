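"""Lifetime quantification: phase/modulation and universal-circle projections.

A single-exponential decay with lifetime ``tau`` sits on the universal
circle ``S^2 = G - G^2``; any mixture lies inside it.  To report a lifetime
for an off-circle pixel, its phasor must be projected onto the circle.
Three standard projections exist, all with ``omega = 2*pi*f*n``:

* tau-phase:      ``tau = S / (omega * G)`` — same polar angle about the
  origin (precise for fast lifetimes),
* tau-modulation: ``tau = sqrt(1/M^2 - 1) / omega`` — same modulus
  (precise for slow lifetimes),
* tau-normalized: project radially from the circle center (1/2, 0);
  with ``theta = atan2(S, G - 1/2)`` in [0, pi], the projected G is
  ``G_N = (1 + cos(theta)) / 2`` and ``tau = sqrt((1 - G_N)/G_N) / omega``.

On the circle all three agree with the exponential's true ``tau`` (this
identity fixes the algebraic form of each estimator and is asserted in the
test suite).  A generalized projection with arbitrary origin and
radial/angular mode covers all of these as special cases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import matplotlib
import numpy as np

from .exceptions import CalibrationWarning, ValidationError
from .field import PhasorField

_CIRCLE_CENTER = (0.5, 0.0)
_CIRCLE_R2 = 0.25


@dataclass
class PolarMeasurement:
    """Per-pixel phase (radians, atan2 convention) and modulation."""

    phase: np.ndarray
    modulation: np.ndarray
    valid: np.ndarray


@dataclass
class LifetimeImage:
    """Per-pixel lifetime in seconds with the projection method used."""

    tau: np.ndarray
    method: str
    valid: np.ndarray


@dataclass
class UniversalCircleProjection:
    """Projected on-circle coordinates for a custom projection."""

    g: np.ndarray
    s: np.ndarray
    origin: tuple[float, float]
    mode: str
    valid: np.ndarray


def phase_modulation(field: PhasorField, harmonic: int = 1) -> PolarMeasurement:
    """Full-quadrant phase ``atan2(S, G)`` and modulation ``sqrt(G^2+S^2)``."""
    g, s = field.coords(harmonic)
    return PolarMeasurement(
        phase=np.arctan2(s, g), modulation=np.hypot(g, s), valid=field.valid.copy()
    )


def _check_calibrated(field: PhasorField, strict: bool) -> None:
    if field.frequency is not None and not field.calibrated:
        msg = "field is not calibrated; lifetime values reflect raw instrument phase"
        if strict:
            raise ValidationError(msg)
        warnings.warn(msg, CalibrationWarning, stacklevel=3)


def lifetime_image(
    field: PhasorField,
    harmonic: int = 1,
    method: str = "phase",
    frequency: float | None = None,
    strict_calibration: bool = False,
) -> LifetimeImage:
    """Project each pixel onto the universal circle and report its lifetime.

    ``method`` is one of ``"phase"``, ``"modulation"``, ``"normalized"``.
    Pixels where the projection is undefined (G <= 0 for phase; M = 0 or
    M > 1 for modulation; S < 0 or the projection degenerate for
    normalized) are flagged invalid, as are pixels whose projected
    lifetime would be negative.
    """
    _check_calibrated(field, strict_calibration)
    if frequency is None:
        frequency = field.frequency
    if frequency is None:
        raise ValidationError("frequency required for lifetime projection")
    omega = 2.0 * np.pi * frequency * int(harmonic)
    g, s = field.coords(harmonic)
    valid = field.valid.copy()

    with np.errstate(divide="ignore", invalid="ignore"):
        if method == "phase":
            ok = g > 0
            tau = np.where(ok, s / (omega * np.where(ok, g, 1.0)), np.nan)
        elif method == "modulation":
            m = np.hypot(g, s)
            ok = (m > 0) & (m <= 1.0)
            msafe = np.where(ok, m, 1.0)
            tau = np.where(ok, np.sqrt(np.maximum(1.0 / msafe**2 - 1.0, 0.0)) / omega, np.nan)
        elif method == "normalized":
            # angle of (G - 1/2, S) lies in [0, pi] only when S >= 0
            ok = s >= 0
            theta = np.arctan2(s, g - 0.5)
            gn = 0.5 * (1.0 + np.cos(theta))
            ok &= gn > 0
            gnsafe = np.where(gn > 0, gn, 1.0)
            tau = np.where(ok, np.sqrt(np.maximum((1.0 - gnsafe) / gnsafe, 0.0)) / omega, np.nan)
        else:
            raise ValidationError(
                f"method must be 'phase', 'modulation' or 'normalized'; got {method!r}"
            )

    valid &= ok & np.isfinite(tau) & (np.nan_to_num(tau, nan=-1.0) >= 0)
    tau = np.where(valid, tau, np.nan)
    return LifetimeImage(tau=tau, method=method, valid=valid)


def custom_projection(
    field: PhasorField,
    origin: tuple[float, float],
    mode: str = "radial",
    harmonic: int = 1,
    frequency: float | None = None,
    strict_calibration: bool = False,
) -> tuple[UniversalCircleProjection, LifetimeImage]:
    """Project pixels onto the universal circle from an arbitrary origin.

    The ray from ``origin`` through each pixel's phasor is intersected with
    the universal circle.  ``mode="radial"`` keeps the nearer intersection
    in the ray direction, ``mode="angular"`` the farther one (for an origin
    strictly inside the circle the two coincide; they differ when the
    origin sits on the circle, e.g. the angular projection from (0, 0) is
    exactly tau-phase).  Tangent rays count as hits; rays that miss the
    circle flag the pixel invalid.  The projected point (G_c, S_c) is
    converted to ``tau = S_c / (omega * G_c)``.
    """
    if mode not in ("radial", "angular"):
        raise ValidationError(f"mode must be 'radial' or 'angular'; got {mode!r}")
    g0, s0 = float(origin[0]), float(origin[1])
    if not (-1.5 <= g0 <= 1.5 and -1.5 <= s0 <= 1.5):
        raise ValidationError(f"origin {origin} outside the phasor region")
    _check_calibrated(field, strict_calibration)
    if frequency is None:
        frequency = field.frequency
    if frequency is None:
        raise ValidationError("frequency required for lifetime projection")
    omega = 2.0 * np.pi * frequency * int(harmonic)
    g, s = field.coords(harmonic)

    dx = g - g0
    dy = s - s0
    rho = np.hypot(dx, dy)
    nonzero = rho > 0
    rsafe = np.where(nonzero, rho, 1.0)
    ux, uy = dx / rsafe, dy / rsafe
    # |origin + t*u - c|^2 = 1/4, c = (1/2, 0)
    ocx, ocy = g0 - _CIRCLE_CENTER[0], s0 - _CIRCLE_CENTER[1]
    b = ux * ocx + uy * ocy
    cterm = ocx * ocx + ocy * ocy - _CIRCLE_R2
    disc = b * b - cterm
    hits = (disc >= -1e-15) & nonzero
    root = np.sqrt(np.maximum(disc, 0.0))
    t1 = -b - root
    t2 = -b + root
    # clamp tiny negative parameters (origin numerically on the circle)
    t1 = np.where(np.abs(t1) < 1e-12, 0.0, t1)
    t2 = np.where(np.abs(t2) < 1e-12, 0.0, t2)
    if mode == "radial":
        t = np.where(t1 >= 0, t1, t2)
    else:
        t = np.where(t2 >= 0, t2, t1)
    hits &= t >= 0
    gc = np.where(hits, g0 + t * ux, np.nan)
    sc = np.where(hits, s0 + t * uy, np.nan)

    valid = field.valid & hits
    if mode == "angular" and (g0, s0) == (0.0, 0.0):
        # definitionally identical to tau-phase; reuse its formula so the
        # two paths agree bit-for-bit
        life = lifetime_image(
            field, harmonic, "phase", frequency, strict_calibration=False
        )
        life = LifetimeImage(tau=life.tau, method="custom", valid=life.valid)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            tau = np.where(valid & (gc > 0), sc / (omega * np.where(gc > 0, gc, 1.0)), np.nan)
        tau_valid = valid & np.isfinite(tau) & (np.nan_to_num(tau, nan=-1.0) >= 0)
        tau = np.where(tau_valid, tau, np.nan)
        life = LifetimeImage(tau=tau, method="custom", valid=tau_valid)
    proj = UniversalCircleProjection(g=gc, s=sc, origin=(g0, s0), mode=mode, valid=valid)
    return proj, life


def gradient_colormap(
    values: np.ndarray | LifetimeImage | PolarMeasurement,
    vmin: float,
    vmax: float,
    colormap: str = "viridis",
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Map values to an RGB uint8 image through a matplotlib colormap.

    Values are clipped to ``[vmin, vmax]`` and mapped affinely onto the
    colormap; invalid pixels render black.
    """
    if not vmin < vmax:
        raise ValidationError(f"vmin ({vmin}) must be < vmax ({vmax})")
    if isinstance(values, LifetimeImage):
        valid = values.valid if valid is None else valid
        values = values.tau
    elif isinstance(values, PolarMeasurement):
        valid = values.valid if valid is None else valid
        values = values.phase
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.isfinite(values)
    frac = np.clip((np.nan_to_num(values, nan=vmin) - vmin) / (vmax - vmin), 0.0, 1.0)
    cmap = matplotlib.colormaps[colormap]
    rgb = (cmap(frac)[..., :3] * 255).round().astype(np.uint8)
    rgb[~valid] = 0
    return rgb
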