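"""Instrument calibration of phasor coordinates.

The instrument response delays and demodulates the measured signal, which
in phasor space is a per-harmonic rotation and scaling.  A reference
measurement of a fluorophore with known single-exponential lifetime
``tau_ref`` pins both: the correction phase shift ``dphi(n)`` and
modulation factor ``k(n)`` map the measured reference phasor onto the
closed-form point for ``tau_ref``.  Applying the correction multiplies each
pixel's phasor ``G + iS`` by ``k(n) * exp(i * dphi(n))``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import DegenerateReferenceError, ValidationError
from .field import PhasorField
from .transform import theoretical_single_exp_phasor


def wrap_angle(phi: float) -> float:
    """Wrap an angle into (-pi, pi]."""
    phi = float(phi)
    wrapped = (phi + np.pi) % (2.0 * np.pi) - np.pi
    if wrapped == -np.pi:
        wrapped = np.pi
    return wrapped


@dataclass
class CalibrationCorrection:
    """Per-harmonic phase shift (radians) and modulation factor (> 0)."""

    phase_shift: dict[int, float]
    mod_factor: dict[int, float]
    provenance: str = "manual"
    tau_ref: float | None = None
    tag: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.phase_shift = {int(n): wrap_angle(v) for n, v in self.phase_shift.items()}
        self.mod_factor = {int(n): float(v) for n, v in self.mod_factor.items()}
        if set(self.phase_shift) != set(self.mod_factor):
            raise ValidationError("phase_shift and mod_factor must cover the same harmonics")
        for n, k in self.mod_factor.items():
            if not k > 0:
                raise ValidationError(f"modulation factor must be > 0 (harmonic {n}: {k})")

    @property
    def harmonics(self) -> tuple[int, ...]:
        return tuple(sorted(self.phase_shift))

    def inverse(self) -> "CalibrationCorrection":
        """The correction undoing this one: (-dphi, 1/k) per harmonic."""
        return CalibrationCorrection(
            phase_shift={n: -v for n, v in self.phase_shift.items()},
            mod_factor={n: 1.0 / v for n, v in self.mod_factor.items()},
            provenance=self.provenance,
            tau_ref=self.tau_ref,
        )

    def to_json(self, path) -> None:
        payload = {
            "provenance": self.provenance,
            "tau_ref": self.tau_ref,
            "tag": self.tag,
            "harmonics": [
                {"n": n, "phase_shift": self.phase_shift[n], "mod_factor": self.mod_factor[n]}
                for n in self.harmonics
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationCorrection":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            phase_shift={h["n"]: h["phase_shift"] for h in payload["harmonics"]},
            mod_factor={h["n"]: h["mod_factor"] for h in payload["harmonics"]},
            provenance=payload.get("provenance", "manual"),
            tau_ref=payload.get("tau_ref"),
            tag=payload.get("tag"),
        )


def reference_phasor(reference: PhasorField, harmonic: int) -> complex:
    """Intensity-weighted mean phasor of the valid reference pixels.

    Pixel phasors are averaged as complex numbers weighted by intensity
    (not as per-pixel phases), which is the estimator consistent with
    phasor linearity.
    """
    if not reference.valid.any():
        raise ValidationError("reference field has no valid pixel")
    w = reference.intensity[reference.valid]
    p = reference.phasor(harmonic)[reference.valid]
    return complex((w * p).sum() / w.sum())


def compute_correction(
    reference: PhasorField,
    tau_ref: float,
    frequency: float | None = None,
    harmonics: tuple[int, ...] | None = None,
) -> CalibrationCorrection:
    """Correction mapping a measured reference onto its theoretical phasor.

    For each harmonic ``n``: ``dphi(n) = phi_theory - phi_measured`` and
    ``k(n) = M_theory / M_measured`` where the theoretical point is
    :func:`theoretical_single_exp_phasor` at ``tau_ref`` and
    ``omega = 2*pi*frequency*n``.
    """
    if tau_ref < 0:
        raise ValidationError("tau_ref must be >= 0")
    if frequency is None:
        frequency = reference.frequency
    if frequency is None:
        raise ValidationError("frequency required (reference field carries none)")
    if harmonics is None:
        harmonics = reference.harmonics
    phase_shift: dict[int, float] = {}
    mod_factor: dict[int, float] = {}
    for n in harmonics:
        meas = reference_phasor(reference, n)
        if abs(meas) == 0:
            raise DegenerateReferenceError(
                f"reference modulation is zero at harmonic {n}"
            )
        gt, st = theoretical_single_exp_phasor(tau_ref, frequency, n)
        theo = gt + 1j * st
        phase_shift[n] = wrap_angle(np.angle(theo) - np.angle(meas))
        mod_factor[n] = abs(theo) / abs(meas)
    return CalibrationCorrection(
        phase_shift=phase_shift,
        mod_factor=mod_factor,
        provenance="reference_file",
        tau_ref=float(tau_ref),
        tag=reference.calibration_tag,
    )


def manual_correction(
    phase_shifts, mod_factors, harmonics: tuple[int, ...] | None = None
) -> CalibrationCorrection:
    """Build a correction from user-entered (dphi, k) pairs.

    ``phase_shifts``/``mod_factors`` may be scalars (applied to harmonic 1),
    sequences (harmonics 1..N), or dicts keyed by harmonic.  Angles are
    wrapped into (-pi, pi].
    """
    if np.isscalar(phase_shifts):
        phase_shifts = [phase_shifts]
    if np.isscalar(mod_factors):
        mod_factors = [mod_factors]
    if isinstance(phase_shifts, dict):
        ps = {int(n): float(v) for n, v in phase_shifts.items()}
        mf = {int(n): float(v) for n, v in mod_factors.items()}
    else:
        if harmonics is None:
            harmonics = tuple(range(1, len(list(phase_shifts)) + 1))
        ps = dict(zip(harmonics, (float(v) for v in phase_shifts)))
        mf = dict(zip(harmonics, (float(v) for v in mod_factors)))
    return CalibrationCorrection(phase_shift=ps, mod_factor=mf, provenance="manual")


def apply_correction(field: PhasorField, correction: CalibrationCorrection) -> PhasorField:
    """Rotate/scale every pixel phasor by the per-harmonic correction.

    Intensity and validity are unchanged; the result is marked calibrated.
    """
    missing = [n for n in field.harmonics if n not in correction.phase_shift]
    if missing:
        raise ValidationError(f"correction lacks harmonics {missing}")
    out = field.copy()
    for i, n in enumerate(field.harmonics):
        factor = correction.mod_factor[n] * np.exp(1j * correction.phase_shift[n])
        p = (field.g[i] + 1j * field.s[i]) * factor
        out.g[i] = p.real
        out.s[i] = p.imag
        out.g[i][~field.valid] = 0.0
        out.s[i][~field.valid] = 0.0
    out.calibrated = True
    return out


class PhasorCalibrator(BaseEstimator, TransformerMixin):
    """Fit a calibration on a reference field, then correct other fields.

    Parameters
    ----------
    tau_ref : float
        Known single-exponential lifetime of the reference fluorophore, s.
    frequency : float, optional
        Repetition frequency in Hz; defaults to the reference field's own.

    Attributes
    ----------
    correction_ : CalibrationCorrection
    phase_shift_, mod_factor_ : dict
        Per-harmonic correction terms.
    """

    def __init__(self, tau_ref: float = 0.0, frequency: float | None = None):
        self.tau_ref = tau_ref
        self.frequency = frequency

    def fit(self, reference: PhasorField, y=None):
        self.correction_ = compute_correction(reference, self.tau_ref, self.frequency)
        self.phase_shift_ = self.correction_.phase_shift
        self.mod_factor_ = self.correction_.mod_factor
        return self

    def transform(self, field: PhasorField) -> PhasorField:
        if not hasattr(self, "correction_"):
            raise ValidationError("PhasorCalibrator is not fitted")
        return apply_correction(field, self.correction_)
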