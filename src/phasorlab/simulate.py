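"""Synthetic decay and spectral stacks with known ground truth.

The generator emulates what the analysis pipeline sees from a real
instrument at desk scale: per-pixel photon-count histograms from
multi-exponential decays (or Gaussian emission bands) with Poisson shot
noise, plus a ground-truth record of the exact photon fractions and
species parameters behind every pixel.

Forward model (lifetime): a species with lifetime ``tau`` under periodic
excitation at frequency ``f = 1/T`` produces the steady-state periodic
exponential, point-sampled at bin centers ``t_k = (k + 1/2) T / B`` and
normalized to unit total, so mixture weights are exactly photon fractions.
The wrapped tail is a constant factor per species and cancels in the
normalization; high-B simulations converge to the continuous closed form.
Bin centers are used independently of the transform's left-edge
convention — the resulting half-bin phase offset is absorbed by
calibration, mirroring how real instruments are handled.  No instrument
response is convolved; phase/modulation distortions are emulated directly
(see :func:`make_reference_stack`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .exceptions import ValidationError
from .stacks import DecayStack, SpectralStack


@dataclass
class LifetimeSpecies:
    """Single-exponential species with lifetime ``tau`` in seconds."""

    tau: float
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValidationError(f"species lifetime must be > 0; got {self.tau}")


@dataclass
class SpectralSpecies:
    """Gaussian emission band: center and width in nm (sigma = 0 -> delta)."""

    center: float
    sigma: float
    name: str | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError(f"emission sigma must be >= 0; got {self.sigma}")


@dataclass
class SceneSpec:
    """Scene description: spatial layout of species mixtures.

    ``layout`` assigns an integer label to every pixel; ``mixtures`` maps
    each label to per-species weights (normalized to sum to 1, which makes
    them the photon fractions of the pixel).  ``noise="poisson"`` draws
    counts from the expected histogram; ``"none"`` returns the expected
    (float) counts, i.e. the infinite-photon limit scaled to
    ``photons_per_pixel``.
    """

    layout: np.ndarray
    species: list
    mixtures: dict[int, tuple[float, ...]]
    photons_per_pixel: float = 1e4
    n_bins: int = 256
    frequency: float | None = None
    band: tuple[float, float] | None = None
    seed: int | None = None
    noise: str = "poisson"

    def __post_init__(self) -> None:
        self.layout = np.atleast_2d(np.asarray(self.layout, dtype=int))
        if not self.photons_per_pixel > 0:
            raise ValidationError("photons_per_pixel must be > 0")
        if self.n_bins < 2:
            raise ValidationError("n_bins must be >= 2")
        if self.noise not in ("poisson", "none"):
            raise ValidationError(f"noise must be 'poisson' or 'none'; got {self.noise!r}")
        norm = {}
        for label, w in self.mixtures.items():
            w = np.asarray(w, dtype=float)
            if w.shape != (len(self.species),) or np.any(w < 0) or w.sum() <= 0:
                raise ValidationError(
                    f"mixture for label {label} must be {len(self.species)} "
                    "non-negative weights"
                )
            norm[int(label)] = tuple(w / w.sum())
        self.mixtures = norm
        present = set(np.unique(self.layout))
        missing = present - set(self.mixtures)
        if missing:
            raise ValidationError(f"layout labels {sorted(missing)} have no mixture")

    @classmethod
    def from_json(cls, path) -> "SceneSpec":
        with open(path) as fh:
            d = json.load(fh)
        species = []
        for sp in d["species"]:
            if "tau_ns" in sp:
                species.append(LifetimeSpecies(tau=sp["tau_ns"] * 1e-9, name=sp.get("name")))
            elif "tau" in sp:
                species.append(LifetimeSpecies(tau=sp["tau"], name=sp.get("name")))
            else:
                species.append(
                    SpectralSpecies(
                        center=sp["center_nm"], sigma=sp["sigma_nm"], name=sp.get("name")
                    )
                )
        freq = d.get("frequency_mhz")
        return cls(
            layout=np.asarray(d["layout"], dtype=int),
            species=species,
            mixtures={int(k): tuple(v) for k, v in d["mixtures"].items()},
            photons_per_pixel=d.get("photons_per_pixel", 1e4),
            n_bins=d.get("n_bins", 256),
            frequency=freq * 1e6 if freq is not None else d.get("frequency"),
            band=tuple(d["band_nm"]) if "band_nm" in d else None,
            seed=d.get("seed"),
            noise=d.get("noise", "poisson"),
        )


@dataclass
class GroundTruth:
    """Exactly what the generator put in each pixel."""

    fractions: np.ndarray  # (n_species, H, W) photon fractions
    species: list
    mixtures: dict[int, tuple[float, ...]]
    truncation: dict[int, float] = dc_field(default_factory=dict)

    def to_json(self, path) -> None:
        species = []
        for sp in self.species:
            if isinstance(sp, LifetimeSpecies):
                species.append({"tau": sp.tau, "name": sp.name})
            else:
                species.append({"center_nm": sp.center, "sigma_nm": sp.sigma, "name": sp.name})
        payload = {
            "species": species,
            "mixtures": {str(k): list(v) for k, v in self.mixtures.items()},
            "fractions": self.fractions.tolist(),
            "truncation": {str(k): v for k, v in self.truncation.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _expand_fractions(spec: SceneSpec) -> np.ndarray:
    n = len(spec.species)
    frac = np.zeros((n,) + spec.layout.shape)
    for label, w in spec.mixtures.items():
        mask = spec.layout == label
        for i in range(n):
            frac[i][mask] = w[i]
    return frac


def _sample(expected: np.ndarray, spec: SceneSpec) -> np.ndarray:
    if spec.noise == "poisson":
        rng = np.random.default_rng(spec.seed)
        return rng.poisson(expected).astype(np.uint32)
    return expected


def decay_profile(tau: float, n_bins: int, period: float) -> np.ndarray:
    """Unit-area periodic single-exponential histogram at bin centers."""
    t = (np.arange(n_bins) + 0.5) * period / n_bins
    p = np.exp(-t / tau)
    return p / p.sum()


def simulate_decay_stack(spec: SceneSpec) -> tuple[DecayStack, GroundTruth]:
    """Generate a time-resolved stack from a lifetime scene."""
    if spec.frequency is None or not spec.frequency > 0:
        raise ValidationError("lifetime scene requires a positive frequency")
    for sp in spec.species:
        if not isinstance(sp, LifetimeSpecies):
            raise ValidationError("simulate_decay_stack needs LifetimeSpecies only")
    period = 1.0 / spec.frequency
    profiles = np.stack(
        [decay_profile(sp.tau, spec.n_bins, period) for sp in spec.species]
    )  # (n_species, B)
    frac = _expand_fractions(spec)
    expected = spec.photons_per_pixel * np.einsum("ib,ihw->bhw", profiles, frac)
    counts = _sample(expected, spec)
    stack = DecayStack(counts=counts, frequency=spec.frequency)
    return stack, GroundTruth(fractions=frac, species=spec.species, mixtures=spec.mixtures)


def emission_profile(
    center: float, sigma: float, n_bins: int, band: tuple[float, float]
) -> tuple[np.ndarray, float]:
    """Discretized Gaussian band; returns (unit-area profile, truncated mass)."""
    lam0, lam1 = band
    d = (lam1 - lam0) / n_bins
    lam = lam0 + (np.arange(n_bins) + 0.5) * d
    if sigma == 0:
        p = np.zeros(n_bins)
        k = int(np.clip((center - lam0) / d, 0, n_bins - 1))
        p[k] = 1.0
        lost = 0.0 if lam0 <= center <= lam1 else 1.0
        return p, lost
    p = np.exp(-0.5 * ((lam - center) / sigma) ** 2)
    total = p.sum()
    if total <= 0:
        raise ValidationError(
            f"emission band at {center} nm has no support in {band}"
        )
    # mass outside the detection band, in the continuous model
    from scipy.stats import norm

    lost = float(norm.cdf((lam0 - center) / sigma) + norm.sf((lam1 - center) / sigma))
    return p / total, lost


def simulate_spectral_stack(spec: SceneSpec) -> tuple[SpectralStack, GroundTruth]:
    """Generate a hyperspectral stack from an emission-band scene."""
    if spec.band is None:
        raise ValidationError("spectral scene requires a band (lambda0, lambda1)")
    for sp in spec.species:
        if not isinstance(sp, SpectralSpecies):
            raise ValidationError("simulate_spectral_stack needs SpectralSpecies only")
    profiles = []
    truncation: dict[int, float] = {}
    for i, sp in enumerate(spec.species):
        p, lost = emission_profile(sp.center, sp.sigma, spec.n_bins, spec.band)
        profiles.append(p)
        if lost > 1e-6:
            truncation[i] = lost
            warnings.warn(
                f"species {sp.name or i}: {lost:.1%} of the emission band falls "
                f"outside {spec.band}; profile truncated",
                stacklevel=2,
            )
    profiles = np.stack(profiles)
    frac = _expand_fractions(spec)
    expected = spec.photons_per_pixel * np.einsum("ib,ihw->bhw", profiles, frac)
    counts = _sample(expected, spec)
    stack = SpectralStack(counts=counts, band=spec.band)
    return stack, GroundTruth(
        fractions=frac, species=spec.species, mixtures=spec.mixtures, truncation=truncation
    )


def make_reference_stack(
    tau_ref: float,
    distortion: tuple[float, float] = (0.0, 1.0),
    shape: tuple[int, int] = (8, 8),
    photons_per_pixel: float = 1e6,
    n_bins: int = 256,
    frequency: float = 80e6,
    seed: int | None = None,
    noise: str = "poisson",
) -> DecayStack:
    """Reference fixture whose phasor is distorted by a known (dphi, k).

    The phase shift is realized as a circular time shift of the continuous
    periodic decay (``delta = dphi / (2 pi f)``), so harmonic ``n`` picks up
    a phase of ``n * dphi`` — exactly how a real instrument delay behaves.
    The modulation factor ``k`` is realized by mixing a fraction ``1 - k``
    of uniform background photons, which scales every harmonic's modulus by
    ``k``; only ``0 < k <= 1`` has a physical count-based realization.
    Both are exact for the continuous model and accurate to discretization
    order for the sampled one, which is what calibration-recovery tests
    need.
    """
    dphi, kfac = distortion
    if not 0.0 < kfac <= 1.0:
        raise ValidationError(
            f"modulation distortion k must be in (0, 1] for a count-based "
            f"realization; got {kfac}"
        )
    if not tau_ref > 0:
        raise ValidationError("tau_ref must be > 0")
    period = 1.0 / frequency
    delta = dphi / (2.0 * np.pi * frequency)
    # bin-integrate the shifted profile (64x oversampling): the wrap
    # discontinuity moves with the fractional-bin shift, and point sampling
    # it would bias the phasor by O(1/B); detectors integrate over bins
    over = 64
    t = (np.arange(n_bins * over) + 0.5) * period / (n_bins * over)
    p = np.exp(-((t - delta) % period) / tau_ref).reshape(n_bins, over).mean(axis=1)
    p /= p.sum()
    profile = kfac * p + (1.0 - kfac) / n_bins
    expected = photons_per_pixel * np.broadcast_to(
        profile[:, None, None], (n_bins,) + tuple(shape)
    )
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(np.uint32)
    else:
        counts = np.array(expected)
    return DecayStack(counts=counts, frequency=frequency)
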