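import numpy as np
import pytest

from phasorlab import (
    LifetimeSpecies,
    PhasorField,
    SceneSpec,
    compute_correction,
    apply_correction,
    phasor_transform,
    simulate_decay_stack,
)

FREQ = 80e6  # Hz, typical Ti:Sapphire repetition rate


def make_field(g, s, intensity=None, valid=None, harmonics=None, frequency=FREQ,
               calibrated=True):
    """Build a PhasorField from per-harmonic coordinate images.

    ``g``/``s`` may be 2-D (single harmonic) or 3-D arrays.
    """
    g = np.asarray(g, dtype=float)
    s = np.asarray(s, dtype=float)
    if g.ndim == 2:
        g = g[None]
        s = s[None]
    if harmonics is None:
        harmonics = tuple(range(1, g.shape[0] + 1))
    if intensity is None:
        intensity = np.ones(g.shape[1:])
    if valid is None:
        valid = np.ones(g.shape[1:], dtype=bool)
    return PhasorField(
        harmonics=harmonics, g=g, s=s, intensity=np.asarray(intensity, float),
        valid=np.asarray(valid, bool), frequency=frequency, calibrated=calibrated,
    )


def noiseless_exponential_field(tau, n_bins=256, harmonics=(1, 2), shape=(2, 2),
                                frequency=FREQ, photons=1e6):
    """Transform of a noiseless sampled exponential (uncalibrated)."""
    spec = SceneSpec(
        layout=np.zeros(shape, dtype=int),
        species=[LifetimeSpecies(tau)],
        mixtures={0: (1.0,)},
        photons_per_pixel=photons,
        n_bins=n_bins,
        frequency=frequency,
        noise="none",
    )
    stack, _ = simulate_decay_stack(spec)
    return phasor_transform(stack, harmonics)


def calibrated_exponential_field(tau, tau_ref=4e-9, n_bins=256, harmonics=(1, 2),
                                 shape=(2, 2), frequency=FREQ):
    """Noiseless exponential transformed and calibrated against tau_ref."""
    field = noiseless_exponential_field(tau, n_bins, harmonics, shape, frequency)
    ref = noiseless_exponential_field(tau_ref, n_bins, harmonics, shape, frequency)
    corr = compute_correction(ref, tau_ref, frequency)
    return apply_correction(field, corr)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
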