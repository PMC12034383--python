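# phasorlab

Phasor analysis for fluorescence lifetime (FLIM) and hyperspectral
microscopy: the discrete phasor transform at arbitrary harmonics,
instrument calibration, universal-circle lifetime maps, cursor and
reciprocity selection, Gaussian-mixture clustering of phasor
distributions, and quantitative multi-harmonic unmixing of fluorescent
components — as a scriptable Python library with a CLI, plus a synthetic
scene generator so every stage is testable without instrument data.

## Who this is for

FLIM and spectral-imaging labs that want model-free, fit-free phasor
workflows in scripts and pipelines: each pixel's photon distribution
(decay histogram or emission spectrum) is mapped to a point in a 2-D
phasor space, where populations separate visually and algebraically
without assuming a decay model.

## The mathematics in brief

For a pixel histogram `I(k)`, `k = 0..B-1`, the harmonic-`n` phasor is

    G = Σ I(k) cos(2πnk/B) / Σ I(k),   S = Σ I(k) sin(2πnk/B) / Σ I(k)

i.e. the normalized discrete Fourier coefficient at harmonic `n`. A
single-exponential decay with lifetime τ at angular frequency `ω = 2πfn`
sits at

    G = 1/(1+(ωτ)²),  S = ωτ/(1+(ωτ)²)

on the **universal circle** `S² = G − G²`; mixtures lie inside it. With
phase `φ = atan2(S, G)` and modulation `M = √(G²+S²)`, the three standard
lifetime projections are

    τ_φ = S/(ωG)        (angular, precise for fast lifetimes)
    τ_M = √(1/M² − 1)/ω (modulus, precise for slow lifetimes)
    τ_N = √((1−G_N)/G_N)/ω,  G_N = ½(1 + cos θ),  θ = atan2(S, G−½)

(τ_N projects radially from the circle center). Instrument delay and
demodulation are corrected per harmonic by a rotation `Δφ(n)` and scaling
`k(n)` fitted on a reference fluorophore of known lifetime.

Phasor coordinates are **linear in photon fractions**, so a pixel holding
`C` species satisfies, across `N` harmonics plus the normalization row, a
`(2N+1) × C` linear system — `N` harmonics resolve up to `2N+1`
components. Components are defined by lifetime (closed form) or measured
empirically (required for spectral species).

## Worked example

```python
import numpy as np
from phasorlab import *

# Two-region scene: left 80:20 fast:slow, right 20:80 (1 ns / 4 ns dyes)
scene = SceneSpec(
    layout=np.repeat([[0, 1]], 16, axis=0).repeat(16, axis=1),
    species=[LifetimeSpecies(1.0e-9, "fast"), LifetimeSpecies(4.0e-9, "slow")],
    mixtures={0: (0.8, 0.2), 1: (0.2, 0.8)},
    photons_per_pixel=5e4, n_bins=256, frequency=80e6, seed=42,
)
stack, truth = simulate_decay_stack(scene)
field = phasor_transform(stack, harmonics=(1, 2))

# Calibrate against a 4 ns single-exponential reference
ref_scene = SceneSpec(layout=np.zeros((4, 4), int), species=[LifetimeSpecies(4e-9)],
                      mixtures={0: (1.0,)}, photons_per_pixel=1e6, n_bins=256,
                      frequency=80e6, noise="none")
ref_stack, _ = simulate_decay_stack(ref_scene)
cal = PhasorCalibrator(tau_ref=4e-9).fit(phasor_transform(ref_stack, (1, 2)))
field = cal.transform(filter_phasor(field, kernel_size=3))

life = lifetime_image(field, harmonic=1, method="phase")
print(f"tau-phase, region means: {np.nanmean(life.tau[:, :16])*1e9:.3f} ns | "
      f"{np.nanmean(life.tau[:, 16:])*1e9:.3f} ns")

cset = ComponentSet([Component("fast", tau=1.0e-9), Component("slow", tau=4.0e-9)],
                    harmonics=(1, 2), frequency=80e6)
result = unmix_field(field, cset)
print(f"mean fast fraction: region A {result.fractions[0, :, :16].mean():.3f} "
      f"(truth 0.800), region B {result.fractions[0, :, 16:].mean():.3f} (truth 0.200)")
```

prints

```
tau-phase, region means: 1.191 ns | 2.453 ns
mean fast fraction: region A 0.788 (truth 0.800), region B 0.213 (truth 0.200)
```

The tau-phase means fall between the two pure lifetimes because each
region is a mixture — a single projected "lifetime" of a mixed pixel is a
summary, not a species lifetime. The two-harmonic unmixing recovers the
actual photon fractions of each species to ~0.01 at this photon budget
(the residual reflects shot noise and the finite 256-bin discretization).

The estimators follow scikit-learn conventions (`fit`/`transform`/
`predict`, `get_params`, fitted attributes with trailing underscores), so
`PhasorTransformer`, `PhasorFilter`, `PhasorCalibrator`, `PhasorGMM` and
`ComponentUnmixer` compose with sklearn tooling.

## Command line

```bash
phasorlab simulate --spec scene.json --seed 1 --out stack.tif
phasorlab transform stack.tif --harmonics 1,2 --filter-size 3 --out phasor.ref.tif
phasorlab calibrate --reference ref.tif --tau-ref 4.0 --out corr.json
phasorlab lifetime phasor.ref.tif --method phase --correction corr.json --out tau.png
phasorlab cluster fit phasor.ref.tif --k 3 --seed 0 --out model.json
phasorlab unmix phasor.ref.tif --components dyes.json --out unmixed/
phasorlab run --config pipeline.json --seed 1 --out results/
```

`run` executes the whole chain from one JSON config and writes a manifest
with the SHA-256 of every artifact; identical configs and seeds reproduce
byte-identical outputs. Phasor fields are stored in a documented "ref"
container (float32 multi-page TIFF: intensity, then per-harmonic phase in
degrees and modulation, with a JSON sidecar).

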