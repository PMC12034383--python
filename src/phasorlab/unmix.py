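"""Quantitative unmixing of fluorescent components via multiple harmonics.

Phasor coordinates are linear in photon fractions: a pixel containing
components with fractions ``f_i`` has, at every harmonic ``n``,
``(G_n, S_n) = sum_i f_i (G_n^i, S_n^i)``.  Stacking the coordinates of
``N`` harmonics plus the normalization row ``sum_i f_i = 1`` gives a
``(2N+1) x C`` linear system, so ``N`` harmonics can resolve up to
``2N + 1`` components.  Components are defined either by a lifetime
(placed on the universal circle by the closed form at each harmonic) or by
an empirical phasor measurement — the latter is how spectral species,
which have no closed form, are unmixed.

Fractions are photon fractions (the linearity above is photon-weighted);
conversion to molar fractions would require brightness factors and is out
of scope.  All harmonics enter the system with equal weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ConditioningError, ValidationError
from .field import PhasorField
from .transform import theoretical_single_exp_phasor

#: Weight of the sum-to-one row under the nonnegative solver; large enough
#: to hold the constraint to ~1e-6 without wrecking conditioning.
NONNEG_SUM_WEIGHT = 1e3


@dataclass
class Component:
    """A pure species: either a lifetime or an empirical phasor signature.

    ``phasor`` maps harmonic number -> (G, S) for empirical components.
    """

    name: str
    tau: float | None = None
    phasor: dict[int, tuple[float, float]] | None = None
    color: tuple[int, int, int] = (255, 255, 255)

    def __post_init__(self) -> None:
        if (self.tau is None) == (self.phasor is None):
            raise ValidationError(
                f"component {self.name!r}: define exactly one of tau or phasor"
            )
        if self.tau is not None and self.tau < 0:
            raise ValidationError(f"component {self.name!r}: tau must be >= 0")

    def coordinates(self, harmonic: int, frequency: float | None) -> tuple[float, float]:
        if self.tau is not None:
            if frequency is None:
                raise ValidationError(
                    f"component {self.name!r} is lifetime-defined; frequency required"
                )
            return theoretical_single_exp_phasor(self.tau, frequency, harmonic)
        try:
            g, s = self.phasor[int(harmonic)]
        except KeyError:
            raise ValidationError(
                f"component {self.name!r} has no phasor at harmonic {harmonic}"
            ) from None
        return float(g), float(s)


@dataclass
class ComponentSet:
    """Pure components plus the harmonics used to unmix them."""

    components: list[Component]
    harmonics: tuple[int, ...] = (1, 2)
    frequency: float | None = None

    def __post_init__(self) -> None:
        self.harmonics = tuple(int(n) for n in self.harmonics)
        if not self.components:
            raise ValidationError("component set is empty")
        limit = 2 * len(self.harmonics) + 1
        if len(self.components) > limit:
            raise ValidationError(
                f"{len(self.components)} components exceed the 2N+1 = {limit} limit "
                f"for {len(self.harmonics)} harmonics"
            )

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.components]

    @property
    def colors(self) -> list[tuple[int, int, int]]:
        return [c.color for c in self.components]


def build_component_matrix(cset: ComponentSet) -> np.ndarray:
    """Stacked coordinate matrix, one column per component.

    Column ``i`` is ``[G_1^i, S_1^i, ..., G_N^i, S_N^i, 1]``.  Raises
    :class:`ConditioningError` naming the closest pair if two components
    coincide in stacked coordinates.
    """
    C = len(cset.components)
    rows = 2 * len(cset.harmonics) + 1
    A = np.ones((rows, C))
    for j, comp in enumerate(cset.components):
        for i, n in enumerate(cset.harmonics):
            A[2 * i, j], A[2 * i + 1, j] = comp.coordinates(n, cset.frequency)
    # pairwise separation in stacked phasor coordinates
    coords = A[:-1]
    for a in range(C):
        for b in range(a + 1, C):
            if np.linalg.norm(coords[:, a] - coords[:, b]) <= 1e-9:
                raise ConditioningError(
                    f"components {cset.components[a].name!r} and "
                    f"{cset.components[b].name!r} have indistinguishable phasors"
                )
    return A


@dataclass
class FractionField:
    """Per-component photon-fraction images with per-pixel residual norm."""

    fractions: np.ndarray  # (C, H, W)
    residual: np.ndarray  # (H, W)
    valid: np.ndarray
    names: list[str]
    colors: list[tuple[int, int, int]] = dc_field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.fractions.shape[0]


class ComponentUnmixer(BaseEstimator, TransformerMixin):
    """Solve per-pixel photon fractions from multi-harmonic phasors.

    With ``C = 2N+1`` components the square system is solved exactly; with
    fewer, by least squares.  ``nonneg=True`` switches to nonnegative least
    squares with the sum-to-one row up-weighted so the constraint holds to
    ~1e-6.  The default solver reports negative fractions as-is — they are
    a useful diagnostic of badly chosen components.

    Attributes
    ----------
    matrix_ : ndarray (2N+1, C)
        Stacked component coordinates.
    component_set_ : ComponentSet
    """

    def __init__(
        self,
        components=None,
        harmonics: tuple[int, ...] = (1, 2),
        frequency: float | None = None,
        nonneg: bool = False,
    ):
        self.components = components
        self.harmonics = harmonics
        self.frequency = frequency
        self.nonneg = nonneg

    def fit(self, X=None, y=None):
        comps = self.components
        if isinstance(comps, ComponentSet):
            cset = comps
        else:
            cset = ComponentSet(
                components=list(comps or []),
                harmonics=tuple(self.harmonics),
                frequency=self.frequency,
            )
        self.component_set_ = cset
        self.matrix_ = build_component_matrix(cset)
        if self.matrix_.shape[1] == self.matrix_.shape[0]:
            cond = np.linalg.cond(self.matrix_)
            if not np.isfinite(cond) or cond > 1e12:
                raise ConditioningError(
                    f"component matrix numerically singular (cond={cond:.3g})"
                )
        return self

    def transform(self, field: PhasorField) -> FractionField:
        if not hasattr(self, "matrix_"):
            self.fit()
        cset = self.component_set_
        missing = [n for n in cset.harmonics if n not in field.harmonics]
        if missing:
            raise ValidationError(f"field lacks harmonics {missing} needed for unmixing")
        A = self.matrix_
        rows, C = A.shape

        idx = np.flatnonzero(field.valid.ravel())
        M = np.ones((rows, idx.size))
        for i, n in enumerate(cset.harmonics):
            hi = field.index(n)
            M[2 * i] = field.g[hi].ravel()[idx]
            M[2 * i + 1] = field.s[hi].ravel()[idx]

        if self.nonneg:
            Aw = A.copy()
            Aw[-1] *= NONNEG_SUM_WEIGHT
            F = np.empty((C, idx.size))
            for j in range(idx.size):
                m = M[:, j].copy()
                m[-1] *= NONNEG_SUM_WEIGHT
                F[:, j], _ = nnls(Aw, m)
        elif C == rows:
            F = np.linalg.solve(A, M)
        else:
            F, *_ = np.linalg.lstsq(A, M, rcond=None)

        resid = np.linalg.norm(A @ F - M, axis=0)
        fractions = np.zeros((C,) + field.shape)
        residual = np.full(field.shape, np.nan)
        fractions.reshape(C, -1)[:, idx] = F
        residual.ravel()[idx] = resid
        return FractionField(
            fractions=fractions,
            residual=residual,
            valid=field.valid.copy(),
            names=cset.names,
            colors=cset.colors,
        )


def unmix_field(
    field: PhasorField, cset: ComponentSet, nonneg: bool = False
) -> FractionField:
    """Functional wrapper over :class:`ComponentUnmixer`."""
    return ComponentUnmixer(components=cset, nonneg=nonneg).fit().transform(field)


def ratio_image(fractions: FractionField, i: int, j: int) -> tuple[np.ndarray, np.ndarray]:
    """Ratio-metric image ``f_i / (f_i + f_j)``.

    Returns ``(ratio, valid)``; pixels where ``f_i + f_j <= 1e-12`` (or
    that were already invalid) are flagged invalid and carry NaN.
    """
    if i == j:
        raise ValidationError("ratio image needs two distinct components")
    fi = fractions.fractions[i]
    fj = fractions.fractions[j]
    denom = fi + fj
    ok = fractions.valid & (denom > 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ok, fi / np.where(ok, denom, 1.0), np.nan)
    return ratio, ok


def empirical_component(
    field: PhasorField,
    region: np.ndarray,
    name: str,
    color: tuple[int, int, int] = (255, 255, 255),
) -> Component:
    """Measure a pure component from an image-space region.

    The component phasor at every harmonic of ``field`` is the
    intensity-weighted mean over the region's valid pixels.
    """
    region = np.asarray(region, dtype=bool)
    if region.shape != field.shape:
        raise ValidationError(
            f"region shape {region.shape} != image shape {field.shape}"
        )
    sel = region & field.valid
    if not sel.any():
        raise ValidationError("region contains no valid pixel")
    w = field.intensity[sel]
    phasor: dict[int, tuple[float, float]] = {}
    for n in field.harmonics:
        p = field.phasor(n)[sel]
        mean = (w * p).sum() / w.sum()
        phasor[n] = (float(mean.real), float(mean.imag))
    return Component(name=name, phasor=phasor, color=color)
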