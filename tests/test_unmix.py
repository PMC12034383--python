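import itertools

import numpy as np
import pytest

from phasorlab import (
    Component,
    ComponentSet,
    ComponentUnmixer,
    DecayStack,
    LifetimeSpecies,
    SceneSpec,
    apply_correction,
    build_component_matrix,
    compute_correction,
    empirical_component,
    phasor_transform,
    ratio_image,
    simulate_decay_stack,
    theoretical_single_exp_phasor,
    unmix_field,
)
from phasorlab.exceptions import ConditioningError, ValidationError

from conftest import FREQ, make_field, noiseless_exponential_field

FIVE_TAUS_NS = (0.5, 1.0, 2.0, 4.0, 8.0)


def five_component_set(nonempirical=True):
    comps = [Component(name=f"dye{i}", tau=t * 1e-9) for i, t in enumerate(FIVE_TAUS_NS)]
    return ComponentSet(components=comps, harmonics=(1, 2), frequency=FREQ)


def field_from_mixture_phasors(A, weights):
    """Synthesize a phasor field whose pixels are convex mixtures in phasor space."""
    M = A[:-1] @ weights.T  # (2H, n_pixels)
    n = weights.shape[0]
    g = np.stack([M[0].reshape(1, n), M[2].reshape(1, n)])
    s = np.stack([M[1].reshape(1, n), M[3].reshape(1, n)])
    return make_field(g, s, harmonics=(1, 2))


class TestComponentMatrix:
    def test_single_component_shape(self):
        cset = ComponentSet(
            [Component("a", tau=2e-9)], harmonics=(1,), frequency=FREQ
        )
        A = build_component_matrix(cset)
        g, s = theoretical_single_exp_phasor(2e-9, FREQ, 1)
        np.testing.assert_allclose(A, [[g], [s], [1.0]])

    def test_zero_lifetime_column(self):
        cset = ComponentSet(
            [Component("fast", tau=0.0)], harmonics=(1, 2), frequency=FREQ
        )
        np.testing.assert_allclose(
            build_component_matrix(cset).ravel(), [1, 0, 1, 0, 1]
        )

    def test_two_lifetime_closed_form_oracle(self):
        cset = ComponentSet(
            [Component("a", tau=1e-9), Component("b", tau=4e-9)],
            harmonics=(1, 2),
            frequency=FREQ,
        )
        A = build_component_matrix(cset)
        assert A.shape == (5, 2)
        for j, tau in enumerate((1e-9, 4e-9)):
            for i, n in enumerate((1, 2)):
                wt = 2 * np.pi * FREQ * n * tau
                assert A[2 * i, j] == pytest.approx(1 / (1 + wt**2), rel=1e-12)
                assert A[2 * i + 1, j] == pytest.approx(wt / (1 + wt**2), rel=1e-12)
        assert (A[-1] == 1).all()

    def test_empirical_components_use_stored_coordinates(self):
        comp = Component("dye", phasor={1: (0.3, 0.4), 2: (0.1, 0.2)})
        cset = ComponentSet([comp], harmonics=(1, 2))
        np.testing.assert_allclose(
            build_component_matrix(cset).ravel(), [0.3, 0.4, 0.1, 0.2, 1.0]
        )

    def test_capacity_limit_and_duplicates(self):
        comps = [Component(f"c{i}", tau=i * 1e-9 + 1e-10) for i in range(6)]
        with pytest.raises(ValidationError):
            ComponentSet(comps, harmonics=(1, 2), frequency=FREQ)
        dup = ComponentSet(
            [Component("a", tau=2e-9), Component("b", tau=2e-9)],
            harmonics=(1,),
            frequency=FREQ,
        )
        with pytest.raises(ConditioningError, match="'a'.*'b'"):
            build_component_matrix(dup)


class TestUnmixField:
    def test_pure_pixel_gets_unit_fraction(self):
        cset = five_component_set()
        A = build_component_matrix(cset)
        w = np.eye(5)
        result = unmix_field(field_from_mixture_phasors(A, w), cset)
        np.testing.assert_allclose(
            result.fractions.reshape(5, -1), np.eye(5), atol=1e-9
        )

    def test_midpoint_of_two_components(self):
        cset = ComponentSet(
            [Component("a", tau=1e-9), Component("b", tau=5e-9)],
            harmonics=(1, 2),
            frequency=FREQ,
        )
        A = build_component_matrix(cset)
        result = unmix_field(
            field_from_mixture_phasors(A, np.array([[0.5, 0.5]])), cset
        )
        np.testing.assert_allclose(result.fractions.ravel(), [0.5, 0.5], atol=1e-12)

    def test_noiseless_identifiability_at_capacity(self, rng):
        """2N+1 = 5 components from N = 2 harmonics, exact-solve branch."""
        cset = five_component_set()
        A = build_component_matrix(cset)
        w = rng.dirichlet(np.ones(5), size=200)
        result = unmix_field(field_from_mixture_phasors(A, w), cset)
        err = np.abs(result.fractions.reshape(5, -1).T - w)
        assert err.max() < 1e-9
        np.testing.assert_allclose(
            result.fractions.sum(axis=0), 1.0, atol=1e-9
        )
        assert np.nanmax(result.residual) < 1e-9

    def test_coarse_simplex_grid_brute_force(self):
        """Exhaustive check on a coarse fraction grid."""
        cset = five_component_set()
        A = build_component_matrix(cset)
        grid = [
            np.array(w) / 4
            for w in itertools.product(range(5), repeat=5)
            if sum(w) == 4
        ]
        w = np.array(grid)
        result = unmix_field(field_from_mixture_phasors(A, w), cset)
        assert np.abs(result.fractions.reshape(5, -1).T - w).max() < 1e-9

    def test_underdetermined_uses_least_squares(self, rng):
        cset = ComponentSet(
            [Component("a", tau=0.5e-9), Component("b", tau=4e-9)],
            harmonics=(1, 2),
            frequency=FREQ,
        )
        A = build_component_matrix(cset)
        w = rng.dirichlet(np.ones(2), size=16)
        result = unmix_field(field_from_mixture_phasors(A, w), cset)
        assert np.abs(result.fractions.reshape(2, -1).T - w).max() < 1e-9

    def test_nonneg_solver_constraints(self, rng):
        cset = five_component_set()
        A = build_component_matrix(cset)
        w = rng.dirichlet(np.ones(5), size=20)
        field = field_from_mixture_phasors(A, w)
        # perturb coordinates so the unconstrained solution goes negative
        field.g += rng.normal(0, 5e-3, field.g.shape)
        field.s += rng.normal(0, 5e-3, field.s.shape)
        result = unmix_field(field, cset, nonneg=True)
        frac = result.fractions.reshape(5, -1)
        assert frac.min() >= 0
        np.testing.assert_allclose(frac.sum(axis=0), 1.0, atol=1e-6)

    def test_missing_harmonic_rejected(self):
        cset = five_component_set()
        field = make_field(np.array([[0.5]]), np.array([[0.3]]))
        with pytest.raises(ValidationError):
            unmix_field(field, cset)

    def test_invalid_pixels_carry_no_fractions(self):
        cset = ComponentSet(
            [Component("a", tau=1e-9), Component("b", tau=5e-9)],
            harmonics=(1, 2),
            frequency=FREQ,
        )
        A = build_component_matrix(cset)
        field = field_from_mixture_phasors(A, np.array([[0.5, 0.5], [0.2, 0.8]]))
        field.valid[0, 0] = False
        result = unmix_field(field, cset)
        assert (result.fractions[:, 0, 0] == 0).all()
        assert np.isnan(result.residual[0, 0])


class TestStackLinearity:
    def test_summed_pure_stacks_unmix_to_photon_shares(self):
        """Bin-wise sum of two pure decays yields their photon-count shares."""
        n_bins = 4096  # high bin count keeps discretization bias tiny
        fa = noiseless_exponential_field(1e-9, n_bins=n_bins, shape=(1, 1), photons=3e5)
        taus = (1e-9, 5e-9)
        spec = dict(layout=np.zeros((1, 1), int), n_bins=n_bins, frequency=FREQ,
                    noise="none")
        stacks = []
        shares = (0.3, 0.7)
        for tau, share in zip(taus, shares):
            s, _ = simulate_decay_stack(SceneSpec(
                species=[LifetimeSpecies(tau)], mixtures={0: (1.0,)},
                photons_per_pixel=1e6 * share, **spec))
            stacks.append(s)
        summed = DecayStack(
            counts=stacks[0].counts + stacks[1].counts, frequency=FREQ
        )
        ref, _ = simulate_decay_stack(SceneSpec(
            species=[LifetimeSpecies(4e-9)], mixtures={0: (1.0,)},
            photons_per_pixel=1e6, **spec))
        corr = compute_correction(phasor_transform(ref, (1, 2)), 4e-9, FREQ)
        field = apply_correction(phasor_transform(summed, (1, 2)), corr)
        cset = ComponentSet(
            [Component("a", tau=taus[0]), Component("b", tau=taus[1])],
            harmonics=(1, 2), frequency=FREQ,
        )
        result = unmix_field(field, cset)
        np.testing.assert_allclose(
            result.fractions[:, 0, 0], shares, atol=1e-4
        )

    def test_scene_level_recovery_under_poisson_noise(self, rng):
        """Pooled fractions of a uniform 32x32 mixture at 1e5 photons/px.

        Per-pixel fractions are noisy (the 5-component system amplifies
        phasor noise ~50x); pooling the scene's aggregate phasor before
        unmixing recovers the mixture to a few 1e-3.
        """
        w_true = np.array([0.1, 0.25, 0.3, 0.2, 0.15])
        scene = SceneSpec(
            layout=np.zeros((32, 32), int),
            species=[LifetimeSpecies(t * 1e-9) for t in FIVE_TAUS_NS],
            mixtures={0: tuple(w_true)},
            photons_per_pixel=1e5,
            n_bins=2048,
            frequency=FREQ,
            seed=2024,
        )
        stack, truth = simulate_decay_stack(scene)
        ref, _ = simulate_decay_stack(SceneSpec(
            layout=np.zeros((1, 1), int), species=[LifetimeSpecies(4e-9)],
            mixtures={0: (1.0,)}, photons_per_pixel=1e6, n_bins=2048,
            frequency=FREQ, noise="none"))
        corr = compute_correction(phasor_transform(ref, (1, 2)), 4e-9, FREQ)
        field = apply_correction(phasor_transform(stack, (1, 2)), corr)
        # aggregate phasor of the whole scene -> single unmixing solve
        agg = make_field(
            np.array([[[(field.intensity * field.g[i]).sum() / field.intensity.sum()]]
                      for i in range(2)]).reshape(2, 1, 1),
            np.array([[[(field.intensity * field.s[i]).sum() / field.intensity.sum()]]
                      for i in range(2)]).reshape(2, 1, 1),
            harmonics=(1, 2),
        )
        result = unmix_field(agg, five_component_set())
        rmse = np.sqrt(np.mean((result.fractions.ravel() - w_true) ** 2))
        assert rmse < 5e-3


class TestRatioImage:
    def test_ratio_arithmetic(self):
        frac = np.zeros((2, 1, 3))
        frac[:, 0, 0] = (0.4, 0.4)
        frac[:, 0, 1] = (0.7, 0.0)
        frac[:, 0, 2] = (0.2, 0.6)
        from phasorlab import FractionField

        ff = FractionField(
            fractions=frac, residual=np.zeros((1, 3)),
            valid=np.ones((1, 3), bool), names=["a", "b"],
        )
        ratio, ok = ratio_image(ff, 0, 1)
        np.testing.assert_allclose(ratio[0], [0.5, 1.0, 0.25])
        assert ok.all()

    def test_vanishing_denominator_invalid(self):
        from phasorlab import FractionField

        ff = FractionField(
            fractions=np.zeros((2, 1, 1)), residual=np.zeros((1, 1)),
            valid=np.ones((1, 1), bool), names=["a", "b"],
        )
        ratio, ok = ratio_image(ff, 0, 1)
        assert not ok[0, 0] and np.isnan(ratio[0, 0])
        with pytest.raises(ValidationError):
            ratio_image(ff, 1, 1)


class TestEmpiricalComponent:
    def test_single_pixel_region(self):
        field = make_field(np.array([[0.3, 0.6]]), np.array([[0.2, 0.1]]))
        comp = empirical_component(field, np.array([[True, False]]), "roi")
        assert comp.phasor[1] == pytest.approx((0.3, 0.2))

    def test_equal_intensity_mean(self):
        field = make_field(np.array([[0.2, 0.6]]), np.array([[0.1, 0.3]]))
        comp = empirical_component(field, np.ones((1, 2), bool), "roi")
        assert comp.phasor[1][0] == pytest.approx(0.4)
        assert comp.phasor[1][1] == pytest.approx(0.2)

    def test_homogeneous_dye_region_matches_theory(self):
        spec = SceneSpec(
            layout=np.zeros((8, 8), int),
            species=[LifetimeSpecies(2e-9)],
            mixtures={0: (1.0,)},
            photons_per_pixel=1e5,
            n_bins=4096,
            frequency=FREQ,
            seed=3,
        )
        stack, _ = simulate_decay_stack(spec)
        ref, _ = simulate_decay_stack(SceneSpec(
            layout=np.zeros((1, 1), int), species=[LifetimeSpecies(4e-9)],
            mixtures={0: (1.0,)}, photons_per_pixel=1e6, n_bins=4096,
            frequency=FREQ, noise="none"))
        corr = compute_correction(phasor_transform(ref, (1,)), 4e-9, FREQ)
        field = apply_correction(phasor_transform(stack, (1,)), corr)
        comp = empirical_component(field, np.ones((8, 8), bool), "dye")
        g, s = theoretical_single_exp_phasor(2e-9, FREQ, 1)
        # pooled over 6.4e6 photons: 3 MC standard errors ~ 1e-3
        assert comp.phasor[1][0] == pytest.approx(g, abs=1.5e-3)
        assert comp.phasor[1][1] == pytest.approx(s, abs=1.5e-3)

    def test_empty_region_rejected(self):
        field = make_field(np.array([[0.5]]), np.array([[0.3]]))
        with pytest.raises(ValidationError):
            empirical_component(field, np.zeros((1, 1), bool), "roi")


class TestEstimatorInterface:
    def test_unmixer_params_and_refit(self):
        from sklearn.base import clone

        est = ComponentUnmixer(
            components=five_component_set(), nonneg=False
        )
        cloned = clone(est)
        cloned.fit()
        assert cloned.matrix_.shape == (5, 5)
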