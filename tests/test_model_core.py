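"""Unit tests for the hazard kernel, cloglog link and complete-data
likelihood, checked against closed forms and a triple-loop oracle."""

import numpy as np
import pytest

import bayescr as b
from bayescr.model_core import observed_data_loglik

from helpers import loglik_bruteforce, random_instance


class TestHazardKernel:
    @pytest.mark.parametrize(
        "d, sigma, theta, expected",
        [
            (0.0, 1.3, 0.75, 1.0),
            (1.7, 1.7, 1.0, np.exp(-0.5)),  # half-normal at d = sigma
            (2.0, 1.0, 0.5, np.exp(-1.0)),  # exponential form: d^(2*0.5) = d
        ],
    )
    def test_closed_forms(self, d, sigma, theta, expected):
        assert b.hazard_kernel(d, sigma, theta) == pytest.approx(expected, rel=1e-12)

    def test_matches_half_normal_at_theta_one(self, rng):
        d = rng.uniform(0, 10, 200)
        sigma = 1.9
        assert np.allclose(
            b.hazard_kernel(d, sigma, 1.0), np.exp(-(d**2) / (2 * sigma**2)), rtol=1e-14
        )

    def test_continuous_in_theta_and_decreasing_in_d(self):
        thetas = np.linspace(0.5, 1.0, 200)
        vals = [b.hazard_kernel(1.7, 1.2, t) for t in thetas]
        assert np.max(np.abs(np.diff(vals))) < 1e-2  # no jumps
        d = np.linspace(0, 20, 500)
        k = b.hazard_kernel(d, 1.2, 0.75)
        assert np.all(np.diff(k) < 0)

    @pytest.mark.parametrize("bad", [dict(d=-1, sigma=1, theta=0.75),
                                     dict(d=1, sigma=0, theta=0.75),
                                     dict(d=1, sigma=1, theta=0.4)])
    def test_rejects_invalid(self, bad):
        with pytest.raises(ValueError):
            b.hazard_kernel(bad["d"], bad["sigma"], bad["theta"])


from hypothesis import assume, given, settings
from hypothesis import strategies as st


class TestKernelProperties:
    @given(d=st.floats(0, 50), sigma=st.floats(0.05, 30),
           theta=st.floats(0.5, 1.0))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_kernel_in_unit_interval_and_dominated_by_origin(self, d, sigma, theta):
        # stay inside the representable regime: exp(-x) underflows past ~745
        assume(d ** (2 * theta) / (2 * sigma**2) < 700)
        k = b.hazard_kernel(d, sigma, theta)
        assert 0.0 < k <= 1.0
        assert k <= b.hazard_kernel(0.0, sigma, theta)

    @given(lam0=st.floats(1e-6, 5.0), kern=st.floats(1e-6, 1.0),
           beta=st.floats(-3, 3))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_probability_valid_and_increasing_in_rate(self, lam0, kern, beta):
        # pi rounds to exactly 1.0 once the hazard passes ~37 (eps scale)
        assume(2.0 * lam0 * np.exp(beta) * kern < 30)
        p = b.encounter_prob(lam0, beta, 1, kern)
        assert 0.0 <= p < 1.0
        assert b.encounter_prob(2.0 * lam0, beta, 1, kern) >= p


class TestEncounterProb:
    def test_closed_form_at_basal_rate(self):
        # centre on the trap (kernel 1), lam0 at the survey scale
        assert b.encounter_prob(0.04, 0.0, 0, 1.0) == pytest.approx(0.039211, abs=1e-6)

    def test_no_hazard_limit(self):
        assert b.encounter_prob(1e-12, 0.0, 0, 1.0) < 1e-11

    def test_cloglog_identity(self, rng):
        lam0 = rng.uniform(0.01, 2.0, 100)
        kern = rng.uniform(0.01, 1.0, 100)
        beta = rng.normal(0, 1, 100)
        for la, ke, be in zip(lam0, kern, beta):
            pi = b.encounter_prob(la, be, 1, ke)
            cloglog = np.log(-np.log(1 - pi))
            # identity is exact in real arithmetic; the float round trip
            # through expm1/log amplifies a few ulp when pi approaches 1
            assert cloglog - np.log(la) - be - np.log(ke) == pytest.approx(0.0, abs=1e-10)

    def test_male_offset_doubles_hazard(self):
        # beta = log 2 with sex = 1 gives pi = 1 - exp(-2*lam0*k)
        la, ke = 0.3, 0.7
        assert b.encounter_prob(la, np.log(2.0), 1, ke) == pytest.approx(
            1 - np.exp(-2 * la * ke), rel=1e-12
        )

    def test_monotone_and_bounded(self, rng):
        p1 = b.encounter_prob(0.5, 0.0, 0, 0.5)
        p2 = b.encounter_prob(1.0, 0.0, 0, 0.5)
        p3 = b.encounter_prob(1.0, 0.0, 0, 0.9)
        assert 0 < p1 < p2 < p3 < 1

    def test_rejects_bad_kernel(self):
        with pytest.raises(ValueError):
            b.encounter_prob(0.5, 0.0, 0, 1.5)


class TestCompleteDataLoglik:
    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            spec, params, latent, data, traps, mask = random_instance(rng)
            fast = b.complete_data_loglik(spec, params, latent, data, traps, mask)
            slow = loglik_bruteforce(spec, params, latent, data, traps, mask)
            assert fast == pytest.approx(slow, abs=1e-10)

    def test_single_cell_hand_case(self):
        # one individual, one occasion, detection at a trap at distance d
        traps = b.TrapArray(np.array(["a", "b"], dtype=object),
                            np.array([0.0, 50.0]), np.array([0.0, 0.0]),
                            np.array([[1], [0]], dtype=np.int8))
        mask = b.HabitatMask(np.array([0.5, 1.5]), np.array([0.0, 0.0]), 1.0,
                             np.array([1, 1]))
        y = np.zeros((1, 2, 1), dtype=np.int8)
        y[0, 0, 0] = 1
        data = b.EncounterData(np.array(["i"], dtype=object), y,
                               np.array(["F"], dtype=object))
        spec = b.ModelSpec("leopard", "shared", "estimated", "fixed", 0.75)
        p = b.Parameters(1.2, 1.2, 0.3, 0.4, psi=0.6, psi_sex=0.7, theta=0.75)
        lat = b.LatentState(z=[1], s=[0], sex=[0])
        d = 0.5
        kern = np.exp(-(d**1.5) / (2 * 1.2**2))
        pi = 1 - np.exp(-0.3 * kern)
        expected = np.log(pi) + np.log(0.6) + np.log(0.7) + np.log(1 / 2)
        got = b.complete_data_loglik(spec, p, lat, data, traps, mask)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_excluded_individual_contributes_only_mass_terms(self):
        traps = b.TrapArray(np.array(["a", "b"], dtype=object),
                            np.array([0.0, 1.0]), np.array([0.0, 0.0]),
                            np.ones((2, 3), dtype=np.int8))
        mask = b.HabitatMask(np.array([0.0, 1.0, 2.0]), np.zeros(3), 1.0,
                             np.ones(3, dtype=int))
        data = b.EncounterData(np.array([], dtype=object),
                               np.zeros((0, 2, 3), dtype=np.int8),
                               np.array([], dtype=object))
        spec = b.ModelSpec("hyena", "shared", "fixed_zero", "fixed", 1.0)
        p = b.Parameters(1.0, 1.0, 0.1, psi=0.3)
        lat = b.LatentState(z=[0], s=[1], sex=[0])
        got = b.complete_data_loglik(spec, p, lat, data, traps, mask)
        assert got == pytest.approx(np.log(0.7) + np.log(1 / 3), abs=1e-12)

    def test_doubling_occasions_doubles_detection_mass(self):
        spec = b.ModelSpec("hyena", "shared", "fixed_zero", "fixed", 1.0)
        p = b.Parameters(1.0, 1.0, 0.1, psi=0.4)
        mask = b.HabitatMask(np.array([0.0, 3.0]), np.zeros(2), 1.0, np.ones(2, dtype=int))
        lat = b.LatentState(z=[1], s=[0], sex=[0])
        out = {}
        for k in (3, 6):
            traps = b.TrapArray(np.array(["a", "b"], dtype=object),
                                np.array([0.0, 1.0]), np.zeros(2),
                                np.ones((2, k), dtype=np.int8))
            data = b.EncounterData(np.array([], dtype=object),
                                   np.zeros((0, 2, k), dtype=np.int8),
                                   np.array([], dtype=object))
            base = np.log(p.psi) + np.log(1 / 2)
            out[k] = b.complete_data_loglik(spec, p, lat, data, traps, mask) - base
        assert out[6] == pytest.approx(2 * out[3], rel=1e-12)

    def test_detection_with_z_zero_is_an_error(self):
        rng = np.random.default_rng(3)
        spec, params, latent, data, traps, mask = random_instance(rng)
        latent.z[0] = 0  # first individual is detected by construction
        with pytest.raises(ValueError, match="z = 0"):
            b.complete_data_loglik(spec, params, latent, data, traps, mask)


class TestObservedDataLoglik:
    def test_matches_latent_enumeration(self):
        """Marginalised likelihood equals the brute-force sum of the
        complete-data likelihood over every latent configuration."""
        rng = np.random.default_rng(11)
        done = 0
        while done < 5:
            spec, params, latent, data, traps, mask = random_instance(rng)
            n, m, p = data.n, latent.m, mask.n_habitat
            nz = m - n
            n_configs = (p**m) * 2**nz * (2**m if spec.uses_sex else 1)
            if n_configs > 40_000:  # keep the brute-force sum tractable
                continue
            done += 1
            total = -np.inf
            import itertools

            for z_aug in itertools.product([0, 1], repeat=nz):
                for s in itertools.product(range(p), repeat=m):
                    sex_space = (
                        itertools.product([0, 1], repeat=m)
                        if spec.uses_sex else [tuple([0] * m)]
                    )
                    for sex in sex_space:
                        sexa = np.array(sex, dtype=np.int8)
                        code = data.sex_code
                        known = code >= 0
                        if spec.uses_sex and np.any(sexa[:n][known] != code[known]):
                            continue
                        lat = b.LatentState(z=list((1,) * n + z_aug), s=list(s), sex=sexa)
                        ll = b.complete_data_loglik(spec, params, lat, data, traps, mask)
                        total = np.logaddexp(total, ll)
            got = observed_data_loglik(spec, params, data, traps, mask, n_augmented=nz)
            # enumeration includes the uniform-s prior mass; observed_data_loglik too
            assert got == pytest.approx(total, abs=1e-8)


class TestRegionsAndSpecs:
    def test_n_real_in_region(self):
        mask = b.HabitatMask(np.arange(4.0), np.zeros(4), 1.0, np.ones(4, dtype=int),
                             region=np.array(["park", "park", "buffer", "buffer"],
                                             dtype=object))
        lat = b.LatentState(z=[1, 1, 0, 1, 0], s=[0, 1, 1, 2, 3], sex=[0] * 5)
        assert b.n_real_in_region(lat, mask, "park") == 2
        assert b.n_real_in_region(lat, mask, "buffer") == 1
        assert b.n_real_in_region(lat, mask, None) == 3  # partition identity
        with pytest.raises(KeyError):
            b.n_real_in_region(lat, mask, "lake")

    def test_all_excluded_gives_zero(self):
        mask = b.HabitatMask(np.arange(2.0), np.zeros(2), 1.0, np.ones(2, dtype=int))
        lat = b.LatentState(z=[0, 0], s=[0, 1], sex=[0, 0])
        assert b.n_real_in_region(lat, mask, None) == 0

    def test_hyena_spec_rejects_sex_structure(self):
        with pytest.raises(ValueError, match="hyena"):
            b.ModelSpec("hyena", "sex_specific", "fixed_zero", "fixed", 1.0)
        with pytest.raises(ValueError, match="hyena"):
            b.ModelSpec("hyena", "shared", "estimated", "fixed", 1.0)

    def test_model_factories(self):
        m5 = b.leopard_model(5)
        assert m5.sigma_mode == "shared" and m5.beta_sex_mode == "estimated"
        assert m5.theta_mode == "fixed" and m5.theta_value == 0.75
        m6 = b.leopard_model(6)
        assert m6.theta_value == 1.0 and m6.sigma_mode == "sex_specific"
        h1 = b.hyena_model(1)
        assert not h1.uses_sex and h1.theta_value == 1.0
        assert b.hyena_model(2).theta_mode == "estimated"
        with pytest.raises(ValueError):
            b.leopard_model(7)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            b.Parameters(-1, 1, 0.1).validate()
        with pytest.raises(ValueError):
            b.Parameters(1, 1, 0.1, theta=0.3).validate()
        with pytest.raises(ValueError):
            b.Parameters(1, 1, 0.1, psi=1.2).validate()
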