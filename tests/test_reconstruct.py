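import warnings

import numpy as np
import pytest

import aucsas
from aucsas.reconstruct import (
    extrapolate_forward,
    first_aucsas,
    forward_intensity_monomer,
    guinier_connect,
    highq_monomer_first,
    improved_aucsas,
    mixture_factor,
)
from aucsas.sas_io import ScatteringProfile, Species, SpeciesDistribution
from aucsas.scattering_models import build_aggregate_model


def guinier_profile(i0=0.1, rg=27.0, n=100, noise=0.0, seed=0, conc=2.0):
    q = np.geomspace(0.008, 0.25, n)
    intensity = i0 * np.exp(-(q**2) * rg**2 / 3.0)
    sigma = np.maximum(0.01 * intensity, 1e-8)
    if noise:
        rng = np.random.default_rng(seed)
        sigma = noise * intensity
        intensity = intensity + rng.normal(size=n) * sigma
    return ScatteringProfile(q=q, intensity=intensity, sigma=sigma,
                             concentration=conc)


def masses_dist(fractions, ff0=1.3, m1=66.5e3):
    species = [
        Species(s20w=1.0 + i, weight_fraction=r, molar_mass=m1 * (i + 1),
                association_number=i + 1)
        for i, r in enumerate(fractions)
    ]
    return SpeciesDistribution(species=species, friction_ratio=ff0)


class TestHighQ:
    def test_identity_at_pure_monomer(self):
        p = guinier_profile()
        out = highq_monomer_first(p, 1.0)
        np.testing.assert_allclose(out.intensity, p.intensity)

    def test_linearity(self):
        p = guinier_profile()
        out = highq_monomer_first(p, 0.8)
        np.testing.assert_allclose(out.intensity, 0.8 * p.intensity)
        np.testing.assert_allclose(out.sigma, 0.8 * p.sigma)

    def test_matches_truth_at_high_q(self, bsa_dataset):
        scenario, profile, dist, truth = bsa_dataset
        i1h = highq_monomer_first(profile, dist.monomer.weight_fraction)
        c1 = dist.monomer.weight_fraction * scenario.concentration
        true_i1 = c1 * aucsas.monomer_curve(scenario).intensity
        high = profile.q * truth["rg1"] > 4.0
        resid = (i1h.intensity[high] - true_i1[high]) / i1h.sigma[high]
        assert np.abs(resid).mean() < 2.0


class TestForwardIntensity:
    def test_monomer_only(self):
        dist = masses_dist([1.0])
        i1, sd = forward_intensity_monomer(0.1, dist, 0.002)
        assert i1 == pytest.approx(0.1)
        assert sd == pytest.approx(0.002)

    def test_closed_form_dimer(self):
        dist = masses_dist([0.8, 0.2])
        i1, _ = forward_intensity_monomer(0.12, dist)
        assert i1 == pytest.approx(0.12 * 0.8 / 1.2, rel=1e-12)

    def test_missing_masses_rejected(self):
        dist = SpeciesDistribution(
            species=[Species(4.3, 1.0)], friction_ratio=1.3
        )
        with pytest.raises(ValueError, match="molar masses"):
            forward_intensity_monomer(0.1, dist)


class TestExtrapolateForward:
    def test_exact_guinier_recovery(self):
        p = guinier_profile(i0=0.25, rg=30.0)
        fit = extrapolate_forward(p, rg_hint=30.0)
        assert fit.i_zero == pytest.approx(0.25, rel=1e-8)
        assert fit.rg == pytest.approx(30.0, rel=1e-8)

    def test_auto_window_matches_hinted(self):
        p = guinier_profile(i0=0.25, rg=30.0)
        fit = extrapolate_forward(p)
        assert fit.rg == pytest.approx(30.0, rel=1e-6)

    def test_noisy_recovery_within_fit_error(self):
        devs = []
        for seed in range(8):
            p = guinier_profile(i0=0.2, rg=28.0, noise=0.01, seed=seed)
            fit = extrapolate_forward(p, rg_hint=28.0)
            devs.append(abs(fit.i_zero - 0.2) / fit.i_zero_sd)
        assert np.mean(devs) < 2.0

    def test_mixture_apparent_rg_is_inflated(self, bsa_dataset):
        scenario, profile, dist, truth = bsa_dataset
        fit = extrapolate_forward(profile)
        assert fit.rg > truth["rg1"] * 1.05

    def test_too_few_points_rejected(self):
        p = guinier_profile(n=100)
        with pytest.raises(ValueError, match="need"):
            extrapolate_forward(p, rg_hint=2000.0)


class TestGuinierConnect:
    def test_exact_guinier_input_recovered(self):
        p = guinier_profile(i0=0.1, rg=27.0)
        conn = guinier_connect(p, 0.1)
        assert conn.rg1 == pytest.approx(27.0, rel=1e-4)
        assert conn.joint_metric < 1e-4
        assert conn.q_connect * conn.rg1 < 1.3  # joint inside Guinier region

    def test_sphere_monomer_rg(self):
        # i1h of an ideal sphere: recovers sqrt(3/5) R within 1%
        R = 35.0
        q = np.geomspace(0.008, 0.25, 120)
        u = q * R
        intensity = 0.1 * (3 * (np.sin(u) - u * np.cos(u)) / u**3) ** 2
        sigma = 0.005 * 0.1 * (1.0 + q / q.max())
        p = ScatteringProfile(q=q, intensity=intensity, sigma=sigma)
        conn = guinier_connect(p, 0.1)
        assert conn.rg1 == pytest.approx(np.sqrt(3 / 5) * R, rel=0.01)

    def test_inconsistent_forward_intensity_rejected(self):
        p = guinier_profile(i0=0.1, rg=27.0)
        with pytest.raises(ValueError):
            guinier_connect(p, 0.1 * np.exp(-10))  # data never fall below G


class TestMixtureFactor:
    def test_monomer_only_is_unity(self):
        q = np.geomspace(0.01, 0.2, 30)
        model = build_aggregate_model(q, [1], 27.0, 1.5)
        s = mixture_factor(q, masses_dist([1.0]), model)
        np.testing.assert_allclose(s, 1.0)

    def test_forward_limit(self):
        q = np.array([1e-8, 0.01])
        model = build_aggregate_model(q, [1, 2], 27.0, 1.5)
        s = mixture_factor(q, masses_dist([0.8, 0.2]), model)
        assert s[0] == pytest.approx(1.2, rel=1e-9)

    def test_high_q_tail_near_unity(self):
        D = 54.0
        q = np.array([100.0 / D])
        model = build_aggregate_model(q, [1, 2, 3], 27.0, 1.5)
        s = mixture_factor(q, masses_dist([0.8, 0.14, 0.06]), model)
        assert s[0] == pytest.approx(1.0, abs=0.01)


class TestConsistencyIdentities:
    def test_eq15_forward_limit_equals_eq4(self):
        """With M_j = j M_1 the q->0 limit of r_1 I(0)/S(0) must equal the
        AUC-weighted forward intensity exactly."""
        dist = masses_dist([0.80, 0.14, 0.06])
        q = np.array([1e-10, 0.01])
        model = build_aggregate_model(q, [1, 2, 3], 27.0, 1.5)
        s0 = mixture_factor(q, dist, model)[0]
        i0_total = 0.117
        lhs = 0.80 * i0_total / s0
        rhs, _ = forward_intensity_monomer(i0_total, dist)
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_improved_and_first_highq_agree(self, bsa_dataset):
        scenario, profile, dist, truth = bsa_dataset
        q = profile.q
        model = build_aggregate_model(
            q, [1, 2, 3], truth["rg1"], truth["axial_ratio"]
        )
        s = mixture_factor(q, dist, model)
        high = q * truth["rg1"] > 3.0
        very_high = q * truth["rg1"] > 6.0
        assert np.abs(1.0 / s[high] - 1.0).max() < 0.02
        assert np.abs(1.0 / s[very_high] - 1.0).max() < 0.01


class TestFirstMethod:
    def test_bias_grows_with_aggregate_fraction(self, solvent):
        """The first method's R_g1 error is monotone in r_a; the improved
        method stays accurate at low r_a."""
        errs = {}
        for ra in (0.06, 0.20):
            scenario = aucsas.bsa_like_scenario(ra=ra, seed=4)
            profile, dist, truth = aucsas.make_dataset(scenario)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dist = aucsas.assign_association_numbers(dist, solvent)
                first = first_aucsas(profile, dist)
                improved = improved_aucsas(profile, dist)
            errs[ra] = abs(first.rg1 - truth["rg1"])
            assert improved.rg1 == pytest.approx(truth["rg1"], rel=0.01)
        assert errs[0.06] < errs[0.20]

    def test_high_aggregate_fraction_biases_rg_high(self, bsa_dataset):
        _, profile, dist, truth = bsa_dataset
        result = first_aucsas(profile, dist)
        assert result.rg1 > truth["rg1"] * 1.01
        assert result.q_connect * result.rg1 > 1.3
        assert any("Guinier region" in w for w in result.warnings)

    def test_monomer_only_passthrough(self, clean_monomer_profile):
        profile, scenario = clean_monomer_profile
        dist = masses_dist([1.0])
        result = first_aucsas(profile, dist)
        # above q_c the output is the input
        above = profile.q >= result.q_connect
        np.testing.assert_allclose(
            result.profile.intensity[above], profile.intensity[above]
        )
        # Guinier-window fit of an ellipsoid carries ~1% curvature bias
        assert result.rg1 == pytest.approx(scenario.monomer_shape.rg, rel=0.01)


class TestImprovedMethod:
    def test_parameter_recovery(self, bsa_dataset):
        _, profile, dist, truth = bsa_dataset
        result = improved_aucsas(profile, dist)
        assert result.rg1 == pytest.approx(truth["rg1"], rel=0.01)
        assert result.i1_zero == pytest.approx(truth["i1_zero"], rel=0.02)
        assert result.method == "improved"
        assert result.q_connect * result.rg1 <= 1.3

    def test_beats_first_method(self, bsa_dataset):
        _, profile, dist, truth = bsa_dataset
        f = first_aucsas(profile, dist)
        i = improved_aucsas(profile, dist)
        assert abs(i.rg1 - truth["rg1"]) < abs(f.rg1 - truth["rg1"])

    def test_monomer_only_single_iteration(self, clean_monomer_profile):
        profile, scenario = clean_monomer_profile
        dist = masses_dist([1.0])
        result = improved_aucsas(profile, dist)
        assert result.iterations == 1
        np.testing.assert_allclose(result.mixture_factor, 1.0)
        above = profile.q >= result.q_connect
        np.testing.assert_allclose(
            result.profile.intensity[above], profile.intensity[above]
        )

    def test_beta_insensitivity_for_mild_anisotropy(self, bsa_dataset):
        # forcing beta = 1 moves R_g1 by < 1% for p <= 1.5 subunits
        _, profile, dist, truth = bsa_dataset
        with_beta = improved_aucsas(profile, dist)
        spherical = improved_aucsas(profile, dist, shape_p=1.0)
        assert abs(spherical.rg1 - with_beta.rg1) / with_beta.rg1 < 0.01

    def test_sigma_scales_linearly_through_pipeline(self, bsa_dataset):
        _, profile, dist, _ = bsa_dataset
        scaled = ScatteringProfile(
            q=profile.q.copy(),
            intensity=profile.intensity.copy(),
            sigma=2.0 * profile.sigma,
            concentration=profile.concentration,
        )
        base = improved_aucsas(profile, dist)
        doubled = improved_aucsas(scaled, dist)
        assert doubled.I1_zero_sd == pytest.approx(2.0 * base.I1_zero_sd, rel=0.05)
        assert doubled.rg1_sd == pytest.approx(2.0 * base.rg1_sd, rel=0.2)

    def test_requires_solvent_when_masses_missing(self, bsa_dataset):
        scenario, profile, _, _ = bsa_dataset
        bare = SpeciesDistribution(
            species=[Species(4.3, 0.8), Species(6.6, 0.2)], friction_ratio=1.15
        )
        with pytest.raises(ValueError, match="SolventConditions"):
            improved_aucsas(profile, bare)
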