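"""Generative-model densities: enumeration oracle, surfaces, likelihood."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import logsumexp

from cosmospot import SimConfig, simulate_dataset
from cosmospot import model as mdl
from cosmospot.aoi_io import OffsetEmpirical
from cosmospot.model import (
    AOIParams,
    Config,
    FrameLatents,
    GlobalParams,
    SpotLatents,
    admissible_configs,
    config_log_prior,
    ideal_image,
    image_loglik,
    joint_logpdf,
    local_prior_logpdf,
    marginal_logpdf,
    spot_surface,
)


class TestConfigEnumeration:
    @pytest.mark.parametrize("K,count", [(1, 3), (2, 8), (3, 20)])
    def test_admissible_combination_count(self, K, count):
        # 2**K free combos at z=0 plus K * 2**(K-1) with a specific spot
        assert len(admissible_configs(K)) == count

    def test_specific_spot_always_present(self):
        for cfg in admissible_configs(3):
            if cfg.theta > 0:
                assert cfg.m[cfg.theta - 1] == 1

    @pytest.mark.parametrize("pi,lam", [(0.15, 0.15), (0.5, 1.0), (0.9, 2.5)])
    def test_prior_normalizes_over_configs(self, pi, lam):
        lps = [
            config_log_prior(c, pi, lam, 2, is_control=False)
            for c in admissible_configs(2)
        ]
        assert logsumexp(lps) == pytest.approx(0.0, abs=1e-9)

    def test_control_prior_normalizes_on_z0(self):
        lps = [
            config_log_prior(c, 0.15, 0.5, 2, is_control=True)
            for c in admissible_configs(2)
        ]
        assert logsumexp(lps) == pytest.approx(0.0, abs=1e-9)


class TestSpotSurface:
    def test_absent_spot_is_zero(self):
        s = spot_surface(0, 1000.0, 1.4, 0.0, 0.0, 6.5, 6.5, 14)
        assert np.all(s == 0.0)

    def test_peak_value_on_pixel_center(self):
        # spot centered exactly on pixel (7, 7): peak h / (2 pi w^2)
        s = spot_surface(1, 1000.0, 1.4, 0.5, 0.5, 6.5, 6.5, 14)
        assert s[7, 7] == pytest.approx(1000.0 / (2 * math.pi * 1.4**2), rel=1e-12)
        assert s[7, 7] == pytest.approx(81.2, abs=0.05)

    def test_integrates_to_total_intensity(self):
        s = spot_surface(1, 1000.0, 1.4, 0.0, 0.0, 24.5, 24.5, 50)
        assert s.sum() == pytest.approx(1000.0, rel=1e-3)

    def test_ideal_image_additivity_and_floor(self):
        s1 = spot_surface(1, 500.0, 1.0, -1.0, 0.0, 6.5, 6.5, 14)
        s2 = spot_surface(1, 800.0, 2.0, 2.0, 1.0, 6.5, 6.5, 14)
        img = ideal_image(100.0, [s1, s2])
        np.testing.assert_allclose(img, 100.0 + s1 + s2)
        assert np.all(img >= 100.0)
        np.testing.assert_allclose(ideal_image(50.0, [np.zeros((6, 6))]), 50.0)


class TestImageLoglik:
    def test_point_mass_offset_reduces_to_gamma(self, rng):
        from cosmospot.distributions import gamma_meanvar_logpdf

        off = OffsetEmpirical(samples=[100.0], weights=[1.0])
        mu = np.full((6, 6), 200.0)
        D = 100.0 + rng.gamma(200.0 / 5.0, 5.0, size=(6, 6))
        expected = np.sum(gamma_meanvar_logpdf(D - 100.0, mu, mu * 5.0))
        assert image_loglik(D, mu, 5.0, off) == pytest.approx(expected, rel=1e-12)

    def test_two_bin_mixture_matches_hand_sum(self):
        from cosmospot.distributions import gamma_meanvar_logpdf

        off = OffsetEmpirical(samples=[90.0, 110.0], weights=[0.6, 0.4])
        mu = np.full((1, 1), 150.0)
        D = np.full((1, 1), 260.0)
        hand = np.logaddexp(
            math.log(0.6) + gamma_meanvar_logpdf(170.0, 150.0, 150.0 * 3),
            math.log(0.4) + gamma_meanvar_logpdf(150.0, 150.0, 150.0 * 3),
        )
        assert image_loglik(D, mu, 3.0, off) == pytest.approx(float(hand), rel=1e-12)

    def test_pixel_below_offset_support_gives_neg_inf(self):
        off = OffsetEmpirical(samples=[100.0], weights=[1.0])
        D = np.full((4, 4), 150.0)
        D[2, 2] = 99.0
        with pytest.warns(RuntimeWarning, match="smallest offset"):
            assert image_loglik(D, np.full((4, 4), 50.0), 5.0, off) == -np.inf

    def test_simulated_noise_moments(self, rng):
        # variance of D - mean(offset) approx mu_I * g
        from cosmospot.distributions import gamma_meanvar_sample

        off = OffsetEmpirical(samples=[90.0, 100.0, 110.0], weights=[0.5, 0.3, 0.2])
        mu, g = 400.0, 7.0
        n = 10**5
        D = gamma_meanvar_sample(rng, mu, mu * g, size=n) + off.sample(rng, size=n)
        assert np.var(D) == pytest.approx(mu * g + off.var, rel=0.03)


def _scalar_spots(m, h, w, x, y):
    return SpotLatents(m=np.asarray(m), h=np.asarray(h), w=np.asarray(w),
                       x=np.asarray(x), y=np.asarray(y))


class TestLocalPrior:
    glob = GlobalParams(g=7.0, sigma_xy=0.5, pi=0.3, lam=0.5)

    def test_control_aoi_cannot_be_specific(self):
        cfg = Config(z=1, theta=1, m=(1, 0))
        sp = _scalar_spots([1, 0], [1000.0, 1000.0], [1.4, 1.4], [0.1, 0.0], [0.0, 0.0])
        lp = local_prior_logpdf(150.0, cfg, sp, 150.0, 20.0, self.glob, True, 14)
        assert lp == -np.inf

    def test_theta_uniform_given_z1(self):
        sp1 = _scalar_spots([1, 1], [1e3, 1e3], [1.4, 1.4], [0.1, 0.2], [0.0, 0.1])
        lp1 = local_prior_logpdf(
            150.0, Config(z=1, theta=1, m=(1, 1)), sp1, 150.0, 20.0, self.glob, False, 14
        )
        # swapping which spot is specific only changes the position-prior factor
        lp2 = local_prior_logpdf(
            150.0, Config(z=1, theta=2, m=(1, 1)), sp1, 150.0, 20.0, self.glob, False, 14
        )
        from cosmospot.distributions import affine_beta_logpdf, uniform_logpdf

        a = mdl.position_bound(14)
        ab = lambda v: affine_beta_logpdf(v, 0.0, 0.5, -a, a)
        un = lambda v: uniform_logpdf(v, -a, a)
        delta = (ab(0.1) + ab(0.0) + un(0.2) + un(0.1)) - (
            un(0.1) + un(0.0) + ab(0.2) + ab(0.1)
        )
        assert lp1 - lp2 == pytest.approx(float(delta), rel=1e-9)

    def test_width_outside_support(self):
        sp = _scalar_spots([0, 0], [1e3, 1e3], [0.5, 1.4], [0.0, 0.0], [0.0, 0.0])
        lp = local_prior_logpdf(
            150.0, Config(z=0, theta=0, m=(0, 0)), sp, 150.0, 20.0, self.glob, False, 14
        )
        assert lp == -np.inf

    def test_impossible_combination(self):
        sp = _scalar_spots([0, 1], [1e3, 1e3], [1.4, 1.4], [0.0, 0.0], [0.0, 0.0])
        lp = local_prior_logpdf(
            150.0, Config(z=1, theta=1, m=(0, 1)), sp, 150.0, 20.0, self.glob, False, 14
        )
        assert lp == -np.inf


def _tiny_dataset(seed=5, N=1, Nc=0, F=2, P=6):
    cfg = SimConfig(N=N, Nc=Nc, F=F, P=P, pi=0.4, lam=0.5, seed=seed)
    ds, _ = simulate_dataset(cfg)
    return ds


def _latents(ds, rng, K=2):
    n, F = ds.n_aoi, ds.F
    glob = GlobalParams(g=7.0, sigma_xy=0.6, pi=0.35, lam=0.45)
    aoi = AOIParams(mu_b=np.full(n, 145.0), sigma_b=np.full(n, 18.0))
    b = rng.uniform(130, 170, (n, F))
    spots = SpotLatents(
        m=np.zeros((K, n, F), dtype=int),
        h=rng.uniform(800, 3000, (K, n, F)),
        w=rng.uniform(1.0, 2.0, (K, n, F)),
        x=rng.uniform(-2, 2, (K, n, F)),
        y=rng.uniform(-2, 2, (K, n, F)),
    )
    return glob, aoi, b, spots


class TestJointAndMarginal:
    def test_marginal_matches_bruteforce_enumeration(self, rng):
        """Exact-enumeration oracle on 1 AOI x 2 frames at P = 6."""
        ds = _tiny_dataset()
        glob, aoi, b, spots = _latents(ds, rng)
        configs = admissible_configs(2)
        glob_lp = mdl.global_prior_logpdf(glob, aoi)
        terms = []
        for cfg_pair in itertools.product(configs, repeat=ds.F):
            frames = FrameLatents(
                b=b,
                z=np.array([[c.z for c in cfg_pair]]),
                theta=np.array([[c.theta for c in cfg_pair]]),
            )
            sp = SpotLatents(
                m=np.array([[[c.m[k] for c in cfg_pair]] for k in range(2)]),
                h=spots.h, w=spots.w, x=spots.x, y=spots.y,
            )
            terms.append(joint_logpdf(ds, glob, aoi, frames, sp) - glob_lp)
        brute = glob_lp + logsumexp(terms)
        marg = marginal_logpdf(ds, glob, aoi, b, spots)
        assert marg == pytest.approx(brute, rel=1e-10)

    def test_joint_factorizes_over_aois(self, rng):
        ds = _tiny_dataset(N=2, F=1)
        glob, aoi, b, spots = _latents(ds, rng)
        frames = FrameLatents(
            b=b, z=np.zeros((2, 1), int), theta=np.zeros((2, 1), int)
        )
        sp0 = SpotLatents(m=np.zeros((2, 2, 1), int), h=spots.h, w=spots.w,
                          x=spots.x, y=spots.y)
        total = joint_logpdf(ds, glob, aoi, frames, sp0)
        glob_lp = mdl.global_prior_logpdf(glob, aoi)
        parts = []
        for a in range(2):
            ds_a = type(ds)(
                data=ds.data[a : a + 1], x_target=ds.x_target[a : a + 1],
                y_target=ds.y_target[a : a + 1], is_control=ds.is_control[a : a + 1],
                offset=ds.offset,
            )
            aoi_a = AOIParams(mu_b=aoi.mu_b[a : a + 1], sigma_b=aoi.sigma_b[a : a + 1])
            fr_a = FrameLatents(b=b[a : a + 1], z=frames.z[a : a + 1],
                                theta=frames.theta[a : a + 1])
            sp_a = SpotLatents(m=sp0.m[:, a : a + 1], h=spots.h[:, a : a + 1],
                               w=spots.w[:, a : a + 1], x=spots.x[:, a : a + 1],
                               y=spots.y[:, a : a + 1])
            lp_a = joint_logpdf(ds_a, glob, aoi_a, fr_a, sp_a)
            parts.append(lp_a - mdl.global_prior_logpdf(glob, aoi_a))
        assert total == pytest.approx(glob_lp + sum(parts), rel=1e-12)

    def test_pi_to_zero_forces_z0_branch(self, rng):
        # pi -> 0 limit (pi = 0 exactly has zero density under the Jeffreys
        # prior); the z = 1 branch weight vanishes as exp(log pi)
        ds = _tiny_dataset(F=1)
        glob, aoi, b, spots = _latents(ds, rng)
        glob.pi = 1e-30
        marg = marginal_logpdf(ds, glob, aoi, b, spots)
        # brute force restricted to z = 0 configurations
        glob_lp = mdl.global_prior_logpdf(glob, aoi)
        terms = []
        for c in admissible_configs(2):
            if c.z != 0:
                continue
            frames = FrameLatents(b=b, z=np.array([[c.z]]), theta=np.array([[c.theta]]))
            sp = SpotLatents(m=np.array(c.m).reshape(2, 1, 1), h=spots.h, w=spots.w,
                             x=spots.x, y=spots.y)
            terms.append(joint_logpdf(ds, glob, aoi, frames, sp) - glob_lp)
        assert marg == pytest.approx(glob_lp + logsumexp(terms), rel=1e-10)

    def test_label_switching_symmetry(self, rng):
        ds = _tiny_dataset(F=2)
        glob, aoi, b, spots = _latents(ds, rng)
        marg = marginal_logpdf(ds, glob, aoi, b, spots)
        flipped = SpotLatents(
            m=spots.m[::-1], h=spots.h[::-1], w=spots.w[::-1],
            x=spots.x[::-1], y=spots.y[::-1],
        )
        assert marginal_logpdf(ds, glob, aoi, b, flipped) == pytest.approx(
            marg, rel=1e-12
        )


class TestEngineAgainstReference:
    def test_engine_marginal_matches_model_module(self, rng):
        """The vectorized fitting path reproduces the reference density."""
        from cosmospot._engine import ConfigTable, forward_backward

        ds = _tiny_dataset(N=2, Nc=1, F=2)
        glob, aoi, b, spots = _latents(ds, rng, K=2)
        vals = {
            "g": glob.g, "sigma_xy": glob.sigma_xy, "pi": glob.pi, "lam": glob.lam,
            "mu_b": aoi.mu_b, "sigma_b": aoi.sigma_b, "b": b,
            "h": spots.h, "w": spots.w, "x": spots.x, "y": spots.y,
        }
        res = forward_backward(
            vals, ds.data, ds.x_target, ds.y_target, ds.is_control,
            ds.offset.samples, np.log(ds.offset.weights),
            ConfigTable.build(2), ds.P, need_grad=False,
        )
        engine_total = res.logp_local + mdl.global_prior_logpdf(glob, aoi)
        ref = marginal_logpdf(ds, glob, aoi, b, spots)
        assert engine_total == pytest.approx(ref, rel=1e-10)

    def test_numba_kernel_matches_numpy_reference(self, rng):
        from cosmospot._kernels import mixture_loglik_grad, mixture_loglik_grad_numpy

        M, T, P, B = 3, 4, 6, 3
        muI = rng.uniform(100, 400, (M, T, P, P))
        samples = np.array([90.0, 100.0, 110.0])
        logw = np.log([0.5, 0.3, 0.2])
        D = rng.uniform(120, 600, (T, P, P))
        v = D[None] - samples[:, None, None, None]
        logv = np.where(v > 0, np.log(np.abs(v) + (v <= 0)), 0.0)
        a = mixture_loglik_grad(muI, 7.0, v, logv, logw, True)
        b_ = mixture_loglik_grad_numpy(muI, 7.0, v, logv, logw, True)
        for x, y in zip(a, b_):
            np.testing.assert_allclose(x, y, rtol=1e-9, atol=1e-12)
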