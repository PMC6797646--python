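"""Euler-Maruyama simulators: diffusion, LCA, UGM and their schedule variants."""

import numpy as np
import pytest

import eamsim as es
from eamsim.sde import linear_threshold_profile, ugm_decision_variable, weibull_threshold_profile

KS_CRIT_1PCT = lambda n: 1.628 * np.sqrt(2.0 / n)

DIFF = dict(v=0.15, a=0.1, z=0.05, ter=0.3)
LCA = dict(v=[0.4, 0.3], b=0.12, t0=0.3, beta=1.0, lam=1.0)
UGM = dict(v=0.15, a=40.0, ter=0.3, tau=0.1)


def diffusion_tolerance(v, a, z, sigma, n, h):
    """3 Monte-Carlo SEs plus the quantified O(sqrt(h)) discretization bias.

    The Euler scheme with post-update boundary checks systematically
    overshoots the bounds; the classic continuity correction shifts each
    boundary outward by 0.5826 sigma sqrt(h).  The allowance is 1.5x the
    absorption-probability change that shift induces in the closed form.
    """
    p_exp = es.wiener_absorption_prob(v, a, z, sigma)
    beta = 0.5826 * sigma * np.sqrt(h)
    p_corr = es.wiener_absorption_prob(v, a + 2 * beta, z + beta, sigma)
    return 3 * np.sqrt(p_exp * (1 - p_exp) / n) + 1.5 * abs(p_corr - p_exp)


class TestDiffusion:
    def test_symmetric_unbiased(self):
        n = 100_000
        p = es.DiffusionParams(v=0.0, a=0.1, z=0.05, ter=0.3)
        t = es.simulate_diffusion(n, p, rng=np.random.default_rng(0))
        assert abs((t.resp == 1).mean() - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_noise_free_ramp(self):
        p = es.DiffusionParams(v=0.13, a=0.1, z=0.05, ter=0.3, sigma=0.0)
        step = es.StepConfig(h=0.001, max_steps=2000)
        t = es.simulate_diffusion(500, p, step=step, rng=np.random.default_rng(1))
        k = int(np.ceil((p.a - p.z) / (p.v * step.h)))
        assert np.all(t.resp == 1)
        assert np.allclose(t.rt, p.ter + k * step.h)

    def test_absorption_probability_matches_closed_form(self, fine_lut):
        n = 100_000
        p = es.DiffusionParams(v=0.1, a=0.1, z=0.05, ter=0.3)
        t = es.simulate_diffusion(n, p, lut=fine_lut, rng=np.random.default_rng(2))
        expected = es.wiener_absorption_prob(p.v, p.a, p.z, p.sigma)
        tol = diffusion_tolerance(p.v, p.a, p.z, p.sigma, n, 0.001)
        assert abs((t.resp == 1).mean() - expected) < tol

    def test_step_halving_consistency(self):
        """Halving h moves the choice probability by less than combined tolerance."""
        n = 30_000
        p = es.DiffusionParams(**DIFF)
        est = []
        for h in (0.001, 0.0005):
            t = es.simulate_diffusion(
                n, p, step=es.StepConfig(h=h, max_steps=int(5 / h)),
                rng=np.random.default_rng(3),
            )
            est.append((t.resp == 1).mean())
        assert abs(est[0] - est[1]) < 2 * diffusion_tolerance(p.v, p.a, p.z, p.sigma, n, 0.001)

    def test_constant_profiles_reduce_bitwise(self):
        n, m = 20_000, 5000
        p = es.DiffusionParams(**DIFF)
        sched = es.SchedulePack(
            drift_profile=np.full(m, p.v),
            upper_profile=np.full(m, p.a),
            lower_profile=np.zeros(m),
        )
        a = es.simulate_diffusion(n, p, rng=np.random.default_rng(4))
        b = es.simulate_diffusion(n, p, schedule=sched, rng=np.random.default_rng(4))
        assert np.array_equal(a.resp, b.resp)
        assert np.array_equal(a.rt, b.rt, equal_nan=True)

    def test_null_piecewise_reduces_distributionally(self):
        n = 100_000
        p = es.DiffusionParams(**DIFF)
        sched = es.SchedulePack(piecewise=es.PiecewiseSpec(swap_time=0.2, t_delay=0.05, v2=p.v))
        a = es.simulate_diffusion(n, p, rng=np.random.default_rng(5))
        b = es.simulate_diffusion(n, p, schedule=sched, rng=np.random.default_rng(6))
        stat, _ = es.ks_two_sample(a.signed_rt(), b.signed_rt())
        assert stat < KS_CRIT_1PCT(min(len(a.terminated()), len(b.terminated())))

    def test_collapsing_bounds_speed_responses(self):
        n, m = 20_000, 5000
        p = es.DiffusionParams(**DIFF)
        upper = weibull_threshold_profile(m, 0.001, a0=p.a, a_inf=0.06, scale=0.4, shape=2.0)
        lower = p.a - upper
        t_fix = es.simulate_diffusion(n, p, rng=np.random.default_rng(7))
        t_col = es.simulate_diffusion(
            n, p, schedule=es.SchedulePack(upper_profile=upper, lower_profile=lower),
            rng=np.random.default_rng(7),
        )
        assert np.nanmean(t_col.rt) < np.nanmean(t_fix.rt)

    def test_mean_rt_monotone_in_threshold(self):
        n = 20_000
        means = []
        for a in (0.08, 0.1, 0.12):
            p = es.DiffusionParams(v=0.15, a=a, z=a / 2, ter=0.3)
            t = es.simulate_diffusion(n, p, rng=np.random.default_rng(8))
            means.append(np.nanmean(t.rt))
        assert means[0] < means[1] < means[2]

    def test_profile_length_mismatch_rejected(self):
        p = es.DiffusionParams(**DIFF)
        with pytest.raises(ValueError):
            es.simulate_diffusion(
                10, p, schedule=es.SchedulePack(drift_profile=np.zeros(10)),
                rng=np.random.default_rng(0),
            )

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            es.DiffusionParams(v=0.1, a=0.1, z=0.15, ter=0.3).validate()
        with pytest.raises(ValueError):
            es.DiffusionParams(v=0.1, a=0.1, z=0.05, ter=0.3, sz=0.2).validate()


class TestWienerAbsorption:
    def test_driftless_limit(self):
        assert es.wiener_absorption_prob(0.0, 0.1, 0.05) == pytest.approx(0.5)
        assert es.wiener_absorption_prob(0.0, 0.1, 0.025) == pytest.approx(0.25)

    def test_boundary_start(self):
        assert es.wiener_absorption_prob(0.1, 0.1, 0.0999999) == pytest.approx(1.0, abs=1e-4)

    def test_frozen_reference_value(self):
        # (1 - e^-1) / (1 - e^-2) = 1 / (1 + e^-1), checked against a
        # fine-step (h = 1e-5) Monte-Carlo run during development
        assert es.wiener_absorption_prob(0.1, 0.1, 0.05, 0.1) == pytest.approx(
            0.7310585786300049, rel=1e-12
        )

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            es.wiener_absorption_prob(0.1, 0.1, 0.2)


def lca_race_oracle(n, v, b, sigma, t0, step, seed):
    """Brute-force two-accumulator independent race (beta = lam = 0).

    Full-array stepping of two floored drifting processes, written
    independently of the LCA implementation.
    """
    rng = np.random.default_rng(seed)
    x = np.zeros((n, 2))
    resp = np.zeros(n, dtype=int)
    steps = np.zeros(n, dtype=int)
    alive = np.ones(n, dtype=bool)
    sqh = np.sqrt(step.h)
    for k in range(step.max_steps):
        x = np.maximum(x + np.asarray(v) * step.h + sigma * sqh * rng.standard_normal((n, 2)), 0.0)
        crossed = x >= b
        hit = alive & crossed.any(axis=1)
        if hit.any():
            resp[hit] = np.argmax(crossed[hit], axis=1) + 1
            steps[hit] = k + 1
            alive &= ~hit
        if not alive.any():
            break
    rt = np.where(resp > 0, t0 + steps * step.h, np.nan)
    return es.TrialSet(resp, rt)


class TestLCA:
    def test_exchangeable_alternatives(self):
        n = 100_000
        p = es.LCAParams(v=[0.3, 0.3, 0.3], b=0.1, t0=0.3, beta=0.5, lam=0.5)
        t = es.simulate_lca(n, p, rng=np.random.default_rng(9))
        for r in (1, 2, 3):
            assert abs((t.resp == r).mean() - 1 / 3) < 3 * np.sqrt((1 / 3) * (2 / 3) / n)

    def test_matches_independent_race_oracle(self):
        n = 100_000
        step = es.StepConfig()
        p = es.LCAParams(v=[0.35, 0.25], b=0.1, t0=0.3, beta=0.0, lam=0.0)
        mine = es.simulate_lca(n, p, step=step, rng=np.random.default_rng(10))
        ref = lca_race_oracle(n, p.v, p.b, p.sigma, p.t0, step, seed=11)
        p1_mine, p1_ref = (mine.resp == 1).mean(), (ref.resp == 1).mean()
        se = np.sqrt(p1_ref * (1 - p1_ref) * 2 / n)
        assert abs(p1_mine - p1_ref) < 3 * se
        stat, _ = es.ks_two_sample(mine.rt[mine.resp == 1], ref.rt[ref.resp == 1])
        assert stat < KS_CRIT_1PCT(min((mine.resp == 1).sum(), (ref.resp == 1).sum()))

    def test_unreachable_threshold_never_terminates(self):
        p = es.LCAParams(v=[0.0, 0.0], b=10.0, t0=0.3, beta=1.0, lam=1.0, sigma=0.001)
        t = es.simulate_lca(1000, p, step=es.StepConfig(max_steps=100),
                            rng=np.random.default_rng(12))
        assert t.n_nonterminated == 1000
        assert np.all(t.resp == 0)

    def test_constant_profiles_reduce_bitwise(self):
        n, m = 20_000, 5000
        p = es.LCAParams(**LCA)
        sched = es.SchedulePack(
            drift_profile=np.tile(p.v, (m, 1)),
            upper_profile=np.full((m, 2), p.b),
        )
        a = es.simulate_lca(n, p, rng=np.random.default_rng(13))
        b = es.simulate_lca(n, p, schedule=sched, rng=np.random.default_rng(13))
        assert np.array_equal(a.resp, b.resp)
        assert np.array_equal(a.rt, b.rt, equal_nan=True)

    def test_null_piecewise_reduces_distributionally(self):
        n = 100_000
        p = es.LCAParams(**LCA)
        sched = es.SchedulePack(piecewise=es.PiecewiseSpec(swap_time=0.1, t_delay=0.05, v2=p.v))
        a = es.simulate_lca(n, p, rng=np.random.default_rng(14))
        b = es.simulate_lca(n, p, schedule=sched, rng=np.random.default_rng(15))
        stat, _ = es.ks_two_sample(a.signed_rt(), b.signed_rt())
        assert stat < KS_CRIT_1PCT(min(len(a.terminated()), len(b.terminated())))

    def test_mean_rt_monotone_in_threshold(self):
        n = 20_000
        means = []
        for b in (0.08, 0.10, 0.12):
            p = es.LCAParams(v=[0.4, 0.3], b=b, t0=0.3, beta=1.0, lam=1.0)
            t = es.simulate_lca(n, p, rng=np.random.default_rng(16))
            means.append(np.nanmean(t.rt))
        assert means[0] < means[1] < means[2]


class TestUGM:
    def test_symmetric_unbiased(self):
        n = 100_000
        p = es.UGMParams(v=0.0, a=40.0, ter=0.3, tau=0.1)
        t = es.simulate_ugm(n, p, rng=np.random.default_rng(17))
        assert abs((t.resp == 1).mean() - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_noise_free_crossing_matches_direct_recursion(self):
        p = es.UGMParams(v=0.2, a=30.0, ter=0.3, tau=0.1, sigma=0.0)
        step = es.StepConfig(h=0.001, max_steps=3000)
        _, y = ugm_decision_variable(p, step)
        k_expected = int(np.argmax(y >= p.a)) + 1
        assert y[k_expected - 1] >= p.a and np.all(y[: k_expected - 1] < p.a)
        t = es.simulate_ugm(200, p, step=step, rng=np.random.default_rng(18))
        assert np.all(t.resp == 1)
        assert np.allclose(t.rt, p.ter + k_expected * step.h)

    def test_filter_converges_geometrically(self):
        """Noise-free low-pass output approaches v as (1 - h/tau)^k."""
        p = es.UGMParams(v=0.2, a=1e9, ter=0.3, tau=0.05, sigma=0.0)
        step = es.StepConfig(h=0.001, max_steps=500)
        e, _ = ugm_decision_variable(p, step)
        k = np.arange(1, step.max_steps + 1)
        expected_gap = abs(p.v) * (1 - step.h / p.tau) ** k
        assert np.allclose(np.abs(e - p.v), expected_gap, rtol=1e-9, atol=1e-12)

    def test_constant_profile_reduces_bitwise(self):
        n, m = 20_000, 5000
        p = es.UGMParams(**UGM)
        sched = es.SchedulePack(drift_profile=np.full(m, p.v))
        a = es.simulate_ugm(n, p, rng=np.random.default_rng(19))
        b = es.simulate_ugm(n, p, schedule=sched, rng=np.random.default_rng(19))
        assert np.array_equal(a.resp, b.resp)
        assert np.array_equal(a.rt, b.rt, equal_nan=True)

    def test_threshold_schedules_rejected(self):
        p = es.UGMParams(**UGM)
        with pytest.raises(ValueError):
            es.simulate_ugm(
                10, p, schedule=es.SchedulePack(upper_profile=np.full(5000, 30.0)),
                rng=np.random.default_rng(0),
            )


@pytest.mark.parametrize("model, params, kwargs", [
    (es.simulate_diffusion, es.DiffusionParams(**DIFF), {}),
    (es.simulate_lca, es.LCAParams(**LCA), {}),
    (es.simulate_ugm, es.UGMParams(**UGM), {}),
])
def test_seed_determinism(model, params, kwargs, fine_lut):
    a = model(5000, params, lut=fine_lut, rng=np.random.default_rng(20), **kwargs)
    b = model(5000, params, lut=fine_lut, rng=np.random.default_rng(20), **kwargs)
    assert np.array_equal(a.resp, b.resp)
    assert np.array_equal(a.rt, b.rt, equal_nan=True)


@pytest.mark.parametrize("model, params", [
    (es.simulate_diffusion, es.DiffusionParams(**DIFF)),
    (es.simulate_lca, es.LCAParams(**LCA)),
    (es.simulate_ugm, es.UGMParams(**UGM)),
])
def test_lut_noise_indistinguishable_from_exact(model, params, fine_lut):
    """LUT-iCDF noise at granularity 1e-4 is not detectably different from
    exact normal noise by a two-sample KS on pooled signed RTs (alpha=0.01,
    pass in >= 4 of 5 seeded repetitions)."""
    n = 30_000
    passes = 0
    for seed in range(5):
        a = model(n, params, lut=fine_lut, rng=np.random.default_rng(100 + seed))
        b = model(n, params, lut=None, rng=np.random.default_rng(200 + seed))
        _, p = es.ks_two_sample(a.signed_rt(), b.signed_rt())
        passes += p > 0.01
    assert passes >= 4


def test_linear_threshold_profile_shape():
    prof = linear_threshold_profile(1000, 0.001, a0=0.1, rate=0.05, floor=0.06)
    assert prof[0] == pytest.approx(0.1 - 0.05 * 0.001)
    assert prof[-1] == pytest.approx(0.06)
    assert np.all(np.diff(prof) <= 0)
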