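"""Brownian dynamics propagation: mobility, stepping, sampling."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

import rnabd as rb
from rnabd.analysis import rg_trace
from rnabd.topology import SecondaryStructure


def free_bead_ff(params):
    ss = SecondaryStructure(1, [])
    net = rb.SpringNetwork(n_beads=1, springs=[])
    return rb.ForceField(net, params)


def dumbbell_ff(params):
    ss = SecondaryStructure(2, [])
    net = rb.build_spring_network(ss)
    ref = np.array([[0.0, 0, 0], [params.l_e1, 0, 0]])
    return rb.ForceField(rb.assign_equilibrium_lengths(net, ref), params), ref


class TestRPYMobility:
    def test_single_bead_is_stokes_einstein(self, params):
        m = rb.rpy_mobility(np.zeros((1, 3)))
        d0_cm2s = params.kBT_cgs / (6 * np.pi * params.eta_s * params.sigma * 1e-8)
        assert np.allclose(m, np.eye(3) * d0_cm2s * 1e4, rtol=1e-12)

    def test_far_field_approaches_oseen(self, params):
        r = 1000 * params.sigma
        m = rb.rpy_mobility(np.array([[0.0, 0, 0], [r, 0, 0]]))
        pref = params.kBT_cgs / (8 * np.pi * params.eta_s * r * 1e-8) * 1e4
        assert abs(m[0, 3] - 2 * pref) / (2 * pref) < 1e-3   # along r: (I+rr)
        assert abs(m[1, 4] - pref) / pref < 1e-3             # perpendicular

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_symmetric_positive_definite_on_random_clouds(self, seed):
        rng = np.random.default_rng(seed)
        cloud = rng.uniform(0, 25, (20, 3))  # includes overlapping beads
        m = rb.rpy_mobility(cloud)
        assert np.allclose(m, m.T)
        assert np.linalg.eigvalsh(m).min() > 0

    def test_coincident_beads_rejected(self):
        with pytest.raises(FloatingPointError):
            rb.rpy_mobility(np.zeros((2, 3)))


class TestBDStep:
    def test_free_bead_displacement_variance(self, params):
        ff = free_bead_ff(params)
        traj = rb.run(ff, np.zeros((1, 3)),
                      rb.BDConfig(dt=0.1, n_steps=100_000, snapshot_every=1,
                                  seed=4))
        steps = np.diff(traj.snapshots[:, 0, :], axis=0)
        var = steps.var(axis=0).mean()
        assert abs(var - 2 * params.bead_D0 * 0.1) / (2 * params.bead_D0 * 0.1) < 0.02

    def test_deterministic_limit_moves_downhill(self, params):
        ff, ref = dumbbell_ff(params)
        x = np.array([[0.0, 0, 0], [1.2 * params.l_e1, 0, 0]])
        rng = np.random.default_rng(0)
        y = rb.bd_step(x, ff, 0.1, rng, noise=False)
        assert y[1, 0] < x[1, 0] and y[0, 0] > x[0, 0]

    def test_hi_step_uses_correlated_noise(self, params):
        ff, ref = dumbbell_ff(params)
        mob = rb.rpy_mobility(ref)
        rng = np.random.default_rng(0)
        y = rb.bd_step(ref, ff, 0.1, rng, mobility=mob)
        assert y.shape == (2, 3) and np.all(np.isfinite(y))

    def test_same_seed_reproduces_trajectory(self, hairpin_ff):
        ff, conf = hairpin_ff
        cfg = rb.BDConfig(n_steps=20_000, snapshot_every=500, seed=11)
        a = rb.run(ff, conf, cfg)
        b = rb.run(ff, conf, cfg)
        assert np.array_equal(a.snapshots, b.snapshots)

    def test_timestep_stability_guard(self, hairpin_ff):
        ff, conf = hairpin_ff
        with pytest.raises(ValueError):
            rb.run(ff, conf, rb.BDConfig(dt=1.0, n_steps=10))


class TestRun:
    def test_zero_steps_returns_initial(self, hairpin_ff):
        ff, conf = hairpin_ff
        traj = rb.run(ff, conf, rb.BDConfig(n_steps=0, snapshot_every=10))
        assert traj.n_snapshots == 1
        assert np.array_equal(traj.snapshots[0], conf.coords)

    def test_free_bead_msd_recovers_stokes_einstein(self, params):
        ff = free_bead_ff(params)
        estimates = []
        for seed in (8, 9, 10):
            traj = rb.run(ff, np.zeros((1, 3)),
                          rb.BDConfig(dt=0.1, n_steps=400_000,
                                      snapshot_every=10, seed=seed))
            res = rb.msd_diffusion(traj, fit_min_ps=1.0, fit_max_fraction=0.002)
            estimates.append(res.D_t)
        d0 = params.bead_D0 * 1e-4
        assert abs(np.mean(estimates) - d0) / d0 < 0.03

    def test_spring_length_sampling_is_boltzmann(self, params):
        """Free-draining BD must reproduce p(l) ~ l^2 exp(-V(l)/kBT)."""
        ff, ref = dumbbell_ff(params)
        traj = rb.run(ff, ref,
                      rb.BDConfig(dt=0.1, n_steps=3_000_000, snapshot_every=50,
                                  equilibration_steps=10_000, seed=17))
        lengths = np.linalg.norm(traj.snapshots[:, 1] - traj.snapshots[:, 0],
                                 axis=1)
        le, H = params.l_e1, params.spring_H
        grid = np.linspace(le - 8 * np.sqrt(1 / H), le + 8 * np.sqrt(1 / H), 4001)
        pdf = grid ** 2 * np.exp(-0.5 * H * (grid - le) ** 2)
        cdf = cumulative_trapezoid(pdf, grid, initial=0.0)
        cdf /= cdf[-1]
        ks = np.abs(np.interp(lengths, grid, cdf) -
                    (np.argsort(np.argsort(lengths)) + 0.5) / len(lengths)).max()
        assert ks < 0.02

    def test_loop_chain_mean_square_spring_length(self, params):
        """6-bead loop chain: <l^2> per spring matches 1-D quadrature."""
        ss = rb.parse_dot_bracket("......")
        net = rb.build_spring_network(ss)
        ref = np.column_stack([np.arange(6) * params.l_e1,
                               np.zeros(6), np.zeros(6)])
        ff = rb.ForceField(rb.assign_equilibrium_lengths(net, ref), params)
        traj = rb.run(ff, ref,
                      rb.BDConfig(dt=0.1, n_steps=1_500_000, snapshot_every=50,
                                  equilibration_steps=10_000, seed=23))
        si, sj, le_arr, _ = ff.network.as_arrays()
        d = traj.snapshots[:, sj] - traj.snapshots[:, si]
        l2 = (d * d).sum(-1).mean(axis=0)
        le, H = params.l_e1, params.spring_H
        grid = np.linspace(max(le - 8 / np.sqrt(H), 1e-3), le + 8 / np.sqrt(H), 4001)
        w = grid ** 2 * np.exp(-0.5 * H * (grid - le) ** 2)
        expect = np.trapezoid(w * grid ** 2, grid) / np.trapezoid(w, grid)
        # neighbouring springs interact only weakly (EV between non-bonded
        # pairs); each spring's length distribution stays near-Boltzmann
        assert np.allclose(l2, expect, rtol=0.03)

    def test_instability_aborts_with_diagnostic(self, params):
        ff, ref = dumbbell_ff(params)
        start = np.array([[0.0, 0, 0], [10 * params.l_e1, 0, 0]])
        with pytest.raises(rb.bd.PropagationError):
            rb.run(ff, start, rb.BDConfig(n_steps=10, snapshot_every=1, seed=0))

    def test_hi_and_nohi_share_equilibrium_rg(self, hairpin_ff):
        """HI changes the dynamics, not the sampled ensemble."""
        ff, conf = hairpin_ff
        nohi = rb.run(ff, conf, rb.BDConfig(n_steps=400_000, snapshot_every=200,
                                            equilibration_steps=40_000, seed=3))
        hi = rb.run(ff, conf, rb.BDConfig(n_steps=120_000, snapshot_every=200,
                                          equilibration_steps=20_000, seed=5,
                                          hi=True, cholesky_every=5))
        rg_a = rg_trace(nohi) ** 2
        rg_b = rg_trace(hi) ** 2
        m_a, s_a = rb.block_stats(rg_a)
        m_b, s_b = rb.block_stats(rg_b)
        assert abs(m_a - m_b) < 2.5 * np.hypot(s_a, s_b)
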