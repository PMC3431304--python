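import numpy as np
import pytest

from symcoev.matrices import (MasterMatrix, derive_fitness_pair,
                              make_ma_master)
from symcoev.dynamics import (DegenerateModelError, PopulationState, SimParams,
                              classify_trivial, equal_state, horizontal_step,
                              loss_step, random_state, selection_step,
                              simulate, simulate_batch)

# label swap H1<->H2, S1<->S2, P1<->P2 in canonical ordering
_ASSOC_SWAP = [3, 5, 4, 0, 2, 1]


def two_species_replicator(wH2, wP2, f0, q0, n):
    """Independent plain 2x2 host-parasite replicator, coded from scratch."""
    f, q = np.array(f0, float), np.array(q0, float)
    out = np.empty((n, 4))
    for t in range(n):
        fit_h = wH2 @ q
        fit_p = wP2 @ f
        f = f * fit_h / (f @ fit_h)
        q = q * fit_p / (q @ fit_p)
        out[t] = np.concatenate([f, q])
    return out


class TestSteps:
    def test_horizontal_identity_cases(self):
        state = random_state(np.random.default_rng(0))
        assert np.allclose(horizontal_step(state, 0.0).f, state.f)
        no_sym = PopulationState([0.4, 0, 0, 0.6, 0, 0], [0.5, 0.5])
        assert np.allclose(horizontal_step(no_sym, 0.3).f, no_sym.f)

    def test_horizontal_mass_action_arithmetic(self):
        state = PopulationState([0.5, 0.25, 0.0, 0.0, 0.0, 0.25], [0.5, 0.5])
        out = horizontal_step(state, 0.1)
        # H1:none loses tau*f*F_s = 0.1*0.5*0.25 to each symbiont class
        assert out.f[1] == pytest.approx(0.25 + 0.0125)
        assert out.f[2] == pytest.approx(0.0125)
        assert out.f[0] == pytest.approx(0.5 - 0.025)
        assert out.f.sum() == pytest.approx(1.0, abs=1e-12)

    def test_horizontal_flux_capped_with_warning(self):
        state = PopulationState([0.1, 0.45, 0.45, 0, 0, 0], [0.5, 0.5])
        with pytest.warns(RuntimeWarning):
            out = horizontal_step(state, 5.0)
        assert out.f[0] >= -1e-15 and out.f.sum() == pytest.approx(1.0)

    def test_selection_identity_under_flat_fitness(self):
        state = random_state(np.random.default_rng(1))
        fp = derive_fitness_pair(MasterMatrix(np.ones((6, 2))), 0.0, 0.0, 0.0)
        out, mwh, mwp = selection_step(state, fp)
        assert np.allclose(out.f, state.f) and np.allclose(out.q, state.q)
        assert mwh == pytest.approx(1.0)

    def test_selection_replicator_arithmetic(self):
        # two classes at 0.4/0.6 with constant row fitnesses 1 and 0.5
        state = PopulationState([0.4, 0, 0, 0.6, 0, 0], [0.5, 0.5])
        m = np.zeros((6, 2))
        m[0] = 1.0   # wH row 1 with s_H=1
        m[3] = 0.5   # wH row 0.5
        fp = derive_fitness_pair(MasterMatrix(m, protective=False), 1.0, 0.0, 0.0)
        out, mwh, _ = selection_step(state, fp)
        assert out.f[0] == pytest.approx(4 / 7)
        assert out.f[3] == pytest.approx(3 / 7)
        assert mwh == pytest.approx(0.7)

    def test_symmetric_parasite_fixed_point(self):
        state = PopulationState(np.full(6, 1 / 6), [0.5, 0.5])
        fp = derive_fitness_pair(make_ma_master(0.0), 0.5, 0.5, 0.0)
        out, _, _ = selection_step(state, fp)
        assert np.allclose(out.q, 0.5)

    def test_loss_step_arithmetic(self):
        state = PopulationState([0.1, 0.2, 0.1, 0.2, 0.2, 0.2], [0.5, 0.5])
        out = loss_step(state, 0.9)
        assert out.f[1] == pytest.approx(0.18)
        assert out.f[0] == pytest.approx(0.1 + 0.1 * (0.2 + 0.1))
        assert out.f.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(loss_step(state, 1.0).f, state.f)
        all_lost = loss_step(state, 0.0)
        assert all_lost.f[[1, 2, 4, 5]].sum() == 0.0

    def test_selection_degenerate_raises(self):
        state = PopulationState([1, 0, 0, 0, 0, 0], [1.0, 0.0])
        m = np.zeros((6, 2))
        fp = derive_fitness_pair(MasterMatrix(m, protective=False), 1.0, 0.0, 0.0)
        with pytest.raises(DegenerateModelError):
            selection_step(state, fp)


class TestSimulate:
    def test_neutral_fixed_point(self):
        init = random_state(np.random.default_rng(2))
        params = SimParams(s_H=0, s_P=0, c=0, v=1.0, tau=0.0,
                           n_generations=50, burn_in=10)
        traj = simulate(MasterMatrix(np.ones((6, 2))), params, init)
        assert np.allclose(traj.f, init.f) and np.allclose(traj.q, init.q)

    def test_frequency_conservation(self, random_masters):
        params = SimParams(s_H=0.8, s_P=0.8, c=0.1, v=0.99, tau=0.01,
                           n_generations=2000, burn_in=1000)
        traj = simulate(random_masters[0], params,
                        random_state(np.random.default_rng(3)))
        assert np.max(np.abs(traj.f.sum(axis=1) - 1)) < 1e-12
        assert np.max(np.abs(traj.q.sum(axis=1) - 1)) < 1e-12

    def test_determinism_bit_identical(self, random_masters):
        params = SimParams(s_H=0.5, s_P=0.5, c=0.1, v=0.99, tau=0.01,
                           n_generations=500, burn_in=100)
        init = random_state(np.random.default_rng(4))
        t1 = simulate(random_masters[1], params, init)
        t2 = simulate(random_masters[1], params, init)
        assert np.array_equal(t1.f, t2.f) and np.array_equal(t1.q, t2.q)

    def test_label_swap_symmetry(self, random_masters):
        master = random_masters[2]
        swapped = MasterMatrix(master.entries[_ASSOC_SWAP][:, ::-1])
        params = SimParams(s_H=0.6, s_P=0.6, c=0.1, v=0.98, tau=0.01,
                           n_generations=300, burn_in=100)
        init = random_state(np.random.default_rng(5))
        init_swapped = PopulationState(init.f[_ASSOC_SWAP], init.q[::-1])
        t1 = simulate(master, params, init)
        t2 = simulate(swapped, params, init_swapped)
        assert np.allclose(t1.f[:, _ASSOC_SWAP], t2.f, atol=1e-12)
        assert np.allclose(t1.q[:, ::-1], t2.q, atol=1e-12)

    def test_trivial_models_lose_symbionts(self, random_masters):
        # cost >= maximal parasite damage and no horizontal transfer
        params = SimParams(s_H=0.3, s_P=0.5, c=0.4, v=1.0, tau=0.0)
        assert classify_trivial(params)
        fits = [derive_fitness_pair(m, params.s_H, params.s_P, params.c)
                for m in random_masters[:8]]
        R = len(fits)
        batch = simulate_batch(
            np.stack([f.host_fitness for f in fits]),
            np.stack([f.parasite_fitness for f in fits]),
            np.ones(R), np.zeros(R),
            np.tile(equal_state().f, (R, 1)), np.tile(equal_state().q, (R, 1)),
            n_generations=20000, burn_in=10000)
        sym_mass = batch.mean_f[:, [1, 2, 4, 5]].sum(axis=1)
        assert np.all(sym_mass < 1e-3)

    def test_boundary_cost_is_trivial(self):
        assert classify_trivial(SimParams(s_H=0.5, s_P=0.5, c=0.5))
        assert not classify_trivial(SimParams(s_H=0.5, s_P=0.5, c=0.0))
        assert not classify_trivial(SimParams(s_H=1.0, s_P=0.5, c=0.5))

    def test_two_species_reduction_matches_independent_replicator(
            self, random_masters):
        master = random_masters[3]
        params = SimParams(s_H=0.7, s_P=0.7, c=0.2, v=1.0, tau=0.0,
                           n_generations=500, burn_in=100)
        init = PopulationState([0.35, 0, 0, 0.65, 0, 0], [0.3, 0.7])
        traj = simulate(master, params, init)
        fp = derive_fitness_pair(master, params.s_H, params.s_P, params.c)
        ref = two_species_replicator(
            fp.host_fitness[[0, 3]], fp.parasite_fitness[:, [0, 3]],
            [0.35, 0.65], [0.3, 0.7], 500)
        assert np.allclose(traj.f[:, [0, 3]], ref[:, :2], atol=1e-10)
        assert np.allclose(traj.q, ref[:, 2:], atol=1e-10)
        assert np.all(traj.f[:, [1, 2, 4, 5]] == 0)


class TestBatchEquivalence:
    @pytest.mark.parametrize("v,tau", [(1.0, 0.0), (0.99, 0.01)])
    def test_batch_matches_scalar_path(self, random_masters, v, tau):
        master = random_masters[4]
        params = SimParams(s_H=0.6, s_P=0.9, c=0.1, v=v, tau=tau,
                           n_generations=1200, burn_in=600)
        init = random_state(np.random.default_rng(6))
        traj = simulate(master, params, init)
        fp = derive_fitness_pair(master, params.s_H, params.s_P, params.c)
        batch = simulate_batch(
            fp.host_fitness[None], fp.parasite_fitness[None],
            np.array([v]), np.array([tau]), init.f[None], init.q[None],
            n_generations=1200, burn_in=600)
        window = slice(600, 1200)
        assert np.allclose(batch.mean_f[0], traj.f[window].mean(axis=0),
                           atol=1e-12)
        assert np.allclose(batch.mean_q[0], traj.q[window].mean(axis=0),
                           atol=1e-12)
        assert np.allclose(batch.mean_wH[0], traj.mean_wH[window].mean(),
                           atol=1e-12)
        assert np.allclose(batch.final_f[0], traj.f[-1], atol=1e-12)

    def test_batch_extrema_match_offline_counter(self, random_masters):
        from symcoev.metrics import count_local_extrema

        master = random_masters[5]
        params = SimParams(s_H=0.5, s_P=0.5, c=0.05, v=1.0, tau=0.0,
                           n_generations=4000, burn_in=2000)
        init = random_state(np.random.default_rng(7))
        traj = simulate(master, params, init)
        fp = derive_fitness_pair(master, params.s_H, params.s_P, params.c)
        batch = simulate_batch(
            fp.host_fitness[None], fp.parasite_fitness[None],
            np.array([1.0]), np.array([0.0]), init.f[None], init.q[None],
            n_generations=4000, burn_in=2000)
        for a in range(6):
            n, _, _ = count_local_extrema(traj.f[2000:, a])
            assert batch.n_extrema[0, a] == n
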