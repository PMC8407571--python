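"""Self-organising network of spatially extended spiking neurons."""

import numpy as np
import pytest

from dendronorm import cable, sorn, tasks


def small_config(**kw):
    defaults = dict(n_e=40, n_i=8, epoch_len=60, theta_spike=kw.pop("theta_spike", 1.0))
    defaults.update(kw)
    return sorn.SornConfig(**defaults)


@pytest.fixture
def state(rng):
    return sorn.init_population(small_config(), rng)


class TestInitPopulation:
    def test_full_ee_connectivity_at_p_one(self, rng):
        cfg = small_config(p_ee=1.0)
        st = sorn.init_population(cfg, rng)
        assert len(st.ee) == cfg.n_e * (cfg.n_e - 1)  # no self-connections

    def test_gamma_weight_moments(self):
        cfg = sorn.SornConfig(n_e=100, n_i=20, theta_spike=1.0, synmax=np.inf)
        gen = np.random.default_rng(0)
        draws = sorn._draw_weights(cfg, gen, 10_000)
        shape, rate = cfg.gamma_params
        assert draws.mean() == pytest.approx(shape / rate, rel=0.05)
        assert draws.var() == pytest.approx(shape / rate**2, rel=0.08)

    def test_mean_sd_parameterisation(self):
        cfg = small_config(gamma_parameterisation="mean_sd")
        assert cfg.gamma_params == (1.0, 5.0)
        gen = np.random.default_rng(1)
        draws = np.random.default_rng(1).gamma(1.0, 1 / 5.0, 20_000)
        assert draws.mean() == pytest.approx(0.2, rel=0.05)
        assert draws.std() == pytest.approx(0.2, rel=0.05)

    def test_no_inhibitory_inhibitory_synapses(self, state):
        # the synapse sets are E->E, E->I and I->E only; I->E carries sign -1
        assert state.ee.sign == +1 and state.ei.sign == +1 and state.ie.sign == -1

    def test_plastic_weights_within_bounds(self, state):
        assert np.all(state.ee.w >= 0)
        assert np.all(state.ee.w <= state.config.synmax)


class TestResizeDendrites:
    def test_length_tracks_connectivity_exactly(self, state, rng):
        sorn.resize_dendrites(state, populations=("e", "i"), rng=rng)
        n_e, n_i = state.afferent_counts()
        ratios_e = state.lengths_e / n_e
        ratios_i = state.lengths_i / n_i
        assert np.ptp(ratios_e) < 1e-12 * ratios_e.mean()
        assert np.ptp(ratios_i) < 1e-12 * ratios_i.mean()

    def test_population_mean_length_preserved(self, rng):
        st = sorn.init_population(small_config(), rng)
        before = st.lengths_e.mean()
        sorn.resize_dendrites(st, populations=("e",), rng=rng)
        assert st.lengths_e.mean() == pytest.approx(before)

    def test_doubling_afferents_doubles_relative_length(self, state, rng):
        n_e, _ = state.afferent_counts()
        target = 0
        extra = state.ee.pre[state.ee.post != target][:: len(state.ee) // n_e[target]]
        # duplicate synapses onto neuron 0 by re-pointing some contacts
        state.ee.post = state.ee.post.copy()
        moved = np.nonzero(state.ee.post != target)[0][: n_e[target]]
        state.ee.post[moved] = target
        sorn.resize_dendrites(state, populations=("e",), rng=rng)
        n_after, _ = state.afferent_counts()
        ratio = state.lengths_e / n_after
        assert np.ptp(ratio) < 1e-9 * ratio.mean()

    def test_synapse_locations_live_on_new_dendrite(self, state, rng):
        sorn.resize_dendrites(state, populations=("e",), rng=rng)
        lam = state.config.cable.lam
        assert np.all(state.ee.x <= state.lengths_e[state.ee.post] / lam)
        assert np.all(state.ee.x >= 0)


class TestStep:
    def test_silence_without_input(self, state):
        sorn.step(state, None)
        sorn.step(state, None)
        assert not state.spikes_e.any() and not state.spikes_i.any()

    def test_proximal_synapse_beats_distal(self, state):
        lengths = state.lengths_e
        cfg = state.config
        big_l = lengths[0] / cfg.cable.lam
        syn = sorn._SynapseSet(
            pre=np.array([0, 1]), post=np.array([0, 0]),
            w=np.array([1.0, 1.0]), x=np.array([0.0, big_l]), sign=+1.0,
        )
        r = sorn._relative_resistance(lengths, syn, cfg)
        assert r[0] > r[1]

    def test_longer_dendrite_attenuates_in_expectation(self, rng):
        """Averaged over placement, a synapse on a 2L dendrite contributes half."""
        cfg = small_config()
        p_short = cable.CableParameters(l=400.0)
        p_long = cable.CableParameters(l=800.0)
        xs_short = rng.uniform(0, p_short.L, 4000)
        xs_long = rng.uniform(0, p_long.L, 4000)
        mean_short = cable.transfer_resistance(p_short, xs_short).mean()
        mean_long = cable.transfer_resistance(p_long, xs_long).mean()
        assert mean_short / mean_long == pytest.approx(2.0, rel=0.05)
        assert mean_short > mean_long

    def test_voltage_matches_cable_module(self, state):
        """Cross-module consistency: the step voltage is the R_L(X) sum."""
        gen = np.random.default_rng(0)
        state.spikes_e = gen.random(state.config.n_e) < 0.3
        state.spikes_i = gen.random(state.config.n_i) < 0.3
        v_e, _ = sorn._voltages(state, state.spikes_e, state.spikes_i)
        i = int(np.argmax(np.abs(v_e)))
        expected = 0.0
        params = state.cable_for(state.lengths_e[i])
        for syn, spk, sign in ((state.ee, state.spikes_e, 1), (state.ie, state.spikes_i, -1)):
            sel = (syn.post == i) & spk[syn.pre]
            for w, x in zip(syn.w[sel], syn.x[sel]):
                expected += sign * w * float(cable.transfer_resistance(params, x))
        assert v_e[i] == pytest.approx(expected, rel=1e-9)

    def test_driven_letter_group_fires(self, state):
        drive = sorn._embed_drive(state.config, tasks.gen_word_stream(1, 1, np.random.default_rng(0)).drive[0])
        sorn.step(state, drive)
        assert np.all(state.spikes_e[drive > 0])


class TestStdp:
    def test_potentiation_saturates_at_synmax(self, state):
        syn = state.ee
        syn.w[:] = state.config.synmax
        state.prev_spikes_e[:] = True
        state.spikes_e[:] = True
        sorn.stdp_update(state)
        assert np.all(syn.w <= state.config.synmax + 1e-15)

    def test_depression_stops_at_zero(self, state):
        state.ee.w[:] = 0.0
        state.prev_spikes_e[:] = True
        state.spikes_e[:] = True
        sorn.stdp_update(state)
        assert np.all(state.ee.w >= 0.0)

    def test_alternating_pattern_converges_to_recurrence_fixed_point(self, rng):
        """Pre/post alternation applies pot then dep each cycle; the scalar
        recurrence w <- (1-eta)(w + eta(synmax - w)) has a closed fixed point."""
        cfg = small_config(eta_stdp=0.1, synmax=0.5)
        st = sorn.init_population(cfg, rng)
        sel = 0  # track one synapse, driving its pre and post alternately
        pre, post = st.ee.pre[sel], st.ee.post[sel]
        eta, wmax = cfg.eta_stdp, cfg.synmax
        w = st.ee.w[sel]
        for _ in range(300):
            w = w + eta * (wmax - w)   # pot: pre fired last step, post now
            w = w - eta * w            # dep: post fired last step, pre now
        fixed = eta * (1 - eta) * wmax / (1 - (1 - eta) ** 2)
        assert w == pytest.approx(fixed, rel=1e-9)
        # the simulated synapse follows the same recurrence
        st.ee.w[sel] = st.ee.w[sel]
        for _ in range(300):
            st.prev_spikes_e[:] = False
            st.spikes_e[:] = False
            st.prev_spikes_e[pre] = True
            st.spikes_e[post] = True
            sorn.stdp_update(st)
            st.prev_spikes_e[:] = False
            st.spikes_e[:] = False
            st.prev_spikes_e[post] = True
            st.spikes_e[pre] = True
            sorn.stdp_update(st)
        assert st.ee.w[sel] == pytest.approx(fixed, rel=1e-6)


class TestRunEpoch:
    def test_frozen_epoch_preserves_weights_and_wiring(self, rng):
        cfg = small_config(eta_stdp=0.0, zeta_set=0.0, epoch_len=30)
        st = sorn.init_population(cfg, rng)
        w0, pre0 = st.ee.w.copy(), st.ee.pre.copy()
        stream = tasks.gen_word_stream(20, 2, rng)
        sorn.run_epoch(st, stream, rng)
        assert np.array_equal(st.ee.w, w0)
        assert np.array_equal(st.ee.pre, pre0)

    def test_ee_edge_count_conserved(self, rng):
        st = sorn.init_population(small_config(), rng)
        before = len(st.ee)
        stream = tasks.gen_word_stream(30, 2, rng)
        for _ in range(3):
            sorn.run_epoch(st, stream, rng)
            assert len(st.ee) == before

    def test_proportionality_restored_after_every_epoch(self, rng):
        st = sorn.init_population(small_config(), rng)
        stream = tasks.gen_word_stream(30, 3, rng)
        for _ in range(3):
            sorn.run_epoch(st, stream, rng)
            n_e, _ = st.afferent_counts()
            ratio = st.lengths_e / n_e
            assert np.ptp(ratio) < 1e-12 * ratio.mean()

    def test_weight_bounds_maintained_throughout(self, rng):
        st = sorn.init_population(small_config(eta_stdp=0.2), rng)
        stream = tasks.gen_word_stream(40, 2, rng)
        for _ in range(3):
            sorn.run_epoch(st, stream, rng)
            assert np.all((st.ee.w >= 0) & (st.ee.w <= st.config.synmax))


class TestReadout:
    def test_score_formula_endpoints(self, rng):
        stream = tasks.gen_word_stream(200, 3, rng)
        w = stream.word_length
        m_star = (w - 0.5) / w
        assert sorn.normalised_score(m_star, stream) == pytest.approx(1.0)
        freqs = np.array([stream.letters.count(c) for c in "abcxyz"]) / len(stream.letters)
        chance = float(np.sum(freqs**2))
        assert sorn.normalised_score(chance, stream) == pytest.approx(0.0)

    def test_uniform_random_predictor_scores_near_zero(self, rng):
        stream = tasks.gen_word_stream(3000, 3, rng)
        letters = stream.letters
        gen = np.random.default_rng(0)
        freqs = np.array([letters.count(c) for c in "abcxyz"]) / len(letters)
        preds = gen.choice(list("abcxyz"), size=len(letters) - 1, p=freqs)
        acc = np.mean([p == letters[t + 1] for t, p in enumerate(preds)])
        assert abs(sorn.normalised_score(acc, stream)) < 0.1

    def test_degenerate_stream_rejected(self, rng):
        st = sorn.init_population(small_config(), rng)
        stream = tasks.gen_word_stream(5, 2, rng)
        stream.letters = "a" * len(stream.letters)
        with pytest.raises(ValueError, match="degenerate"):
            sorn.readout_and_score(st, stream, rng)


class TestPointNeuronControl:
    def test_fixed_resistance_independent_of_length(self, rng):
        cfg = small_config(point_neuron=True)
        st = sorn.point_neuron_control(cfg, rng)
        r = sorn._relative_resistance(st.lengths_e, st.ee, st.config, st.point_resistance_e)
        assert np.ptp(r) == 0.0

    def test_silent_without_synapses(self, rng):
        cfg = small_config(point_neuron=True)
        st = sorn.point_neuron_control(cfg, rng)
        st.ee.w[:] = 0.0
        st.ei.w[:] = 0.0
        st.ie.w[:] = 0.0
        sorn.step(st, None)
        sorn.step(st, None)
        assert not st.spikes_e.any() and not st.spikes_i.any()

    def test_same_seed_matches_extended_model_structure(self, rng):
        seed = 7
        a = sorn.init_population(small_config(), np.random.default_rng(seed))
        b = sorn.point_neuron_control(small_config(point_neuron=True), np.random.default_rng(seed))
        assert np.array_equal(a.ee.pre, b.ee.pre)
        assert np.array_equal(a.ee.w, b.ee.w)
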