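"""Connectome handling, hop distances, biophysical simulation, weight fitting."""

import itertools

import networkx as nx
import numpy as np
import pytest

from sigprop.anatomy import (AgreementReport, BiophysParams, Connectome,
                             assign_polarities, average_connectomes,
                             biophys_simulate, dv_response_matrix, fit_weights,
                             hop_distances, r2_agreement, steady_dv)

P = BiophysParams()


def conn_from_adj(adj, gap=None, sign=None):
    adj = np.asarray(adj, float)
    n = adj.shape[0]
    gap = np.zeros((n, n)) if gap is None else np.asarray(gap, float)
    # adj[j, i] = edge j -> i; chem is post x pre
    return Connectome(adj.T.copy(), gap, sign)


class TestHopDistances:
    def test_direct_edge(self):
        c = conn_from_adj([[0, 1], [0, 0]])
        assert hop_distances(c).l[1, 0] == 1

    def test_two_hop_chain(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 2] = 1
        l = hop_distances(conn_from_adj(adj)).l
        assert l[2, 0] == 2 and np.isinf(l[0, 2])

    def test_gap_edges_bidirectional(self):
        gap = np.zeros((2, 2))
        gap[0, 1] = gap[1, 0] = 1
        l = hop_distances(Connectome(np.zeros((2, 2)), gap)).l
        assert l[0, 1] == 1 and l[1, 0] == 1

    def test_exhaustive_small_digraphs_match_bfs(self):
        # every digraph on 3 nodes plus random 4-node ones
        for bits in range(2 ** 6):
            adj = np.zeros((3, 3))
            for b, (i, j) in enumerate((i, j) for i in range(3) for j in range(3) if i != j):
                adj[i, j] = (bits >> b) & 1
            self._check(adj)

    def test_random_digraphs_match_bfs(self, rng):
        for _ in range(100):
            n = 30
            adj = (rng.random((n, n)) < 0.08).astype(float)
            np.fill_diagonal(adj, 0)
            self._check(adj)

    @staticmethod
    def _check(adj):
        l = hop_distances(conn_from_adj(adj)).l
        g = nx.from_numpy_array(adj, create_using=nx.DiGraph)
        sp = dict(nx.all_pairs_shortest_path_length(g))
        n = adj.shape[0]
        for i, j in itertools.product(range(n), range(n)):
            ref = sp.get(i, {}).get(j, np.inf)
            assert l[j, i] == ref or (np.isinf(l[j, i]) and np.isinf(ref))


class TestBiophysics:
    def two_neuron(self, n_syn=5, sign=None, gap_w=0.0):
        chem = np.zeros((2, 2))
        chem[1, 0] = n_syn
        gap = np.zeros((2, 2))
        gap[0, 1] = gap[1, 0] = gap_w
        return Connectome(chem, gap, sign)

    def test_zero_input_equilibrium(self):
        c = self.two_neuron()
        _, dv = biophys_simulate(c, P, stim=0, current=0.0, duration=5.0,
                                 t_total=60.0)
        assert np.max(np.abs(dv)) < 1e-9

    def test_excitatory_raises_inhibitory_lowers(self):
        exc = self.two_neuron()
        _, dv = biophys_simulate(exc, P, 0, 1e-12, 5.0, 20.0)
        assert dv[:, 1].max() > 0 and dv[:, 1].max() > -dv[:, 1].min()
        inh = self.two_neuron(sign=np.array([[1.0, 1.0], [-1.0, 1.0]]))
        _, dvi = biophys_simulate(inh, P, 0, 1e-12, 5.0, 20.0)
        assert dvi[:, 1].min() < 0 and -dvi[:, 1].min() > dvi[:, 1].max()

    def test_gap_junction_symmetry(self):
        c = self.two_neuron(n_syn=0, gap_w=3.0)
        _, a = biophys_simulate(c, P, 0, 1e-12, 5.0, 20.0)
        _, b = biophys_simulate(c, P, 1, 1e-12, 5.0, 20.0)
        assert np.max(np.abs(a[:, 1] - b[:, 0])) < 1e-9

    def test_small_signal_linearity(self):
        c = self.two_neuron()
        _, d1 = biophys_simulate(c, P, 0, 1e-16, 5.0, 20.0)
        _, d10 = biophys_simulate(c, P, 0, 1e-15, 5.0, 20.0)
        pk1 = np.max(np.abs(d1[:, 1]))
        pk10 = np.max(np.abs(d10[:, 1]))
        assert abs(pk10 / (10 * pk1) - 1) < 0.02

    def test_steady_state_matches_ode_plateau(self):
        c = self.two_neuron()
        dv = steady_dv(c, P, 0, 1e-12)
        _, traj = biophys_simulate(c, P, 0, 1e-12, duration=30.0, t_total=30.0)
        np.testing.assert_allclose(traj[-1], dv, atol=1e-6)


class TestDvMatrix:
    def test_empty_connectome_silent(self):
        c = Connectome(np.zeros((3, 3)), np.zeros((3, 3)))
        dv = dv_response_matrix(c, P, method="steady")
        off = ~np.eye(3, dtype=bool)
        assert np.max(np.abs(dv[off])) < 1e-12

    def test_synapse_count_monotonicity(self):
        # weak-coupling regime: tonic synaptic conductance stays below leak,
        # so the resting point barely moves and response grows with count
        weak = BiophysParams(g_syn_unit=1e-12)
        peaks = []
        for n_syn in (2, 4):
            chem = np.zeros((2, 2))
            chem[1, 0] = n_syn
            c = Connectome(chem, np.zeros((2, 2)))
            dv = dv_response_matrix(c, weak, current=1e-12, method="steady")
            peaks.append(abs(dv[1, 0]))
        assert peaks[1] >= peaks[0]


class TestPolarities:
    def _c(self):
        chem = np.ones((2, 2)) - np.eye(2)
        return Connectome(chem, np.zeros((2, 2)),
                          labels=["AVAL", "AVAR"])

    def test_empty_table_all_excitatory(self):
        out = assign_polarities(self._c(), {})
        assert np.all(out.sign == 1)

    def test_single_negative_entry(self):
        out = assign_polarities(self._c(), {("AVAL", "AVAR"): -1})
        # subtype aggregation: AVA -> AVA covers both directions
        assert out.sign[1, 0] == -1 and out.sign[0, 1] == -1

    def test_conflicting_entries_tie_to_excitatory(self):
        out = assign_polarities(self._c(), {("AVAL", "AVAR"): -1,
                                            ("AVAR", "AVAL"): 1})
        assert np.all(out.sign == 1)


class TestAgreement:
    def test_exact_scaling(self, rng):
        pred = rng.random(20)
        rep = r2_agreement(2.0 * pred, pred)
        assert rep.slope == pytest.approx(2.0)
        assert rep.r2 == pytest.approx(1.0)

    def test_uncorrelated_can_be_negative(self, rng):
        meas = rng.standard_normal(50) + 5.0
        pred = rng.standard_normal(50)
        assert r2_agreement(meas, pred).r2 < 0.5

    def test_closed_form_oracle(self):
        meas = np.array([1.0, 2.0, 3.0, 4.0])
        pred = np.array([0.5, 0.8, 1.9, 1.6])
        m = np.dot(meas, pred) / np.dot(pred, pred)
        r2 = 1 - np.sum((meas - m * pred) ** 2) / np.sum((meas - meas.mean()) ** 2)
        rep = r2_agreement(meas, pred)
        assert rep.slope == pytest.approx(m) and rep.r2 == pytest.approx(r2)

    def test_zero_prediction_rejected(self):
        with pytest.raises(ValueError):
            r2_agreement(np.ones(3), np.zeros(3))


class TestFitWeights:
    def _toy(self, rng, n=5):
        adj = (rng.random((n, n)) < 0.35).astype(float) * rng.integers(1, 8, (n, n))
        np.fill_diagonal(adj, 0)
        sign = np.where(rng.random((n, n)) < 0.2, -1.0, 1.0)
        return Connectome(adj, np.zeros((n, n)), sign)

    def test_self_recovery(self, rng):
        c = self._toy(rng)
        dv = dv_response_matrix(c, P, method="steady")
        measured = {(j, i): 2.0 * dv[i, j]
                    for j in range(c.n) for i in range(c.n) if i != j}
        fitted, rep = fit_weights(c, measured, P)
        assert rep.r2 > 0.95

    def test_mask_respected(self, rng):
        c = self._toy(rng)
        dv = dv_response_matrix(c, P, method="steady")
        measured = {(j, i): dv[i, j] for j in range(c.n) for i in range(c.n) if i != j}
        fitted, _ = fit_weights(c, measured, P)
        assert np.all(fitted.chem[c.chem == 0] == 0)

    def test_extrasynaptic_edges_limit_fit(self, rng):
        # measured amplitudes from a network with an un-wired functional edge
        # fit worse than the fully wired case
        c = self._toy(rng, n=5)
        dv = dv_response_matrix(c, P, method="steady")
        measured = {(j, i): dv[i, j] for j in range(5) for i in range(5) if i != j}
        _, full = fit_weights(c, measured, P)
        # delete the strongest wired edge: its measured response is now
        # "extrasynaptic" (forbidden to the fit)
        iw, jw = np.unravel_index(np.argmax(c.chem), c.chem.shape)
        chem2 = c.chem.copy()
        chem2[iw, jw] = 0
        c2 = Connectome(chem2, c.gap, c.sign)
        _, partial = fit_weights(c2, measured, P)
        assert partial.r2 < full.r2 + 1e-9


class TestAverageConnectomes:
    def test_per_dataset_normalization(self):
        a = np.array([[0.0, 2.0], [4.0, 0.0]])
        out = average_connectomes([a, 10 * a])
        # both datasets carry the same relative structure; totals averaged
        expected = a / a.sum() * np.mean([a.sum(), 10 * a.sum()])
        np.testing.assert_allclose(out, expected)
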